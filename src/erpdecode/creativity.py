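"""Creativity Index scoring and extreme-group selection.

Raw figural-test scores — fluency (F), originality (O), elaboration (E),
resistance to premature closure (C) and creative strengths (CS) — are first
normalized by the participant's age group's mean of the same variable (the
index compares individuals within, not across, age groups). From the
normalized variables, each subtest contributes a composite:

    CR1 = (F + O/F + E/F) / 3                  (circles subtest)
    CR2 = ((E/F + C/F) / 2 + F + O/F) / 3      (incomplete figures subtest)

and the Creativity Index is CI = (CR1 + CR2 + CS) / 3, with CS entering
undivided. Dividing O, E and C by fluency reduces their strong correlation
with it. A participant exactly at their group mean on every variable has
CI = 1, and rescaling all of an age group's raw scores by a positive constant
leaves every CI unchanged.

Within each age group the bottom and top n participants by CI form the less
creative and creative groups; the middle is discarded. Ties break by
(CI, participant id) for determinism.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import SCORE_VARS, SUBTESTS

CIRCLES, INCOMPLETE_FIGURES = SUBTESTS


def normalize_scores(raw: pd.DataFrame) -> pd.DataFrame:
    """Divide each variable by its age-group mean (per subtest).

    Expects columns participant, age_group, subtest, F, O, E, C, CS. Raises
    on non-positive fluency or zero group means. NaN variables (e.g. closure
    in the circles subtest) stay NaN.
    """
    if (raw["F"] <= 0).any():
        raise ValueError("fluency must be strictly positive for every participant")
    out = raw.copy()
    for var in SCORE_VARS:
        grp_mean = raw.groupby(["age_group", "subtest"], observed=True)[var].transform("mean")
        bad = (grp_mean == 0) & raw[var].notna()
        if bad.any():
            raise ValueError(f"zero group mean for variable {var}")
        out[var] = raw[var] / grp_mean
    return out


def creativity_index(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-participant CR1, CR2, normalized CS and CI from normalized scores."""
    rows = []
    for (pid, age), sub in normalized.groupby(["participant", "age_group"], observed=True):
        by_test = sub.set_index("subtest")
        for needed in (CIRCLES, INCOMPLETE_FIGURES):
            if needed not in by_test.index:
                raise ValueError(f"participant {pid}: missing subtest {needed}")
        c = by_test.loc[CIRCLES]
        if c["F"] <= 0:
            raise ValueError(f"participant {pid}: non-positive normalized fluency")
        cr1 = (c["F"] + c["O"] / c["F"] + c["E"] / c["F"]) / 3.0
        i = by_test.loc[INCOMPLETE_FIGURES]
        if i["F"] <= 0:
            raise ValueError(f"participant {pid}: non-positive normalized fluency")
        cr2 = ((i["E"] / i["F"] + i["C"] / i["F"]) / 2.0 + i["F"] + i["O"] / i["F"]) / 3.0
        cs = float(sub["CS"].iloc[0])
        rows.append({
            "participant": pid,
            "age_group": age,
            "CR1": float(cr1),
            "CR2": float(cr2),
            "CS_norm": cs,
            "CI": float((cr1 + cr2 + cs) / 3.0),
        })
    return pd.DataFrame(rows).sort_values("participant", ignore_index=True)


LESS_CREATIVE, DISCARDED, CREATIVE = "less_creative", "discarded", "creative"


def select_extreme_groups(ci: pd.DataFrame, n_per_group: int = 12) -> pd.DataFrame:
    """Assign less_creative / discarded / creative within each age group.

    Bottom ``n_per_group`` by CI become less creative, top ``n_per_group``
    creative; requires at least ``2 * n_per_group`` participants per age
    group. Stable deterministic ordering by (CI, participant).
    """
    out = ci.copy()
    out["creativity_group"] = DISCARDED
    for age, sub in ci.groupby("age_group", observed=True):
        if len(sub) < 2 * n_per_group:
            raise ValueError(
                f"age group {age}: {len(sub)} participants < 2 × {n_per_group}"
            )
        order = sub.sort_values(["CI", "participant"], kind="stable")
        out.loc[order.index[:n_per_group], "creativity_group"] = LESS_CREATIVE
        out.loc[order.index[-n_per_group:], "creativity_group"] = CREATIVE
    return out


def score_creativity(raw: pd.DataFrame, n_per_group: int | None = None) -> pd.DataFrame:
    """Normalize, score and (optionally) select extreme groups in one call."""
    ci = creativity_index(normalize_scores(raw))
    if n_per_group is not None:
        ci = select_extreme_groups(ci, n_per_group)
    return ci
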