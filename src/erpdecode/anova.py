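"""Balanced mixed-design ANOVA with partial eta squared and Tukey HSD.

Implements the classical univariate sums-of-squares decomposition for fully
crossed designs with between-subject factors (subject nested in their cells)
and within-subject factors. Sums of squares are computed by inclusion-
exclusion over "uncorrected" sums of squared cell totals, which is exact for
balanced, complete data — the only designs accepted here (the experimental
design is balanced; unbalanced input raises).

Error terms follow the standard mixed-model partition: between-subject
effects are tested against subjects-within-groups; any effect involving a
within-subject set W is tested against the W × subjects-within-groups
interaction. No sphericity correction is applied by default (uncorrected
degrees of freedom); a Greenhouse-Geisser flag is intentionally not provided
at this layer.

Effect size is partial eta squared, SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


def _check_balanced(df: pd.DataFrame, subject: str, between, within) -> None:
    # every subject appears in exactly one between-cell
    if between:
        per_sub = df.groupby(subject, observed=True)[list(between)].nunique()
        if (per_sub != 1).any().any():
            raise ValueError("a subject appears in more than one between-subject cell")
        cells = df.drop_duplicates(subject).groupby(list(between), observed=True)[subject].count()
        if cells.nunique() != 1 or len(cells) != np.prod([df[b].nunique() for b in between]):
            raise ValueError("between-subject design is unbalanced or incomplete")
    counts = df.groupby([subject, *within] if within else [subject], observed=True).size()
    if counts.nunique() != 1:
        raise ValueError("within-subject design is unbalanced")
    n_within_cells = int(np.prod([df[w].nunique() for w in within])) if within else 1
    per_subject = df.groupby(subject, observed=True).size()
    if (per_subject != n_within_cells * counts.iloc[0]).any():
        raise ValueError("within-subject design is incomplete")


def mixed_anova(df: pd.DataFrame, dv: str, subject: str,
                between=(), within=()) -> pd.DataFrame:
    """ANOVA table for a balanced mixed design.

    Returns one row per effect (all main effects and interactions among
    ``between`` and ``within`` factors) with columns effect, ss, df1, df2,
    ms, ms_error, F, p, eta_p2.
    """
    between = list(between)
    within = list(within)
    factors = between + within
    if not factors:
        raise ValueError("at least one factor required")
    df = df.copy()
    _check_balanced(df, subject, between, within)

    y = df[dv].to_numpy(float)
    n_total = len(y)
    grand = y.sum() ** 2 / n_total

    def U(cols: tuple) -> float:
        """Sum over cells of (cell total)^2 / cell size."""
        if not cols:
            return grand
        g = df.groupby(list(cols), observed=True)[dv]
        totals = g.sum().to_numpy(float)
        sizes = g.size().to_numpy(float)
        return float(np.sum(totals**2 / sizes))

    cache: dict[frozenset, float] = {}

    def u(cols) -> float:
        key = frozenset(cols)
        if key not in cache:
            cache[key] = U(tuple(key))
        return cache[key]

    def incl_excl(effect: tuple) -> float:
        ss = 0.0
        for r in range(len(effect) + 1):
            for sub in combinations(effect, r):
                ss += (-1) ** (len(effect) - r) * u(sub)
        return ss

    levels = {f: df[f].nunique() for f in factors}
    n_subjects = df[subject].nunique()
    n_between_cells = int(np.prod([levels[b] for b in between])) if between else 1

    # subjects-within-groups error term
    ss_subj = u((subject,)) - u(tuple(between))
    df_subj = n_subjects - n_between_cells

    def within_error(wset: tuple) -> tuple[float, float]:
        """SS and df of the (wset × subject-within-groups) interaction."""
        ss = 0.0
        for r in range(len(wset) + 1):
            for sub in combinations(wset, r):
                sign = (-1) ** (len(wset) - r)
                ss += sign * (u((*sub, subject)) - u((*sub, *between)))
        dfe = df_subj * int(np.prod([levels[w] - 1 for w in wset]))
        return ss, dfe

    rows = []
    for k in range(1, len(factors) + 1):
        for effect in combinations(factors, k):
            ss = incl_excl(effect)
            df1 = int(np.prod([levels[f] - 1 for f in effect]))
            wset = tuple(f for f in effect if f in within)
            if wset:
                ss_err, df2 = within_error(wset)
            else:
                ss_err, df2 = ss_subj, df_subj
            ms = ss / df1
            ms_err = ss_err / df2
            F = ms / ms_err if ms_err > 0 else np.inf
            p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
            rows.append({
                "effect": " * ".join(effect),
                "ss": ss, "df1": df1, "df2": df2,
                "ms": ms, "ms_error": ms_err,
                "F": F, "p": p,
                "eta_p2": ss / (ss + ss_err) if (ss + ss_err) > 0 else np.nan,
            })
    return pd.DataFrame(rows)


def total_ss_decomposition(df: pd.DataFrame, dv: str, subject: str,
                           between=(), within=()) -> tuple[float, float]:
    """(total corrected SS, sum of all component SS) — should agree.

    Components: every effect, subjects-within-groups, and each within-set ×
    subjects-within-groups error stratum.
    """
    table = mixed_anova(df, dv, subject, between, within)
    y = df[dv].to_numpy(float)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    parts = float(table["ss"].sum())
    # unique error strata
    seen = set()
    for _, row in table.iterrows():
        key = (row["df2"], round(row["ms_error"] * row["df2"], 9))
        if key not in seen:
            seen.add(key)
            parts += row["ms_error"] * row["df2"]
    return ss_total, parts


def tukey_hsd(cell_means: pd.Series, n_per_cell: float, ms_error: float,
              df_error: float) -> pd.DataFrame:
    """Pairwise Tukey HSD over cell means.

    ``cell_means`` is indexed by cell label; ``n_per_cell`` is the number of
    observations behind each mean. The adjusted p-value is the survival
    function of the studentized range with k cells and ``df_error`` degrees
    of freedom at q = |m_i - m_j| / sqrt(MS_error / n).
    """
    if len(cell_means) < 2:
        raise ValueError("need at least two cells for pairwise comparison")
    k = len(cell_means)
    se = np.sqrt(ms_error / n_per_cell)
    rows = []
    labels = list(cell_means.index)
    for i, j in combinations(range(k), 2):
        diff = float(cell_means.iloc[i] - cell_means.iloc[j])
        q = abs(diff) / se if se > 0 else np.inf
        p = float(stats.studentized_range.sf(q, k, df_error)) if np.isfinite(q) else 0.0
        rows.append({"cell_a": labels[i], "cell_b": labels[j],
                     "diff": diff, "q": q, "p": p})
    return pd.DataFrame(rows)


def tukey_posthoc(df: pd.DataFrame, dv: str, subject: str, between, within,
                  factors) -> pd.DataFrame:
    """Tukey HSD on the cells of ``factors`` using the matching ANOVA error term.

    For purely between-subject factor sets the error term is subjects-within-
    groups; for sets touching within-subject factors it is that within-set's
    interaction with subjects-within-groups.
    """
    factors = [factors] if isinstance(factors, str) else list(factors)
    table = mixed_anova(df, dv, subject, between, within)
    effect_name = " * ".join(factors)
    match = table[table["effect"] == effect_name]
    if match.empty:
        raise ValueError(f"{effect_name!r} is not an effect of this design")
    ms_error = float(match["ms_error"].iloc[0])
    df_error = float(match["df2"].iloc[0])
    g = df.groupby(factors, observed=True)[dv]
    means = g.mean()
    n = g.size()
    if n.nunique() != 1:
        raise ValueError("unbalanced cells")
    if len(factors) > 1:
        means.index = [" / ".join(map(str, ix)) for ix in means.index]
    return tukey_hsd(means, float(n.iloc[0]), ms_error, df_error)
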