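#!/usr/bin/env python
"""Baseline-correct epochs and reject artifact trials.

Applies the -100..0 ms baseline and the peak-to-peak rejection rule
(>100 μV on any channel, or <2 μV everywhere). The simulator's band-limited
output needs no further filtering (real recordings would pass through the
30 Hz Kaiser FIR low-pass first). Clean epochs go to
scratch/analysis/clean/; the rejection log to results/rejection_log.tsv.
"""

import argparse

import numpy as np
import pandas as pd

import erpdecode as ed
from study_config import RESULTS, SCRATCH, ensure_dirs


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()
    ensure_dirs()
    clean_dir = SCRATCH / "clean"
    clean_dir.mkdir(parents=True, exist_ok=True)

    logs = []
    for path in sorted((SCRATCH / "epochs").glob("*.h5")):
        ep = ed.EpochSet.load_h5(path)
        ep = ed.baseline_correct(ep)
        clean, log = ed.reject_artifacts(ep)
        log["subject"] = ep.subject
        logs.append(log)
        clean.save_h5(clean_dir / path.name, dtype=np.float32)
        print(f"  {ep.subject}: kept {clean.n_epochs}/{ep.n_epochs} epochs")
    log = (pd.concat(logs, ignore_index=True) if logs
           else pd.DataFrame(columns=["epoch", "reason", "extreme_range_uv",
                                      "subject"]))
    log.to_csv(RESULTS / "rejection_log.tsv", sep="\t", index=False)
    print(f"{len(log)} epochs rejected in total; "
          f"log at {RESULTS / 'rejection_log.tsv'}")


if __name__ == "__main__":
    main()
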