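#!/usr/bin/env python
"""Preprocess the simulated cohort: 1250 -> 625 Hz, 60-Hz notch, 1-s resting
segmentation / 3-s chirp epoching, artifact screening, exclusion decisions.

Reads results/cohort/ written by 01_simulate_cohort.py and writes a
per-animal preprocessing report (rejection fractions, keep/exclude) to
results/preprocessing_report.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from chirpeeg import io as cio
from chirpeeg import preprocess as pp
from chirpeeg import workflows as wf


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path,
                    default=Path("results/preprocessing_report.csv"))
    args = ap.parse_args()

    manifest = pd.read_csv(args.cohort / "manifest.csv")
    rows = []
    for row in manifest.itertuples():
        resting = cio.read_recording(args.cohort / f"{row.subject}_resting.h5")
        segs = wf.resting_segments(resting)
        seg_decision, seg_frac = pp.exclusion_decision(segs.rejected)

        session = cio.read_recording(args.cohort / f"{row.subject}_chirp.h5")
        ep = pp.detect_artifacts(
            pp.epoch_chirp(wf.preprocess_recording(session)))
        ep_decision, ep_frac = pp.exclusion_decision(ep.rejected)

        rows.append({
            "subject": row.subject, "group": row.group,
            "resting_segments": len(segs.rejected),
            "resting_rejected_frac": round(seg_frac, 4),
            "resting_decision": seg_decision,
            "chirp_trials": len(ep.rejected),
            "chirp_rejected_frac": round(ep_frac, 4),
            "chirp_decision": ep_decision,
        })
        print(f"{row.subject}: resting {seg_frac:.1%} rejected "
              f"({seg_decision}); chirp {ep_frac:.1%} rejected ({ep_decision})")

    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
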