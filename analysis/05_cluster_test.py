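#!/usr/bin/env python
"""Cluster-based Monte-Carlo permutation comparison of the two groups'
ITPC matrices, with the significant clusters outlined on the group
difference map.

Reads the per-subject matrices from results/itpc/ (04_chirp_itpc.py);
writes results/cluster_test.csv and results/cluster_difference.png.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from chirpeeg import clusterstats as cs


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--itpc", type=Path, default=Path("results/itpc"))
    ap.add_argument("--region", default="LF")
    ap.add_argument("--n-perm", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=19)
    args = ap.parse_args()

    manifest = pd.read_csv(args.cohort / "manifest.csv")
    maps, labels = [], []
    for row in manifest.itertuples():
        maps.append(np.load(args.itpc / f"{row.subject}_{args.region}.npy"))
        labels.append(row.group)
    g = cs.GroupedMaps(maps=np.stack(maps), group_labels=np.array(labels))

    res = cs.cluster_permutation_test(g, n_perm=args.n_perm, seed=args.seed)
    rows = [{"sign": c.sign, "size": c.size, "mass": round(c.mass, 1),
             "p": c.p_value,
             "significant": c.p_value <= res.alpha_per_tail}
            for c in sorted(res.clusters, key=lambda c: c.p_value)[:20]]
    out = pd.DataFrame(rows)
    out.to_csv(args.itpc.parent / "cluster_test.csv", index=False)
    n_sig = int(out["significant"].sum()) if len(out) else 0
    print(f"{len(res.clusters)} clusters, {n_sig} significant "
          f"(alpha {res.alpha_per_tail}/tail, {res.n_permutations} permutations)")
    print(out.head(8).to_string(index=False))

    groups = sorted(set(labels))
    diff = g.maps[g.group_labels == 0].mean(0) - \
        g.maps[g.group_labels == 1].mean(0)
    fig, ax = plt.subplots(figsize=(7, 4))
    im = ax.imshow(diff, origin="lower", aspect="auto",
                   extent=[-0.5, 2.5, 1, 100], cmap="RdBu_r",
                   vmin=-0.4, vmax=0.4)
    ax.contour(np.linspace(-0.5, 2.5, 625), np.arange(1, 101),
               res.significance_mask.astype(float), levels=[0.5],
               colors="k", linewidths=1.0)
    ax.set(xlabel="time (s)", ylabel="frequency (Hz)",
           title=f"ITPC difference {groups[0]} - {groups[1]}, "
                 "significant clusters outlined")
    fig.colorbar(im, ax=ax, label="ITPC difference")
    fig.savefig(args.itpc.parent / "cluster_difference.png", dpi=120)
    print(f"wrote {args.itpc.parent / 'cluster_difference.png'}")


if __name__ == "__main__":
    main()
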