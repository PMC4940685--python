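"""Voxel-level overlap between ROI methods (Jaccard index).

Two methods can deliver similar FA while picking different voxels; the
Jaccard index |A n B| / |A u B| over the slices included in both ROIs makes
that distinction visible.  Reads the per-subject pairwise table written by
01_run_study.py and reports mean +/- sd per method pair.
"""

import pandas as pd

OUT = "results/study"


def main() -> None:
    jac = pd.read_csv(f"{OUT}/jaccard.csv")
    summary = (
        jac.groupby(["method_a", "method_b"])["jaccard"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    summary.to_csv(f"{OUT}/jaccard_summary.csv", index=False)
    print("pairwise Jaccard overlap between ROI methods:")
    print(summary.round(3).to_string(index=False))
    best = summary.loc[summary["mean"].idxmax()]
    print(f"\nhighest overlap: {best.method_a} vs {best.method_b} "
          f"({best['mean']:.2f} +/- {best['sd']:.2f})")


if __name__ == "__main__":
    main()
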