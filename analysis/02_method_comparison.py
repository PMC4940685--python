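"""Compare FA between the four ROI methods, per 5 mm section.

Reads results/study/measurements.csv (written by 01_run_study.py), averages
FA across sides per subject, summarises each method per section (mean, SD,
CV) and contrasts every method pair with Tukey-Kramer-adjusted paired tests.
Writes the summary and contrast tables and an FA-by-position figure.
"""

import pandas as pd

from tractroi.plots import plot_fa_by_position
from tractroi.stats import compare_methods, normality_report, section_summaries

OUT = "results/study"


def main() -> None:
    table = pd.read_csv(f"{OUT}/measurements.csv")
    base = table.query("scan == 0 and repeat == 0")
    first_rater = sorted(base["rater"].unique())[0]
    base = base[base["rater"] == first_rater]

    summaries = section_summaries(base)
    summaries.to_csv(f"{OUT}/section_summaries.csv", index=False)
    print("FA by method and section (mean over subjects, sides averaged):")
    print(summaries.round(3).to_string(index=False))

    per_subject = base.groupby(["method", "subject"])["fa"].mean()
    w, p = normality_report(per_subject)
    print(f"\nnormality (advisory Shapiro-Wilk on subject means): W={w:.3f} p={p:.3f}")

    comp = compare_methods(base)
    comp.to_csv(f"{OUT}/method_comparisons.csv", index=False)
    print("\npairwise contrasts (Tukey-Kramer adjusted):")
    print(comp.round(4).to_string(index=False))

    high = comp.query("section in (2, 3)")
    grouping = {}
    for _, r in high.iterrows():
        pair = (r.method_a, r.method_b)
        grouping[pair] = grouping.get(pair, 0) + (r.p_adjusted < 0.05)
    sig = [p for p, c in grouping.items() if c]
    print(f"\nsignificant section-2/3 pairs: {sig}")

    plot_fa_by_position(base, f"{OUT}/fa_by_position.png")
    print(f"figure written to {OUT}/fa_by_position.png")


if __name__ == "__main__":
    main()
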