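"""Region statistics: one-way ANOVA + Tukey-Kramer across NM/EM/LM.

XRD metrics are compared per scan pattern; pSHG organization per acquisition
mean (the two granularities of the study design are kept distinct).  Writes
one pairwise CSV per metric and a combined JSON report under results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from colhier import io, stats
from colhier.xrd import METRIC_COLUMNS


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--xrd", default="results/xrd_metrics.csv")
    ap.add_argument("--pshg", default="results/pshg_acquisitions.csv")
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    reports = {}

    xrd_df = pd.read_csv(args.xrd)
    metrics = [c for c in METRIC_COLUMNS if c != "preferred_orientation_deg"]
    if "relative_twist" in xrd_df.columns:
        metrics.append("relative_twist")
    for col in metrics:
        rep = stats.compare_regions(xrd_df, col, "label", alpha=args.alpha)
        rep["pairwise"].to_csv(out / f"stats_xrd_{col}.csv", index=False)
        print(f"{col}: F = {rep['f_statistic']:.5g}, p = {rep['anova_p']:.3g}, "
              "pairs: "
              + ", ".join(f"{r.group1}-{r.group2} {r.stars}"
                          for r in rep["pairwise"].itertuples()))
        rep["pairwise"] = rep["pairwise"].to_dict(orient="records")
        reports[f"xrd:{col}"] = rep

    pshg_df = pd.read_csv(args.pshg)
    rep = stats.compare_regions(pshg_df, "mean_i2", "region", alpha=args.alpha)
    rep["pairwise"].to_csv(out / "stats_pshg_mean_i2.csv", index=False)
    print(f"mean_i2: F = {rep['f_statistic']:.5g}, p = {rep['anova_p']:.3g}, "
          "pairs: "
          + ", ".join(f"{r.group1}-{r.group2} {r.stars}"
                      for r in rep["pairwise"].itertuples()))
    rep["pairwise"] = rep["pairwise"].to_dict(orient="records")
    reports["pshg:mean_i2"] = rep

    (out / "stats_reports.json").write_text(json.dumps(reports, indent=2))
    io.write_manifest(
        out / "stats_reports.manifest.json", "analysis/05_compare_regions",
        config=vars(args), inputs=[args.xrd, args.pshg],
        counts={"reports": len(reports)},
    )


if __name__ == "__main__":
    main()
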