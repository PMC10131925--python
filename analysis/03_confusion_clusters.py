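"""Confusion-row composition and grouped-confidence cluster analysis.

Reproduces, from the published reference prediction-row counts, every
derived percentage of the best model's confusion analysis: the true-
positive share of each prediction row and the cumulative confidence once
co-confused SDoH classes are grouped.  If 02_exp1_grid.py has produced a
confusion matrix for the best synthetic configuration, the same analysis
is applied to it for comparison.

Usage: python analysis/03_confusion_clusters.py
"""

import argparse
from pathlib import Path

import pandas as pd

from pn_sdoh.grid import (
    ConfusionSummary,
    grouped_confidence,
    published_confusion_summary,
    row_composition,
)
from pn_sdoh.pipeline import grouped_confidence_report


def analyze(cs: ConfusionSummary, title: str) -> pd.DataFrame:
    print(f"\n== {title} ==")
    rows = []
    for cls in cs.classes:
        if cs.row_total(cls) == 0:
            continue
        comp = row_composition(cs, cls)
        top = ", ".join(f"{c} {p:.1f}%" for c, _, p in comp[:3])
        m = min(4, len(cs.classes))
        gc = grouped_confidence(cs, cls, m)
        print(f"predicted {cls} (n={cs.row_total(cls)}): {top}; "
              f"top-{m} cluster covers {gc:.1f}%")
        rows.append({"predicted": cls, "row_total": cs.row_total(cls),
                     "own_pct": comp[0][2] if comp[0][0] == cls else None,
                     f"cluster_top{m}_pct": round(gc, 1)})
    return pd.DataFrame(rows)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--exp1-dir", type=Path, default=Path("results/exp1"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/exp1"))
    args = ap.parse_args()

    cs = published_confusion_summary()
    table = analyze(cs, "reference prediction rows (best model of the original study)")
    args.out_dir.mkdir(parents=True, exist_ok=True)
    grouped_confidence_report(cs).to_csv(
        args.out_dir / "published_grouped_confidence.csv", index=False
    )
    print("\nkey reference numbers recomputed from the row counts:")
    print(f"  language row true positives: "
          f"{row_composition(cs, 'language_interpreter')[0][2]}% (137/173)")
    print(f"  language top-3 cluster: "
          f"{grouped_confidence(cs, 'language_interpreter', 3):.1f}%")
    print(f"  fear top-4 cluster: {grouped_confidence(cs, 'fear', 4):.1f}% (21/22)")
    print(f"  social support top-4 cluster: "
          f"{grouped_confidence(cs, 'social_practical_support', 4):.1f}% (52/59)")
    print(f"  insurance top-5 cluster: "
          f"{grouped_confidence(cs, 'insurance_uninsured_underinsured', 5):.1f}% (29/34)")

    best_csv = args.exp1_dir / "best_confusion.csv"
    if best_csv.exists():
        matrix = pd.read_csv(best_csv, index_col=0)
        analyze(ConfusionSummary(matrix=matrix), "best synthetic configuration")
    else:
        print(f"\n(no {best_csv}; run 02_exp1_grid.py for the synthetic comparison)")


if __name__ == "__main__":
    main()
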