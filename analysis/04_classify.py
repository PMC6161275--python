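"""Assign temporal-pattern cluster labels and score recovery vs truth.

Applies the strict rules: acute_sustained needs a significant positive
acute response on all three exercise days; chronic_FOR needs elevation on
at least one recovery morning with no acute response in either direction.
Compares labels with the planted ground truth.
"""

import json
from pathlib import Path

import pandas as pd

from forpanel.classify import classify_results, summarize_clusters

OUT = Path("results/analysis")


def main() -> None:
    results = pd.read_csv(OUT / "contrasts.tsv", sep="\t")
    truth = pd.read_csv(OUT / "truth.tsv", sep="\t", keep_default_na=False)

    classifications = classify_results(results, mode="strict")
    counts, table = summarize_clusters(classifications)
    table.to_csv(OUT / "classifications.tsv", sep="\t", index=False)

    merged = table.merge(truth[["protein_id", "klass"]], on="protein_id")
    metrics = {
        "sensitivity_acute_sustained": float(
            (merged[merged.klass == "acute"].label == "acute_sustained").mean()
        ),
        "sensitivity_chronic_FOR": float(
            (merged[merged.klass == "chronic"].label == "chronic_FOR").mean()
        ),
        "fpr_null_any_label": float(
            (merged[merged.klass == "null"].label != "none").mean()
        ),
    }
    with open(OUT / "classification_metrics.json", "w") as fh:
        json.dump({"counts": counts, "metrics": metrics}, fh, indent=2, sort_keys=True)

    print("cluster counts:", counts)
    print("planted-pattern recovery:",
          {k: round(v, 3) for k, v in metrics.items()})


if __name__ == "__main__":
    main()
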