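#!/usr/bin/env python
"""Split-batch reliability of the utility scores.

The three batches are parallel 6-observation measurements of every item, so
their pairwise correlations and the standardized Cronbach's alpha quantify
the internal consistency of the norms (the full study reported r = .57 and
alpha = .80).  Writes results/reliability.json.
"""

import json
from pathlib import Path

import pandas as pd

from bwsnorm import reliability as rel

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    scores = pd.read_csv(ROOT / "scores.tsv", sep="\t", dtype={"batch": str})
    report = rel.reliability_report(scores)

    print("inter-batch Pearson correlations:")
    print(report.correlation_matrix.round(3).to_string())
    print(
        f"mean off-diagonal r = {report.mean_offdiagonal:.3f}; "
        f"Cronbach's alpha = {report.alpha:.3f} over {report.n_items} items"
    )

    pooled = scores[scores["batch"] == "pooled"]["score"]
    gran = rel.granularity_report(pooled)
    print(
        f"pooled scale: {gran['n_distinct']} distinct values, "
        f"skew {gran['skew']:.2f}, excess kurtosis {gran['kurtosis']:.2f}"
    )

    payload = report.to_dict()
    payload["pooled_granularity"] = {
        k: gran[k] for k in ("n_distinct", "n_items", "mean", "sd", "skew", "kurtosis")
    }
    (ROOT / "reliability.json").write_text(json.dumps(payload, indent=2))
    print(f"wrote {ROOT}/reliability.json")


if __name__ == "__main__":
    main()
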