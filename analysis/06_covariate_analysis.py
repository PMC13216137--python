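#!/usr/bin/env python
"""Relate the utility norms to lexical covariates.

Clustered correlation matrix (hierarchically ordered, Pearson below /
Spearman above the diagonal in the written tables), OLS multiple regression
of pooled utility on the synthetic covariates, and the residual-extreme
tables (items more or less useful than their lexical profile predicts).
Writes tables under results/analysis/.
"""

from pathlib import Path

import pandas as pd

from bwsnorm import norms_analysis as na

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "analysis"
COVARIATES = [
    "frequency_zipf", "familiarity", "prevalence_probit", "length", "aoa",
    "concreteness", "valence", "arousal", "centrality",
]


def main() -> None:
    scores = pd.read_csv(ROOT / "scores.tsv", sep="\t", dtype={"batch": str})
    pooled = scores[scores["batch"] == "pooled"][["item_id", "score"]]
    pool = pd.read_csv(ROOT / "design" / "pool.tsv", sep="\t")
    OUT.mkdir(parents=True, exist_ok=True)

    merged = pool[["item_id"] + COVARIATES].merge(pooled, on="item_id")
    cm = na.clustered_correlation_matrix(merged.drop(columns="item_id"))
    cm["pearson"].round(3).to_csv(OUT / "correlations_pearson.tsv", sep="\t")
    cm["spearman"].round(3).to_csv(OUT / "correlations_spearman.tsv", sep="\t")
    print("cluster order:", " | ".join(cm["order"]))

    report = na.fit_utility_regression(pooled, pool[["item_id"] + COVARIATES])
    print(f"OLS: R^2 = {report.r_squared:.3f} over n = {report.n} complete cases")
    coef = report.coefficients.copy()
    coef[["coef", "se", "t"]] = coef[["coef", "se", "t"]].round(4)
    print(coef.to_string(index=False))
    coef.to_csv(OUT / "regression_coefficients.tsv", sep="\t", index=False)

    ext = na.residual_extremes(report, items=pool, top_n=20)
    ext["positive"].to_csv(OUT / "residuals_positive.tsv", sep="\t", index=False)
    ext["negative"].to_csv(OUT / "residuals_negative.tsv", sep="\t", index=False)
    top = ext["positive"].iloc[0]
    print(
        f"largest positive residual: {top['Word']} "
        f"(utility {top['Utility']:.2f} vs predicted {top['Predicted Utility']:.2f})"
    )

    imp = na.permutation_importance(
        report, pool[["item_id"] + COVARIATES], pooled.set_index("item_id")["score"], seed=7
    )
    imp.round(5).to_csv(OUT / "permutation_importance.tsv", sep="\t", index=False)
    print("top permutation importances:", imp.head(3)["term"].tolist())
    print(f"wrote tables under {OUT}")


if __name__ == "__main__":
    main()
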