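"""Cross-validated single-feature ROC screen for MD-vs-SV severity.

Evaluates every feature with stratified five-fold cross-validated AUC
(orientation fixed on the training folds), ranks the features and
details the top discriminator with its fold-percentile CI.
"""

from pathlib import Path

import pandas as pd

from bandstates import screen_all_features, stratified_kfold_auc

SEED = 13
OUT = Path("results")


def main() -> None:
    table = pd.read_csv(OUT / "feature_table.csv")
    ranking = screen_all_features(table, positive="MD", negative="SV", seed=SEED)
    ranking.to_csv(OUT / "roc_ranking.csv", index=False)
    print("top 5 discriminative features (mean CV AUC):")
    print(ranking.head(5).to_string(index=False))

    top = ranking.iloc[0]
    sub = table[table.group.isin(["MD", "SV"])][[top.feature, "group"]].dropna()
    res = stratified_kfold_auc(
        sub[top.feature].to_numpy(), sub["group"].tolist(), positive="MD",
        seed=SEED, feature=top.feature,
    )
    print(
        f"\nbest feature {res.feature}: mean AUC {res.mean_auc:.3f} "
        f"(fold 95% CI {res.ci_low:.3f}-{res.ci_high:.3f}), "
        f"Mann-Whitney p = {res.p:.2e}, orientation {res.orientation}"
    )


if __name__ == "__main__":
    main()
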