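"""Group-level inference on the microstate features.

Runs the two-way mixed ANOVA (group x microstate class) per band and
temporal metric, then the MD-vs-SV pairwise tests (Levene-gated
pooled/Welch t with Cohen's d, Mann-Whitney U as robustness check)
over every feature.  Prints the planted biomarker's row.
"""

from pathlib import Path

import pandas as pd

from bandstates import PipelineConfig
from bandstates.pipeline import _anova_stage, _pairwise_stage

OUT = Path("results")


def main() -> None:
    table = pd.read_csv(OUT / "feature_table.csv")
    config = PipelineConfig()
    anova = _anova_stage(table, config)
    anova.to_csv(OUT / "anova.csv", index=False)
    sig = anova[anova["p"] < 0.05]
    print(f"ANOVA: {len(sig)}/{len(anova)} effects with p < 0.05")
    inter = sig[sig.effect == "Interaction"]
    if not inter.empty:
        print("significant group x class interactions:")
        print(inter.to_string(index=False))

    pairwise = _pairwise_stage(table, config)
    pairwise.to_csv(OUT / "pairwise_md_sv.csv", index=False)
    row = pairwise[pairwise.feature == "Delta_TP_C-B"]
    if not row.empty:
        r = row.iloc[0]
        print(
            f"\npipeline-recovered Delta_TP_C-B  MD {r.mean_md:.3f}+/-{r.sd_md:.3f} "
            f"(n={r.n_md}) vs SV {r.mean_sv:.3f}+/-{r.sd_sv:.3f} (n={r.n_sv}): "
            f"{r.test} t = {r.t:.2f}, p = {r.p:.2e}, d = {r.cohens_d:.2f}, "
            f"U = {r.U:.1f} (p = {r.p_mw:.2e})"
        )

    # ground-truth contrast: the same test on the planted transition entries
    from bandstates.stats import auto_two_group_test

    clinical = pd.read_csv(OUT / "cohort_clinical.csv")
    md = clinical[clinical.group == "MD"]["delta_planted_TP_C-B"]
    sv = clinical[clinical.group == "SV"]["delta_planted_TP_C-B"]
    res = auto_two_group_test(md, sv)
    print(
        f"planted delta C->B entries       MD {md.mean():.3f}+/-{md.std():.3f} vs "
        f"SV {sv.mean():.3f}+/-{sv.std():.3f}: {res.test} t = {res.statistic:.2f}, "
        f"p = {res.p:.2e}, d = {res.effect_size:.2f}"
    )
    print(
        "note: 80 ms state switching is broadband; delta-band filtering keeps only\n"
        "its slow spectral content, so the planted delta transition structure is\n"
        "attenuated in the recovered features and surfaces instead as cross-band\n"
        "occupancy differences (see docs/methods.md)."
    )


if __name__ == "__main__":
    main()
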