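# bandstates

Frequency-band-resolved EEG microstate analysis for severity-biomarker
discovery, with a fully planted synthetic validation cohort.

Resting-state EEG spends most of its time in a handful of quasi-stable
scalp topographies ("microstates", classes A–D) that alternate every
60–120 ms. This package segments EEG into microstates *per frequency
band* (delta 1–4, theta 4–8, alpha 8–13, beta 13–30 Hz) and asks
whether the temporal statistics of those states — especially the
transition probabilities between classes — separate clinical severity
groups, for example moderate (MD) versus severe (SV) central vertigo.

The pipeline is the standard microstate stack, band-resolved:

1. zero-phase FIR band-pass (1–40 Hz), resample to 256 Hz, average
   reference; per-trial QC keeps the first 10 s with no sample beyond
   ±100 µV;
2. per band: GFP peaks (min spacing 10 samples, ≤1000 maps/subject),
   polarity-invariant **modified K-means** on peaks pooled over all
   subjects, K scanned 2–10 by a predictive-residual criterion with
   K = 4 forced by convention, canonical A–D labeling;
3. back-fitting by highest |spatial correlation|, 30 ms minimum-duration
   smoothing, then per subject and band: mean duration, coverage,
   occurrence, GEV and the 4×4 segment-wise transition matrix
   (`Delta_TP_C-B` = probability that a delta-band C state is succeeded
   by B);
4. inference: mixed group × class ANOVA with Holm–Šídák post hocs,
   Welch/pooled t + Mann–Whitney for MD vs SV, Spearman screens of all
   112 features against VAS/ABC with Benjamini–Hochberg FDR (q = 0.05),
   and stratified five-fold cross-validated single-feature ROC AUC.

Since clinical EEG of this kind is not publicly deposited, the package
ships a synthetic generator that plants every quantity the pipeline
estimates: per-band templates, semi-Markov state sequences
(gamma dwells, mean 80 ms), group-dependent transition matrices and
clinical scores monotonically coupled to a planted transition entry.
All tests validate the pipeline by parameter recovery against this
ground truth.

## Worked example

```python
import numpy as np
from bandstates import cohens_d_from_stats, stratified_kfold_auc, two_group_t_from_stats

# printed group summaries of the delta-band C->B transition probability
md = (31, 0.383, 0.104)   # n, mean, sd — moderate group
sv = (19, 0.162, 0.040)   # severe group

print(cohens_d_from_stats(*md, *sv))                      # 2.576
print(two_group_t_from_stats(*md, *sv).statistic)          # 8.842

rng = np.random.default_rng(0)
values = np.r_[rng.normal(0.383, 0.104, 31), rng.normal(0.162, 0.040, 19)]
labels = ["MD"] * 31 + ["SV"] * 19
res = stratified_kfold_auc(values, labels, positive="MD", seed=0)
print(res.mean_auc)                                        # 0.975
```

The effect size (pooled Cohen's d ≈ 2.58) says the two groups are ~2.6
pooled standard deviations apart — nearly disjoint distributions; the
pooled t of 8.84 on 48 df makes the difference overwhelming; and the
cross-validated AUC ≈ 0.97 matches the analytic overlap of the two
normal laws, Φ(0.221/√(0.104²+0.040²)) ≈ 0.98: a randomly drawn MD
value exceeds a randomly drawn SV value about 97–98% of the time.

## End-to-end analysis

The `analysis/` drivers run the whole study on a synthetic cohort
(31 HC / 31 MD / 19 SV, 60 s each, SNR 3):

```bash
python analysis/01_simulate_cohort.py      # recordings -> scratch/, clinical -> results/
python analysis/02_extract_features.py     # clustering + 81 x 112 feature table
python analysis/03_group_stats.py          # ANOVA + MD-vs-SV pairwise tests
python analysis/04_clinical_correlations.py
python analysis/05_roc_screen.py           # ranked CV-AUC table
```

Script 03 prints both the pipeline-recovered biomarker and the planted
ground truth (planted delta C→B: d ≈ 2.6; recovered: attenuated —
80 ms switching is spectrally broadband, so delta filtering keeps only
its slow content; see `docs/methods.md`). A `bandstates` CLI
(`simulate`, `features`, `correlate`, `roc`, `run-all`) wraps the same
stages for on-disk cohorts.

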