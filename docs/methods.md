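# Methods

## Signal model

The observable per sample *i* and region *r* is a pair of counts:
detected CpG observations `n_ir` and methylated observations `k_ir`,
summarised as the average methylation fraction AMF = `k/n` (missing when
`n = 0`). Counts are modelled beta-binomially: `k ~ Binomial(n, p)` with
`p ~ Beta(μ, ρ)` parameterised by mean `μ` and dispersion
`ρ = 1/(a+b+1)`-style concentration `(1−ρ)/ρ`. Overdispersion relative
to the binomial is the norm in region-level bisulfite data
(biological cell-to-cell heterogeneity plus conversion noise), which is
why a plain binomial is not used.

Plasma cfDNA from a cancer patient is a mixture: a latent tumor
fraction `f_i` of the template derives from tumor. At an informative
(truly differentially methylated) region the latent mean is the dilution

    μ_ir = (1 − f_i)·bg_r + f_i·m_tumor,

where `bg_r` is the region's healthy background and `m_tumor` the tumor
tissue methylation level. Healthy plasma and white-blood-cell (WBC)
samples sit at `bg_r`; tumor tissue has `f = 1`; benign-disease plasma
carries a configurable fraction of the cancer effect
(`benign_effect_scale`), reflecting the partial epigenetic overlap of
inflammatory and neoplastic lung disease that makes the benign contrast
the hard one.

## Synthetic cohort generator

`SimulationConfig` defaults describe a full marker-development study:

| parameter | default | rationale |
|---|---|---|
| n_cancer / n_benign / n_healthy | 190 / 135 / 188 | training-scale three-group plasma cohort (the pipeline default enlarges these to 254/180/251 and holds out 64/45/63 for validation) |
| n_tumor_tissue / n_wbc | 20 / 20 | tissue verification panels |
| n_regions / n_true_dmr | 165 / 15 | a targeted panel with a curated informative core |
| healthy_beta_mean | 0.02 | hypermethylation markers are chosen for near-zero healthy plasma background |
| healthy_beta_dispersion | 0.05 | mild overdispersion; region backgrounds additionally jittered (Beta, concentration 100) so some regions exceed the 5% background filter, as in real panels |
| tumor_beta_mean | 0.60 | strong tissue-level hypermethylation |
| tumor_fraction_range | 0.01–0.20 | ctDNA fractions in symptomatic/screening cohorts span orders of magnitude; this range keeps desk-scale runs informative. Real early-stage fractions can be ≤ 0.1%; `stress_preset()` gives 0.001–0.01 |
| benign_effect_scale | 0.20 | benign disease shows a minority share of the cancer effect |
| coverage_mean | 200 (Poisson) | comfortably above the 100× coverage filter |
| stage_distribution | I .43, II .15, III .24, IV .18 | early-stage-weighted case mix |
| cea_params | lognormal, cancer ln-mean 1.17 vs 1.00, σ 0.80 | tuned analytically so standalone CEA AUC ≈ Φ(0.17/(0.8√2)) ≈ 0.56 — a deliberately weak serum covariate |

Tumor sizes are log-normal with median 2 cm; all randomness flows from
one `numpy` generator seeded by `seed`, so identical configs are
bit-identical.

What the generator does **not** emulate: read-level bisulfite sequence
or conversion errors, fragment-length and GC effects, batch/center
effects, age- or smoking-associated methylation drift, correlated
regions (regions are independent given their background), and
non-uniform per-region coverage profiles. Passing tests on these
cohorts therefore demonstrate the correctness and calibration of the
*procedure* (selection, training, evaluation arithmetic), not the
clinical performance of any marker panel on real plasma.

The qPCR simulator maps latent methylated-template abundance `μ` to a
marker Ct of `Ct_ref − log₂ μ` plus Gaussian cycle noise (default SD
0.15), censored at the conventional 40-cycle detection limit; the
reference gene is disease-independent. The matching quantifier applies
the standard relative-quantification transform `2^(Ct_ref − Ct_marker)`
(configurable), reading censored wells as zero signal.

## Quantification choices

The coverage rule "at least 100×" is aggregated as: a region is kept
when its **median** detected-CpG count across samples reaches the
threshold, and any individual cell below the threshold is masked to
missing. Median-based retention keeps regions that are systematically
well covered, while per-cell masking avoids treating a 12-read AMF as
data; the filter is idempotent. Per-sample or cohort-total aggregations
are defensible alternatives; this one is a documented package choice.

Missing AMF values downstream are imputed with medians computed
strictly inside training folds (and stored in the fitted model for
deployment); no statistic ever crosses the train/validation boundary.

## Marker funnel

Per region: group AMF means; fold change = (cancer mean + ε)/(healthy
mean + ε) with pseudocount ε = 1e−4 to keep ratios finite; two-sided
tie-corrected Mann-Whitney p (the same rank test used everywhere else
in the package, and the natural choice for bounded, non-normal AMF
distributions); Benjamini–Hochberg q across regions (appropriate for a
100+-region panel); single-marker AUC taken directly from the
Mann-Whitney U statistic (`U/(n₁n₂)`, ties counting half). Regions with
identical values everywhere are flagged degenerate (AUC 0.5, p 1).

Discovery keeps q ≤ 0.05 ∧ FC > 1 ∧ healthy background ≤ 0.05 AMF (the
background cap operationalises "low methylation in healthy plasma" for
hypermethylated markers; 5% is the package default), ranks by
(AUC desc, FC desc, region id) — a lexicographic key chosen because
separation power is the primary published ranking signal and fold
change the stated secondary one — and returns the top 50.

Verification is a conjunction — log₂ plasma FC > 1, p < 0.05, log₁₀
tumor/WBC ratio > 1 — applied after an optional user allowlist. The
allowlist stands in for manual gene-ontology/literature curation and
primer-designability triage, which is judgment, not computation, and is
therefore an explicit input rather than an algorithm.

## Classifier construction

Both models are linear log-odds (logistic) classifiers on standardized
AMF features with a light ridge penalty (strength 1.0), which keeps
coefficients finite under perfect separation — a real risk with
near-zero-background markers at small n.

Subset search: the anchor is the marker with the highest single-marker
cross-validated AUC; each greedy step adds the marker that maximises
the combined 10 × 4-fold CV AUC, with fold assignment re-randomised per
repeat (repeat *r* uses seed `base + r`) and stratified by class. The
final subset is the global AUC argmax along the greedy path — not a
first-decline stop — with ties broken toward the smaller subset, then
panel order. The chosen subset is refit on all training data.

Each training sample keeps two distinct scores: the out-of-fold score
averaged over the 10 repeats (used for cutoff calibration and training
operating points) and the refit-model score (used for deployment). They
are never mixed.

Cutoffs: mode S takes the **largest** cutoff whose training (out-of-
fold) sensitivity still meets the target (default 0.90) — maximal
specificity subject to the sensitivity floor; mode D takes the
**smallest** cutoff meeting the benign-specificity target (default
0.95) — maximal sensitivity subject to the specificity floor. The
targets are configurable; the defaults reproduce screening-style and
triage-style training operating points (≈92% sensitivity for S, ≈98%
benign specificity for D at full scale). Unattainable targets return
the boundary cutoff with a warning rather than failing.

Training contrasts: S is trained cancer-vs-healthy and merely *tested*
on benign samples; D is trained cancer-vs-benign and tested on healthy.
The S and D selections are independent runs over the same verified
panel; shared markers may or may not recur.

## Evaluation

Confusion metrics are exact rational ratios; percentages are displayed
rounded half-up to one decimal. AUC is the tie-corrected rank statistic
and equals brute-force pair enumeration (a property the tests enforce
up to n = 50). Confidence intervals are percentile intervals
(2.5/97.5) from 1000 class-stratified bootstrap resamples, seeded.

The cascade applies D only to S-positives; a final positive requires
both calls, so cascade TP and FP can never exceed the screening
model's — the conjunction inequalities are asserted on every run.
Prevalence-adjusted predictive values use Bayes' rule on (sensitivity,
specificity, prevalence); at the sample prevalence they reproduce the
raw count-based PPV/NPV exactly. Covariate association uses pairwise
two-sided Mann-Whitney with BH adjustment when a covariate has more
than two levels. CEA enters the combination model as log₁₀(value + 1)
(right-skewed serum marker); a constant CEA column falls back to the D
score alone with a warning.

## Problem sizes in the test suite

The suite exercises: 1000-region null cohorts (raw p < 0.05 fraction
within a 3σ binomial band of 5%; BH discovery fraction ≤ 5%); a
20-seed planted-DMR recovery battery at 100 samples/group (all planted
regions outrank all noise regions by single-marker AUC in ≥ 19/20
seeds); greedy-vs-exhaustive subset search on 6-marker panels (within
0.02 CV AUC of the exhaustive optimum on identical folds); a 20-seed
S/D asymmetry battery at 40/30/40 samples per group with 3 CV repeats;
and label-permutation leakage checks (mean CV AUC within [0.4, 0.6]).
These sizes were chosen so the whole suite runs in well under a minute
while keeping each statistical assertion comfortably powered; the
acceptance script additionally runs one full-scale study
(685 plasma samples, 165 regions).

## Known limitations

* Regions are simulated independently; correlated DMR blocks (e.g. HOX
  clusters) are not represented, so multiplicity behaviour on real
  panels may differ.
* The benign group is modelled as a scaled cancer effect, not as a
  distinct inflammatory methylation signature.
* Cutoff calibration assumes the training score distribution transfers
  to deployment; no recalibration layer is provided.
* The qPCR model is a single-efficiency, single-reference idealisation;
  plate effects and multiplexing interference are out of scope.
* Greedy forward selection is near-optimal on small panels (tested to
  6 markers) but carries no global guarantee for large ones.
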