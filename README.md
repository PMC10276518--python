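# methcascade

A pipeline for developing and validating a two-stage blood test for lung
cancer from circulating cell-free DNA (cfDNA) methylation. Tumor-derived
DNA in plasma carries hypermethylated marker regions; because the
circulating-tumor fraction is small, the observed plasma signal at a
differentially methylated region (DMR) is a dilution of the tumor signal
over the healthy background. `methcascade` implements the full
development arc on that signal:

1. **Quantification** — region-level bisulfite counts become the average
   methylation fraction, AMF = methylated CpGs / detected CpGs, with a
   coverage filter (default 100×) and an optional qPCR route
   (relative signal = 2^(Ct_ref − Ct_marker), censored at cycle 40).
2. **Marker selection** — a two-stage funnel: plasma discovery
   (Mann-Whitney p with Benjamini–Hochberg adjustment, fold change > 1,
   low healthy background, ranked by single-marker AUC then fold change,
   top 50), then verification requiring log₂(FC cancer vs. healthy) > 1,
   p < 0.05 and log₁₀(FC tumor vs. WBC) > 1, with an optional curation
   allowlist.
3. **Model training** — two logistic panel classifiers built by
   anchor-based greedy forward selection under 10 × 4-fold stratified
   cross-validation: a screening model **S** (cancer vs. healthy, cutoff
   calibrated to ≥ 90% training sensitivity) and a diagnostic model **D**
   (cancer vs. benign disease, cutoff calibrated to ≥ 95% benign
   specificity).
4. **Evaluation** — sensitivity/specificity/PPV/NPV with 1000-resample
   stratified-bootstrap CIs, tie-corrected rank AUC, the sequential
   **S → D cascade** (final positive requires both calls),
   prevalence-adjusted predictive values via Bayes' rule, Mann-Whitney
   covariate association, and combination of the D score with serum CEA.
5. **Synthetic cohorts** — a beta-binomial generator with planted
   hypermethylated DMRs and per-patient latent tumor fractions, so the
   whole pipeline is exercised end to end without patient data.

It also includes the standard sample-size formula for diagnostic
accuracy studies, n = z²·P(1−P)/d².

Intended users: computational biologists building or stress-testing
cfDNA methylation classifiers, and methodologists who need a transparent
reference implementation of the screening/triage cascade design.

## Worked example

```python
from methcascade import demo_config, run_pipeline, pct

report = run_pipeline(demo_config(seed=0))
s = report["s_model"]["validation"]
c = report["cascade"]
print("verified markers:", report["markers"]["n_verified"])
print("S validation AUC %.3f, sensitivity %s%%" % (s["auc"], pct(s["sensitivity"])))
print("cascade sensitivity %s%%, specificity %s%%"
      % (pct(c["sensitivity"]), pct(c["specificity"])))
```

prints, on the small built-in demo study (160 plasma samples, 40
regions, 6 planted DMRs):

```
verified markers: 6
S validation AUC 1.000, sensitivity 100.0%
cascade sensitivity 90.0%, specificity 100.0%
```

All 6 verified markers are the planted DMRs; the screening model
separates validation cancers from healthy controls perfectly at this
effect size, and chaining the diagnostic model after it trades 10
points of sensitivity for perfect combined specificity — the
characteristic cascade behaviour. The default (non-demo)
`PipelineConfig` runs a full-scale study: 254/180/251
cancer/benign/healthy plasma samples with a 64/45/63 validation
hold-out, 20 + 20 tumor/WBC tissue references, 165 regions with 15
planted DMRs.

The same steps are available from a shell:

```bash
methcascade simulate --out cohort/ --seed 7
methcascade select-markers --counts cohort/counts.tsv --samples cohort/samples.csv --out panel.tsv
methcascade train --mode S --counts cohort/counts.tsv --samples cohort/samples.csv \
    --panel panel.tsv --seed 7 --out model_S.json
methcascade run --seed 7 --out study/        # the whole pipeline
methcascade samplesize --p 0.9 --d 0.1      # -> 35
```

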