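# atf6scope

`atf6scope` is a tested re-implementation of the bespoke computational
procedures used to study ATF6α activation in hepatocellular carcinoma (HCC):
building an activation signature from differential expression, scoring it
per sample, pooling tumour/non-tumour contrasts across cohorts, stratifying
survival, quantifying single-cell spatial imaging data (IMC/MIBI), and
testing mouse–human copy-number synteny. Every stage can be exercised on
synthetic data with known ground truth, so the statistical machinery is
testable without any patient data.

## What it computes

**Signature & scoring.** From a differential-expression table, genes with
|log₂FC| ≥ 1 and BH-adjusted p < 0.05 define paired UP/DN gene sets. Each
sample is scored with single-sample GSEA: walking the sample's
descending-expression ranking, the enrichment score is
ES = Σᵢ [P_in(i) − P_out(i)], where P_in accumulates rank-statistic weights
rᵅ (α = 0.25) over set genes normalized to 1 and P_out accumulates uniform
mass over the complement. The activation score is
ES_combined = ES_UP − ES_DN. High/low calls use nearest-template prediction
(correlation distance to ±1 templates on gene-standardized expression, with
a random-gene-set permutation null and BH FDR < 0.05), and score–phenotype
association uses the information coefficient
IC = sign(ρ)·√(1 − e^(−2I)) with a KDE mutual-information estimate I.

**Meta-analysis.** Per-dataset tumour vs non-tumour contrasts are Hedges g
standardized mean differences pooled with the DerSimonian–Laird
random-effects estimator: τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)),
w*ᵢ = 1/(vᵢ + τ²), with a 95% normal CI.

**Survival.** Median split of the activation score (ties to low), follow-up
administratively censored at 60 months (events after the horizon are
treated as alive at 60 months), Kaplan–Meier product-limit curves and the
Mantel–Cox log-rank test.

**Spatial (IMC).** Cytoplasm = cell minus nucleus pixels; nuclei/cytoplasm
are mapped to parent cells by centroid containment (overlap-maximal
tie-break); mean marker intensity per compartment; threshold gating to
positivity flags and lineages; tissue regions classified ATF6α-hi/low by
positive-cell fraction; neighborhood profiles within a radius of
1.5 × the mean equivalent-circle cell diameter.

**MIBI QC.** Cells outside area 71–3,318 px, nuclear sum intensity
< 9.21 a.u., or nuclear proportion outside 0.3–99.8% are excluded with
per-rule counts; retained intensities are capped at the 99.9th percentile,
scaled ×10 and arcsinh-transformed; group comparisons use Mann–Whitney U
and Kolmogorov–Smirnov tests.

**Synteny.** Mouse CNA regions map to human homologues through an explicit
homology table; a pair is concordant when the same CNA type exceeds 5%
carrier frequency in human samples (strict); concordant/discordant counts
against a caller-chosen background form a 2×2 table tested with the
two-tailed Fisher's exact test.

## Worked example

```sh
atf6scope simulate --kind survival --seed 3 --outdir sim
atf6scope survival --survival sim/survival.tsv --out surv.json
cat surv.json
```

```json
{
  "n_high": 50,
  "n_low": 50,
  "logrank_chi2": 24.37991084034743,
  "logrank_p": 7.908915254599216e-07
}
```

The simulated cohort of 100 patients has a planted log-hazard of 1 per
standard deviation of the activation score; the median split produces two
groups of 50, and the log-rank test strongly rejects equal survival
(χ² = 24.4, p ≈ 8×10⁻⁷), recovering the planted association.

The same generators drive every other stage, e.g.
`atf6scope simulate --kind cohort` followed by `atf6scope score` produces
per-sample `es_up` / `es_dn` / `es_combined` scores in which the tumour
group scores higher exactly because of the planted UP/DN shift.

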