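# Methods

This note records the models, parameter choices and numerical conventions
behind `atf6scope`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Per-sample enrichment scoring

The scorer is single-sample GSEA. Within each sample, genes are ordered by
descending expression; ties break by ascending gene-id lexicographic order,
so constant or discretized samples still rank deterministically. Walking
down the ordering, the in-set running sum accumulates weights r^α — r the
rank statistic, N at the top of the list, 1 at the bottom — normalized to
total 1 over the set; the out-of-set sum accumulates uniform mass
1/(N − m). The score is Σᵢ (P_in(i) − P_out(i)) over all N positions.

Choices:

- **α = 0.25, no min–max rescaling** — the defaults of the standard
  single-sample GSEA module. The score is therefore a running-sum area, not
  a normalized statistic; only contrasts of scores within one cohort are
  meaningful.
- **One scorer for every stage.** Per-sample enrichment appears both in the
  cross-cohort meta-analysis and in survival stratification; both use this
  single ssGSEA implementation (recorded in output metadata) rather than
  mixing two rank-based scorers with nearly identical behaviour.
- **Absent set genes are dropped, not zero-filled**: phantom zeros would
  distort the rank statistic. If a set loses all its genes the call errors.
- The degenerate full-universe set (m = N) defines P_out ≡ 0, making the
  score the sum of the in-set CDF — the contract the tests pin down.
- Because weights depend only on ranks, scores are invariant under strictly
  monotone per-sample transforms for every α, which is the property test.

## Nearest-template prediction

Templates are +1 on UP genes and −1 on DN genes (high) and the negation
(low). Expression is first gene-wise standardized across the cohort; without
this, a cohort-wide per-gene baseline that happens to correlate with the
template pulls *every* sample toward one class, which is a property of the
baseline, not of any sample. Distance is 1 − Pearson correlation between a
sample's standardized signature-gene vector and each template; the nearer
template wins. The null draws `n_perm` random gene sets of matched size and
recomputes the distance; p is the fraction of null distances at or below
the observed one (with the +1 correction), BH-adjusted across samples;
calls are significant at FDR < 0.05. Monte-Carlo error scales as 1/√n_perm,
which the stability test (1000 vs 4000 permutations) verifies.

## Information coefficient

IC = sign(ρ)·√(1 − e^(−2I)) with ρ the Pearson correlation and I a Gaussian
kernel-density mutual-information estimate. The KDE uses per-variable
Silverman bandwidths (diagonal bandwidth matrix), so perfectly dependent
data do not produce a singular joint covariance, and a leave-one-out
resubstitution average, which removes most of the upward bias that plain
resubstitution shows on independent data. Negative I estimates are clipped
to 0. Constant vectors yield IC = 0 with a logged warning. Significance is
an empirical permutation test shuffling y. The exact bandwidth/grid of the
estimator's published lineage is not fixed anywhere authoritative; this is
a faithful reconstruction, and the tests assert only coarse, stable
properties (|IC| > 0.9 under exact dependence, small and insignificant
under independence, antisymmetry under y → −y).

## Meta-analysis

Per-dataset contrasts are Hedges g (bias-corrected standardized mean
difference) of per-sample scores, with the standard closed-form sampling
variance. Pooling is plain DerSimonian–Laird: fixed weights 1/vᵢ give
Cochran's Q; τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)); random-effects weights
1/(vᵢ + τ²); the CI multiplier is the normal 1.96, no Knapp–Hartung
adjustment. When τ̂² = 0 the estimator reduces exactly to fixed-effect
inverse-variance pooling (a property test), and the pooled estimate always
lies within the range of the inputs.

The recovery experiment plants the effect at the score level
(`gen_score_panel`: tumour ~ N(μ_d + δ, 1), control ~ N(μ_d, 1), so the
true SMD is exactly δ). Planting the effect in expression space and scoring
with a rank-based set statistic rescales the effect nonlinearly (averaging
over a set inflates the score-level SMD), so expression-level panels are
checked qualitatively — sign, significance, determinism — while coverage
and type-I error are measured where the truth is known exactly.

## Survival

Median split assigns scores strictly above the median to "high" and ties to
"low", so with 370 distinct scores the groups are 185/185. Follow-up is
administratively censored at 60 months: any record beyond the horizon
becomes (60, censored); the operation is idempotent and the KM curve of its
output has no support beyond 60 months. The KM estimator is the standard
product-limit form; censored-only times shrink the risk set without a step.
The log-rank test computes (O − E)²/V from per-event-time hypergeometric
moments and refers to χ²(1); it matches `lifelines` to ~1e-12 on shared
inputs (cross-check test) and its asymptotic p agrees with a 10,000-draw
permutation null within Monte-Carlo error at n = 40.

The survival generator uses exponential event times with hazard
h₀·exp(β·z(score)), h₀ = ln2/30 months (median survival 30 months at the
mean score). Censoring marks a Bernoulli(censor_rate) subset and draws their
observation time uniformly on (0, T): this hits the requested censoring
fraction exactly and is independent of the group labels under the null,
which is what the type-I-error property requires. It is *not*
independent-of-T censoring; none of the tested properties depend on that
distinction.

## Spatial (IMC)

- Cytoplasm is literal set subtraction (cell pixels minus all nucleus
  pixels), labels inherited from the cell mask.
- "Most central coordinates" is implemented as the pixel-rounded centroid;
  for objects whose centroid falls outside their own pixel set, the member
  pixel nearest the centroid substitutes, making the rule total.
- A cell keeps at most one nucleus; when several centroids land inside, the
  nucleus with the largest pixel overlap wins and the rest stay unassigned
  (logged). A brute-force maximal-overlap oracle confirms the assignment on
  synthetic tissues.
- The neighborhood radius is 1.5 × the mean equivalent-circle diameter
  2·√(area/π), computed **per image** (the per-image vs global choice is
  open in the source procedure; per-image is exposed via `radius_factor`).
  Neighbor distance is centroid-to-centroid, boundary inclusive, self
  excluded; the relation is symmetric by construction and checked against
  an all-pairs oracle.
- Gating thresholds are explicit inputs (≥ is positive); lineage rules are
  an ordered first-match table. Tissue-region classification defaults to a
  median split of the positive-cell fraction with ties to "low" (the
  quantitative rule is unstated in the source procedure; an absolute-cutoff
  override is provided).

## MIBI QC and normalization

The filter drops cells with area < 71 px or > 3,318 px, nuclear sum
intensity < 9.21 a.u., or nuclear proportion outside 0.3–99.8% — the fixed
values, with every bound exposed as a parameter; boundary values are kept
(the exclusion wording is strict). Counts are reported per rule plus a
deduplicated total, and the filter is idempotent. Normalization is exactly
the cap-at-99.9th-percentile → ×10 → arcsinh chain; no further
normalization precedes the cap. Group comparisons wrap scipy's two-sided
Mann–Whitney U and two-sample KS tests.

## Synteny

Pairs come from an explicit mouse→human homology table (one-to-many
retained; dangling keys error; unmapped mouse regions are reported).
Concordance is strict: same-type human carrier frequency > 0.05. When
frequencies must be derived from per-sample calls, a sample counts if a
same-type call overlaps the region by ≥ 1 bp (0-based half-open intervals
throughout). The 2×2 table's second stratum is caller-supplied — the one
genuinely open degree of freedom in the procedure — and the synthetic
recovery test uses a low-concordance background panel. Fisher's exact test
is the two-sided point-probability method (scipy); an independent
full-enumeration oracle over all margin-consistent tables verifies it to
1e-10 in the tests.

## Synthetic-data generators

Defaults aim at the emulated study conditions: 22 datasets (the size of the
expression meta-analysis panel), 50 samples per group, 2,000 genes with a
100/50 UP/DN signature (a desk-scale stand-in for the 888/266 mouse-derived
sets), standardized effect 0.8, survival n = 370 with β = 1 and 30%
censoring, 5 px cell radius with a concentric half-radius nucleus,
lognormal markers with a 4-log-SD positive/negative separation, and 20 CNA
region pairs. Expression noise is Gaussian on the log scale — the scorer is
rank-based, so only ordering structure matters. Cells are hard discs placed
by rejection sampling (bounded retries, then an error suggesting fewer
cells); the mapping and neighborhood operators only consume centroids,
areas and containment, which discs provide exactly.

What the generators deliberately omit: marker spillover, doublets,
segmentation errors, batch effects beyond per-dataset mean shifts,
platform-specific expression distributions, and non-exponential hazards.
Passing tests therefore demonstrate the *statistical machinery* —
calibration, recovery, oracle equivalence — not robustness to those
real-data artifacts.

## Problem sizes and determinism

Simulation-based checks use 100 replicates for meta-analysis coverage, 200
for survival type-I error, 100 for power, 10 planted cohorts for NTP and 20
for score-difference nulls — sizes at which binomial Monte-Carlo error is
small relative to the asserted bands (e.g. a 3σ band around 5% at 200
replicates). All randomness flows through explicit
`numpy.random.Generator` objects seeded per run; no global state. Every
generator is bit-reproducible under a fixed seed, which the determinism
tests assert frame-for-frame.
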