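# Methods

## Overview

`repgvhd` implements a repertoire-analysis chain for TRB clonotype
tables from sorted T-cell subsets sampled longitudinally around donor
lymphocyte infusion: depth normalization → diversity/clonality metrics →
healthy-control-referenced classification → longitudinal change →
competing-risk incidence comparison. This note records the statistical
conventions, defaults, and design choices, and what the synthetic
validation does and does not demonstrate.

## Clonotype tables and identity

A clonotype is keyed by (V call, J call, CDR3 nucleotide sequence) by
default; amino-acid-level aggregation (V, J, CDR3aa) is a configuration
switch that merges synonymous nucleotide variants by summing counts.
Frequencies are always recomputed from counts; frequency columns in
input files are advisory and a disagreement is logged, not trusted.
Upstream alignment/assembly and PCR-error correction are the aligner's
job (MIXCR or equivalent); this package consumes its exported tables in
VDJtools-style or AIRR Rearrangement TSV dialects.

## Depth normalization

Diversity statistics are depth-dependent, so every sample is randomly
downsampled to a common target (default **20,000 reads**) before any
metric is computed. The default scheme draws reads **without
replacement** from the observed read pool, i.e. per-clone counts are
multivariate hypergeometric over the input counts — this treats the
observed reads as the finite population being subsampled. A multinomial
(with-replacement) variant exists for sensitivity checks. Samples below
the target cannot be equalized; by default they are flagged and excluded
from comparisons (`short_policy="skip"`), since the point of the step is
fair comparison at equal depth. Downsampling is bit-reproducible per
(table, target, seed).

## Metrics

* Inverse Simpson 1/D = 1/Σpᵢ², bounded by [1, S] with S the number of
  unique clonotypes.
* Clonal-space occupancy at thresholds {0.25, 0.5, 0.75, 1.0}: the
  minimal k such that the k largest frequencies sum to **at least** the
  threshold ("≥" at the boundary, no fractional clones). The comparison
  is performed on integer count cumsums against threshold × total reads,
  so the boundary is exact rather than subject to floating-point
  accumulation.
* Top-N proportion (default N = 20): summed frequency of the N most
  abundant clonotypes.

Ties in abundance are broken deterministically: count descending, then
lexicographic (V|J|CDR3nt) key. This makes results identical across
runs and platforms; any other fixed convention would change nothing
statistically since tied clones are exchangeable.

## Healthy-control reference and classification

Healthy individuals are sampled repeatedly, so the reference band is
built **per individual** by default: each individual contributes the
arithmetic mean of their samples' 1/D, and the 25th/75th percentiles are
taken over those means (linear interpolation between order statistics —
the common numpy default, fixed here for reproducibility). A pooled
`all_samples` mode is also implemented and reported alongside, because
pooling is a defensible alternative when per-individual sampling is
balanced; the pipeline labels which mode produced each threshold.

Classification is a strict inequality: 1/D **< p25 ⇒ expanded**, 1/D ≥
p25 ⇒ healthy-like. A value exactly at the percentile is healthy-like.

Longitudinal pairs take, for event subjects, the latest sample strictly
before the anchor (e.g. GVHD onset) and the earliest sample at/after it.
Control subjects are "matched for timing" by a deterministic rule: the
consecutive sample pair minimizing summed absolute distance to the event
group's median pre/post sampling days, ties resolved toward earlier
timepoints. Changes are reported as 100·(post − pre)/pre.

## Group tests

Two-group comparisons run a Shapiro–Wilk gate at α = 0.05 on each group
(on paired differences for paired designs): normal → two-tailed Student
t-test; otherwise Mann–Whitney (exact when both groups ≤ 25 without
ties, tie-corrected normal approximation beyond) or the Wilcoxon
matched-pairs signed-rank test. All-zero paired differences are reported
as p = 1 with a flag rather than an error. Categorical 2×2 tables use
Fisher's exact test (two-tailed by summing hypergeometric probabilities
≤ the observed table's).

## Competing-risk statistics

Event records carry a time in months (administratively censored at 36)
and a code: endpoint event, competing event, or censored.

* **Cumulative incidence**: Aalen–Johansen,
  CIF(t) = Σ_{tᵢ≤t} S(tᵢ⁻)·dᵢ/nᵢ with S the all-cause Kaplan–Meier
  survival. Tied events at a time use the risk set just before it.
* **Mantel–Haenszel hazard ratio**: HR = (O₁/E₁)/(O₂/E₂) from summed
  2×2 risk tables at endpoint event times, CI =
  exp(log HR ± 1.96/√V) with V the summed hypergeometric variances.
  Competing events are **censored** for this statistic (the common
  software convention; it estimates the cause-specific hazard ratio,
  not the subdistribution one — a documented choice, since curves and
  Gray's test below retain competing events).
* **Gray's test** (ρ = 0, two groups): implemented in
  modified-risk-set log-rank form. Each group's subdistribution risk
  set is R_g(t) = Y_g(t)·(1 − F̂₁g(t⁻))/Ŝ_g(t⁻), which keeps subjects
  with prior competing events represented; the score
  U = Σ_t [d₁A − d₁·R_A/R] and variance
  V = Σ_t d₁·(R_A/R)(R_B/R)·(R − d₁)/(R − 1) then take the log-rank
  form. This variance omits the correction for estimating the risk-set
  weights, a deliberate simplification with three consequences, all
  verified by the test suite: (i) with zero competing events the
  statistic and p-value reduce *exactly* to the standard log-rank
  test; (ii) against the reference R implementation (`cmprsk::cuminc`)
  the chi-square statistic differs by a few percent on small tables
  (a frozen cross-check value is asserted at 10% tolerance); (iii)
  type-I error under a simulated null (n = 30/group, 1,000 replicates)
  is calibrated within [0.03, 0.07].

With eight subjects the exact permutation distribution of the statistic
has support steps of 1/70, so the asymptotic chi-square p-value is
compared to the permutation oracle only coarsely (±0.1); the asymptotic
reference is intended for cohort-sized groups, not n = 8.

## Synthetic data

The generators reproduce the statistical structure the analysis relies
on and deliberately nothing else:

* **Clone-size law**: latent clone masses from a power law with tail
  exponent α = 2.0 (typical of TRB clone-size fits; a log-normal
  alternative is provided for robustness checks), 2,000 clones and
  100,000 reads per sample by default so the 20,000-read normalization
  stage is always exercised.
* **Expansion**: the masses of the top m = 5 clones are multiplied by a
  factor E ≥ 1; E = 1 is healthy-like, E = 20 reproduces the expanded
  signature (lower 1/D, smaller clonal-space counts, larger top-20).
  Longitudinal pairs share one clone pool and re-weight the top clones
  in the post sample, guaranteeing key overlap between timepoints.
* **Sequences**: random in-frame CDR3 nucleotide strings of 27–51 nt
  with uniform V/J calls. No V(D)J recombination statistics, no
  sequencing error, no shared/public clones between individuals.
* **Cohorts**: constant cause-specific hazards (events/month) for the
  endpoint and two competing causes (defaults 0.03 endpoint for
  healthy-like subjects, 0.02 relapse, 0.01 non-relapse mortality,
  chosen to give event frequencies over 36 months comparable to a DLI
  cohort in which roughly half the subjects develop GVHD); expanded
  subjects carry `hazard_ratio_expanded` (default 2.5) times the
  endpoint hazard. First event wins; administrative censoring at 36
  months.

Passing tests on these data show the *machinery* is correct (estimators
match oracles and reference implementations, classification recovers a
known planted structure, survival statistics are calibrated). They do
not show that real T_reg/T_con repertoires follow a power law, that real
effect sizes match the planted ones, or that 1/D thresholds transfer
across sequencing protocols.

## Problem sizes used in validation

Metric oracle equivalence uses 10,000 random tables of ≤ 30 clones;
downsampling checks use 500 seeded draws on 5-clone tables; Gray's
type-I calibration uses 1,000 null cohorts of 30/group; hazard-ratio CI
coverage uses 500 cohorts of 40/group at true HR 3; the end-to-end
recovery experiment uses 200 replicate cohorts (9 healthy controls × 2
samples; 20 expanded + 20 healthy-like subjects, E = 20 vs 1, hazard
ratio 2.5), which completes in a couple of minutes on one CPU.

## Known limitations

* The Gray's-test variance simplification above; for publication-grade
  subdistribution inference on real cohorts, cross-check with
  `cmprsk::cuminc`.
* The Mantel–Haenszel HR on competing-risk data estimates a
  cause-specific quantity; it is reported alongside Gray's test, not as
  a substitute.
* Under-depth samples are excluded rather than rarefaction-corrected;
  no Chao/Shannon-style richness estimation is attempted.
* The synthetic clone-size law is a stand-in; all synthetic defaults
  are labelled as such in the generator docstrings.
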