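# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the limits of what the test suite demonstrates.

## Study design and data model

The pipeline assumes a *replicated perturbation design*: two independent
experiments, each with one control group and several treatment groups of
equal size (default five mice), a positive-valued phenotype matrix
(metabolic parameters and qPCR gene expression, analysed on the log2
scale) and an OTU count table per experiment. All inference is
meta-analytic: nothing is called significant unless it replicates across
both experiments in direction and survives combined-evidence thresholds.

## Differential statistics

**Outlier handling.** Per feature, group and experiment, a two-sided
Grubbs test (α = 0.05) removes at most one extreme value per single pass;
the critical value is ((N−1)/√N)·√(t²/(N−2+t²)) with t the upper α/(2N)
Student quantile on N−2 df. Groups of n < 3 or zero variance pass through.
Outlier removal applies to the differential branch only; correlations are
computed on the full data (rank statistics are already outlier-resistant,
and deleting values would break the paired-sample structure).

**Moderated two-group fit.** The empirical-Bayes formulation: per feature,
pooled variance s² on d = n₁+n₂−2 df; across features, the scaled
inverse-chi-square prior (d₀, s₀²) is estimated by the method of moments
on log s², using E[log χ²_d] = ψ(d/2) + log 2 and Var[log χ²_d] = ψ′(d/2);
the trigamma inverse is solved by Newton iteration. The posterior variance
s²_post = (d₀s₀² + ds²)/(d₀+d) yields a t statistic on d₀+d df (normal
limit when d₀ → ∞, which is also the flag for "no excess variance spread
across features"). Setting d₀ = 0 recovers the ordinary pooled t exactly —
a tested identity. The implementation was cross-checked against the
reference empirical-Bayes implementation in Bioconductor's limma on a
frozen fixture (agreement ≈ 1e-8); note that a simulation check of the
hyperparameter estimator must draw variances from the *inverse*
chi-square prior — drawing from a direct χ²_d0/d0 biases the recovered s₀²
by exp(2(ψ(2)−log 2)) ≈ 0.58 and is a misread of the model.

**Meta-analysis.** Fisher's method (−2Σln p on 2k df; zero p-values are
clamped to the smallest positive normal, never propagated as −∞), BH FDR
per comparison across its features (the FDR family is one
treatment-vs-control comparison; the family choice is configurable but not
derivable from first principles). The composite call requires direction
agreement, per-experiment p < `p_individual`, combined p < `p_combined`
and q < `fdr` — defaults 0.20 / 0.05 / 0.10, with a stricter diversity
profile 0.02 / 0.001 / 0.001.

**Permutation t-test.** Exhaustive over label arrangements when there are
≤ 20,000 of them (exact conditional p), Monte-Carlo with the +1 correction
otherwise. At n = 5 vs 5 the exhaustive two-sided floor is 2/252 ≈ 0.0079.
A structural consequence: the diversity profile's FDR < 0.1% is reachable
from that floor only when the comparison family is small (the combined-p
floor is ≈ 6.7e-4, and BH multiplies by m/rank). The pipeline reports the
full five-comparison family honestly; the single-contrast test
demonstrates the planted-signal behaviour.

## Microbiome preparation

Order of operations: cumulative-abundance filter (99% of total counts,
descending by OTU total, boundary ties retained) → CSS → quantile
normalization for the analysis branch; rarefaction (without replacement,
multivariate hypergeometric) → Shannon H (log2) for the diversity branch
only. CSS uses a fixed percentile (default: median of a sample's nonzero
counts) — the adaptive percentile search of the original CSS method is out
of scope. log2 of normalized abundances uses a +1 offset (configurable)
because zeros survive normalization. Quantile normalization averages
column-sorted values positionwise and assigns by average rank; with ties
it is idempotent only up to tie-averaging, exactly idempotent on
continuous data. Rarefaction depth defaults to 200,000 reads (the depth
appropriate for real 16S libraries); synthetic runs use 10,000, matched to
the generator's library sizes — both ship in the config.

## Network inference

Spearman ρ is the Pearson correlation of midranks. p-values: exact by full
enumeration of the n! pairings when n ≤ 8 (per-group correlations at
n = 5), t-approximation t = ρ√((n−2)/(1−ρ²)) otherwise (all-sample,
n ≈ 29–30). Pairs with zero variance in either member are recorded as
undefined and skipped. Four edge classes with independent BH families;
OTU–OTU pairs are never computed.

Filters are a pure conjunction, so order does not affect the result; every
candidate pair carries a verdict per filter in the output ledger.
Numerical sign handling: |log2 FC| and |ρ| below 1e-9 count as zero
(direction undefined), which can only make filters stricter.

**Causality compliancy** is operationalized as sign concordance: an edge
with correlation sign s is compliant in (group, experiment) iff
sign(FC_a)·sign(FC_b) = s with both fold changes nonzero, and passes iff
some group is compliant in both experiments. Node fold changes are
differences of group medians of log2 values versus control (medians for
robustness at n = 5, matching the use of medians for node coloring;
the differential *statistics* use means — both conventions are recorded).

**Visualization rule.** A retained phenotype edge is flagged for display
iff its |ρ| (cross-experiment median of all-sample ρ) exceeds the minimum
|ρ| among retained OTU–phenotype edges incident to *either* endpoint; the
stricter both-endpoints reading is available via config. Topology (degree,
per-component-normalized betweenness) is computed by default on this
"figure" network — OTU edges plus flagged phenotype edges — with an
`analysis` mode for the full retained set.

**Ranking.** S = max_g(a_g)·|median_g(r_g)|, per-group values reduced to
cross-experiment medians first (median of two = their mean); groups with
undefined ρ are skipped in the median; edges undefined in every group are
unrankable and placed last. The abundance a_g defaults to relative
abundance on the filtered raw counts (configurable to the normalized
table — the source table is not dictated by the procedure itself).

## Synthetic-data generator

The generator emulates the study's *shape*, not its biology: two
experiments drawn independently from an identical law, six groups × five
mice, 24 phenotypes (4 metabolic + 20 liver/ileum genes), 200 OTUs.

* Phenotypes: value = 2^(baseline + group effect + σ_p·noise), σ_p = 0.5
  log2 units (≈ 40% CV, typical of metabolic phenotypes).
* OTU counts: per-sample composition from 2^(baseline + effect + σ_o·noise)
  with σ_o = 1.0 log2 for ordinary taxa; library sizes log-uniform on
  [2×10⁵, 10⁶]; counts gamma-Poisson with dispersion 0.5 (overdispersion
  typical of 16S counts). Baseline log2 weights are N(0, 2) — a realistic,
  strongly concentrated community.
* Planted microbe–phenotype correlations: a per-mouse latent Gaussian is
  shared between an OTU's log abundance and a phenotype's log value. The
  target Spearman ρ_S maps to a latent Pearson ρ_P = 2 sin(πρ_S/6), which
  is then inflated to offset the known transmission losses: gamma-Poisson
  counting noise (log-gamma variance ψ′(1/dispersion), plus 1/μ), the
  compositional denominator (delta-method variance of the log total,
  excluding the OTU's own term), and a 0.97 rank-transmission factor for
  the CSS + quantile chain, estimated once by simulation. If the required
  shared fraction exceeds 1 the generator plants the strongest achievable
  coupling and warns. Planted-edge taxa are modelled as hyper-variable
  microbes (σ = 4 log2 units) at ~1% baseline share: a strong rank
  correlation with a host phenotype is only physically transmissible
  through counting noise when the microbe's biological variation dominates,
  and only visible to rank-based normalization when the taxon is mobile in
  the within-sample ranking rather than pinned at the top.
* The canonical planted scenario (`default_truth`): eight phenotypes with
  ±1.5 SD effects and ten differential OTUs in the strong-perturbation
  groups (cocktail, ampicillin, vancomycin), and three |ρ| = 0.9 edges
  whose endpoints' fold-change directions are aligned with the correlation
  sign, so the edges are causality-compliant by construction. Planted-edge
  OTUs carry 8-fold effects: with dispersion 0.5 the per-observation log2
  noise floor is ≈ 1.2, so a 4-fold change at n = 5 has ≈ 65–70% composite
  detection power at best — 8-fold changes (still orders of magnitude below
  what strong antibiotics do to susceptible taxa) are the smallest planted
  effect whose direction and significance replicate reliably.
* Determinism: all draws flow from one master seed through named
  SeedSequence streams (baselines; one stream per experiment). An optional
  between-experiment heterogeneity term (off by default) jitters effect
  sizes per experiment.

What the generator does **not** emulate: phylogenetic structure and
taxonomy, read-level artifacts (chimeras, primer bias), antibiotic
pharmacokinetics, co-occurrence structure between taxa beyond the shared
compositional denominator, and batch effects. Passing recovery tests
therefore show that the *procedure* recovers the structure it defines —
not that real microbes obeying none of these simplifications would be
found.

## Problem sizes and test design

Simulation-based tests use 40-OTU studies (the full candidate-pair space
at 200 OTUs adds nothing to the properties being measured, only runtime):
100 label-permuted null studies for calibration, 50 planted studies for
edge recovery, 200 replicates for phenotype power and for hyperparameter
recovery. The phenotype power scenario plants 1.5-SD effects on all 24
phenotypes — the panel plays the role of measurements chosen for
responsiveness, and this removes the arbitrary influence of FDR-family
density on the measured per-effect power (the per-experiment p < 20%
conjunction alone caps attainable power at ≈ 74% at this effect size, so
the ≈ 71% measured is close to the design's ceiling).

## Known limitations

* The FDR family (per comparison) and the quantile-normalization scope
  (within experiment) are conventions, stated and configurable, not
  derivable facts.
* Exact permutation p-values are conditional on observed ties; at n = 5
  their granularity (multiples of 1/120 per orientation) makes
  per-group p-values coarse — which is why the per-group filters use only
  the correlation sign.
* The causality-compliancy predicate is a sign-concordance
  operationalization of "fold-change relationship satisfied"; richer
  formulations (magnitude-aware, dose-aware) would need information the
  two-group design does not provide. The predicate is pluggable.
* Betweenness normalization is per connected component; comparing BC
  across components of very different sizes is not meaningful.
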