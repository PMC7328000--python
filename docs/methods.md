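# Methods

## Data model and scope

The atomic observation is a peptide-spectrum match (PSM) carrying
reporter-ion intensities for the channels of one TMT10 plex. Intensities
are taken as given (peak integration and search are upstream concerns);
zero or absent intensities are treated as missing, never imputed. A
design table maps (plex, channel) to sample, condition and the pooled
reference flag; every plex must contain at least one reference channel.
Isotope-impurity correction, ratio-compression correction and plex
bridging beyond the common reference are out of scope.

## Identification

Target-decoy filtering uses the plain count estimator
FDR(s) = #decoys(score ≥ s) / max(1, #targets(score ≥ s)) with cutoff
s\* = min{s : FDR(s) ≤ α}, α = 0.01 by default. No +1 pseudo-count and no
q-value monotonization are applied at the PSM level; if no cutoff
achieves α the filter returns nothing and warns rather than raising.
This estimator is monotone in α (property-tested).

Protein inference is a greedy set cover under Occam's razor. Peptides are
identified by sequence + modification string. Iteratively, the protein
explaining the most uncovered peptides is selected (ties broken by
lexicographically smallest accession, for determinism); the peptides it
claims become its razor peptides, so every peptide is razor-assigned to
exactly one group. Groups with ≥ 2 razor peptides are accepted.
Non-accepted proteins whose peptide sets are subsets of an accepted
lead's set are folded into that group as members (their razor claims
transfer); unselected proteins that are not subsets of any single
accepted lead are discarded by parsimony. Greedy set cover is not
guaranteed to find the minimum cover; on random toy instances it matches
an exhaustive search in > 90% of cases and overshoots by at most one
protein otherwise (tested against full enumeration).

## Quantification

**Filters.** A PSM is removed if its peptide's candidate proteins span
more than one accepted group (shared peptide) or if its mean reporter
intensity is below 10³. The mean is taken over the channels carrying a
positive value; a PSM with no positive channel is removed. The
per-PSM (rather than per-channel) reading of the intensity rule was
chosen because the filter removes whole PSM entries.

**Ratios.** For PSM i and non-reference channel c,
r = log₂(I_c / mean of the plex's reference-channel intensities),
missing when I_c ≤ 0 or the reference mean ≤ 0.

**Dixon's Q.** Outliers among a peptide's PSM ratios are removed per
(peptide, channel) — the only axis on which the ratios are comparable —
and only when more than two PSMs identify the peptide. The
range-appropriate statistic is used: r10 for n 3–7, r11 for 8–10, r21
for 11–13, r22 for 14–30, with the standard two-tailed 95% critical
values (0.970 at n=3 down to 0.426 at n=30); the suspect value is the
more extreme tail's. Removal recurses until no outlier is flagged or
fewer than 3 values remain; vectors longer than 30 are left untouched.
Degenerate cases (zero range, zero sub-range denominators) are treated
as "no outlier". The recursion is verified exhaustively against a naive
reimplementation on all small integer multisets.

**Roll-ups.** Medians of non-missing child values, PSM → peptide and
peptide → protein (via razor assignment, accepted groups only);
representative intensities are rolled up as medians alongside.

**Mode alignment.** Per sample, a 3-component Gaussian mixture is fitted
to the protein log₂-ratios by EM with a deterministic initialization
(means at the 25th/50th/75th percentiles, equal weights, component SDs =
overall SD), relative log-likelihood tolerance 1e-8, at most 2000
iterations, and SDs floored at 1e-3 (the floor also resolves
single-point component collapse). The sample is shifted by the mode of
the fitted density — located on a 2001-point grid spanning mean ± 6 SD
and refined by a bounded golden-section pass. The mode (density argmax)
was chosen over the dominant component's mean as the reading of
"maximum likelihood centered at zero"; the component parameters are
exposed in the fit object for comparison. Because EM from a
quantile-based start is translation-equivariant, refitting after the
shift returns a mode within numerical precision of zero (asserted at
|mode| ≤ 0.01). Samples with fewer than 30 ratios fall back to median
centering with a warning. The EM trajectory is retained and its
monotonicity asserted in tests; the fit is cross-checked against
scikit-learn's GaussianMixture started from the same initialization.

**Trimmed scaling.** Per sample, the standard deviation is computed
excluding (a) ratios in the top/bottom 5% quantiles of ratio value and
(b) ratios of proteins in the top/bottom 5% quantiles of that sample's
protein intensity (median of contributing PSM intensities); all of the
sample's ratios — including trimmed ones — are then divided by it.
Quantile membership is scale-invariant, so recomputing the trimmed SD
after scaling returns exactly 1 (asserted at ±1e-6). A zero/undefined
trimmed SD skips scaling for that sample with a warning. Alignment
precedes scaling. Scaling standardizes each sample, so contrast
estimates are on a per-sample standardized scale; the provenance log
records each sample's divisor, and multiplying back reconstructs raw
log₂ fold changes (the pipeline recovers planted log2FC = 1 effects to
within ±0.1 this way).

## Differential abundance

Per protein, a group-means linear model on non-missing values gives the
contrast estimate (difference of group means), pooled residual variance
s²_g and residual df d_g = n_A + n_B − 2; proteins with fewer than 2
observations in either group are reported with missing statistics, and
the BH multiplicity count m includes only tested proteins. The
empirical-Bayes squeeze estimates the prior (d₀, s₀²) by moment matching
on e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the excess of Var(e) over the
mean trigamma term is inverted through ψ′ (Newton iteration) to give
d₀, and s₀² = exp(mean e + ψ(d₀/2) − log(d₀/2)). When the observed
spread does not exceed sampling noise, d₀ = ∞ and s₀² is the arithmetic
mean of the variances (all-equal variances are then a fixed point). Zero
variances are offset to 1e-5 × median before taking logs. The posterior
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) feeds the moderated
t = estimate/√(s̃²(1/n_A + 1/n_B)) on d₀ + d_g df (normal when d₀ = ∞).
The squeeze is validated against Bioconductor limma's `squeezeVar` and,
in the d₀ → 0 limit, collapses to the ordinary pooled t-test. BH
adjustment is the textbook step-up, cross-checked against statsmodels.
With d₀ = 0 there is no moderation; with disperse variances the
estimated d₀ is small and the posterior tracks s²_g.

Metric MDS uses pairwise Euclidean distances over the proteins
non-missing in both samples, double-centering and eigendecomposition;
PCA uses column-centered SVD on listwise-complete proteins with a
deterministic sign convention (largest-magnitude loading positive). On
complete matrices the two coincide up to sign (tested).

## Small-sample group statistics

The two-sided Mann-Whitney test is exact for n_A + n_B ≤ 25: the
permutation null of the rank sum is evaluated by a subset-count dynamic
program over the doubled mid-ranks, which enumerates all C(n, n_A)
group assignments (exact under ties, conditional on the observed rank
multiset). The two-sided p doubles the smaller tail and caps at 1 — the
convention under which complete separation at 5 vs 5 gives
p = 2/252 ≈ 0.0079, the smallest attainable value for that design.
Larger samples use the tie-corrected normal approximation with
continuity correction, flagged as such in the result. Comparative-C_T
fold changes are 2^−ΔΔCT.

## Synthetic data

The generator emulates the study conditions end to end: one 10-plex with
channel 126 as pooled reference, 4 WT and 3 Cko samples; 1000 proteins
of which 10% carry a +1 log₂ fold change in Cko (an optional
"stefin-like" block adds a few proteins at +2); 1 + Poisson(2) peptides
per protein and 1 + Poisson(1) PSMs per peptide; base abundances
log10-normal (location 4.5, spread 0.6); peptide ionization efficiencies
log₂-normal (SD 1); multiplicative PSM measurement noise of 0.3 on the
log₂ scale; 5% shared peptides; 5% of PSMs rescaled below the 10³
intensity threshold; 2% outlier PSMs shifted by ±U(2,4) log₂ units in
one random channel; 30% decoy rows with scores stochastically below the
targets (N(18,6) vs N(40,8)). The reference channel carries the exact
mean of the sample intensities of the PSM — the pooled-lysate reading —
with an optional independent-noise variant. Determinism: one master RNG
per dataset plus per-protein substreams seeded by (seed, protein index),
so identical seeds give byte-identical tables.

For calibration studies needing hundreds of replicates, a protein-level
matrix generator stands in for the full PSM pipeline at the level the
moderated t actually consumes. Its per-protein variances are drawn from
the scaled inverse-chi-square family (prior df 10 by default), mirroring
the heterogeneity real roll-up output exhibits because proteins differ
in peptide/PSM support; a constant-variance null is available via
`var_prior_df=inf` but is not the default, as it represents an
exchangeability corner case rather than realistic data.

What the generator does *not* emulate: ratio compression from co-isolated
precursors, isotope impurity leakage between channels, intensity-
dependent (heteroscedastic) measurement noise, missingness correlated
with abundance, batch effects across plexes, and real decoy score
distributions. Passing tests therefore demonstrate the correctness and
calibration of the algorithms under the stated model, not robustness to
every artifact of instrument data.

## Problem sizes and numerical choices

Default analyses use 1000 simulated proteins (≈ 7-8k PSMs, ~1 CPU-second
per pipeline stage); calibration studies use 2000 proteins × 200 null
replicates and 50 planted-effect replicates at the matrix level. Medians
and SDs ignore missing values throughout. Ties in the greedy cover, the
mode grid search and PCA signs are broken deterministically so that runs
are exactly reproducible; all randomness flows from a single integer
seed.

## Known limitations

- Peptide- and protein-level FDR are not computed (PSM-level only).
- The 10³ intensity filter is interpreted per PSM (mean reporter
  intensity); a per-channel masking variant would retain partial PSMs.
- Mixture-mode alignment assumes the unchanged-protein bulk dominates;
  with a majority of regulated proteins the mode is not a null anchor.
- The normal-approximation branch of the Mann-Whitney test (n > 25) is
  asymptotic; confidence intervals are not provided.
- Scaling standardizes per sample, which equalizes apparent effect
  sizes across samples with different dispersion; consumers needing raw
  log₂ fold changes must unscale via the provenance divisors.
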