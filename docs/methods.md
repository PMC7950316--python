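# Methods

This note documents the statistical models, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer would want to know.

## Quantification model and sign convention

Every analysis works on per-replicate peptide ratios
x = log2(light/heavy) = log2(KO/WT). The sign convention is fixed
throughout: a peptide the aminopeptidase normally **destroys** is more
abundant when the enzyme is knocked out, so it carries a **positive**
log-fold-change and is called *sensitive*; a peptide the enzyme's
trimming **creates** carries a negative log-fold-change and is called
*dependent*. Absolute intensities never enter any statistic — columns of
the peptide × replicate ratio matrix are median-centered (offsets
recorded), which removes global labelling/loading differences while
preserving ranks.

## Empirical-Bayes moderation

With two replicates each peptide contributes one residual degree of
freedom, far too few for a stable per-peptide variance. The moderated
test therefore shrinks each sample variance s² toward a prior (d0, s0²)
estimated from all peptides by the moments method on log variances:
writing e = log s² − ψ(d/2) + log(d/2), the excess of var(e) over
ψ′(d/2) equals ψ′(d0/2) (solved by Newton on the inverse trigamma), and
mean(e) gives s0² after bias correction. Degenerate regimes are handled
explicitly: numerically constant variances return d0 = ∞ with s0² equal
to that constant (no dispersion to shrink against), and d0 = 0
reproduces the ordinary t exactly. The moderated statistic is
t = x̄/√(s̃²/n_eff) with s̃² = (d0 s0² + d s²)/(d0 + d) on d + d0 df;
n_eff is the number of finite ratio cells of the peptide. Peptides
quantified in a single replicate (d = 0) cannot be moderated and are
reported separately, as are single-channel-only peptides.

FDR calibration uses Storey q-values: π0(λ) = #{p > λ}/(m(1−λ)) on the
grid λ = 0.05…0.95 is smoothed with a cubic spline and read off at
λ = 0.95, clamped to (0, 1]; with fewer than 100 p-values π0 falls back
to 1, where the q-value reduces exactly to Benjamini–Hochberg (a unit
test pins this equivalence to 1e-12). The classification threshold
defaults to q < 0.01, i.e. 1% expected false discoveries among calls.
Self-calibration on planted-truth simulations (5,000 peptides, 10% + 10%
planted at |log2FC| = 1.5, noise sd 0.4, 2 replicates, 20 seeds) gives a
realized false-discovery proportion of ~0.6–0.8%, and ≥ 95% power at the
larger |log2FC| = 2.45 effect scale.

## PSSM allele models and percentile binding scores

Allele models are position-specific scoring matrices with log-odds
log2((c + β·b)/(n + β)/b) against a background b (uniform by default,
injectable, e.g. a proteome composition). β is the total pseudocount
mass; the default β = 20 is one pseudocount per residue (Laplace) under
the uniform background. The binding score of a peptide is the percentile
rank (mid-rank for ties) of its summed log-odds within a fixed
population of 10,000 background-sampled reference peptides drawn with a
hard-coded seed, so scores are reproducible across processes. These
percentile scores live on [0, 1] and the conventional thresholds are
carried over (> 0.6 good, > 0.8 strong, > 0.9 for restriction
screening) — but note they are rank percentiles against a background,
**not** neural-network presentation probabilities; absolute values are
not comparable to tools trained on eluted-ligand data.

## Gibbs motif deconvolution

Mixed ligand sets are deconvoluted by annealed Gibbs sampling over
cluster assignments. Scoring: each peptide's log-odds under a cluster
PSSM with leave-one-out counts; the move score of candidate cluster c is
that log-odds minus λ·(best log-odds under any other cluster), which
penalizes redundant clusters (λ = 0.7 default). Assignments are
resampled synchronously each iteration with probability ∝ exp(move/T),
T following a geometric schedule from σ = 5 down to 0.1 over 60
iterations; each restart ends with a zero-temperature sweep that accepts
single moves only when the global objective does not decrease (the
objective trajectory is therefore monotone at the end, and is recorded).
Solutions are computed for every cluster number g′ = 1…g (5 random
restarts each) and the best penalized objective wins, ties preferring
fewer clusters. This per-cluster-number search is essential: at fixed
g a motif split across two clusters is a local optimum that
single-peptide moves cannot escape. Peptides whose best cluster score
falls below the trash threshold (3 bits default) are labelled trash
(−1) — outliers explicitly not assigned to any motif.

One identifiability caveat, found while validating on planted mixtures:
two families that differ at a *single* anchor position with two
equiprobable residues each (e.g. PΩ ∈ {Y,F} vs PΩ ∈ {K,R}) are **not**
identifiable under a position-independent PSSM mixture — the pairing
{Y,K} vs {F,R} yields an identical likelihood by symmetry. Recovery
tests therefore plant families with two disjoint anchor positions
(P2 + PΩ), the realistic shape of class I motifs; there the adjusted
Rand index over assigned peptides is ≥ 0.95.

## Entropy-weighted landscapes

For a set of equal-length peptides, position p gets Shannon entropy H_p
(bits over the 20 residues) and weight w_p = 1 − H_p/log2(20). The
bounded linear form was chosen over 1/H alternatives because it has no
singularity at fully conserved positions and still lets anchor-like
(low-entropy) positions dominate the metric. The residue dissimilarity
R defaults to 1 − min-max-normalized BLOSUM62 over the 20 canonical
residues with the diagonal forced to 0; on this matrix the weighted
distance is symmetric, satisfies the identity property and the triangle
inequality (tested). Any 20×20 matrix can be injected instead. Peptides
of different lengths belong in separate landscapes.

The 2-D embedding is non-metric MDS: per ordination, isotonic
disparities in the rank order of the input dissimilarities alternate
with Guttman transforms; Kruskal stress-1 is tracked per iteration with
a descent safeguard (stop on non-improvement), so the recorded
trajectory is non-increasing; the configuration scale is pinned to the
dissimilarity RMS each iteration because stress-1 is scale-invariant and
the iteration otherwise drifts toward zero coordinates. Ten ordinations
of up to 500 iterations are run (convergence tolerance 1e-6 on stress)
and the least-stress configuration is kept.

DBSCAN runs on the embedding coordinates by default (a distance-matrix
mode is available); minPts defaults to max(5, 1% of n); eps comes from
the elbow (maximum second difference) of the sorted k-distance curve.
For discrete sequence data the raw elbow rule is unreliable — the curve
has a duplicate-stack floor at the start and an outlier tail at the end,
both with spuriously large curvature — so the landscape builder
restricts the curvature search to the 25th–95th percentile of a lightly
smoothed curve. The plain rule remains the default of the standalone
`knee_eps` and behaves as expected on continuous geometries (two blobs,
uniform grids).

## Enrichment statistics

The positional test for residue r at position p between groups A and B
is the exact two-sided Fisher test on [[#A with r, #A without r],
[#B with r, #B without r]], computed by full hypergeometric enumeration:
the p-value sums the probabilities of all tables no more likely than the
observed one, with a relative tie tolerance of 1e-9 (for the table sizes
in scope, distinct probabilities share a common denominator and differ
by far more, so the tolerance only absorbs floating-point noise in exact
ties; an exact rational oracle pins the implementation to 1e-12 in the
tests). Bonferroni correction is ×20 residues. Odds ratios use a Haldane
0.5 correction when a margin cell is zero — display only, never in the
p-value. When the landscape used entropy weighting, anchor positions
(default P2 and PΩ) are excluded from positional testing, since they
dominate the clustering by construction; the anchor set is configurable.

Cluster-level class imbalance uses Pearson's χ² (df = 1, no continuity
correction by default; a Yates flag exists) on in-cluster vs out-of-
cluster × sensitive vs dependent, Bonferroni-corrected by the number of
clusters. Whether a goodness-of-fit across all clusters simultaneously
would be preferable is an open choice; the 2×2 per-cluster form is
implemented because it gives a per-cluster effect direction.

GRAVY is the mean Kyte–Doolittle hydropathy over residues (the published
scale is embedded as a constant, injectable). Group comparisons use
Kruskal–Wallis plus Dunn's post-hoc z from pooled mid-ranks with tie
correction, Bonferroni over all pairs.

## Synthetic data: what it emulates, what it does not

The generator draws peptides position-independently from per-allele
positional weight vectors (anchors concentrated, non-anchors
near-uniform), then plants effect classes gated on sequence predicates
(defaults: sensitive requires P1 ∈ {A,K,R}, dependent requires
P2 ∈ {F,Y} — the composition effects an N-terminal trimming enzyme
produces), assigns true log2(KO/WT) of +δ / −δ / 0, and emits per-record
intensities heavy = 1e6·lognormal(sd 1), light = heavy·2^(truth + ε)
with ε ~ N(0, noise_sd). A fraction of records receives one random
disqualifying flag; `NoQuanValues` also blanks the light channel, so the
filter stage is genuinely exercised. Class counts are floor(frac·n) per
class, remainder unaffected; deficits of rule-eligible sequences raise a
named error rather than silently re-balancing.

Defaults are fixed at the simulated study conditions: 9-mers, 2
replicates, noise_sd 0.4, δ = 1.5 (with 2.45 as the large-effect
anchor), 10% sensitive + 10% dependent, 5% flagged records. The
Gaussian log-ratio noise model is an assumption — the noise law of real
SILAC ratio measurements is not specified by any quantity we reproduce —
as is position independence within a peptide. The generator does not
simulate MS spectra, retention time, search-engine scoring, identity
errors, intensity-dependent variance, shared-peptide protein inference,
or correlated replicates; passing tests therefore demonstrate the
statistics are correctly calibrated *given* exchangeable Gaussian ratio
noise, not that real data satisfy those assumptions.

The planted-submotif set for landscape validation (150 P2-F/Y + 150
P7-L + 200 background 9-mers of one PΩ-Y allele) gives the base motif
concentrated preferences at the planted positions (acidic P2, small P7)
and leaves other positions near-uniform. A variant with secondary
preferences at every position was evaluated and rejected: under entropy
weighting it inflates within-group spread without adding between-group
contrast, destroying separability — the minimal design is the one whose
geometry matches what the method is built to resolve.

## Pipeline determinism

A single master seed determines every stochastic stage: child seeds are
SHA-256 hashes of (master seed, stage name), so stages are decoupled —
changing the Gibbs stage cannot silently shift the landscape stage's
stream. Stage intermediates are plain TSV/JSON; re-running the pipeline
with the same seed produces a byte-identical summary (tested). Timings
go to the log, never into the summary.

## Known limitations

- The percentile binding score is a rank statistic against a sampled
  background; it saturates at 1 − 1/20000 and cannot discriminate
  between two peptides that both beat the entire reference population.
- NMDS stress around 0.15–0.2 is typical for discrete sequence data in
  2-D; the embedding is a visualization and clustering substrate, not a
  faithful metric map, which is why a distance-matrix DBSCAN mode
  exists.
- The Gibbs objective compares cluster numbers via the λ-penalized
  likelihood; it has no Bayesian Occam term, so λ = 0 removes the only
  guard against redundant clusters.
- Fisher enumeration is exact but O(min(margins)) per table; for tables
  with margins in the tens of thousands a normal approximation would be
  preferable (not implemented; out of scope at current data sizes).
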