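# Methods

## The model

RNA degradation removes reads non-uniformly along a transcript —
typically from the 5′ end under poly(A)+ protocols — and does so to a
different extent in every gene and every sample. Global normalizations
(total-count, upper-quartile, TMM) apply one factor per sample and
cannot correct a bias that varies per gene.

`degnorm` works on per-gene read **coverage curves** over the *total
transcript*: the concatenation of a gene's merged exons, positions
`x = 1..L`. For gene *i*, let `F` be the `p × L` matrix whose row *j* is
the coverage curve of sample *j*. The model assumes a gene-specific
envelope shape `E(x)` shared by all samples, scaled per sample by `K[j]`
(the confounded product of sequencing depth and abundance), with
degradation only ever *removing* coverage:

```
minimize   Q(K, E) = Σ_{j,x} (K[j]·E[x] − F[j,x])²
subject to K[j]·E[x] ≥ F[j,x],  K ≥ 0,  E ≥ 0          (rank-one NMF-OA)
```

The per-sample **degradation index** is the fitted area fraction lost:

```
ρ[j] = 1 − Σ_x F[j,x] / Σ_x K[j]·E[x]   ∈ [0, 1)
```

ρ is *relative* by construction: a gene degraded identically in every
sample has consistent curves, fits tightly, and gets ρ ≈ 0 — in that
case the raw counts already reflect relative abundance and no correction
is needed (or possible).

Counts are corrected by extrapolation, `X̃ = X / (1 − ρ)`, and depth
factors are recomputed from the corrected totals,
`s[j] = Σ_i X̃[i,j] / median_j Σ_i X̃[i,j]`, so degradation no longer
leaks into the depth estimate.

## The solver

For fixed `K`, the constrained optimum in `E` has closed form: the
constraint forces `E[x] ≥ max_j F[j,x]/K[j]`, and the unconstrained
least-squares value `Σ_j K[j]F[j,x] / Σ_j K[j]²` provably never exceeds
that bound (each `F[j,x] ≤ K[j]·maxratio`), so the minimizer is exactly
the **max-ratio envelope**. Symmetrically, for fixed `E` the optimal
scales are `K[j] = max_x F[j,x]/E[x]`. The solver alternates these two
exact block updates — loss monotone non-increasing, every iterate
feasible — until the relative loss change drops below `tol` (default
1e−5, at most 100 sweeps).

Block coordinate descent can stall at fixed points where the scales are
jointly unbalanced (on small adversarial matrices the stall can cost
several times the optimal loss). A **polish** step therefore runs
normalized-subgradient descent with an Armijo line search on
`q(K) = Q(K, maxratio(K))` in log-scale space (q is scale-invariant),
followed by a short re-alternation. Against a heavy multistart
Nelder-Mead/L-BFGS reference the polished solution matches the
constrained optimum to numerical precision on random small matrices and
on full-size gene matrices. An earlier scheme that alternated a
rank-one SVD of a lifted working matrix `G = max(F, K·Eᵀ)` with the lift
itself was abandoned: once the iterate becomes feasible, `G` equals
`K·Eᵀ` and the alternation freezes wherever it happens to be, which
inflated DI scores severely.

Identifiability: `(K, E)` is scale-ambiguous, fixed by `‖E‖₂ = √L` so
the envelope has unit mean square and `K` stays on the coverage scale.

## Baseline-bin refinement

A heavily degraded sample would otherwise drag the envelope down and
hide its own degradation. Each gene is divided into 20 equal-width bins
(the last absorbs the remainder; genes shorter than 20 bp use one
position per bin). Iteratively: fit NMF-OA on the retained bins, compute
the normalized residuals `(K·Eᵀ − F) / max(F, 1)` — identical to the
plain relative residual `R/F` wherever at least one read was observed,
finite where none was. The floor matters at the extremes: scoring `F = 0`
cells as zero would make a completely dead region look pristine (and end
up selected as baseline under severe degradation), while dividing by
sub-read coverage would let shot noise in naturally sparse tails
dominate the ranking; flooring the denominator at one read penalizes a
cell in proportion to the coverage the fit expects there. Drop the
single bin with the largest sum of squares (ties to the lowest index),
and refit — stopping when the maximum retained-region DI
is ≤ 0.1 or when `floor(0.8 × 20) = 16` bins have been dropped. The
scales `K*` from the final retained ("baseline") region are kept, the
full-length envelope is rebuilt as `E(x) = max_j F[j,x]/K*[j]`, and ρ is
computed on the full-length curves. Intermediate drop-loop fits exist
only to rank bins, so they use the fast alternation without polish; the
final `K*` fit is polished. Consecutive refits warm-start from the
previous scales; a warm start is rejected if it would give a
zero scale to a sample that still has signal.

## The outer loop

1. From the current per-gene fits compute ρ (clamped at `rho_max = 0.9`
   before extrapolation; the raw values are also reported), `X̃`, and `s`.
2. Rescale the raw coverage curves by `1/s[j]` and re-run the
   baseline-refined fit per gene (warm-started; baseline bins are
   recomputed every iteration).

Iteration 0 takes `s` from raw totals with ρ = 0. The loop stops when
`max_j |Δs_j| < 1e−3` and `median |Δρ| < 1e−3`, or after 5 outer
iterations (a warning flags non-convergence; in practice settings I–IV
converge in 2–3). The coverage rescaling is always applied to the *raw*
curves with the current `s` — re-dividing the running curves would
diverge whenever `s` converges to anything other than one. Samples with
zero coverage for an active gene are excluded from that gene's fit and
get ρ = 0 (nothing to extrapolate). Genes failing the expression filter
(any sample count < 1 or max per-base coverage < 5, both configurable)
are inactive: ρ = 0, counts pass through.

Adjusted counts stay real-valued internally; the DE export rounds
half-to-even. An upper-quartile variant of the depth factor is available
for outlier-heavy data.

## Synthetic data

The generator reproduces a two-condition bulk RNA-seq design:

* **Latent counts** — per gene, a (mean, dispersion) pair from a pool:
  log₁₀ mean ~ Normal(2.2, 0.8) truncated to [0.5, 4.5]; dispersion
  follows the canonical decreasing trend `φ = 0.1 + 2/μ` with
  Lognormal(0, 0.25) jitter. The pool stands in for values fitted to a
  reference dataset and is user-replaceable. 5% of genes are up- and 5%
  down-regulated with fold `1.5 + γ`, `γ ~ Exp(mean 1)`. Gene means are
  scaled so each sample's expected total matches a depth drawn uniformly
  from 40–60 million reads (scaled proportionally with gene count at
  desk scale: 4–6 million for 2,000 genes, which preserves per-gene
  coverage).
* **Gene structure** — lengths lognormal with median 1,500 bp, log-sd
  0.6, truncated to [300, 15,000]; read length 100. One read per count
  unit.
* **Read starts** — per gene a 2–4 component Gaussian mixture (means
  uniform on [0.1L, 0.9L], sds on [0.05L, 0.3L], Dirichlet(1) weights),
  truncated to the valid start range and shared across samples, so
  undegraded shapes are consistent within a gene.
* **Degradation** — a read starting at scaled position `u = start/L`
  survives with probability `CDF_Lognormal(u; μ, σ=0.4)`: removal is
  near-certain at the 5′ end and the survival ramp reaches ≈ 1 before
  mid-transcript (removal < 1% beyond u = 0.75), confining degradation
  to the 5′ side so degraded and intact curves re-join on the 3′
  baseline region. The base μ is calibrated numerically so the expected
  removed fraction under a uniform start distribution is 0.30. Per-gene
  severity is parameterized directly as that expected removed fraction —
  Normal(0.30, 0.15) truncated to [0.02, 0.85], with μ derived per gene —
  so the severity distribution is independent of the ramp sharpness;
  realized removal varies further with each gene's start mixture
  (5′-heavy genes lose more). Settings: **I** no degradation; **II** 80%
  of genes, 3–5 of the 8 samples each; **III** 80% of genes, all samples
  of one randomly chosen condition (confounded design); **IV** 80% of
  genes, two control samples at the base severity plus a systematic
  per-sample gradient (removal offsets linspace(−0.15, 0.15)) across all
  treatment samples.

All randomness flows from the single config seed; identical configs give
byte-identical outputs. What the generator does **not** emulate:
sequencing error, positional GC/hexamer bias, isoform switching, 3′-end
protocols, mate-pair structure. Passing tests on it demonstrate the
estimator's behavior under the stated model, not performance on any
particular real dataset.

## DE testing and evaluation

The DE engine is a self-contained two-group NB exact test: counts are
depth-equalized with the supplied factors (scaled to geometric mean one)
and rounded; dispersions maximize the exact conditional likelihood given
group totals on a 60-point log grid — a common value plus tagwise
values shrunk by weighted likelihood (prior weight 10); each gene is
tested by the conditional distribution of one group's total given the
overall total, doubling the smaller tail. Totals above 20,000 use a
continuity-corrected normal limit of the same conditional law.
Calibration is verified against Uniform(0,1) on null data and against an
exact binomial oracle in the Poisson limit.

Metrics: p-value ECDFs; CV-vs-expression curves (per-gene sd/mean across
samples against min–max-scaled log mean, lowess-smoothed, frac 0.3);
sensitivity at a fixed empirical FPR (rank-based threshold, the FPR
quantile of the null p-values, linearly interpolated); ROC AUC
(Mann-Whitney form); Storey q-values (π₀ from a smoothing spline over
the λ grid 0.05..0.95; with π₀ = 1 the q-values reduce exactly to
Benjamini–Hochberg).

## Numerical and design notes

* Coordinates: 0-based half-open genomic; 1-based inclusive transcript.
  Coverage is strand-agnostic by default (`stranded=same|opposite`
  restricts); minus-strand transcript coordinates run in genomic order —
  the factorization is orientation-invariant, so the flag matters only
  for reporting.
* Paired-end fragments union their mates' aligned bases (CIGAR M/=/X/D
  cover; N does not); a fragment with one unmapped mate counts through
  the mapped mate. Reads hitting several overlapping genes count for
  each.
* The DI clamp `rho_max = 0.9` bounds the variance of `1/(1 − ρ)`;
  raw ρ is always reported alongside.
* Scale equivariance (rescaling one sample's curve rescales only its
  `K`) holds exactly on rank-one input but only approximately under
  noise: the quadratic loss weights a larger-magnitude row more, which
  is precisely why the outer loop depth-normalizes curves before
  fitting.
* Desk-scale benchmark sizes (2,000 genes, 5 replicates, 4–6M reads)
  keep per-gene coverage identical to the full-scale design while the
  whole study runs on a laptop-class machine.

## Known limitations

* The DI estimate carries a positive bias that grows as per-gene
  coverage falls (the max-ratio envelope sits on the upper edge of the
  sampling noise). At the default desk-scale depth the per-sample median
  DI under a no-degradation design is ≈ 0.15; the bias is largely
  shared across samples within a gene and mostly cancels in DE.
* The same noise floor (DI sd ≈ 0.1 per cell at ~2,500 reads/gene)
  limits per-cell agreement between estimated DI and the planted
  removed fraction (Pearson r ≈ 0.79 at mean coverage ≥ 10, ≈ 0.92 at
  ≥ 50, setting II); uniform (position-independent) degradation
  components are invisible by design, since the baseline region
  absorbs them into `K*`.
* Degradation confounded with a large true abundance change in the same
  gene cannot be fully separated; the envelope is estimated per gene
  with no information sharing across genes.
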