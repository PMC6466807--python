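# degnorm

Gene- and sample-specific normalization of RNA-seq transcript
degradation.

RNA degradation removes reads non-uniformly along transcripts (typically
from the 5′ end) and to a different extent in every gene of every
sample. Global normalizations — total-count, upper-quartile, TMM —
apply a single factor per sample and cannot remove a bias that varies
per gene; when degradation is confounded with the biological condition
they leave it in place entirely. `degnorm` estimates the bias from the
read **coverage curves** themselves and corrects the counts, for anyone
running bulk RNA-seq differential expression on samples of uneven RNA
quality (clinical tissue, FFPE, long-stored material).

## The model

For gene *i* with total-transcript length `L` (concatenated merged
exons) and coverage curves `F ∈ ℝ^{p×L}` across `p` samples, a shared
envelope shape `E(x)` scaled per sample by `K[j]` is fitted under the
constraint that degradation only removes coverage — a rank-one
non-negative matrix factorization with over-approximation (NMF-OA):

```
min Q(K,E) = Σ_{j,x} (K[j]E[x] − F[j,x])²   s.t.  K[j]E[x] ≥ F[j,x], K, E ≥ 0
```

The **degradation index** of sample *j* is the fitted area fraction
lost, `ρ[j] = 1 − Σ_x F[j,x] / Σ_x K[j]E[x] ∈ [0, 1)`; counts are
corrected by extrapolation `X̃ = X/(1−ρ)` and sequencing-depth factors
are recomputed from the corrected totals
(`s_j = Σ_i X̃_ij / median_j Σ_i X̃_ij`). Scale estimation is refined on a
per-gene "baseline" region found by progressively dropping the 20
coverage bins with the worst normalized residuals, and the whole
procedure alternates degradation estimation and depth normalization
until both stabilize. See `docs/methods.md` for the solver, the
refinement rules and the simulation model.

## Worked example

Simulate a condition-confounded degradation study (80% of genes
degraded in all samples of one random condition), normalize it, and
compare differential-expression sensitivity against plain upper-quartile
normalization:

```python
import numpy as np
from degnorm import SimulationConfig, simulate_dataset, run_degnorm
from degnorm.evaluation import nb_exact_test, sensitivity_at_fpr
from degnorm.pipeline import upper_quartile_factors

cfg = SimulationConfig(n_genes=600, depth_range=(1.2e6, 1.8e6), setting="III", seed=7)
ds = simulate_dataset(cfg)
res = run_degnorm(ds.coverage, ds.observed_counts)

print("depth factors:", np.round(res.s, 3))
deg = ds.degraded_mask.any(axis=1)
print("median DI, degraded genes:   %.3f" % np.median(res.rho_raw[deg & res.active]))
print("median DI, undegraded genes: %.3f" % np.median(res.rho_raw[~deg & res.active]))

positives = ds.de_labels != "null"
adj = res.rounded_counts()
de_dn = nb_exact_test(adj, cfg.groups, upper_quartile_factors(adj))
de_uq = nb_exact_test(ds.observed_counts, cfg.groups,
                      upper_quartile_factors(ds.observed_counts))
print("TPR at FPR 0.05  degnorm: %.2f   upper-quartile: %.2f"
      % (sensitivity_at_fpr(de_dn.p_values, positives),
         sensitivity_at_fpr(de_uq.p_values, positives)))
```

prints

```
depth factors: [1.016 1.055 0.998 0.751 0.816 1.018 1.002 0.819]
median DI, degraded genes:   0.235
median DI, undegraded genes: 0.171
TPR at FPR 0.05  degnorm: 0.68   upper-quartile: 0.43
```

Degraded genes separate from undegraded ones in DI (0.235 vs 0.171 —
the undegraded level is the estimator's positive bias at this coverage,
shared across samples and largely cancelling in DE), and sensitivity at
a fixed empirical false-positive rate improves substantially over the
global normalization, which cannot see a bias confounded with the
condition.

## Command line

```sh
degnorm coverage --bam a.bam --bam b.bam --gtf ann.gtf --out covdir   # BAM+GTF -> curves
degnorm simulate --config sim.yaml --out simdir                       # synthetic study
degnorm run --coverage simdir --out rundir                            # DI + adjusted counts
degnorm evaluate --counts rundir/adjusted_counts.tsv \
    --truth simdir/truth.tsv --groups simdir/design.tsv --out evaldir
```

`run` writes `di_scores.tsv`, `adjusted_counts.tsv` (rounded),
`adjusted_counts_raw.tsv`, `depth_factors.tsv` and `run_log.json`;
`evaluate` writes per-gene DE results, ECDF/ROC/CV tables and a
`summary.json`.

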