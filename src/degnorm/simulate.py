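"""Synthetic RNA-seq generator with planted degradation.

Latent (pre-degradation) counts are negative-binomial with a canonical
mean-dispersion trend; 5% of genes are up- and 5% down-regulated in the
treatment condition with fold factor (1.5 + gamma), gamma ~ Exp(mean 1).
Read start positions follow a per-gene Gaussian mixture covering the
whole transcript (shared across samples, so undegraded coverage shapes
are consistent).  Degradation removes each read of a selected
gene-sample cell independently with probability
``1 - CDF_lognormal(start / L)``: removal is near-certain at the 5' end
and decays toward the 3' end.

Degradation designs:

* ``I``   — no degradation (depth variation only);
* ``II``  — 80% of genes degraded; per degraded gene 3, 4 or 5 of the 8
  samples are thinned, severity random per gene, same distribution;
* ``III`` — 80% of genes degraded; per degraded gene *all* samples of one
  randomly chosen condition are thinned (degradation confounded with
  condition);
* ``IV``  — 80% of genes degraded; two random control samples are thinned
  with the base expected severity while every treatment sample carries a
  sample-specific systematic severity offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats

from degnorm.coverage import CoverageMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_latent_counts",
    "sample_read_starts",
    "coverage_from_starts",
    "apply_degradation",
    "calibrate_lognormal_mu",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    """Study-design parameters of the generator.

    Defaults are the full-scale two-condition design: 20,000 genes,
    4 control vs 4 treatment samples, 40-60 million reads each, 5% up-
    and 5% down-regulated genes.  ``depth_range`` scales down
    proportionally with ``n_genes`` for desk-scale runs.
    """

    n_genes: int = 20000
    n_control: int = 4
    n_treatment: int = 4
    depth_range: tuple[float, float] = (40e6, 60e6)
    frac_up: float = 0.05
    frac_down: float = 0.05
    read_length: int = 100
    # gene lengths: lognormal, median 1500 bp, truncated
    gene_length_log_median: float = math.log(1500.0)
    gene_length_log_sd: float = 0.6
    gene_length_range: tuple[int, int] = (300, 15000)
    # NB parameter pool: log10-mean normal(2.2, 0.8) truncated; dispersion
    # follows the decreasing trend 0.1 + 2/mu with lognormal jitter
    nb_log10_mean: tuple[float, float] = (2.2, 0.8)
    nb_log10_mean_range: tuple[float, float] = (0.5, 4.5)
    nb_disp_trend: tuple[float, float] = (0.1, 2.0)
    nb_disp_jitter_sd: float = 0.25
    # read-start Gaussian mixtures
    mix_components: tuple[int, int] = (2, 4)
    mix_mean_range: tuple[float, float] = (0.1, 0.9)   # fraction of L
    mix_sd_range: tuple[float, float] = (0.05, 0.3)    # fraction of L
    # degradation
    setting: str = "I"
    frac_genes_degraded: float = 0.8
    # sigma = 0.4 confines removal to the 5' side: survival reaches ~1
    # before mid-transcript, so degraded and intact curves re-join on the
    # 3' (baseline) region instead of staying offset end to end
    deg_sigma: float = 0.4
    # per-gene severity is parameterized directly as the expected removed
    # fraction; the lognormal mu is derived from it, so the severity
    # distribution does not depend on the ramp sharpness
    deg_mean_removal: float = 0.3
    deg_removal_sd: float = 0.15      # per-gene severity spread (II/III)
    deg_removal_range: tuple[float, float] = (0.02, 0.85)
    deg_iv_offset_range: tuple[float, float] = (-0.15, 0.15)
    seed: int = 0

    def __post_init__(self):
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must be at most 1")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth_range must be positive and ordered")
        if self.setting not in ("I", "II", "III", "IV"):
            raise ValueError(f"unknown degradation setting {self.setting!r}")
        if not (0 <= self.frac_genes_degraded <= 1):
            raise ValueError("frac_genes_degraded must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_control + self.n_treatment

    @property
    def sample_names(self) -> list[str]:
        return [f"control_{j+1}" for j in range(self.n_control)] + [
            f"treatment_{j+1}" for j in range(self.n_treatment)
        ]

    @property
    def groups(self) -> np.ndarray:
        return np.array(
            ["control"] * self.n_control + ["treatment"] * self.n_treatment
        )


@dataclass
class SimulatedDataset:
    """Everything a pipeline run and its evaluation need, plus the truth."""

    config: SimulationConfig
    gene_ids: list[str]
    gene_lengths: np.ndarray
    latent_counts: np.ndarray        # (n, p) ints
    observed_counts: np.ndarray      # (n, p) ints, <= latent
    coverage: list[CoverageMatrix]   # degraded coverage, X = observed counts
    de_labels: np.ndarray            # {"up", "down", "null"} per gene
    fold_factors: np.ndarray         # 1.0 for null genes
    true_deg_fraction: np.ndarray    # (n, p) in [0, 1)
    degraded_mask: np.ndarray        # (n, p) bool: cells selected for thinning

    @property
    def samples(self) -> list[str]:
        return self.config.sample_names

    def counts_frame(self, which: str = "observed") -> pd.DataFrame:
        m = self.observed_counts if which == "observed" else self.latent_counts
        return pd.DataFrame(m, index=self.gene_ids, columns=self.samples)

    def truth_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"de_label": self.de_labels, "fold_factor": self.fold_factors},
            index=pd.Index(self.gene_ids, name="gene_id"),
        )
        for j, s in enumerate(self.samples):
            df[f"deg_frac_{s}"] = self.true_deg_fraction[:, j]
        return df


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Inverse-CDF sampling of a truncated normal; vectorized in the bounds."""
    a = special.ndtr((lo - mean) / sd)
    b = special.ndtr((hi - mean) / sd)
    u = rng.uniform(size=size)
    return mean + sd * special.ndtri(a + u * (b - a))


def _nb_draw(rng, mean, dispersion, size=None):
    """NB draws in the (mean, dispersion) parameterization var = mu + phi mu^2."""
    mean = np.asarray(mean, dtype=np.float64)
    k = 1.0 / np.asarray(dispersion, dtype=np.float64)
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=size)


def simulate_latent_counts(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw latent NB counts, DE labels and fold factors.

    Returns ``(latent_counts, de_labels, fold_factors, nb_means, nb_disp)``.
    Gene means are scaled so each sample's expected total matches its
    drawn sequencing depth.
    """
    n, p = config.n_genes, config.n_samples
    lo, hi = config.nb_log10_mean_range
    log10_mu = _truncated_normal(rng, *config.nb_log10_mean, lo, hi, size=n)
    mu = 10.0**log10_mu
    a, b = config.nb_disp_trend
    phi = (a + b / mu) * np.exp(rng.normal(0.0, config.nb_disp_jitter_sd, size=n))

    n_up = int(np.floor(config.frac_up * n))
    n_down = int(np.floor(config.frac_down * n))
    perm = rng.permutation(n)
    labels = np.full(n, "null", dtype=object)
    labels[perm[:n_up]] = "up"
    labels[perm[n_up : n_up + n_down]] = "down"
    gamma = rng.exponential(1.0, size=n)
    fold = np.ones(n)
    de = labels != "null"
    fold[de] = 1.5 + gamma[de]

    depth = rng.uniform(*config.depth_range, size=p)
    scale = depth / mu.sum()  # expected total ~ drawn depth
    mean_mat = mu[:, None] * scale[None, :]
    tcols = np.arange(p) >= config.n_control
    up = labels == "up"
    down = labels == "down"
    mean_mat[np.ix_(up, tcols)] *= fold[up, None]
    mean_mat[np.ix_(down, tcols)] /= fold[down, None]
    counts = _nb_draw(rng, mean_mat, phi[:, None])
    return counts.astype(np.int64), labels, fold, mu, phi


def _draw_mixture(config: SimulationConfig, L: int, rng: np.random.Generator):
    """Per-gene Gaussian-mixture parameters over transcript positions."""
    k = rng.integers(config.mix_components[0], config.mix_components[1] + 1)
    means = rng.uniform(*config.mix_mean_range, size=k) * L
    sds = rng.uniform(*config.mix_sd_range, size=k) * L
    w = rng.dirichlet(np.ones(k))
    return means, sds, w


def sample_read_starts(
    n_reads: int,
    L: int,
    read_length: int,
    mixture: tuple[np.ndarray, np.ndarray, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Integer read starts in [1, L - read_length + 1] from a truncated
    Gaussian mixture (inverse-CDF component sampling)."""
    means, sds, w = mixture
    hi = L - read_length + 1
    comp = rng.choice(len(w), size=n_reads, p=w)
    x = _truncated_normal(rng, means[comp], sds[comp], 1.0, hi + 1.0, size=n_reads)
    return np.minimum(np.floor(x).astype(np.int64), hi)


def mixture_start_cdf(
    positions: np.ndarray,
    L: int,
    read_length: int,
    mixture: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> np.ndarray:
    """Exact CDF of the discretized truncated start distribution, i.e.
    P(start <= position); used for distributional self-tests."""
    means, sds, w = mixture
    hi = L - read_length + 1
    x = np.minimum(np.asarray(positions, dtype=np.float64) + 1.0, hi + 1.0)
    lo_cdf = special.ndtr((1.0 - means[:, None]) / sds[:, None])
    hi_cdf = special.ndtr((hi + 1.0 - means[:, None]) / sds[:, None])
    val = special.ndtr((x[None, :] - means[:, None]) / sds[:, None])
    comp = (val - lo_cdf) / (hi_cdf - lo_cdf)
    return np.clip(w @ comp, 0.0, 1.0)


def coverage_from_starts(starts: np.ndarray, L: int, read_length: int) -> np.ndarray:
    """Per-base coverage from fixed-length reads at the given starts."""
    diff = np.zeros(L + 1, dtype=np.int64)
    np.add.at(diff, starts - 1, 1)
    np.add.at(diff, starts - 1 + read_length, -1)
    return np.cumsum(diff[:-1]).astype(np.float64)


def calibrate_lognormal_mu(mean_removal: float, sigma: float) -> float:
    """Base lognormal log-scale mu such that the expected removed fraction
    of reads with starts uniform over the transcript equals ``mean_removal``.

    Removal probability of a read starting at scaled position u in (0, 1]
    is 1 - CDF_lognormal(u; mu, sigma); larger mu shifts the survival ramp
    toward the 3' end and removes more.
    """
    if not (0 < mean_removal < 1):
        raise ValueError("mean_removal must be in (0, 1)")

    def expected_removal(mu):
        f = lambda u: 1.0 - stats.lognorm.cdf(u, s=sigma, scale=math.exp(mu))  # noqa: E731
        val, _ = integrate.quad(f, 0.0, 1.0, limit=200)
        return val

    return optimize.brentq(
        lambda m: expected_removal(m) - mean_removal, -15.0, 8.0, xtol=1e-10
    )


def apply_degradation(
    starts: np.ndarray,
    L: int,
    mu: float,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean keep-mask: each read survives with probability
    CDF_lognormal(start / L; mu, sigma) (5'-anchored thinning)."""
    u = np.asarray(starts, dtype=np.float64) / L
    survive = stats.lognorm.cdf(u, s=sigma, scale=math.exp(mu))
    return rng.uniform(size=len(u)) < survive


def _mu_of_removal(config: SimulationConfig):
    """Interpolator mapping a target expected removed fraction to the
    lognormal mu that achieves it at the configured sigma."""
    grid = np.linspace(0.01, 0.9, 60)
    mus = np.array([calibrate_lognormal_mu(r, config.deg_sigma) for r in grid])

    def f(removal):
        return np.interp(np.asarray(removal, dtype=float), grid, mus)

    return f


def _degradation_plan(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Which (gene, sample) cells are thinned and with which lognormal mu."""
    n, p = config.n_genes, config.n_samples
    mask = np.zeros((n, p), dtype=bool)
    mu = np.full((n, p), -np.inf)
    if config.setting == "I":
        return mask, mu
    mu_of = _mu_of_removal(config)
    lo, hi = config.deg_removal_range

    def gene_severity():
        return float(
            np.clip(rng.normal(config.deg_mean_removal, config.deg_removal_sd), lo, hi)
        )

    deg_genes = rng.permutation(n)[: int(round(config.frac_genes_degraded * n))]
    if config.setting == "II":
        for i in deg_genes:
            k = min(int(rng.integers(3, 6)), p)  # 3, 4 or 5 of the samples
            cols = rng.choice(p, size=k, replace=False)
            mask[i, cols] = True
            mu[i, cols] = mu_of(gene_severity())
    elif config.setting == "III":
        for i in deg_genes:
            if rng.uniform() < 0.5:
                cols = np.arange(config.n_control)
            else:
                cols = np.arange(config.n_control, p)
            mask[i, cols] = True
            mu[i, cols] = mu_of(gene_severity())
    elif config.setting == "IV":
        offsets = np.linspace(*config.deg_iv_offset_range, config.n_treatment)
        base = config.deg_mean_removal
        for i in deg_genes:
            cols = rng.choice(config.n_control, size=2, replace=False)
            mask[i, cols] = True
            mu[i, cols] = mu_of(base)
            t = np.arange(config.n_control, p)
            mask[i, t] = True
            mu[i, t] = mu_of(np.clip(base + offsets, lo, hi))
    return mask, mu


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full dataset: latent counts, degraded coverage curves,
    observed counts and the planted truth.  Byte-identical under a fixed
    config (including its seed)."""
    rng = np.random.default_rng(config.seed)
    latent, labels, fold, _, _ = simulate_latent_counts(config, rng)
    n, p = latent.shape
    r = config.read_length
    lo_len, hi_len = config.gene_length_range
    lengths = np.round(
        np.exp(
            _truncated_normal(
                rng,
                config.gene_length_log_median,
                config.gene_length_log_sd,
                math.log(lo_len),
                math.log(hi_len),
                size=n,
            )
        )
    ).astype(np.int64)
    deg_mask, deg_mu = _degradation_plan(config, rng)

    gene_ids = [f"gene_{i+1:05d}" for i in range(n)]
    observed = np.zeros_like(latent)
    deg_frac = np.zeros((n, p))
    coverages = []
    samples = config.sample_names
    for i in range(n):
        L = int(lengths[i])
        mixture = _draw_mixture(config, L, rng)
        counts_i = latent[i]
        total = int(counts_i.sum())
        if total == 0:
            F = np.zeros((p, L))
        else:
            # one draw for all samples of the gene (shared start mixture)
            starts = sample_read_starts(total, L, r, mixture, rng)
            sample_of = np.repeat(np.arange(p), counts_i)
            if deg_mask[i].any():
                keep = np.ones(total, dtype=bool)
                cell_mu = np.where(deg_mask[i], deg_mu[i], 0.0)
                scale = np.exp(cell_mu)[sample_of]
                survive = stats.lognorm.cdf(
                    starts / L, s=config.deg_sigma, scale=scale
                )
                thinned = deg_mask[i][sample_of]
                u = rng.uniform(size=total)
                keep = ~thinned | (u < survive)
                starts = starts[keep]
                sample_of = sample_of[keep]
            # stack fixed-length reads per sample in one pass
            diff = np.zeros(p * (L + 1), dtype=np.int64)
            base = sample_of * (L + 1)
            np.add.at(diff, base + starts - 1, 1)
            np.add.at(diff, base + starts - 1 + r, -1)
            F = np.cumsum(diff.reshape(p, L + 1), axis=1)[:, :L].astype(np.float64)
            observed[i] = np.bincount(sample_of, minlength=p)
        pos = counts_i > 0
        deg_frac[i, pos] = 1.0 - observed[i, pos] / counts_i[pos]
        X = observed[i]
        active = bool((X >= 1).all() and F.max() >= 5.0)
        coverages.append(
            CoverageMatrix(gene_ids[i], samples, F, X.copy(), active=active)
        )
    return SimulatedDataset(
        config=config,
        gene_ids=gene_ids,
        gene_lengths=lengths,
        latent_counts=latent,
        observed_counts=observed,
        coverage=coverages,
        de_labels=np.asarray(labels, dtype=object),
        fold_factors=fold,
        true_deg_fraction=deg_frac,
        degraded_mask=deg_mask,
    )
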