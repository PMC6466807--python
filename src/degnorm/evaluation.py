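"""Differential-expression testing and normalization-quality metrics.

The DE engine is a self-contained two-group negative-binomial exact test
in the spirit of the classic qCML approach: counts are equalized to a
common depth with the supplied normalization factors, dispersions are
estimated by maximizing the conditional (given the group totals)
log-likelihood — a common value across genes plus tagwise estimates
shrunk toward it by weighted likelihood — and each gene is tested by the
exact conditional distribution of one group's total given the overall
total, doubling the smaller tail.

The remaining operations score normalization quality the way simulation
benchmarks usually do: p-value ECDFs, coefficient-of-variation curves
over the expression range, sensitivity at a fixed empirical
false-positive rate, ROC AUC and Storey q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "DEResult",
    "nb_exact_test",
    "pvalue_ecdf",
    "cv_curve",
    "sensitivity_at_fpr",
    "roc_auc",
    "storey_qvalues",
]


@dataclass
class DEResult:
    genes: list
    p_values: np.ndarray
    log2_fold_change: np.ndarray
    q_values: np.ndarray
    dispersion: np.ndarray
    method: str = "nb_exact"

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p_value": self.p_values,
                "log2_fold_change": self.log2_fold_change,
                "q_value": self.q_values,
                "dispersion": self.dispersion,
            },
            index=pd.Index(self.genes, name="gene_id"),
        )


def _conditional_loglik(y: np.ndarray, groups_idx: list[np.ndarray], k: float) -> np.ndarray:
    """Per-gene conditional log-likelihood of dispersion 1/k given the
    group totals (equal library sizes assumed)."""
    ll = np.zeros(y.shape[0])
    for idx in groups_idx:
        yg = y[:, idx]
        ng = len(idx)
        z = yg.sum(axis=1)
        ll += (
            special.gammaln(yg + k).sum(axis=1)
            + special.gammaln(ng * k)
            - special.gammaln(z + ng * k)
            - ng * special.gammaln(k)
        )
    return ll


def _estimate_dispersions(
    y: np.ndarray, groups_idx: list[np.ndarray], prior_weight: float = 10.0
) -> tuple[np.ndarray, float]:
    """Tagwise dispersions via weighted conditional likelihood on a grid,
    shrunk toward the common maximizer."""
    grid = np.exp(np.linspace(np.log(1e-4), np.log(5.0), 60))
    ll = np.stack([_conditional_loglik(y, groups_idx, 1.0 / phi) for phi in grid], axis=1)
    common_curve = ll.mean(axis=0)
    phi_common = float(grid[np.argmax(common_curve)])
    wl = ll + prior_weight * common_curve[None, :]
    phi_tag = grid[np.argmax(wl, axis=1)]
    return phi_tag, phi_common


_EXACT_TOTAL_CAP = 20_000  # above this the conditional normal limit is used


def _exact_conditional_p(z_a: int, total: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact test of group-A total z_a given the overall total,
    under NB sampling with equal per-sample means; smaller tail doubled.

    For very large totals the exact enumeration is replaced by a
    continuity-corrected normal approximation of the same conditional
    distribution, which is indistinguishable at that scale.
    """
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    k = 1.0 / max(phi, 1e-8)
    size_a, size_b = n_a * k, n_b * k
    m_a = n_a * mu
    m_b = total - m_a
    v_a = m_a + m_a * m_a / size_a
    v_b = m_b + m_b * m_b / size_b
    if total > _EXACT_TOTAL_CAP:
        # conditional mean/var of S_A | S_A + S_B = total in the normal limit
        cond_m = m_a + v_a / (v_a + v_b) * (total - m_a - m_b)
        cond_v = v_a * v_b / (v_a + v_b)
        z = (abs(z_a - cond_m) - 0.5) / np.sqrt(cond_v)
        return float(min(1.0, 2.0 * special.ndtr(-max(z, 0.0))))
    sd = np.sqrt(v_a)
    lo = max(0, int(np.floor(min(z_a, m_a) - 20 * sd - 5)))
    hi = min(total, int(np.ceil(max(z_a, m_a) + 20 * sd + 5)))
    s = np.arange(lo, hi + 1)
    logp = stats.nbinom.logpmf(s, size_a, size_a / (size_a + m_a)) + stats.nbinom.logpmf(
        total - s, size_b, size_b / (size_b + (total - m_a))
    )
    logp -= special.logsumexp(logp)
    prob = np.exp(logp)
    at = z_a - lo
    if at < 0 or at > hi - lo:
        return min(1.0, 2.0 * float(prob.min()))
    p_low = float(prob[: at + 1].sum())
    p_high = float(prob[at:].sum())
    return min(1.0, 2.0 * min(p_low, p_high))


def nb_exact_test(
    counts: np.ndarray | pd.DataFrame,
    groups,
    norm_factors: np.ndarray | None = None,
    prior_weight: float = 10.0,
) -> DEResult:
    """Two-group NB exact test on depth-equalized pseudo-counts.

    Parameters
    ----------
    counts : (n, p) non-negative matrix (DataFrame keeps gene ids).
    groups : length-p two-level factor (e.g. "control"/"treatment").
    norm_factors : positive length-p factors (defaults to total-count);
        counts are divided by the factors (scaled to geometric mean one)
        and rounded, emulating equal library sizes.
    """
    if isinstance(counts, pd.DataFrame):
        genes = list(counts.index)
        X = counts.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(counts, dtype=np.float64)
        genes = list(range(X.shape[0]))
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("groups must have exactly two levels")
    idx_a = np.flatnonzero(groups == levels[0])
    idx_b = np.flatnonzero(groups == levels[1])
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("need at least 2 samples per group")
    if norm_factors is None:
        tot = X.sum(axis=0)
        if (tot <= 0).any():
            raise ValueError("a sample has all-zero counts")
        norm_factors = tot / np.exp(np.mean(np.log(tot)))
    norm_factors = np.asarray(norm_factors, dtype=np.float64)
    if (norm_factors <= 0).any():
        raise ValueError("normalization factors must be positive")
    r = norm_factors / np.exp(np.mean(np.log(norm_factors)))
    y = np.rint(X / r[None, :]).astype(np.int64)
    if y[:, idx_a].sum() == 0 or y[:, idx_b].sum() == 0:
        raise ValueError("one group has zero counts for every gene")

    phi_tag, _ = _estimate_dispersions(y, [idx_a, idx_b], prior_weight=prior_weight)
    n_a, n_b = len(idx_a), len(idx_b)
    pvals = np.ones(y.shape[0])
    for i in range(y.shape[0]):
        z_a = int(y[i, idx_a].sum())
        tot = int(y[i].sum())
        pvals[i] = _exact_conditional_p(z_a, tot, n_a, n_b, phi_tag[i])
    mean_a = y[:, idx_a].mean(axis=1)
    mean_b = y[:, idx_b].mean(axis=1)
    lfc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    q = storey_qvalues(pvals)
    return DEResult(
        genes=genes,
        p_values=pvals,
        log2_fold_change=lfc,
        q_values=q,
        dispersion=phi_tag,
    )


def pvalue_ecdf(p_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of p-values: sorted grid and cumulative fractions."""
    p = np.sort(np.asarray(p_values, dtype=np.float64))
    if p.size == 0:
        raise ValueError("empty p-value vector")
    frac = np.arange(1, p.size + 1) / p.size
    return p, frac


def cv_curve(
    norm_counts: np.ndarray,
    subset: np.ndarray | None = None,
    frac: float = 0.3,
    grid_size: int = 100,
) -> pd.DataFrame:
    """Coefficient of variation vs scaled log-mean expression.

    Per-gene CV = sd/mean across samples; the x-axis is the log mean
    linearly rescaled to the 0-1 range.  Returns the per-gene points plus
    a lowess-smoothed curve evaluated on an even grid (columns ``x``,
    ``cv``, ``x_grid``, ``cv_smooth``; grid columns padded with NaN).
    Genes with zero mean are excluded.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    M = np.asarray(norm_counts, dtype=np.float64)
    if M.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if subset is not None:
        M = M[np.asarray(subset)]
    mean = M.mean(axis=1)
    keep = mean > 0
    mean = mean[keep]
    cv = M[keep].std(axis=1, ddof=1) / mean
    lx = np.log(mean)
    x = (lx - lx.min()) / (lx.max() - lx.min()) if lx.max() > lx.min() else np.zeros_like(lx)
    sm = lowess(cv, x, frac=frac, return_sorted=True)
    xg = np.linspace(0, 1, grid_size)
    cg = np.interp(xg, sm[:, 0], sm[:, 1])
    n_rows = max(x.size, grid_size)

    def _pad(v):
        out = np.full(n_rows, np.nan)
        out[: len(v)] = v
        return out

    return pd.DataFrame(
        {"x": _pad(x), "cv": _pad(cv), "x_grid": _pad(xg), "cv_smooth": _pad(cg)}
    )


def sensitivity_at_fpr(
    p_values: np.ndarray, is_positive: np.ndarray, fpr: float = 0.05
) -> float:
    """True-positive rate at the p-value threshold where the empirical
    false-positive rate among true nulls equals ``fpr`` (interpolated)."""
    p = np.asarray(p_values, dtype=np.float64)
    pos = np.asarray(is_positive, dtype=bool)
    if (~pos).sum() == 0:
        raise ValueError("no true-negative genes")
    thr = np.quantile(p[~pos], fpr, method="linear")
    return float((p[pos] <= thr).mean())


def roc_auc(p_values: np.ndarray, is_positive: np.ndarray) -> float:
    """Area under the ROC curve for score = -p (Mann-Whitney form; ties
    count one half)."""
    p = np.asarray(p_values, dtype=np.float64)
    pos = np.asarray(is_positive, dtype=bool)
    ranks = stats.rankdata(-p)
    n_pos, n_neg = pos.sum(), (~pos).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative genes")
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def storey_pi0(p_values: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's pi0 with the smoother over a lambda grid (0.05..0.95)."""
    p = np.asarray(p_values, dtype=np.float64)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
    if np.allclose(pi0_l, pi0_l[0]):
        return float(min(1.0, pi0_l[0]))
    from scipy.interpolate import UnivariateSpline

    spl = UnivariateSpline(lambdas, pi0_l, k=3, s=len(lambdas) / 2)
    pi0 = float(spl(lambdas[-1]))
    return float(min(max(pi0, 1e-8), 1.0))


def storey_qvalues(p_values: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: q_(i) = min_{j >= i} pi0 * n * p_(j) / j.

    With ``pi0`` forced to 1 this reduces exactly to Benjamini-Hochberg."""
    p = np.asarray(p_values, dtype=np.float64)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if pi0 is None:
        pi0 = storey_pi0(p)
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * n * p[order] / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
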