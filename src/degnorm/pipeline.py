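"""DegNorm outer loop: alternate degradation estimation and depth normalization.

Each outer iteration (1) computes per-sample DI scores from the current
per-gene NMF-OA fits, extrapolates adjusted counts ``X_adj = X / (1 - rho)``
and derives depth factors ``s_j`` from the adjusted column totals, then
(2) rescales the raw coverage curves by ``1/s_j`` and re-runs the
baseline-refined NMF-OA per gene.  Iteration stops when both the depth
factors and the DI scores have stabilized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from degnorm.coverage import CoverageMatrix
from degnorm.nmfoa import select_baseline

__all__ = [
    "DegNormResult",
    "adjust_counts",
    "depth_factors",
    "upper_quartile_factors",
    "run_degnorm",
]


@dataclass
class DegNormResult:
    """Output of the DegNorm pipeline.

    ``rho`` holds the DI scores actually used for count adjustment
    (clamped at ``rho_max``); ``rho_raw`` the unclamped estimates.
    ``X_adj`` keeps full-precision adjusted counts; use
    :meth:`rounded_counts` for a differential-expression export.
    """

    genes: list
    samples: list
    rho: np.ndarray            # (n, p), clamped at rho_max
    rho_raw: np.ndarray        # (n, p), as estimated
    X_adj: np.ndarray          # (n, p), real-valued
    X: np.ndarray              # (n, p), input counts
    s: np.ndarray              # (p,), final depth factors
    active: np.ndarray         # (n,) bool
    n_iter: int = 0
    converged: bool = True
    trace: list = field(default_factory=list)

    def rounded_counts(self) -> np.ndarray:
        """Adjusted counts rounded half-to-even, as integers."""
        return np.rint(self.X_adj).astype(np.int64)

    def rho_frame(self, raw: bool = False) -> pd.DataFrame:
        m = self.rho_raw if raw else self.rho
        return pd.DataFrame(m, index=self.genes, columns=self.samples)

    def counts_frame(self, rounded: bool = False) -> pd.DataFrame:
        m = self.rounded_counts() if rounded else self.X_adj
        return pd.DataFrame(m, index=self.genes, columns=self.samples)


def adjust_counts(X: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Extrapolated counts ``X / (1 - rho)`` elementwise; zeros stay zero."""
    X = np.asarray(X, dtype=np.float64)
    rho = np.asarray(rho, dtype=np.float64)
    if (rho < 0).any() or (rho >= 1).any():
        raise ValueError("DI scores must lie in [0, 1); clamp before adjusting")
    return X / (1.0 - rho)


def depth_factors(X_adj: np.ndarray, samples: list | None = None) -> np.ndarray:
    """Depth factor s_j = column total / median of column totals.

    The median over an even number of samples is the mean of the two
    middle totals, so median(s) = 1 always holds.
    """
    X_adj = np.asarray(X_adj, dtype=np.float64)
    totals = X_adj.sum(axis=0)
    if (totals <= 0).any():
        j = int(np.flatnonzero(totals <= 0)[0])
        name = samples[j] if samples is not None else f"column {j}"
        raise ValueError(f"sample {name!r} has non-positive adjusted total")
    return totals / np.median(totals)


def upper_quartile_factors(X: np.ndarray) -> np.ndarray:
    """Upper-quartile depth factors: 75th percentile of each sample's
    positive counts, scaled to median one.  A robust alternative to the
    adjusted-total median when extreme outliers are a concern."""
    X = np.asarray(X, dtype=np.float64)
    uq = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        col = col[col > 0]
        if col.size == 0:
            raise ValueError(f"sample column {j} has no positive counts")
        uq[j] = np.quantile(col, 0.75)
    return uq / np.median(uq)


def run_degnorm(
    coverages: list[CoverageMatrix],
    X: np.ndarray | pd.DataFrame | None = None,
    max_iter: int = 5,
    rho_max: float = 0.9,
    n_bins: int = 20,
    di_stop: float = 0.1,
    max_drop_frac: float = 0.8,
    nmf_max_iter: int = 100,
    nmf_tol: float = 1e-5,
    tol_s: float = 1e-3,
    tol_rho: float = 1e-3,
    depth_method: str = "adjusted_total",
    correct_degradation: bool = True,
) -> DegNormResult:
    """Run the full degradation-normalization pipeline.

    Parameters
    ----------
    coverages : list of CoverageMatrix
        One per gene; all must share the same sample ordering.  Genes
        flagged inactive pass their counts through with DI = 0.
    X : (n, p) array or DataFrame, optional
        Raw counts; defaults to the per-gene counts stored on the
        coverage objects.
    depth_method : {"adjusted_total", "upper_quartile"}
        How the per-iteration depth factors are computed from the
        adjusted counts.
    correct_degradation : bool
        If False, DI scores are forced to zero and the result reduces to
        plain depth normalization of the raw counts.
    """
    if not coverages:
        raise ValueError("no coverage matrices given")
    samples = list(coverages[0].samples)
    p = len(samples)
    for cov in coverages:
        if list(cov.samples) != samples:
            raise ValueError(f"sample ordering mismatch for gene {cov.gene_id}")
    genes = [c.gene_id for c in coverages]
    if X is None:
        X = np.stack([c.X for c in coverages]).astype(np.float64)
    elif isinstance(X, pd.DataFrame):
        X = X.loc[genes, samples].to_numpy(dtype=np.float64)
    else:
        X = np.asarray(X, dtype=np.float64)
    n = len(genes)
    if X.shape != (n, p):
        raise ValueError("counts do not match coverage gene/sample layout")
    active = np.array([c.active for c in coverages], dtype=bool)

    if depth_method == "adjusted_total":
        depth_fn = lambda M: depth_factors(M, samples)  # noqa: E731
    elif depth_method == "upper_quartile":
        depth_fn = upper_quartile_factors
    else:
        raise ValueError(f"unknown depth_method {depth_method!r}")

    s = depth_fn(X)
    rho = np.zeros((n, p))
    if not correct_degradation:
        return DegNormResult(
            genes=genes, samples=samples, rho=rho, rho_raw=rho.copy(),
            X_adj=X.copy(), X=X, s=s, active=active, n_iter=0, converged=True,
            trace=[{"iter": 0, "s": s.tolist(), "median_abs_drho": 0.0}],
        )

    warm: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    trace: list[dict] = []
    converged = False
    n_done = 0
    for t in range(1, max_iter + 1):
        s_prev = s
        rho_prev = rho
        rho = np.zeros((n, p))
        for gi in np.flatnonzero(active):
            F = coverages[gi].F / s[:, None]
            rows = F.sum(axis=1) > 0
            if rows.sum() == 0:
                continue
            fit = select_baseline(
                F[rows],
                n_bins=n_bins,
                di_stop=di_stop,
                max_drop_frac=max_drop_frac,
                max_iter=nmf_max_iter,
                tol=nmf_tol,
                init=warm.get(gi),
            )
            rho[gi, rows] = fit.rho
            warm[gi] = (fit.K, fit.E)
        rho_used = np.minimum(rho, rho_max)
        X_adj = adjust_counts(X, rho_used)
        s = depth_fn(X_adj)
        ds = float(np.abs(s - s_prev).max())
        dr = float(np.median(np.abs(rho - rho_prev)))
        trace.append({"iter": t, "s": s.tolist(), "max_abs_ds": ds,
                      "median_abs_drho": dr})
        n_done = t
        if ds < tol_s and dr < tol_rho:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"DegNorm outer loop did not converge in {max_iter} iterations "
            f"(last max|ds| = {trace[-1]['max_abs_ds']:.2e}); returning last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    rho_used = np.minimum(rho, rho_max)
    X_adj = adjust_counts(X, rho_used)
    return DegNormResult(
        genes=genes, samples=samples, rho=rho_used, rho_raw=rho, X_adj=X_adj,
        X=X, s=s, active=active, n_iter=n_done, converged=converged, trace=trace,
    )
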