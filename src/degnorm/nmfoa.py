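"""Rank-one non-negative matrix factorization with over-approximation (NMF-OA).

For one gene, let ``F`` be the p x L matrix of per-base coverage curves
(one row per sample).  We model the ideal, degradation-free curve of
sample j as ``K[j] * E``, where ``E`` is a gene-specific *envelope* shape
shared across samples and ``K[j]`` is the confounded depth-times-abundance
scale of sample j.  The factors are estimated by minimizing the quadratic
loss

    Q(K, E) = sum_{j,x} (K[j] * E[x] - F[j, x])**2

subject to the elementwise dominance constraint ``K[j]*E[x] >= F[j, x]``
with ``K, E >= 0``.  The area lost below the fitted envelope defines the
per-sample degradation index (DI)

    rho[j] = 1 - sum_x F[j, x] / sum_x K[j] * E[x]   in [0, 1).

``select_baseline`` refines the scales on a "baseline" (least-degraded)
region found by progressively dropping the coverage bins with the worst
normalized residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NMFOAFit", "fit_nmfoa", "compute_di", "select_baseline"]


@dataclass
class NMFOAFit:
    """Result of a rank-one NMF-OA fit for one gene.

    Attributes
    ----------
    K : (p,) array
        Per-sample scale factors (depth x abundance, confounded).
    E : (L,) array
        Envelope values; ``K[j] * E[x]`` dominates ``F[j, x]`` elementwise.
    rho : (p,) array or None
        Per-sample degradation index scores (filled by the refinement path).
    loss : float
        Quadratic loss Q(K, E) of the final factors on the fitted matrix.
    loss_trace : (n_iter,) array
        Loss after each over-approximation lift.
    baseline_mask : (n_bins,) bool array or None
        True for bins retained in the baseline region.
    bins_dropped : int
    n_iter : int
        Number of lift iterations of the final inner fit.
    """

    K: np.ndarray
    E: np.ndarray
    rho: np.ndarray | None
    loss: float
    loss_trace: np.ndarray = field(repr=False, default=None)
    baseline_mask: np.ndarray | None = None
    bins_dropped: int = 0
    n_iter: int = 0


def _validate(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 2:
        raise ValueError("F must be a 2-D (samples x positions) matrix")
    if not np.isfinite(F).all():
        raise ValueError("coverage matrix contains non-finite entries")
    if (F < 0).any():
        raise ValueError("coverage matrix contains negative entries")
    if not (F > 0).any():
        raise ValueError("degenerate gene: coverage matrix is identically zero")
    return F


def _envelope_given_K(F: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Optimal feasible envelope for fixed scales: E[x] = max_j F[j,x]/K[j].

    The constraint forces E[x] >= max_j F[j,x]/K[j]; the unconstrained
    least-squares value sum_j K[j] F[j,x] / sum_j K[j]^2 never exceeds that
    bound (each F[j,x] <= K[j] * max-ratio), and the quadratic loss grows
    above it, so the constrained minimizer is exactly the max-ratio.
    """
    if (K > 0).all():
        return (F / K[:, None]).max(axis=0)
    pos = K > 0
    if not pos.any():
        return np.zeros(F.shape[1])
    return (F[pos] / K[pos, None]).max(axis=0)


def _scales_given_E(F: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Optimal feasible scales for a fixed envelope: K[j] = max_x F[j,x]/E[x].

    Same boundary argument per row: the row's least-squares scale
    (F[j]·E)/(E·E) never exceeds max_x F[j,x]/E[x].  Rows that are zero
    wherever E is positive get K[j] = 0.
    """
    if (E > 0).all():
        return (F / E[None, :]).max(axis=1)
    pos = E > 0
    if not pos.any():
        return np.zeros(F.shape[0])
    return (F[:, pos] / E[pos]).max(axis=1)


def _q_and_grad(F: np.ndarray, K: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss q(K) = Q(K, max-ratio envelope of K) and its subgradient with
    respect to log K (valid wherever the per-position argmax is unique)."""
    p, L = F.shape
    R = F / K[:, None]
    jmax = R.argmax(axis=0)
    m = R[jmax, np.arange(L)]
    D = K[:, None] * m[None, :] - F  # >= 0 by construction
    q = float((D * D).sum())
    g = 2.0 * (D * m[None, :]).sum(axis=1)
    # envelope positions owned by sample j move with K[j]: dm/dK_j = -m/K_j
    w = 2.0 * (D * K[:, None]).sum(axis=0)
    g -= np.bincount(jmax, weights=w * m, minlength=p) / K
    return q, g * K  # chain rule to log-space


def _polish_scales(
    F: np.ndarray, K: np.ndarray, max_iter: int = 15, tol: float = 1e-7
) -> np.ndarray:
    """Backtracking (sub)gradient descent on q(K) in log-space.

    The block coordinate descent can stall at a fixed point where the
    scales are jointly unbalanced; this normalized-gradient polish with an
    Armijo line search moves all scales together and reliably reaches the
    optimum basin.  q is scale-invariant, so only the direction of K
    matters."""
    lk = np.log(np.maximum(K, 1e-12))
    q, g = _q_and_grad(F, np.exp(lk))
    step = 1.0
    for _ in range(max_iter):
        gn = float(np.sqrt((g * g).sum()))
        if gn <= 1e-14:
            break
        improved = False
        while step > 1e-12:
            lk2 = np.clip(lk - step * g / gn, -40.0, 40.0)
            q2, g2 = _q_and_grad(F, np.exp(lk2))
            if q2 < q - 1e-4 * step * gn:
                small = (q - q2) <= tol * max(q, 1e-300)
                lk, q, g = lk2, q2, g2
                step *= 1.7
                improved = not small
                break
            step *= 0.5
        if not improved:
            break
    return np.exp(lk)


def fit_nmfoa(
    F: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-5,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    polish: bool = True,
    validate: bool = True,
) -> NMFOAFit:
    """Fit the rank-one over-approximation ``K E^T >= F`` minimizing Q(K, E).

    Exact block coordinate descent: for fixed K the constrained optimum in
    E is the max-ratio envelope ``E[x] = max_j F[j,x]/K[j]``, and for fixed
    E the optimum in K is ``K[j] = max_x F[j,x]/E[x]`` (both closed form;
    see the helper docstrings for the boundary argument).  Each half-step
    solves its subproblem exactly, so the loss is monotone non-increasing
    and every iterate after the first half-step is feasible.  Iteration
    stops when the relative loss change falls below ``tol``.  With
    ``polish=True`` (the default) the coordinate-descent fixed point is
    then refined by a joint gradient polish of the scales (see
    ``_polish_scales``) followed by a short re-alternation; the refinement
    never increases the loss.

    The scale ambiguity (cK, E/c) is fixed by ``||E||_2 = sqrt(L)`` so the
    mean square of the envelope is one and K stays on the coverage scale.

    Rows that are entirely zero get ``K[j] = 0``; callers normally exclude
    such samples beforehand.

    Parameters
    ----------
    init : (K0, E0), optional
        Warm start (E0 is ignored; K0 seeds the alternation).  Used
        heavily by the baseline refinement, where consecutive fits differ
        by a single bin.
    """
    if validate:
        F = _validate(F)
    p, L = F.shape

    K = None
    if init is not None:
        K0 = np.asarray(init[0], dtype=np.float64)
        # a warm start must give every row with signal a positive scale,
        # else that sample stays locked out of the envelope
        if (
            K0.shape == (p,)
            and (K0 > 0).any()
            and not ((K0 <= 0) & (F > 0).any(axis=1)).any()
        ):
            K = K0.copy()
    if K is None:
        # least-squares leading pair as a scale-aware start
        K = F.sum(axis=1)
        E = F.T @ K / max(K @ K, np.finfo(float).tiny)
        K = F @ E / max(E @ E, np.finfo(float).tiny)
        K = np.maximum(K, 0.0)
        if not (K > 0).any():
            K = F.sum(axis=1)

    trace = []
    prev = np.inf
    n_iter = 0
    sum_f2 = float((F * F).sum())
    E = _envelope_given_K(F, K)
    for n_iter in range(1, max_iter + 1):
        K = _scales_given_E(F, E)
        E = _envelope_given_K(F, K)
        # Q expanded: (K.K)(E.E) - 2 K'F E + sum F^2 (avoids the outer product)
        loss = float((K @ K) * (E @ E) - 2.0 * (K @ (F @ E)) + sum_f2)
        loss = max(loss, 0.0)
        trace.append(loss)
        if abs(prev - loss) <= tol * max(prev, 1e-12):
            break
        prev = loss

    if polish and (K > 0).any():
        Kp = _polish_scales(F, K)
        for _ in range(2):
            Ep = _envelope_given_K(F, Kp)
            Kp = _scales_given_E(F, Ep)
        Ep = _envelope_given_K(F, Kp)
        loss_p = max(
            float((Kp @ Kp) * (Ep @ Ep) - 2.0 * (Kp @ (F @ Ep)) + sum_f2), 0.0
        )
        if loss_p < loss:
            K, E, loss = Kp, Ep, loss_p
            trace.append(loss)

    # identifiability: mean-square envelope = 1 (loss is scale-invariant)
    nrm = np.linalg.norm(E)
    if nrm > 0:
        c = np.sqrt(L) / nrm
        E = E * c
        K = K / c
    return NMFOAFit(
        K=K, E=E, rho=None, loss=loss, loss_trace=np.asarray(trace), n_iter=n_iter
    )


def compute_di(F: np.ndarray, K: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Degradation index rho[j] = 1 - sum_x F[j,x] / (K[j] * sum_x E[x]).

    Under the over-approximation constraint the ratio is at most one, so
    rho lies in [0, 1).  Samples with zero fitted area and zero observed
    area get rho = 0; a zero fitted area with positive observed area is an
    invariant breach and raises.
    """
    F = np.asarray(F, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    E = np.asarray(E, dtype=np.float64)
    obs = F.sum(axis=1)
    fitted = K * E.sum()
    bad = (fitted <= 0) & (obs > 0)
    if bad.any():
        raise ValueError(
            "zero envelope area with positive observed coverage for sample(s) "
            f"{np.flatnonzero(bad).tolist()}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(fitted > 0, 1.0 - obs / np.where(fitted > 0, fitted, 1.0), 0.0)
    return np.maximum(rho, 0.0)  # clip float dust below zero


def _bin_ids(L: int, n_bins: int) -> tuple[np.ndarray, int]:
    """Equal-width bin labels over positions 0..L-1; last bin absorbs the
    remainder; genes shorter than n_bins use one position per bin."""
    nb = min(n_bins, L)
    width = L // nb
    ids = np.minimum(np.arange(L) // width, nb - 1)
    return ids, nb


def select_baseline(
    F: np.ndarray,
    n_bins: int = 20,
    di_stop: float = 0.1,
    max_drop_frac: float = 0.8,
    max_iter: int = 100,
    tol: float = 1e-5,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> NMFOAFit:
    """NMF-OA with baseline-bin refinement.

    The gene is divided into ``n_bins`` equal-width bins.  Starting from a
    fit on the full matrix, the bin with the largest sum of squared
    normalized residuals ``((K E^T - F)/F)**2`` (cells with F = 0
    contribute 0) is dropped and the factorization re-fit on the retained
    bins, until either the maximum DI score on the retained region is at
    most ``di_stop`` or ``floor(max_drop_frac * n_bins)`` bins have been
    dropped.  Ties go to the lowest bin index; one bin is dropped per
    iteration.

    The scales fit on the final retained ("baseline") region, ``K*``, are
    kept, the full-length envelope is rebuilt as
    ``E[x] = max_j F[j, x] / K*[j]`` and the returned ``rho`` is computed
    on the full-length curves against ``K* E``.

    The intermediate fits of the drop loop only rank bins by residual, so
    they use the fast coordinate descent alone; the final baseline fit
    that produces ``K*`` is gradient-polished.
    """
    F = _validate(F)
    p, L = F.shape
    bin_id, nb = _bin_ids(L, n_bins)
    max_drop = int(np.floor(max_drop_frac * nb))
    retained = np.ones(nb, dtype=bool)
    dropped = 0

    warm = init
    fit = None
    while True:
        cols = retained[bin_id]
        Fb = F[:, cols]
        if not (Fb > 0).any() or retained.sum() < 2:
            # fewer than 2 retainable bins (or empty region): plain fit
            fit = fit_nmfoa(F, max_iter=max_iter, tol=tol, init=init, validate=False)
            retained[:] = True
            dropped = 0
            break
        fit = fit_nmfoa(Fb, max_iter=max_iter, tol=tol, init=warm, polish=False, validate=False)
        rho_b = compute_di(Fb, fit.K, fit.E)
        if rho_b.max() <= di_stop or dropped >= max_drop:
            fit = fit_nmfoa(Fb, max_iter=max_iter, tol=tol, init=(fit.K, fit.E), validate=False)
            break
        # normalized residuals on the retained region: R/F with the
        # denominator floored at one read.  Identical to R/F wherever
        # F >= 1; keeps cells with no observed coverage finite while
        # penalizing them in proportion to the coverage the fit expects
        # there — scoring F = 0 cells as zero would make a completely
        # dead region look pristine, and dividing by sub-read coverage
        # would let shot noise in sparse tails dominate the ranking
        R = fit.K[:, None] * fit.E[None, :] - Fb
        NR = R / np.maximum(Fb, 1.0)
        per_pos = (NR**2).sum(axis=0)
        score = np.bincount(bin_id[cols], weights=per_pos, minlength=nb)
        score[~retained] = -np.inf
        worst = int(np.argmax(score))  # argmax -> lowest index on ties
        retained[worst] = False
        dropped += 1
        warm = (fit.K, None)

    K = fit.K
    # full-length envelope from the refined scales
    kpos = K > 0
    if kpos.any():
        E_full = (F[kpos] / K[kpos, None]).max(axis=0)
    else:
        E_full = np.zeros(L)
    rho = np.zeros(p)
    ok = kpos.copy()
    # samples with no coverage on the baseline region but reads elsewhere
    # carry no usable scale information; their DI defaults to 0
    if ok.any():
        rho[ok] = compute_di(F[ok], K[ok], E_full)
    return NMFOAFit(
        K=K,
        E=E_full,
        rho=rho,
        loss=fit.loss,
        loss_trace=fit.loss_trace,
        baseline_mask=retained,
        bins_dropped=int(dropped),
        n_iter=fit.n_iter,
    )
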