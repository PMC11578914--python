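"""Two-step polychoric moment estimation for ordinal items.

Stage one estimates per-item thresholds from cumulative category proportions;
stage two maximizes, per item pair, the bivariate-normal multinomial
likelihood of the contingency table over the correlation alone, holding
thresholds fixed (the standard two-step estimator behind DWLS/WLSMV
pipelines).  Missing data are handled by pairwise deletion.

The full asymptotic covariance of the stacked statistic vector
(thresholds, polychoric correlations) is assembled from analytic influence
functions of both stages; its diagonal supplies the DWLS weights and the full
matrix feeds the robust (mean-and-variance-adjusted) test statistic and
sandwich standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from ._bvn import bvn_cdf, bvn_pdf

__all__ = [
    "PolychoricMoments",
    "estimate_thresholds",
    "estimate_polychoric",
    "moments_and_weights",
]

_RHO_BOUND = 0.999
_TINY = 1e-12


class DegenerateItemError(ValueError):
    """An item's category distribution cannot support threshold estimation."""


def estimate_thresholds(category_counts, strict: bool = False) -> np.ndarray:
    """Thresholds tau_c = Phi^-1(cumulative proportion through category c).

    ``category_counts`` has length C (categories 1..C).  An interior empty
    category is collapsed with its lower neighbour (with a warning), which
    shortens the returned vector; in strict mode it raises instead.  All mass
    in a single category raises (the item is degenerate).
    """
    counts = np.asarray(category_counts, dtype=float)
    if np.any(counts < 0) or counts.sum() <= 0:
        raise ValueError("category counts must be nonnegative with positive total")
    if np.count_nonzero(counts) < 2:
        raise DegenerateItemError("all responses in a single category")
    nz = np.nonzero(counts)[0]
    interior_empty = np.any(counts[nz[0] : nz[-1] + 1] == 0)
    if interior_empty:
        if strict:
            raise DegenerateItemError("interior empty category (strict mode)")
        warnings.warn(
            "interior empty category collapsed with lower neighbour",
            stacklevel=2,
        )
    cum = np.cumsum(counts)[:-1] / counts.sum()
    cum = cum[(cum > 0) & (cum < 1)]
    # collapsing duplicates (empty interior category gives a repeated cum value)
    cum = np.unique(cum)
    return ndtri(cum)


def _cell_probs(rho: float, t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """(C1, C2) rectangle probabilities of the bivariate normal."""
    a = np.concatenate(([-np.inf], t1, [np.inf]))
    b = np.concatenate(([-np.inf], t2, [np.inf]))
    F = bvn_cdf(a[:, None], b[None, :], rho)
    return np.diff(np.diff(F, axis=0), axis=1)


def _cell_dprobs_drho(rho: float, t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """d(cell prob)/d rho = corner differences of the bivariate density."""
    a = np.concatenate(([-np.inf], t1, [np.inf]))
    b = np.concatenate(([-np.inf], t2, [np.inf]))
    D = np.zeros((a.size, b.size))
    fin_a = np.isfinite(a)
    fin_b = np.isfinite(b)
    D[np.ix_(fin_a, fin_b)] = bvn_pdf(a[fin_a][:, None], b[fin_b][None, :], rho)
    return np.diff(np.diff(D, axis=0), axis=1)


def _cell_dprobs_dtau(rho: float, t1: np.ndarray, t2: np.ndarray):
    """Derivatives of cell probs wrt each threshold of item 1 and item 2.

    Returns ``(d1, d2)`` with ``d1[c, i, j] = dP_ij / d t1_c`` and analogously
    for ``d2``.
    """
    s = np.sqrt(max(1.0 - rho * rho, _TINY))
    a = np.concatenate(([-np.inf], t1, [np.inf]))
    b = np.concatenate(([-np.inf], t2, [np.inf]))
    C1, C2 = t1.size + 1, t2.size + 1
    # edge density along a = t1_c: phi(t) * [Phi((b_j - rho t)/s) - Phi((b_{j-1} - rho t)/s)]
    cb = ndtr((b[None, :] - rho * t1[:, None]) / s)  # (C1-1, C2+1)
    edge1 = norm.pdf(t1)[:, None] * np.diff(cb, axis=1)  # (C1-1, C2)
    ca = ndtr((a[None, :] - rho * t2[:, None]) / s)
    edge2 = norm.pdf(t2)[:, None] * np.diff(ca, axis=1)  # (C2-1, C1)
    d1 = np.zeros((t1.size, C1, C2))
    for c in range(t1.size):
        d1[c, c, :] = edge1[c]
        d1[c, c + 1, :] = -edge1[c]
    d2 = np.zeros((t2.size, C1, C2))
    for c in range(t2.size):
        d2[c, :, c] = edge2[c]
        d2[c, :, c + 1] = -edge2[c]
    return d1, d2


def estimate_polychoric(pair_table, t1, t2, return_var: bool = True):
    """Two-step polychoric correlation from a C1 x C2 contingency table.

    Solves the score equation of the one-parameter multinomial likelihood
    (thresholds fixed) by bracketed root finding on (-0.999, 0.999); a score
    with no sign change means the likelihood is maximized at the boundary,
    in which case the clipped estimate is returned with a warning.

    Returns ``rho`` or ``(rho, avar)`` where ``avar`` is the observed-information
    asymptotic variance of the one-parameter likelihood (1 / (n * info)).
    """
    table = np.asarray(pair_table, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    n = table.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("contingency table has a zero margin")

    def score(rho):
        P = np.clip(_cell_probs(rho, t1, t2), _TINY, None)
        dP = _cell_dprobs_drho(rho, t1, t2)
        return float(np.sum(table * dP / P))

    lo, hi = -_RHO_BOUND, _RHO_BOUND
    s_lo, s_hi = score(lo), score(hi)
    if s_lo > 0 and s_hi > 0:
        warnings.warn("polychoric likelihood maximized at upper boundary", stacklevel=2)
        rho = hi
    elif s_lo < 0 and s_hi < 0:
        warnings.warn("polychoric likelihood maximized at lower boundary", stacklevel=2)
        rho = lo
    else:
        rho = brentq(score, lo, hi, xtol=1e-10)
    if not return_var:
        return rho
    P = np.clip(_cell_probs(rho, t1, t2), _TINY, None)
    dP = _cell_dprobs_drho(rho, t1, t2)
    info = float(np.sum((dP**2) / P))  # expected information per observation
    avar = 1.0 / (n * max(info, _TINY))
    return rho, avar


def _batch_cell_probs(rho: np.ndarray, t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Cell probabilities for a batch of pairs: rho (P,), t1/t2 (P, C-1)."""
    Pn, Cm1 = t1.shape
    a = np.concatenate([np.full((Pn, 1), -np.inf), t1, np.full((Pn, 1), np.inf)], axis=1)
    b = np.concatenate([np.full((Pn, 1), -np.inf), t2, np.full((Pn, 1), np.inf)], axis=1)
    F = bvn_cdf(a[:, :, None], b[:, None, :], rho[:, None, None])
    return np.diff(np.diff(F, axis=1), axis=2)


def _batch_score(rho: np.ndarray, t1: np.ndarray, t2: np.ndarray, tables: np.ndarray) -> np.ndarray:
    """Score of the pairwise likelihood wrt rho, vectorized over pairs."""
    Pn, Cm1 = t1.shape
    P = np.clip(_batch_cell_probs(rho, t1, t2), _TINY, None)
    D = np.zeros((Pn, Cm1 + 2, Cm1 + 2))
    D[:, 1:-1, 1:-1] = bvn_pdf(t1[:, :, None], t2[:, None, :], rho[:, None, None])
    dP = np.diff(np.diff(D, axis=1), axis=2)
    return np.sum(tables * dP / P, axis=(1, 2))


def _batch_polychoric(tables: np.ndarray, t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Vectorized bracketed root finding of all pairwise polychoric scores.

    Bisection to ~1e-12 on (-0.999, 0.999); pairs whose score has no sign
    change (perfect association) are clipped to the boundary.
    """
    Pn = tables.shape[0]
    lo = np.full(Pn, -_RHO_BOUND)
    hi = np.full(Pn, _RHO_BOUND)
    s_lo = _batch_score(lo, t1, t2, tables)
    s_hi = _batch_score(hi, t1, t2, tables)
    at_hi = (s_lo > 0) & (s_hi > 0)
    at_lo = (s_lo < 0) & (s_hi < 0)
    for _ in range(45):
        mid = (lo + hi) / 2.0
        s = _batch_score(mid, t1, t2, tables)
        up = s > 0
        lo = np.where(up, mid, lo)
        hi = np.where(up, hi, mid)
    rho = (lo + hi) / 2.0
    rho[at_hi] = _RHO_BOUND
    rho[at_lo] = -_RHO_BOUND
    if np.any(at_hi | at_lo):
        warnings.warn("polychoric likelihood maximized at boundary for some pairs", stacklevel=2)
    return rho


@dataclass
class PolychoricMoments:
    """Sample moments of one group: thresholds, polychorics, asymptotic covariance."""

    thresholds: np.ndarray  # (K, C-1)
    corr: np.ndarray  # (K, K) polychoric correlation matrix
    gamma: np.ndarray | None  # (m, m) avar of sqrt(n)*(s - sigma)
    n: int
    pairwise_n: np.ndarray  # (K, K)
    group: object = None

    @property
    def n_items(self) -> int:
        return self.corr.shape[0]

    @property
    def stats(self) -> np.ndarray:
        """Stacked statistic vector: thresholds row-major, then corr for j < k."""
        K = self.n_items
        iu = np.triu_indices(K, 1)
        return np.concatenate([self.thresholds.ravel(), self.corr[iu]])

    @property
    def weights(self) -> np.ndarray:
        """Diagonal DWLS weights (variances of the statistics)."""
        if self.gamma is None:
            return np.ones(self.stats.size)
        return np.clip(np.diag(self.gamma), _TINY, None)

    def to_dict(self) -> dict:
        return {
            "group": None if self.group is None else str(self.group),
            "n": int(self.n),
            "thresholds": self.thresholds.tolist(),
            "polychoric_corr": self.corr.tolist(),
            "pairwise_n": self.pairwise_n.tolist(),
            "stat_variances": (self.weights / 1.0).tolist(),
        }


def moments_and_weights(dataset, group, strict: bool = False) -> PolychoricMoments:
    """Thresholds, polychoric matrix and influence-based Gamma for one group.

    ``dataset`` is an :class:`~ordinvar.simulate.OrdinalDataset` (or any object
    with ``.data``/``.groups``/``.n_categories``).  Pairwise deletion
    throughout; the influence functions of incomplete statistics are rescaled
    by n / n_available so Gamma refers to sqrt(n) * (s - sigma) with n the
    group's row count.
    """
    X = dataset.data[dataset.groups == group]
    C = dataset.n_categories
    n, K = X.shape
    if K < 2:
        raise ValueError("need at least 2 items")
    if n == 0:
        raise ValueError(f"group {group!r} is empty")
    obs = ~np.isnan(X)

    taus = []
    for j in range(K):
        counts = np.bincount(X[obs[:, j], j].astype(int), minlength=C + 1)[1:]
        try:
            tau_j = estimate_thresholds(counts, strict=strict)
        except DegenerateItemError as err:
            raise DegenerateItemError(f"item {j + 1} in group {group!r}: {err}") from err
        if tau_j.size != C - 1:
            raise DegenerateItemError(
                f"item {j + 1} in group {group!r}: empty category prevents "
                f"a full set of {C - 1} thresholds"
            )
        taus.append(tau_j)
    tau = np.vstack(taus)

    m = K * (C - 1) + K * (K - 1) // 2
    Psi = np.zeros((n, m))
    # threshold influence columns
    for j in range(K):
        oj = obs[:, j]
        nj = oj.sum()
        xj = X[oj, j]
        for c in range(C - 1):
            p = ndtr(tau[j, c])
            col = j * (C - 1) + c
            Psi[oj, col] = ((xj <= c + 1) - p) / norm.pdf(tau[j, c]) * (n / nj)

    P = np.eye(K)
    pairwise_n = np.zeros((K, K), dtype=int)
    np.fill_diagonal(pairwise_n, obs.sum(axis=0))
    pairs = [(j, k) for j in range(K) for k in range(j + 1, K)]
    tables = np.zeros((len(pairs), C, C))
    pair_idx = []
    for q, (j, k) in enumerate(pairs):
        both = obs[:, j] & obs[:, k]
        njk = int(both.sum())
        pairwise_n[j, k] = pairwise_n[k, j] = njk
        idx = (X[both, j].astype(int) - 1) * C + (X[both, k].astype(int) - 1)
        tables[q] = np.bincount(idx, minlength=C * C).reshape(C, C)
        pair_idx.append((both, idx))
        if np.any(tables[q].sum(axis=1) == 0) or np.any(tables[q].sum(axis=0) == 0):
            raise DegenerateItemError(
                f"pair (item {j + 1}, item {k + 1}) in group {group!r} has a zero margin"
            )
    rhos = _batch_polychoric(tables, tau[[j for j, _ in pairs]], tau[[k for _, k in pairs]])
    col = K * (C - 1)
    for q, (j, k) in enumerate(pairs):
        both, idx = pair_idx[q]
        njk = pairwise_n[j, k]
        table = tables[q]
        rho = float(np.clip(rhos[q], -_RHO_BOUND, _RHO_BOUND))
        P[j, k] = P[k, j] = rho
        # influence function of the two-step estimator
        Pc = np.clip(_cell_probs(rho, tau[j], tau[k]), _TINY, None)
        dP = _cell_dprobs_drho(rho, tau[j], tau[k])
        s_cell = dP / Pc
        A = float(np.sum(dP * s_cell))  # expected information
        d1, d2 = _cell_dprobs_dtau(rho, tau[j], tau[k])
        b_j = -np.tensordot(d1, s_cell, axes=([1, 2], [0, 1]))  # (C-1,)
        b_k = -np.tensordot(d2, s_cell, axes=([1, 2], [0, 1]))
        s_row = np.zeros(n)
        s_row[both] = s_cell.ravel()[idx] * (n / max(njk, 1))
        tj = slice(j * (C - 1), (j + 1) * (C - 1))
        tk = slice(k * (C - 1), (k + 1) * (C - 1))
        Psi[:, col] = (s_row + Psi[:, tj] @ b_j + Psi[:, tk] @ b_k) / A
        col += 1

    gamma = (Psi.T @ Psi) / n
    return PolychoricMoments(
        thresholds=tau,
        corr=P,
        gamma=gamma,
        n=n,
        pairwise_n=pairwise_n,
        group=group,
    )
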