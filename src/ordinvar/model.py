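"""One-factor ordinal confirmatory factor analysis, single- and multi-group.

The model for item j in group g is a normal-ogive factor model on the latent
response variate::

    y*_jg = nu_jg + lambda_jg * eta + eps_jg,   eta ~ N(kappa_g, phi_g)

with observed categories produced by thresholds tau_jcg, correlated residuals
for declared item pairs, and delta parameterization (the total y* variance is
the group scale parameter ``sd_jg``; the reference group is standardized to
sd = 1, kappa = 0, phi = 1).

Estimation is diagonally weighted least squares on the polychoric moment
vector (thresholds + correlations) with weights from the influence-based
asymptotic covariance; the test statistic is the mean-and-variance-adjusted
(scaled-and-shifted) form and standard errors are sandwich estimates — the
combination usually labelled WLSMV.

The public surface follows the statsmodels convention: build an
:class:`OrdinalFactorModel` from data, call :meth:`~OrdinalFactorModel.fit`,
inspect the returned :class:`OrdinalFactorResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .polychoric import PolychoricMoments, moments_and_weights

__all__ = [
    "OrdinalFactorModel",
    "OrdinalFactorResults",
    "ConvergenceError",
    "fit_indices",
    "omega_reliability",
    "LEVELS",
]

LEVELS = ("configural", "thresholds", "loadings", "scalar")
_THETA_FLOOR = 1e-6
_PEN = 1e4


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# parameter table
# ---------------------------------------------------------------------------

def _empty_free_items() -> dict:
    return {"thresholds": set(), "loadings": set(), "intercepts": set()}


@dataclass
class ParameterTable:
    """Maps each group-level parameter to a free-parameter id or a fixed value.

    Index arrays hold the free-parameter index (>= 0) or -1 for fixed; the
    parallel ``fixed`` arrays hold the fixed values.  Equality constraints
    across groups are realized by sharing a free index.
    """

    K: int
    C: int
    n_groups: int
    resid_pairs: list
    idx: dict = field(default_factory=dict)  # kind -> (G, ...) int arrays
    fixed: dict = field(default_factory=dict)
    n_free: int = 0
    names: list = field(default_factory=list)

    def expand(self, p: np.ndarray, g: int) -> dict:
        """Free vector -> group-g parameter arrays."""
        out = {}
        for kind in ("tau", "lam", "sd", "nu", "rc"):
            ix = self.idx[kind][g]
            vals = self.fixed[kind][g].copy()
            mask = ix >= 0
            vals[mask] = p[ix[mask]]
            out[kind] = vals
        for kind in ("kappa", "phi"):
            ix = self.idx[kind][g]
            out[kind] = p[ix] if ix >= 0 else self.fixed[kind][g]
        return out


def build_parameter_table(
    K: int,
    C: int,
    n_groups: int,
    resid_pairs: list,
    level: str,
    free_items: dict | None = None,
    baseline: bool = False,
) -> ParameterTable:
    """Construct the constraint map for an invariance level.

    Identification schedule (reference group = 0, delta parameterization):

    * configural — thresholds and loadings free per group; nu = 0, sd = 1,
      kappa = 0, phi = 1 everywhere.
    * thresholds — tau equated across groups; per-item nu and sd freed in
      non-reference groups (the C - 1 >= 3 equated thresholds per item make
      them identified); kappa = 0, phi = 1.
    * loadings — additionally lambda equated; phi freed in non-reference
      groups.
    * scalar — additionally nu equated (at 0); kappa freed in non-reference
      groups.  Latent means and variances are now comparable.

    ``free_items`` maps step name -> set of 0-based item indices exempted
    from that step's equality constraint (partial invariance).  An item with
    freed thresholds keeps configural-style identification (nu = 0, sd = 1)
    in every group.
    """
    if level not in LEVELS and not baseline:
        raise ValueError(f"unknown level {level!r}")
    fi = _empty_free_items()
    if free_items:
        for k, v in free_items.items():
            if k not in fi:
                raise ValueError(f"unknown step {k!r} in free_items")
            fi[k] = set(v)
    G = n_groups
    npairs = len(resid_pairs)
    t = ParameterTable(K=K, C=C, n_groups=G, resid_pairs=list(resid_pairs))
    shapes = {
        "tau": (G, K, C - 1),
        "lam": (G, K),
        "sd": (G, K),
        "nu": (G, K),
        "rc": (G, npairs),
        "kappa": (G,),
        "phi": (G,),
    }
    for kind, shp in shapes.items():
        t.idx[kind] = np.full(shp, -1, dtype=int)
        t.fixed[kind] = np.zeros(shp)
    t.fixed["sd"][:] = 1.0
    t.fixed["phi"][:] = 1.0

    counter = [0]

    def new(name):
        i = counter[0]
        counter[0] += 1
        t.names.append(name)
        return i

    lvl = -1 if baseline else LEVELS.index(level)
    tau_free_items = fi["thresholds"]
    lam_free_items = fi["loadings"]
    nu_free_items = fi["intercepts"]

    # thresholds
    for j in range(K):
        per_group = baseline or lvl == 0 or j in tau_free_items
        if per_group:
            for g in range(G):
                for c in range(C - 1):
                    t.idx["tau"][g, j, c] = new(f"tau[g{g},i{j},c{c}]")
        else:
            for c in range(C - 1):
                i = new(f"tau[i{j},c{c}]")
                t.idx["tau"][:, j, c] = i
    if baseline:
        return _finalize(t, counter[0])

    # loadings
    for j in range(K):
        if lvl <= 1 or j in lam_free_items:
            for g in range(G):
                t.idx["lam"][g, j] = new(f"lam[g{g},i{j}]")
        else:
            i = new(f"lam[i{j}]")
            t.idx["lam"][:, j] = i

    # nu and sd: freed in non-reference groups from the thresholds step on,
    # except items with group-specific thresholds (configural-style identification)
    if lvl >= 1:
        for j in range(K):
            if j in tau_free_items:
                continue
            for g in range(1, G):
                t.idx["sd"][g, j] = new(f"sd[g{g},i{j}]")
                if lvl < 3 or j in nu_free_items:
                    t.idx["nu"][g, j] = new(f"nu[g{g},i{j}]")

    # latent moments
    if lvl >= 2:
        for g in range(1, G):
            t.idx["phi"][g] = new(f"phi[g{g}]")
    if lvl >= 3:
        for g in range(1, G):
            t.idx["kappa"][g] = new(f"kappa[g{g}]")

    # residual correlations: free per group at every level
    for g in range(G):
        for q, (a, b) in enumerate(resid_pairs):
            t.idx["rc"][g, q] = new(f"rc[g{g},({a},{b})]")

    return _finalize(t, counter[0])


def _finalize(t: ParameterTable, n_free: int) -> ParameterTable:
    t.n_free = n_free
    return t


# ---------------------------------------------------------------------------
# implied moments and Jacobian
# ---------------------------------------------------------------------------

def implied_moments(pars: dict, K: int, C: int, resid_pairs: list):
    """Model-implied standardized thresholds and latent-response correlations.

    Returns ``(sigma, extras)`` where sigma stacks thresholds (row-major) and
    the upper-triangular correlations, matching
    :attr:`~ordinvar.polychoric.PolychoricMoments.stats`.
    """
    tau, lam, sd, nu = pars["tau"], pars["lam"], pars["sd"], pars["nu"]
    kappa, phi, rc = pars["kappa"], pars["phi"], pars["rc"]
    theta = sd**2 - lam**2 * phi
    theta_c = np.maximum(theta, _THETA_FLOOR)
    t = (tau - nu[:, None] - lam[:, None] * kappa) / sd[:, None]
    P = np.outer(lam, lam) * phi
    rt = np.sqrt(theta_c)
    for q, (a, b) in enumerate(resid_pairs):
        P[a, b] += rc[q] * rt[a] * rt[b]
        P[b, a] = P[a, b]
    P /= np.outer(sd, sd)
    iu = np.triu_indices(K, 1)
    sigma = np.concatenate([t.ravel(), P[iu]])
    return sigma, {"t": t, "P": P, "theta": theta, "theta_c": theta_c}


def implied_jacobian(pars: dict, K: int, C: int, resid_pairs: list):
    """Analytic Jacobian of the implied moment vector wrt the group's raw
    parameters, ordered [tau (K*(C-1)), lam (K), sd (K), nu (K), kappa, phi,
    rc (npairs)].  Returns ``(sigma, J)``."""
    sigma, ex = implied_moments(pars, K, C, resid_pairs)
    tau, lam, sd, nu = pars["tau"], pars["lam"], pars["sd"], pars["nu"]
    kappa, phi, rc = pars["kappa"], pars["phi"], pars["rc"]
    t, P, theta = ex["t"], ex["P"], ex["theta_c"]
    npairs = len(resid_pairs)
    nt = K * (C - 1)
    npar = nt + 3 * K + 2 + npairs
    m = sigma.size
    J = np.zeros((m, npar))
    o_lam, o_sd, o_nu, o_kap, o_phi, o_rc = (
        nt,
        nt + K,
        nt + 2 * K,
        nt + 3 * K,
        nt + 3 * K + 1,
        nt + 3 * K + 2,
    )
    # threshold rows
    for j in range(K):
        for c in range(C - 1):
            r = j * (C - 1) + c
            J[r, r] = 1.0 / sd[j]
            J[r, o_nu + j] = -1.0 / sd[j]
            J[r, o_lam + j] = -kappa / sd[j]
            J[r, o_kap] = -lam[j] / sd[j]
            J[r, o_sd + j] = -t[j, c] / sd[j]
    # correlation rows
    pair_rc = {tuple(p): q for q, p in enumerate(resid_pairs)}
    iu = np.triu_indices(K, 1)
    rt = np.sqrt(theta)
    for r_off, (j, k) in enumerate(zip(*iu)):
        r = nt + r_off
        q = pair_rc.get((j, k))
        denom = sd[j] * sd[k]
        # d/d lam
        dj = lam[k] * phi
        dk = lam[j] * phi
        if q is not None:
            dj += rc[q] * (-lam[j] * phi) * rt[k] / rt[j]
            dk += rc[q] * (-lam[k] * phi) * rt[j] / rt[k]
        J[r, o_lam + j] = dj / denom
        J[r, o_lam + k] = dk / denom
        # d/d sd
        dsj = -P[j, k] / sd[j]
        dsk = -P[j, k] / sd[k]
        if q is not None:
            dsj += rc[q] * sd[j] * rt[k] / rt[j] / denom
            dsk += rc[q] * sd[k] * rt[j] / rt[k] / denom
        J[r, o_sd + j] = dsj
        J[r, o_sd + k] = dsk
        # d/d phi
        dphi = lam[j] * lam[k]
        if q is not None:
            dphi += rc[q] * (-(lam[j] ** 2) * rt[k] / rt[j] - (lam[k] ** 2) * rt[j] / rt[k]) / 2.0
        J[r, o_phi] = dphi / denom
        # d/d rc
        if q is not None:
            J[r, o_rc + q] = rt[j] * rt[k] / denom
    return sigma, J


def _scatter_group_jac(J_group: np.ndarray, table: ParameterTable, g: int) -> tuple:
    """Column index map from group raw-parameter order to free parameters."""
    K, C = table.K, table.C
    nt = K * (C - 1)
    cols = np.concatenate(
        [
            table.idx["tau"][g].ravel(),
            table.idx["lam"][g],
            table.idx["sd"][g],
            table.idx["nu"][g],
            np.array([table.idx["kappa"][g], table.idx["phi"][g]]),
            table.idx["rc"][g].ravel() if table.idx["rc"][g].size else np.array([], dtype=int),
        ]
    )
    mask = cols >= 0
    return cols[mask], mask


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class OrdinalFactorModel:
    """One-factor ordinal CFA fitted by DWLS to polychoric moments.

    Parameters
    ----------
    data : OrdinalDataset, DataFrame or None
        Item responses.  A DataFrame needs ``items`` (columns) and optionally
        ``group_col``.
    resid_pairs : list of (j, k)
        0-based item pairs given a correlated residual.
    """

    def __init__(
        self,
        data=None,
        items=None,
        group_col: str = "group",
        n_categories: int | None = None,
        resid_pairs=None,
        moments=None,
        group_labels=None,
        strict: bool = False,
    ):
        self.resid_pairs = [tuple(p) for p in (resid_pairs or [])]
        self._baseline_cache = None
        if moments is not None:
            self.moments = list(moments)
            self.group_labels = (
                list(group_labels)
                if group_labels is not None
                else [m.group if m.group is not None else i for i, m in enumerate(self.moments)]
            )
            self.K = self.moments[0].n_items
            self.C = self.moments[0].thresholds.shape[1] + 1
            return
        if data is None:
            raise ValueError("either data or moments is required")
        from .simulate import OrdinalDataset

        if isinstance(data, pd.DataFrame):
            if items is None:
                items = [c for c in data.columns if c.startswith("item_")]
            groups = (
                data[group_col].to_numpy()
                if group_col in data.columns
                else np.zeros(len(data), dtype=int)
            )
            X = data[items].to_numpy(dtype=float)
            C = n_categories or int(np.nanmax(X))
            data = OrdinalDataset(
                data=X, groups=groups, n_categories=C, item_names=list(items)
            )
        self.dataset = data
        self.K = data.n_items
        self.C = data.n_categories
        self.group_labels = data.group_labels()
        self.moments = [
            moments_and_weights(data, g, strict=strict) for g in self.group_labels
        ]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, items=None, group_col="group", **kw):
        return cls(df, items=items, group_col=group_col, **kw)

    @classmethod
    def from_moments(cls, moments, group_labels=None, resid_pairs=None):
        return cls(moments=moments, group_labels=group_labels, resid_pairs=resid_pairs)

    # -- internals ---------------------------------------------------------

    @property
    def n_groups(self) -> int:
        return len(self.moments)

    @property
    def n_total(self) -> int:
        return int(sum(m.n for m in self.moments))

    def _start_values(self, table: ParameterTable) -> np.ndarray:
        p = np.zeros(table.n_free)
        counts = np.zeros(table.n_free)
        K = self.K
        for g, mom in enumerate(self.moments):
            P = mom.corr
            w, v = np.linalg.eigh(P)
            lead = v[:, -1] * np.sqrt(max(w[-1], 0.0))
            if lead.sum() < 0:
                lead = -lead
            lam0 = np.clip(np.abs(lead), 0.2, 0.9)
            vals = {
                "tau": mom.thresholds,
                "lam": lam0,
                "sd": np.ones(K),
                "nu": np.zeros(K),
                "kappa": np.atleast_1d(0.0),
                "phi": np.atleast_1d(1.0),
                "rc": np.array(
                    [
                        np.clip(P[a, b] - lam0[a] * lam0[b], -0.5, 0.5)
                        for (a, b) in table.resid_pairs
                    ]
                ),
            }
            for kind in ("tau", "lam", "sd", "nu", "kappa", "phi", "rc"):
                ix = np.atleast_1d(table.idx[kind][g]).ravel()
                vv = np.atleast_1d(vals[kind]).ravel()
                mask = ix >= 0
                np.add.at(p, ix[mask], vv[mask])
                np.add.at(counts, ix[mask], 1.0)
        counts[counts == 0] = 1.0
        return p / counts

    def _bounds(self, table: ParameterTable):
        lo = np.full(table.n_free, -8.0)
        hi = np.full(table.n_free, 8.0)
        for g in range(table.n_groups):
            for kind, (a, b) in {
                "lam": (-3.0, 3.0),
                "sd": (0.2, 5.0),
                "rc": (-0.95, 0.95),
                "nu": (-6.0, 6.0),
                "kappa": (-5.0, 5.0),
                "phi": (0.05, 10.0),
            }.items():
                ix = np.atleast_1d(table.idx[kind][g]).ravel()
                ix = ix[ix >= 0]
                lo[ix], hi[ix] = a, b
        return list(zip(lo, hi))

    def _objective(self, p: np.ndarray, table: ParameterTable):
        N = self.n_total
        F = 0.0
        grad = np.zeros(table.n_free)
        for g, mom in enumerate(self.moments):
            pars = table.expand(p, g)
            sigma, J = implied_jacobian(pars, self.K, self.C, table.resid_pairs)
            r = mom.stats - sigma
            winv = 1.0 / mom.weights
            wfac = mom.n / N
            F += wfac * float(r @ (winv * r))
            cols, mask = _scatter_group_jac(J, table, g)
            gg = -2.0 * wfac * (J.T @ (winv * r))
            np.add.at(grad, cols, gg[mask])
            # inadmissibility penalty keeps theta > 0
            theta = pars["sd"] ** 2 - pars["lam"] ** 2 * pars["phi"]
            bad = theta < _THETA_FLOOR
            if np.any(bad):
                d = _THETA_FLOOR - theta[bad]
                F += _PEN * float(np.sum(d**2))
                # d theta / d lam = -2 lam phi ; / d sd = 2 sd ; / d phi = -lam^2
                K, C = self.K, self.C
                nt = K * (C - 1)
                gpen = np.zeros(nt + 3 * K + 2 + len(table.resid_pairs))
                idx_bad = np.where(bad)[0]
                gpen[nt + idx_bad] = _PEN * 2 * d * (2 * pars["lam"][idx_bad] * pars["phi"])
                gpen[nt + K + idx_bad] = _PEN * 2 * d * (-2 * pars["sd"][idx_bad])
                gpen[nt + 3 * K + 1] += _PEN * 2 * float(
                    np.sum(d * pars["lam"][idx_bad] ** 2)
                )
                np.add.at(grad, cols, gpen[mask])
        return F, grad

    def _identification_check(self, table: ParameterTable, p0: np.ndarray) -> None:
        m = sum(mom.stats.size for mom in self.moments)
        if m < table.n_free:
            raise ValueError(
                f"model not identified: {table.n_free} free parameters, {m} moments"
            )
        Delta = self._delta(p0, table)
        rank = np.linalg.matrix_rank(Delta)
        if rank < table.n_free:
            raise ValueError(
                f"model not identified: Jacobian rank {rank} < {table.n_free} free parameters"
            )

    def _delta(self, p: np.ndarray, table: ParameterTable) -> np.ndarray:
        """Stacked Jacobian d sigma / d free parameters (m_total x n_free)."""
        rows = []
        for g in range(self.n_groups):
            pars = table.expand(p, g)
            _, J = implied_jacobian(pars, self.K, self.C, table.resid_pairs)
            cols, mask = _scatter_group_jac(J, table, g)
            Jg = np.zeros((J.shape[0], table.n_free))
            Jg[:, cols] = J[:, mask]
            rows.append(Jg)
        return np.vstack(rows)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        level: str = "configural",
        free_items: dict | None = None,
        start: np.ndarray | None = None,
        compute_se: bool = True,
        check_identification: bool = False,
        _baseline: bool = False,
    ) -> "OrdinalFactorResults":
        """Fit the model at an invariance level; returns :class:`OrdinalFactorResults`."""
        table = build_parameter_table(
            self.K,
            self.C,
            self.n_groups,
            self.resid_pairs if not _baseline else [],
            level,
            free_items,
            baseline=_baseline,
        )
        p0 = start if start is not None else self._start_values(table)
        if check_identification:
            self._identification_check(table, p0)
        res = optimize.minimize(
            self._objective,
            p0,
            jac=True,
            method="L-BFGS-B",
            args=(table,),
            bounds=self._bounds(table),
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-9},
        )
        gnorm = float(np.max(np.abs(res.jac)))
        if gnorm > 1e-2:
            raise ConvergenceError(
                f"optimizer did not converge (max |gradient| = {gnorm:.3g})"
            )
        converged = gnorm < 1e-4 or res.success
        return OrdinalFactorResults(
            model=self,
            table=table,
            params=res.x,
            fmin=float(res.fun),
            level="baseline" if _baseline else level,
            free_items={k: sorted(v) for k, v in (free_items or {}).items() if v},
            converged=bool(converged),
            grad_norm=gnorm,
            compute_se=compute_se,
        )

    def fit_baseline(self) -> "OrdinalFactorResults":
        """Null model: free thresholds, all correlations zero (cached)."""
        if self._baseline_cache is None:
            self._baseline_cache = self.fit(_baseline=True, compute_se=False)
        return self._baseline_cache


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

class OrdinalFactorResults:
    """Estimates, robust test statistic, fit indices and parameter tables."""

    def __init__(
        self,
        model: OrdinalFactorModel,
        table: ParameterTable,
        params: np.ndarray,
        fmin: float,
        level: str,
        free_items: dict,
        converged: bool,
        grad_norm: float,
        compute_se: bool = True,
    ):
        self.model = model
        self.table = table
        self.params = params
        self.fmin = fmin
        self.level = level
        self.free_items = free_items
        self.converged = converged
        self.grad_norm = grad_norm
        self.n_total = model.n_total
        self.n_groups = model.n_groups
        m_total = sum(mom.stats.size for mom in model.moments)
        self.df = m_total - table.n_free
        self.chi2_raw = self.n_total * fmin
        self._compute_scaled()
        if compute_se:
            self._compute_se()
        else:
            self.param_cov = None
            self.bse = None
        self.heywood = bool(
            any(
                np.any(
                    table.expand(params, g)["sd"] ** 2
                    - table.expand(params, g)["lam"] ** 2 * table.expand(params, g)["phi"]
                    < 10 * _THETA_FLOOR
                )
                for g in range(self.n_groups)
            )
        )
        if self.heywood:
            warnings.warn("inadmissible solution: residual variance at boundary (Heywood)")
        self._indices = None

    # -- robust statistic --------------------------------------------------

    def _compute_scaled(self):
        model, table, p = self.model, self.table, self.params
        N = self.n_total
        Delta = model._delta(p, table)
        has_gamma = all(m.gamma is not None for m in model.moments)
        v = np.concatenate(
            [(m.n / N) / m.weights for m in model.moments]
        )  # diagonal of V
        H = (Delta * v[:, None]).T @ Delta
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            Hinv = np.linalg.pinv(H)
        self._Delta, self._v, self._Hinv = Delta, v, Hinv
        if not has_gamma:
            self.scale_a, self.scale_b = 1.0, 0.0
            self.chi2 = self.chi2_raw
            return
        # M = U Gamma* with U = V - V D H^- D' V; write M = B - P where
        # B = V Gamma* (block diagonal) and P = L H^-1 R is low rank with
        # L = V Delta, R = Delta' V Gamma*.  All traces reduce to small
        # (block or n_free-sized) products.
        trB = 0.0
        trB2 = 0.0
        m_total = Delta.shape[0]
        L = np.zeros((m_total, table.n_free))
        R = np.zeros((table.n_free, m_total))
        blocks = []
        offset = 0
        for g, mom in enumerate(model.moments):
            mblk = mom.stats.size
            sl = slice(offset, offset + mblk)
            Gs = (N / mom.n) * mom.gamma
            Vg = v[sl]
            Bg = Vg[:, None] * Gs
            trB += float(np.trace(Bg))
            trB2 += float(np.sum(Bg * Bg.T))
            L[sl] = Vg[:, None] * Delta[sl]
            R[:, sl] = (Delta[sl].T * Vg) @ Gs
            blocks.append((sl, Bg))
            offset += mblk
        C1 = R @ L  # Delta' V Gamma* V Delta
        trM = trB - float(np.trace(Hinv @ C1))
        LH = L @ Hinv
        trBP = 0.0
        for sl, Bg in blocks:
            Pblk = LH[sl] @ R[:, sl]
            trBP += float(np.sum(Bg.T * Pblk))
        S = R @ LH
        trP2 = float(np.sum(S * S.T))
        trM2 = trB2 - 2.0 * trBP + trP2
        self._C1 = C1
        df = max(self.df, 1)
        if trM2 <= 0 or trM <= 0:
            self.scale_a, self.scale_b = 1.0, 0.0
            self.chi2 = self.chi2_raw
            return
        a = np.sqrt(df / trM2)
        b = df - a * trM
        self.scale_a, self.scale_b = float(a), float(b)
        self.chi2 = float(max(a * self.chi2_raw + b, 0.0))

    def _compute_se(self):
        if not all(m.gamma is not None for m in self.model.moments):
            self.param_cov = None
            self.bse = None
            return
        acov = self._Hinv @ self._C1 @ self._Hinv / self.n_total
        self.param_cov = acov
        self.bse = np.sqrt(np.clip(np.diag(acov), 0.0, None))

    # -- parameter access --------------------------------------------------

    def group_params(self, g) -> dict:
        if not isinstance(g, (int, np.integer)):
            g = self.model.group_labels.index(g)
        out = self.table.expand(self.params, g)
        out["theta"] = out["sd"] ** 2 - out["lam"] ** 2 * out["phi"]
        return out

    @property
    def loadings(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self.group_params(g)["lam"] for g in range(self.n_groups)],
            index=self.model.group_labels,
            columns=[f"item_{j + 1}" for j in range(self.model.K)],
        )

    @property
    def latent_means(self) -> pd.Series:
        return pd.Series(
            [float(self.group_params(g)["kappa"]) for g in range(self.n_groups)],
            index=self.model.group_labels,
            name="kappa",
        )

    @property
    def latent_variances(self) -> pd.Series:
        return pd.Series(
            [float(self.group_params(g)["phi"]) for g in range(self.n_groups)],
            index=self.model.group_labels,
            name="phi",
        )

    def param_index(self, name: str) -> int:
        return self.table.names.index(name)

    def param_se(self, name: str) -> float:
        if self.bse is None:
            raise ValueError("standard errors were not computed")
        return float(self.bse[self.param_index(name)])

    # -- fit indices -------------------------------------------------------

    @property
    def indices(self) -> dict:
        if self._indices is None:
            baseline = self.model.fit_baseline() if self.level != "baseline" else None
            self._indices = fit_indices(self, baseline, self.n_total, self.n_groups)
        return self._indices

    @property
    def cfi(self):
        return self.indices["cfi"]

    @property
    def tli(self):
        return self.indices["tli"]

    @property
    def rmsea(self):
        return self.indices["rmsea"]

    @property
    def srmr(self):
        return self.indices["srmr"]

    def residuals(self) -> list:
        """Per-group residual vectors s - sigma."""
        out = []
        for g, mom in enumerate(self.model.moments):
            sigma, _ = implied_moments(
                self.table.expand(self.params, g), self.model.K, self.model.C, self.table.resid_pairs
            )
            out.append(mom.stats - sigma)
        return out

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Ordinal one-factor CFA (DWLS, delta parameterization)",
            f"  level: {self.level}   groups: {self.n_groups}   N: {self.n_total}",
            f"  chi2(scaled) = {self.chi2:.3f}  df = {self.df}  "
            f"CFI = {self.cfi:.4f}  TLI = {self.tli:.4f}" if self.level != "baseline" else
            f"  chi2(scaled) = {self.chi2:.3f}  df = {self.df}",
        ]
        if self.level != "baseline":
            lo, hi = self.indices["rmsea_ci"]
            lines.append(
                f"  RMSEA = {self.rmsea:.4f} (90% CI {lo:.4f}-{hi:.4f})  SRMR = {self.srmr:.4f}"
            )
        lines.append(f"  converged: {self.converged}   Heywood: {self.heywood}")
        if self.free_items:
            lines.append(f"  freed items (partial invariance): {self.free_items}")
        lines.append("")
        lines.append("Loadings:")
        lines.append(self.loadings.round(3).to_string())
        if self.level == "scalar":
            lines.append("")
            lines.append("Latent means (kappa) / variances (phi):")
            df = pd.DataFrame(
                {"kappa": self.latent_means, "phi": self.latent_variances}
            )
            lines.append(df.round(3).to_string())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "level": self.level,
            "n_groups": self.n_groups,
            "n_total": self.n_total,
            "chi2_scaled": self.chi2,
            "chi2_raw": self.chi2_raw,
            "scale_a": self.scale_a,
            "scale_b": self.scale_b,
            "df": self.df,
            "fmin": self.fmin,
            "converged": self.converged,
            "heywood": self.heywood,
            "free_items": self.free_items,
            "param_names": list(self.table.names),
            "params": self.params.tolist(),
        }
        if self.level != "baseline":
            d.update(
                cfi=self.cfi,
                tli=self.tli,
                rmsea=self.rmsea,
                rmsea_ci=list(self.indices["rmsea_ci"]),
                srmr=self.srmr,
            )
        if self.bse is not None:
            d["bse"] = self.bse.tolist()
        return d


# ---------------------------------------------------------------------------
# fit indices and reliability
# ---------------------------------------------------------------------------

def fit_indices(fit, baseline, N_total: int, n_groups: int) -> dict:
    """CFI / TLI / RMSEA (+90% CI) / SRMR from scaled statistics.

    The multigroup RMSEA multiplies the per-group noncentrality form by
    sqrt(G); CFI and TLI use the standard noncentrality ratios with max(., 0)
    guards so degenerate baselines still yield defined indices.
    """
    T, df = fit.chi2, fit.df
    out = {}
    if baseline is not None:
        Tb, dfb = baseline.chi2, baseline.df
        num = max(T - df, 0.0)
        den = max(Tb - dfb, T - df, 0.0)
        out["cfi"] = 1.0 - (num / den if den > 0 else 0.0)
        if Tb > dfb > 0 and df > 0:
            tli = ((Tb / dfb) - (T / df)) / ((Tb / dfb) - 1.0)
            out["tli"] = float(min(tli, 1.0))
        else:
            out["tli"] = 1.0
    G = n_groups
    denom = df * max(N_total - G, 1)
    out["rmsea"] = float(np.sqrt(G * max(T - df, 0.0) / denom)) if df > 0 else 0.0
    out["rmsea_ci"] = _rmsea_ci(T, df, N_total, G)
    res = fit.residuals()
    K = fit.model.K
    npairs = K * (K - 1) // 2
    sq = np.concatenate([r[-npairs:] for r in res]) ** 2
    out["srmr"] = float(np.sqrt(sq.mean()))
    return out


def _rmsea_ci(T: float, df: int, N: int, G: int, level: float = 0.90):
    """Noncentral-chi-square inversion for the RMSEA confidence interval."""
    if df <= 0 or not np.isfinite(T):
        return (0.0, 0.0)
    a = (1.0 - level) / 2.0

    def nc_for(prob):
        # find lambda with ncx2.cdf(T, df, lambda) = prob
        if stats.ncx2.cdf(T, df, 0.0) < prob:
            return 0.0
        hi = max(4.0 * (T - df), 10.0)
        while stats.ncx2.cdf(T, df, hi) > prob and hi < 1e7:
            hi *= 2
        return optimize.brentq(lambda l: stats.ncx2.cdf(T, df, l) - prob, 0.0, hi)

    denom = df * max(N - G, 1)
    lo = nc_for(1.0 - a)
    hi = nc_for(a)
    return (float(np.sqrt(G * lo / denom)), float(np.sqrt(G * hi / denom)))


def omega_reliability(fit: OrdinalFactorResults, group=0) -> float:
    """McDonald's omega on the latent-response scale for one group.

    omega = (sum lambda)^2 phi / ((sum lambda)^2 phi + sum theta
            + 2 sum residual covariances).
    """
    pars = fit.group_params(group)
    lam, phi, theta = pars["lam"], pars["phi"], pars["theta"]
    if np.any(theta < 0):
        raise ValueError("inadmissible residual variance (theta < 0)")
    common = float(lam.sum() ** 2 * phi)
    resid = float(theta.sum())
    for q, (a, b) in enumerate(fit.table.resid_pairs):
        resid += 2.0 * pars["rc"][q] * np.sqrt(theta[a] * theta[b])
    return common / (common + resid) if common + resid > 0 else 0.0
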