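"""Synthetic multi-group ordinal survey data from a one-factor normal-ogive model.

The generator emulates a repeated cross-sectional adolescent symptom survey:
K ordinal items (default 6) on a C-point scale (default 4), groups formed by
survey-year x gender x age-band cells, one correlated-residual item pair, and
item-level missingness.  Each group g has its own latent mean kappa_g and
variance phi_g, loadings lambda_jg, latent-response intercepts nu_jg,
thresholds tau_jcg and residual variances theta_jg, so measurement
noninvariance of any kind can be injected exactly where a study design
requires it.

Responses arise by thresholding the latent response variate
``y*_j = nu_j + lambda_j * eta + eps_j`` with ``eta ~ N(kappa_g, phi_g)`` and
correlated multivariate-normal residuals.  The reference (first) group is
scaled delta-style: kappa = 0, phi = 1 and Var(y*_j) = 1.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroupParams",
    "PopulationSpec",
    "OrdinalDataset",
    "build_spec",
    "simulate_dataset",
    "inject_noninvariance",
    "DEFAULT_LOADINGS",
    "DEFAULT_THRESHOLDS",
]

# Defaults mirror the target instrument: six items, loadings spanning the
# 0.65-0.86 range typical of a short internalizing-symptom scale, right-skewed
# thresholds (most respondents endorse the lowest categories), and a
# correlated residual between items 3 and 4 (overlapping item content).
DEFAULT_LOADINGS = np.array([0.80, 0.70, 0.86, 0.83, 0.65, 0.75])
DEFAULT_THRESHOLDS = np.array(
    [
        [-0.30, 0.55, 1.40],
        [-0.10, 0.75, 1.55],
        [-0.20, 0.65, 1.45],
        [0.00, 0.80, 1.60],
        [0.10, 0.90, 1.70],
        [-0.40, 0.50, 1.35],
    ]
)
DEFAULT_RESID_PAIR = (2, 3)  # 0-based items 3 and 4
DEFAULT_RESID_RHO = 0.25
DEFAULT_MISSING = 0.055  # item-level missingness of the emulated survey


@dataclass
class GroupParams:
    """Generating parameters of the ordinal factor model for one group."""

    kappa: float
    phi: float
    loadings: np.ndarray  # (K,)
    intercepts: np.ndarray  # (K,) nu on the y* scale
    thresholds: np.ndarray  # (K, C-1), strictly increasing per row
    theta: np.ndarray  # (K,) residual variances
    resid_corr: dict = field(default_factory=dict)  # {(j, k): rho}, j < k

    def copy(self) -> "GroupParams":
        return GroupParams(
            kappa=self.kappa,
            phi=self.phi,
            loadings=self.loadings.copy(),
            intercepts=self.intercepts.copy(),
            thresholds=self.thresholds.copy(),
            theta=self.theta.copy(),
            resid_corr=dict(self.resid_corr),
        )

    def residual_cov(self) -> np.ndarray:
        K = len(self.theta)
        cov = np.diag(self.theta.astype(float))
        for (j, k), rho in self.resid_corr.items():
            cov[j, k] = cov[k, j] = rho * np.sqrt(self.theta[j] * self.theta[k])
        return cov

    def ystar_sd(self) -> np.ndarray:
        return np.sqrt(self.loadings**2 * self.phi + self.theta)


@dataclass
class PopulationSpec:
    """Complete data-generating process for a multi-group ordinal dataset."""

    n_items: int
    n_categories: int
    groups: list
    params: dict  # label -> GroupParams
    n_per_group: dict  # label -> int
    missing_rate: float = 0.0
    missing_mode: str = "mcar"  # "mcar" | "mar"
    mar_slope: float = 0.0  # logit slope on eta when missing_mode == "mar"
    n_clusters: int = 0  # per group; 0 = no clustering
    cluster_icc: float = 0.0  # share of latent variance at cluster level
    provenance: list = field(default_factory=list)

    def validate(self) -> None:
        if self.n_items < 2:
            raise ValueError("need at least 2 items")
        if self.n_categories < 2:
            raise ValueError("need at least 2 categories")
        for g in self.groups:
            p = self.params[g]
            if p.phi <= 0:
                raise ValueError(f"phi must be > 0 in group {g!r}")
            if np.any(p.theta <= 0):
                j = int(np.argmax(p.theta <= 0))
                raise ValueError(f"theta must be > 0 (item {j + 1}, group {g!r})")
            if np.any(np.diff(p.thresholds, axis=1) <= 0):
                j = int(np.argmax(np.any(np.diff(p.thresholds, axis=1) <= 0, axis=1)))
                raise ValueError(
                    f"thresholds must be strictly increasing (item {j + 1}, group {g!r})"
                )
            for (a, b), rho in p.resid_corr.items():
                if not (0 <= a < b < self.n_items):
                    raise ValueError(f"residual pair {(a, b)} out of range")
                if abs(rho) >= 1:
                    raise ValueError(f"|residual correlation| must be < 1 for pair {(a, b)}")
            cov = p.residual_cov()
            if np.linalg.eigvalsh(cov)[0] <= 0:
                raise ValueError(f"residual covariance not positive definite in group {g!r}")
        ref = self.params[self.groups[0]]
        if abs(ref.kappa) > 1e-12 or abs(ref.phi - 1.0) > 1e-12:
            raise ValueError("reference group must have kappa = 0, phi = 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing rate must be in [0, 1)")

    def total_n(self) -> int:
        return int(sum(self.n_per_group[g] for g in self.groups))

    def copy(self) -> "PopulationSpec":
        new = copy.copy(self)
        new.params = {g: self.params[g].copy() for g in self.groups}
        new.groups = list(self.groups)
        new.n_per_group = dict(self.n_per_group)
        new.provenance = list(self.provenance)
        return new


@dataclass
class OrdinalDataset:
    """Item responses (NaN = missing), group labels, optional cluster IDs."""

    data: np.ndarray  # (n, K) float, categories 1..C, NaN missing
    groups: np.ndarray  # (n,) labels
    n_categories: int
    item_names: list
    clusters: np.ndarray | None = None
    seed: int | None = None
    eta: np.ndarray | None = None  # latent scores (kept for diagnostics)

    @property
    def n_items(self) -> int:
        return self.data.shape[1]

    def group_labels(self) -> list:
        seen: dict = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def group_data(self, label) -> np.ndarray:
        return self.data[self.groups == label]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=self.item_names)
        df["group"] = self.groups
        if self.clusters is not None:
            df["cluster"] = self.clusters
        return df


def _default_group_params(K: int, C: int, loadings, thresholds, resid_corr) -> GroupParams:
    lam = np.asarray(loadings, dtype=float)
    tau = np.asarray(thresholds, dtype=float)
    theta = 1.0 - lam**2  # delta scaling: Var(y*) = 1 with phi = 1
    return GroupParams(
        kappa=0.0,
        phi=1.0,
        loadings=lam,
        intercepts=np.zeros(K),
        thresholds=tau,
        theta=theta,
        resid_corr=dict(resid_corr),
    )


def build_spec(
    n_groups: int | None = None,
    group_labels: list | None = None,
    n_per_group: int | dict = 2000,
    n_items: int = 6,
    n_categories: int = 4,
    loadings=None,
    thresholds=None,
    resid_corr: dict | None = None,
    kappa: dict | list | None = None,
    phi: dict | list | None = None,
    missing_rate: float = DEFAULT_MISSING,
    missing_mode: str = "mcar",
    mar_slope: float = 1.0,
    n_clusters: int = 0,
    cluster_icc: float = 0.0,
    year_gender_age: tuple | None = None,
) -> PopulationSpec:
    """Build a validated :class:`PopulationSpec`.

    With no arguments beyond group count, every group shares the same
    measurement parameters (a fully invariant DGP).  ``year_gender_age``
    takes ``(n_years, n_genders, n_ages)`` and builds the full label grid.

    Parameters omitted fall back to the documented defaults: K = 6 items,
    C = 4 categories, loadings 0.65-0.86, kappa = 0, phi = 1, the items-3/4
    correlated residual, and 5.5% MCAR item-level missingness.
    """
    K, C = n_items, n_categories
    if year_gender_age is not None:
        ny, ngen, nage = year_gender_age
        group_labels = [
            f"y{2010 + y}_g{g + 1}_a{a + 1}"
            for y in range(ny)
            for g in range(ngen)
            for a in range(nage)
        ]
    if group_labels is None:
        if n_groups is None:
            n_groups = 1
        group_labels = [f"g{i + 1}" for i in range(n_groups)]
    if loadings is None:
        loadings = DEFAULT_LOADINGS[:K] if K <= 6 else np.full(K, 0.75)
    loadings = np.asarray(loadings, dtype=float)
    if loadings.size == 1:
        loadings = np.full(K, float(loadings))
    if thresholds is None:
        if K <= 6 and C == 4:
            thresholds = DEFAULT_THRESHOLDS[:K]
        else:
            base = np.linspace(-1.0, 1.5, C - 1)
            thresholds = np.tile(base, (K, 1))
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim == 1:
        thresholds = np.tile(thresholds, (K, 1))
    if resid_corr is None:
        resid_corr = (
            {DEFAULT_RESID_PAIR: DEFAULT_RESID_RHO} if (K == 6 and C == 4) else {}
        )

    base = _default_group_params(K, C, loadings, thresholds, resid_corr)
    params = {}
    for i, g in enumerate(group_labels):
        gp = base.copy()
        if kappa is not None:
            gp.kappa = float(kappa[g] if isinstance(kappa, dict) else kappa[i])
        if phi is not None:
            gp.phi = float(phi[g] if isinstance(phi, dict) else phi[i])
        params[g] = gp
    if isinstance(n_per_group, dict):
        npg = {g: int(n_per_group[g]) for g in group_labels}
    else:
        npg = {g: int(n_per_group) for g in group_labels}
    spec = PopulationSpec(
        n_items=K,
        n_categories=C,
        groups=list(group_labels),
        params=params,
        n_per_group=npg,
        missing_rate=float(missing_rate),
        missing_mode=missing_mode,
        mar_slope=float(mar_slope),
        n_clusters=int(n_clusters),
        cluster_icc=float(cluster_icc),
    )
    spec.validate()
    return spec


def inject_noninvariance(
    spec: PopulationSpec,
    item: int,
    parameter: str,
    shift,
    target_groups,
) -> PopulationSpec:
    """Return a new spec with ``parameter`` of ``item`` shifted in ``target_groups``.

    ``parameter`` is one of ``"threshold"`` (location shift of all C-1
    thresholds, or a per-threshold vector), ``"loading"`` or ``"intercept"``.
    An intercept shift on nu is distributionally equivalent to shifting all
    of the item's thresholds by the opposite amount; both entry points exist.
    """
    if parameter not in {"threshold", "loading", "intercept"}:
        raise ValueError(f"unknown parameter kind {parameter!r}")
    if not (0 <= item < spec.n_items):
        raise ValueError(f"item index {item} out of range")
    for g in target_groups:
        if g not in spec.params:
            raise ValueError(f"unknown group {g!r}")
    new = spec.copy()
    for g in target_groups:
        p = new.params[g]
        if parameter == "loading":
            p.loadings[item] += float(shift)
            if p.loadings[item] <= 0:
                raise ValueError(f"loading shift makes loading <= 0 (item {item + 1}, group {g!r})")
        elif parameter == "intercept":
            p.intercepts[item] += float(shift)
        else:
            vec = np.asarray(shift, dtype=float)
            if vec.ndim == 0:
                vec = np.full(spec.n_categories - 1, float(vec))
            p.thresholds[item] = p.thresholds[item] + vec
            if np.any(np.diff(p.thresholds[item]) <= 0):
                raise ValueError(
                    f"threshold shift breaks monotonicity (item {item + 1}, group {g!r})"
                )
    new.provenance.append(
        {
            "item": item,
            "parameter": parameter,
            "shift": np.asarray(shift, dtype=float).tolist(),
            "groups": list(target_groups),
        }
    )
    return new


def simulate_dataset(spec: PopulationSpec, seed: int) -> OrdinalDataset:
    """Draw an :class:`OrdinalDataset` from the spec.

    One root seed spawns an independent child stream per group (keyed by the
    group's position), so adding a group never perturbs the draws of the
    others.  Same spec + seed is bit-identical.
    """
    spec.validate()
    K, C = spec.n_items, spec.n_categories
    blocks, labels, cluster_col, etas = [], [], [], []
    for gi, g in enumerate(spec.groups):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(gi,)))
        p = spec.params[g]
        n = spec.n_per_group[g]
        if spec.n_clusters > 0 and spec.cluster_icc > 0:
            icc = spec.cluster_icc
            cl = rng.integers(0, spec.n_clusters, size=n)
            u = rng.normal(0.0, np.sqrt(icc * p.phi), size=spec.n_clusters)
            eta = p.kappa + u[cl] + rng.normal(0.0, np.sqrt((1 - icc) * p.phi), size=n)
            cluster_col.append(np.char.add(f"{g}_c", cl.astype(str)))
        else:
            eta = rng.normal(p.kappa, np.sqrt(p.phi), size=n)
            cluster_col.append(np.full(n, "", dtype=object))
        cov = p.residual_cov()
        L = np.linalg.cholesky(cov)
        eps = rng.standard_normal((n, K)) @ L.T
        ystar = p.intercepts + eta[:, None] * p.loadings + eps
        y = np.ones((n, K)) + (ystar[:, :, None] > p.thresholds[None, :, :]).sum(axis=2)
        if spec.missing_rate > 0:
            if spec.missing_mode == "mar":
                # logistic in eta, intercept solved so the marginal rate matches
                from scipy.optimize import brentq
                from scipy.special import expit

                s = spec.mar_slope
                z = s * (eta - p.kappa) / np.sqrt(p.phi)
                a = brentq(
                    lambda a0: expit(a0 + z).mean() - spec.missing_rate, -20, 20
                )
                pm = expit(a + z)[:, None]
            else:
                pm = spec.missing_rate
            miss = rng.random((n, K)) < pm
            y = np.where(miss, np.nan, y)
        blocks.append(y)
        labels.append(np.full(n, g, dtype=object))
        etas.append(eta)
    clusters = np.concatenate(cluster_col)
    has_clusters = spec.n_clusters > 0 and spec.cluster_icc > 0
    return OrdinalDataset(
        data=np.concatenate(blocks),
        groups=np.concatenate(labels),
        n_categories=C,
        item_names=[f"item_{j + 1}" for j in range(K)],
        clusters=clusters if has_clusters else None,
        seed=seed,
        eta=np.concatenate(etas),
    )
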