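"""Factor-count assessment: parallel analysis and the eigenvalue-ratio rule.

Parallel analysis compares the eigenvalues of the observed item correlation
matrix with a tail percentile (default 95th) of eigenvalues from reference
datasets of identical dimensions.  The default reference scheme permutes
each observed column independently, preserving the ordinal margins; an
independent-multinomial scheme is available.  Factors are retained
sequentially while the observed eigenvalue exceeds its reference percentile.
A first-to-second eigenvalue ratio above 4 is taken as supporting essential
unidimensionality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .polychoric import DegenerateItemError, _batch_polychoric, estimate_thresholds

__all__ = ["DimensionalityReport", "parallel_analysis"]


@dataclass
class DimensionalityReport:
    eigenvalues: np.ndarray
    reference_eigenvalues: np.ndarray  # per-component percentile
    n_retained: int
    ratio_first_second: float
    unidimensional: bool  # ratio > 4
    n_sets: int
    percentile: float
    correlation: str
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "reference_eigenvalues": self.reference_eigenvalues.tolist(),
            "n_retained": self.n_retained,
            "ratio_first_second": self.ratio_first_second,
            "unidimensional": self.unidimensional,
            "n_sets": self.n_sets,
            "percentile": self.percentile,
            "correlation": self.correlation,
            "seed": self.seed,
        }

    def scree_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "component": np.arange(1, self.eigenvalues.size + 1),
                "observed": self.eigenvalues,
                "reference": self.reference_eigenvalues,
            }
        )


def _corr_matrix(X: np.ndarray, C: int, method: str) -> np.ndarray:
    """Pairwise-complete correlation matrix (polychoric or Pearson)."""
    n, K = X.shape
    obs = ~np.isnan(X)
    if method == "pearson":
        import pandas as pd

        return pd.DataFrame(X).corr(min_periods=2).to_numpy()
    taus = []
    for j in range(K):
        counts = np.bincount(X[obs[:, j], j].astype(int), minlength=C + 1)[1:]
        tau_j = estimate_thresholds(counts)
        if tau_j.size != C - 1:
            raise DegenerateItemError(f"item {j + 1}: empty category")
        taus.append(tau_j)
    tau = np.vstack(taus)
    pairs = [(j, k) for j in range(K) for k in range(j + 1, K)]
    tables = np.zeros((len(pairs), C, C))
    for q, (j, k) in enumerate(pairs):
        both = obs[:, j] & obs[:, k]
        idx = (X[both, j].astype(int) - 1) * C + (X[both, k].astype(int) - 1)
        tables[q] = np.bincount(idx, minlength=C * C).reshape(C, C)
        if np.any(tables[q].sum(axis=1) == 0) or np.any(tables[q].sum(axis=0) == 0):
            raise DegenerateItemError(f"pair ({j + 1},{k + 1}): zero margin")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhos = _batch_polychoric(tables, tau[[j for j, _ in pairs]], tau[[k for _, k in pairs]])
    P = np.eye(K)
    for q, (j, k) in enumerate(pairs):
        P[j, k] = P[k, j] = rhos[q]
    return P


def parallel_analysis(
    data,
    group=None,
    n_sets: int = 200,
    percentile: float = 95.0,
    correlation: str = "polychoric",
    reference: str = "permute",
    seed: int | None = None,
    min_rows: int = 50,
) -> DimensionalityReport:
    """Parallel analysis of one dataset (or one group slice).

    ``data`` is an OrdinalDataset, an ndarray (categories 1..C, NaN missing)
    or a DataFrame of item columns.  ``reference`` is ``"permute"``
    (column-wise permutation of the observed data, margin-preserving) or
    ``"multinomial"`` (independent draws from each item's margin).  If the
    polychoric matrix fails on a reference set, that set falls back to
    Pearson with a warning.
    """
    import pandas as pd

    if hasattr(data, "data"):
        X = data.group_data(group) if group is not None else data.data
        C = data.n_categories
    elif isinstance(data, pd.DataFrame):
        X = data.to_numpy(dtype=float)
        C = int(np.nanmax(X))
    else:
        X = np.asarray(data, dtype=float)
        C = int(np.nanmax(X))
    n, K = X.shape
    if n < min_rows:
        raise ValueError(f"group has {n} rows; parallel analysis floor is {min_rows}")

    R = _corr_matrix(X, C, correlation)
    eig = np.sort(np.linalg.eigvalsh(R))[::-1]

    rng = np.random.default_rng(seed)
    ref_eigs = np.empty((n_sets, K))
    obs = ~np.isnan(X)
    for s in range(n_sets):
        if reference == "permute":
            Xr = np.column_stack([rng.permutation(X[:, j]) for j in range(K)])
        elif reference == "multinomial":
            Xr = np.empty_like(X)
            for j in range(K):
                vals = X[obs[:, j], j]
                Xr[:, j] = rng.choice(vals, size=n, replace=True)
        else:
            raise ValueError(f"unknown reference scheme {reference!r}")
        try:
            Rr = _corr_matrix(Xr, C, correlation)
        except (DegenerateItemError, np.linalg.LinAlgError):
            warnings.warn("polychoric failed on a reference set; Pearson fallback")
            Rr = _corr_matrix(Xr, C, "pearson")
        ref_eigs[s] = np.sort(np.linalg.eigvalsh(Rr))[::-1]
    ref_pct = np.percentile(ref_eigs, percentile, axis=0)

    n_retained = 0
    for comp in range(K):
        if eig[comp] > ref_pct[comp]:
            n_retained += 1
        else:
            break
    ratio = float(eig[0] / eig[1]) if eig[1] > 0 else np.inf
    return DimensionalityReport(
        eigenvalues=eig,
        reference_eigenvalues=ref_pct,
        n_retained=n_retained,
        ratio_first_second=ratio,
        unidimensional=bool(ratio > 4.0),
        n_sets=n_sets,
        percentile=percentile,
        correlation=correlation,
        seed=seed,
    )
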