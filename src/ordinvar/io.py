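"""Survey-table I/O and the end-to-end analysis pipeline.

The pipeline chains dimensionality checking, the invariance ladder, effect
sizes, latent trends, the freed-vs-fixed sensitivity comparison, clustering
ICCs and dynamic fit-index cutoffs, and writes a machine-readable manifest
plus delimited tables.  Identical config + seed gives an identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dimensionality import parallel_analysis
from .effectsize import dmacs_table
from .invariance import LadderConfig, run_ladder
from .model import OrdinalFactorModel, omega_reliability
from .simulate import OrdinalDataset, build_spec, simulate_dataset
from .trends import NotComparableError, descriptives, freed_vs_fixed, icc_oneway, latent_trend

__all__ = [
    "PipelineConfig",
    "read_survey_table",
    "write_survey_table",
    "run_pipeline",
    "write_report",
]


def write_survey_table(dataset: OrdinalDataset, path) -> None:
    """Write a dataset as delimited text; missing cells are empty fields."""
    df = dataset.to_frame()
    df.to_csv(path, index=False, na_rep="")


def read_survey_table(
    path,
    item_columns=None,
    group_col: str = "group",
    cluster_col: str = "cluster",
    n_categories: int | None = None,
) -> OrdinalDataset:
    """Read a delimited survey table into an :class:`OrdinalDataset`.

    Item categories must be integer-coded 1..C; out-of-range or non-integer
    codes raise a validation error naming the offending cell.
    """
    df = pd.read_csv(path)
    if item_columns is None:
        item_columns = [c for c in df.columns if c.startswith("item_")]
    if not item_columns:
        raise ValueError("no item columns found (expected names like 'item_1')")
    X = df[item_columns].to_numpy(dtype=float)
    C = int(n_categories) if n_categories else int(np.nanmax(X))
    finite = ~np.isnan(X)
    bad = finite & ((X < 1) | (X > C) | (X != np.round(X)))
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid category value {X[r, c]!r} in row {r}, column {item_columns[c]!r} "
            f"(expected integers 1..{C})"
        )
    groups = (
        df[group_col].to_numpy()
        if group_col in df.columns
        else np.full(len(df), "all", dtype=object)
    )
    for g, cnt in pd.Series(groups).value_counts().items():
        if cnt == 0:
            raise ValueError(f"empty group {g!r}")
    clusters = df[cluster_col].to_numpy() if cluster_col in df.columns else None
    return OrdinalDataset(
        data=X,
        groups=groups,
        n_categories=C,
        item_names=list(item_columns),
        clusters=clusters,
    )


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    input_path: str | None = None
    synthetic: dict | None = None  # kwargs for build_spec
    item_columns: list | None = None
    group_col: str = "group"
    reference_group: object = None
    resid_pairs: list = field(default_factory=lambda: [[2, 3]])
    ladder: dict = field(default_factory=dict)
    run_dimensionality: bool = True
    run_dmacs: bool = True
    run_freed_vs_fixed: bool = True
    run_icc: bool = False
    run_dfi: bool = False
    parallel_sets: int = 200
    dfi_reps: int = 100
    seed: int = 0
    outdir: str = "ordinvar_out"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        cfg = yaml.safe_load(text)
        return cls(**cfg)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def _load_dataset(config: PipelineConfig) -> OrdinalDataset:
    if config.input_path:
        return read_survey_table(
            config.input_path,
            item_columns=config.item_columns,
            group_col=config.group_col,
        )
    spec = build_spec(**(config.synthetic or {"n_groups": 4}))
    return simulate_dataset(spec, seed=config.seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns the report bundle (a nested dict).

    Stage order: dimensionality -> invariance ladder -> (d_MACS, trends,
    freed-vs-fixed, ICC, DFI as toggled).  Any stage error is re-raised with
    the stage name; completed stages are preserved in the partial bundle.
    """
    bundle: dict = {"config": config.to_dict(), "seed": config.seed, "stages": {}}
    stage = "load"
    try:
        dataset = _load_dataset(config)
        bundle["stages"]["load"] = {
            "n_rows": int(dataset.data.shape[0]),
            "n_items": dataset.n_items,
            "groups": {str(g): int((dataset.groups == g).sum()) for g in dataset.group_labels()},
            "n_missing_cells": int(np.isnan(dataset.data).sum()),
        }
        bundle["tables"] = {"descriptives": descriptives(dataset)}

        if config.run_dimensionality:
            stage = "dimensionality"
            rep = parallel_analysis(
                dataset, n_sets=config.parallel_sets, seed=config.seed
            )
            bundle["stages"]["dimensionality"] = rep.to_dict()
            bundle["tables"]["scree"] = rep.scree_table()

        stage = "invariance"
        resid_pairs = [tuple(p) for p in config.resid_pairs]
        model = OrdinalFactorModel(dataset, resid_pairs=resid_pairs)
        ladder = run_ladder(None, model=model, config=LadderConfig(**config.ladder))
        bundle["stages"]["invariance"] = ladder.to_dict()
        bundle["tables"]["mi_table"] = ladder.summary_table()

        if ladder.latent_means_comparable:
            stage = "trends"
            ref = config.reference_group
            trend = latent_trend(ladder, ref)
            bundle["tables"]["latent_trend"] = trend.to_frame()
            bundle["stages"]["trends"] = {"variant": trend.variant}

            if config.run_dmacs:
                stage = "dmacs"
                ref_idx = 0 if ref is None else ref
                bundle["tables"]["dmacs"] = dmacs_table(ladder.final, ref_idx)

            freed = sorted(ladder.freed.get("intercepts", []))
            if config.run_freed_vs_fixed and freed:
                stage = "freed_vs_fixed"
                cmp = freed_vs_fixed(model, freed, reference_group=ref)
                bundle["tables"]["trend_freed"] = cmp["freed"].to_frame()
                bundle["tables"]["trend_fixed"] = cmp["fixed"].to_frame()
                bundle["stages"]["freed_vs_fixed"] = {
                    "freed_items": freed,
                    "max_abs_difference": cmp["max_abs_difference"],
                }
        else:
            bundle["stages"]["trends"] = {
                "status": f"latent means not comparable (achieved {ladder.achieved!r})"
            }

        if config.run_icc and dataset.clusters is not None:
            stage = "icc"
            iccs = {}
            for j, name in enumerate(dataset.item_names):
                iccs[name] = icc_oneway(dataset.data[:, j], dataset.clusters)
            bundle["stages"]["icc"] = iccs

        if config.run_dfi:
            stage = "dfi"
            from .dfi import dfi_cutoffs

            pooled = OrdinalFactorModel(
                OrdinalDataset(
                    data=dataset.data,
                    groups=np.full(dataset.data.shape[0], "all", dtype=object),
                    n_categories=dataset.n_categories,
                    item_names=dataset.item_names,
                ),
                resid_pairs=resid_pairs,
            )
            fit = pooled.fit(level="configural")
            cuts = dfi_cutoffs(fit, reps=config.dfi_reps, seed=config.seed)
            bundle["stages"]["dfi"] = cuts.to_dict()
            bundle["stages"]["dfi"]["observed_acceptable_level1"] = bool(
                cuts.acceptable(fit, level=1)
            )
            bundle["stages"]["dfi"]["pooled_omega"] = omega_reliability(fit)
    except NotComparableError:
        raise
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return bundle


def write_report(bundle: dict, outdir) -> list:
    """Write the bundle: JSON manifest + one CSV per table.

    Returns the list of written paths; the manifest names every table file.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    tables = bundle.get("tables", {})
    manifest = {k: v for k, v in bundle.items() if k != "tables"}
    manifest["tables"] = {}
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        manifest["tables"][name] = p.name
        written.append(p)
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=_json_default, sort_keys=True))
    written.append(mpath)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    return str(obj)
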