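"""End-to-end pipeline: files in, tidy result tables and a manifest out.

``run_pipeline`` chains the stages — read and validate, trait annotation,
extinction magnitudes (plus interval rate estimators when the stage
sequence allows), size reduction, and the selectivity regressions — and
writes ``extinction.csv``, ``size_reduction.csv``, ``regressions.csv``,
optionally ``interval_rates.csv``, a reject report, and a JSON run
manifest (config hash, seed, package versions, row counts). The same
config and seed give bit-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    DataError,
    StageSequence,
    build_genus_summaries,
    attach_geographic_ranges,
    read_occurrences,
    read_sizes,
)
from .extinction import (
    estimates_to_frame,
    interval_rates,
    proportional_extinction,
    stratified_comparison,
    STRATA_DESIGNS,
)
from .selectivity import (
    ALL_COVARIATES,
    encode_design,
    logistic_fit,
    ols_fit,
    selectivity_report,
)
from .size_reduction import results_to_frame, size_selectivity_table
from .traits import (
    assign_traits,
    capacity_values,
    apply_capacities,
    default_trait_table,
    lookup,
    read_trait_table,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """Validated run configuration (YAML-loadable; CLI flags override keys)."""

    occurrences: str
    output_dir: str
    sizes: str | None = None
    traits: str | None = None
    stages: Sequence[str] = ("Changhsingian", "Induan")
    boundary_index: int = 0
    cohort: str = "boundary_interval"
    geo_range_method: str = "n_localities"
    ci_method: str = "clopper_pearson"
    ci_level: float = 0.95
    capacity_mode: str = "ordinal"  # ordinal | custom
    custom_capacities: Mapping[str, float] | None = None
    bootstrap_B: int = 1000
    seed: int = 0
    strict: bool = False
    covariates: Sequence[str] = ALL_COVARIATES
    clade_effects: bool = False
    column_map: Mapping[str, str] | None = None
    size_column_map: Mapping[str, str] | None = None

    def stage_sequence(self) -> StageSequence:
        return StageSequence(tuple(self.stages), self.boundary_index)


_SCHEMA: dict[str, type | tuple[type, ...]] = {
    "occurrences": str,
    "output_dir": str,
    "sizes": (str, type(None)),
    "traits": (str, type(None)),
    "stages": (list, tuple),
    "boundary_index": int,
    "cohort": str,
    "geo_range_method": str,
    "ci_method": str,
    "ci_level": float,
    "capacity_mode": str,
    "custom_capacities": (dict, type(None)),
    "bootstrap_B": int,
    "seed": int,
    "strict": bool,
    "covariates": (list, tuple),
    "clade_effects": bool,
    "column_map": (dict, type(None)),
    "size_column_map": (dict, type(None)),
}


def load_config(path: str | Path, overrides: Mapping | None = None) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are errors."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise DataError(f"{path}: config must be a mapping")
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise DataError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("occurrences", "output_dir"):
        if key not in raw:
            raise DataError(f"{path}: missing required key {key!r}")
    for key, expected in _SCHEMA.items():
        if key in raw and raw[key] is not None:
            if key == "ci_level" and isinstance(raw[key], int):
                raw[key] = float(raw[key])
            if not isinstance(raw[key], expected):
                raise DataError(f"{path}: key {key!r} must be {expected}, got {type(raw[key])}")
    return PipelineConfig(**raw)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return len(df)


@dataclass
class PipelineResult:
    """In-memory bundle of every table the pipeline wrote."""

    extinction: pd.DataFrame
    size_reduction: pd.DataFrame | None
    regressions: pd.DataFrame
    interval_rates: pd.DataFrame | None
    manifest: dict
    notes: list[str] = field(default_factory=list)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis described by ``config``. See module docstring."""
    stages = config.stage_sequence()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    notes: list[str] = []

    # --- stage: data_model -------------------------------------------------
    try:
        occ = read_occurrences(
            config.occurrences, stages, config.column_map, strict=config.strict
        )
        summaries = build_genus_summaries(occ.records, stages, cohort=config.cohort)
        summaries = attach_geographic_ranges(
            summaries, occ.records, method=config.geo_range_method
        )
    except DataError as exc:
        raise DataError(f"[data_model] {exc}") from exc

    # --- stage: trait_assignment ------------------------------------------
    try:
        table = read_trait_table(config.traits) if config.traits else default_trait_table()
        if config.capacity_mode == "custom":
            table = apply_capacities(
                table, capacity_values("custom", config.custom_capacities)
            )
        elif config.capacity_mode != "ordinal":
            raise DataError(f"capacity_mode must be ordinal/custom, got {config.capacity_mode!r}")
        annotated, dropped = assign_traits(summaries, table, strict=config.strict)
        if dropped:
            notes.append(f"{len(dropped)} genera dropped (unmapped clades)")
    except DataError as exc:
        raise DataError(f"[trait_assignment] {exc}") from exc

    # --- stage: extinction_metrics -----------------------------------------
    try:
        ests = []
        for group_by in ("clade", "protein_group", "circulatory"):
            for e in proportional_extinction(
                annotated, group_by, config.ci_level, config.ci_method
            ):
                ests.append((group_by, e))
        carbonate = [s for s in annotated if s.traits.is_carbonate]
        for e in proportional_extinction(
            carbonate, "protein_group", config.ci_level, config.ci_method
        ):
            ests.append(("carbonate_protein_group", e))
        for design in STRATA_DESIGNS:
            for e in stratified_comparison(annotated, design, config.ci_level, config.ci_method):
                ests.append((design, e))
        ext_frames = []
        for grouping, e in ests:
            row = estimates_to_frame([e])
            row.insert(0, "grouping", grouping)
            ext_frames.append(row)
        extinction_df = pd.concat(ext_frames, ignore_index=True)

        rates_df = None
        if stages.supports_rate_estimators:
            parts = [interval_rates(annotated, stages, group="all")]
            for g in ("diffusion", "hemerythrin", "hemocyanin", "hemoglobin"):
                members = [s for s in annotated if s.traits.protein_group == g]
                if members:
                    try:
                        parts.append(interval_rates(members, stages, group=g))
                    except DataError as exc:
                        notes.append(f"rate estimators skipped for {g}: {exc}")
            rates_df = pd.concat(parts, ignore_index=True)
        else:
            notes.append(
                "stage sequence has < 4 intervals: per-capita/three-timer/"
                "gap-filler rates not computable; proportional extinction only"
            )
    except DataError as exc:
        raise DataError(f"[extinction_metrics] {exc}") from exc

    # --- stage: size_reduction ---------------------------------------------
    size_df = None
    size_results_by_group: dict[str, float] = {}
    if config.sizes:
        try:
            sizes = read_sizes(config.sizes, stages, config.size_column_map, strict=config.strict)
            frames = []
            for label, kwargs in (
                ("clade", dict(group_by="clade")),
                ("protein_group", dict(group_by="protein_group")),
                ("carbonate_protein_group", dict(group_by="protein_group", carbonate_only=True)),
                (
                    "hemocyanin_by_circulatory",
                    dict(group_by="circulatory", restrict=("protein_group", "hemocyanin")),
                ),
                (
                    "open_circulatory_by_protein",
                    dict(group_by="protein_group", restrict=("circulatory", "open")),
                ),
            ):
                res = size_selectivity_table(
                    sizes.records, table, stages,
                    B=config.bootstrap_B, seed=config.seed, **kwargs,
                )
                if res:
                    df = results_to_frame(res)
                    df.insert(0, "grouping", label)
                    frames.append(df)
                    if label == "protein_group":
                        size_results_by_group = {r.group: r.reduction_pct for r in res}
            size_df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        except DataError as exc:
            raise DataError(f"[size_reduction] {exc}") from exc

    # --- stage: selectivity_models ------------------------------------------
    try:
        fits = []
        clade_ests = [e for g, e in ests if g == "clade"]
        cap_by_clade = {t.clade: t.o2_capacity for t in table}
        x = [cap_by_clade[lookup(table, e.group).clade] for e in clade_ests]
        y = [e.value for e in clade_ests]
        if len(set(x)) > 1 and len(x) >= 3:
            fits.append(ols_fit(x, y, label="ols_extinction_vs_capacity_clades"))
        carb_ests = [e for g, e in ests if g == "carbonate_protein_group"]
        caps = capacity_values()  # group -> capacity for group-level points
        if config.capacity_mode == "custom":
            caps = capacity_values("custom", config.custom_capacities)
        if len(carb_ests) >= 3:
            fits.append(
                ols_fit(
                    [caps[e.group] for e in carb_ests],
                    [e.value for e in carb_ests],
                    label="ols_extinction_vs_capacity_carbonate",
                )
            )
        if size_results_by_group and len(size_results_by_group) >= 3:
            groups = sorted(size_results_by_group)
            fits.append(
                ols_fit(
                    [caps[g] for g in groups],
                    [size_results_by_group[g] for g in groups],
                    label="ols_size_reduction_vs_capacity",
                )
            )
        for mode in ("continuous", "categorical"):
            X, yv = encode_design(
                annotated, config.covariates, capacity_mode=mode,
                clade_effects=config.clade_effects,
            )
            fits.append(logistic_fit(X, yv, label=f"logistic_{mode}_capacity"))
        regressions_df = selectivity_report(fits)
    except DataError as exc:
        raise DataError(f"[selectivity_models] {exc}") from exc

    # --- outputs -------------------------------------------------------------
    counts = {
        "occurrence_rows": len(occ.records),
        "occurrence_rejects": len(occ.rejects),
        "genera": len(summaries),
        "genera_annotated": len(annotated),
        "extinction_rows": _write_csv(extinction_df, outdir / "extinction.csv"),
        "regression_rows": _write_csv(regressions_df, outdir / "regressions.csv"),
    }
    if rates_df is not None:
        counts["interval_rate_rows"] = _write_csv(rates_df, outdir / "interval_rates.csv")
    if size_df is not None:
        counts["size_rows"] = _write_csv(size_df, outdir / "size_reduction.csv")
    if occ.rejects:
        rej = pd.DataFrame([{"line": r.line, "reason": r.reason} for r in occ.rejects])
        _write_csv(rej, outdir / "rejects.csv")

    manifest = {
        "package": "paleoselect",
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "stages": list(stages.names),
        "boundary_index": stages.boundary_index,
        "counts": counts,
        "notes": notes,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        extinction=extinction_df,
        size_reduction=size_df,
        regressions=regressions_df,
        interval_rates=rates_df,
        manifest=manifest,
        notes=notes,
    )
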