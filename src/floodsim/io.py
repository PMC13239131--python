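"""Configuration parsing, result serialization and run manifests.

All outputs are plain CSV/JSON: the data volumes are tiny and diff-able
text aids review and reproducibility. Collapse probabilities are written at
full float precision and are exact rationals (n_collapsed / n_reps), so a
round-trip through ``cells.csv`` is lossless.
"""

from __future__ import annotations

import dataclasses
import json
import math
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .engine import SimulationResult
from .params import ModelParams, ParameterError
from .sweep import (
    CellResult,
    SweepGrid,
    cells_from_dataframe,
    cells_to_dataframe,
    heatmap_matrix,
)
from .threshold import RegimeReport, ThresholdSummary

__all__ = [
    "parse_config",
    "trajectory_frame",
    "write_trajectory",
    "write_cells",
    "read_cells",
    "write_heatmaps",
    "write_thresholds",
    "write_results",
    "write_manifest",
]

_SWEEP_KEYS = {
    "m_values",
    "penalty_values",
    "paternity_values",
    "n_replicates",
    "base_seed",
}

CELLS_COLUMNS = [
    "m",
    "penalty",
    "paternity",
    "n_reps",
    "n_collapsed",
    "collapse_probability",
    "n_extinct",
]


def parse_config(path: str | Path | None) -> tuple[ModelParams, SweepGrid]:
    """Read a YAML config into validated (ModelParams, SweepGrid).

    Keys mirror :class:`ModelParams` field names exactly, plus the sweep
    keys ``m_values``, ``penalty_values``, ``paternity_values``,
    ``n_replicates`` and ``base_seed``. Unknown keys are an error (typo
    safety); an absent or empty file yields the full documented defaults
    (K = 1000, 100 generations, 50 replicates, m grid 0.05-0.40).
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ParameterError(
                f"config must be a mapping of parameter names to values, "
                f"got {type(loaded).__name__}"
            )
        raw = loaded
    model_fields = set(ModelParams.field_names())
    unknown = sorted(set(raw) - model_fields - _SWEEP_KEYS)
    if unknown:
        raise ParameterError(
            f"unknown config key(s): {', '.join(unknown)}; valid keys are "
            f"{sorted(model_fields | _SWEEP_KEYS)}"
        )
    model_kwargs = {k: v for k, v in raw.items() if k in model_fields}
    sweep_kwargs = {k: v for k, v in raw.items() if k in _SWEEP_KEYS}
    params = ModelParams(**model_kwargs)
    grid = SweepGrid(base_params=params, **sweep_kwargs)
    return params, grid


def trajectory_frame(
    result: SimulationResult,
    replicate: int | None = None,
    condition: dict | None = None,
) -> pd.DataFrame:
    """Tidy per-generation census frame (one row per generation)."""
    rows = {
        "generation": [c.generation for c in result.trajectory],
        "n": [c.pop_size for c in result.trajectory],
        "count_W1": [c.counts["W1"] for c in result.trajectory],
        "count_W2": [c.counts["W2"] for c in result.trajectory],
        "count_L1": [c.counts["L1"] for c in result.trajectory],
        "count_L2": [c.counts["L2"] for c in result.trajectory],
        "extinct": [c.pop_size == 0 for c in result.trajectory],
    }
    frame = pd.DataFrame(rows)
    if replicate is not None:
        frame.insert(0, "replicate", replicate)
    if condition:
        for i, (key, value) in enumerate(condition.items()):
            frame.insert(i, key, value)
    return frame


def write_trajectory(result: SimulationResult, path: str | Path, **kwargs) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trajectory_frame(result, **kwargs).to_csv(path, index=False)
    return path


def write_cells(results: list[CellResult], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = cells_to_dataframe(results)[CELLS_COLUMNS]
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_cells(path: str | Path) -> list[CellResult]:
    return cells_from_dataframe(pd.read_csv(path))


def write_heatmaps(results: list[CellResult], out_dir: str | Path) -> list[Path]:
    """One dense (penalty x m) collapse-probability matrix per paternity level."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for paternity in sorted({c.paternity for c in results}):
        matrix = heatmap_matrix(results, paternity)
        path = out_dir / f"heatmap_{paternity}.csv"
        matrix.to_csv(path, float_format="%.17g")
        paths.append(path)
    return paths


def _regime_report_dict(report: RegimeReport) -> dict:
    return {
        "penalty": report.condition[0],
        "paternity": report.condition[1],
        "nonmonotonic": report.nonmonotonic,
        "m_c": report.m_c,
        "max_probability": report.max_probability,
        "flagged": [
            {"m": m, "drop": drop, "two_se": two_se}
            for (m, drop, two_se) in report.flagged
        ],
        "regimes": {f"{m:g}": label for m, label in report.regimes.items()},
    }


def write_thresholds(
    summary: ThresholdSummary,
    out_dir: str | Path,
    reports: list[RegimeReport] | None = None,
    m_max_fit: float | None = None,
) -> tuple[Path, Path]:
    """Write ``thresholds.csv`` and ``summary.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        {
            "penalty": [e.condition[0] for e in summary.estimates],
            "paternity": [e.condition[1] for e in summary.estimates],
            "m_c": [e.m_c for e in summary.estimates],
            "slope": [e.slope for e in summary.estimates],
            "method": [e.method for e in summary.estimates],
            "ci_low": [e.ci_low for e in summary.estimates],
            "ci_high": [e.ci_high for e in summary.estimates],
        }
    )
    csv_path = out_dir / "thresholds.csv"
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    payload = {
        "mean_m_c": summary.mean_m_c,
        "sd_m_c": summary.sd_m_c,
        "n_conditions": len(summary.estimates),
        "dispersion_semantics": (
            "sd_m_c is the sample standard deviation of per-condition m_c "
            "estimates across mating-penalty and mating-structure conditions"
        ),
    }
    if m_max_fit is not None:
        payload["m_max_fit"] = m_max_fit
    if reports is not None:
        payload["regime_reports"] = [_regime_report_dict(r) for r in reports]
        payload["any_nonmonotonic"] = any(r.nonmonotonic for r in reports)
    json_path = out_dir / "summary.json"
    json_path.write_text(json.dumps(_jsonable(payload), indent=2) + "\n")
    return csv_path, json_path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def write_results(
    cells: list[CellResult],
    out_dir: str | Path,
    grid: SweepGrid | None = None,
    summary: ThresholdSummary | None = None,
    reports: list[RegimeReport] | None = None,
    m_max_fit: float | None = None,
) -> list[Path]:
    """Write the full file set for a sweep (and optional threshold analysis):
    cells.csv, heatmap matrices, thresholds.csv + summary.json, manifest."""
    out_dir = Path(out_dir)
    written = [write_cells(cells, out_dir / "cells.csv")]
    written.extend(write_heatmaps(cells, out_dir))
    if summary is not None:
        written.extend(
            write_thresholds(summary, out_dir, reports=reports, m_max_fit=m_max_fit)
        )
    params = grid.base_params if grid is not None else ModelParams()
    written.append(
        write_manifest(
            out_dir,
            "write_results",
            params,
            grid=grid,
            base_seed=grid.base_seed if grid is not None else None,
            outputs=written,
        )
    )
    return written


def write_manifest(
    out_dir: str | Path,
    command: str,
    params: ModelParams,
    grid: SweepGrid | None = None,
    base_seed: int | None = None,
    outputs: list[str | Path] | None = None,
) -> Path:
    """Machine-readable provenance: the manifest plus the package version
    suffices to regenerate every listed output bit-for-bit."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "floodsim_version": __version__,
        "command": command,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "model_params": dataclasses.asdict(params),
        "base_seed": base_seed,
        "outputs": [str(Path(p).name) for p in (outputs or [])],
    }
    if grid is not None:
        manifest["sweep_grid"] = {
            "m_values": list(grid.m_values),
            "penalty_values": list(grid.penalty_values),
            "paternity_values": list(grid.paternity_values),
            "n_replicates": grid.n_replicates,
            "base_seed": grid.base_seed,
        }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(_jsonable(manifest), indent=2) + "\n")
    return path
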