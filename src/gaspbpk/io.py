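"""CSV writers/readers and the run-configuration schema.

All interchange is tidy, text-only CSV.  Numeric output is pinned to nine
significant digits so that identical runs produce byte-identical files and
a written time series can be re-read without visible loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .core import DosingSchedule, SimulationResult, SolverConfig
from .metrics import PKSummary

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_run_config",
    "write_timeseries",
    "read_timeseries",
    "write_summary",
    "write_residuals",
]

FLOAT_FMT = "%.9e"


class ConfigError(ValueError):
    """Invalid run configuration; the message carries the field path."""


@dataclass(frozen=True)
class RunConfig:
    """One simulation request: subject, schedule, solver, outputs.

    The model is deterministic, so there is no random seed anywhere.
    """

    species: str
    gas: str
    schedule: DosingSchedule
    overrides: dict[str, float] = field(default_factory=dict)
    solver: SolverConfig = field(default_factory=SolverConfig)
    outputs: tuple[str, ...] = ("timeseries", "summary")

    VALID_OUTPUTS = ("timeseries", "summary", "residuals", "reference_report")

    def __post_init__(self) -> None:
        for out in self.outputs:
            if out not in self.VALID_OUTPUTS:
                raise ConfigError(
                    f"outputs: unknown output {out!r}; "
                    f"valid: {', '.join(self.VALID_OUTPUTS)}"
                )


def _get(doc: Mapping, key: str, where: str, required: bool = True, default=None):
    if key not in doc:
        if required:
            raise ConfigError(f"{where}{key}: missing required field")
        return default
    return doc[key]


def _parse_schedule(doc: Mapping, gas: str, where: str = "schedule.") -> DosingSchedule:
    episodes_doc = _get(doc, "episodes", where)
    if not isinstance(episodes_doc, list) or not episodes_doc:
        raise ConfigError(f"{where}episodes: expected a non-empty list")
    repeat = doc.get("repeat")
    if repeat is not None:
        if len(episodes_doc) != 1:
            raise ConfigError(
                f"{where}repeat: repetition expands exactly one episode template"
            )
        ep = episodes_doc[0]
        try:
            return DosingSchedule.repeated(
                gas,
                inhaled_percent=float(ep["percent"]),
                duration_min=float(ep["duration_min"]),
                start_min=float(ep.get("start_min", 0.0)),
                period_min=float(repeat["period_min"]),
                count=int(repeat["count"]),
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"{where}: {exc}") from exc
    from .core import DoseEpisode

    eps = []
    for i, ep in enumerate(episodes_doc):
        try:
            eps.append(
                DoseEpisode(
                    start_min=float(ep.get("start_min", 0.0)),
                    duration_min=float(ep["duration_min"]),
                    inhaled_percent=float(ep["percent"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"{where}episodes[{i}]: {exc}") from exc
    try:
        return DosingSchedule(gas, tuple(eps))
    except ValueError as exc:
        raise ConfigError(f"{where}episodes: {exc}") from exc


def _parse_solver(doc: Mapping | None, where: str = "solver.") -> SolverConfig:
    if doc is None:
        return SolverConfig()
    kwargs: dict[str, float] = {}
    mapping = {
        "max_step_s": ("max_step_min", lambda v: float(v) / 60.0),
        "max_step_min": ("max_step_min", float),
        "rtol": ("rtol", float),
        "atol": ("atol", float),
        "sample_interval_min": ("sample_interval_min", float),
        "fine_sample_interval_min": ("fine_sample_interval_min", float),
        "fine_window_min": ("fine_window_min", float),
        "post_dose_horizon_min": ("post_dose_horizon_min", float),
    }
    for key, value in doc.items():
        if key not in mapping:
            raise ConfigError(f"{where}{key}: unknown solver setting")
        name, conv = mapping[key]
        kwargs[name] = conv(value)
    try:
        return SolverConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def load_run_config(path: Path | str) -> RunConfig:
    """Parse a YAML run configuration (strict: unknown keys are errors)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("config file must hold a mapping")
    known = {"species", "gas", "schedule", "overrides", "solver", "outputs"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    species = _get(doc, "species", "")
    gas = _get(doc, "gas", "")
    schedule = _parse_schedule(_get(doc, "schedule", ""), gas)
    overrides = doc.get("overrides") or {}
    if not isinstance(overrides, dict):
        raise ConfigError("overrides: expected a mapping of dotted paths")
    outputs = tuple(doc.get("outputs") or ("timeseries", "summary"))
    return RunConfig(
        species=species,
        gas=gas,
        schedule=schedule,
        overrides={k: float(v) for k, v in overrides.items()},
        solver=_parse_solver(doc.get("solver")),
        outputs=outputs,
    )


# ---------------------------------------------------------------------------
# Writers / readers
# ---------------------------------------------------------------------------


def write_timeseries(result: SimulationResult, path: Path | str) -> None:
    """Tidy CSV: time_min, compartment, concentration_mol_per_l."""
    result.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def read_timeseries(path: Path | str) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Re-read a written time series: (time grid, compartment→series)."""
    df = pd.read_csv(path)
    expected = {"time_min", "compartment", "concentration_mol_per_l"}
    if set(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {sorted(expected)}")
    series: dict[str, np.ndarray] = {}
    time: np.ndarray | None = None
    for comp, group in df.groupby("compartment", sort=False):
        series[comp] = group["concentration_mol_per_l"].to_numpy()
        if time is None:
            time = group["time_min"].to_numpy()
    assert time is not None
    return time, series


def write_summary(summary: PKSummary, path: Path | str) -> None:
    summary.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def write_residuals(summary: PKSummary, path: Path | str) -> None:
    records = [
        {"compartment": comp, "cycle": cycle, "residual_mol_per_l": value}
        for comp, pairs in summary.residuals.items()
        for cycle, value in pairs
    ]
    pd.DataFrame.from_records(records).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )
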