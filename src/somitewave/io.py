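"""Delimited-text readers/writers, config loading and run reports.

All tables use one dialect: comma separator, "." decimal, UTF-8, mandatory
header row.  Configuration files are YAML with nested sections.  Each CLI
run writes a JSON run report (command, config echo, seed, fitted numbers,
warnings, package version) from which every numeric result is
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .morphogen import (
    BoundarySeries,
    ClockSchedule,
    KymographTrace,
    MorphogenParams,
    ThresholdChange,
    ThresholdRule,
    UniformSource,
)
from .synth import GeneSpec, SynthConfig

__all__ = [
    "CT_COLUMNS",
    "RATE_COLUMNS",
    "read_ct_csv",
    "write_ct_csv",
    "read_rate_csv",
    "write_rate_csv",
    "write_boundary_series",
    "read_boundary_series",
    "write_kymograph",
    "read_kymograph",
    "load_synth_config",
    "load_scenario",
    "RunReport",
]

CT_COLUMNS = ["sample", "gene", "temperature_C", "stage", "time_h", "replicate", "ct"]
RATE_COLUMNS = ["observable", "temperature_C", "rate", "sd"]


class SchemaError(ValueError):
    """A delimited-text file does not match the expected schema."""


def read_ct_csv(path) -> pd.DataFrame:
    """Read and validate a replicate Ct table.

    Expects the header ``sample,gene,temperature_C,stage,time_h,replicate,ct``.
    ``stage`` or ``time_h`` may be empty per row, but not both.  Malformed
    rows are reported together with their 1-based file line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")

    bad_lines: list[int] = []
    for col in ("temperature_C", "stage", "time_h", "ct"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        bad_lines.extend((df.index[bad] + 2).tolist())  # +2: header + 1-based
        df[col] = coerced
    both_empty = df["stage"].isna() & df["time_h"].isna()
    bad_lines.extend((df.index[both_empty] + 2).tolist())
    nonfinite_ct = df["ct"].isna() | ~np.isfinite(df["ct"].fillna(np.nan))
    bad_lines.extend((df.index[nonfinite_ct] + 2).tolist())
    if bad_lines:
        raise SchemaError(
            f"{path.name}: malformed row(s) at line(s) {sorted(set(bad_lines))}"
        )
    df["replicate"] = df["replicate"].astype(int)
    return df[CT_COLUMNS]


def write_ct_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, encoding="utf-8")


def read_rate_csv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in RATE_COLUMNS if c not in df.columns and c != "sd"]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    return df


def write_rate_csv(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, index=False, encoding="utf-8")


def write_boundary_series(series: BoundarySeries, path) -> None:
    series.to_frame().to_csv(path, index=False, encoding="utf-8")


def read_boundary_series(path) -> BoundarySeries:
    df = pd.read_csv(path)
    return BoundarySeries(
        index=df["n"].to_numpy(dtype=int),
        times=df["t_h"].to_numpy(dtype=float),
        positions=df["x_um"].to_numpy(dtype=float),
        sizes=df["l_um"].to_numpy(dtype=float),
    )


def write_kymograph(trace: KymographTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False, encoding="utf-8")


def read_kymograph(path, sampling_h: float | None = None) -> KymographTrace:
    df = pd.read_csv(path)
    t = df["t_h"].to_numpy(dtype=float)
    if sampling_h is None:
        sampling_h = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return KymographTrace(
        times=t,
        tail_um=df["tail_um"].to_numpy(dtype=float),
        psm_um=df["psm_um"].to_numpy(dtype=float),
        front_um=df["front_um"].to_numpy(dtype=float),
        sampling_h=sampling_h,
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def load_synth_config(path, seed: int | None = None) -> SynthConfig:
    """Build a :class:`SynthConfig` from a YAML file.

    Top-level keys mirror the SynthConfig fields; ``genes`` is a list of
    ``{name, slope_per_stage, intercept}`` mappings.  A ``seed`` given as
    argument overrides one in the file.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    if seed is not None:
        raw["seed"] = seed
    if "seed" not in raw:
        raise ValueError("a seed is required (config key 'seed' or --seed)")
    if "genes" in raw:
        raw["genes"] = tuple(GeneSpec(**g) for g in raw["genes"])
    for key in ("temperatures", "stages", "time_grid"):
        if raw.get(key) is not None:
            raw[key] = tuple(float(v) for v in raw[key])
    return SynthConfig(**raw)


def load_scenario(path) -> dict[str, Any]:
    """Load a morphogen-field scenario config.

    Sections: ``field`` (amplitude_F0, decay_length_um, decay_time_h),
    ``clock`` (period_h, n_somites, t0), ``threshold`` (eta_t,
    transfer_slope), and optional ``perturbation`` — either
    ``{type: threshold_change, factor, from_index}`` or
    ``{type: uniform_source, rate, intercept}`` (a linear-in-time uniform
    offset c(t) = rate*t + intercept).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    for section in ("field", "clock", "threshold"):
        if section not in raw:
            raise ValueError(f"scenario config missing section {section!r}")
    out: dict[str, Any] = {
        "params": MorphogenParams(**raw["field"]),
        "clock": ClockSchedule(**raw["clock"]),
        "rule": ThresholdRule(**raw["threshold"]),
        "perturbation": None,
    }
    pert = raw.get("perturbation")
    if pert is not None:
        kind = pert.get("type")
        if kind == "threshold_change":
            out["perturbation"] = ThresholdChange(
                factor=float(pert["factor"]),
                from_index=int(pert.get("from_index", 0)),
            )
        elif kind == "uniform_source":
            rate = float(pert.get("rate", 0.0))
            intercept = float(pert.get("intercept", 0.0))
            out["perturbation"] = UniformSource(offset=lambda t: rate * t + intercept)
        else:
            raise ValueError(f"unknown perturbation type {kind!r}")
    return out


# ---------------------------------------------------------------------------
# Run reports
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if callable(obj):
        return repr(obj)
    return obj


@dataclass
class RunReport:
    """Reproducible record of one CLI run."""

    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    version: str = ""

    def __post_init__(self):
        if not self.version:
            from . import __version__

            self.version = __version__

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_jsonable(dataclasses.asdict(self)), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunReport":
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(**raw)
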