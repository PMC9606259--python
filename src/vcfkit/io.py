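"""Plain-text trace files and run configuration.

Traces are CSV with a fixed column order (time_ms, voltage_mV,
fluorescence_au, optional current_uA) and ``# key=value`` comment lines
carrying metadata (construct, holding_mV, sampling_Hz, seed, step window).
Run configurations are YAML or JSON validated against a strict schema
(unknown keys are rejected so typos fail loudly).
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .metrics import VcfTrace

__all__ = [
    "read_trace",
    "write_trace",
    "RunConfig",
    "ProtocolConfig",
    "ScenarioConfig",
    "FitOptions",
    "RecoverOptions",
    "load_config",
    "dump_config",
]

_COLUMNS = ("time_ms", "voltage_mV", "fluorescence_au")
_CURRENT_COL = "current_uA"

# metadata values that should round-trip as numbers
_NUMERIC_META = {"holding_mV", "sampling_Hz", "t_on_ms", "t_off_ms", "test_mV"}
_INT_META = {"seed"}


def write_trace(trace: VcfTrace, path: str | Path) -> None:
    """Write a sweep as commented-header CSV (17 significant digits)."""
    path = Path(path)
    cols = {"time_ms": trace.t, "voltage_mV": trace.V, "fluorescence_au": trace.F}
    if trace.I is not None:
        cols[_CURRENT_COL] = trace.I
    df = pd.DataFrame(cols)
    with path.open("w", encoding="utf-8") as fh:
        for key in sorted(trace.meta):
            fh.write(f"# {key}={trace.meta[key]}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_trace(path: str | Path) -> VcfTrace:
    """Read a trace CSV written by :func:`write_trace` (lossless round trip)."""
    path = Path(path)
    meta: dict = {}
    body_lines = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" not in stripped:
                    raise ValueError(
                        f"{path}:{lineno}: malformed metadata line {line.strip()!r} "
                        "(expected '# key=value')"
                    )
                key, value = stripped.split("=", 1)
                key, value = key.strip(), value.strip()
                if key in _INT_META:
                    meta[key] = int(value)
                elif key in _NUMERIC_META:
                    meta[key] = float(value)
                else:
                    meta[key] = value
            else:
                body_lines.append((lineno, line))
    if not body_lines:
        raise ValueError(f"{path}: no data rows found")

    text = "".join(line for _, line in body_lines)
    try:
        # round_trip parsing: %.17g written values must re-read bit-exactly
        df = pd.read_csv(_io.StringIO(text), float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV body: {exc}") from exc

    for col in _COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    present = [c for c in (*_COLUMNS, _CURRENT_COL) if c in df.columns]
    numeric = df[present].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.argmax(bad.values))
        raise ValueError(
            f"{path}:{body_lines[1 + row][0]}: malformed row (non-numeric or missing value)"
        )
    df = numeric

    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"{path}: time_ms is not strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1.0):
            raise ValueError(f"{path}: mixed sampling intervals in time_ms")

    I = df[_CURRENT_COL].to_numpy(dtype=float) if _CURRENT_COL in df.columns else None
    return VcfTrace(
        t=t,
        F=df["fluorescence_au"].to_numpy(dtype=float),
        V=df["voltage_mV"].to_numpy(dtype=float),
        I=I,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_StrictModel):
    holding_mV: float = -60.0
    test_mV: list[float] = Field(default=[-60.0, -20.0, 20.0, 60.0, 100.0])
    step_ms: float = 1000.0
    pre_ms: float = 100.0
    post_ms: float = 300.0
    dt_ms: float = 0.5


class ScenarioConfig(_StrictModel):
    presets: list[str] = Field(
        default=["no-quencher", "weak-quencher", "strong-quencher"]
    )
    noise_sd: float = 0.001
    bleach_fraction: float = 0.05
    bleach_tau_ms: float = 20_000.0
    include_current: bool = False


class FitOptions(_StrictModel):
    share_kinetics: bool = True
    n_starts: int = 16
    max_nfev: int = 300
    weighting: str = "uniform"


class RecoverOptions(_StrictModel):
    preset: str = "weak-quencher"
    noise_sd: float = 0.004
    n_replicates: int = 50
    n_starts: int = 4


class RunConfig(_StrictModel):
    seed: int = 0
    outdir: str = "out"
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    fit: FitOptions = Field(default_factory=FitOptions)
    recover: RecoverOptions = Field(default_factory=RecoverOptions)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML/JSON run configuration (defaults if None)."""
    if path is None:
        return RunConfig()
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        # surface the offending key path prominently
        locs = ", ".join(".".join(str(p) for p in e["loc"]) or "<root>" for e in exc.errors())
        raise ValueError(f"invalid configuration {path}: offending key(s): {locs}\n{exc}")


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the resolved configuration beside run outputs (JSON, sorted keys)."""
    Path(path).write_text(
        json.dumps(config.model_dump(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
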