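"""Reading and writing assay traces as commented CSV with JSON sidecars.

Trace files are plain comma-separated text (dot decimal, UTF-8) with
``#``-prefixed metadata header lines of the form ``# key: value``. Progress
traces carry columns ``time_min, signal``; activity time courses carry
``time_min, residual_activity``. A minimal two-column file with no metadata
is also accepted on read (condition defaults must then be supplied by the
caller). When a generating mechanism spec is given on write, it is stored
in a ``<stem>.spec.json`` sidecar for provenance.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Optional, Tuple

import pandas as pd

from .models import AssayConditions
from .simulate import ActivityTimeCourse, MechanismSpec, ProgressTrace

__all__ = [
    "write_progress_trace",
    "read_progress_trace",
    "write_activity_course",
    "read_activity_course",
]

_COND_KEYS = ("S", "Km", "I", "E0", "Vmax", "extinction_coeff", "path_length")


def _write_sidecar(path: Path, spec: Optional[MechanismSpec]) -> None:
    if spec is not None:
        sidecar = path.with_suffix(".spec.json")
        sidecar.write_text(json.dumps(spec.model_dump(), indent=2))


def _meta_header(meta: dict) -> str:
    # values are JSON-encoded so None/strings survive the round trip
    lines = [f"# {k}: {json.dumps(v)}" for k, v in meta.items()]
    return "\n".join(lines) + "\n"


def _split_header(text: str) -> Tuple[dict, str]:
    meta: dict = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("# ").strip()
            if ":" in stripped:
                key, _, raw = stripped.partition(":")
                raw = raw.strip()
                try:
                    meta[key.strip()] = json.loads(raw)
                except json.JSONDecodeError:
                    meta[key.strip()] = raw
        else:
            body_lines.append(line)
    return meta, "\n".join(body_lines)


def write_progress_trace(
    trace: ProgressTrace, path, spec: Optional[MechanismSpec] = None
) -> Path:
    """Write a progress trace as commented CSV; optional spec sidecar."""
    path = Path(path)
    c = trace.condition
    meta = {
        "trace_type": "progress",
        "time_units": "min",
        "signal_units": trace.signal_units,
        "concentration_units": "molar",
        **{f"cond_{k}": getattr(c, k) for k in _COND_KEYS},
        "noise_sd": trace.noise_sd,
        "seed": trace.seed,
    }
    df = pd.DataFrame({"time_min": trace.times, "signal": trace.signal})
    path.write_text(_meta_header(meta) + df.to_csv(index=False))
    _write_sidecar(path, spec)
    return path


def read_progress_trace(path, condition: Optional[AssayConditions] = None) -> ProgressTrace:
    """Read a progress trace written by :func:`write_progress_trace`.

    A bare two-column CSV (``time_min, signal``) is accepted if an explicit
    ``condition`` is supplied.
    """
    meta, body = _split_header(Path(path).read_text())
    df = pd.read_csv(_io.StringIO(body))
    if not {"time_min", "signal"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_min, signal")
    if condition is None:
        cond_kwargs = {
            k: meta[f"cond_{k}"] for k in _COND_KEYS if meta.get(f"cond_{k}") is not None
        }
        if not cond_kwargs:
            raise ValueError(
                f"{path}: no condition metadata in header and no condition supplied"
            )
        condition = AssayConditions(**cond_kwargs)
    return ProgressTrace(
        times=df["time_min"].to_numpy(),
        signal=df["signal"].to_numpy(),
        condition=condition,
        signal_units=meta.get("signal_units", "absorbance"),
        noise_sd=float(meta.get("noise_sd", 0.0) or 0.0),
        seed=meta.get("seed"),
    )


def write_activity_course(
    tc: ActivityTimeCourse, path, spec: Optional[MechanismSpec] = None
) -> Path:
    """Write a residual-activity time course as commented CSV."""
    path = Path(path)
    meta = {
        "trace_type": "activity",
        "time_units": "min",
        **{f"meta_{k}": v for k, v in tc.metadata.items()},
        "noise_sd": tc.noise_sd,
        "seed": tc.seed,
    }
    df = pd.DataFrame({"time_min": tc.times, "residual_activity": tc.residual_activity})
    path.write_text(_meta_header(meta) + df.to_csv(index=False))
    _write_sidecar(path, spec)
    return path


def read_activity_course(path) -> ActivityTimeCourse:
    """Read an activity time course written by :func:`write_activity_course`."""
    meta, body = _split_header(Path(path).read_text())
    df = pd.read_csv(_io.StringIO(body))
    if not {"time_min", "residual_activity"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_min, residual_activity")
    extra = {k[5:]: v for k, v in meta.items() if k.startswith("meta_")}
    return ActivityTimeCourse(
        times=df["time_min"].to_numpy(),
        residual_activity=df["residual_activity"].to_numpy(),
        metadata=extra,
        noise_sd=float(meta.get("noise_sd", 0.0) or 0.0),
        seed=meta.get("seed"),
    )
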