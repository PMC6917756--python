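"""File formats: deflection records, trace tables, response profiles, config.

Records travel as a binary NumPy array (``.npy``) plus a JSON sidecar
(``.json``) carrying the acquisition metadata, or — for small fixtures — as
a plain two-column text file (time [s], deflection [a.u.]) with metadata in
``# key = value`` header lines.  Traces are tab-separated tables; response
profiles and analysis reports are JSON.  No timestamps are written anywhere,
so a rerun with the same seeds is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .pipeline import NormalizedTrace
from .features import Minimum, ResponseProfile

__all__ = [
    "SCHEMA_VERSION",
    "RecordFormatError",
    "read_record",
    "write_record",
    "read_trace",
    "write_trace",
    "profile_to_dict",
    "write_profile",
    "read_profile",
    "RunConfig",
]

SCHEMA_VERSION = 1


class RecordFormatError(ValueError):
    """Raised for malformed or incomplete record files."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_record(record, path) -> Path:
    """Write a record; ``.npy`` + JSON sidecar, or two-column text for ``.tsv``/``.txt``."""
    path = Path(path)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "sampling_rate": record.sampling_rate,
        "stimulus_time": record.stimulus_time,
        "condition": record.condition,
        "replicate_id": record.replicate_id,
        "seed": record.seed,
    }
    if path.suffix in {".tsv", ".txt"}:
        with open(path, "w") as fh:
            for key, val in meta.items():
                fh.write(f"# {key} = {json.dumps(val)}\n")
            t = record.times()
            for ti, xi in zip(t, record.samples):
                fh.write(f"{ti:.9g}\t{xi:.12g}\n")
        return path
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    np.save(path, record.samples)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")
    return path


def _record_from(meta: dict, samples: np.ndarray, source: Path):
    from .signal_model import DeflectionRecord

    if "sampling_rate" not in meta or meta["sampling_rate"] is None:
        raise RecordFormatError(f"{source}: missing required field 'sampling_rate'")
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise RecordFormatError(
            f"{source}: schema version {version!r} not supported "
            f"(expected {SCHEMA_VERSION})"
        )
    if np.isnan(samples).any():
        raise RecordFormatError(f"{source}: record contains NaN samples")
    return DeflectionRecord(
        samples=samples,
        sampling_rate=float(meta["sampling_rate"]),
        stimulus_time=(
            None if meta.get("stimulus_time") is None else float(meta["stimulus_time"])
        ),
        condition=str(meta.get("condition", "")),
        replicate_id=str(meta.get("replicate_id", "")),
        seed=None if meta.get("seed") is None else int(meta["seed"]),
    )


def read_record(path):
    """Read a record from the binary container or the text fixture format."""
    path = Path(path)
    if path.suffix in {".tsv", ".txt"}:
        meta: dict = {}
        times, vals = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if "=" in body:
                        key, _, raw = body.partition("=")
                        meta[key.strip()] = json.loads(raw.strip())
                    continue
                cols = line.split()
                if len(cols) != 2:
                    raise RecordFormatError(f"{path}: expected 2 columns, got {len(cols)}")
                times.append(float(cols[0]))
                vals.append(float(cols[1]))
        return _record_from(meta, np.array(vals), path)
    if path.suffix == "":
        path = path.with_suffix(".npy")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise RecordFormatError(f"{path}: missing JSON sidecar {sidecar.name}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    samples = np.load(path)
    return _record_from(meta, samples, path)


_TRACE_COLUMNS = ["t_center_rel_s", "value_pct", "sd_pct", "n", "is_partial_bin"]


def write_trace(trace: NormalizedTrace, path) -> Path:
    """Write a normalized trace as a TSV table with a JSON metadata header."""
    path = Path(path)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "condition": trace.condition,
        "replicate_id": trace.replicate_id,
        "baseline_mean": trace.baseline_mean,
        "baseline_n": trace.baseline_n,
        "bin_width": trace.bin_width,
        "window_length": trace.window_length,
    }
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(meta)}\n")
        fh.write("\t".join(_TRACE_COLUMNS) + "\n")
        for i in range(trace.times.size):
            sd = "" if trace.sd is None else f"{trace.sd[i]:.6g}"
            n = "" if trace.n is None else str(int(trace.n[i]))
            part = "" if trace.is_partial is None else str(bool(trace.is_partial[i]))
            fh.write(
                f"{trace.times[i]:.6g}\t{trace.values[i]:.8g}\t{sd}\t{n}\t{part}\n"
            )
    return path


def read_trace(path) -> NormalizedTrace:
    """Read a normalized trace written by :func:`write_trace`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise RecordFormatError(f"{path}: missing metadata header line")
        meta = json.loads(header.lstrip("#").strip())
        colnames = fh.readline().strip().split("\t")
        if colnames != _TRACE_COLUMNS:
            raise RecordFormatError(f"{path}: unexpected columns {colnames}")
        times, values, sds, ns, parts = [], [], [], [], []
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            times.append(float(cols[0]))
            values.append(float(cols[1]))
            sds.append(float(cols[2]) if cols[2] else np.nan)
            ns.append(int(cols[3]) if cols[3] else -1)
            parts.append(cols[4] == "True" if cols[4] else False)
    have_sd = not all(np.isnan(sds))
    have_n = any(n >= 0 for n in ns)
    return NormalizedTrace(
        times=np.array(times),
        values=np.array(values),
        baseline_mean=float(meta["baseline_mean"]),
        baseline_n=int(meta["baseline_n"]),
        bin_width=None if meta.get("bin_width") is None else float(meta["bin_width"]),
        window_length=float(meta.get("window_length", 30.0)),
        sd=np.array(sds) if have_sd else None,
        n=np.array(ns) if have_n else None,
        is_partial=np.array(parts) if meta.get("bin_width") is not None else None,
        condition=str(meta.get("condition", "")),
        replicate_id=str(meta.get("replicate_id", "")),
    )


def profile_to_dict(profile: ResponseProfile) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "condition": profile.condition,
        "recovered": profile.recovered,
        "end_level_pct": profile.end_level_pct,
        "minima": [dataclasses.asdict(m) for m in profile.minima],
    }


def write_profile(profile: ResponseProfile, path, config: dict | None = None) -> Path:
    """Write a response profile (optionally embedding the config used) as JSON."""
    path = Path(path)
    payload = profile_to_dict(profile)
    if config is not None:
        payload["config"] = config
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
    return path


def read_profile(path) -> ResponseProfile:
    with open(path) as fh:
        payload = json.load(fh)
    minima = tuple(Minimum(**m) for m in payload["minima"])
    return ResponseProfile(
        minima=minima,
        recovered=payload.get("recovered"),
        end_level_pct=payload.get("end_level_pct"),
        condition=payload.get("condition", ""),
    )


@dataclasses.dataclass
class RunConfig:
    """End-to-end run parameters; round-trips losslessly through YAML."""

    window_length: float = 30.0
    bin_width: float = 240.0
    smooth_width: int = 5
    min_depth: float = 0.1
    min_separation: float = 240.0
    recovery_tolerance: float = 0.1
    preset: str = "P0"
    sigma0: float = 1.0
    phi: float = 0.95
    sigma_meas: float = 0.0
    drift_slope: float = 1e-4
    baseline_duration: float = 1200.0
    post_duration: float = 2700.0
    sampling_rate: float = 2000.0
    seeds: tuple[int, ...] = (1, 2, 3)
    out_dir: str = "."

    def __post_init__(self) -> None:
        self.seeds = tuple(int(s) for s in self.seeds)
        if not 180.0 <= self.bin_width <= 300.0:
            raise ValueError("bin_width must be in [180, 300] s")
        if self.smooth_width < 1 or self.smooth_width % 2 == 0:
            raise ValueError("smooth_width must be a positive odd integer")
        if not 0 < self.min_depth < 1:
            raise ValueError("min_depth must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seeds"] = list(self.seeds)
        return d

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)
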