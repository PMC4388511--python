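"""File I/O: TIFF stacks, detection/truth CSVs, fit reports, run configs.

Conventions: all pixel coordinates in files are 0-based integers with
``row`` = y increasing downward; spatial calibration is never read from
TIFF tags — it comes from explicit arguments, CLI flags or a config file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detect import DetectionParams, EndosomeDetection, ImageStack
from .kinetics import DoseResponseFit, SigmoidFit
from .synthetic import GroundTruthSpot, SimulationSpec

__all__ = [
    "StackFormatError",
    "RunConfig",
    "read_stack",
    "write_stack",
    "write_detections",
    "read_detections",
    "write_truth",
    "read_truth",
    "write_fit",
    "read_fit",
    "write_config",
    "read_config",
]

_DETECTION_COLUMNS = ["t_min", "row", "col", "peak_intensity", "correlation"]
_TRUTH_COLUMNS = ["row", "col", "sigma", "amplitude"]
_SUPPORTED_DTYPES = ("uint8", "uint16", "float32", "float64")


class StackFormatError(ValueError):
    """Raised when a TIFF's layout or bit depth cannot be interpreted."""


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Full parameter set of a run; round-trips through a flat YAML file."""

    detection: DetectionParams = dataclasses.field(default_factory=DetectionParams)
    simulation: SimulationSpec = dataclasses.field(default_factory=SimulationSpec)
    pixel_size: float = 0.13
    z_step: float = 0.49
    frame_interval: float = 1.0
    seed: int = 0
    log_level: str = "INFO"


def read_stack(
    path,
    layout: str = "ZYX",
    pixel_size: float = 0.13,
    z_step: float = 0.49,
    frame_interval: float = 1.0,
    n_z: int | None = None,
) -> list[ImageStack]:
    """Read a multi-page grayscale TIFF as one stack per timepoint.

    ``layout`` declares how pages map to dimensions: "YX" (one plane),
    "ZYX" (one z-stack), "TYX" (time series of single planes) or "TZYX"
    (time series of z-stacks; requires ``n_z`` unless the file is natively
    4D). Timestamps are ``index * frame_interval`` minutes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if str(arr.dtype) not in _SUPPORTED_DTYPES:
        raise StackFormatError(
            f"{path}: unsupported bit depth {arr.dtype}; expected one of {_SUPPORTED_DTYPES}"
        )
    arr = arr.astype(np.float64)

    def mk(vol: np.ndarray, t_index: int) -> ImageStack:
        return ImageStack(
            vol,
            pixel_size=pixel_size,
            z_step=z_step,
            timestamp=t_index * frame_interval,
        )

    if layout == "YX":
        if arr.ndim != 2:
            raise StackFormatError(f"{path}: layout YX expects 2D data, got {arr.shape}")
        return [mk(arr[None], 0)]
    if layout == "ZYX":
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise StackFormatError(f"{path}: layout ZYX expects 3D data, got {arr.shape}")
        return [mk(arr, 0)]
    if layout == "TYX":
        if arr.ndim != 3:
            raise StackFormatError(f"{path}: layout TYX expects 3D data, got {arr.shape}")
        return [mk(arr[i][None], i) for i in range(arr.shape[0])]
    if layout == "TZYX":
        if arr.ndim == 4:
            return [mk(arr[i], i) for i in range(arr.shape[0])]
        if arr.ndim == 3:
            if not n_z:
                raise StackFormatError(f"{path}: layout TZYX on paged TIFF requires n_z")
            if arr.shape[0] % n_z != 0:
                raise StackFormatError(
                    f"{path}: {arr.shape[0]} pages not divisible by n_z={n_z}"
                )
            vols = arr.reshape(arr.shape[0] // n_z, n_z, *arr.shape[1:])
            return [mk(vols[i], i) for i in range(vols.shape[0])]
        raise StackFormatError(f"{path}: layout TZYX expects 3D/4D data, got {arr.shape}")
    raise StackFormatError(f"unknown layout {layout!r}")


def write_stack(path, array: np.ndarray) -> None:
    """Write an image array as a float32 multi-page TIFF."""
    tifffile.imwrite(Path(path), np.asarray(array, dtype=np.float32))


def write_detections(detections, path) -> None:
    """Write detections as CSV: t_min,row,col,peak_intensity,correlation."""
    rows = [
        {
            "t_min": d.timestamp,
            "row": d.row,
            "col": d.col,
            "peak_intensity": d.peak_intensity,
            "correlation": d.correlation,
        }
        for d in detections
    ]
    pd.DataFrame(rows, columns=_DETECTION_COLUMNS).to_csv(
        Path(path), index=False, float_format="%.17g"
    )


def read_detections(path) -> list[EndosomeDetection]:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    missing = set(_DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        EndosomeDetection(
            row=int(r.row),
            col=int(r.col),
            peak_intensity=float(r.peak_intensity),
            correlation=float(r.correlation),
            timestamp=float(r.t_min),
        )
        for r in df.itertuples()
    ]


def write_truth(truth, path) -> None:
    """Write ground-truth spots as CSV: row,col,sigma,amplitude."""
    rows = [
        {"row": t.row, "col": t.col, "sigma": t.sigma, "amplitude": t.amplitude}
        for t in truth
    ]
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(
        Path(path), index=False, float_format="%.17g"
    )


def read_truth(path) -> list[GroundTruthSpot]:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    missing = set(_TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        GroundTruthSpot(float(r.row), float(r.col), float(r.sigma), float(r.amplitude))
        for r in df.itertuples()
    ]


def write_fit(fit, path) -> None:
    """Write a SigmoidFit or DoseResponseFit as JSON with a 'kind' tag."""
    if isinstance(fit, SigmoidFit):
        kind = "sigmoid"
    elif isinstance(fit, DoseResponseFit):
        kind = "dose_response"
    else:
        raise TypeError(f"cannot serialize fit of type {type(fit).__name__}")
    payload = {"kind": kind, **dataclasses.asdict(fit)}
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")


def read_fit(path):
    payload = json.loads(Path(path).read_text())
    kind = payload.pop("kind", None)
    if kind == "sigmoid":
        return SigmoidFit(**payload)
    if kind == "dose_response":
        return DoseResponseFit(**payload)
    raise ValueError(f"{path}: unknown fit kind {kind!r}")


def _flatten_config(config: RunConfig) -> dict:
    flat: dict = {}
    for key, value in dataclasses.asdict(config.detection).items():
        flat[f"detection.{key}"] = value
    for key, value in dataclasses.asdict(config.simulation).items():
        flat[f"simulation.{key}"] = list(value) if isinstance(value, tuple) else value
    for key in ("pixel_size", "z_step", "frame_interval", "seed", "log_level"):
        flat[key] = getattr(config, key)
    return flat


def write_config(config: RunConfig, path) -> None:
    """Write a run configuration as flat dotted-key YAML."""
    Path(path).write_text(yaml.safe_dump(_flatten_config(config), sort_keys=True))


def read_config(path) -> RunConfig:
    flat = yaml.safe_load(Path(path).read_text()) or {}
    det_kw, sim_kw, top_kw = {}, {}, {}
    for key, value in flat.items():
        if key.startswith("detection."):
            det_kw[key.split(".", 1)[1]] = value
        elif key.startswith("simulation."):
            name = key.split(".", 1)[1]
            sim_kw[name] = tuple(value) if name == "field_shape" else value
        else:
            top_kw[key] = value
    return RunConfig(
        detection=DetectionParams(**det_kw),
        simulation=SimulationSpec(**sim_kw),
        **top_kw,
    )
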