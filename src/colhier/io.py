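"""File formats, run configuration and manifests.

Rasters travel as multi-page TIFF with a JSON sidecar (geometry, positions,
polarization angles, ground truth when synthetic); tables as CSV; run
configuration as YAML.  Masked pixels use the sentinel -1, documented in
every sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__
from .geometry import MASKED, DetectorGeometry
from .pshg import PSHGStack, DEFAULT_PIXEL_SIZE_UM
from .synthetic import ScanPattern, ScatterScene
from .xrd import ReductionConfig

USABLE_Q_RANGE = (0.2, 5.0)


# ---------------------------------------------------------------------------
# Geometry (de)serialization


def geometry_to_dict(geometry: DetectorGeometry) -> dict:
    d = dataclasses.asdict(geometry)
    d["detector_shape"] = list(geometry.detector_shape)
    if geometry.beam_center is not None:
        d["beam_center"] = list(geometry.beam_center)
    return d


def geometry_from_dict(d: dict) -> DetectorGeometry:
    kwargs = dict(d)
    if "detector_shape" in kwargs:
        kwargs["detector_shape"] = tuple(int(v) for v in kwargs["detector_shape"])
    if kwargs.get("beam_center") is not None:
        kwargs["beam_center"] = tuple(float(v) for v in kwargs["beam_center"])
    return DetectorGeometry(**kwargs)


# ---------------------------------------------------------------------------
# Scatter maps


def write_scatter_map(
    directory,
    patterns: list[ScanPattern],
    geometry: DetectorGeometry,
    scenes: dict[str, ScatterScene] | None = None,
    seed: int | None = None,
) -> Path:
    """Write a scan as one multi-page TIFF plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # page-by-page write: dense scans do not fit in memory twice
    with tifffile.TiffWriter(directory / "map.tif") as tif:
        for p in patterns:
            tif.write(p.image.astype(np.float32), contiguous=True,
                      photometric="minisblack")
    sidecar = {
        "format": "colhier-scatter-map",
        "version": __version__,
        "masked_sentinel": MASKED,
        "geometry": geometry_to_dict(geometry),
        "seed": seed,
        "positions": [
            dict(row=p.row, col=p.col, x_um=p.x_um, y_um=p.y_um, label=p.label)
            for p in patterns
        ],
    }
    if scenes is not None:
        sidecar["ground_truth"] = {
            lab: dataclasses.asdict(sc) for lab, sc in scenes.items()
        }
    (directory / "map.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def read_scatter_map(directory):
    """Read a scan written by :func:`write_scatter_map`.

    Returns (patterns, geometry, sidecar dict).
    """
    directory = Path(directory)
    sidecar = json.loads((directory / "map.json").read_text())
    stack = tifffile.imread(directory / "map.tif").astype(np.float32, copy=False)
    if stack.ndim == 2:
        stack = stack[None]
    positions = sidecar["positions"]
    if len(positions) != stack.shape[0]:
        raise ValueError(
            f"page/position count mismatch: {stack.shape[0]} TIFF pages vs "
            f"{len(positions)} sidecar positions"
        )
    patterns = [
        ScanPattern(
            row=pos["row"], col=pos["col"], x_um=pos["x_um"], y_um=pos["y_um"],
            label=pos.get("label", ""), image=stack[i],
        )
        for i, pos in enumerate(positions)
    ]
    return patterns, geometry_from_dict(sidecar["geometry"]), sidecar


# ---------------------------------------------------------------------------
# pSHG stacks


def write_pshg_stack(
    path,
    intensities: np.ndarray,
    angles_deg,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    ground_truth: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write a pSHG acquisition as an n_angles-page TIFF + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = np.moveaxis(np.asarray(intensities, dtype=np.float32), 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "format": "colhier-pshg-stack",
        "version": __version__,
        "angles_deg": [float(a) for a in angles_deg],
        "pixel_size_um": pixel_size_um,
        "seed": seed,
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = ground_truth
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_pshg_stack(path) -> tuple[PSHGStack, dict]:
    """Read a pSHG stack + sidecar; page/angle mismatch is rejected."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    pages = tifffile.imread(path).astype(float)
    if pages.ndim == 2:
        pages = pages[None]
    angles = np.asarray(sidecar["angles_deg"], dtype=float)
    if pages.shape[0] != angles.size:
        raise ValueError(
            f"page/angle count mismatch: {pages.shape[0]} TIFF pages vs "
            f"{angles.size} angles in the sidecar"
        )
    stack = PSHGStack(
        np.moveaxis(pages, 0, 2),
        angles,
        pixel_size_um=float(sidecar.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)),
    )
    return stack, sidecar


# ---------------------------------------------------------------------------
# Run configuration


@dataclasses.dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    geometry: DetectorGeometry
    reduction: ReductionConfig
    threshold_fraction: float = 0.10
    bin_factor: int = 1
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self):
        lo, hi = USABLE_Q_RANGE
        d = self.reduction.d_window
        t = self.reduction.intermolecular_window
        for name, win in (("D-period", d), ("intermolecular", t)):
            if not (lo <= win[0] < win[1] <= hi):
                raise ValueError(
                    f"{name} window {win} outside usable Q range {USABLE_Q_RANGE}"
                )
        if d[1] >= t[0]:
            raise ValueError("peak windows must not overlap")
        if self.bin_factor < 1:
            raise ValueError("bin_factor must be >= 1")
        if not 0 <= self.threshold_fraction < 1:
            raise ValueError("threshold fraction must be in [0, 1)")


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "geometry" not in raw:
        raise ValueError("config is missing the required 'geometry' block")
    geometry = geometry_from_dict(raw["geometry"])
    windows = raw.get("windows", {})
    red_kwargs = dict(raw.get("reduction", {}))
    if "d_period" in windows:
        red_kwargs["d_window"] = tuple(windows["d_period"])
    if "intermolecular" in windows:
        red_kwargs["intermolecular_window"] = tuple(windows["intermolecular"])
    reduction = ReductionConfig(**red_kwargs)
    threshold = raw.get("threshold", {})
    return RunConfig(
        geometry=geometry,
        reduction=reduction,
        threshold_fraction=float(threshold.get("fraction", 0.10)),
        bin_factor=int(raw.get("bin_factor", 1)),
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "results")),
    )


# ---------------------------------------------------------------------------
# Manifests


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path,
    command: str,
    seed: int | None = None,
    config: dict | None = None,
    inputs: list | None = None,
    counts: dict | None = None,
) -> Path:
    """Emit a JSON run manifest making the invocation auditable."""
    manifest = {
        "tool": "colhier",
        "version": __version__,
        "command": command,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        "seed": seed,
        "config": config or {},
        "inputs": [
            {"path": str(p), "sha256": file_checksum(p)} for p in (inputs or [])
        ],
        "counts": counts or {},
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2))
    return path
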