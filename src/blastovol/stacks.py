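"""Core containers for 3D image stacks and label maps, plus their disk formats.

All grids use ``(z, y, x)`` axis order with anisotropic physical spacing
``(L_z, L_y, L_x)`` in micrometres.  Physical coordinates refer to voxel
centres at 0-based index positions, i.e. voxel ``(i, j, k)`` sits at
``(i*L_z, j*L_y, k*L_x)`` µm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Default voxel spacing (L_z, L_y, L_x) in µm of the light-sheet acquisition.
DEFAULT_SPACING: tuple[float, float, float] = (math.sqrt(2.0), 0.16, 0.16)

#: Default number of optical sections per stack.
DEFAULT_N_Z: int = 50

#: Default interval between consecutive stacks, seconds.
DEFAULT_INTERVAL_S: float = 30.0


def _validate_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths, got {spacing!r}")
    return spacing


@dataclass
class ImageStack:
    """A single-channel 3D intensity grid with physical metadata.

    Parameters
    ----------
    voxels
        Non-negative intensities, shape ``(n_z, n_y, n_x)``.
    spacing
        ``(L_z, L_y, L_x)`` in µm.
    channel
        Either ``"membrane"`` or ``"chromatin"``.
    timepoint
        Index of the stack within a time series.
    interval
        Time between consecutive stacks, seconds.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    channel: str = "membrane"
    timepoint: int = 0
    interval: float = DEFAULT_INTERVAL_S

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (z, y, x) array")
        self.spacing = _validate_spacing(self.spacing)
        if self.channel not in ("membrane", "chromatin"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        lz, ly, lx = self.spacing
        return lz * ly * lx

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        return replace(self, voxels=voxels)


@dataclass
class LabelMap:
    """Integer-labelled voxel grid: 0 = outside the embryo, 1..n = cells."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D (z, y, x) array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def n_cells(self) -> int:
        return int(self.labels.max(initial=0))

    def label_of(self, name: str) -> int:
        for lab, nm in self.names.items():
            if nm == name:
                return int(lab)
        raise KeyError(f"no label named {name!r}")

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def voxel_centers_um(shape, spacing) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Open (broadcastable) grids of physical voxel-centre coordinates, µm."""
    lz, ly, lx = _validate_spacing(spacing)
    nz, ny, nx = shape
    zz = (np.arange(nz, dtype=np.float32) * lz)[:, None, None]
    yy = (np.arange(ny, dtype=np.float32) * ly)[None, :, None]
    xx = (np.arange(nx, dtype=np.float32) * lx)[None, None, :]
    return zz, yy, xx


# ---------------------------------------------------------------------------
# Disk formats: multi-page TIFF for grids, CSV/JSON for tables and metadata.
# ---------------------------------------------------------------------------

def write_stack(path, stack: ImageStack) -> None:
    """Write an ImageStack as a multi-page TIFF (one page per z-plane)."""
    meta = {
        "spacing_um": list(stack.spacing),
        "channel": stack.channel,
        "timepoint": stack.timepoint,
        "interval_s": stack.interval,
    }
    tifffile.imwrite(
        str(path), np.asarray(stack.voxels, dtype=np.float32),
        metadata=meta, photometric="minisblack",
    )


def read_stack(path, spacing=None, channel="membrane", timepoint=0) -> ImageStack:
    with tifffile.TiffFile(str(path)) as tif:
        voxels = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    spacing = spacing or tuple(meta.get("spacing_um", DEFAULT_SPACING))
    return ImageStack(
        voxels=voxels,
        spacing=spacing,
        channel=meta.get("channel", channel),
        timepoint=int(meta.get("timepoint", timepoint)),
        interval=float(meta.get("interval_s", DEFAULT_INTERVAL_S)),
    )


def write_labelmap(path, labels: LabelMap, names_path=None) -> None:
    """Write a LabelMap as 16-bit multi-page TIFF plus a label->name JSON."""
    if labels.n_cells > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit storage")
    tifffile.imwrite(
        str(path), labels.labels.astype(np.uint16),
        metadata={"spacing_um": list(labels.spacing)}, photometric="minisblack",
    )
    if names_path is None:
        names_path = Path(str(path)).with_suffix(".names.json")
    Path(names_path).write_text(
        json.dumps({str(k): v for k, v in labels.names.items()}, indent=1, sort_keys=True)
    )


def read_labelmap(path, names_path=None, spacing=None) -> LabelMap:
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    spacing = spacing or tuple(meta.get("spacing_um", DEFAULT_SPACING))
    if names_path is None:
        candidate = Path(str(path)).with_suffix(".names.json")
        names_path = candidate if candidate.exists() else None
    names: dict[int, str] = {}
    if names_path is not None:
        names = {int(k): v for k, v in json.loads(Path(names_path).read_text()).items()}
    return LabelMap(labels=arr.astype(np.int32), spacing=spacing, names=names)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
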