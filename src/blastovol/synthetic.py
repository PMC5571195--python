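"""Synthetic ground-truth embryos, rendered two-channel stacks and fixtures.

No imaging data ship with the package; every downstream stage is exercised on
synthetic embryos that emulate what a light-sheet acquisition of an early
C. elegans embryo delivers: sphere-packed blastomeres inside an ellipsoidal
eggshell, a bright membrane shell per cell with a dimmer cytoplasm, one
chromatin blob per cell at the nucleus/metaphase-plate position, anisotropic
voxel spacing (L_z = sqrt(2) µm versus 0.16 µm in-plane) and additive camera
noise.  Ground truth (centres, radii, plate offsets, lineage names and
volumes) is carried alongside so that segmentation and geometry measurements
can be scored exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import capmodel
from .stacks import (DEFAULT_INTERVAL_S, DEFAULT_N_Z, DEFAULT_SPACING,
                     ImageStack, voxel_centers_um, write_stack)

# ---------------------------------------------------------------------------
# Ground-truth containers
# ---------------------------------------------------------------------------

GERMLINE_CELLS = frozenset({"P0", "P1", "P2", "P3", "P4"})


@dataclass
class GroundTruthCell:
    """A spherical blastomere with its division geometry.

    ``division_axis`` is a unit vector pointing toward the side of the future
    *smaller* (for the germline: the new germline) daughter; the metaphase
    plate sits at ``center + plate_offset * division_axis``.
    """

    name: str
    lineage_class: str  # "germline" | "somatic"
    center: np.ndarray  # (z, y, x) µm
    radius: float
    plate_offset: float = 0.0
    division_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.division_axis = np.asarray(self.division_axis, dtype=float)
        if self.radius <= 0:
            raise ValueError(f"radius of {self.name} must be positive")
        norm = np.linalg.norm(self.division_axis)
        if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-6):
            raise ValueError(f"division_axis of {self.name} must be a unit vector")
        if self.lineage_class not in ("germline", "somatic"):
            raise ValueError(f"unknown lineage_class {self.lineage_class!r}")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius ** 3

    @property
    def plate_center(self) -> np.ndarray:
        return self.center + self.plate_offset * self.division_axis


@dataclass
class EmbryoGroundTruth:
    """A set of non-overlapping cells, optionally confined by an eggshell."""

    cells: list[GroundTruthCell]
    shell: tuple[float, float, float] | None = None  # semi-axes (z, y, x) µm
    timepoint: int = 0
    overlap_tolerance: float = 0.05  # µm of allowed centre-distance shortfall

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("an embryo needs at least one cell")
        for i, a in enumerate(self.cells):
            for b in self.cells[i + 1:]:
                gap = np.linalg.norm(a.center - b.center) - (a.radius + b.radius)
                if gap < -self.overlap_tolerance:
                    raise ValueError(
                        f"cells {a.name} and {b.name} overlap by {-gap:.3f} µm"
                    )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            cz, cy, cx = c.center
            az, ay, ax = c.division_axis
            rows.append(dict(name=c.name, lineage_class=c.lineage_class,
                             cx=cx, cy=cy, cz=cz, radius=c.radius,
                             plate_offset=c.plate_offset,
                             axis_x=ax, axis_y=ay, axis_z=az))
        return pd.DataFrame(rows)


@dataclass
class DisplacementSample:
    """A signed metaphase-plate displacement for one cell, µm."""

    name: str
    lineage_class: str
    displacement: float


# ---------------------------------------------------------------------------
# Lineage fixture: the pre-gastrulation division table
# ---------------------------------------------------------------------------

#: Pre-gastrulation divisions in rough temporal order: (mother, daughter1,
#: daughter2, lineage class).  daughter1 is the anterior (somatic divisions)
#: or the somatic daughter (germline divisions).  The default fixture uses
#: the first 25 entries (26-cell stage); the last two AB16 divisions overlap
#: gastrulation onset and complete the full 27-division roster.
DIVISION_ROSTER: tuple[tuple[str, str, str, str], ...] = (
    ("P0", "AB", "P1", "germline"),
    ("AB", "ABa", "ABp", "somatic"),
    ("P1", "EMS", "P2", "germline"),
    ("ABa", "ABal", "ABar", "somatic"),
    ("ABp", "ABpl", "ABpr", "somatic"),
    ("EMS", "MS", "E", "somatic"),
    ("P2", "C", "P3", "germline"),
    ("ABal", "ABala", "ABalp", "somatic"),
    ("ABar", "ABara", "ABarp", "somatic"),
    ("ABpl", "ABpla", "ABplp", "somatic"),
    ("ABpr", "ABpra", "ABprp", "somatic"),
    ("MS", "MSa", "MSp", "somatic"),
    ("E", "Ea", "Ep", "somatic"),
    ("C", "Ca", "Cp", "somatic"),
    ("P3", "D", "P4", "germline"),
    ("MSa", "MSaa", "MSap", "somatic"),
    ("MSp", "MSpa", "MSpp", "somatic"),
    ("Ca", "Caa", "Cap", "somatic"),
    ("Cp", "Cpa", "Cpp", "somatic"),
    ("ABala", "ABalaa", "ABalap", "somatic"),
    ("ABalp", "ABalpa", "ABalpp", "somatic"),
    ("ABara", "ABaraa", "ABarap", "somatic"),
    ("ABarp", "ABarpa", "ABarpp", "somatic"),
    ("ABpla", "ABplaa", "ABplap", "somatic"),
    ("ABpra", "ABpraa", "ABprap", "somatic"),
    ("ABplp", "ABplpa", "ABplpp", "somatic"),
    ("ABprp", "ABprpa", "ABprpp", "somatic"),
)

#: Ground-truth volume ratios of the mothers that divide significantly
#: asymmetrically; all other divisions are symmetric (VR = 1).  Values are
#: chosen to sit above the resolution-dependent uncertainty band at the
#: default voxel spacing (ABar only marginally so).
DEFAULT_TRUE_VR: dict[str, float] = {
    "P0": 1.4, "P1": 1.7, "P2": 1.5, "P3": 2.0,
    "EMS": 1.15, "MSa": 1.4, "MSp": 1.3, "Ca": 1.4, "Cp": 1.3,
    "ABar": 1.12,
}

#: Default zygote volume, µm³ (a typical C. elegans egg interior).
DEFAULT_P0_VOLUME: float = 25000.0


def make_lineage_fixture(vr: Mapping[str, float] | None = None,
                         n_divisions: int = 25,
                         p0_volume: float = DEFAULT_P0_VOLUME) -> pd.DataFrame:
    """Build the ground-truth pre-gastrulation division table.

    Parameters
    ----------
    vr
        Mapping mother -> ground-truth volume ratio.  ``None`` uses
        :data:`DEFAULT_TRUE_VR`; an empty mapping makes every division
        symmetric.  Mothers not listed divide symmetrically.
    n_divisions
        How many divisions of :data:`DIVISION_ROSTER` to include (max 27).
    p0_volume
        Zygote volume in µm³; all daughter volumes cascade from it under
        exact volume conservation.

    Returns
    -------
    DataFrame
        Columns ``mother, daughter1, daughter2, lineage_class, v_mother,
        v1, v2, vr_true``.
    """
    if not 1 <= n_divisions <= len(DIVISION_ROSTER):
        raise ValueError(f"n_divisions must be in 1..{len(DIVISION_ROSTER)}")
    if p0_volume <= 0:
        raise ValueError("p0_volume must be positive")
    vr = DEFAULT_TRUE_VR if vr is None else dict(vr)
    roster = DIVISION_ROSTER[:n_divisions]
    mothers = {m for m, *_ in roster}
    unknown = set(vr) - {m for m, *_ in DIVISION_ROSTER}
    if unknown:
        raise ValueError(f"unknown cell name(s) in VR config: {sorted(unknown)}")
    for mother, ratio in vr.items():
        if ratio <= 0:
            raise ValueError(f"VR of {mother} must be positive, got {ratio}")
    volumes = {"P0": float(p0_volume)}
    rows = []
    for mother, d1, d2, cls in roster:
        if mother not in volumes:
            raise ValueError(f"mother {mother} divides before being born")
        v = volumes[mother]
        ratio = float(vr.get(mother, 1.0))
        v1 = v * ratio / (1.0 + ratio)
        v2 = v / (1.0 + ratio)
        volumes[d1] = v1
        volumes[d2] = v2
        rows.append(dict(mother=mother, daughter1=d1, daughter2=d2,
                         lineage_class=cls, v_mother=v, v1=v1, v2=v2,
                         vr_true=ratio))
    _ = mothers
    return pd.DataFrame(rows)


def generate_germline_truth(V_P1: float, shift: float) -> dict[str, float]:
    """Ground-truth germline volumes (EMS, P2, C, P3, D, P4) in µm³.

    Delegates to the spherical-cap recursion so that synthetic truth and the
    analytical model agree exactly.
    """
    return capmodel.predict_germline(V_P1, shift).volumes


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

@dataclass
class NoiseSettings:
    """Rendering parameters for the two synthetic channels.

    The membrane channel paints, per cell, a bright shell over the band
    ``(R - shell_thickness, R]`` and a dimmer cytoplasm inside it; the
    chromatin channel adds one Gaussian blob per cell at the metaphase-plate
    position.  ``additive_sigma`` is the camera-noise scale (intensity
    units); ``shadow_attenuation`` optionally dims the image cumulatively
    along the illumination (x) axis behind bright structures.
    """

    shell_thickness: float = 0.4        # µm
    shell_level: float = 180.0          # membrane intensity
    interior_level: float = 60.0        # cytoplasm intensity
    chromatin_amplitude: float = 200.0
    chromatin_sigma: float = 0.5        # µm (blob of ~1 µm width)
    additive_sigma: float = 5.0
    shadow_attenuation: float | None = None  # e.g. 0.999 per bright voxel

    def __post_init__(self) -> None:
        if min(self.shell_level, self.interior_level, self.chromatin_amplitude) <= 0:
            raise ValueError("intensity levels must be positive")
        if self.shell_thickness <= 0 or self.chromatin_sigma <= 0:
            raise ValueError("length scales must be positive")
        if self.additive_sigma < 0:
            raise ValueError("additive noise scale must be non-negative")


def _fov_shape(truth: EmbryoGroundTruth, spacing, margin: float):
    lz, ly, lx = spacing
    if truth.shell is not None:
        sz, sy, sx = truth.shell
        ext = np.array([2 * sz, 2 * sy, 2 * sx]) + 2 * margin
        nz = max(int(math.ceil(ext[0] / lz)) + 1, DEFAULT_N_Z)
        ny = int(math.ceil(ext[1] / ly)) + 1
        nx = int(math.ceil(ext[2] / lx)) + 1
        return (nz, ny, nx)
    hi = np.max([c.center + c.radius for c in truth.cells], axis=0) + margin
    return tuple(int(math.ceil(h / s)) + 1 for h, s in zip(hi, spacing))


def render_embryo_stack(truth: EmbryoGroundTruth,
                        noise: NoiseSettings | None = None,
                        seed: int = 0,
                        spacing=DEFAULT_SPACING,
                        shape: tuple[int, int, int] | None = None,
                        margin: float = 2.0,
                        interval: float = DEFAULT_INTERVAL_S,
                        ) -> tuple[ImageStack, ImageStack]:
    """Render a two-channel stack (membrane, chromatin) of an embryo.

    Identical ``(truth, noise, seed)`` produce bit-identical stacks.  Raises
    if any cell extends beyond the field of view.
    """
    noise = noise or NoiseSettings()
    shape = shape or _fov_shape(truth, spacing, margin)
    zz, yy, xx = voxel_centers_um(shape, spacing)
    extent = np.array([zz.max(), yy.max(), xx.max()])
    for c in truth.cells:
        pad = c.radius
        if np.any(c.center - pad < 0) or np.any(c.center + pad > extent):
            raise ValueError(f"cell {c.name} does not fit into the field of view")
    membrane = np.zeros(shape, dtype=np.float32)
    chromatin = np.zeros(shape, dtype=np.float32)
    shell_mask = np.zeros(shape, dtype=bool)
    for c in truth.cells:
        d = np.sqrt((zz - c.center[0]) ** 2 + (yy - c.center[1]) ** 2
                    + (xx - c.center[2]) ** 2)
        interior = d <= c.radius - noise.shell_thickness
        shell = (d <= c.radius) & ~interior
        membrane[interior] = noise.interior_level
        shell_mask |= shell
        p = c.plate_center
        d2 = ((zz - p[0]) ** 2 + (yy - p[1]) ** 2 + (xx - p[2]) ** 2)
        chromatin += noise.chromatin_amplitude * np.exp(
            -d2 / (2.0 * noise.chromatin_sigma ** 2)
        ).astype(np.float32)
    membrane[shell_mask] = noise.shell_level  # membrane dominates at contacts
    if noise.shadow_attenuation is not None:
        bright = np.cumsum(membrane > 0.5 * noise.shell_level, axis=2)
        membrane *= noise.shadow_attenuation ** bright
    if noise.additive_sigma > 0:
        rng = np.random.default_rng(seed)
        membrane = np.clip(
            membrane + rng.normal(0, noise.additive_sigma, shape), 0, None
        ).astype(np.float32)
        chromatin = np.clip(
            chromatin + rng.normal(0, noise.additive_sigma, shape), 0, None
        ).astype(np.float32)
    mk = dict(spacing=spacing, timepoint=truth.timepoint, interval=interval)
    return (ImageStack(membrane, channel="membrane", **mk),
            ImageStack(chromatin, channel="chromatin", **mk))


def seeds_from_truth(truth: EmbryoGroundTruth, spacing=DEFAULT_SPACING):
    """(names, voxel coordinates) of one seed per cell at each cell centre."""
    coords = np.array(
        [np.round(c.center / np.asarray(spacing)).astype(int) for c in truth.cells]
    )
    return [c.name for c in truth.cells], coords


# ---------------------------------------------------------------------------
# Displacement samples
# ---------------------------------------------------------------------------

#: (µ_som, σ_som, germline shift, σ_germ) in µm.  Somatic displacements are
#: zero-mean-ish normal; germline displacements cluster around a constant
#: shift.  σ_germ is a small spread around the reported germline median.
DEFAULT_DISPLACEMENT_PARAMS: tuple[float, float, float, float] = (-0.1, 0.56, 1.36, 0.2)


def sample_displacements(n_somatic: int, n_germline: int,
                         params: Sequence[float] = DEFAULT_DISPLACEMENT_PARAMS,
                         seed: int = 0) -> list[DisplacementSample]:
    """Draw signed spindle displacements for somatic and germline cells.

    Somatic samples come from Normal(µ_som, σ_som), germline samples from
    Normal(shift_germ, σ_germ); reproducible under ``seed``.
    """
    mu_som, sd_som, shift_germ, sd_germ = (float(p) for p in params)
    if n_somatic < 0 or n_germline < 0:
        raise ValueError("sample counts must be non-negative")
    if sd_som < 0 or sd_germ < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    som = mu_som + sd_som * rng.standard_normal(n_somatic)
    germ = shift_germ + sd_germ * rng.standard_normal(n_germline)
    out = [DisplacementSample(f"somatic_{i:04d}", "somatic", float(x))
           for i, x in enumerate(som)]
    out += [DisplacementSample(f"germline_{i:04d}", "germline", float(x))
            for i, x in enumerate(germ)]
    return out


def displacements_to_frame(samples: list[DisplacementSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(name=s.name, lineage_class=s.lineage_class,
              displacement=s.displacement) for s in samples]
    )


# ---------------------------------------------------------------------------
# Ready-made embryos
# ---------------------------------------------------------------------------

DEFAULT_SHELL_SEMI_AXES: tuple[float, float, float] = (15.0, 15.0, 27.0)  # (z, y, x)


def two_cell_embryo(mother_radius: float = 9.0, margin: float = 2.0,
                    vr: float = 1.0) -> EmbryoGroundTruth:
    """A compact AB + P1 style two-cell embryo, spheres tangent along x."""
    r3 = mother_radius ** 3
    r1 = (r3 * vr / (1 + vr)) ** (1.0 / 3.0)
    r2 = (r3 / (1 + vr)) ** (1.0 / 3.0)
    cy = cz = margin + max(r1, r2)
    c1 = np.array([cz, cy, margin + r1])
    c2 = np.array([cz, cy, margin + 2 * r1 + r2])
    return EmbryoGroundTruth(cells=[
        GroundTruthCell("AB", "somatic", c1, r1),
        GroundTruthCell("P1", "germline", c2, r2,
                        plate_offset=0.0, division_axis=np.array([0.0, 0.0, 1.0])),
    ])


def division_pair_embryos(mother_radius: float = 9.0, shift: float = 1.75,
                          margin: float = 2.0
                          ) -> tuple[EmbryoGroundTruth, EmbryoGroundTruth]:
    """Ground truth before and after one off-centre division of a mother.

    Timepoint 0 holds the spherical mother; timepoint 1 the two daughter
    spheres (volumes from the cap model at ``shift``), tangent along x at
    conserved total volume.
    """
    v1, v2 = capmodel.cap_volumes(mother_radius, shift)
    r1 = capmodel.radius_from_volume(v1)
    r2 = capmodel.radius_from_volume(v2)
    cy = cz = margin + mother_radius
    cx = margin + max(mother_radius, r1)
    mother = GroundTruthCell(
        "P1", "germline", np.array([cz, cy, cx]), mother_radius,
        plate_offset=shift, division_axis=np.array([0.0, 0.0, 1.0]),
    )
    d1 = GroundTruthCell("EMS", "somatic", np.array([cz, cy, cx - 0.0]), r1)
    d2 = GroundTruthCell(
        "P2", "germline", np.array([cz, cy, cx + r1 + r2]), r2,
    )
    before = EmbryoGroundTruth(cells=[mother], timepoint=0)
    after = EmbryoGroundTruth(cells=[d1, d2], timepoint=1)
    return before, after


def single_germline_cell(radius: float, plate_offset: float = 1.36,
                         name: str = "P2", margin: float = 2.0,
                         axis=(0.0, 0.0, 1.0),
                         center_jitter=None) -> EmbryoGroundTruth:
    """One germline cell with an eccentric metaphase plate along ``axis``.

    ``center_jitter`` (3-vector, µm) offsets the centre from its default
    grid-tied position; real cells sit at arbitrary sub-voxel positions, so
    measurement studies should jitter the centre to decorrelate voxel-grid
    alignment from cell size.
    """
    center = np.full(3, margin + radius)
    if center_jitter is not None:
        center = center + np.asarray(center_jitter, dtype=float)
    return EmbryoGroundTruth(cells=[
        GroundTruthCell(name, "germline", center, radius,
                        plate_offset=plate_offset,
                        division_axis=np.asarray(axis, dtype=float)),
    ])


def synthetic_track(cell: GroundTruthCell, n_stacks: int = 3,
                    separation: float = 1.0, step: float = 0.0):
    """Daughter-chromatin positions for stacks S1..Sn after metaphase.

    daughter1 is the future larger (somatic) daughter on the far side of the
    plate from the displacement direction; daughter2 the smaller (germline)
    daughter on the near side.  ``step`` moves both assemblies apart by an
    extra amount per stack.
    """
    u = cell.division_axis
    r0 = cell.plate_center
    r1 = np.array([r0 - (separation + i * step) * u for i in range(n_stacks)])
    r2 = np.array([r0 + (separation + i * step) * u for i in range(n_stacks)])
    return r1, r2


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_embryo(out_dir, truth: EmbryoGroundTruth,
                 noise: NoiseSettings | None = None, seed: int = 0,
                 spacing=DEFAULT_SPACING, config: dict | None = None) -> dict:
    """Render an embryo and write TIFFs, ground-truth CSV and config JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    membrane, chromatin = render_embryo_stack(truth, noise=noise, seed=seed,
                                              spacing=spacing)
    paths = {
        "membrane": out / f"membrane_t{truth.timepoint:03d}.tif",
        "chromatin": out / f"chromatin_t{truth.timepoint:03d}.tif",
        "truth": out / f"truth_t{truth.timepoint:03d}.csv",
        "config": out / "config.json",
    }
    write_stack(paths["membrane"], membrane)
    write_stack(paths["chromatin"], chromatin)
    truth.to_frame().to_csv(paths["truth"], index=False)
    cfg = dict(config or {})
    cfg.update(seed=seed, spacing=list(spacing),
               noise=vars(noise or NoiseSettings()))
    paths["config"].write_text(json.dumps(cfg, indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
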