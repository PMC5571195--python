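"""Cell volumetry: voxel volumes, volume ratios and asymmetry significance.

A segmented cell's volume is the voxel count times the voxel volume,
``V_i = L_x * L_y * L_z * m_i``.  Because segmentation may or may not include
one extra voxel layer around a cell, even a perfectly symmetric division can
show an apparent volume ratio different from 1.  With cells modelled as
spheres of radius ``R = (3V/4π)^(1/3)`` the ambiguous layer contributes

* ``ΔV1 = 4π R² L_x − 2π R L_z L_x`` from the in-plane layers (a surface
  shell of thickness L_x over the spherical zone between top and bottom
  sections), and
* ``ΔV2 = π L_z (R L_z − L_z²/6) / 2`` from the half-height caps in the top
  and bottom sections (the axial sampling L_z is much coarser than L_x),

and including-or-not each is a coin flip, so the expected ambiguous volume is
``ΔV = (ΔV1 + ΔV2)/2``.  A division is deemed significantly asymmetric only
when its volume ratio leaves the band
``[(V_sym − ΔV)/(V_sym + ΔV), (V_sym + ΔV)/(V_sym − ΔV)]`` computed for a
symmetric split ``V_sym`` of the mother.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .capmodel import radius_from_volume
from .stacks import DEFAULT_SPACING, LabelMap


class CellTooSmallError(ValueError):
    """The cell volume is below the segmentation ambiguity at this resolution."""


@dataclass
class DivisionRecord:
    """One mother -> (daughter1, daughter2) division with volumes in µm³.

    ``daughter1`` holds the more anterior daughter for somatic divisions and
    the somatic daughter for germline divisions, so that ``VR = v1 / v2``
    follows the standard ratio conventions in both cases.
    """

    mother: str
    daughter1: str
    daughter2: str
    lineage_class: str
    v_mother: float
    v1: float
    v2: float

    @property
    def vr(self) -> float:
        return volume_ratio(self.v1, self.v2)


def cell_volume(labels: LabelMap, label: int | None = None):
    """Voxel volume(s) in µm³ of one label or of all labels.

    Returns a float when ``label`` is given, otherwise a dict mapping every
    label in ``1..n_cells`` to its volume.  An absent label yields volume 0
    with a warning.
    """
    lz, ly, lx = labels.spacing
    vox = lz * ly * lx
    if label is not None:
        m = int(np.count_nonzero(labels.labels == label))
        if m == 0:
            warnings.warn(f"label {label} absent from label map; volume 0")
        return vox * m
    counts = np.bincount(labels.labels.ravel(), minlength=labels.n_cells + 1)
    out = {}
    for lab in range(1, labels.n_cells + 1):
        if counts[lab] == 0:
            warnings.warn(f"label {lab} absent from label map; volume 0")
        out[lab] = vox * float(counts[lab])
    return out


def volumes_by_name(labels: LabelMap) -> dict[str, float]:
    """Volumes keyed by cell name using the label map's name table."""
    vols = cell_volume(labels)
    return {labels.names.get(lab, str(lab)): v for lab, v in vols.items()}


def volume_ratio(v1: float, v2: float) -> float:
    """Daughter volume ratio ``VR = v1 / v2``.

    By convention ``v1`` is the more anterior daughter (somatic divisions) or
    the somatic daughter (germline divisions, whose new germline cell is the
    smaller one and sits in the denominator).
    """
    if v1 <= 0 or v2 <= 0:
        raise ValueError(f"daughter volumes must be positive, got {v1}, {v2}")
    return v1 / v2


def ambiguous_volume(V_sym: float, spacing=DEFAULT_SPACING) -> tuple[float, float, float]:
    """Return (ΔV1, ΔV2, ΔV) for a cell of volume ``V_sym`` µm³."""
    lz, ly, lx = spacing
    R = radius_from_volume(V_sym)
    dv1 = 4.0 * math.pi * R * R * lx - 2.0 * math.pi * R * lz * lx
    dv2 = math.pi * lz * (R * lz - lz * lz / 6.0) / 2.0
    return dv1, dv2, 0.5 * (dv1 + dv2)


def uncertainty_bounds(V_sym: float, spacing=DEFAULT_SPACING) -> tuple[float, float]:
    """Apparent-asymmetry band (VR_min, VR_max) for a symmetric division.

    Parameters
    ----------
    V_sym
        Daughter volume of the hypothetical symmetric division, µm³.
    spacing
        ``(L_z, L_y, L_x)`` voxel spacing in µm.

    Raises
    ------
    CellTooSmallError
        When ``V_sym <= ΔV`` the bounds are undefined: the cell is too small
        to assess at this resolution.
    """
    lz = spacing[0]
    R = radius_from_volume(V_sym)
    if R <= lz / 2.0:
        # the layer decomposition needs the cell to span at least one
        # z-section; below that ΔV1 turns negative and the model is invalid
        raise CellTooSmallError(
            f"radius {R:.3f} µm does not exceed half the section spacing "
            f"L_z/2 = {lz / 2:.3f} µm; cell too small to assess"
        )
    _, _, dv = ambiguous_volume(V_sym, spacing)
    if V_sym <= dv:
        raise CellTooSmallError(
            f"V_sym = {V_sym:.2f} µm³ does not exceed the segmentation "
            f"ambiguity ΔV = {dv:.2f} µm³ at spacing {tuple(spacing)}"
        )
    vr_max = (V_sym + dv) / (V_sym - dv)
    return 1.0 / vr_max, vr_max


def classify_divisions(table: pd.DataFrame, spacing=DEFAULT_SPACING
                       ) -> tuple[pd.DataFrame, float]:
    """Flag significantly asymmetric divisions and report their fraction.

    Parameters
    ----------
    table
        One row per division with columns ``mother, daughter1, daughter2,
        lineage_class, v_mother, v1, v2`` (see :class:`DivisionRecord` for
        the ordering conventions behind ``v1``/``v2``).
    spacing
        Voxel spacing used for the uncertainty band.

    Returns
    -------
    (annotated, fraction)
        Copy of the table with ``vr, vr_min, vr_max, significant,
        assessable`` columns, and the fraction of assessable divisions whose
        VR lies strictly outside its uncertainty band.  A division whose
        ``V_sym = v_mother / 2`` fails the bound precondition is flagged
        non-assessable and excluded from the fraction (with a warning).
    """
    required = {"mother", "v_mother", "v1", "v2"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"division table lacks columns {sorted(missing)}")
    out = table.copy()
    vr, vr_lo, vr_hi, sig, ok = [], [], [], [], []
    for row in out.itertuples(index=False):
        vr.append(volume_ratio(row.v1, row.v2))
        try:
            lo, hi = uncertainty_bounds(row.v_mother / 2.0, spacing)
        except CellTooSmallError:
            warnings.warn(
                f"division of {row.mother} is unassessable at this resolution"
            )
            vr_lo.append(np.nan)
            vr_hi.append(np.nan)
            sig.append(False)
            ok.append(False)
            continue
        vr_lo.append(lo)
        vr_hi.append(hi)
        # strict exceedance: VR exactly on a bound is not significant
        sig.append(bool(vr[-1] > hi or vr[-1] < lo))
        ok.append(True)
    out["vr"] = vr
    out["vr_min"] = vr_lo
    out["vr_max"] = vr_hi
    out["significant"] = sig
    out["assessable"] = ok
    n_ok = int(np.sum(ok))
    if n_ok == 0:
        raise ValueError("no assessable division in the table")
    fraction = float(np.sum(np.asarray(sig)[np.asarray(ok)]) / n_ok)
    return out, fraction


def median_volume_series(volumes: pd.DataFrame) -> pd.Series:
    """Median volume per cell over all timepoints where the cell exists.

    ``volumes`` is tidy with columns ``name, timepoint, volume``; zero
    volumes (absent label) are ignored.
    """
    v = volumes[volumes["volume"] > 0]
    return v.groupby("name")["volume"].median()
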