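"""Spherical-cap division geometry and the constant-spindle-shift germline model.

A blastomere is idealised as a sphere of radius :math:`R_0`.  If the mitotic
spindle (and hence the metaphase plate, which sets the cleavage plane) is
displaced by :math:`\\Delta x` from the cell centre along the division axis,
cytokinesis splits the mother into two spherical caps of heights
:math:`R_0 + \\Delta x` and :math:`R_0 - \\Delta x` with volumes

.. math::

    V_1 = \\frac{\\pi}{3}(R_0 + \\Delta x)^2 (2R_0 - \\Delta x), \\qquad
    V_2 = \\frac{\\pi}{3}(R_0 - \\Delta x)^2 (2R_0 + \\Delta x),

which conserve the mother volume exactly.  Applying this scheme recursively
down the germline (P1 -> EMS + P2, P2 -> C + P3, P3 -> D + P4) with a single,
cell-size *independent* shift predicts all germline daughter volumes from the
volume of P1 alone.  The shift that best matches observed volumes is found by
a grid search over the mean absolute relative deviation
(:class:`ConstantShiftModel`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

#: Constant spindle shift (µm) that reproduces observed germline volumes.
DEFAULT_SHIFT_UM: float = 1.75

#: Daughters predicted by the germline recursion, in prediction order.
GERMLINE_ORDER: tuple[str, ...] = ("EMS", "P2", "C", "P3", "D", "P4")

#: (mother, somatic daughter, germline daughter) triplets of the recursion.
GERMLINE_CHAIN: tuple[tuple[str, str, str], ...] = (
    ("P1", "EMS", "P2"),
    ("P2", "C", "P3"),
    ("P3", "D", "P4"),
)


def cap_volumes(R0: float, dx: float) -> tuple[float, float]:
    """Volumes (µm³) of the two spherical caps of a sphere split off-centre.

    Parameters
    ----------
    R0
        Mother-cell radius, µm.
    dx
        Signed displacement of the cleavage plane from the centre, µm.
        ``|dx| < R0``; a positive shift makes ``V1 >= V2``.

    Returns
    -------
    (V1, V2)
        Cap volumes with heights ``R0 + dx`` and ``R0 - dx``.  Their sum is
        exactly ``(4/3) * pi * R0**3``.
    """
    if R0 <= 0:
        raise ValueError(f"R0 must be positive, got {R0}")
    if abs(dx) >= R0:
        raise ValueError(f"|dx| = {abs(dx)} must be smaller than R0 = {R0}")
    v1 = math.pi / 3.0 * (R0 + dx) ** 2 * (2.0 * R0 - dx)
    v2 = math.pi / 3.0 * (R0 - dx) ** 2 * (2.0 * R0 + dx)
    return v1, v2


def radius_from_volume(V: float) -> float:
    """Apparent radius R = (3V / 4π)^(1/3) of a sphere with volume ``V`` µm³."""
    if V <= 0:
        raise ValueError(f"volume must be positive, got {V}")
    return (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)


def ellipsoid_cap_volumes(semi_axes: Sequence[float], dx: float) -> tuple[float, float]:
    """Volumes on either side of the plane ``x = dx`` through an ellipsoid.

    The plane normal lies along the first semi-axis ``a``.  Under the affine
    map that turns the ellipsoid into the unit sphere the cut becomes a
    spherical cap at ``dx / a``, so the cap volumes are the unit-sphere cap
    volumes scaled by ``a * b * c``.
    """
    a, b, c = (float(s) for s in semi_axes)
    if min(a, b, c) <= 0:
        raise ValueError(f"semi-axes must be positive, got {semi_axes}")
    if abs(dx) >= a:
        raise ValueError(f"|dx| = {abs(dx)} must be smaller than semi-axis a = {a}")
    v1u, v2u = cap_volumes(1.0, dx / a)
    return a * b * c * v1u, a * b * c * v2u


@dataclass
class GermlinePrediction:
    """Outcome of the iterative cap-model prediction for the germline."""

    v_p1: float
    shift: float
    volumes: dict[str, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.volumes[c] for c in GERMLINE_ORDER])


def predict_germline(V_P1: float, dx: float) -> GermlinePrediction:
    """Predict EMS, P2, C, P3, D and P4 volumes from the volume of P1.

    Each germline mother is assumed spherical with radius
    ``R = (3V/4π)^(1/3)`` and divides into two caps separated by a plane at
    the constant shift ``dx`` from the centre; the larger cap is the somatic
    daughter, the smaller one the new germline cell, which then divides again
    by the same rule.

    Raises
    ------
    ValueError
        If the shift reaches or exceeds the radius at any generation; the
        message names the failing mother.
    """
    if V_P1 <= 0:
        raise ValueError("V_P1 must be positive")
    if dx < 0:
        raise ValueError("shift must be non-negative")
    volumes: dict[str, float] = {}
    v_germ = V_P1
    for mother, somatic, germ in GERMLINE_CHAIN:
        radius = radius_from_volume(v_germ)
        if dx >= radius:
            raise ValueError(
                f"shift {dx} µm reaches the radius {radius:.3f} µm of {mother}"
            )
        v1, v2 = cap_volumes(radius, dx)
        volumes[somatic] = v1
        volumes[germ] = v2
        v_germ = v2
    return GermlinePrediction(v_p1=V_P1, shift=dx, volumes=volumes)


def _deviation(observed: Mapping[str, float], predicted: Mapping[str, float]) -> float:
    devs = [
        abs(predicted[c] - observed[c]) / observed[c]
        for c in GERMLINE_ORDER
        if c in observed and np.isfinite(observed[c])
    ]
    return float(np.mean(devs))


class ConstantShiftModel:
    """Fit a constant spindle shift to observed germline volumes.

    Parameters
    ----------
    observed
        Mapping from cell name to volume in µm³.  Must contain ``"P1"`` (the
        sole model input) and at least one of EMS, P2, C, P3, D, P4.

    Examples
    --------
    >>> truth = predict_germline(4188.79, 1.75).volumes
    >>> res = ConstantShiftModel({"P1": 4188.79, **truth}).fit()
    >>> round(res.shift_, 2)
    1.75
    """

    def __init__(self, observed: Mapping[str, float]):
        if "P1" not in observed:
            raise ValueError("observed volumes must include P1")
        if not any(c in observed for c in GERMLINE_ORDER):
            raise ValueError(
                "observed volumes must include at least one germline daughter "
                f"of {GERMLINE_ORDER}"
            )
        self.observed = {k: float(v) for k, v in observed.items()}

    @classmethod
    def from_dataframe(cls, df, cell_col: str = "cell", volume_col: str = "volume"):
        """Build from a tidy table with one row per cell."""
        return cls(dict(zip(df[cell_col], df[volume_col])))

    def predict(self, dx: float) -> dict[str, float]:
        return predict_germline(self.observed["P1"], dx).volumes

    def fit(self, grid: tuple[float, float, float] = (0.0, 3.0, 0.01)) -> "ShiftFitResult":
        """Grid search for the shift minimising the mean relative deviation.

        Parameters
        ----------
        grid
            ``(dx_min, dx_max, step)`` in µm; both ends inclusive.
        """
        dx_min, dx_max, step = grid
        if step <= 0 or dx_max < dx_min:
            raise ValueError(f"invalid grid {grid!r}")
        n = int(round((dx_max - dx_min) / step)) + 1
        shifts = np.linspace(dx_min, dx_max, n)
        devs = np.full(n, np.inf)
        for i, dx in enumerate(shifts):
            try:
                pred = predict_germline(self.observed["P1"], float(dx)).volumes
            except ValueError:
                continue  # shift exceeds a generation's radius
            devs[i] = _deviation(self.observed, pred)
        if not np.isfinite(devs).any():
            raise ValueError("no grid point admits a valid germline prediction")
        best = int(np.argmin(devs))
        return ShiftFitResult(
            model=self,
            shift_=float(shifts[best]),
            deviation_=float(devs[best]),
            grid_=shifts,
            deviations_=devs,
        )


@dataclass
class ShiftFitResult:
    """Result of :meth:`ConstantShiftModel.fit`.

    Attributes
    ----------
    shift_ : float
        Grid minimiser of the mean absolute relative volume deviation, µm.
    deviation_ : float
        Mean relative deviation at the minimiser (dimensionless).
    grid_, deviations_ : ndarray
        The full deviation curve.
    """

    model: ConstantShiftModel
    shift_: float
    deviation_: float
    grid_: np.ndarray
    deviations_: np.ndarray

    @property
    def predicted_(self) -> dict[str, float]:
        return self.model.predict(self.shift_)

    def summary(self) -> str:
        obs, pred = self.model.observed, self.predicted_
        lines = [
            "Constant spindle-shift cap model",
            "=" * 48,
            f"input volume V(P1)        {obs['P1']:12.2f} µm³",
            f"fitted shift dx*          {self.shift_:12.3f} µm",
            f"mean relative deviation   {self.deviation_:12.4g}",
            "-" * 48,
            f"{'cell':<6}{'V_obs [µm³]':>14}{'V_theo [µm³]':>14}{'rel.dev':>10}",
        ]
        for cell in GERMLINE_ORDER:
            if cell in obs:
                rel = (pred[cell] - obs[cell]) / obs[cell]
                lines.append(f"{cell:<6}{obs[cell]:>14.1f}{pred[cell]:>14.1f}{rel:>+10.2%}")
        return "\n".join(lines)

    def plot_deviation(self, ax=None):
        """Plot the relative-deviation curve over the shift grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ok = np.isfinite(self.deviations_)
        ax.plot(self.grid_[ok], self.deviations_[ok])
        ax.axvline(self.shift_, ls="--", color="k")
        ax.set_xlabel("spindle shift Δx [µm]")
        ax.set_ylabel("mean relative volume deviation")
        return ax


def fit_shift(observed: Mapping[str, float],
              grid: tuple[float, float, float] = (0.0, 3.0, 0.01)) -> ShiftFitResult:
    """Functional wrapper: ``ConstantShiftModel(observed).fit(grid)``."""
    return ConstantShiftModel(observed).fit(grid)
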