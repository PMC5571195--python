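"""Closed-form one-dimensional spindle mechanics with constant cortical forces.

Constant pulling forces ``F_A < F_P`` act on the anterior and posterior
spindle poles; the spindle resists stretching as a Hookean spring (constant
``k``, resting length ``L0``) and the poles move overdamped with friction
``γ``.  With pole displacements ``x_A, x_P`` (both 0 at t = 0) the equations
of motion

    −γ dx_A/dt + k (x_P − x_A) − F_A = 0
    −γ dx_P/dt − k (x_P − x_A) + F_P = 0

have the closed-form solution

    x_MP(t) = (x_A + x_P)/2 = (F_P − F_A) t / (2γ)
    s(t)    = x_P − x_A     = (F_P + F_A)/(2k) · (1 − exp(−2kt/γ))

The spindle ruptures (anaphase onset) at the extension ``s_max``, at time
``T = −γ/(2k) · ln(1 − 2k s_max/(F_P + F_A))``, having travelled
``Δx = (F_P − F_A) T / (2γ)``.  None of these quantities references cell
size, so the model predicts a cell-size independent spindle displacement.
If ``s_max`` is not below the asymptotic extension ``(F_P + F_A)/(2k)`` the
spindle never ruptures and mitosis stalls.  No units are imposed; results
depend only on dimensionless combinations such as ``k t / γ``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class SpindleStallError(ValueError):
    """The total force is too low to stretch the spindle to ``s_max``."""


@dataclass(frozen=True)
class SpindleParams:
    """Forces, spring constant, geometry and friction of the spindle model.

    All values are positive and ``F_P >= F_A``; ``L0`` does not enter the
    displacement formulas (only extensions do) but allows reporting the
    absolute spindle length ``L0 + s(t)``.
    """

    F_A: float
    F_P: float
    k: float
    gamma: float
    L0: float = 1.0
    s_max: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.F_A, self.F_P, self.k, self.gamma, self.L0, self.s_max)
        if any(v <= 0 for v in vals):
            raise ValueError(f"all spindle parameters must be positive: {self}")
        if self.F_P < self.F_A:
            raise ValueError("posterior force F_P must be at least F_A")

    @property
    def s_asymptote(self) -> float:
        """Extension limit (F_P + F_A)/(2k) approached at infinite time."""
        return (self.F_P + self.F_A) / (2.0 * self.k)


@dataclass
class SpindleTrajectory:
    """Pole, plate and extension trajectories plus rupture outcome.

    ``T`` and ``dx_final`` are ``None`` when the spindle stalls (``s_max``
    unreachable).
    """

    times: np.ndarray
    x_A: np.ndarray
    x_P: np.ndarray
    x_MP: np.ndarray
    s: np.ndarray
    T: float | None
    dx_final: float | None


def trajectories(params: SpindleParams, times) -> SpindleTrajectory:
    """Evaluate the closed-form solution on a time grid (all times >= 0)."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    x_mp = (params.F_P - params.F_A) * t / (2.0 * params.gamma)
    s = params.s_asymptote * (1.0 - np.exp(-2.0 * params.k * t / params.gamma))
    x_a = x_mp - s / 2.0
    x_p = x_mp + s / 2.0
    try:
        T = rupture_time(params)
        dx = final_displacement(params)
    except SpindleStallError:
        T = dx = None
    return SpindleTrajectory(times=t, x_A=x_a, x_P=x_p, x_MP=x_mp, s=s,
                             T=T, dx_final=dx)


def rupture_time(params: SpindleParams) -> float:
    """Time T at which the extension reaches ``s_max``.

    Raises
    ------
    SpindleStallError
        When ``s_max >= (F_P + F_A)/(2k)``: the asymptote is reached only at
        infinite time, so mitosis stalls in late metaphase.
    """
    ratio = 2.0 * params.k * params.s_max / (params.F_P + params.F_A)
    if ratio >= 1.0:
        raise SpindleStallError(
            f"s_max = {params.s_max} is not below the extension asymptote "
            f"{params.s_asymptote}; the spindle never ruptures"
        )
    return -(params.gamma / (2.0 * params.k)) * math.log1p(-ratio)


def final_displacement(params: SpindleParams) -> float:
    """Maximum plate travel ``Δx = (F_P − F_A) T / (2γ)`` before rupture."""
    T = rupture_time(params)
    return (params.F_P - params.F_A) * T / (2.0 * params.gamma)


class SpindleModel:
    """Thin model wrapper around the closed forms.

    Examples
    --------
    >>> m = SpindleModel(SpindleParams(F_A=1, F_P=2, k=1, gamma=1, s_max=1))
    >>> round(m.rupture_time(), 4)
    0.5493
    >>> round(m.final_displacement(), 4)
    0.2747
    """

    def __init__(self, params: SpindleParams):
        self.params = params

    def solve(self, t_max: float, n: int = 200) -> SpindleTrajectory:
        return trajectories(self.params, np.linspace(0.0, t_max, n))

    def rupture_time(self) -> float:
        return rupture_time(self.params)

    def final_displacement(self) -> float:
        return final_displacement(self.params)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Constant-force Hookean spindle model",
            "=" * 44,
            f"F_A, F_P        {p.F_A:g}, {p.F_P:g}",
            f"k, gamma        {p.k:g}, {p.gamma:g}",
            f"L0, s_max       {p.L0:g}, {p.s_max:g}",
            f"s asymptote     {p.s_asymptote:g}",
        ]
        try:
            lines.append(f"rupture time T  {self.rupture_time():g}")
            lines.append(f"final shift Δx  {self.final_displacement():g}")
        except SpindleStallError:
            lines.append("outcome         stalled (s_max unreachable)")
        return "\n".join(lines)
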