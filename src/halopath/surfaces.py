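"""Analytic energy surfaces for the synthetic steered-pull engine.

Each :class:`EnergySurface` bundles an energy function (kcal/mol), its analytic
gradient (kcal/mol/Å), and a scalar reaction-coordinate map with its gradient.
Three constructors cover the package's needs:

* :func:`build_two_step_surface` — a 1-D surrogate whose five prescribed
  stationary levels mimic a two-step reaction profile (reactant, first
  transition state, intermediate, second transition state, product) on one
  concatenated reaction-coordinate axis;
* :func:`harmonic_surface` — a quadratic well with a closed-form PMF, the
  analytic oracle for estimator-recovery tests;
* :func:`build_collinear_toy` — a four-particle collinear chain mimicking the
  K79-H···O–Cl···C7 arrangement, so distance-combination coordinates can be
  steered in Cartesian space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from .errors import SurfaceConstructionError


@dataclass(frozen=True)
class EnergySurface:
    """Analytic potential with reaction-coordinate map.

    ``energy``/``gradient`` act on a configuration vector of length
    ``dimension``; ``rc_map``/``rc_gradient`` give the scalar reaction
    coordinate and its Cartesian gradient.  ``rc_is_identity`` marks 1-D
    surfaces whose configuration *is* the reaction coordinate, enabling the
    exact Ornstein-Uhlenbeck treatment of the harmonic bias during steering.
    """

    dimension: int
    energy: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    rc_map: Callable[[np.ndarray], float]
    rc_gradient: Callable[[np.ndarray], np.ndarray]
    rc_is_identity: bool = False
    name: str = "custom"
    meta: dict = field(default_factory=dict)

    def default_x0(self) -> np.ndarray:
        x0 = self.meta.get("x0")
        if x0 is None:
            return np.zeros(self.dimension)
        return np.asarray(x0, dtype=float).copy()


def check_gradient(surface: EnergySurface, points: Sequence[np.ndarray],
                   rtol: float = 1e-5, h: float = 1e-5) -> float:
    """Central-finite-difference check of the analytic gradient.

    Returns the worst relative deviation over the supplied points; raises if
    it exceeds ``rtol`` (scaled by the local gradient magnitude).
    """
    worst = 0.0
    for x in points:
        x = np.asarray(x, dtype=float)
        g = np.asarray(surface.gradient(x), dtype=float)
        fd = np.empty_like(g)
        for d in range(surface.dimension):
            e = np.zeros_like(x)
            e[d] = h
            fd[d] = (surface.energy(x + e) - surface.energy(x - e)) / (2 * h)
        scale = max(1.0, float(np.max(np.abs(g))))
        dev = float(np.max(np.abs(g - fd))) / scale
        worst = max(worst, dev)
    if worst > rtol:
        raise SurfaceConstructionError(
            f"analytic gradient deviates from finite differences by {worst:g} (> {rtol:g})"
        )
    return worst


def _alternation_ok(levels: np.ndarray) -> bool:
    # min, max, min, max, min — strict alternation
    return bool(
        levels[1] > levels[0] and levels[1] > levels[2]
        and levels[3] > levels[2] and levels[3] > levels[4]
    )


def build_two_step_surface(levels: Sequence[float], positions: Sequence[float]) -> EnergySurface:
    """1-D surrogate surface through five prescribed stationary points.

    A cubic Hermite spline with zero slope at every knot interpolates the
    (position, level) pairs exactly, so the interior stationary values equal
    the prescribed levels to machine precision and the segments between knots
    are monotone.  Beyond the terminal knots the potential continues as a
    confining parabola matched in value and (zero) slope.
    """
    levels = np.asarray(levels, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if levels.shape != (5,) or positions.shape != (5,):
        raise SurfaceConstructionError("exactly five levels and five positions are required")
    if not np.all(np.diff(positions) > 0):
        raise SurfaceConstructionError("positions must be strictly increasing")
    if not _alternation_ok(levels):
        raise SurfaceConstructionError(
            "levels must alternate minimum/maximum/minimum/maximum/minimum"
        )

    spline = CubicHermiteSpline(positions, levels, np.zeros(5))
    dspline = spline.derivative()
    xl, xr = positions[0], positions[-1]
    # confine escapes with curvature comparable to the steepest adjacent segment
    kl = max(6.0 * abs(levels[1] - levels[0]) / (positions[1] - positions[0]) ** 2, 10.0)
    kr = max(6.0 * abs(levels[3] - levels[4]) / (positions[4] - positions[3]) ** 2, 10.0)

    def energy(x: np.ndarray) -> float:
        v = float(np.asarray(x).reshape(-1)[0])
        if v < xl:
            return float(levels[0] + 0.5 * kl * (v - xl) ** 2)
        if v > xr:
            return float(levels[-1] + 0.5 * kr * (v - xr) ** 2)
        return float(spline(v))

    def gradient(x: np.ndarray) -> np.ndarray:
        v = float(np.asarray(x).reshape(-1)[0])
        if v < xl:
            return np.array([kl * (v - xl)])
        if v > xr:
            return np.array([kr * (v - xr)])
        return np.array([float(dspline(v))])

    return EnergySurface(
        dimension=1,
        energy=energy,
        gradient=gradient,
        rc_map=lambda x: float(np.asarray(x).reshape(-1)[0]),
        rc_gradient=lambda x: np.array([1.0]),
        rc_is_identity=True,
        name="two_step",
        meta={
            "levels": levels.tolist(),
            "positions": positions.tolist(),
            "x0": [float(positions[0])],
        },
    )


def harmonic_surface(kappa: float, center: float = 0.0) -> EnergySurface:
    """1-D harmonic well U = kappa/2 (x - center)^2; the PMF oracle is U itself."""
    if kappa <= 0:
        raise SurfaceConstructionError("kappa must be positive")

    return EnergySurface(
        dimension=1,
        energy=lambda x: float(0.5 * kappa * (np.asarray(x).reshape(-1)[0] - center) ** 2),
        gradient=lambda x: np.array([kappa * (float(np.asarray(x).reshape(-1)[0]) - center)]),
        rc_map=lambda x: float(np.asarray(x).reshape(-1)[0]),
        rc_gradient=lambda x: np.array([1.0]),
        rc_is_identity=True,
        name="harmonic",
        meta={"kappa": kappa, "center": center, "x0": [center]},
    )


def build_collinear_toy(
    s0: float = 4.0,
    half_width: float = 0.5,
    barrier: float = 5.0,
    k_asym: float = 50.0,
    k_mid: float = 100.0,
    b0: float = 2.8,
    k_tether: float = 5.0,
) -> EnergySurface:
    """Four collinear particles (H, O, Cl, C) with a double-well along -d(H,O)-d(Cl,C).

    Internal coordinates: a = d(H,O), b = d(O,Cl), c = d(Cl,C), with
    s = a + c.  The potential is a symmetric quartic double well in s (minima
    at s0 ± half_width, barrier height ``barrier``), harmonic restraints on
    the asymmetry u = a - c and the middle bond b, and a weak tether on the
    first particle that removes the rigid-translation zero mode.  The reaction
    coordinate is the distance combination rc = -a - c = -s, so the analytic
    equilibrium rc values are -(s0 ± half_width).
    """
    hw = half_width
    if hw <= 0 or barrier <= 0:
        raise SurfaceConstructionError("half_width and barrier must be positive")

    def _internal(x: np.ndarray):
        x = np.asarray(x, dtype=float).reshape(-1)
        a = x[1] - x[0]
        b = x[2] - x[1]
        c = x[3] - x[2]
        return x, a, b, c

    def energy(x: np.ndarray) -> float:
        x, a, b, c = _internal(x)
        s = a + c
        u = a - c
        w = barrier * ((s - s0) ** 2 - hw**2) ** 2 / hw**4
        return float(w + 0.5 * k_asym * u**2 + 0.5 * k_mid * (b - b0) ** 2
                     + 0.5 * k_tether * x[0] ** 2)

    def gradient(x: np.ndarray) -> np.ndarray:
        x, a, b, c = _internal(x)
        s = a + c
        u = a - c
        dw_ds = barrier * 4.0 * ((s - s0) ** 2 - hw**2) * (s - s0) / hw**4
        du = k_asym * u
        db = k_mid * (b - b0)
        # chain rule through a = x1-x0, b = x2-x1, c = x3-x2
        g = np.zeros(4)
        g[0] = -(dw_ds + du) + k_tether * x[0]
        g[1] = (dw_ds + du) - db
        g[2] = db - (dw_ds - du)
        g[3] = dw_ds - du
        return g

    rc_grad = np.array([1.0, -1.0, 1.0, -1.0])  # d(-a-c)/dx

    def rc_map(x: np.ndarray) -> float:
        x, a, _, c = _internal(x)
        return float(-a - c)

    s_min = s0 - hw
    x0 = np.array([0.0, s_min / 2.0, s_min / 2.0 + b0, s_min + b0])
    return EnergySurface(
        dimension=4,
        energy=energy,
        gradient=gradient,
        rc_map=rc_map,
        rc_gradient=lambda x: rc_grad.copy(),
        rc_is_identity=False,
        name="collinear_toy",
        meta={
            "x0": x0.tolist(),
            "rc_minima": [-(s0 - hw), -(s0 + hw)],
            "barrier": barrier,
        },
    )


_SURFACE_BUILDERS = {
    "two_step": build_two_step_surface,
    "harmonic": harmonic_surface,
    "collinear_toy": build_collinear_toy,
}


def surface_from_config(name: str, params: dict | None = None) -> EnergySurface:
    """Build a named surface from a configuration mapping (used by the pipeline)."""
    if name not in _SURFACE_BUILDERS:
        raise SurfaceConstructionError(
            f"unknown surface '{name}'; available: {sorted(_SURFACE_BUILDERS)}"
        )
    return _SURFACE_BUILDERS[name](**(params or {}))
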