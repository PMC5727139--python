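"""Steered overdamped-Langevin pulls with a moving harmonic bias.

The engine emulates the statistical structure of multiple steered molecular
dynamics (MSMD): a harmonic restraint ``V(lambda; t) = k/2 (rc(x) - lambda(t))^2``
whose center sweeps a reaction-coordinate schedule, per-step accumulated
external work, forward and reverse pull pairs from relaxed initial states, and
deterministic adiabatic mapping (restrained minimization along a grid).

Dynamics are overdamped (Brownian):  ``zeta dx = -grad(U_total) dt + noise``,
with ``zeta`` the drag coefficient in kcal mol^-1 fs Å^-2 and diffusion
``D = kB*T/zeta``.  For 1-D surfaces whose configuration *is* the reaction
coordinate, the stiff harmonic bias plus the locally frozen surface gradient
is propagated as an exact Ornstein-Uhlenbeck step, which is stable at the
stiff bias constants typical of steered QM/MM-MD (5000 kcal/mol/Å^2 at
0.5 fs); general surfaces use explicit Euler-Maruyama.

Work convention (shared with the estimators): the bias center moves in
``n_substeps`` micro-increments per schedule step, and each micro-increment
accumulates the exact center-displacement work at the pre-move configuration,
``V(x, lambda + dlambda) - V(x, lambda) = -k (rc(x) - lambda_mid) dlambda``.
Summed over substeps this is the thermodynamic-integration work dV/dlambda
evaluated before each move (positive when pulling uphill), and it makes the
discrete pull protocol satisfy the Crooks fluctuation theorem exactly — a
naive single-increment-per-step rule at a stiff bias under-counts every step
by ``k dlambda^2 / 2`` and under-resolves the trap correlation time, which
would bias all downstream free-energy estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np
from scipy.optimize import minimize

from .errors import AdiabaticMapError, IntegrationError
from .surfaces import EnergySurface
from .thermo import KB_KCAL_MOL_K, ThermoContext

#: Default pull schedule parameters for chlorine-transfer (Å) and
#: proton-transfer (dimensionless mid-plane) coordinates.
RC1_RANGE = (-4.7, -2.6)
RC2_RANGE = (0.3, 0.8)
DEFAULT_N_STEPS = 3000
DEFAULT_DT_FS = 0.5
DEFAULT_BIAS_K = 5000.0


@dataclass(frozen=True)
class SteeringSchedule:
    """Linear bias-center schedule lambda(t) with a harmonic force constant.

    ``k`` is in kcal mol^-1 per (RC unit)^2 — Å^-2 for distance-combination
    coordinates, dimensionless^-2 for the mid-plane ratio.
    """

    lambda_start: float
    lambda_end: float
    n_steps: int = DEFAULT_N_STEPS
    dt: float = DEFAULT_DT_FS  # fs
    k: float = DEFAULT_BIAS_K
    direction: str = "forward"

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.k <= 0:
            raise ValueError("bias force constant k must be positive")
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be 'forward' or 'reverse'")

    def centers(self) -> np.ndarray:
        """Bias centers lambda_0 .. lambda_N (length n_steps + 1)."""
        return np.linspace(self.lambda_start, self.lambda_end, self.n_steps + 1)

    def times(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt

    def reversed(self) -> "SteeringSchedule":
        flipped = "reverse" if self.direction == "forward" else "forward"
        return replace(self, lambda_start=self.lambda_end,
                       lambda_end=self.lambda_start, direction=flipped)


@dataclass(frozen=True)
class LangevinParams:
    """Overdamped-Langevin parameters.

    ``friction`` is the drag coefficient zeta in kcal mol^-1 fs Å^-2 (diffusion
    constant D = kB*T/zeta).  ``n_substeps`` subdivides each schedule step —
    both the dynamics and the bias-center motion — so that the integrator
    resolves the bias-trap correlation time zeta/k; at the defaults
    (zeta = 100, k = 5000, dt = 0.5 fs) the substep is 0.02 fs, matching it.
    The recorded trace keeps one entry per schedule step regardless.
    """

    temperature: float = 300.0  # K
    friction: float = 100.0
    seed: int = 0
    boltzmann_constant: float = KB_KCAL_MOL_K
    n_substeps: int = 25

    def __post_init__(self):
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")

    @property
    def kT(self) -> float:
        return self.boltzmann_constant * self.temperature

    def thermo(self) -> ThermoContext:
        if self.temperature == 0:
            raise ValueError("ThermoContext undefined at zero temperature")
        return ThermoContext(temperature=self.temperature, kB=self.boltzmann_constant)


@dataclass
class WorkTrace:
    """Per-step record of one steered pull.

    Arrays of length ``n_steps + 1``: time (fs), bias center, realized reaction
    coordinate, and cumulative external work (kcal/mol, zero at t = 0).
    """

    t: np.ndarray
    lambda_center: np.ndarray
    rc_value: np.ndarray
    work: np.ndarray
    direction: str = "forward"
    seed: int = 0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.lambda_center = np.asarray(self.lambda_center, dtype=float)
        self.rc_value = np.asarray(self.rc_value, dtype=float)
        self.work = np.asarray(self.work, dtype=float)
        n = len(self.t)
        for name in ("lambda_center", "rc_value", "work"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from t")
        if abs(self.work[0]) > 1e-12:
            raise ValueError("cumulative work must be zero at t = 0")
        d = np.diff(self.lambda_center)
        if len(d) and not (np.all(d >= -1e-12) or np.all(d <= 1e-12)):
            raise ValueError("bias center must follow the schedule monotonically")

    @property
    def n_steps(self) -> int:
        return len(self.t) - 1

    @property
    def total_work(self) -> float:
        return float(self.work[-1])


@dataclass
class PullEnsemble:
    """Forward and reverse work traces at a stated temperature.

    ``schedule`` is the *forward* schedule; reverse traces traverse
    lambda_end -> lambda_start with the same step count.
    """

    forward: List[WorkTrace]
    reverse: List[WorkTrace]
    thermo: ThermoContext
    schedule: SteeringSchedule

    def __post_init__(self):
        n = self.schedule.n_steps
        for tr in self.forward:
            if tr.n_steps != n:
                raise ValueError("forward trace step count differs from schedule")
        for tr in self.reverse:
            if tr.n_steps != n:
                raise ValueError("reverse trace step count differs from schedule")
            if not np.isclose(tr.lambda_center[0], self.schedule.lambda_end):
                raise ValueError("reverse traces must start at the forward schedule's end")

    @property
    def n_forward(self) -> int:
        return len(self.forward)

    @property
    def n_reverse(self) -> int:
        return len(self.reverse)


def _ou_step(x: float, lam: float, g: float, k: float, zeta: float, kT: float,
             h: float, rng: np.random.Generator) -> float:
    """Exact OU update for the harmonic bias with the surface force frozen at x."""
    mu = lam - g / k
    decay = math.exp(-(k / zeta) * h)
    noise_var = (kT / k) * (1.0 - decay * decay)
    xn = mu + (x - mu) * decay
    if noise_var > 0.0:
        xn += math.sqrt(noise_var) * rng.standard_normal()
    return xn


def _propagate(surface: EnergySurface, x: np.ndarray, lam: float, n_steps: int,
               schedule: SteeringSchedule, params: LangevinParams,
               rng: np.random.Generator, step_offset: int = 0) -> np.ndarray:
    """Advance the biased dynamics ``n_steps`` schedule steps at fixed bias center."""
    k = schedule.k
    zeta = params.friction
    kT = params.kT
    h = schedule.dt / params.n_substeps
    if surface.rc_is_identity and surface.dimension == 1:
        v = float(x[0])
        for i in range(n_steps * params.n_substeps):
            g = float(surface.gradient(np.array([v]))[0])
            v = _ou_step(v, lam, g, k, zeta, kT, h, rng)
            if not math.isfinite(v):
                raise IntegrationError(step_offset + i // params.n_substeps)
        return np.array([v])
    sig = math.sqrt(2.0 * kT * h / zeta) if kT > 0 else 0.0
    for i in range(n_steps * params.n_substeps):
        force = -(np.asarray(surface.gradient(x))
                  + k * (surface.rc_map(x) - lam) * np.asarray(surface.rc_gradient(x)))
        x = x + force * (h / zeta)
        if sig > 0.0:
            x = x + sig * rng.standard_normal(surface.dimension)
        if not np.all(np.isfinite(x)):
            raise IntegrationError(step_offset + i // params.n_substeps)
    return x


def simulate_pull(
    surface: EnergySurface,
    schedule: SteeringSchedule,
    params: LangevinParams,
    x0: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    return_final_state: bool = False,
):
    """One steered pull; returns a :class:`WorkTrace` (reproducible from the seed).

    ``x0`` defaults to the surface's reference configuration (for identity-RC
    surfaces, the schedule start).  When ``return_final_state`` is true, the
    final configuration vector is returned alongside the trace.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if x0 is None:
        if surface.rc_is_identity and surface.dimension == 1:
            x = np.array([schedule.lambda_start])
        else:
            x = surface.default_x0()
    else:
        x = np.asarray(x0, dtype=float).copy()

    centers = schedule.centers()
    n = schedule.n_steps
    n_sub = params.n_substeps
    k = schedule.k
    zeta = params.friction
    kT = params.kT
    h = schedule.dt / n_sub
    identity = surface.rc_is_identity and surface.dimension == 1
    if identity:
        decay = math.exp(-(k / zeta) * h)
        noise_sd = math.sqrt((kT / k) * (1.0 - decay * decay)) if kT > 0 else 0.0
        v = float(x[0])
    sig = math.sqrt(2.0 * kT * h / zeta) if kT > 0 else 0.0

    rc = np.empty(n + 1)
    work = np.empty(n + 1)
    w = 0.0
    for i in range(n):
        lam = float(centers[i])
        dlam_sub = (float(centers[i + 1]) - lam) / n_sub
        if identity:
            rc[i] = v
            work[i] = w
            if not math.isfinite(v):
                raise IntegrationError(i)
            for _ in range(n_sub):
                # exact center-displacement work at the pre-move configuration
                w += -k * (v - (lam + 0.5 * dlam_sub)) * dlam_sub
                lam += dlam_sub
                g = float(surface.gradient(np.array([v]))[0])
                mu = lam - g / k
                v = mu + (v - mu) * decay
                if noise_sd > 0.0:
                    v += noise_sd * rng.standard_normal()
        else:
            rci = surface.rc_map(x)
            if not math.isfinite(rci) or not math.isfinite(surface.energy(x)):
                raise IntegrationError(i)
            rc[i] = rci
            work[i] = w
            for _ in range(n_sub):
                rci = surface.rc_map(x)
                w += -k * (rci - (lam + 0.5 * dlam_sub)) * dlam_sub
                lam += dlam_sub
                force = -(np.asarray(surface.gradient(x))
                          + k * (surface.rc_map(x) - lam)
                          * np.asarray(surface.rc_gradient(x)))
                x = x + force * (h / zeta)
                if sig > 0.0:
                    x = x + sig * rng.standard_normal(surface.dimension)
                if not np.all(np.isfinite(x)):
                    raise IntegrationError(i)
    if identity:
        if not math.isfinite(v):
            raise IntegrationError(n)
        x = np.array([v])
    rc[n] = surface.rc_map(x)
    work[n] = w
    trace = WorkTrace(t=schedule.times(), lambda_center=centers, rc_value=rc,
                      work=work, direction=schedule.direction, seed=params.seed)
    if return_final_state:
        return trace, x
    return trace


def _child_seed(master: int, stream: int, index: int) -> int:
    """Counter-based child seed derivation (stable across runs, < 2^31)."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=(stream, index))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_msmd(
    surface: EnergySurface,
    schedule: SteeringSchedule,
    params: LangevinParams,
    n_forward: int = 15,
    n_reverse: int = 15,
    relax_steps: int = 1000,
) -> PullEnsemble:
    """Multiple steered pulls: forward from relaxed starts, reverse from forward endpoints.

    Each forward pull starts from an independently relaxed initial state
    (``relax_steps`` of dynamics with the bias held at lambda_start, distinct
    counter-derived seeds).  Reverse pulls start from the forward endpoints,
    re-relaxed with the bias held at lambda_end, and traverse the schedule
    backwards.  All per-trace seeds are recorded; identical master seeds give
    identical ensembles.
    """
    if n_forward < 1 or n_reverse < 0:
        raise ValueError("n_forward must be >= 1 and n_reverse >= 0")
    rev_schedule = schedule.reversed()
    forward: List[WorkTrace] = []
    endpoints: List[np.ndarray] = []
    for i in range(n_forward):
        seed_i = _child_seed(params.seed, 0, i)
        rng = np.random.default_rng(seed_i)
        p_i = replace(params, seed=seed_i)
        x = (np.array([schedule.lambda_start])
             if surface.rc_is_identity and surface.dimension == 1
             else surface.default_x0())
        if relax_steps > 0:
            x = _propagate(surface, x, schedule.lambda_start, relax_steps,
                           schedule, p_i, rng)
        trace, xf = simulate_pull(surface, schedule, p_i, x0=x, rng=rng,
                                  return_final_state=True)
        forward.append(trace)
        endpoints.append(xf)

    reverse: List[WorkTrace] = []
    for j in range(n_reverse):
        seed_j = _child_seed(params.seed, 1, j)
        rng = np.random.default_rng(seed_j)
        p_j = replace(params, seed=seed_j)
        x = endpoints[j % n_forward].copy()
        if relax_steps > 0:
            x = _propagate(surface, x, schedule.lambda_end, relax_steps,
                           rev_schedule, p_j, rng)
        reverse.append(simulate_pull(surface, rev_schedule, p_j, x0=x, rng=rng))

    return PullEnsemble(forward=forward, reverse=reverse,
                        thermo=params.thermo(), schedule=schedule)


def adiabatic_map(
    surface: EnergySurface,
    rc_grid: np.ndarray,
    restraint_k: float = DEFAULT_BIAS_K,
    x0: Optional[np.ndarray] = None,
    gtol: float = 1e-8,
) -> np.ndarray:
    """Deterministic reaction-path scan by restrained minimization.

    At each grid value the full configuration is minimized under
    ``U(x) + restraint_k/2 (rc(x) - lambda)^2``, warm-started from the previous
    grid point's minimizer.  Returns the unrestrained energy at each minimizer,
    shifted so the first grid point is zero.
    """
    rc_grid = np.asarray(rc_grid, dtype=float)
    if rc_grid.size == 0:
        raise ValueError("rc_grid must be non-empty")
    x = np.asarray(x0, dtype=float).copy() if x0 is not None else surface.default_x0()
    if surface.rc_is_identity and surface.dimension == 1:
        x = np.array([rc_grid[0]])

    energies = np.empty(rc_grid.size)
    for idx, lam in enumerate(rc_grid):
        def objective(xv, lam=lam):
            rc = surface.rc_map(xv)
            e = surface.energy(xv) + 0.5 * restraint_k * (rc - lam) ** 2
            g = (np.asarray(surface.gradient(xv))
                 + restraint_k * (rc - lam) * np.asarray(surface.rc_gradient(xv)))
            return e, g

        res = minimize(objective, x, jac=True, method="L-BFGS-B",
                       options={"gtol": gtol, "maxiter": 500})
        if not res.success and np.linalg.norm(res.jac) > 1e-4:
            raise AdiabaticMapError(idx, float(lam), res.message)
        x = res.x
        energies[idx] = surface.energy(x)
    return energies - energies[0]
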