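"""Mechanistic post-analysis of reaction profiles and trajectories.

Turns free-energy / potential-energy profiles into stationary points,
per-step barriers and multi-step energy diagrams; turns charged trajectories
into fragment-charge series along the reaction coordinate and into
stationary-state geometry summaries (mean ± std of named distances/angles
inside reaction-coordinate windows).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .coords import (
    ReactionCoordinate,
    Trajectory,
    angle,
    distance,
    rc_series,
)
from .errors import HalopathError, NoTransitionStateError
from .estimators import PMFProfile


@dataclass(frozen=True)
class StationaryPoints:
    """Reactant / transition-state / product of one reaction step, as (rc, energy)."""

    reactant: Tuple[float, float]
    transition: Tuple[float, float]
    product: Tuple[float, float]

    def __post_init__(self):
        if self.transition[1] < max(self.reactant[1], self.product[1]) - 1e-12:
            raise ValueError("transition energy must not lie below the neighboring minima")


@dataclass(frozen=True)
class StepEnergetics:
    """Forward barrier, reaction energy and the implied backward barrier (kcal/mol).

    The identity backward = forward - reaction holds by construction and is
    validated to 1e-9 when all three are supplied.
    """

    dg_forward_barrier: float
    dg_reaction: float
    dg_backward_barrier: float = None  # type: ignore[assignment]
    sem: Optional[Tuple[float, float, float]] = None

    def __post_init__(self):
        implied = self.dg_forward_barrier - self.dg_reaction
        if self.dg_backward_barrier is None:
            object.__setattr__(self, "dg_backward_barrier", implied)
        elif abs(self.dg_backward_barrier - implied) > 1e-9:
            raise ValueError(
                "backward barrier inconsistent with forward barrier minus reaction energy"
            )


@dataclass(frozen=True)
class EnergyDiagram:
    """Cumulative multi-step energy diagram relative to the initial reactant.

    ``cumulative_levels`` lists RC1, TS1, PC1(=RC2), TS2, PC2, ... as prefix
    sums of the per-step energetics; ``global_max`` is the highest cumulative
    transition-state level and ``total_reaction`` the sum of step reaction
    energies.
    """

    step_energetics: Tuple[StepEnergetics, ...]
    cumulative_levels: Tuple[float, ...]
    global_max: float
    total_reaction: float


@dataclass(frozen=True)
class FragmentDef:
    """Named set of atom indices whose charges are summed into one fragment charge."""

    name: str
    atom_indices: Tuple[int, ...]

    def __init__(self, name: str, atom_indices: Sequence[int]):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "atom_indices", tuple(int(i) for i in atom_indices))
        if not self.atom_indices:
            raise ValueError(f"fragment '{name}' has no atoms")


@dataclass(frozen=True)
class CoordinateSpec:
    """Named internal coordinate: a distance (2 atoms) or an angle (3 atoms)."""

    name: str
    kind: str  # "distance" | "angle"
    atoms: Tuple[int, ...]

    def __post_init__(self):
        if self.kind == "distance" and len(self.atoms) != 2:
            raise ValueError("distance coordinate needs exactly two atoms")
        if self.kind == "angle" and len(self.atoms) != 3:
            raise ValueError("angle coordinate needs exactly three atoms")
        if self.kind not in ("distance", "angle"):
            raise ValueError(f"unknown coordinate kind '{self.kind}'")

    def evaluate(self, frame) -> float:
        if self.kind == "distance":
            return distance(frame, *self.atoms)
        return angle(frame, *self.atoms)


@dataclass
class StateWindowSummary:
    """Mean ± sample std of named coordinates over frames inside one RC window."""

    rc_window: Tuple[float, float]
    n_frames: int
    stats: Dict[str, Tuple[float, float]]  # name -> (mean, std)


ProfileLike = Union[PMFProfile, Tuple[np.ndarray, np.ndarray]]


def _profile_arrays(profile: ProfileLike) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(profile, PMFProfile):
        occ = profile.occupied
        return profile.grid.centers[occ], profile.g0[occ]
    x, y = profile
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    return x[ok], y[ok]


def _local_maxima(y: np.ndarray) -> List[int]:
    """Interior strict local maxima; plateaus count once at their first bin."""
    idx = []
    n = y.size
    i = 1
    while i < n - 1:
        j = i
        while j < n - 1 and y[j + 1] == y[j]:
            j += 1  # skip over a flat run
        if y[i] > y[i - 1] and j < n - 1 and y[j] > y[j + 1]:
            idx.append(i)
        i = j + 1
    return idx


def locate_stationary_points(profile: ProfileLike,
                             n_steps: Optional[int] = None) -> List[StationaryPoints]:
    """Stationary points of a (possibly multi-step) profile.

    Transition states are the highest bins between basins (the raw bin
    maximum — appropriate for profiles whose peaks are only resolved to the
    bin width); basin minima are the lowest bins of the segments delimited by
    the interior maxima.  Returns one :class:`StationaryPoints` per step; a
    profile with no interior maximum raises :class:`NoTransitionStateError`.

    On noisy estimated profiles every small wiggle is a strict local maximum;
    pass ``n_steps`` to keep only the ``n_steps`` most prominent interior
    peaks (peak prominence in the usual topographic sense).
    """
    x, y = _profile_arrays(profile)
    if x.size < 3:
        raise HalopathError("profile needs at least three occupied bins")
    maxima = _local_maxima(y)
    if not maxima:
        raise NoTransitionStateError("profile has no interior maximum between basins")
    if n_steps is not None and len(maxima) > n_steps:
        from scipy.signal import peak_prominences
        prom = peak_prominences(y, maxima)[0]
        keep = np.sort(np.argsort(prom)[-n_steps:])
        maxima = [maxima[i] for i in keep]
    bounds = [0] + maxima + [y.size - 1]
    minima = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        lo, hi = (a, b + 1) if b == y.size - 1 else (a, b)
        if a in maxima:
            lo = a + 1
        seg = slice(lo, hi)
        minima.append(lo + int(np.argmin(y[seg])))
    steps = []
    for k, m in enumerate(maxima):
        steps.append(StationaryPoints(
            reactant=(float(x[minima[k]]), float(y[minima[k]])),
            transition=(float(x[m]), float(y[m])),
            product=(float(x[minima[k + 1]]), float(y[minima[k + 1]])),
        ))
    return steps


def step_energetics(points: StationaryPoints) -> StepEnergetics:
    """Barriers and reaction energy of one step from its stationary points."""
    r, t, p = points.reactant[1], points.transition[1], points.product[1]
    return StepEnergetics(dg_forward_barrier=t - r, dg_reaction=p - r)


def compose_diagram(steps: Sequence[StepEnergetics]) -> EnergyDiagram:
    """Chain per-step energetics into a cumulative diagram.

    Each step's reactant is the previous step's product, so cumulative levels
    are prefix sums; the global maximum is reported relative to the initial
    reactant complex.
    """
    steps = tuple(steps)
    if not steps:
        raise ValueError("compose_diagram needs at least one step")
    levels = [0.0]
    base = 0.0
    ts_levels = []
    for s in steps:
        ts = base + s.dg_forward_barrier
        base = base + s.dg_reaction
        ts_levels.append(ts)
        levels.extend([ts, base])
    return EnergyDiagram(
        step_energetics=steps,
        cumulative_levels=tuple(levels),
        global_max=float(max(ts_levels)),
        total_reaction=float(base),
    )


def extend_diagram(diagram: EnergyDiagram, steps: Sequence[StepEnergetics]) -> EnergyDiagram:
    """Append further steps to an existing diagram (associative with compose)."""
    return compose_diagram(tuple(diagram.step_energetics) + tuple(steps))


def aggregate_fragment_charges(
    traj: Trajectory,
    fragments: Sequence[FragmentDef],
    rc_spec: ReactionCoordinate,
) -> pd.DataFrame:
    """Per-frame fragment charges indexed by the frame's reaction-coordinate value.

    Returns a long-form frame with columns ``frame``, ``rc``, ``fragment``,
    ``charge`` (a.u.).  Fragments must be disjoint; every frame must carry
    charges.
    """
    seen: set[int] = set()
    for fr in fragments:
        overlap = seen.intersection(fr.atom_indices)
        if overlap:
            raise ValueError(f"fragment '{fr.name}' overlaps earlier fragments at atoms {sorted(overlap)}")
        seen.update(fr.atom_indices)
    n_atoms = traj.n_atoms
    if seen and max(seen) >= n_atoms:
        raise IndexError("fragment atom index out of range")

    rcs = rc_series(traj, rc_spec)
    rows = []
    for k, frame in enumerate(traj):
        if frame.charges is None:
            raise ValueError(f"frame {k} carries no charges")
        for fr in fragments:
            rows.append((k, rcs[k], fr.name,
                         float(frame.charges[list(fr.atom_indices)].sum())))
    return pd.DataFrame(rows, columns=["frame", "rc", "fragment", "charge"])


def bin_fragment_charges(series: pd.DataFrame, edges: Sequence[float]) -> pd.DataFrame:
    """Average a fragment-charge series over reaction-coordinate bins.

    Returns columns ``rc`` (bin center), ``fragment``, ``mean_charge``,
    ``std`` — the Figure-9-style ensemble average along the pull coordinate.
    """
    edges = np.asarray(edges, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = series.copy()
    out["bin"] = np.clip(np.searchsorted(edges, out["rc"], side="right") - 1,
                         0, len(centers) - 1)
    grouped = (out.groupby(["bin", "fragment"])["charge"]
               .agg(["mean", "std", "count"]).reset_index())
    grouped["rc"] = centers[grouped["bin"]]
    grouped["std"] = grouped["std"].fillna(0.0)
    return grouped.rename(columns={"mean": "mean_charge"})[
        ["rc", "fragment", "mean_charge", "std", "count"]]


def state_summary(
    traj: Trajectory,
    rc_spec: ReactionCoordinate,
    windows: Sequence[Tuple[float, float]],
    coords: Sequence[CoordinateSpec],
) -> List[StateWindowSummary]:
    """Mean ± sample std of named coordinates in each reaction-coordinate window.

    Windows are inclusive ``(low, high)`` intervals on the reaction
    coordinate; an empty window is an error naming the window.  A single-frame
    window reports std 0.0 (the sample estimator is undefined there).
    """
    rcs = rc_series(traj, rc_spec)
    summaries = []
    for lo, hi in windows:
        mask = (rcs >= lo) & (rcs <= hi)
        n = int(np.count_nonzero(mask))
        if n == 0:
            raise HalopathError(f"window ({lo}, {hi}) captures no frames")
        stats: Dict[str, Tuple[float, float]] = {}
        frames = [traj[i] for i in np.flatnonzero(mask)]
        for spec in coords:
            vals = np.array([spec.evaluate(fr) for fr in frames])
            std = float(np.std(vals, ddof=1)) if n > 1 else 0.0
            stats[spec.name] = (float(np.mean(vals)), std)
        summaries.append(StateWindowSummary(rc_window=(float(lo), float(hi)),
                                            n_frames=n, stats=stats))
    return summaries
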