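"""Cartesian frames, reaction coordinates and hydrogen-bond statistics.

A :class:`Frame` holds one snapshot of atomic Cartesian coordinates (Å) with
element labels and optional per-atom partial charges (a.u.).  Reaction
coordinates come in two flavours used in electrophilic aromatic substitution
studies:

* :class:`LinearDistanceRC` — a signed linear combination of interatomic
  distances, e.g. ``d[O-Cl] - d[Cl-C]`` tracking simultaneous bond breaking
  and bond formation during chlorine transfer;
* :class:`MidplaneRC` — the dimensionless proton-transfer coordinate r/R,
  the scalar projection of the donor→hydrogen vector onto the donor→acceptor
  axis divided by the donor–acceptor distance.  Values below 0.5 mean the
  hydrogen is still on the donor carbon; 0.5 is the halfway point.

Atom indexing is 0-based everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import GeometryError


@dataclass
class Frame:
    """One Cartesian snapshot: element labels, positions (Å), optional charges (a.u.)."""

    elements: list[str]
    positions: np.ndarray
    charges: Optional[np.ndarray] = None
    time: Optional[float] = None  # fs

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if len(self.elements) != self.positions.shape[0]:
            raise ValueError("elements and positions disagree on atom count")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.shape != (self.positions.shape[0],):
                raise ValueError("charges must have one entry per atom")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def _check_index(self, *indices: int) -> None:
        for i in indices:
            if not (0 <= i < self.n_atoms):
                raise IndexError(f"atom index {i} out of range for {self.n_atoms} atoms")


@dataclass
class Trajectory:
    """Ordered list of frames sharing one atom count and element list."""

    frames: list[Frame]

    def __post_init__(self):
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        ref = self.frames[0]
        for k, fr in enumerate(self.frames):
            if fr.n_atoms != ref.n_atoms:
                raise ValueError(f"frame {k} has {fr.n_atoms} atoms, expected {ref.n_atoms}")
            if fr.elements != ref.elements:
                raise ValueError(f"frame {k} element labels differ from frame 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, k):
        return self.frames[k]

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def elements(self) -> list[str]:
        return self.frames[0].elements


@dataclass(frozen=True)
class LinearDistanceRC:
    """Signed linear combination of interatomic distances, in Å.

    ``terms`` is a sequence of ``(coefficient, (i, j))`` pairs; the value is
    ``sum(c * d(i, j))``.
    """

    terms: Tuple[Tuple[float, Tuple[int, int]], ...]

    def __init__(self, terms: Sequence[Tuple[float, Tuple[int, int]]]):
        terms = tuple((float(c), (int(p[0]), int(p[1]))) for c, p in terms)
        if not terms:
            raise ValueError("LinearDistanceRC needs at least one term")
        for _, (i, j) in terms:
            if i == j:
                raise ValueError(f"degenerate atom pair ({i}, {j}) in reaction coordinate")
        object.__setattr__(self, "terms", terms)


@dataclass(frozen=True)
class MidplaneRC:
    """Mid-plane proton-transfer coordinate r/R over (donor C, transferring H, acceptor O)."""

    c_atom: int
    h_atom: int
    o_atom: int

    def __post_init__(self):
        if len({self.c_atom, self.h_atom, self.o_atom}) != 3:
            raise ValueError("mid-plane coordinate needs three distinct atom indices")


ReactionCoordinate = Union[LinearDistanceRC, MidplaneRC]


@dataclass(frozen=True)
class HBondCriterion:
    """Distance (and optionally angle) criterion for one donor-H···acceptor contact.

    The angle criterion needs the donor heavy atom; ``donor`` is therefore
    required whenever ``min_angle`` is given.  The default criterion is
    distance-only.
    """

    donor_h: int
    acceptor: int
    max_distance: float  # Å
    min_angle: Optional[float] = None  # degrees, donor–H···acceptor
    donor: Optional[int] = None

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if self.min_angle is not None:
            if not (0.0 <= self.min_angle <= 180.0):
                raise ValueError("min_angle must lie in [0, 180] degrees")
            if self.donor is None:
                raise ValueError("an angle criterion requires the donor heavy-atom index")


@dataclass
class HBondStats:
    """Occupancy percentage and the histogram-mode donor-H···acceptor distance."""

    occupancy_percent: float
    mode_distance: float
    n_frames: int
    bin_width: float = 0.05


def distance(frame: Frame, i: int, j: int) -> float:
    """Euclidean distance between atoms ``i`` and ``j`` in Å."""
    if i == j:
        raise ValueError("distance is undefined for a degenerate pair (i == j)")
    frame._check_index(i, j)
    return float(np.linalg.norm(frame.positions[i] - frame.positions[j]))


def angle(frame: Frame, i: int, j: int, k: int) -> float:
    """Angle i–j–k in degrees with ``j`` at the vertex, in [0, 180]."""
    if len({i, j, k}) != 3:
        raise ValueError("angle needs three distinct atom indices")
    frame._check_index(i, j, k)
    a = frame.positions[i] - frame.positions[j]
    b = frame.positions[k] - frame.positions[j]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise GeometryError("angle undefined: vertex coincides with an arm atom")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def eval_linear_rc(frame: Frame, spec: LinearDistanceRC) -> float:
    """Evaluate a signed distance-combination reaction coordinate (Å)."""
    return float(sum(c * distance(frame, i, j) for c, (i, j) in spec.terms))


def eval_midplane_rc(frame: Frame, spec: MidplaneRC) -> float:
    """Evaluate the dimensionless mid-plane coordinate r/R.

    R is the donor–acceptor distance; r is the scalar projection of the
    donor→hydrogen vector onto the donor→acceptor unit vector.  The value is
    reported as-is (it may be negative when H lies behind the donor).
    """
    frame._check_index(spec.c_atom, spec.h_atom, spec.o_atom)
    co = frame.positions[spec.o_atom] - frame.positions[spec.c_atom]
    R = np.linalg.norm(co)
    if R == 0.0:
        raise GeometryError("mid-plane coordinate undefined: donor and acceptor coincide")
    ch = frame.positions[spec.h_atom] - frame.positions[spec.c_atom]
    r = float(np.dot(ch, co) / R)
    return r / float(R)


def evaluate_rc(frame: Frame, spec: ReactionCoordinate) -> float:
    """Dispatch on the reaction-coordinate kind."""
    if isinstance(spec, LinearDistanceRC):
        return eval_linear_rc(frame, spec)
    if isinstance(spec, MidplaneRC):
        return eval_midplane_rc(frame, spec)
    raise TypeError(f"unknown reaction-coordinate spec {type(spec).__name__}")


def rc_series(traj: Trajectory, spec: ReactionCoordinate) -> np.ndarray:
    """Reaction-coordinate value for every frame of a trajectory."""
    return np.array([evaluate_rc(fr, spec) for fr in traj])


def hbond_occupancy(traj: Trajectory, crit: HBondCriterion, bin_width: float = 0.05) -> HBondStats:
    """Fraction of frames satisfying a hydrogen-bond criterion, plus the modal distance.

    The modal donor-H···acceptor distance is the center of the highest-count
    histogram bin over all frames (fixed ``bin_width``, default 0.05 Å, edges
    anchored at multiples of the bin width); ties break toward the smaller
    distance.
    """
    dists = np.array([distance(fr, crit.donor_h, crit.acceptor) for fr in traj])
    ok = dists <= crit.max_distance
    if crit.min_angle is not None:
        angs = np.array([angle(fr, crit.donor, crit.donor_h, crit.acceptor) for fr in traj])
        ok &= angs >= crit.min_angle
    occupancy = 100.0 * float(np.count_nonzero(ok)) / len(dists)

    lo = np.floor(dists.min() / bin_width) * bin_width
    hi = np.ceil(dists.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(dists, bins=edges)
    mode_idx = int(np.argmax(counts))  # argmax returns the first (smallest-distance) tie
    mode = 0.5 * (edges[mode_idx] + edges[mode_idx + 1])
    return HBondStats(occupancy_percent=occupancy, mode_distance=float(mode),
                      n_frames=len(dists), bin_width=bin_width)
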