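"""Readers and writers for the package's plain-text formats.

Trajectories travel as standard multi-frame XYZ (count line, comment line,
``element x y z`` records, 0-based atom indexing in all companion tables);
per-atom charges as a CSV keyed by ``(frame_index, atom_index)``; work traces
as one CSV per pull plus a JSON sidecar holding the schedule, thermodynamic
parameters and seeds; PMF profiles as CSV plus JSON metadata; diagrams and
summaries as JSON and aligned text tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from .coords import Frame, Trajectory
from .errors import XYZParseError
from .estimators import BinGrid, FreeEnergySeries, PMFProfile
from .mechanism import EnergyDiagram, StateWindowSummary, StepEnergetics
from .steered import PullEnsemble, SteeringSchedule, WorkTrace
from .thermo import ThermoContext

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# XYZ trajectories
# ---------------------------------------------------------------------------

def read_xyz(path: PathLike) -> Trajectory:
    """Read a multi-frame XYZ file.

    Raises :class:`XYZParseError` with the offending 1-based line number on
    malformed count or coordinate lines.
    """
    lines = Path(path).read_text().splitlines()
    frames: List[Frame] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(i + 1, f"expected an atom count, got {lines[i]!r}")
        if n_atoms <= 0:
            raise XYZParseError(i + 1, "atom count must be positive")
        if i + 1 + n_atoms >= n_lines + 1 and i + 1 + n_atoms > n_lines:
            raise XYZParseError(i + 1, f"frame declares {n_atoms} atoms but file ends early")
        comment = lines[i + 1] if i + 1 < n_lines else ""
        time = _parse_time(comment)
        elements = []
        positions = np.empty((n_atoms, 3))
        for a in range(n_atoms):
            ln = i + 2 + a
            if ln >= n_lines:
                raise XYZParseError(ln + 1, "unexpected end of file inside a frame")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZParseError(ln + 1, f"expected 'element x y z', got {lines[ln]!r}")
            elements.append(parts[0])
            try:
                positions[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise XYZParseError(ln + 1, f"non-numeric coordinate in {lines[ln]!r}")
        frames.append(Frame(elements=elements, positions=positions, time=time))
        i += 2 + n_atoms
    if not frames:
        raise XYZParseError(1, "file contains no frames")
    try:
        return Trajectory(frames)
    except ValueError as exc:
        raise XYZParseError(1, str(exc)) from exc


def _parse_time(comment: str) -> Optional[float]:
    # recognise "t= <fs>" written by write_xyz; anything else is ignored
    for tok in comment.split():
        if tok.startswith("t=") and len(tok) > 2:
            try:
                return float(tok[2:])
            except ValueError:
                return None
    return None


def write_xyz(traj: Trajectory, path: PathLike) -> None:
    """Write a multi-frame XYZ file (coordinates to 1e-10 Å, round-trips with read_xyz)."""
    with open(path, "w") as fh:
        for k, frame in enumerate(traj):
            fh.write(f"{frame.n_atoms}\n")
            comment = f"frame {k}"
            if frame.time is not None:
                comment += f" t={frame.time:g}"
            fh.write(comment + "\n")
            for el, (x, y, z) in zip(frame.elements, frame.positions):
                fh.write(f"{el} {x:.10f} {y:.10f} {z:.10f}\n")


def read_charges_csv(path: PathLike) -> pd.DataFrame:
    """Charge table with columns frame_index, atom_index, charge (a.u., 0-based)."""
    df = pd.read_csv(path)
    required = {"frame_index", "atom_index", "charge"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"charge table missing columns {sorted(missing)}")
    return df


def attach_charges(traj: Trajectory, charges: pd.DataFrame) -> Trajectory:
    """Attach per-atom charges to every frame; every (frame, atom) must be present."""
    for k, frame in enumerate(traj):
        sub = charges[charges["frame_index"] == k]
        if len(sub) != traj.n_atoms:
            raise ValueError(
                f"frame {k}: charge table has {len(sub)} entries, expected {traj.n_atoms}"
            )
        q = np.empty(traj.n_atoms)
        q[sub["atom_index"].to_numpy(dtype=int)] = sub["charge"].to_numpy(dtype=float)
        frame.charges = q
    return traj


def write_charges_csv(traj: Trajectory, path: PathLike) -> None:
    rows = []
    for k, frame in enumerate(traj):
        if frame.charges is None:
            raise ValueError(f"frame {k} carries no charges")
        for a, q in enumerate(frame.charges):
            rows.append((k, a, float(q)))
    pd.DataFrame(rows, columns=["frame_index", "atom_index", "charge"]).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# work traces / ensembles
# ---------------------------------------------------------------------------

def write_work_trace(trace: WorkTrace, path: PathLike) -> None:
    pd.DataFrame({
        "step": np.arange(len(trace.t)),
        "t_fs": trace.t,
        "lambda_center": trace.lambda_center,
        "rc_value": trace.rc_value,
        "work_kcal_mol": trace.work,
    }).to_csv(path, index=False)


def read_work_trace(path: PathLike, direction: str, seed: int) -> WorkTrace:
    df = pd.read_csv(path)
    return WorkTrace(
        t=df["t_fs"].to_numpy(),
        lambda_center=df["lambda_center"].to_numpy(),
        rc_value=df["rc_value"].to_numpy(),
        work=df["work_kcal_mol"].to_numpy(),
        direction=direction,
        seed=seed,
    )


def write_ensemble(ensemble: PullEnsemble, directory: PathLike) -> None:
    """One CSV per trace plus ensemble.json (schedule, thermo, seeds)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "schedule": asdict(ensemble.schedule),
        "temperature": ensemble.thermo.temperature,
        "kB": ensemble.thermo.kB,
        "forward": [], "reverse": [],
    }
    for tag, traces in (("forward", ensemble.forward), ("reverse", ensemble.reverse)):
        for k, tr in enumerate(traces):
            name = f"{tag}_{k:03d}.csv"
            write_work_trace(tr, d / name)
            meta[tag].append({"file": name, "seed": tr.seed})
    (d / "ensemble.json").write_text(json.dumps(meta, indent=2))


def read_ensemble(directory: PathLike) -> PullEnsemble:
    d = Path(directory)
    meta = json.loads((d / "ensemble.json").read_text())
    schedule = SteeringSchedule(**meta["schedule"])
    thermo = ThermoContext(temperature=meta["temperature"], kB=meta["kB"])
    fwd = [read_work_trace(d / e["file"], "forward", e["seed"]) for e in meta["forward"]]
    rev = [read_work_trace(d / e["file"], "reverse", e["seed"]) for e in meta["reverse"]]
    return PullEnsemble(forward=fwd, reverse=rev, thermo=thermo, schedule=schedule)


# ---------------------------------------------------------------------------
# PMF profiles, diagrams, summaries
# ---------------------------------------------------------------------------

def write_pmf(profile: PMFProfile, csv_path: PathLike,
              json_path: Optional[PathLike] = None, **extra_meta) -> None:
    sem = profile.sem if profile.sem is not None else np.full(profile.grid.n_bins, np.nan)
    pd.DataFrame({
        "bin_center": profile.grid.centers,
        "g0_kcal_mol": profile.g0,
        "sem_kcal_mol": sem,
    }).to_csv(csv_path, index=False)
    if json_path is not None:
        meta = {
            "estimator": profile.estimator_tag,
            "anchored": profile.anchored,
            "edges": profile.grid.edges.tolist(),
            **{k: v for k, v in profile.meta.items()},
            **extra_meta,
        }
        Path(json_path).write_text(json.dumps(meta, indent=2, default=float))


def read_pmf(csv_path: PathLike, json_path: Optional[PathLike] = None) -> PMFProfile:
    df = pd.read_csv(csv_path)
    meta = {}
    tag = ""
    if json_path is not None and Path(json_path).exists():
        meta = json.loads(Path(json_path).read_text())
        tag = meta.pop("estimator", "")
        edges = np.asarray(meta.pop("edges"))
    else:
        centers = df["bin_center"].to_numpy()
        half = 0.5 * np.median(np.diff(centers))
        edges = np.concatenate([centers - half, [centers[-1] + half]])
    sem = df["sem_kcal_mol"].to_numpy()
    return PMFProfile(
        grid=BinGrid(edges),
        g0=df["g0_kcal_mol"].to_numpy(),
        sem=None if np.all(np.isnan(sem)) else sem,
        estimator_tag=tag,
        meta=meta,
    )


def write_free_energy_series(series: FreeEnergySeries, path: PathLike) -> None:
    pd.DataFrame({"t_fs": series.times, "delta_f_kcal_mol": series.delta_f}).to_csv(
        path, index=False)


def diagram_to_dict(diagram: EnergyDiagram) -> dict:
    return {
        "steps": [
            {
                "dg_forward_barrier": s.dg_forward_barrier,
                "dg_reaction": s.dg_reaction,
                "dg_backward_barrier": s.dg_backward_barrier,
                "sem": list(s.sem) if s.sem is not None else None,
            }
            for s in diagram.step_energetics
        ],
        "cumulative_levels": list(diagram.cumulative_levels),
        "global_max": diagram.global_max,
        "total_reaction": diagram.total_reaction,
    }


def diagram_from_dict(d: dict) -> EnergyDiagram:
    from .mechanism import compose_diagram
    steps = [StepEnergetics(
        dg_forward_barrier=s["dg_forward_barrier"],
        dg_reaction=s["dg_reaction"],
        sem=tuple(s["sem"]) if s.get("sem") else None,
    ) for s in d["steps"]]
    return compose_diagram(steps)


def write_diagram(diagram: EnergyDiagram, path: PathLike) -> None:
    Path(path).write_text(json.dumps(diagram_to_dict(diagram), indent=2))


def format_diagram_table(diagram: EnergyDiagram) -> str:
    """Aligned text table of per-step energetics and cumulative levels (kcal/mol)."""
    lines = [f"{'step':>4}  {'dG':>8}  {'dG_fwd':>8}  {'dG_bwd':>8}"]
    for i, s in enumerate(diagram.step_energetics, start=1):
        lines.append(f"{i:>4}  {s.dg_reaction:>8.2f}  {s.dg_forward_barrier:>8.2f}"
                     f"  {s.dg_backward_barrier:>8.2f}")
    labels = ["RC1"]
    for i in range(len(diagram.step_energetics)):
        labels += [f"TS{i + 1}", f"PC{i + 1}"]
    lines.append("")
    lines.append("cumulative levels (relative to initial reactant):")
    for lab, lev in zip(labels, diagram.cumulative_levels):
        lines.append(f"  {lab:<4} {lev:>8.2f}")
    lines.append(f"global max      {diagram.global_max:>8.2f}")
    lines.append(f"total reaction  {diagram.total_reaction:>8.2f}")
    return "\n".join(lines)


def format_state_summaries(summaries: List[StateWindowSummary]) -> str:
    """Aligned text table mirroring stationary-state geometry summaries."""
    names: List[str] = []
    for s in summaries:
        for n in s.stats:
            if n not in names:
                names.append(n)
    head = f"{'coordinate':<24}" + "".join(
        f"  {f'[{lo:g}, {hi:g}]':>18}" for (lo, hi) in [s.rc_window for s in summaries])
    lines = [head]
    for n in names:
        row = f"{n:<24}"
        for s in summaries:
            if n in s.stats:
                m, sd = s.stats[n]
                row += f"  {f'{m:.2f} ± {sd:.2f}':>18}"
            else:
                row += f"  {'—':>18}"
        lines.append(row)
    return "\n".join(lines)
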