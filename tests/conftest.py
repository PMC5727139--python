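"""Shared fixtures: small geometries, trajectories and pull ensembles."""

import numpy as np
import pytest

import halopath as hp


def make_frame(points, elements=None, charges=None):
    """Frame from a list of 3-vectors."""
    pts = np.asarray(points, dtype=float)
    els = elements or ["X"] * len(pts)
    return hp.Frame(elements=els, positions=pts, charges=charges)


def rigid_transform(rng):
    """Random proper rotation + translation."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=5.0, size=3)
    return Q, t


@pytest.fixture(scope="session")
def harmonic_ensemble():
    """Stiff-trap pulls across a harmonic well: PMF oracle is U = kappa/2 x^2."""
    surface = hp.harmonic_surface(2.0)
    schedule = hp.SteeringSchedule(-1.2, 1.2, n_steps=3000, k=5000.0)
    params = hp.LangevinParams(seed=2024)
    ens = hp.run_msmd(surface, schedule, params, n_forward=12, n_reverse=12,
                      relax_steps=300)
    return surface, schedule, ens


@pytest.fixture(scope="session")
def tiny_ensemble():
    """Hand-sized synthetic ensemble (3 traces x 4 slices) for oracle equivalence."""
    rng = np.random.default_rng(99)
    schedule = hp.SteeringSchedule(0.0, 1.0, n_steps=3, dt=1.0, k=3.0)
    thermo = hp.ThermoContext(temperature=300.0)

    def trace(direction, lam0, lam1, seed):
        centers = np.linspace(lam0, lam1, 4)
        rc = centers + rng.normal(scale=0.3, size=4)
        w = np.concatenate([[0.0], np.cumsum(rng.normal(scale=0.4, size=3))])
        return hp.WorkTrace(t=np.arange(4.0), lambda_center=centers,
                            rc_value=rc, work=w, direction=direction, seed=seed)

    fwd = [trace("forward", 0.0, 1.0, s) for s in range(3)]
    rev = [trace("reverse", 1.0, 0.0, 10 + s) for s in range(3)]
    return hp.PullEnsemble(forward=fwd, reverse=rev, thermo=thermo, schedule=schedule)
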