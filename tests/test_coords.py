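"""Reaction coordinates, internal coordinates and H-bond statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import halopath as hp
from halopath.errors import GeometryError

from conftest import make_frame, rigid_transform


class TestDistanceAngle:
    def test_unit_and_345_distances(self):
        fr = make_frame([[0, 0, 0], [1, 0, 0], [3, 4, 0]])
        assert hp.distance(fr, 0, 1) == pytest.approx(1.0)
        assert hp.distance(fr, 0, 2) == pytest.approx(5.0)
        assert hp.distance(fr, 2, 0) == pytest.approx(5.0)  # symmetric

    def test_degenerate_pair_and_bad_index(self):
        fr = make_frame([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            hp.distance(fr, 1, 1)
        with pytest.raises(IndexError):
            hp.distance(fr, 0, 5)

    @pytest.mark.parametrize("pts,expected", [
        ([[0, 0, 0], [1, 0, 0], [2, 0, 0]], 180.0),   # collinear, vertex mid
        ([[1, 0, 0], [0, 0, 0], [0, 1, 0]], 90.0),
        ([[1, 0, 0], [0, 0, 0], [1, 1, 0]], 45.0),
    ])
    def test_angle_analytic(self, pts, expected):
        fr = make_frame(pts)
        assert hp.angle(fr, 0, 1, 2) == pytest.approx(expected, abs=1e-9)

    def test_angle_coincident_vertex_errors(self):
        fr = make_frame([[0, 0, 0], [0, 0, 0], [1, 0, 0]])
        with pytest.raises(GeometryError):
            hp.angle(fr, 0, 1, 2)


def frame_with_distances(d_oc_cl, d_cl_c):
    """Collinear O–Cl–C arrangement realizing two prescribed distances."""
    return make_frame([[0, 0, 0], [d_oc_cl, 0, 0], [d_oc_cl + d_cl_c, 0, 0]],
                      elements=["O", "Cl", "C"])


class TestLinearRC:
    spec = hp.LinearDistanceRC([(1.0, (0, 1)), (-1.0, (1, 2))])

    @pytest.mark.parametrize("d1,d2,expected", [
        (2.1, 2.0, 0.1),    # chlorine mid-transfer
        (3.3, 1.8, 1.5),    # chlorine fully transferred
        (1.8, 2.5, -0.7),   # pre-transfer arrangement
        (2.0, 2.0, 0.0),    # exact cancellation
    ])
    def test_worked_examples(self, d1, d2, expected):
        fr = frame_with_distances(d1, d2)
        assert hp.eval_linear_rc(fr, self.spec) == pytest.approx(expected, abs=1e-12)

    def test_proton_transfer_combination(self):
        # d[C-H] - d[H-O] with a bent geometry realizing both distances
        fr = make_frame([[0, 0, 0], [1.2, 0, 0], [1.2 + 1.5, 0, 0]],
                        elements=["C", "H", "O"])
        spec = hp.LinearDistanceRC([(1.0, (0, 1)), (-1.0, (1, 2))])
        assert hp.eval_linear_rc(fr, spec) == pytest.approx(-0.3)

    def test_rejects_empty_and_degenerate_terms(self):
        with pytest.raises(ValueError):
            hp.LinearDistanceRC([])
        with pytest.raises(ValueError):
            hp.LinearDistanceRC([(1.0, (2, 2))])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(scale=3.0, size=(4, 3))
        spec = hp.LinearDistanceRC([(1.0, (0, 1)), (-0.7, (1, 2)), (0.3, (2, 3))])
        v0 = hp.eval_linear_rc(make_frame(pts), spec)
        Q, t = rigid_transform(rng)
        v1 = hp.eval_linear_rc(make_frame(pts @ Q.T + t), spec)
        assert v1 == pytest.approx(v0, abs=1e-9)


class TestMidplaneRC:
    spec = hp.MidplaneRC(c_atom=0, h_atom=1, o_atom=2)

    def test_halfway_collinear_is_half(self):
        fr = make_frame([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        assert hp.eval_midplane_rc(fr, self.spec) == 0.5

    def test_h_on_donor_is_zero(self):
        fr = make_frame([[0, 0, 0], [0, 0, 0], [2, 0, 0]])
        assert hp.eval_midplane_rc(fr, self.spec) == 0.0

    def test_off_axis_projection(self):
        fr = make_frame([[0, 0, 0], [0.5, 0.5, 0], [2, 0, 0]])
        assert hp.eval_midplane_rc(fr, self.spec) == pytest.approx(0.25)

    def test_coincident_heavy_atoms_error(self):
        fr = make_frame([[0, 0, 0], [1, 0, 0], [0, 0, 0]])
        with pytest.raises(GeometryError):
            hp.eval_midplane_rc(fr, self.spec)

    def test_negative_when_h_behind_donor(self):
        fr = make_frame([[0, 0, 0], [-0.5, 0, 0], [2, 0, 0]])
        assert hp.eval_midplane_rc(fr, self.spec) == pytest.approx(-0.25)

    def test_collinear_equals_distance_ratio(self):
        fr = make_frame([[0, 0, 0], [0.7, 0, 0], [2.5, 0, 0]])
        assert hp.eval_midplane_rc(fr, self.spec) == pytest.approx(0.7 / 2.5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 10.0))
    def test_rigid_motion_and_scaling_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        pts = rng.normal(scale=2.0, size=(3, 3))
        v0 = hp.eval_midplane_rc(make_frame(pts), self.spec)
        Q, t = rigid_transform(rng)
        v1 = hp.eval_midplane_rc(make_frame(scale * (pts @ Q.T) + t), self.spec)
        assert v1 == pytest.approx(v0, abs=1e-9)


class TestHBondOccupancy:
    @staticmethod
    def traj_with_inside_fraction(n_in, n_out, rng):
        frames = []
        for _ in range(n_in):
            d = rng.uniform(1.55, 1.65)
            frames.append(make_frame([[0, 0, 0], [d, 0, 0]], elements=["H", "O"]))
        for _ in range(n_out):
            d = rng.uniform(3.0, 4.0)
            frames.append(make_frame([[0, 0, 0], [d, 0, 0]], elements=["H", "O"]))
        return hp.Trajectory(frames)

    def test_constructed_88_percent(self):
        rng = np.random.default_rng(5)
        traj = self.traj_with_inside_fraction(88, 12, rng)
        crit = hp.HBondCriterion(donor_h=0, acceptor=1, max_distance=2.0)
        stats = hp.hbond_occupancy(traj, crit)
        assert stats.occupancy_percent == pytest.approx(88.0)
        assert 1.55 <= stats.mode_distance <= 1.65

    def test_saturated_and_empty(self):
        rng = np.random.default_rng(6)
        crit = hp.HBondCriterion(donor_h=0, acceptor=1, max_distance=2.0)
        full = self.traj_with_inside_fraction(10, 0, rng)
        none = self.traj_with_inside_fraction(0, 10, rng)
        assert hp.hbond_occupancy(full, crit).occupancy_percent == 100.0
        assert hp.hbond_occupancy(none, crit).occupancy_percent == 0.0

    def test_frame_reordering_invariance(self):
        rng = np.random.default_rng(7)
        traj = self.traj_with_inside_fraction(30, 20, rng)
        crit = hp.HBondCriterion(donor_h=0, acceptor=1, max_distance=2.0)
        s0 = hp.hbond_occupancy(traj, crit)
        perm = rng.permutation(len(traj))
        shuffled = hp.Trajectory([traj[i] for i in perm])
        s1 = hp.hbond_occupancy(shuffled, crit)
        assert s1.occupancy_percent == s0.occupancy_percent
        assert s1.mode_distance == s0.mode_distance

    def test_angle_criterion_filters_bent_contacts(self):
        # contact within distance but bent to 90 degrees at H
        bent = make_frame([[-1, 0, 0], [0, 0, 0], [0, 1.5, 0]], elements=["N", "H", "O"])
        straight = make_frame([[-1, 0, 0], [0, 0, 0], [1.5, 0, 0]], elements=["N", "H", "O"])
        traj = hp.Trajectory([bent, straight])
        crit = hp.HBondCriterion(donor_h=1, acceptor=2, max_distance=2.0,
                                 min_angle=150.0, donor=0)
        assert hp.hbond_occupancy(traj, crit).occupancy_percent == pytest.approx(50.0)

    def test_angle_without_donor_rejected(self):
        with pytest.raises(ValueError):
            hp.HBondCriterion(donor_h=0, acceptor=1, max_distance=2.0, min_angle=120.0)
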