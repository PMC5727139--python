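"""Stationary points, step energetics, diagrams, charges and state summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import halopath as hp
from halopath.errors import HalopathError, NoTransitionStateError

from conftest import make_frame


class TestLocateStationaryPoints:
    def test_v_shape_has_no_transition_state(self):
        x = np.linspace(0, 1, 11)
        y = np.abs(x - 0.5)
        with pytest.raises(NoTransitionStateError):
            hp.locate_stationary_points((x, y))

    def test_symmetric_single_barrier_ts_at_midpoint(self):
        x = np.linspace(-1, 1, 21)
        y = 1.0 - x**2
        pts = hp.locate_stationary_points((x, y))
        assert len(pts) == 1
        assert pts[0].transition[0] == pytest.approx(0.0)
        assert pts[0].reactant[0] == pytest.approx(-1.0)
        assert pts[0].product[0] == pytest.approx(1.0)

    def test_two_step_surrogate_sampled_profile(self):
        surf = hp.build_two_step_surface([0.0, 3.0, -2.4, 3.6, -22.8],
                                         [-4.1, -3.4, -3.0, 0.5, 0.8])
        x = np.linspace(-4.1, 0.8, 295)  # knots lie on the grid
        y = np.array([surf.energy(np.array([v])) for v in x])
        pts = hp.locate_stationary_points((x, y), n_steps=2)
        got = [pts[0].reactant[1], pts[0].transition[1], pts[0].product[1],
               pts[1].transition[1], pts[1].product[1]]
        for g, want in zip(got, [0.0, 3.0, -2.4, 3.6, -22.8]):
            assert g == pytest.approx(want, abs=0.05)

    def test_prominence_filter_ignores_noise_wiggles(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0, 1, 101)
        y = np.sin(np.pi * x) + rng.normal(scale=0.01, size=x.size)
        pts = hp.locate_stationary_points((x, y), n_steps=1)
        assert len(pts) == 1
        assert pts[0].transition[0] == pytest.approx(0.5, abs=0.1)


class TestStepEnergetics:
    def test_first_step_worked_example(self):
        pts = hp.StationaryPoints(reactant=(0.0, 0.0), transition=(0.5, 3.0),
                                  product=(1.0, -2.4))
        s = hp.step_energetics(pts)
        assert s.dg_forward_barrier == pytest.approx(3.0)
        assert s.dg_reaction == pytest.approx(-2.4)
        assert s.dg_backward_barrier == pytest.approx(5.4)

    def test_second_step_worked_example(self):
        # printed 26.5 reflects rounding of +-SEM inputs; the identity holds
        # exactly on the unrounded values
        s = hp.StepEnergetics(dg_forward_barrier=6.0, dg_reaction=-20.4)
        assert s.dg_backward_barrier == pytest.approx(26.4)

    def test_degenerate_transition_zero_barrier(self):
        pts = hp.StationaryPoints(reactant=(0.0, 1.0), transition=(0.5, 1.0),
                                  product=(1.0, 0.0))
        assert hp.step_energetics(pts).dg_forward_barrier == 0.0

    def test_inconsistent_backward_rejected(self):
        with pytest.raises(ValueError):
            hp.StepEnergetics(dg_forward_barrier=3.0, dg_reaction=-2.4,
                              dg_backward_barrier=5.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(fwd=st.floats(0, 50), rxn=st.floats(-50, 50))
    def test_identity_holds_on_all_inputs(self, fwd, rxn):
        s = hp.StepEnergetics(dg_forward_barrier=fwd, dg_reaction=rxn)
        assert abs(s.dg_backward_barrier - (fwd - rxn)) < 1e-9


class TestComposeDiagram:
    def test_free_energy_two_step_totals(self):
        d = hp.compose_diagram([
            hp.StepEnergetics(dg_forward_barrier=3.0, dg_reaction=-2.4),
            hp.StepEnergetics(dg_forward_barrier=6.0, dg_reaction=-20.4),
        ])
        assert d.global_max == pytest.approx(3.6)
        assert d.total_reaction == pytest.approx(-22.8)
        assert d.cumulative_levels == pytest.approx((0.0, 3.0, -2.4, 3.6, -22.8))

    def test_potential_energy_two_step_total(self):
        d = hp.compose_diagram([
            hp.StepEnergetics(dg_forward_barrier=4.0, dg_reaction=-8.6),
            hp.StepEnergetics(dg_forward_barrier=9.4, dg_reaction=-24.3),
        ])
        assert d.total_reaction == pytest.approx(-32.9)

    def test_single_step_reduces_to_itself(self):
        s = hp.StepEnergetics(dg_forward_barrier=2.0, dg_reaction=-1.0)
        d = hp.compose_diagram([s])
        assert d.global_max == 2.0
        assert d.total_reaction == -1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hp.compose_diagram([])

    def test_associativity_over_step_concatenation(self):
        s1 = hp.StepEnergetics(dg_forward_barrier=3.0, dg_reaction=-2.4)
        s2 = hp.StepEnergetics(dg_forward_barrier=6.0, dg_reaction=-20.4)
        all_at_once = hp.compose_diagram([s1, s2])
        extended = hp.extend_diagram(hp.compose_diagram([s1]), [s2])
        assert extended.cumulative_levels == pytest.approx(all_at_once.cumulative_levels)
        assert extended.global_max == all_at_once.global_max
        assert extended.total_reaction == all_at_once.total_reaction


def charged_traj(n_frames=11, n_atoms=4, transfer=0.4, rng=None):
    """Linear charge transfer of ``transfer`` a.u. between atom groups along x."""
    frames = []
    for k in range(n_frames):
        f = k / (n_frames - 1)
        pos = np.array([[0.0, 0, 0], [1.0 + f, 0, 0], [3.0, 0, 0], [4.0, 0, 0]])
        q = np.array([0.2 + transfer * f, 0.1, -0.1 - transfer * f, -0.2])
        frames.append(make_frame(pos, elements=["A", "B", "C", "D"], charges=q))
    return hp.Trajectory(frames)


class TestFragmentCharges:
    rc = hp.LinearDistanceRC([(1.0, (0, 1))])

    def test_partition_sums_to_total_charge(self):
        traj = charged_traj()
        frs = [hp.FragmentDef("left", [0, 1]), hp.FragmentDef("right", [2, 3])]
        series = hp.aggregate_fragment_charges(traj, frs, self.rc)
        for k, frame in enumerate(traj):
            total = series[series["frame"] == k]["charge"].sum()
            assert total == pytest.approx(frame.charges.sum(), abs=1e-12)

    def test_single_atom_fragments_are_identity(self):
        traj = charged_traj(n_frames=3)
        frs = [hp.FragmentDef(f"a{i}", [i]) for i in range(4)]
        series = hp.aggregate_fragment_charges(traj, frs, self.rc)
        for k, frame in enumerate(traj):
            sub = series[series["frame"] == k].sort_values("fragment")
            assert np.allclose(sub["charge"].to_numpy(), frame.charges)

    def test_linear_transfer_endpoints_differ_by_amount(self):
        traj = charged_traj(transfer=0.4)
        frs = [hp.FragmentDef("donor", [0, 1]), hp.FragmentDef("acceptor", [2, 3])]
        series = hp.aggregate_fragment_charges(traj, frs, self.rc)
        for name, sign in (("donor", 1.0), ("acceptor", -1.0)):
            sub = series[series["fragment"] == name].sort_values("frame")
            delta = sub["charge"].iloc[-1] - sub["charge"].iloc[0]
            assert delta == pytest.approx(sign * 0.4, abs=1e-12)

    def test_overlapping_fragments_rejected(self):
        traj = charged_traj(n_frames=2)
        with pytest.raises(ValueError, match="overlap"):
            hp.aggregate_fragment_charges(
                traj, [hp.FragmentDef("a", [0, 1]), hp.FragmentDef("b", [1, 2])], self.rc)

    def test_missing_charges_rejected(self):
        traj = hp.Trajectory([make_frame([[0, 0, 0], [1, 0, 0]])])
        with pytest.raises(ValueError, match="charges"):
            hp.aggregate_fragment_charges(traj, [hp.FragmentDef("a", [0])],
                                          hp.LinearDistanceRC([(1.0, (0, 1))]))

    def test_refined_partition_conserves_totals(self):
        traj = charged_traj()
        coarse = [hp.FragmentDef("all", [0, 1, 2, 3])]
        fine = [hp.FragmentDef("l", [0, 1]), hp.FragmentDef("r", [2, 3])]
        sc = hp.aggregate_fragment_charges(traj, coarse, self.rc)
        sf = hp.aggregate_fragment_charges(traj, fine, self.rc)
        for k in range(len(traj)):
            assert (sf[sf["frame"] == k]["charge"].sum()
                    == pytest.approx(sc[sc["frame"] == k]["charge"].sum(), abs=1e-12))

    def test_binned_series_shape(self):
        traj = charged_traj()
        frs = [hp.FragmentDef("donor", [0, 1]), hp.FragmentDef("acceptor", [2, 3])]
        series = hp.aggregate_fragment_charges(traj, frs, self.rc)
        binned = hp.bin_fragment_charges(series, np.linspace(1.0, 2.0, 6))
        assert set(binned.columns) >= {"rc", "fragment", "mean_charge", "std"}
        assert binned["fragment"].nunique() == 2


class TestStateSummary:
    rc = hp.LinearDistanceRC([(1.0, (0, 1))])
    coords = [hp.CoordinateSpec("d01", "distance", (0, 1)),
              hp.CoordinateSpec("a012", "angle", (0, 1, 2))]

    @staticmethod
    def traj_with_d01(values, jitter=0.0, rng=None):
        frames = []
        for v in values:
            dy = rng.normal(scale=jitter) if jitter else 0.0
            frames.append(make_frame([[0, 0, 0], [v + dy, 0, 0], [v, 1.0, 0]]))
        return hp.Trajectory(frames)

    def test_constant_geometry_zero_std(self):
        traj = self.traj_with_d01([1.5] * 6)
        out = hp.state_summary(traj, self.rc, [(1.0, 2.0)], self.coords)
        mean, std = out[0].stats["d01"]
        assert mean == pytest.approx(1.5)
        assert std == 0.0

    def test_two_frame_window_sample_std(self):
        traj = self.traj_with_d01([1.0, 2.0])
        out = hp.state_summary(traj, self.rc, [(0.5, 2.5)], self.coords)
        mean, std = out[0].stats["d01"]
        assert mean == pytest.approx(1.5)
        assert std == pytest.approx(np.sqrt(0.5), abs=1e-9)  # ~0.71

    def test_gaussian_noise_std_recovered(self):
        rng = np.random.default_rng(12)
        n = 400
        traj = self.traj_with_d01([1.5] * n, jitter=0.1, rng=rng)
        out = hp.state_summary(traj, self.rc, [(1.0, 2.0)], self.coords)
        _, std = out[0].stats["d01"]
        # sampling band: 3 sigma / sqrt(2n)
        assert std == pytest.approx(0.1, abs=3 * 0.1 / np.sqrt(2 * n))

    def test_empty_window_names_window(self):
        traj = self.traj_with_d01([1.5, 1.6])
        with pytest.raises(HalopathError, match="9"):
            hp.state_summary(traj, self.rc, [(9.0, 10.0)], self.coords)
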