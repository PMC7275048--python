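"""Geometric descriptors, triple-helix classification, release detection."""

import numpy as np
import pytest

from introntoggle import descriptors as dsc
from introntoggle import structio, synth
from introntoggle.descriptors import State
from introntoggle.errors import (
    ConsistencyError,
    DescriptorError,
    ParameterError,
    SelectionError,
    SummaryError,
)

from conftest import random_rigid_transform


def make_series(values, dt=1.0, name="d", units="A"):
    values = np.asarray(values, dtype=float)
    return dsc.DescriptorSeries(name, np.arange(len(values)) * dt, values, units)


class TestPairDistance:
    def test_three_four_five(self):
        atoms = [
            structio.Atom(1, "A1", "X", 1, "A", "C", np.zeros(3)),
            structio.Atom(2, "A2", "X", 2, "A", "C", np.array([3.0, 4.0, 0.0])),
        ]
        s = structio.Structure(atoms)
        traj = structio.Trajectory.from_structure(s)
        a = structio.select_atoms(s, "resnum 1")
        b = structio.select_atoms(s, "resnum 2")
        assert dsc.pair_distance(traj, a, b).values[0] == pytest.approx(5.0)

    def test_synthetic_fixture_hits_target(self, helix_trajectory, helix_structure):
        a = structio.select_atoms(helix_structure, "resnum 289 and name O2")
        b = structio.select_atoms(helix_structure, "resnum 358 and name N4")
        d = dsc.pair_distance(helix_trajectory, a, b)
        assert d.values[0] == pytest.approx(2.70, abs=1e-9)
        assert d.units == "A"

    def test_multi_atom_selection_rejected(self, helix_trajectory, helix_structure):
        many = structio.select_atoms(helix_structure, "heavy")
        one = structio.select_atoms(helix_structure, "resnum 288 and name N7")
        with pytest.raises(SelectionError):
            dsc.pair_distance(helix_trajectory, many, one)


class TestBasePlaneAngle:
    def test_coplanar_bases_give_zero(self):
        s = synth.active_site_structure(target_d=2.7, target_alpha=0.0)
        traj = structio.Trajectory.from_structure(s)
        assert dsc.base_plane_angle(traj, 358, 385).values[0] == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_bases_give_half_pi(self):
        s = synth.active_site_structure(target_d=2.7, target_alpha=np.pi / 2)
        traj = structio.Trajectory.from_structure(s)
        assert dsc.base_plane_angle(traj, 358, 385).values[0] == pytest.approx(np.pi / 2, abs=1e-9)

    def test_missing_ring_atom_is_named(self, helix_structure):
        keep = [i for i, a in enumerate(helix_structure.atoms)
                if not (a.residue_number == 385 and a.name == "C5")]
        pruned = helix_structure.subset(keep)
        traj = structio.Trajectory.from_structure(pruned)
        with pytest.raises(DescriptorError, match="C5"):
            dsc.base_plane_angle(traj, 358, 385)

    def test_angle_folds_into_first_quadrant(self):
        s = synth.active_site_structure(target_d=2.7, target_alpha=0.63)
        traj = structio.Trajectory.from_structure(s)
        val = dsc.base_plane_angle(traj, 358, 385).values[0]
        assert 0.0 <= val <= np.pi / 2
        assert val == pytest.approx(0.63, abs=1e-9)


class TestRigidInvariance:
    def test_descriptors_invariant_under_rigid_transform(self, helix_structure, rng):
        traj = structio.Trajectory.from_structure(helix_structure)
        a = structio.select_atoms(helix_structure, "resnum 289 and name O2")
        b = structio.select_atoms(helix_structure, "resnum 358 and name N4")
        d0 = dsc.pair_distance(traj, a, b).values[0]
        alpha0 = dsc.base_plane_angle(traj, 358, 385).values[0]
        for _ in range(5):
            rot, trans = random_rigid_transform(rng)
            moved = structio.Trajectory(
                helix_structure, (helix_structure.coords @ rot.T + trans)[None],
                np.array([0.0]))
            assert dsc.pair_distance(moved, a, b).values[0] == pytest.approx(d0, abs=1e-6)
            assert dsc.base_plane_angle(moved, 358, 385).values[0] == pytest.approx(alpha0, abs=1e-6)


class TestClassifyTripleHelix:
    @pytest.mark.parametrize("d, alpha, expected", [
        (2.7, 0.17, State.TRIPLE_HELIX),   # crystallized pre-hydrolytic values
        (4.88, 0.63, State.DISRUPTED),     # post-release trajectory averages
        (3.0, 0.35, State.TRIPLE_HELIX),   # boundaries are inclusive
        (3.0001, 0.17, State.DISRUPTED),
        (2.7, 0.3501, State.DISRUPTED),
    ])
    def test_labels(self, d, alpha, expected):
        states = dsc.classify_triple_helix(make_series([d]), make_series([alpha], units="rad"))
        assert states.labels[0] == expected

    def test_time_mismatch_raises(self):
        d = make_series([2.7, 2.8])
        alpha = dsc.DescriptorSeries("alpha", np.array([0.0, 2.0]), np.array([0.1, 0.1]), "rad")
        with pytest.raises(ConsistencyError):
            dsc.classify_triple_helix(d, alpha)

    def test_monotone_in_both_descriptors(self, rng):
        d_vals = rng.uniform(1.5, 5.0, 200)
        a_vals = rng.uniform(0.0, 1.0, 200)
        base = dsc.classify_triple_helix(make_series(d_vals), make_series(a_vals, units="rad"))
        bumped = dsc.classify_triple_helix(
            make_series(d_vals + 0.7), make_series(a_vals + 0.2, units="rad"))
        for before, after in zip(base.labels, bumped.labels):
            if before == State.DISRUPTED:
                assert after == State.DISRUPTED


class TestDetectIonRelease:
    def test_constant_bound_series_has_no_events(self):
        d = make_series(np.full(200, 2.9), dt=0.5)
        assert dsc.detect_ion_release(d) == []

    def test_step_series_event_at_step_time(self):
        values = np.concatenate([np.full(101, 2.9), np.full(100, 8.0)])
        d = make_series(values, dt=1.0)  # bound 0-100 ns, released after
        events = dsc.detect_ion_release(d, bound_cutoff=3.5, released_cutoff=6.0, dwell=1.0)
        assert len(events) == 1
        assert events[0].release_time == pytest.approx(101.0, abs=1.0)

    def test_no_event_when_never_beyond_released_cutoff(self, rng):
        d = make_series(rng.uniform(2.0, 5.9, 300), dt=0.1)
        assert dsc.detect_ion_release(d, released_cutoff=6.0, dwell=1.0) == []

    def test_rebinding_starts_a_new_event(self):
        values = np.concatenate([
            np.full(50, 2.9), np.full(30, 8.0), np.full(50, 2.9), np.full(30, 8.0),
        ])
        d = make_series(values, dt=1.0)
        events = dsc.detect_ion_release(d, dwell=2.0)
        assert len(events) == 2

    def test_transient_excursion_shorter_than_dwell_ignored(self):
        values = np.concatenate([np.full(50, 2.9), np.full(3, 8.0), np.full(50, 2.9)])
        d = make_series(values, dt=1.0)
        assert dsc.detect_ion_release(d, dwell=10.0) == []

    def test_dwell_beyond_span_is_rejected(self):
        d = make_series([2.9, 8.0, 8.0], dt=1.0)
        with pytest.raises(ParameterError):
            dsc.detect_ion_release(d, dwell=100.0)

    def test_generator_truth_recovered_across_seeds(self):
        hits = total = 0
        for seed in range(20):
            params = synth.TogglingParams(seed=seed)
            _, _, k1_series, truth = synth.gen_toggling_series(params)
            if truth.release_time is None or truth.release_time > k1_series.times[-1] - 1.0:
                continue
            total += 1
            events = dsc.detect_ion_release(k1_series)
            if events and abs(events[0].release_time - truth.release_time) <= 1.0:
                hits += 1
        assert total > 10
        assert hits == total


class TestSummarize:
    def test_constant_series(self):
        s = make_series(np.full(10, 4.24))
        out = dsc.summarize(s, discard=0.0)
        assert out.mean == pytest.approx(4.24)
        assert out.sd == pytest.approx(0.0)

    def test_hand_computed_values(self):
        s = dsc.DescriptorSeries("d", np.array([30.0, 31.0, 32.0]),
                                 np.array([1.0, 2.0, 3.0]), "A")
        out = dsc.summarize(s, discard=25.0)
        assert (out.mean, out.sd, out.n_frames) == (2.0, 1.0, 3)

    def test_discard_drops_equilibration(self):
        times = np.arange(0.0, 50.0, 1.0)
        values = np.where(times < 25.0, 100.0, 2.98)
        s = dsc.DescriptorSeries("d", times, values, "A")
        out = dsc.summarize(s, discard=25.0)
        assert out.mean == pytest.approx(2.98)
        assert out.n_frames == 25

    def test_too_few_frames_raises(self):
        s = make_series([1.0, 2.0, 3.0], dt=1.0)
        with pytest.raises(SummaryError):
            dsc.summarize(s, discard=25.0)

    def test_generator_emission_statistics_recovered(self):
        params = synth.TogglingParams(
            rate_to_toggled=1e-9, rate_to_helix=1.0,
            sd_helix=(0.27, 0.045, 0.10), n_frames=10_000, seed=3,
            mean_helix=(2.98, 0.17, 2.98),
        )
        d, _, _, _ = synth.gen_toggling_series(params)
        out = dsc.summarize(d, discard=0.0)
        se_mean = 0.27 / np.sqrt(10_000)
        assert abs(out.mean - 2.98) < 3 * se_mean
        se_sd = 0.27 / np.sqrt(2 * (10_000 - 1))
        assert abs(out.sd - 0.27) < 3 * se_sd


class TestCoordinationCount:
    @staticmethod
    def ion_with_shell(distances, extra_h=0):
        atoms = [structio.Atom(1, "K", "K", 1001, "A", "K", np.zeros(3))]
        for i, r in enumerate(distances):
            ang = 2 * np.pi * i / max(len(distances), 1)
            atoms.append(structio.Atom(
                2 + i, "O", "HOH", 2000 + i, "A", "O",
                np.array([r * np.cos(ang), r * np.sin(ang), 0.0])))
        for j in range(extra_h):
            atoms.append(structio.Atom(100 + j, "H", "HOH", 2000 + j, "A", "H",
                                       np.array([1.0 + 0.01 * j, 0.0, 0.0])))
        return structio.Structure(atoms)

    def test_counts_atoms_within_cutoff(self):
        s = self.ion_with_shell([2.8, 2.8, 2.8, 2.8, 5.0])
        traj = structio.Trajectory.from_structure(s)
        ion = structio.select_atoms(s, "element K")
        assert dsc.coordination_count(traj, ion, cutoff=3.5).values[0] == 4

    def test_cutoff_below_all_distances_gives_zero(self):
        s = self.ion_with_shell([2.8, 2.9, 3.0])
        traj = structio.Trajectory.from_structure(s)
        ion = structio.select_atoms(s, "element K")
        assert dsc.coordination_count(traj, ion, cutoff=1.0).values[0] == 0

    def test_hydrogens_never_counted(self):
        s = self.ion_with_shell([2.8], extra_h=3)
        traj = structio.Trajectory.from_structure(s)
        ion = structio.select_atoms(s, "element K")
        assert dsc.coordination_count(traj, ion, cutoff=3.5).values[0] == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        atoms = [structio.Atom(1, "K", "K", 1001, "A", "K", np.zeros(3))]
        for i in range(n):
            atoms.append(structio.Atom(
                2 + i, "O", "RES", 2 + i, "A", "O", rng.uniform(-5, 5, 3)))
        s = structio.Structure(atoms)
        traj = structio.Trajectory.from_structure(s)
        ion = structio.select_atoms(s, "element K")
        got = dsc.coordination_count(traj, ion, cutoff=3.5).values[0]
        want = sum(
            1 for a in s.atoms[1:]
            if np.linalg.norm(a.position - s.atoms[0].position) <= 3.5
        )
        assert got == want


class TestStateOccupancy:
    def test_label_fraction_converges_to_stationary_occupancy(self):
        params = synth.TogglingParams(
            rate_to_toggled=1.0, rate_to_helix=1.0, n_frames=100_000,
            frame_interval=0.1, seed=11, reversible_k1=True,
        )
        d, alpha, _, truth = synth.gen_toggling_series(params)
        states = dsc.classify_triple_helix(d, alpha)
        frac = states.fraction(State.TRIPLE_HELIX)
        # autocorrelation-aware standard error of the occupancy estimate
        tau = 1.0 / (params.rate_to_toggled + params.rate_to_helix)
        total_time = params.n_frames * params.frame_interval
        se = np.sqrt(2 * 0.25 * tau / total_time)
        assert abs(frac - params.stationary_helix_occupancy) < 3 * se + 0.01
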