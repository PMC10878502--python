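import numpy as np
import pytest
from hypothesis import given, strategies as st

from bindscape import contacts as cm
from bindscape.trajectory_io import SelectionError, Trajectory

from conftest import make_topology, static_trajectory


def pair_trajectory(separation, n_frames=10, dt=0.1):
    """Two single-particle residues on different chains at a fixed distance."""
    top = make_topology([("BB", 1, "ALA", "A"), ("BB", 1, "GLY", "B")])
    coords = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
    return static_trajectory(top, coords, n_frames=n_frames, dt=dt)


class TestContactFrequency:
    def test_within_cutoff_every_frame(self):
        p = cm.contact_frequency(pair_trajectory(5.0), "chain A", "chain B")
        assert p.frequency == pytest.approx([1.0])

    def test_beyond_cutoff_never(self):
        p = cm.contact_frequency(pair_trajectory(20.0), "chain A", "chain B")
        assert p.frequency == pytest.approx([0.0])

    def test_alternating_distance_half(self):
        traj = pair_trajectory(5.0)
        coords = traj.coordinates.copy()
        coords[1::2, 1, 0] = 9.0
        traj = Trajectory(traj.topology, coords, traj.dt)
        p = cm.contact_frequency(traj, "chain A", "chain B")
        assert p.frequency == pytest.approx([0.5])

    def test_monotone_in_cutoff(self, rng):
        top = make_topology(
            [("BB", i, "ALA", "A") for i in range(1, 6)] + [("BB", i, "GLY", "B") for i in range(1, 6)]
        )
        traj = Trajectory(top, rng.random((20, 10, 3)) * 15, dt=0.1)
        f_small = cm.contact_frequency(traj, "chain A", "chain B", cutoff=5.0).frequency
        f_large = cm.contact_frequency(traj, "chain A", "chain B", cutoff=8.0).frequency
        assert np.all(f_small <= f_large)

    def test_empty_or_overlapping_selection_errors(self):
        traj = pair_trajectory(5.0)
        with pytest.raises(SelectionError):
            cm.contact_frequency(traj, "chain C", "chain B")
        with pytest.raises(SelectionError):
            cm.contact_frequency(traj, "all", "chain B")

    def test_zero_frames_error(self, two_chain_topology):
        traj = Trajectory(two_chain_topology, np.zeros((0, 4, 3)), dt=1.0)
        with pytest.raises(ValueError, match="zero frames"):
            cm.contact_frequency(traj, "chain A", "chain B")


class TestNormalize:
    def test_divide_by_max(self):
        p = cm.ContactProfile([1, 2], np.array([0.2, 0.4]))
        out = cm.normalize_profile(p)
        assert out.frequency == pytest.approx([0.5, 1.0])
        assert out.normalized and not p.normalized

    def test_all_zero_warns_and_flags(self):
        p = cm.ContactProfile([1, 2], np.zeros(2))
        with pytest.warns(UserWarning, match="all-zero"):
            out = cm.normalize_profile(p)
        assert out.normalized
        assert out.frequency == pytest.approx([0.0, 0.0])

    def test_renormalizing_is_error(self):
        p = cm.normalize_profile(cm.ContactProfile([1], np.array([0.3])))
        with pytest.raises(ValueError, match="already"):
            cm.normalize_profile(p)


class TestProfileRMSE:
    def test_identical_zero(self):
        p = cm.ContactProfile([1, 2, 3], np.array([1.0, 0.5, 0.0]), normalized=True)
        assert cm.profile_rmse(p, np.array([1.0, 0.5, 0.0])) == 0.0

    def test_orthogonal_unit_vectors(self):
        p = cm.ContactProfile([1, 2], np.array([1.0, 0.0]), normalized=True)
        assert cm.profile_rmse(p, np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_brute_force_oracle_and_symmetry(self, rng):
        for _ in range(20):
            a = rng.random(50)
            b = rng.random(50)
            pa = cm.ContactProfile(list(range(50)), a / a.max(), normalized=True)
            pb = cm.ContactProfile(list(range(50)), b / b.max(), normalized=True)
            expected = np.sqrt(sum((x - y) ** 2 for x, y in zip(a / a.max(), b / b.max())) / 50)
            assert cm.profile_rmse(pa, b) == pytest.approx(expected, abs=1e-12)
            assert cm.profile_rmse(pa, b) == pytest.approx(cm.profile_rmse(pb, a), abs=1e-12)

    @given(st.integers(2, 30), st.integers(0, 2**31 - 1))
    def test_bounded_by_one_for_unit_vectors(self, n, seed):
        r = np.random.default_rng(seed)
        a, b = r.random(n), r.random(n)
        p = cm.ContactProfile(list(range(n)), a / max(a.max(), 1e-12), normalized=True)
        assert 0.0 <= cm.profile_rmse(p, b) <= 1.0 + 1e-12

    def test_length_mismatch(self):
        p = cm.ContactProfile([1, 2], np.array([1.0, 0.0]), normalized=True)
        with pytest.raises(ValueError, match="mismatch"):
            cm.profile_rmse(p, np.array([1.0]))


class TestEncounterTime:
    def test_first_contact_frame_time(self):
        traj = pair_trajectory(20.0, n_frames=50, dt=0.02)
        coords = traj.coordinates.copy()
        coords[37:, 1, 0] = 5.0
        traj = Trajectory(traj.topology, coords, 0.02)
        rec = cm.encounter_time(traj, "chain A", "chain B")
        assert rec.encounter_time == pytest.approx(0.74)

    def test_contact_in_frame_zero(self):
        rec = cm.encounter_time(pair_trajectory(5.0), "chain A", "chain B")
        assert rec.encounter_time == 0.0

    def test_no_contact_absent_and_excluded_from_stats(self):
        never = cm.encounter_time(pair_trajectory(30.0), "chain A", "chain B")
        assert never.encounter_time is None
        some = cm.EncounterRecord(1, 2.0)
        stats = cm.encounter_statistics([never, some, cm.EncounterRecord(2, 4.0)], n_resamples=100)
        assert stats["n_no_contact"] == 1
        assert stats["n_replicas"] == 3
        assert 2.0 <= stats["mean_ns"] <= 4.0


class TestDomainTimeseries:
    def _two_domain_traj(self):
        top = make_topology(
            [
                ("BB", 1, "ALA", "L", "DBD"),
                ("BB", 2, "ALA", "L", "linker"),
                ("BB", 1, "GLY", "R", "receptor"),
            ]
        )
        coords = np.array([[30.0, 0, 0], [4.0, 0, 0], [0.0, 0, 0]])
        return static_trajectory(top, coords, n_frames=6, dt=0.5)

    def test_only_contacting_domain_counts(self):
        traj = self._two_domain_traj()
        df = cm.domain_contact_timeseries(traj, "chain L", "chain R")
        assert set(df.columns) == {"DBD", "linker"}
        assert (df["linker"] == 1).all()
        assert (df["DBD"] == 0).all()

    def test_single_domain_equals_total(self):
        top = make_topology([("BB", 1, "ALA", "L", "DBD"), ("BB", 1, "GLY", "R", "receptor")])
        traj = static_trajectory(top, np.array([[3.0, 0, 0], [0.0, 0, 0]]), n_frames=4)
        df = cm.domain_contact_timeseries(traj, "chain L", "chain R")
        assert list(df.columns) == ["DBD"]
        assert (df["DBD"] == 1).all()

    def test_all_beyond_cutoff_zero(self):
        traj = self._two_domain_traj()
        df = cm.domain_contact_timeseries(traj, "chain L", "chain R", cutoff=1.0)
        assert (df == 0).all().all()

    def test_untagged_particle_errors(self):
        top = make_topology([("BB", 1, "ALA", "L"), ("BB", 1, "GLY", "R", "receptor")])
        traj = static_trajectory(top, np.array([[3.0, 0, 0], [0.0, 0, 0]]))
        with pytest.raises(ValueError, match="domain tag"):
            cm.domain_contact_timeseries(traj, "chain L", "chain R")

    def test_block_average_window(self):
        traj = self._two_domain_traj()
        df = cm.domain_contact_timeseries(traj, "chain L", "chain R", window=3)
        assert len(df) == 2


class TestBootstrap:
    def test_constant_vector(self):
        mean, sem = cm.bootstrap_mean_sem([2.5] * 10, n_resamples=500, seed=0)
        assert mean == pytest.approx(2.5)
        assert sem == pytest.approx(0.0)

    def test_gaussian_sem_matches_analytic(self, rng):
        values = rng.normal(0.0, 1.0, 50)
        _, sem = cm.bootstrap_mean_sem(values, n_resamples=10_000, seed=0)
        assert sem == pytest.approx(1.0 / np.sqrt(50), rel=0.15)

    def test_seed_reproducible(self):
        v = list(range(20))
        assert cm.bootstrap_mean_sem(v, seed=5) == cm.bootstrap_mean_sem(v, seed=5)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            cm.bootstrap_mean_sem([])


def test_interface_recovery_from_single_site_simulation():
    """With one binding site facing a patch of receptor residues, the
    top-contact-frequency residues are exactly the residues the reference
    profile generator would mark as the interface."""
    from bindscape import synthetic_data as sd

    site = sd.BindingSiteSpec((13.0, 0.0, 0.0), 3.0, 4.0)
    cfg = sd.SimConfig(sites=[site], n_replicas=10, n_steps=160_000, seed=0)
    trajs = sd.simulate_binding_replicas(cfg)
    profiles = [cm.contact_frequency(t, sd.RECEPTOR_SEL, sd.LIGAND_SEL) for t in trajs]
    freq = np.mean([p.frequency for p in profiles], axis=0)
    residue_ids = np.array(profiles[0].residue_ids)

    top = trajs[0].topology
    rec_idx = top.select(sd.RECEPTOR_SEL)
    coords = trajs[0].coordinates[0][rec_idx]
    d = np.linalg.norm(coords - site.center_array, axis=1)
    interface = {top.particles[i].residue_id for i, near in zip(rec_idx, d < 9.0) if near}

    ranked = residue_ids[np.argsort(freq)[::-1]]
    assert set(ranked[: len(interface)].tolist()) == interface
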