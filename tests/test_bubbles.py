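import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnabreathe import (
    PromoterSequence,
    TrajectoryEnsemble,
    detect_bubbles,
    lifetime_profile,
    opening_indicator,
    profile_to_tsv,
    read_profile,
    write_profile,
)
from dnabreathe.synth import PlantedEvent, make_planted_trajectory
from conftest import brute_force_runs


def planted_ensemble(trajs, seq=None, sample_dt=1.0):
    trajs = np.asarray(trajs)
    if seq is None:
        seq = PromoterSequence("p", "ATGC" * (trajs.shape[2] // 4), 10)
    return TrajectoryEnsemble(
        displacements=trajs, sample_dt_ps=sample_dt, seq=seq
    )


class TestOpeningIndicator:
    @pytest.mark.parametrize(
        "frame,expected",
        [((2.0, 2.0, 2.0), True), ((2.0, 1.0, 2.0), False)],
    )
    def test_simultaneous_exceedance_over_window(self, frame, expected):
        assert opening_indicator(np.array(frame), 0, 3, 1.5) is expected

    def test_length_one_is_single_site_exceedance(self):
        frame = np.array([0.0, 2.0, 0.0])
        assert opening_indicator(frame, 1, 1, 1.5)
        assert not opening_indicator(frame, 0, 1, 1.5)

    def test_bounds_violation_rejected(self):
        with pytest.raises(ValueError):
            opening_indicator(np.zeros(3), 2, 2, 1.0)


class TestDetectBubbles:
    def test_crafted_plateau_recovered_exactly(self):
        traj = make_planted_trajectory(
            20, 50, [PlantedEvent(5, 3, 10, 20, 3.0)]
        )
        events = detect_bubbles(traj, 1.5, 3, sample_dt_ps=1.0)
        starts = {e.start_index for e in events}
        assert 5 in starts
        (ev,) = [e for e in events if e.start_index == 5]
        assert (ev.birth_frame, ev.death_frame) == (10, 20)
        assert ev.lifetime_ps == 10.0
        assert not ev.censored

    def test_all_zero_trajectory_has_no_events(self):
        assert detect_bubbles(np.zeros((40, 10)), 0.5, 2) == []

    def test_event_reaching_final_frame_is_censored(self):
        traj = make_planted_trajectory(
            10, 30, [PlantedEvent(2, 2, 25, 30, 3.0)]
        )
        events = [e for e in detect_bubbles(traj, 1.5, 2) if e.start_index == 2]
        assert len(events) == 1 and events[0].censored

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_scan_on_random_fields(self, seed):
        """Run-length extraction equals exhaustive per-cell scanning."""
        rng = np.random.default_rng(seed)
        n_frames = int(rng.integers(1, 50))
        traj = (rng.random((n_frames, 20)) < 0.4).astype(float) * 2.0
        for length in (1, 2, 5):
            events = detect_bubbles(traj, 1.0, length)
            got = sorted(
                (e.start_index, e.birth_frame, e.death_frame) for e in events
            )
            above = traj >= 1.0
            windows = np.column_stack(
                [
                    above[:, p : p + length].all(axis=1)
                    for p in range(20 - length + 1)
                ]
            )
            assert got == sorted(brute_force_runs(windows))


class TestLifetimeProfile:
    @pytest.fixture
    def fixture_profile(self):
        traj = make_planted_trajectory(
            20, 50, [PlantedEvent(5, 3, 10, 20, 3.0)]
        )
        ens = planted_ensemble(np.stack([traj] * 4))
        return lifetime_profile(ens, thresholds=(0.5, 1.5), l_max=4)

    def test_pooled_mean_lifetime_and_event_count(self, fixture_profile):
        prof = fixture_profile
        ti = prof.threshold_index(1.5)
        li = 2  # length 3
        pi = 0  # internal site 5 is the first margin-kept position
        assert prof.event_count[ti, li, pi] == 4
        assert prof.mean_lifetime[ti, li, pi] == pytest.approx(10.0)

    def test_occupancy_is_open_frame_fraction(self, fixture_profile):
        prof = fixture_profile
        ti = prof.threshold_index(1.5)
        assert prof.occupancy[ti, 2, 0] == pytest.approx(10.0 / 50.0)

    def test_occupancy_monotone_in_threshold_and_length(self, fixture_profile):
        occ = fixture_profile.occupancy
        assert np.all(occ[1] <= occ[0])  # stricter threshold
        assert np.all(np.diff(occ, axis=1) <= 0)  # longer bubbles

    def test_simulated_profile_monotonicity_is_exact(self, tiny_ensemble):
        prof = lifetime_profile(tiny_ensemble, l_max=8)
        assert np.all(np.diff(prof.occupancy, axis=0) <= 0)
        assert np.all(np.diff(prof.occupancy, axis=1) <= 0)
        assert prof.occupancy.min() >= 0 and prof.occupancy.max() <= 1

    def test_mean_lifetime_at_least_sample_dt_where_events(self, tiny_ensemble):
        prof = lifetime_profile(tiny_ensemble, l_max=8)
        has = ~prof.mean_lifetime.mask
        assert np.all(
            prof.mean_lifetime[has] >= prof.sample_dt_ps - 1e-12
        )

    def test_replica_order_does_not_change_profile(self, tiny_ensemble):
        prof1 = lifetime_profile(tiny_ensemble, l_max=5)
        flipped = TrajectoryEnsemble(
            displacements=tiny_ensemble.displacements[::-1].copy(),
            sample_dt_ps=tiny_ensemble.sample_dt_ps,
            seq=tiny_ensemble.seq,
        )
        prof2 = lifetime_profile(flipped, l_max=5)
        assert np.array_equal(prof1.occupancy, prof2.occupancy)
        assert np.array_equal(prof1.event_count, prof2.event_count)
        assert np.ma.allequal(prof1.mean_lifetime, prof2.mean_lifetime)

    def test_positions_are_tss_relative_with_margin(self):
        seq = PromoterSequence("p", "ATGC" * 5, 10)
        traj = np.zeros((5, 20))
        prof = lifetime_profile(
            planted_ensemble(traj[None], seq), thresholds=(0.5,), l_max=2
        )
        # margin of 5 excluded each end; internal 5..14 -> coords -5..+5 (no 0)
        assert prof.positions[0] == -5 and prof.positions[-1] == 5
        assert 0 not in prof.positions

    def test_censored_events_excluded_from_means_by_default(self):
        traj = make_planted_trajectory(
            20, 30,
            [PlantedEvent(6, 1, 0, 10, 3.0), PlantedEvent(6, 1, 15, 20, 3.0)],
        )
        ens = planted_ensemble(traj[None])
        drop = lifetime_profile(ens, thresholds=(1.5,), l_max=1)
        keep = lifetime_profile(
            ens, thresholds=(1.5,), l_max=1, censoring_policy="keep"
        )
        ti, li = 0, 0  # internal site 6 maps to kept-position index 1
        assert drop.event_count[ti, li, 1] == 2
        assert drop.mean_lifetime[ti, li, 1] == pytest.approx(5.0)
        assert keep.mean_lifetime[ti, li, 1] == pytest.approx(7.5)

    def test_empty_ensemble_rejected(self):
        seq = PromoterSequence("p", "ATGC" * 5, 10)
        with pytest.raises(ValueError):
            lifetime_profile(planted_ensemble(np.zeros((1, 0, 20)), seq))

    def test_unsorted_or_repeated_thresholds_rejected(self, tiny_ensemble):
        with pytest.raises(ValueError):
            lifetime_profile(tiny_ensemble, thresholds=(1.0, 1.0))


class TestPersistence:
    def test_hdf5_roundtrip_is_lossless(self, tmp_path, tiny_ensemble):
        prof = lifetime_profile(tiny_ensemble, l_max=6)
        path = tmp_path / "p.h5"
        write_profile(prof, path)
        back = read_profile(path)
        assert np.array_equal(back.occupancy, prof.occupancy)
        assert np.array_equal(back.event_count, prof.event_count)
        assert np.ma.allequal(back.mean_lifetime, prof.mean_lifetime)
        assert np.array_equal(back.positions, prof.positions)
        assert back.provenance == prof.provenance
        assert back.sample_dt_ps == prof.sample_dt_ps

    def test_version_mismatch_rejected(self, tmp_path, tiny_ensemble):
        import h5py

        prof = lifetime_profile(tiny_ensemble, l_max=2)
        path = tmp_path / "p.h5"
        write_profile(prof, path)
        with h5py.File(path, "a") as f:
            f.attrs["format_version"] = 999
        with pytest.raises(IOError, match="version"):
            read_profile(path)

    def test_tsv_row_count_and_masked_cells(self, tmp_path, tiny_ensemble):
        prof = lifetime_profile(tiny_ensemble, l_max=6)
        path = tmp_path / "p.tsv"
        profile_to_tsv(prof, path)
        lines = path.read_text().splitlines()
        expected = (
            len(prof.thresholds) * len(prof.lengths) * len(prof.positions)
        )
        assert len(lines) == expected + 1  # header
        # masked cells export an empty lifetime field
        empties = [l for l in lines[1:] if l.split("\t")[3] == ""]
        assert len(empties) == int(prof.mean_lifetime.mask.sum())
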