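import numpy as np
import pytest

from dnabreathe import (
    ChainState,
    EPBDParameters,
    K_BOLTZMANN,
    LangevinConfig,
    PromoterSequence,
    equilibrium_opening_probability_oracle,
    initialize_state,
    kinetic_temperature,
    langevin_step,
    read_ensemble,
    simulate_ensemble,
    total_potential,
    write_ensemble,
)
from dnabreathe.dynamics import _replica_rng, sample_single_site


def short_config(**kw):
    base = dict(
        n_equil_steps=500,
        n_prod_steps=2000,
        sample_stride=10,
        n_replicas=2,
        seed=1,
    )
    base.update(kw)
    return LangevinConfig(**base)


class TestConfigValidation:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            LangevinConfig(temperature=-1)
        with pytest.raises(ValueError):
            LangevinConfig(n_prod_steps=5, sample_stride=10)
        with pytest.raises(ValueError):
            LangevinConfig(y_floor=1.0)

    def test_stability_guard_rejects_coarse_step(self, params):
        cfg = LangevinConfig(dt_fs=200.0)
        with pytest.raises(ValueError, match="unstable"):
            cfg.check_stability(params)

    def test_sample_dt_is_stride_times_dt(self):
        cfg = short_config(dt_fs=2.0, sample_stride=25)
        assert cfg.sample_dt_ps == pytest.approx(0.05)


class TestInitialization:
    def test_same_seed_gives_identical_state(self, params, seq_small):
        cfg = short_config()
        s1 = initialize_state(seq_small, params, cfg, _replica_rng(3, 0))
        s2 = initialize_state(seq_small, params, cfg, _replica_rng(3, 0))
        assert np.array_equal(s1.v, s2.v)
        assert np.all(s1.y == 0.0)

    def test_zero_temperature_gives_zero_velocities(self, params, seq_small):
        cfg = short_config(temperature=0.0)
        s = initialize_state(seq_small, params, cfg, _replica_rng(3, 0))
        assert np.all(s.v == 0.0)

    def test_maxwell_boltzmann_kinetic_energy(self, params):
        """Mean KE per dof of drawn velocities ~ kB*T/2 (N = 10^4)."""
        seq = PromoterSequence("big", "AT" * 5000, 0)
        cfg = short_config(temperature=300.0)
        s = initialize_state(seq, params, cfg, _replica_rng(0, 0))
        ke_per_dof = 0.5 * params.mass * np.mean(s.v**2)
        assert ke_per_dof == pytest.approx(
            0.5 * K_BOLTZMANN * 300.0, rel=0.05
        )


class TestLangevinStep:
    def test_fixed_seed_is_bit_identical(self, params, seq_small):
        cfg = short_config()
        s0 = initialize_state(seq_small, params, cfg, _replica_rng(9, 0))
        a = langevin_step(s0, seq_small, params, cfg, _replica_rng(9, 1), 100)
        b = langevin_step(s0, seq_small, params, cfg, _replica_rng(9, 1), 100)
        assert np.array_equal(a.y, b.y) and np.array_equal(a.v, b.v)

    def test_reflecting_wall_mirrors_position_and_flips_velocity(self, params):
        seq = PromoterSequence("aa", "AA", 0)
        cfg = short_config(
            temperature=0.0, friction=0.0, y_wall=1.0, dt_fs=2.0
        )
        # both sites on the Morse plateau moving fast toward the wall
        v0 = 0.2  # A per internal time unit; crosses the wall in one step
        s0 = ChainState(np.array([0.999, 0.999]), np.array([v0, v0]))
        s1 = langevin_step(s0, seq, params, cfg, _replica_rng(0, 0), 1)
        assert np.all(s1.y <= 1.0)
        assert np.all(s1.v < 0.0)

    def test_deterministic_limit_conserves_energy(self, params):
        """gamma = 0, T = 0: drift < 1e-6 eV over 1e5 velocity-Verlet steps."""
        seq = PromoterSequence("gg", "GG", 0)
        cfg = short_config(temperature=0.0, friction=0.0, dt_fs=2.0)
        y0 = np.array([0.002, -0.002])
        s = ChainState(y0, np.zeros(2))

        def energy(state):
            ke = 0.5 * params.mass * np.sum(state.v**2)
            return ke + total_potential(state, seq, params)

        e0 = energy(s)
        drift = 0.0
        for _ in range(10):
            s = langevin_step(s, seq, params, cfg, _replica_rng(0, 0), 10000)
            drift = max(drift, abs(energy(s) - e0))
        assert drift < 1e-6


class TestEnsembles:
    def test_same_config_gives_identical_ensembles(self, params, seq_small):
        cfg = short_config(n_replicas=3)
        e1 = simulate_ensemble(seq_small, params, cfg)
        e2 = simulate_ensemble(seq_small, params, cfg)
        assert np.array_equal(e1.displacements, e2.displacements)

    def test_single_stride_production_stores_one_frame(self, params, seq_small):
        cfg = short_config(n_prod_steps=10, sample_stride=10)
        ens = simulate_ensemble(seq_small, params, cfg)
        assert ens.n_frames == 1

    def test_at_homopolymer_opens_more_than_gc(self, params):
        cfg = short_config(
            n_equil_steps=5000, n_prod_steps=20000, sample_stride=20,
            n_replicas=4, seed=8,
        )
        at = simulate_ensemble(
            PromoterSequence("at", "A" * 30, 15), params, cfg
        )
        gc = simulate_ensemble(
            PromoterSequence("gc", "G" * 30, 15), params, cfg
        )
        assert at.displacements.mean() > gc.displacements.mean()

    def test_walls_bound_every_stored_frame(self, tiny_ensemble):
        cfg = tiny_ensemble.config
        assert tiny_ensemble.displacements.max() <= cfg.y_wall
        assert tiny_ensemble.displacements.min() >= cfg.y_floor

    def test_hdf5_roundtrip(self, tmp_path, tiny_ensemble):
        path = tmp_path / "ens.h5"
        write_ensemble(tiny_ensemble, path)
        back = read_ensemble(path)
        assert np.array_equal(back.displacements, tiny_ensemble.displacements)
        assert np.array_equal(back.velocities, tiny_ensemble.velocities)
        assert back.seq.bases == tiny_ensemble.seq.bases
        assert back.config == tiny_ensemble.config
        assert back.params == tiny_ensemble.params


class TestThermostatDiagnostics:
    def test_kinetic_temperature_requires_velocities(self, params, seq_small):
        cfg = short_config(store_velocities=False)
        ens = simulate_ensemble(seq_small, params, cfg)
        with pytest.raises(ValueError, match="velocities"):
            kinetic_temperature(ens)

    def test_doubling_temperature_doubles_estimate(self, params):
        seq = PromoterSequence("t", "ATGC" * 10, 20)

        def t_kin(T):
            cfg = LangevinConfig(
                temperature=T, friction=1.0, n_equil_steps=5000,
                n_prod_steps=25000, sample_stride=10, n_replicas=2,
                seed=4, store_velocities=True,
            )
            return kinetic_temperature(simulate_ensemble(seq, params, cfg))

        assert t_kin(600.0) / t_kin(300.0) == pytest.approx(2.0, rel=0.1)

    def test_occupancy_increases_with_temperature(self, params):
        seq = PromoterSequence("t", "ATATATAT" * 4, 16)

        def occ(T, thr=0.5):
            cfg = LangevinConfig(
                temperature=T, friction=0.5, n_equil_steps=10000,
                n_prod_steps=40000, sample_stride=20, n_replicas=3, seed=6,
            )
            ens = simulate_ensemble(seq, params, cfg)
            return float((ens.displacements >= thr).mean())

        o = [occ(T) for T in (250.0, 300.0, 350.0)]
        assert o[0] < o[1] < o[2]


class TestBoltzmannOracle:
    def test_degenerate_thresholds(self, params):
        assert equilibrium_opening_probability_oracle(
            "AT", params, 300.0, -2.0
        ) == 1.0
        assert equilibrium_opening_probability_oracle(
            "AT", params, 300.0, 20.0
        ) == 0.0

    def test_monotone_decreasing_in_threshold(self, params):
        ps = [
            equilibrium_opening_probability_oracle("AT", params, 300.0, t)
            for t in (0.5, 1.0, 1.5, 5.0)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_gc_less_open_than_at(self, params):
        at = equilibrium_opening_probability_oracle("AT", params, 300.0, 1.5)
        gc = equilibrium_opening_probability_oracle("GC", params, 300.0, 1.5)
        assert gc < at

    def test_langevin_occupancy_matches_quadrature(self, params):
        """Single-site MD occupancy vs the Boltzmann integral, 3 SE."""
        cfg = LangevinConfig(
            friction=0.5, dt_fs=2.0, n_equil_steps=50000,
            n_prod_steps=250000, sample_stride=50, n_replicas=6, seed=123,
        )
        y, _ = sample_single_site("AT", params, cfg)
        for thr in (0.5, 1.0, 1.5):
            occ = (y >= thr).mean(axis=(1, 2))
            se = occ.std(ddof=1) / np.sqrt(occ.size)
            expected = equilibrium_opening_probability_oracle(
                "AT", params, cfg.temperature, thr,
                cfg.y_floor, cfg.y_wall,
            )
            assert abs(occ.mean() - expected) <= 3.0 * se + 1e-9
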