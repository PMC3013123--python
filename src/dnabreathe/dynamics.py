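"""Langevin dynamics of the EPBD chain at fixed temperature.

The integrator is a stochastic velocity-Verlet (BBK-class) scheme: the
thermal kick with impulse variance 2*gamma*m*kB*T*dt is split across the
two half-kicks, and the second half-kick carries the implicit
1/(1 + gamma*dt/2) friction factor.  In the gamma = 0, T = 0 limit the
scheme reduces exactly to velocity Verlet, so closed-system energy
conservation is a free correctness test.

Reflecting walls bound the displacement on both sides.  The Morse plateau
makes the unbounded single-site partition function divergent; sharing the
walls between the dynamics and the quadrature oracle makes the
MD-vs-quadrature comparison exact rather than approximate.

Seeding contract: replica i of a run with master seed s draws all its
randomness from ``numpy.random.SeedSequence(s, spawn_key=(i,))``, so
results depend only on (s, i), never on execution order or thread count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from numba import njit
from scipy.integrate import quad

from .model import (
    ChainState,
    EPBDParameters,
    K_BOLTZMANN,
    TIME_UNIT_FS,
    onsite_potential,
)
from .sequences import PromoterSequence

logger = logging.getLogger(__name__)

#: Dimensionless stability bound on dt * a_max * thermal velocity.
STABILITY_LIMIT = 0.1


class SimulationError(RuntimeError):
    """Raised on numerical instability during integration."""


@dataclass(frozen=True)
class LangevinConfig:
    """Thermostat and sampling settings.

    Parameters
    ----------
    temperature : float
        Bath temperature, K.
    friction : float
        Langevin friction gamma, 1/ps.  The default 0.05/ps is weak
        coupling: it thermalizes without overdamping the breathing modes.
    dt_fs : float
        Integration step, fs.  The default 2 fs keeps the step small on
        the steep inner Morse wall, where plateau-returning sites carry
        several kB*T of kinetic energy; coarser steps bias occupancy
        measurably upward.
    n_equil_steps, n_prod_steps : int
        Discarded equilibration steps, then production steps.
    sample_stride : int
        Store every sample_stride-th production frame.
    n_replicas : int
        Independent trajectories per ensemble.
    seed : int
        Master seed; per-replica streams are spawned from it.
    y_floor, y_wall : float
        Reflecting walls, A (floor < 0 < wall).
    store_velocities : bool
        Keep velocities alongside positions (needed for kinetic
        diagnostics; doubles storage).
    """

    temperature: float = 300.0
    friction: float = 0.05
    dt_fs: float = 2.0
    n_equil_steps: int = 25000
    n_prod_steps: int = 500000
    sample_stride: int = 25
    n_replicas: int = 100
    seed: int = 0
    y_floor: float = -2.0
    y_wall: float = 20.0
    store_velocities: bool = False

    def __post_init__(self):
        # Zero friction/temperature selects the deterministic (velocity
        # Verlet, microcanonical) limit used for conservation checks.
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        if self.dt_fs <= 0:
            raise ValueError("dt must be > 0")
        if not self.n_prod_steps >= self.sample_stride >= 1:
            raise ValueError("need n_prod_steps >= sample_stride >= 1")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if not self.y_floor < 0 < self.y_wall:
            raise ValueError("need y_floor < 0 < y_wall")

    # -- derived quantities (internal units) --
    @property
    def dt_internal(self) -> float:
        return self.dt_fs / TIME_UNIT_FS

    @property
    def friction_internal(self) -> float:
        return self.friction * (TIME_UNIT_FS / 1e3)

    @property
    def sample_dt_ps(self) -> float:
        return self.dt_fs * self.sample_stride / 1e3

    def check_stability(self, params: EPBDParameters) -> None:
        """Guard dt against the steepest Morse wall at this temperature."""
        vth = np.sqrt(K_BOLTZMANN * self.temperature / params.mass)
        q = self.dt_internal * params.a_max * vth
        if q >= STABILITY_LIMIT:
            raise ValueError(
                f"dt={self.dt_fs} fs unstable: dt*a_max*sqrt(kB*T/m) = "
                f"{q:.3f} >= {STABILITY_LIMIT} internal units"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LangevinConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "LangevinConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class TrajectoryEnsemble:
    """Replicated sampled trajectories of one sequence.

    ``displacements`` has shape (n_replicas, n_frames, N) in angstrom;
    ``velocities`` (same shape, internal A per time-unit) is present only
    when the run stored them.
    """

    displacements: np.ndarray
    sample_dt_ps: float
    seq: PromoterSequence
    config: LangevinConfig | None = None
    params: EPBDParameters | None = None
    replica_seeds: list[int] | None = None
    velocities: np.ndarray | None = None

    def __post_init__(self):
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        if self.displacements.ndim != 3:
            raise ValueError("displacements must be (replicas, frames, sites)")
        if self.displacements.shape[2] != len(self.seq):
            raise ValueError("site dimension does not match sequence length")
        if self.velocities is not None and (
            self.velocities.shape != self.displacements.shape
        ):
            raise ValueError("velocities shape must match displacements")

    @property
    def n_replicas(self) -> int:
        return self.displacements.shape[0]

    @property
    def n_frames(self) -> int:
        return self.displacements.shape[1]


# ---------------------------------------------------------------------------
# JIT kernels
# ---------------------------------------------------------------------------

@njit(cache=False)
def _forces_inplace(y, D_site, a_site, k_step, rho, beta, f):
    n = y.size
    for i in range(n):
        e = np.exp(-a_site[i] * y[i])
        f[i] = -2.0 * D_site[i] * a_site[i] * e * (1.0 - e)
    for i in range(1, n):
        dy = y[i] - y[i - 1]
        g = rho * np.exp(-beta * (y[i] + y[i - 1]))
        k = k_step[i - 1]
        harmonic = k * (1.0 + g) * dy
        modulation = 0.5 * k * beta * g * dy * dy
        f[i] += -harmonic + modulation
        f[i - 1] += harmonic + modulation


@njit(cache=False)
def _bbk_chunk(
    y, v, f,
    D_site, a_site, k_step, rho, beta,
    mass, gamma, dt, kick, noise,
    y_floor, y_wall,
    out_y, out_v, stride, store, sample_phase,
):
    """Advance noise.shape[0] steps; store every stride-th frame if store.

    ``kick`` = sqrt(2*gamma*mass*kB*T*dt); one Gaussian per site per step,
    its impulse split over the two half-kicks.  Returns the number of
    frames written and the updated sample phase.
    """
    n_steps = noise.shape[0]
    n = y.size
    half = 0.5 * dt / mass
    denom = 1.0 + 0.5 * gamma * dt
    written = 0
    for s in range(n_steps):
        for i in range(n):
            imp = 0.5 * kick * noise[s, i] / mass
            v[i] = v[i] * (1.0 - 0.5 * gamma * dt) + half * f[i] + imp
            y[i] += dt * v[i]
            # reflecting walls
            if y[i] > y_wall:
                y[i] = 2.0 * y_wall - y[i]
                v[i] = -v[i]
            elif y[i] < y_floor:
                y[i] = 2.0 * y_floor - y[i]
                v[i] = -v[i]
        _forces_inplace(y, D_site, a_site, k_step, rho, beta, f)
        for i in range(n):
            imp = 0.5 * kick * noise[s, i] / mass
            v[i] = (v[i] + half * f[i] + imp) / denom
        sample_phase += 1
        if store and sample_phase == stride:
            sample_phase = 0
            for i in range(n):
                out_y[written, i] = y[i]
                out_v[written, i] = v[i]
            written += 1
    return written, sample_phase


def _replica_rng(master_seed: int, replica: int) -> np.random.Generator:
    ss = np.random.SeedSequence(master_seed, spawn_key=(replica,))
    return np.random.Generator(np.random.PCG64(ss))


def initialize_state(
    seq: PromoterSequence,
    params: EPBDParameters,
    config: LangevinConfig,
    rng: np.random.Generator,
) -> ChainState:
    """Closed duplex (y=0) with Maxwell-Boltzmann velocities at T."""
    n = len(seq)
    sigma_v = np.sqrt(K_BOLTZMANN * config.temperature / params.mass)
    v = rng.normal(0.0, sigma_v, size=n)
    return ChainState(np.zeros(n), v, 0.0)


def langevin_step(
    state: ChainState,
    seq: PromoterSequence,
    params: EPBDParameters,
    config: LangevinConfig,
    rng: np.random.Generator,
    n_steps: int = 1,
) -> ChainState:
    """Advance ``n_steps`` BBK steps and return the new state."""
    config.check_stability(params)
    D_site, a_site, k_step = params.site_arrays(seq)
    y, v = state.y.copy(), state.v.copy()
    f = np.empty_like(y)
    _forces_inplace(y, D_site, a_site, k_step, params.rho, params.beta_stack, f)
    dt = config.dt_internal
    gamma = config.friction_internal
    kick = np.sqrt(
        2.0 * gamma * params.mass * K_BOLTZMANN * config.temperature * dt
    )
    noise = rng.standard_normal((n_steps, y.size))
    dummy = np.empty((1, y.size))
    _bbk_chunk(
        y, v, f, D_site, a_site, k_step, params.rho, params.beta_stack,
        params.mass, gamma, dt, kick, noise,
        config.y_floor, config.y_wall,
        dummy, dummy, n_steps + 1, False, 0,
    )
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(v))):
        raise SimulationError(
            "non-finite state after integration; reduce dt_fs"
        )
    return ChainState(y, v, state.time + n_steps * config.dt_fs / 1e3)


_NOISE_CHUNK = 20000  # steps of noise generated at a time (bounds memory)


def _run_replica(seq, params, config, replica, D_site, a_site, k_step):
    rng = _replica_rng(config.seed, replica)
    state = initialize_state(seq, params, config, rng)
    y, v = state.y, state.v
    n = y.size
    f = np.empty_like(y)
    _forces_inplace(y, D_site, a_site, k_step, params.rho, params.beta_stack, f)
    dt = config.dt_internal
    gamma = config.friction_internal
    kick = np.sqrt(
        2.0 * gamma * params.mass * K_BOLTZMANN * config.temperature * dt
    )
    n_samples = config.n_prod_steps // config.sample_stride
    out_y = np.empty((n_samples, n))
    out_v = np.empty((n_samples, n))

    def run(n_steps, store, phase):
        done, total = 0, 0
        while total < n_steps:
            m = min(_NOISE_CHUNK, n_steps - total)
            noise = rng.standard_normal((m, n))
            w, phase = _bbk_chunk(
                y, v, f, D_site, a_site, k_step,
                params.rho, params.beta_stack,
                params.mass, gamma, dt, kick, noise,
                config.y_floor, config.y_wall,
                out_y[done:], out_v[done:],
                config.sample_stride, store, phase,
            )
            done += w
            total += m
        return done

    run(config.n_equil_steps, False, 0)
    written = run(config.n_prod_steps, True, 0)
    if written != n_samples:
        raise SimulationError(
            f"replica {replica}: wrote {written} frames, expected {n_samples}"
        )
    if not np.all(np.isfinite(out_y)):
        raise SimulationError(
            f"replica {replica}: non-finite trajectory; reduce dt_fs"
        )
    return out_y, out_v


def simulate_ensemble(
    seq: PromoterSequence,
    params: EPBDParameters,
    config: LangevinConfig,
) -> TrajectoryEnsemble:
    """Run n_replicas independent Langevin trajectories of ``seq``."""
    config.check_stability(params)
    D_site, a_site, k_step = params.site_arrays(seq)
    ys, vs, seeds = [], [], []
    for r in range(config.n_replicas):
        out_y, out_v = _run_replica(
            seq, params, config, r, D_site, a_site, k_step
        )
        ys.append(out_y)
        vs.append(out_v)
        seeds.append(r)
    logger.info(
        "simulated %d replicas x %d frames of %r (N=%d) at %g K",
        config.n_replicas, ys[0].shape[0], seq.name, len(seq),
        config.temperature,
    )
    return TrajectoryEnsemble(
        displacements=np.stack(ys),
        velocities=np.stack(vs) if config.store_velocities else None,
        sample_dt_ps=config.sample_dt_ps,
        seq=seq,
        config=config,
        params=params,
        replica_seeds=seeds,
    )


def sample_single_site(
    base_class: str,
    params: EPBDParameters,
    config: LangevinConfig,
):
    """Langevin-sample one uncoupled site (no stacking partner).

    Returns (displacements, velocities) arrays of shape
    (n_replicas, n_frames, 1).  This is the sampler counterpart of
    :func:`equilibrium_opening_probability_oracle`: both see exactly the
    Morse on-site well between the same reflecting walls.
    """
    config.check_stability(params)
    D_site = np.array([params.D[base_class]])
    a_site = np.array([params.a[base_class]])
    k_step = np.zeros(0)

    class _OneSite:
        name = f"single-{base_class}"
        bases = "G" if base_class == "GC" else "A"

        def __len__(self):
            return 1

    seq = _OneSite()
    ys, vs = [], []
    for r in range(config.n_replicas):
        out_y, out_v = _run_replica(
            seq, params, config, r, D_site, a_site, k_step
        )
        ys.append(out_y)
        vs.append(out_v)
    return np.stack(ys), np.stack(vs)


def write_ensemble(ensemble: TrajectoryEnsemble, path) -> None:
    """HDF5 container: one group per replica plus full provenance attrs."""
    import json

    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["sample_dt_ps"] = ensemble.sample_dt_ps
        f.attrs["sequence_name"] = ensemble.seq.name
        f.attrs["bases"] = ensemble.seq.bases
        f.attrs["tss_index"] = ensemble.seq.tss_index
        if ensemble.config is not None:
            f.attrs["config"] = json.dumps(ensemble.config.to_dict())
        if ensemble.params is not None:
            f.attrs["params"] = json.dumps(ensemble.params.to_dict())
        if ensemble.replica_seeds is not None:
            f.attrs["replica_seeds"] = ensemble.replica_seeds
        for r in range(ensemble.n_replicas):
            g = f.create_group(f"replica_{r:04d}")
            g.create_dataset("y", data=ensemble.displacements[r])
            if ensemble.velocities is not None:
                g.create_dataset("v", data=ensemble.velocities[r])


def read_ensemble(path) -> TrajectoryEnsemble:
    import json

    import h5py

    with h5py.File(path, "r") as f:
        names = sorted(k for k in f if k.startswith("replica_"))
        ys = np.stack([f[k]["y"][:] for k in names])
        vs = (
            np.stack([f[k]["v"][:] for k in names])
            if "v" in f[names[0]]
            else None
        )
        seq = PromoterSequence(
            name=str(f.attrs["sequence_name"]),
            bases=str(f.attrs["bases"]),
            tss_index=int(f.attrs["tss_index"]),
        )
        config = (
            LangevinConfig.from_dict(json.loads(f.attrs["config"]))
            if "config" in f.attrs
            else None
        )
        params = (
            EPBDParameters.from_dict(json.loads(f.attrs["params"]))
            if "params" in f.attrs
            else None
        )
        seeds = (
            [int(s) for s in f.attrs["replica_seeds"]]
            if "replica_seeds" in f.attrs
            else None
        )
        sample_dt = float(f.attrs["sample_dt_ps"])
    return TrajectoryEnsemble(
        displacements=ys,
        velocities=vs,
        sample_dt_ps=sample_dt,
        seq=seq,
        config=config,
        params=params,
        replica_seeds=seeds,
    )


def kinetic_temperature(ensemble: TrajectoryEnsemble) -> float:
    """Equipartition estimate <m v^2>/kB over all frames, sites, replicas."""
    if ensemble.velocities is None:
        raise ValueError(
            "ensemble holds no velocities; rerun with store_velocities=True"
        )
    if ensemble.params is None:
        raise ValueError("ensemble lacks parameter provenance")
    msq = np.mean(ensemble.velocities**2)
    return float(ensemble.params.mass * msq / K_BOLTZMANN)


def equilibrium_opening_probability_oracle(
    base_class: str,
    params: EPBDParameters,
    temperature: float,
    threshold: float,
    y_floor: float = -2.0,
    y_wall: float = 20.0,
) -> float:
    """Single-site Boltzmann opening probability by adaptive quadrature.

    Integrates exp(-V(y)/kB T) of the Morse on-site well between shared
    reflecting walls; this is the independent oracle the Langevin sampler
    is validated against (an uncoupled site, so no stacking term).
    """
    if not y_floor <= threshold <= y_wall:
        raise ValueError("need y_floor <= threshold <= y_wall")
    if threshold == y_floor:
        return 1.0
    if threshold == y_wall:
        return 0.0
    kt = K_BOLTZMANN * temperature

    def boltzmann(y):
        return np.exp(-onsite_potential(y, base_class, params) / kt)

    opts = dict(epsabs=0.0, epsrel=1e-10, limit=500)
    num, _ = quad(boltzmann, threshold, y_wall, **opts)
    den_lo, _ = quad(boltzmann, y_floor, threshold, **opts)
    return num / (num + den_lo)
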