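"""The EPBD potential energy surface and its analytic forces.

The model assigns one transverse coordinate y_n (angstrom) to each base
pair: the stretch of the hydrogen bonds joining the two bases.  Hydrogen
bonding is a Morse well

    V_n(y) = D_n (exp(-a_n y) - 1)^2

with class-dependent depth/width (AT pairs: two H-bonds, shallower well;
GC pairs: three H-bonds, deeper and narrower).  Neighbouring pairs couple
through an anharmonic stacking term

    W_n = (k_n/2) (1 + rho * exp(-beta (y_n + y_{n-1}))) (y_n - y_{n-1})^2

whose effective stiffness drops from k(1+rho) toward k as both pairs open,
which is what makes openings cooperative and bubbles long-lived.  The
"extended" variant makes k_n depend on the dinucleotide step; the
homogeneous single-k form recovers the classical PBD model.

Internal unit system: angstrom, amu, eV.  The derived time unit is
t0 = 1 A * sqrt(amu/eV) ~= 10.18 fs; conversion to fs/ps happens only at
the interface (see :mod:`dnabreathe.dynamics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import yaml

from .sequences import PromoterSequence, BASE_CLASS

# ---------------------------------------------------------------------------
# Physical constants and unit conversions (angstrom / amu / eV system)
# ---------------------------------------------------------------------------

#: Boltzmann constant, eV/K.
K_BOLTZMANN = 8.617333e-5

#: Internal time unit in femtoseconds: 1 A * sqrt(1 amu / 1 eV).
TIME_UNIT_FS = 1e5 * np.sqrt(1.66053906660e-27 / 1.602176634e-19)  # ~10.1805

DINUCLEOTIDE_STEPS = tuple("".join(p) for p in product("ACGT", repeat=2))


class ParameterError(ValueError):
    """Raised for invalid or missing model parameters."""


@dataclass(frozen=True)
class EPBDParameters:
    """Constants of the EPBD Hamiltonian.

    Defaults follow the standard PBD parameterization used throughout the
    breathing-dynamics literature; every value is config-overridable.

    Parameters
    ----------
    D : dict
        Morse depth (eV) per base class, keys "AT" and "GC".
    a : dict
        Morse inverse width (1/A) per base class.
    k_stack : float or dict
        Harmonic stacking constant (eV/A^2).  A scalar applies one
        homogeneous k; a dict must cover all 16 dinucleotide steps.
    rho : float
        Anharmonic stacking amplitude (dimensionless, >= 0).
    beta_stack : float
        Stacking nonlinearity decay (1/A, >= 0).
    mass : float
        Reduced base-pair mass (amu).
    allow_inverted_depths : bool
        Explicit override for the sanity check D[AT] < D[GC].
    """

    D: dict = field(default_factory=lambda: {"AT": 0.05, "GC": 0.075})
    a: dict = field(default_factory=lambda: {"AT": 4.2, "GC": 6.9})
    k_stack: float | dict = 0.025
    rho: float = 2.0
    beta_stack: float = 0.35
    mass: float = 300.0
    allow_inverted_depths: bool = False

    def __post_init__(self):
        for name, table in (("D", self.D), ("a", self.a)):
            for cls in ("AT", "GC"):
                if cls not in table:
                    raise ParameterError(f"{name} missing base class {cls!r}")
                if not table[cls] > 0:
                    raise ParameterError(f"{name}[{cls}] must be > 0")
        if isinstance(self.k_stack, dict):
            missing = set(DINUCLEOTIDE_STEPS) - set(self.k_stack)
            if missing:
                raise ParameterError(
                    f"inhomogeneous stacking table missing steps: "
                    f"{sorted(missing)}"
                )
            if any(v <= 0 for v in self.k_stack.values()):
                raise ParameterError("all stacking constants must be > 0")
        elif not self.k_stack > 0:
            raise ParameterError("k_stack must be > 0")
        if self.rho < 0 or self.beta_stack < 0:
            raise ParameterError("rho and beta_stack must be >= 0")
        if not self.mass > 0:
            raise ParameterError("mass must be > 0")
        if self.D["AT"] >= self.D["GC"] and not self.allow_inverted_depths:
            raise ParameterError(
                "D[AT] >= D[GC] contradicts the 2-vs-3 hydrogen-bond "
                "ordering; pass allow_inverted_depths=True to override"
            )

    @property
    def a_max(self) -> float:
        return max(self.a.values())

    def k_for_step(self, step: str) -> float:
        if isinstance(self.k_stack, dict):
            try:
                return self.k_stack[step]
            except KeyError:
                raise ParameterError(f"unknown dinucleotide step {step!r}") from None
        return self.k_stack

    def site_arrays(self, seq: PromoterSequence):
        """Per-site (D, a) and per-step k arrays for vectorized evaluation."""
        classes = seq.base_classes
        D_site = np.array([self.D[c] for c in classes])
        a_site = np.array([self.a[c] for c in classes])
        k_step = np.array(
            [self.k_for_step(seq.bases[i : i + 2]) for i in range(len(seq) - 1)]
        )
        return D_site, a_site, k_step

    def to_dict(self) -> dict:
        return {
            "D": dict(self.D),
            "a": dict(self.a),
            "k_stack": dict(self.k_stack)
            if isinstance(self.k_stack, dict)
            else self.k_stack,
            "rho": self.rho,
            "beta_stack": self.beta_stack,
            "mass": self.mass,
            "k_B": K_BOLTZMANN,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EPBDParameters":
        d = dict(d)
        d.pop("k_B", None)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "EPBDParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class ChainState:
    """Instantaneous state of the lattice: displacements and velocities.

    ``y`` in angstrom, ``v`` in angstrom per internal time unit, ``time``
    in picoseconds.
    """

    y: np.ndarray
    v: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.y.shape != self.v.shape or self.y.ndim != 1:
            raise ValueError("y and v must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.v))):
            raise ValueError("non-finite entries in chain state")

    def copy(self) -> "ChainState":
        return ChainState(self.y.copy(), self.v.copy(), self.time)


# ---------------------------------------------------------------------------
# Potential terms
# ---------------------------------------------------------------------------

def onsite_potential(y: float, base_class: str, params: EPBDParameters) -> float:
    """Morse hydrogen-bond energy D (exp(-a y) - 1)^2, eV."""
    try:
        D, a = params.D[base_class], params.a[base_class]
    except KeyError:
        raise ParameterError(f"unknown base class {base_class!r}") from None
    return D * (np.exp(-a * y) - 1.0) ** 2


def stacking_potential(
    y_n: float, y_prev: float, step: str, params: EPBDParameters
) -> float:
    """Anharmonic stacking energy between neighbouring pairs, eV."""
    k = params.k_for_step(step)
    w = 1.0 + params.rho * np.exp(-params.beta_stack * (y_n + y_prev))
    return 0.5 * k * w * (y_n - y_prev) ** 2


def _check_lengths(state: ChainState, seq: PromoterSequence) -> None:
    if state.y.size != len(seq):
        raise ValueError(
            f"state length {state.y.size} != sequence length {len(seq)}"
        )


def total_potential(
    state: ChainState, seq: PromoterSequence, params: EPBDParameters
) -> float:
    """Total EPBD potential energy of the chain (eV), open boundaries."""
    _check_lengths(state, seq)
    D_site, a_site, k_step = params.site_arrays(seq)
    return potential_from_arrays(
        state.y, D_site, a_site, k_step, params.rho, params.beta_stack
    )


def total_force(
    state: ChainState, seq: PromoterSequence, params: EPBDParameters
) -> np.ndarray:
    """Exact analytic force -dV/dy_n on every site (eV/A)."""
    _check_lengths(state, seq)
    D_site, a_site, k_step = params.site_arrays(seq)
    return force_from_arrays(
        state.y, D_site, a_site, k_step, params.rho, params.beta_stack
    )


def potential_from_arrays(y, D_site, a_site, k_step, rho, beta) -> float:
    """Vectorized total potential on raw parameter arrays."""
    e = np.exp(-a_site * y)
    onsite = np.sum(D_site * (e - 1.0) ** 2)
    dy = y[1:] - y[:-1]
    w = 1.0 + rho * np.exp(-beta * (y[1:] + y[:-1]))
    return float(onsite + 0.5 * np.sum(k_step * w * dy**2))


def force_from_arrays(y, D_site, a_site, k_step, rho, beta) -> np.ndarray:
    """Vectorized analytic gradient matching :func:`potential_from_arrays`.

    The stacking derivative includes both the harmonic factor and the
    derivative of the rho*exp(-beta(y_n + y_{n-1})) modulation.
    """
    e = np.exp(-a_site * y)
    f = -2.0 * D_site * a_site * e * (1.0 - e)  # -dV_morse/dy
    dy = y[1:] - y[:-1]
    g = rho * np.exp(-beta * (y[1:] + y[:-1]))
    # d/dy_n of (k/2)(1+g)dy^2: harmonic part +-k(1+g)dy, modulation part
    # -(k/2)beta g dy^2 (identical on both partners).
    harmonic = k_step * (1.0 + g) * dy
    modulation = 0.5 * k_step * beta * g * dy**2
    f[1:] += -harmonic + modulation
    f[:-1] += harmonic + modulation
    return f
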