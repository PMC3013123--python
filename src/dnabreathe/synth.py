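"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* promoter-like sequences with controlled AT/GC composition — an AT-rich
  block embedded near the TSS in GC-richer background emulates the
  composition contrast that drives TSS-focused breathing;
* displacement trajectories with *planted* bubbles of known position,
  size and lifetime, for exact detector validation;
* qPCR Ct tables constructed by inverting the comparative-CT formula, so
  the true fold changes are recovered exactly at zero noise.

All generators are deterministic functions of (design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import CtTable, DEFAULT_REFERENCE_GENE
from .sequences import PromoterSequence


class DesignError(ValueError):
    """Raised for invalid synthetic designs."""


@dataclass(frozen=True)
class Block:
    """A composition block: [start, start+length) with fixed composition.

    ``composition`` is "AT" (A/T only), "GC" (G/C only), or a float GC
    fraction in [0, 1].
    """

    start: int
    length: int
    composition: str | float

    def __post_init__(self):
        if self.length < 1 or self.start < 0:
            raise DesignError("block must have start >= 0 and length >= 1")
        if isinstance(self.composition, str):
            if self.composition not in ("AT", "GC"):
                raise DesignError(
                    f"composition {self.composition!r} not in {{'AT','GC'}}"
                )
        elif not 0.0 <= float(self.composition) <= 1.0:
            raise DesignError("gc fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SequenceDesign:
    """Recipe for a synthetic promoter sequence."""

    length: int
    background_gc: float = 0.5
    blocks: tuple = ()
    tss_index: int | None = None
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self):
        if self.length < 2:
            raise DesignError("length must be >= 2")
        if not 0.0 <= self.background_gc <= 1.0:
            raise DesignError("background_gc must lie in [0, 1]")
        spans = []
        for b in self.blocks:
            if b.start + b.length > self.length:
                raise DesignError(f"block {b} exceeds sequence length")
            spans.append((b.start, b.start + b.length))
        spans.sort()
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise DesignError("blocks overlap")
        tss = self.length // 2 if self.tss_index is None else self.tss_index
        if not 0 <= tss < self.length:
            raise DesignError("tss_index out of range")


def make_sequence(design: SequenceDesign) -> PromoterSequence:
    """Draw a sequence from the design (deterministic per seed)."""
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(design.seed))
    )
    n = design.length
    bases = np.empty(n, dtype="<U1")
    gc_mask = rng.random(n) < design.background_gc
    strand = rng.random(n) < 0.5
    bases[gc_mask & strand] = "G"
    bases[gc_mask & ~strand] = "C"
    bases[~gc_mask & strand] = "A"
    bases[~gc_mask & ~strand] = "T"
    for b in design.blocks:
        sl = slice(b.start, b.start + b.length)
        m = b.length
        if b.composition == "AT":
            frac_gc = 0.0
        elif b.composition == "GC":
            frac_gc = 1.0
        else:
            frac_gc = float(b.composition)
        bgc = rng.random(m) < frac_gc
        bst = rng.random(m) < 0.5
        blk = np.empty(m, dtype="<U1")
        blk[bgc & bst] = "G"
        blk[bgc & ~bst] = "C"
        blk[~bgc & bst] = "A"
        blk[~bgc & ~bst] = "T"
        bases[sl] = blk
    tss = design.length // 2 if design.tss_index is None else design.tss_index
    return PromoterSequence(
        name=design.name, bases="".join(bases), tss_index=tss
    )


def focused_design(seed: int = 0, name: str = "focused") -> SequenceDesign:
    """60 bp, GC-rich (0.8) background, 10-bp AT-only block centred on the
    TSS — the shipped stand-in for a promoter with an AT-rich TSS element."""
    return SequenceDesign(
        length=60,
        background_gc=0.8,
        blocks=(Block(start=25, length=10, composition="AT"),),
        tss_index=30,
        seed=seed,
        name=name,
    )


def flat_design(seed: int = 0, name: str = "flat") -> SequenceDesign:
    """60 bp, uniform GC-rich (0.8) background, no blocks — the shipped
    stand-in for a promoter without a TSS-proximal AT element."""
    return SequenceDesign(
        length=60, background_gc=0.8, blocks=(), tss_index=30,
        seed=seed, name=name,
    )


@dataclass(frozen=True)
class PlantedEvent:
    """Ground-truth bubble: plateau ``amplitude`` on sites [start,
    start+length) during frames [birth, death)."""

    start: int
    length: int
    birth: int
    death: int
    amplitude: float


def make_planted_trajectory(
    n_sites: int,
    n_frames: int,
    events: list[PlantedEvent] | tuple = (),
    noise_sigma: float = 0.0,
    noise_ceiling: float = 0.4,
    seed: int = 0,
) -> np.ndarray:
    """Trajectory (frames x sites) with planted plateau bubbles.

    The baseline is |Gaussian(0, noise_sigma)| clipped below
    ``noise_ceiling`` (kept under every detection threshold), so planted
    events are recovered exactly even at noise_sigma > 0.
    """
    if noise_sigma < 0:
        raise DesignError("noise_sigma must be >= 0")
    occupied = np.zeros((n_frames, n_sites), dtype=bool)
    for ev in events:
        if not (
            0 <= ev.start and ev.start + ev.length <= n_sites
            and 0 <= ev.birth < ev.death <= n_frames and ev.length >= 1
        ):
            raise DesignError(f"event {ev} outside trajectory bounds")
        if ev.amplitude <= noise_ceiling:
            raise DesignError(
                f"event amplitude {ev.amplitude} must exceed the noise "
                f"ceiling {noise_ceiling}"
            )
        cell = occupied[ev.birth : ev.death, ev.start : ev.start + ev.length]
        if cell.any():
            raise DesignError(f"event {ev} overlaps a previous event")
        cell[:] = True
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    if noise_sigma > 0:
        traj = np.minimum(
            np.abs(rng.normal(0.0, noise_sigma, size=(n_frames, n_sites))),
            noise_ceiling * 0.999,
        )
    else:
        traj = np.zeros((n_frames, n_sites))
    for ev in events:
        traj[ev.birth : ev.death, ev.start : ev.start + ev.length] = ev.amplitude
    return traj


def make_ct_table(
    genes: list[tuple],
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    n_replicates: int = 3,
    ct_base: float = 22.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> CtTable:
    """Ct table with known true fold changes per gene.

    ``genes`` lists (label, true_fold).  Control Ct = ct_base + noise;
    treated Ct = ct_base - log2(true_fold) + noise; the reference gene is
    generated with fold 1, so zero-noise tables invert the
    comparative-CT computation exactly.
    """
    if n_replicates < 1:
        raise DesignError("n_replicates must be >= 1")
    if noise_sigma < 0:
        raise DesignError("noise_sigma must be >= 0")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    rows = []
    all_genes = [(reference_gene, 1.0)] + list(genes)
    for label, fold in all_genes:
        if not fold > 0:
            raise DesignError(f"gene {label!r}: true fold must be > 0")
        for cond in ("control", "treated"):
            shift = 0.0 if cond == "control" else -np.log2(fold)
            for rep in range(n_replicates):
                noise = rng.normal(0.0, noise_sigma) if noise_sigma else 0.0
                rows.append(
                    {
                        "gene": label,
                        "condition": cond,
                        "replicate": rep,
                        "ct": ct_base + shift + noise,
                    }
                )
    return CtTable(pd.DataFrame(rows), reference_gene=reference_gene)
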