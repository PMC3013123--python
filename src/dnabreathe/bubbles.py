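"""Bubble detection and the average-lifetime breathing profile.

A bubble at (position p, length L, threshold h) is a maximal run of
consecutive sampled frames in which every displacement y_j, j in
[p, p+L), is >= h simultaneously.  Positions index the bubble's 5'-most
base pair.  Events whose run touches the first or last frame are
*censored* (their true lifetime is only bounded below) and are dropped
from lifetime means by default.

The ensemble aggregate is a grid over (threshold x length x TSS-relative
position) of mean bubble lifetime (ps), occupancy (fraction of sampled
frames open), and event counts, with a margin trimmed at both chain ends
to keep open-boundary artefacts out of reported profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import h5py

from .dynamics import TrajectoryEnsemble
from .sequences import PromoterSequence

PROFILE_FORMAT_VERSION = 1

#: Default amplitude thresholds (A), spanning the conventional range for
#: breathing studies, and the largest bubble length tracked (bp).
DEFAULT_THRESHOLDS = (0.5, 1.0, 1.5, 2.1)
DEFAULT_L_MAX = 20

#: Base pairs excluded at each chain end (open-boundary margin).
END_MARGIN = 5


@dataclass(frozen=True)
class BubbleEvent:
    """One detected opening: [birth_frame, death_frame) at a fixed cell."""

    start_index: int
    length: int
    threshold: float
    birth_frame: int
    death_frame: int
    lifetime_ps: float
    replica_id: int = 0
    censored: bool = False


@dataclass
class BreathingProfile:
    """Ensemble bubble statistics over (threshold x length x position).

    ``mean_lifetime`` is a masked array (masked where no events);
    ``lifetime_n`` counts the events entering each mean (after the
    censoring policy), while ``event_count`` counts all detected events.
    ``positions`` are signed TSS-relative coordinates (no 0).
    """

    thresholds: np.ndarray
    lengths: np.ndarray
    positions: np.ndarray
    mean_lifetime: np.ma.MaskedArray
    occupancy: np.ndarray
    event_count: np.ndarray
    lifetime_n: np.ndarray
    sample_dt_ps: float
    censoring_policy: str = "drop"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        shape = (len(self.thresholds), len(self.lengths), len(self.positions))
        for name in ("occupancy", "event_count", "lifetime_n"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape != {shape}")
        if self.mean_lifetime.shape != shape:
            raise ValueError(f"mean_lifetime shape != {shape}")
        if np.any(self.occupancy < 0) or np.any(self.occupancy > 1):
            raise ValueError("occupancy outside [0, 1]")

    def threshold_index(self, threshold: float) -> int:
        idx = np.flatnonzero(np.isclose(self.thresholds, threshold))
        if idx.size == 0:
            raise KeyError(
                f"threshold {threshold} not in profile grid "
                f"{list(self.thresholds)}"
            )
        return int(idx[0])


def opening_indicator(frame, position: int, length: int, threshold: float) -> bool:
    """True iff y_j >= threshold for every j in [position, position+length)."""
    frame = np.asarray(frame)
    if not (0 <= position and position + length <= frame.size and length >= 1):
        raise ValueError(
            f"window [{position}, {position + length}) outside frame of "
            f"size {frame.size}"
        )
    return bool(np.all(frame[position : position + length] >= threshold))


def _runs_per_column(mask: np.ndarray):
    """Run (start, end) frame pairs for each column of a (frames, cols) mask.

    Returns (col_ids, birth_frames, death_frames) with runs listed
    column-major, i.e. grouped by column in frame order.
    """
    n_frames = mask.shape[0]
    padded = np.zeros((mask.shape[1], n_frames + 2), dtype=np.int8)
    padded[:, 1:-1] = mask.T
    d = np.diff(padded, axis=1)
    cols_b, births = np.nonzero(d == 1)
    cols_d, deaths = np.nonzero(d == -1)
    # identical run counts per column guarantee alignment
    return cols_b, births, deaths


def detect_bubbles(
    trajectory: np.ndarray,
    threshold: float,
    length: int,
    sample_dt_ps: float = 1.0,
    replica_id: int = 0,
) -> list[BubbleEvent]:
    """Extract all maximal opening runs from one (frames x sites) trajectory."""
    traj = np.asarray(trajectory, dtype=np.float64)
    if traj.ndim != 2:
        raise ValueError("trajectory must be 2-D (frames, sites)")
    n_frames, n_sites = traj.shape
    if not 1 <= length <= n_sites:
        raise ValueError(f"length {length} outside [1, {n_sites}]")
    open_ = _rolling_all_open(traj >= threshold, length)
    cols, births, deaths = _runs_per_column(open_)
    events = []
    for p, b, dth in zip(cols, births, deaths):
        events.append(
            BubbleEvent(
                start_index=int(p),
                length=length,
                threshold=threshold,
                birth_frame=int(b),
                death_frame=int(dth),
                lifetime_ps=(int(dth) - int(b)) * sample_dt_ps,
                replica_id=replica_id,
                censored=(b == 0 or dth == n_frames),
            )
        )
    events.sort(key=lambda e: (e.start_index, e.birth_frame))
    return events


def _rolling_all_open(above: np.ndarray, length: int) -> np.ndarray:
    """(frames, sites-length+1) mask: all of a length-window above threshold."""
    out = above
    for l in range(2, length + 1):
        out = out[:, :-1] & above[:, l - 1 :]
    return out if length > 1 else above


def lifetime_profile(
    ensemble: TrajectoryEnsemble,
    thresholds=DEFAULT_THRESHOLDS,
    l_max: int = DEFAULT_L_MAX,
    censoring_policy: str = "drop",
    end_margin: int = END_MARGIN,
) -> BreathingProfile:
    """Aggregate an ensemble into the breathing profile grid.

    For each (threshold, length, position) the profile pools bubble
    events across replicas: occupancy is the open fraction of all
    (frame, replica) samples, mean lifetime averages event lifetimes
    under the censoring policy ("drop" excludes boundary-censored
    events; "keep" retains them as observed lifetimes).
    """
    thresholds = np.asarray(sorted(thresholds), dtype=np.float64)
    if thresholds.size == 0 or np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be non-empty and strictly increasing")
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    if censoring_policy not in ("drop", "keep"):
        raise ValueError("censoring_policy must be 'drop' or 'keep'")
    if ensemble.n_replicas == 0 or ensemble.n_frames == 0:
        raise ValueError("empty ensemble")

    seq = ensemble.seq
    n = len(seq)
    keep = np.arange(end_margin, n - end_margin)
    if keep.size == 0:
        raise ValueError(
            f"sequence of length {n} vanishes under end margin {end_margin}"
        )
    lengths = np.arange(1, l_max + 1)
    shape = (thresholds.size, lengths.size, keep.size)
    occ_sum = np.zeros(shape)
    n_events = np.zeros(shape, dtype=np.int64)
    life_sum = np.zeros(shape)
    life_n = np.zeros(shape, dtype=np.int64)

    n_frames = ensemble.n_frames
    total_samples = ensemble.n_replicas * n_frames
    for rep in range(ensemble.n_replicas):
        traj = ensemble.displacements[rep]
        for ti, thr in enumerate(thresholds):
            above = traj >= thr
            open_ = above
            for li, length in enumerate(lengths):
                if length > 1:
                    open_ = open_[:, :-1] & above[:, length - 1 :]
                # start positions valid for this length, then margin-trim
                valid_keep = keep[keep < open_.shape[1]]
                sub = open_[:, valid_keep]
                occ_sum[ti, li, : valid_keep.size] += sub.sum(axis=0)
                cols, births, deaths = _runs_per_column(sub)
                if cols.size:
                    np.add.at(n_events[ti, li], cols, 1)
                    lifetimes = (deaths - births).astype(np.float64)
                    if censoring_policy == "drop":
                        unc = (births > 0) & (deaths < n_frames)
                        cols_u, lifetimes_u = cols[unc], lifetimes[unc]
                    else:
                        cols_u, lifetimes_u = cols, lifetimes
                    np.add.at(life_sum[ti, li], cols_u, lifetimes_u)
                    np.add.at(life_n[ti, li], cols_u, 1)

    occupancy = occ_sum / total_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = life_sum / life_n * ensemble.sample_dt_ps
    mean_lifetime = np.ma.masked_array(
        np.nan_to_num(mean), mask=(life_n == 0)
    )
    positions = np.array([seq.tss_coordinate(i) for i in keep])
    prov = {"sequence_name": seq.name, "tss_index": seq.tss_index}
    if ensemble.config is not None:
        prov["config"] = ensemble.config.to_dict()
    if ensemble.params is not None:
        prov["params"] = ensemble.params.to_dict()
    return BreathingProfile(
        thresholds=thresholds,
        lengths=lengths,
        positions=positions,
        mean_lifetime=mean_lifetime,
        occupancy=occupancy,
        event_count=n_events,
        lifetime_n=life_n,
        sample_dt_ps=ensemble.sample_dt_ps,
        censoring_policy=censoring_policy,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def write_profile(profile: BreathingProfile, path) -> None:
    """Lossless HDF5 container for a profile (see read_profile)."""
    import json

    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = PROFILE_FORMAT_VERSION
        f.attrs["sample_dt_ps"] = profile.sample_dt_ps
        f.attrs["censoring_policy"] = profile.censoring_policy
        f.attrs["provenance"] = json.dumps(profile.provenance)
        f.create_dataset("thresholds", data=profile.thresholds)
        f.create_dataset("lengths", data=profile.lengths)
        f.create_dataset("positions", data=profile.positions)
        f.create_dataset("mean_lifetime", data=profile.mean_lifetime.filled(0.0))
        f.create_dataset("lifetime_mask", data=profile.mean_lifetime.mask)
        f.create_dataset("occupancy", data=profile.occupancy)
        f.create_dataset("event_count", data=profile.event_count)
        f.create_dataset("lifetime_n", data=profile.lifetime_n)


def read_profile(path) -> BreathingProfile:
    import json

    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != PROFILE_FORMAT_VERSION:
            raise IOError(
                f"profile format version {version} != "
                f"{PROFILE_FORMAT_VERSION}"
            )
        return BreathingProfile(
            thresholds=f["thresholds"][:],
            lengths=f["lengths"][:],
            positions=f["positions"][:],
            mean_lifetime=np.ma.masked_array(
                f["mean_lifetime"][:], mask=f["lifetime_mask"][:]
            ),
            occupancy=f["occupancy"][:],
            event_count=f["event_count"][:],
            lifetime_n=f["lifetime_n"][:],
            sample_dt_ps=float(f.attrs["sample_dt_ps"]),
            censoring_policy=str(f.attrs["censoring_policy"]),
            provenance=json.loads(f.attrs["provenance"]),
        )


def profile_to_tsv(profile: BreathingProfile, path) -> None:
    """Flat TSV export: one row per (threshold, length, tss_position)."""
    with open(path, "w") as fh:
        fh.write(
            "threshold\tlength\ttss_position\tmean_lifetime_ps\t"
            "occupancy\tn_events\n"
        )
        for ti, thr in enumerate(profile.thresholds):
            for li, length in enumerate(profile.lengths):
                for pi, pos in enumerate(profile.positions):
                    masked = profile.mean_lifetime.mask[ti, li, pi]
                    life = (
                        "" if masked
                        else f"{profile.mean_lifetime[ti, li, pi]:.6g}"
                    )
                    fh.write(
                        f"{thr:g}\t{length}\t{pos:+d}\t{life}\t"
                        f"{profile.occupancy[ti, li, pi]:.6g}\t"
                        f"{profile.event_count[ti, li, pi]}\n"
                    )


def plot_profile(profile: BreathingProfile, threshold: float, ax=None):
    """Qualitative heatmap (position x length, colour = mean lifetime)."""
    import matplotlib.pyplot as plt

    ti = profile.threshold_index(threshold)
    if ax is None:
        _, ax = plt.subplots()
    data = profile.mean_lifetime[ti]
    im = ax.pcolormesh(
        np.arange(profile.positions.size), profile.lengths, data,
        shading="nearest", cmap="inferno",
    )
    step = max(1, profile.positions.size // 10)
    ax.set_xticks(np.arange(profile.positions.size)[::step])
    ax.set_xticklabels([f"{p:+d}" for p in profile.positions[::step]])
    ax.set_xlabel("position relative to TSS (+1) [bp]")
    ax.set_ylabel("bubble size [bp]")
    ax.figure.colorbar(im, ax=ax, label="mean bubble lifetime [ps]")
    ax.set_title(
        f"{profile.provenance.get('sequence_name', '')} "
        f"(threshold {profile.thresholds[ti]:g} Å, qualitative)"
    )
    return ax
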