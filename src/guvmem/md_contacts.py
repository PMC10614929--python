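"""Trajectory analytics: per-residue membrane-contact frequencies, residues-
in-contact time series with replicate aggregation, and Ca2+-lipid
coordination events.

A residue contacts the membrane in a frame when any of its (heavy) atoms lies
within ``contact_cutoff`` of any lipid atom under the minimum-image
convention.  Class-resolved frequencies (PS, PC, acyl) use the corresponding
lipid atom subsets.  Coordination events are maximal runs of consecutive
sampled frames in which an ion sits within ``coordination_cutoff`` of one
lipid's phosphate oxygens; their duration is the run length times the frame
spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GridMismatchError, ParameterError
from .io_formats import Trajectory
from .stats import StatResult, unpaired_t_test

__all__ = [
    "ContactParams",
    "ContactProfile",
    "ContactSeries",
    "CoordinationEvent",
    "ReplicateAggregate",
    "min_image_distance",
    "residue_lipid_contact_frequency",
    "residues_in_contact_timeseries",
    "aggregate_replicates",
    "compare_conditions",
    "detect_coordination_events",
]


@dataclass
class ContactParams:
    """Analysis settings, in the trajectory's native units (nm, ns)."""

    contact_cutoff: float = 0.40
    coordination_cutoff: float = 0.35
    sample_interval_ns: float = 2.0
    analysis_window_ns: float = 1000.0
    lipid_oxygen_atom_names: tuple[str, ...] = ("O13", "O14", "O11", "O12")
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        if min(self.contact_cutoff, self.coordination_cutoff,
               self.sample_interval_ns, self.analysis_window_ns) <= 0:
            raise ParameterError("cutoffs, interval and window must be positive")


@dataclass
class ContactProfile:
    """Per-residue contact frequencies, in percent of analyzed frames."""

    residue_ids: np.ndarray
    frequency_any: np.ndarray
    frequency_PS: np.ndarray
    frequency_PC: np.ndarray
    frequency_acyl: np.ndarray
    n_frames: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residue_ids,
                "frequency_any": self.frequency_any,
                "frequency_PS": self.frequency_PS,
                "frequency_PC": self.frequency_PC,
                "frequency_acyl": self.frequency_acyl,
            }
        )


@dataclass
class ContactSeries:
    """Number of residues in membrane contact per sampled frame."""

    times_ns: np.ndarray
    counts: np.ndarray
    replicate_id: str = ""


@dataclass(frozen=True)
class CoordinationEvent:
    ion_index: int
    lipid_residue: int
    t_start_ns: float
    t_end_ns: float
    duration_ns: float


@dataclass
class ReplicateAggregate:
    """Pointwise mean +/- SE curve and windowed per-replicate averages."""

    times_ns: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    replicate_means: np.ndarray
    grand_mean: float
    sd: float


def min_image_distance(a, b, box) -> float:
    """Euclidean distance under the per-axis minimum-image convention."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ParameterError("box lengths must be positive")
    delta = a - b
    delta -= box * np.round(delta / box)
    return float(np.sqrt(np.sum(delta**2, axis=-1)))


def _pair_distances(pos_a: np.ndarray, pos_b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """(n_a, n_b) min-image distance matrix for one frame."""
    delta = pos_a[:, None, :] - pos_b[None, :, :]
    delta -= box * np.round(delta / box)
    return np.sqrt(np.sum(delta**2, axis=-1))


def _is_hydrogen(name: str) -> bool:
    stripped = name.lstrip("0123456789")
    return stripped[:1] in ("H", "h")


def _sampled_frame_indices(times_ns: np.ndarray, interval_ns: float) -> np.ndarray:
    """Nearest-time subsampling of the native frames onto the sample grid."""
    t0, t1 = times_ns[0], times_ns[-1]
    targets = t0 + interval_ns * np.arange(int(np.floor((t1 - t0) / interval_ns)) + 1)
    idx = np.searchsorted(times_ns, targets)
    idx = np.clip(idx, 0, len(times_ns) - 1)
    left = np.clip(idx - 1, 0, len(times_ns) - 1)
    pick_left = np.abs(times_ns[left] - targets) <= np.abs(times_ns[idx] - targets)
    chosen = np.where(pick_left, left, idx)
    return np.unique(chosen)


def _window_frames(traj: Trajectory, params: ContactParams) -> np.ndarray:
    """Sampled frame indices inside the final analysis window."""
    times_ns = traj.times_ps / 1000.0
    span = times_ns[-1] - times_ns[0]
    if span + 1e-9 < params.analysis_window_ns:
        raise ParameterError(
            f"analysis window {params.analysis_window_ns} ns exceeds the "
            f"trajectory span {span} ns"
        )
    start = times_ns[-1] - params.analysis_window_ns
    in_window = np.nonzero(times_ns > start - 1e-9)[0]
    sampled = _sampled_frame_indices(times_ns[in_window], params.sample_interval_ns)
    return in_window[sampled]


def _contact_atoms(traj: Trajectory, params: ContactParams):
    """Protein atom indices grouped by residue and lipid atom index subsets."""
    protein: dict[int, list[int]] = {}
    lipid_idx, ps_mask, pc_mask, acyl_mask = [], [], [], []
    for a in traj.atoms:
        if not params.include_hydrogens and _is_hydrogen(a.name):
            continue
        if a.category == "protein":
            protein.setdefault(a.residue_number, []).append(a.index)
        elif a.category in ("lipid_PS", "lipid_PC"):
            lipid_idx.append(a.index)
            ps_mask.append(a.category == "lipid_PS")
            pc_mask.append(a.category == "lipid_PC")
            acyl_mask.append(a.lipid_region == "acyl")
    return (
        protein,
        np.asarray(lipid_idx, dtype=int),
        np.asarray(ps_mask, dtype=bool),
        np.asarray(pc_mask, dtype=bool),
        np.asarray(acyl_mask, dtype=bool),
    )


def _contact_matrix(
    traj: Trajectory, frames: np.ndarray, params: ContactParams
):
    """Per (frame, residue) boolean contact flags for any/PS/PC/acyl."""
    protein, lipid_idx, ps_mask, pc_mask, acyl_mask = _contact_atoms(traj, params)
    residues = sorted(protein)
    flags = {
        kind: np.zeros((len(frames), len(residues)), dtype=bool)
        for kind in ("any", "PS", "PC", "acyl")
    }
    if lipid_idx.size == 0 or not residues:
        return residues, flags
    for fi, f in enumerate(frames):
        lipid_pos = traj.coords[f, lipid_idx]
        box = traj.boxes[f]
        for ri, resid in enumerate(residues):
            dists = _pair_distances(traj.coords[f, protein[resid]], lipid_pos, box)
            near = (dists < params.contact_cutoff).any(axis=0)
            if not near.any():
                continue
            flags["any"][fi, ri] = True
            flags["PS"][fi, ri] = bool(near[ps_mask].any())
            flags["PC"][fi, ri] = bool(near[pc_mask].any())
            flags["acyl"][fi, ri] = bool(near[acyl_mask].any())
    return residues, flags


def residue_lipid_contact_frequency(
    traj: Trajectory, params: ContactParams | None = None
) -> ContactProfile:
    """Contact frequency per residue over the final analysis window.

    Frames are restricted to the trailing ``analysis_window_ns`` and
    subsampled at ``sample_interval_ns``; frequencies are percentages of the
    analyzed frames.
    """
    if params is None:
        params = ContactParams()
    frames = _window_frames(traj, params)
    residues, flags = _contact_matrix(traj, frames, params)
    n = len(frames)
    pct = {k: 100.0 * v.sum(axis=0) / n for k, v in flags.items()}
    return ContactProfile(
        residue_ids=np.asarray(residues, dtype=int),
        frequency_any=pct["any"],
        frequency_PS=pct["PS"],
        frequency_PC=pct["PC"],
        frequency_acyl=pct["acyl"],
        n_frames=n,
    )


def residues_in_contact_timeseries(
    traj: Trajectory, params: ContactParams | None = None, replicate_id: str = ""
) -> ContactSeries:
    """Count of residues in membrane contact per sampled frame, full trajectory."""
    if params is None:
        params = ContactParams()
    times_ns = traj.times_ps / 1000.0
    frames = _sampled_frame_indices(times_ns, params.sample_interval_ns)
    _, flags = _contact_matrix(traj, frames, params)
    counts = flags["any"].sum(axis=1).astype(int)
    return ContactSeries(times_ns[frames], counts, replicate_id)


def aggregate_replicates(
    series_list: list[ContactSeries], window_ns: float = 1000.0
) -> ReplicateAggregate:
    """Mean +/- SE curve across replicates, plus windowed scalar summaries.

    All replicates must share an identical time grid (no interpolation).  The
    scalar summary is each replicate's time-averaged contact count over the
    final ``window_ns``, reported with the across-replicate mean and sample
    SD.
    """
    if len(series_list) < 2:
        raise ParameterError("need at least two replicates")
    grid = series_list[0].times_ns
    for s in series_list[1:]:
        if s.times_ns.shape != grid.shape or not np.array_equal(s.times_ns, grid):
            raise GridMismatchError("replicate time grids differ")
    counts = np.stack([s.counts.astype(float) for s in series_list])
    mean = counts.mean(axis=0)
    se = counts.std(axis=0, ddof=1) / np.sqrt(len(series_list))
    in_window = grid > grid[-1] - window_ns + 1e-9
    if not in_window.any():
        raise ParameterError("window contains no sampled frames")
    rep_means = counts[:, in_window].mean(axis=1)
    return ReplicateAggregate(
        times_ns=grid,
        mean=mean,
        se=se,
        replicate_means=rep_means,
        grand_mean=float(rep_means.mean()),
        sd=float(rep_means.std(ddof=1)),
    )


def compare_conditions(cond_a, cond_b, tails: int = 1) -> StatResult:
    """Student's t-test that condition B shows *reduced* binding vs A.

    One-tailed by default (alternative: mean_b < mean_a), as used when
    comparing mutant replicate contact averages against wild type.
    """
    return unpaired_t_test(cond_a, cond_b, tails=tails, alternative="greater")


def detect_coordination_events(
    traj: Trajectory, params: ContactParams | None = None
) -> tuple[list[CoordinationEvent], dict[int, tuple[np.ndarray, np.ndarray]]]:
    """Ca2+-lipid coordination events plus nearest-lipid distance series.

    For every (ion, lipid molecule) pair, an event is a maximal run of
    consecutive sampled frames in which the ion's minimum distance to that
    lipid's listed oxygen atoms is below ``coordination_cutoff``; its
    duration is the run length times the sampled frame spacing.  The second
    return value maps each ion atom index to its per-frame distance to the
    nearest lipid atom of any type (basis of the '> 0.5 nm' summary).
    """
    if params is None:
        params = ContactParams()
    times_ns = traj.times_ps / 1000.0
    frames = _sampled_frame_indices(times_ns, params.sample_interval_ns)
    sample_times = times_ns[frames]
    frame_dt = float(sample_times[1] - sample_times[0]) if len(frames) > 1 \
        else params.sample_interval_ns

    ions = traj.atom_indices("ion_Ca")
    if ions.size == 0:
        return [], {}
    lipid_all = np.concatenate(
        [traj.atom_indices("lipid_PS"), traj.atom_indices("lipid_PC")]
    )
    oxygens: dict[int, list[int]] = {}
    names = set(params.lipid_oxygen_atom_names)
    for a in traj.atoms:
        if a.category in ("lipid_PS", "lipid_PC") and a.name in names:
            oxygens.setdefault(a.residue_number, []).append(a.index)

    events: list[CoordinationEvent] = []
    nearest: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for ion in ions:
        ion_pos = traj.coords[frames][:, ion, :]
        if lipid_all.size:
            dmin = np.empty(len(frames))
            for fi, f in enumerate(frames):
                dmin[fi] = _pair_distances(
                    ion_pos[fi][None, :], traj.coords[f, lipid_all], traj.boxes[f]
                ).min()
            nearest[int(ion)] = (sample_times, dmin)
        else:
            nearest[int(ion)] = (sample_times, np.full(len(frames), np.inf))
        for lipid_resid, oxy_idx in sorted(oxygens.items()):
            below = np.empty(len(frames), dtype=bool)
            for fi, f in enumerate(frames):
                d = _pair_distances(
                    ion_pos[fi][None, :], traj.coords[f, oxy_idx], traj.boxes[f]
                ).min()
                below[fi] = d < params.coordination_cutoff
            for start, end in _runs(below):
                t0 = float(sample_times[start])
                t1 = float(sample_times[end])
                events.append(
                    CoordinationEvent(int(ion), lipid_resid, t0, t1, t1 - t0 + frame_dt)
                )
    events.sort(key=lambda e: (e.ion_index, e.lipid_residue, e.t_start_ns))
    return events, nearest


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, end) index pairs."""
    runs = []
    start = None
    for i, v in enumerate(flags):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs
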