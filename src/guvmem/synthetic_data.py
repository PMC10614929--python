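"""Synthetic GUV scenes and membrane trajectories with planted ground truth.

Every downstream stage of the package is testable without external data:

* :func:`generate_guv_scene` renders a confocal-style multi-channel image —
  lipid channel with annular Gaussian rings (GUV equators), protein channels
  with 2-D Gaussian puncta planted *on* the rings (membrane-bound by
  construction), plus a constant background offset and additive Gaussian
  noise clipped to the bit-depth range.
* :func:`generate_trajectory` emits a trajectory of pseudo-residues above a
  static planar lipid slab, with per-residue nearest-lipid distances scripted
  below/above the contact cutoff frame by frame, and Ca2+ ions whose
  distances to PS phosphate oxygens follow scripted coordination intervals.
  Only distances matter to the downstream analytics, not lipid dynamics.

Both generators are bit-reproducible under a fixed seed and return a truth
object reporting exactly what was planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError
from .guv_detection import GUVRegion, circle_bbox
from .io_formats import Atom, MultiChannelImage, Trajectory

__all__ = [
    "GUVSpec",
    "PunctumSpec",
    "SceneSpec",
    "PlantedPunctum",
    "SceneTruth",
    "generate_guv_scene",
    "random_scene_spec",
    "TrajSpec",
    "ContactTruth",
    "generate_trajectory",
    "random_traj_spec",
]


# ---------------------------------------------------------------------------
# GUV scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GUVSpec:
    """One planted vesicle: ring center/radius plus ring profile."""

    center: tuple[float, float]
    radius: float
    ring_amplitude: float = 300.0
    ring_thickness: float = 1.5
    edge_touching: bool = False


@dataclass(frozen=True)
class PunctumSpec:
    """A protein spot planted on a GUV ring at angular position ``angle``."""

    guv_index: int
    angle: float
    amplitude: float = 200.0
    sigma: float = 1.5


@dataclass
class SceneSpec:
    """Full description of a synthetic scene.

    ``puncta`` maps a protein channel role to the list of planted spots.
    The lipid channel is always first in ``channel_roles``.
    """

    height: int = 256
    width: int = 256
    channel_roles: tuple[str, ...] = ("lipid", "proteinA")
    guvs: list[GUVSpec] = field(default_factory=list)
    puncta: Mapping[str, list[PunctumSpec]] = field(default_factory=dict)
    noise_sigma: float = 20.0
    background_offset: float = 100.0
    bit_depth: int = 16
    pixel_size_um: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sigma < 0 or self.background_offset < 0:
            raise ParameterError("noise_sigma and background_offset must be >= 0")
        if "lipid" not in self.channel_roles:
            raise ParameterError("scene needs a lipid channel")
        for g in self.guvs:
            if g.radius <= 0 or g.ring_amplitude < 0 or g.ring_thickness <= 0:
                raise ParameterError("GUV radius/thickness must be positive, amplitude >= 0")
            r, c = g.center
            inside = (g.radius <= r < self.height - g.radius
                      and g.radius <= c < self.width - g.radius)
            if not inside and not g.edge_touching:
                raise ParameterError(
                    f"GUV at {g.center} exits the frame; flag edge_touching to allow"
                )
        for role, plist in self.puncta.items():
            if role not in self.channel_roles or role == "lipid":
                raise ParameterError(f"puncta assigned to unknown channel {role!r}")
            for p in plist:
                if p.sigma <= 0:
                    raise ParameterError("punctum sigma must be positive")
                if p.amplitude < 0:
                    raise ParameterError("punctum amplitude must be >= 0")
                if not 0 <= p.guv_index < len(self.guvs):
                    raise ParameterError("punctum references a missing GUV")


@dataclass(frozen=True)
class PlantedPunctum:
    center: tuple[float, float]
    amplitude: float
    sigma: float


@dataclass
class SceneTruth:
    """Exactly what :func:`generate_guv_scene` planted.

    ``puncta[role][g]`` lists the planted spots of channel ``role`` on GUV
    ``g``.  ``coloc_flags[(roleA, roleB)][g]`` carries per-punctum flags for
    both channels: a planted punctum is colocalized with the partner channel
    iff some partner spot on the same GUV lies within ``2 * (sigma_a +
    sigma_b)`` of it.
    """

    regions: list[GUVRegion]
    puncta: dict[str, list[list[PlantedPunctum]]]
    coloc_flags: dict[tuple[str, str], list[tuple[list[bool], list[bool]]]]

    def proportion_with_puncta(self, role: str) -> float:
        if not self.regions:
            raise ParameterError("scene has no GUVs")
        per_guv = self.puncta[role]
        return sum(1 for p in per_guv if p) / len(self.regions)

    def coloc_proportion(self, role_a: str, role_b: str) -> float:
        """Scene-level planted colocalization: sum of colocalized puncta in the
        per-GUV majority channel over the sum of per-GUV majority counts."""
        key = (role_a, role_b) if (role_a, role_b) in self.coloc_flags else (role_b, role_a)
        num = den = 0
        for flags_a, flags_b in self.coloc_flags[key]:
            na, nb = len(flags_a), len(flags_b)
            if max(na, nb) == 0:
                continue
            if na > nb:
                n_co = sum(flags_a)
            elif nb > na:
                n_co = sum(flags_b)
            else:
                n_co = max(sum(flags_a), sum(flags_b))
            num += n_co
            den += max(na, nb)
        return num / den if den else 0.0


def _punctum_center(guv: GUVSpec, angle: float) -> tuple[float, float]:
    return (
        guv.center[0] + guv.radius * math.sin(angle),
        guv.center[1] + guv.radius * math.cos(angle),
    )


def generate_guv_scene(spec: SceneSpec) -> tuple[MultiChannelImage, SceneTruth]:
    """Render a scene and report its planted truth.

    Identical spec (including seed) produces a bit-identical image.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    roles = list(spec.channel_roles)
    img = np.full((h, w, len(roles)), float(spec.background_offset))
    rows, cols = np.mgrid[0:h, 0:w].astype(float)

    lipid_idx = roles.index("lipid")
    for g in spec.guvs:
        d = np.hypot(rows - g.center[0], cols - g.center[1])
        img[:, :, lipid_idx] += g.ring_amplitude * np.exp(
            -((d - g.radius) ** 2) / (2.0 * g.ring_thickness**2)
        )

    truth_puncta: dict[str, list[list[PlantedPunctum]]] = {}
    protein_roles = [r for r in roles if r != "lipid"]
    for role in protein_roles:
        per_guv: list[list[PlantedPunctum]] = [[] for _ in spec.guvs]
        ch = roles.index(role)
        for p in spec.puncta.get(role, []):
            guv = spec.guvs[p.guv_index]
            pr, pc = _punctum_center(guv, p.angle)
            d2 = (rows - pr) ** 2 + (cols - pc) ** 2
            img[:, :, ch] += p.amplitude * np.exp(-d2 / (2.0 * p.sigma**2))
            per_guv[p.guv_index].append(PlantedPunctum((pr, pc), p.amplitude, p.sigma))
        truth_puncta[role] = per_guv

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    np.clip(img, 0.0, 2**spec.bit_depth - 1, out=img)

    regions = [
        GUVRegion(g.center, g.radius, circle_bbox(g.center, g.radius))
        for g in spec.guvs
    ]

    coloc: dict[tuple[str, str], list[tuple[list[bool], list[bool]]]] = {}
    for i, ra in enumerate(protein_roles):
        for rb in protein_roles[i + 1:]:
            pairs = []
            for g in range(len(spec.guvs)):
                pa, pb = truth_puncta[ra][g], truth_puncta[rb][g]

                def near(x: PlantedPunctum, y: PlantedPunctum) -> bool:
                    lim = 2.0 * (x.sigma + y.sigma)
                    return math.hypot(
                        x.center[0] - y.center[0], x.center[1] - y.center[1]
                    ) <= lim

                flags_a = [any(near(x, y) for y in pb) for x in pa]
                flags_b = [any(near(y, x) for x in pa) for y in pb]
                pairs.append((flags_a, flags_b))
            coloc[(ra, rb)] = pairs

    image = MultiChannelImage(img, roles, spec.bit_depth, spec.pixel_size_um)
    return image, SceneTruth(regions, truth_puncta, coloc)


def random_scene_spec(
    seed: int,
    n_guvs: int = 10,
    shape: tuple[int, int] = (256, 256),
    radius_range: tuple[float, float] = (10.0, 14.0),
    frac_with_puncta: float = 0.7,
    max_puncta: int = 2,
    channel_roles: tuple[str, ...] = ("lipid", "proteinA"),
    coloc_fraction: float | None = None,
    spot_amplitude: float = 200.0,
    spot_sigma: float = 1.5,
    noise_sigma: float = 20.0,
    background_offset: float = 100.0,
    ring_amplitude: float = 300.0,
    ring_thickness: float = 1.5,
) -> SceneSpec:
    """Lay out a random but well-separated scene for benchmarking.

    GUVs sit on a jittered grid so that center separations exceed twice the
    largest radius.  ``round(frac_with_puncta * n_guvs)`` GUVs receive 1 to
    ``max_puncta`` spots in the first protein channel; spots sharing a ring
    are kept more than 6 spot sigmas apart along the arc.  When a second
    protein channel is present, each first-channel spot gets a partner spot
    that is colocalized (same position) with probability ``coloc_fraction``
    and planted on the far side of the ring otherwise.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    r_max = radius_range[1]
    margin = int(r_max + 4 * ring_thickness + 2)
    n_cols = int(math.ceil(math.sqrt(n_guvs)))
    n_rows = int(math.ceil(n_guvs / n_cols))
    pitch_r = (h - 2 * margin) / n_rows
    pitch_c = (w - 2 * margin) / n_cols
    if min(pitch_r, pitch_c) < 2 * r_max + 8:
        raise ParameterError("frame too small for that many separated GUVs")
    jitter = (min(pitch_r, pitch_c) - 2 * r_max - 4) / 2

    guvs = []
    cells = [(i, j) for i in range(n_rows) for j in range(n_cols)][:n_guvs]
    for i, j in cells:
        cr = margin + (i + 0.5) * pitch_r + rng.uniform(-jitter, jitter)
        cc = margin + (j + 0.5) * pitch_c + rng.uniform(-jitter, jitter)
        radius = rng.uniform(*radius_range)
        guvs.append(GUVSpec((cr, cc), radius, ring_amplitude, ring_thickness))

    n_positive = int(round(frac_with_puncta * n_guvs))
    positive = rng.choice(n_guvs, size=n_positive, replace=False)
    protein_roles = [r for r in channel_roles if r != "lipid"]
    puncta: dict[str, list[PunctumSpec]] = {r: [] for r in protein_roles}
    for g in positive:
        n_spots = int(rng.integers(1, max_puncta + 1))
        min_arc = 6.0 * spot_sigma / guvs[g].radius  # angular separation
        angles: list[float] = []
        while len(angles) < n_spots:
            a = float(rng.uniform(0, 2 * math.pi))
            if all(
                min(abs(a - b), 2 * math.pi - abs(a - b)) > min_arc for b in angles
            ):
                angles.append(a)
        for a in angles:
            puncta[protein_roles[0]].append(
                PunctumSpec(int(g), a, spot_amplitude, spot_sigma)
            )
            if len(protein_roles) > 1 and coloc_fraction is not None:
                if rng.uniform() < coloc_fraction:
                    b_angle = a
                else:
                    b_angle = a + math.pi  # far side of the ring
                puncta[protein_roles[1]].append(
                    PunctumSpec(int(g), b_angle, spot_amplitude, spot_sigma)
                )

    return SceneSpec(
        height=h,
        width=w,
        channel_roles=channel_roles,
        guvs=guvs,
        puncta=puncta,
        noise_sigma=noise_sigma,
        background_offset=background_offset,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

#: schedule target -> (lipid class, lipid region)
_TARGETS = {
    "PS_headgroup": ("lipid_PS", "headgroup"),
    "PS_acyl": ("lipid_PS", "acyl"),
    "PC_headgroup": ("lipid_PC", "headgroup"),
    "PC_acyl": ("lipid_PC", "acyl"),
}


@dataclass
class TrajSpec:
    """Scripted trajectory: who touches the membrane, and when.

    ``contact_schedule[resid][target]`` is the set of frames in which that
    residue's nearest-lipid distance is placed inside the contact cutoff via
    the given target atom (see :data:`_TARGETS`).  ``ion_schedule[ion]`` is a
    list of inclusive frame intervals in which the ion sits within the
    coordination cutoff of its designated PS lipid's phosphate oxygen.
    Distances are drawn uniformly in ``[0.7, 0.95] * cutoff`` inside
    scheduled frames and ``[1.5, 3] * cutoff`` outside.
    """

    n_frames: int
    residue_ids: Sequence[int]
    dt_ps: float = 2000.0
    box_nm: tuple[float, float, float] = (14.0, 14.0, 10.0)
    lattice_spacing_nm: float = 2.0
    membrane_z_nm: float = 2.0
    ps_fraction_pattern: int = 3  # site k is PS iff k % 10 < pattern (~30% PS)
    contact_cutoff_nm: float = 0.40
    coordination_cutoff_nm: float = 0.35
    contact_schedule: Mapping[int, Mapping[str, frozenset | set]] = field(default_factory=dict)
    ion_schedule: Mapping[int, Sequence[tuple[int, int]]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ParameterError("need at least one frame")
        if self.dt_ps <= 0 or min(self.box_nm) <= 0:
            raise ParameterError("dt and box lengths must be positive")
        for resid, targets in self.contact_schedule.items():
            if resid not in set(self.residue_ids):
                raise ParameterError(f"schedule references unknown residue {resid}")
            seen: set[int] = set()
            for target, frames in targets.items():
                if target not in _TARGETS:
                    raise ParameterError(f"unknown schedule target {target!r}")
                for f in frames:
                    if not 0 <= f < self.n_frames:
                        raise ParameterError(f"schedule frame {f} out of range")
                    if f in seen:
                        raise ParameterError(
                            f"residue {resid} scheduled to two targets in frame {f}"
                        )
                    seen.add(f)
        for ion, intervals in self.ion_schedule.items():
            last_end = -1
            for start, end in sorted(intervals):
                if not (0 <= start <= end < self.n_frames):
                    raise ParameterError(f"ion interval ({start}, {end}) out of range")
                if start <= last_end:
                    raise ParameterError(f"overlapping intervals for ion {ion}")
                last_end = end


@dataclass
class ContactTruth:
    """Planted truth for a generated trajectory.

    ``contact_frames[resid][kind]`` is the exact set of frames in which the
    residue touches the membrane (``kind`` in any/PS/PC/acyl); ``events`` are
    the exact coordination episodes as ``(ion_id, lipid_resid, start_frame,
    end_frame)`` with times derived from ``dt_ns``.
    """

    n_frames: int
    dt_ns: float
    contact_frames: dict[int, dict[str, frozenset]]
    events: list[tuple[int, int, int, int]]

    def fraction(self, resid: int, kind: str = "any",
                 frames: Sequence[int] | None = None) -> float:
        sel = self.contact_frames[resid][kind]
        if frames is None:
            return len(sel) / self.n_frames
        frames = list(frames)
        return sum(1 for f in frames if f in sel) / len(frames)

    def event_times_ns(self) -> list[tuple[int, int, float, float, float]]:
        """Events as (ion, lipid, t_start_ns, t_end_ns, duration_ns)."""
        out = []
        for ion, lipid, s, e in self.events:
            t0, t1 = s * self.dt_ns, e * self.dt_ns
            out.append((ion, lipid, t0, t1, t1 - t0 + self.dt_ns))
        return out


def _build_slab(spec: TrajSpec):
    """Static lipid lattice: per molecule a P (headgroup), PS oxygens, and a
    laterally offset C2 pseudo-atom standing in for the acyl region."""
    lx, ly, _ = spec.box_nm
    s = spec.lattice_spacing_nm
    nx, ny = int(lx // s), int(ly // s)
    lipids = []  # (class, dict atom_name -> xyz)
    k = 0
    for i in range(nx):
        for j in range(ny):
            x, y, z = (i + 0.5) * s, (j + 0.5) * s, spec.membrane_z_nm
            cls = "lipid_PS" if k % 10 < spec.ps_fraction_pattern else "lipid_PC"
            atoms = {"P": (x, y, z), "C2": (x + s / 2.0, y, z)}
            if cls == "lipid_PS":
                atoms["O13"] = (x + 0.1, y, z)
                atoms["O14"] = (x - 0.1, y, z)
            lipids.append((cls, atoms))
            k += 1
    return lipids


def generate_trajectory(spec: TrajSpec) -> tuple[Trajectory, ContactTruth]:
    """Emit a trajectory realizing the scripted contact and ion schedules.

    Geometry is arranged so that the scheduled distance *is* the residue's
    (or ion's) nearest relevant distance: every other membrane atom is at
    least one lattice half-spacing away laterally, far outside both cutoff
    bands.  The returned truth therefore holds exactly, for any analysis
    cutoff equal to the spec's.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lipids = _build_slab(spec)
    residue_ids = list(spec.residue_ids)

    ps_idx = [i for i, (cls, _) in enumerate(lipids) if cls == "lipid_PS"]
    pc_idx = [i for i, (cls, _) in enumerate(lipids) if cls == "lipid_PC"]
    n_res, n_ion = len(residue_ids), len(spec.ion_schedule)
    if len(ps_idx) < n_res + n_ion or len(pc_idx) < n_res:
        raise ParameterError("membrane slab too small for the scheduled actors")

    # dedicated, non-shared target lipids per residue and per ion
    res_target = {
        resid: {"lipid_PS": ps_idx[k], "lipid_PC": pc_idx[k]}
        for k, resid in enumerate(residue_ids)
    }
    ion_ids = sorted(spec.ion_schedule)
    ion_target = {ion: ps_idx[n_res + k] for k, ion in enumerate(ion_ids)}

    # --- topology -----------------------------------------------------------
    atoms: list[Atom] = []
    base_positions: list[tuple[float, float, float]] = []

    def add(name, resnum, resname, category, region, xyz):
        atoms.append(Atom(len(atoms), name, resnum, resname, category, region))
        base_positions.append(xyz)

    for resid in residue_ids:
        home = lipids[res_target[resid]["lipid_PS"]][1]["P"]
        add("CA", resid, "ALA", "protein", "n/a", home)
    lipid_resnums: list[int] = []
    next_resnum = max(residue_ids, default=0) + 1
    for cls, lat in lipids:
        resname = "DOPS" if cls == "lipid_PS" else "DOPC"
        lipid_resnums.append(next_resnum)
        for name, xyz in lat.items():
            region = "acyl" if name == "C2" else "headgroup"
            add(name, next_resnum, resname, cls, region, xyz)
        next_resnum += 1
    ion_resnums = {}
    for ion in ion_ids:
        ion_resnums[ion] = next_resnum
        add("CA", next_resnum, "CA", "ion_Ca", "n/a",
            lipids[ion_target[ion]][1]["O13"])
        next_resnum += 1

    # --- frames -------------------------------------------------------------
    cc, ic = spec.contact_cutoff_nm, spec.coordination_cutoff_nm
    coords = np.tile(np.asarray(base_positions), (spec.n_frames, 1, 1))
    contact_frames: dict[int, dict[str, set]] = {
        r: {"any": set(), "PS": set(), "PC": set(), "acyl": set()}
        for r in residue_ids
    }

    for a_i, resid in enumerate(residue_ids):
        schedule = spec.contact_schedule.get(resid, {})
        frame_target: dict[int, str] = {}
        for target, frames in schedule.items():
            for f in frames:
                frame_target[f] = target
        for f in range(spec.n_frames):
            target = frame_target.get(f)
            if target is None:
                anchor = lipids[res_target[resid]["lipid_PS"]][1]["P"]
                dist = rng.uniform(1.5 * cc, 3.0 * cc)
            else:
                cls, region = _TARGETS[target]
                atom = "P" if region == "headgroup" else "C2"
                anchor = lipids[res_target[resid][cls]][1][atom]
                dist = rng.uniform(0.7 * cc, 0.95 * cc)
                contact_frames[resid]["any"].add(f)
                contact_frames[resid]["PS" if cls == "lipid_PS" else "PC"].add(f)
                if region == "acyl":
                    contact_frames[resid]["acyl"].add(f)
            coords[f, a_i] = (anchor[0], anchor[1], anchor[2] + dist)

    events: list[tuple[int, int, int, int]] = []
    for k, ion in enumerate(ion_ids):
        a_i = next(i for i, a in enumerate(atoms)
                   if a.category == "ion_Ca" and a.residue_number == ion_resnums[ion])
        scheduled = np.zeros(spec.n_frames, dtype=bool)
        for start, end in spec.ion_schedule[ion]:
            scheduled[start:end + 1] = True
            events.append((ion, lipid_resnums[ion_target[ion]], start, end))
        anchor = lipids[ion_target[ion]][1]["O13"]
        for f in range(spec.n_frames):
            dist = (rng.uniform(0.7 * ic, 0.95 * ic) if scheduled[f]
                    else rng.uniform(1.5 * ic, 3.0 * ic))
            coords[f, a_i] = (anchor[0], anchor[1], anchor[2] + dist)

    times = spec.dt_ps * np.arange(spec.n_frames)
    boxes = np.tile(np.asarray(spec.box_nm), (spec.n_frames, 1))
    traj = Trajectory(atoms, coords, times, boxes)
    truth = ContactTruth(
        n_frames=spec.n_frames,
        dt_ns=spec.dt_ps / 1000.0,
        contact_frames={
            r: {k: frozenset(v) for k, v in d.items()}
            for r, d in contact_frames.items()
        },
        events=sorted(events),
    )
    return traj, truth


def random_traj_spec(
    seed: int,
    n_residues: int = 6,
    n_frames: int = 50,
    dt_ps: float = 2000.0,
    contact_prob: float = 0.4,
    n_ions: int = 2,
    mean_event_len: int = 2,
) -> TrajSpec:
    """Draw a random schedule: each residue contacts a random target type in
    a Bernoulli(``contact_prob``) subset of frames; each ion receives a few
    short, disjoint coordination intervals."""
    rng = np.random.default_rng(seed)
    residue_ids = list(range(30, 30 + n_residues))
    targets = list(_TARGETS)
    schedule: dict[int, dict[str, set]] = {}
    for resid in residue_ids:
        per_target: dict[str, set] = {}
        for f in range(n_frames):
            if rng.uniform() < contact_prob:
                t = targets[int(rng.integers(len(targets)))]
                per_target.setdefault(t, set()).add(f)
        if per_target:
            schedule[resid] = per_target
    ion_schedule: dict[int, list[tuple[int, int]]] = {}
    for ion in range(n_ions):
        intervals: list[tuple[int, int]] = []
        f = int(rng.integers(0, max(1, n_frames // 4)))
        while f < n_frames:
            length = 1 + int(rng.poisson(mean_event_len - 1))
            end = min(f + length - 1, n_frames - 1)
            intervals.append((f, end))
            f = end + 2 + int(rng.integers(0, max(2, n_frames // 4)))
        ion_schedule[ion] = intervals
    return TrajSpec(
        n_frames=n_frames,
        residue_ids=residue_ids,
        dt_ps=dt_ps,
        contact_schedule=schedule,
        ion_schedule=ion_schedule,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
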