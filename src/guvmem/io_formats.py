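"""Readers and writers for every external format the pipeline touches.

Images travel as multi-page TIFF (one page per channel), binary masks as PNG,
tabular results as CSV, detections and synthetic ground truth as JSON, and
structures/trajectories as (multi-model) PDB.  Coordinates are stored
internally in nanometres; PDB files carry angstroms and are converted on
read/write.  Pixel coordinates are 0-based ``(row, col)`` and bounding boxes
are half-open ``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError, ParameterError

__all__ = [
    "MultiChannelImage",
    "Atom",
    "Trajectory",
    "DetectionRecord",
    "read_multichannel_image",
    "write_multichannel_image",
    "read_trajectory",
    "write_trajectory",
    "read_detections",
    "write_detections",
    "write_results_table",
    "write_mask_png",
    "DEFAULT_CATEGORY_MAP",
    "DEFAULT_HEADGROUP_ATOMS",
]

CHANNEL_ROLES = ("lipid", "proteinA", "proteinB")

#: nm per angstrom
NM_PER_ANGSTROM = 0.1

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: residue-name -> category mapping used when reading trajectories
DEFAULT_CATEGORY_MAP: Mapping[str, str] = {
    **{aa: "protein" for aa in STANDARD_AMINO_ACIDS},
    "DOPS": "lipid_PS",
    "POPS": "lipid_PS",
    "DOPC": "lipid_PC",
    "POPC": "lipid_PC",
    "CA": "ion_Ca",
    "CAL": "ion_Ca",
}

#: lipid atom names treated as headgroup; all other lipid atoms are acyl
DEFAULT_HEADGROUP_ATOMS = ("P", "O11", "O12", "O13", "O14", "N")


@dataclass
class MultiChannelImage:
    """An H x W x C intensity raster with per-channel role tags.

    Intensities are kept as floating point in memory; they are quantised to
    ``bit_depth`` (8 or 16) only on write.
    """

    pixels: np.ndarray
    channel_roles: list[str]
    bit_depth: int = 16
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise ParameterError("pixels must be an H x W x C array")
        if self.pixels.shape[2] != len(self.channel_roles):
            raise ParameterError(
                f"{self.pixels.shape[2]} planes but "
                f"{len(self.channel_roles)} channel roles"
            )
        if self.bit_depth not in (8, 16):
            raise ParameterError("bit_depth must be 8 or 16")
        if np.any(self.pixels < 0):
            raise ParameterError("intensities must be nonnegative")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    def channel(self, role: str) -> np.ndarray:
        """Return the 2-D plane tagged with ``role``."""
        try:
            idx = self.channel_roles.index(role)
        except ValueError:
            raise ParameterError(f"no channel with role {role!r}") from None
        return self.pixels[:, :, idx]


def write_multichannel_image(image: MultiChannelImage, path: str | Path) -> None:
    """Write one TIFF page per channel, quantised to the declared bit depth.

    A YAML sidecar ``<path>.yaml`` records the channel roles, bit depth and
    pixel size so that :func:`read_multichannel_image` can restore them.
    """
    path = Path(path)
    if np.any(image.pixels > image.max_value):
        raise ParameterError(
            f"intensities exceed {image.max_value} for bit depth {image.bit_depth}"
        )
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    planes = np.rint(image.pixels).astype(dtype)
    tifffile.imwrite(path, np.moveaxis(planes, 2, 0))
    sidecar = {
        "channel_roles": list(image.channel_roles),
        "bit_depth": image.bit_depth,
        "pixel_size_um": image.pixel_size_um,
    }
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_multichannel_image(
    path: str | Path,
    channel_roles: Sequence[str] | None = None,
    bit_depth: int | None = None,
    pixel_size_um: float | None = None,
) -> MultiChannelImage:
    """Read a multi-page TIFF; planes map to channels in file order.

    Channel roles come from the ``channel_roles`` argument or, if omitted,
    from the YAML sidecar written alongside the image.  They are never
    guessed from pixel content.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        planes = [page.asarray() for page in tif.pages]
    if not planes:
        raise FormatError(f"{path}: TIFF contains no image planes")
    shapes = {p.shape for p in planes}
    if len(shapes) != 1 or planes[0].ndim != 2:
        raise FormatError(f"{path}: planes have mismatched shapes {shapes}")
    if not 1 <= len(planes) <= 4:
        raise FormatError(f"{path}: expected 1-4 planes, found {len(planes)}")

    sidecar_path = Path(str(path) + ".yaml")
    sidecar = {}
    if sidecar_path.exists():
        sidecar = yaml.safe_load(sidecar_path.read_text()) or {}
    if channel_roles is None:
        channel_roles = sidecar.get("channel_roles")
    if channel_roles is None:
        raise FormatError(
            f"{path}: channel roles not given and no sidecar config found"
        )
    if len(channel_roles) != len(planes):
        raise FormatError(
            f"{path}: {len(planes)} planes but {len(channel_roles)} roles"
        )
    if bit_depth is None:
        bit_depth = sidecar.get("bit_depth")
    if bit_depth is None:
        bit_depth = 8 if planes[0].dtype == np.uint8 else 16
    if pixel_size_um is None:
        pixel_size_um = sidecar.get("pixel_size_um")
    stack = np.stack(planes, axis=-1).astype(float)
    return MultiChannelImage(stack, list(channel_roles), bit_depth, pixel_size_um)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit PNG (255 = foreground)."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One labelled particle of a trajectory."""

    index: int
    name: str
    residue_number: int
    residue_name: str
    category: str          # protein | lipid_PS | lipid_PC | ion_Ca
    lipid_region: str      # headgroup | acyl | n/a


@dataclass
class Trajectory:
    """Timestamped frames of labelled atoms in a periodic orthorhombic box.

    ``coords`` has shape (n_frames, n_atoms, 3) in nm, ``times_ps`` is
    strictly increasing, and ``boxes`` has shape (n_frames, 3) in nm.
    """

    atoms: list[Atom]
    coords: np.ndarray
    times_ps: np.ndarray
    boxes: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        n_frames, n_atoms = self.coords.shape[:2]
        if n_atoms != len(self.atoms):
            raise ParameterError("coords second axis must match atom count")
        if self.times_ps.shape != (n_frames,):
            raise ParameterError("one time per frame required")
        if n_frames > 1 and not np.all(np.diff(self.times_ps) > 0):
            raise ParameterError("frame times must be strictly increasing")
        if self.boxes.shape != (n_frames, 3):
            raise ParameterError("one (lx, ly, lz) box per frame required")
        if np.any(self.boxes <= 0):
            raise ParameterError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_indices(self, category: str, lipid_region: str | None = None) -> np.ndarray:
        sel = [
            a.index
            for a in self.atoms
            if a.category == category
            and (lipid_region is None or a.lipid_region == lipid_region)
        ]
        return np.asarray(sel, dtype=int)

    @property
    def protein_residues(self) -> list[int]:
        return sorted({a.residue_number for a in self.atoms if a.category == "protein"})


def _classify_atoms(
    names: Sequence[str],
    resids: Sequence[int],
    resnames: Sequence[str],
    category_map: Mapping[str, str],
    headgroup_atoms: Sequence[str],
) -> list[Atom]:
    atoms = []
    head = set(headgroup_atoms)
    warned: set[str] = set()
    for i, (name, resid, resname) in enumerate(zip(names, resids, resnames)):
        category = category_map.get(resname)
        if category is None:
            if resname not in warned:
                warnings.warn(
                    f"residue name {resname!r} not in category map; treating as protein"
                )
                warned.add(resname)
            category = "protein"
        if category in ("lipid_PS", "lipid_PC"):
            region = "headgroup" if name in head else "acyl"
        else:
            region = "n/a"
        atoms.append(Atom(i, name, int(resid), resname, category, region))
    return atoms


def read_trajectory(
    topology_path: str | Path,
    frames_path: str | Path,
    dt_ps: float = 2000.0,
    t0_ps: float = 0.0,
    category_map: Mapping[str, str] | None = None,
    headgroup_atoms: Sequence[str] = DEFAULT_HEADGROUP_ATOMS,
) -> Trajectory:
    """Read a PDB topology plus multi-model PDB frames into a :class:`Trajectory`.

    PDB carries no time axis, so frame times are synthesised as
    ``t0_ps + i * dt_ps``.  Categories are assigned from residue names via
    ``category_map`` (default :data:`DEFAULT_CATEGORY_MAP`); lipid atoms are
    split into headgroup/acyl by ``headgroup_atoms``.  GRO/XTC frame files are
    accepted transparently (MDAnalysis dispatches on extension).
    """
    import MDAnalysis as mda

    if category_map is None:
        category_map = DEFAULT_CATEGORY_MAP
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MDAnalysis guesses elements noisily
            u = mda.Universe(str(topology_path), str(frames_path))
            # a global CRYST1 (outside the MODEL blocks) is only exposed via
            # the topology; use it when frames carry no per-model box
            top_dims = mda.Universe(str(topology_path)).dimensions
            n_atoms = len(u.atoms)
            coords = []
            boxes = []
            for ts in u.trajectory:
                if ts.positions.shape[0] != n_atoms:
                    raise FormatError("atom count differs between models")
                dims = ts.dimensions if ts.dimensions is not None else top_dims
                if dims is None or np.any(dims[:3] <= 0):
                    raise FormatError("frames must carry a positive CRYST1 box")
                if not np.allclose(dims[3:], 90.0):
                    raise FormatError("only orthorhombic boxes are supported")
                coords.append(ts.positions.astype(float) * NM_PER_ANGSTROM)
                boxes.append(dims[:3].astype(float) * NM_PER_ANGSTROM)
    except FormatError:
        raise
    except Exception as exc:  # MDAnalysis raises assorted types on bad input
        raise FormatError(f"could not read trajectory: {exc}") from exc

    atoms = _classify_atoms(
        [a.name for a in u.atoms],
        [a.resid for a in u.atoms],
        [a.resname for a in u.atoms],
        category_map,
        headgroup_atoms,
    )
    times = t0_ps + dt_ps * np.arange(len(coords))
    return Trajectory(atoms, np.asarray(coords), times, np.asarray(boxes))


def write_trajectory(traj: Trajectory, topology_path: str | Path, frames_path: str | Path) -> None:
    """Write a topology PDB (frame 0) and a multi-model PDB of all frames.

    Coordinates are converted nm -> angstrom; PDB's fixed-width fields give
    1e-3 angstrom precision, i.e. 1e-4 nm.
    """
    import MDAnalysis as mda

    n_atoms = traj.n_atoms
    resid_keys = [(a.residue_number, a.residue_name) for a in traj.atoms]
    unique_res: list[tuple[int, str]] = []
    resindex = np.empty(n_atoms, dtype=int)
    for i, key in enumerate(resid_keys):
        if not unique_res or unique_res[-1] != key:
            unique_res.append(key)
        resindex[i] = len(unique_res) - 1

    u = mda.Universe.empty(
        n_atoms,
        n_residues=len(unique_res),
        atom_resindex=resindex,
        residue_segindex=np.zeros(len(unique_res), dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in traj.atoms])
    u.add_TopologyAttr("resids", [r[0] for r in unique_res])
    u.add_TopologyAttr("resnames", [r[1] for r in unique_res])
    u.add_TopologyAttr("elements", [""] * n_atoms)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.positions = traj.coords[0] / NM_PER_ANGSTROM
        u.dimensions = [*(traj.boxes[0] / NM_PER_ANGSTROM), 90.0, 90.0, 90.0]
        u.atoms.write(str(topology_path))
        with mda.Writer(str(frames_path), n_atoms, multiframe=True) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f] / NM_PER_ANGSTROM
                u.dimensions = [*(traj.boxes[f] / NM_PER_ANGSTROM), 90.0, 90.0, 90.0]
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# detections and result tables
# ---------------------------------------------------------------------------

@dataclass
class DetectionRecord:
    """Externally produced GUV detections for one image.

    ``regions`` entries are dicts with keys ``center`` (row, col), ``radius``
    (px) and ``bbox`` (r0, r1, c0, c1), half-open.
    """

    image_id: str
    regions: list[dict] = field(default_factory=list)


def write_detections(records: Sequence[DetectionRecord], path: str | Path) -> None:
    payload = [
        {
            "image_id": rec.image_id,
            "regions": [
                {
                    "center": [float(r["center"][0]), float(r["center"][1])],
                    "radius": float(r["radius"]),
                    "bbox": [int(v) for v in r["bbox"]],
                }
                for r in rec.regions
            ],
        }
        for rec in records
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_detections(path: str | Path) -> list[DetectionRecord]:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    records = []
    for entry in payload:
        records.append(
            DetectionRecord(
                image_id=str(entry["image_id"]),
                regions=[
                    {
                        "center": tuple(r["center"]),
                        "radius": float(r["radius"]),
                        "bbox": tuple(r["bbox"]),
                    }
                    for r in entry.get("regions", [])
                ],
            )
        )
    return records


def write_results_table(records: Sequence[Mapping], path: str | Path) -> None:
    """Write result rows as CSV with a deterministic row order.

    Rows are sorted by ``image_id`` then ``region_index`` when those columns
    exist; floats keep at least 8 significant digits.  Empty input yields a
    header-only file (header from the canonical column set).
    """
    columns = ["image_id", "region_index", "channel", "n_puncta", "value"]
    df = pd.DataFrame(list(records))
    if df.empty:
        df = pd.DataFrame(columns=columns)
    sort_cols = [c for c in ("image_id", "region_index") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False, float_format="%.8g")
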