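"""Backbone superposition and RMSD over a residue range.

Implements the Kabsch least-squares rigid superposition: the proper rotation
(det = +1, reflections sign-corrected) and translation minimizing the RMSD
between paired coordinate sets, and the residue-range backbone RMSD built on
it.  Coordinates are in angstroms throughout (the PDB convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError, ParameterError

__all__ = ["BACKBONE_ATOMS", "StructModel", "kabsch_superpose", "backbone_rmsd"]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class StructModel:
    """Ordered residues with backbone coordinates in angstroms.

    ``coords[(residue_number, atom_name)] -> (3,) array``.  Residue numbers
    must be strictly increasing in ``residues``.
    """

    residues: list[tuple[int, str]]
    coords: dict[tuple[int, str], np.ndarray]

    def __post_init__(self) -> None:
        numbers = [n for n, _ in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ParameterError("residue numbers must be strictly increasing")

    @classmethod
    def from_pdb(cls, path, chain: str | None = None, model_index: int = 0) -> "StructModel":
        """Read backbone atoms of one chain from a PDB/mmCIF file."""
        import gemmi

        structure = gemmi.read_structure(str(path))
        if len(structure) == 0:
            raise FormatError(f"{path}: no models")
        model = structure[model_index]
        chains = [c for c in model if chain is None or c.name == chain]
        if not chains:
            raise FormatError(f"{path}: chain {chain!r} not found")
        residues: list[tuple[int, str]] = []
        coords: dict[tuple[int, str], np.ndarray] = {}
        for res in chains[0]:
            num = res.seqid.num
            residues.append((num, res.name))
            for atom in res:
                if atom.name in BACKBONE_ATOMS:
                    pos = atom.pos
                    coords[(num, atom.name)] = np.array([pos.x, pos.y, pos.z])
        return cls(residues, coords)


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``coords_b`` onto ``coords_a``.

    Returns ``(rotation, translation, rmsd)`` with ``rotation`` a proper
    rotation (det = +1) such that ``coords_b @ rotation.T + translation``
    best fits ``coords_a`` in the least-squares sense, and ``rmsd`` that
    minimum in the units of the input.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ParameterError("coordinate sets must both be (n, 3)")
    n = a.shape[0]
    if n < 3:
        raise ParameterError("need at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    # degenerate geometry: collinear points leave the rotation underdetermined
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise ParameterError("degenerate (collinear) geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ca - rotation @ cb
    fitted = b0 @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - a0) ** 2, axis=1))))
    return rotation, translation, rmsd


def backbone_rmsd(
    model_a: StructModel,
    model_b: StructModel,
    residue_range: tuple[int, int],
    atoms: tuple[str, ...] = BACKBONE_ATOMS,
) -> float:
    """Backbone RMSD after optimal superposition over a residue range.

    Atoms are paired by residue number and atom name across the inclusive
    ``residue_range``; any missing residue or atom is an error listing the
    gaps.  ``atoms=('CA',)`` selects a CA-only superposition.
    """
    lo, hi = residue_range
    if lo > hi:
        raise ParameterError("empty residue range")
    wanted = [(num, name) for num in range(lo, hi + 1) for name in atoms]
    gaps = [key for key in wanted
            if key not in model_a.coords or key not in model_b.coords]
    if gaps:
        shown = ", ".join(f"{n}:{a}" for n, a in gaps[:8])
        more = "" if len(gaps) <= 8 else f" (+{len(gaps) - 8} more)"
        raise ParameterError(f"missing backbone atoms in range: {shown}{more}")
    a = np.array([model_a.coords[key] for key in wanted])
    b = np.array([model_b.coords[key] for key in wanted])
    _, _, rmsd = kabsch_superpose(a, b)
    return rmsd
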