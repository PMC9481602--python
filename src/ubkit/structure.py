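"""Residue minimum-distance descriptors of structural ensembles.

Given an ensemble of conformations (frames), two descriptors summarize the
local packing around a residue: the per-frame minimum interatomic distance
between a residue pair (e.g. position 11 versus E34 across the helix), and
the residue × residue matrix of per-frame minimum distances truncated at a
cutoff (default 1 nm) and averaged over frames — the classic mdmat-style
contact map.  Differencing a variant matrix against the wild-type matrix
highlights where a modification pushes residues apart or pulls them
together.

Internal unit is nm; PDB coordinates (Å) are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

from .errors import TopologyError, ValidationError

__all__ = [
    "StructureEnsemble",
    "DistanceMatrix",
    "read_ensemble",
    "write_ensemble",
    "pair_min_distance",
    "mean_min_distance_matrix",
    "difference_matrix",
    "write_distance_matrix",
]

ANGSTROM_TO_NM = 0.1

#: Hydrogen element symbols (excluded in heavy-atom-only mode).
_HYDROGENS = {"H", "D"}


@dataclass
class StructureEnsemble:
    """Coordinate frames sharing one residue/atom topology.

    ``coords`` has shape (n_frames, n_atoms, 3) in nm; atoms are sorted so
    that each residue occupies a contiguous block.  ``atom_residues`` gives
    the 1-based residue number of every atom; ``elements`` its element
    symbol.
    """

    coords: np.ndarray
    atom_residues: np.ndarray
    elements: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise ValidationError("non-finite coordinates")
        if self.coords.shape[1] != len(self.atom_residues):
            raise TopologyError("atom_residues length mismatch")
        # contiguous residue blocks are required for the block reductions
        r = self.atom_residues
        changes = np.flatnonzero(np.diff(r)) + 1
        starts = np.concatenate([[0], changes])
        if len(np.unique(r[starts])) != len(starts):
            raise TopologyError("atoms of one residue must be contiguous")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def residue_numbers(self) -> List[int]:
        r = self.atom_residues
        starts = np.concatenate([[0], np.flatnonzero(np.diff(r)) + 1])
        return [int(x) for x in r[starts]]

    def atom_indices(self, residue: int) -> np.ndarray:
        idx = np.flatnonzero(self.atom_residues == residue)
        if len(idx) == 0:
            raise ValidationError(f"residue {residue} not in ensemble")
        return idx

    def heavy_atom_mask(self) -> np.ndarray:
        return ~np.isin(self.elements, list(_HYDROGENS))


@dataclass
class DistanceMatrix:
    """Mean minimum-distance map (nm), entries capped at ``cutoff``."""

    residues: List[int]
    values: np.ndarray  # (R, R), symmetric, zero diagonal
    cutoff: float
    n_frames: int

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.residues), len(self.residues)):
            raise ValidationError("matrix shape does not match residue list")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix must be symmetric")

    def entry(self, res_i: int, res_j: int) -> float:
        i = self.residues.index(res_i)
        j = self.residues.index(res_j)
        return float(self.values[i, j])


def read_ensemble(path: str | Path, label: Optional[str] = None) -> StructureEnsemble:
    """Read a (multi-model) PDB file as an ensemble; Å converted to nm.

    Frames follow MODEL order; a single-structure file yields one frame.
    Hydrogens are retained when present.  Models must share the same atom
    topology.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(label or path.stem, str(path))
    frames = []
    topo: Optional[List[Tuple[int, str]]] = None
    residues_per_model = []
    elements_per_model = []
    for model in structure:
        atoms = []
        for chain in model:
            for residue in chain:
                het, resseq, _ = residue.get_id()
                if het.strip():
                    continue  # skip waters/heteroatoms
                for atom in residue:
                    atoms.append((resseq, atom.get_name(), atom.coord, atom.element))
        atoms.sort(key=lambda a: (a[0], a[1]))
        signature = [(a[0], a[1]) for a in atoms]
        if topo is None:
            topo = signature
        elif signature != topo:
            raise TopologyError(f"{path}: models disagree on atom topology")
        frames.append(np.array([a[2] for a in atoms], dtype=float) * ANGSTROM_TO_NM)
        residues_per_model = [a[0] for a in atoms]
        elements_per_model = [str(a[3]).upper() for a in atoms]
    if not frames:
        raise ValidationError(f"{path}: no models found")
    return StructureEnsemble(
        coords=np.stack(frames),
        atom_residues=np.array(residues_per_model, dtype=int),
        elements=np.array(elements_per_model, dtype=object),
        label=label or path.stem,
    )


def write_ensemble(e: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as a minimal multi-model PDB (nm back to Å)."""
    lines: List[str] = []
    for frame in range(e.n_frames):
        lines.append(f"MODEL     {frame + 1:4d}")
        serial = 1
        for i in range(e.coords.shape[1]):
            x, y, z = e.coords[frame, i] / ANGSTROM_TO_NM
            element = str(e.elements[i])
            name = f"{element}{i % 99:d}"[:4]
            lines.append(
                f"ATOM  {serial:5d} {name:>4s} GLY A{int(e.atom_residues[i]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def pair_min_distance(
    e: StructureEnsemble, res_a: int, res_b: int, heavy_only: bool = False
) -> np.ndarray:
    """Per-frame minimum interatomic distance between two residues (nm)."""
    ia = e.atom_indices(res_a)
    ib = e.atom_indices(res_b)
    if heavy_only:
        mask = e.heavy_atom_mask()
        ia = ia[mask[ia]]
        ib = ib[mask[ib]]
        if len(ia) == 0 or len(ib) == 0:
            raise ValidationError("no heavy atoms left for one residue")
    out = np.empty(e.n_frames)
    for f in range(e.n_frames):
        out[f] = cdist(e.coords[f, ia], e.coords[f, ib]).min()
    return out


def mean_min_distance_matrix(
    e: StructureEnsemble, cutoff: float = 1.0, heavy_only: bool = False
) -> DistanceMatrix:
    """Residue × residue mean minimum-distance matrix, capped at ``cutoff``.

    Per frame, the minimum distance of each residue pair is truncated at
    the cutoff; truncated values are then averaged over frames
    (truncate-then-average, mdmat semantics).
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be > 0")
    atom_res = e.atom_residues
    coords = e.coords
    if heavy_only:
        mask = e.heavy_atom_mask()
        atom_res = atom_res[mask]
        coords = coords[:, mask]
    starts = np.concatenate([[0], np.flatnonzero(np.diff(atom_res)) + 1])
    residues = [int(x) for x in atom_res[starts]]
    n_res = len(residues)
    acc = np.zeros((n_res, n_res))
    for f in range(e.n_frames):
        d = cdist(coords[f], coords[f])
        # block-minimum over residue segments, rows then columns
        d = np.minimum.reduceat(d, starts, axis=0)
        d = np.minimum.reduceat(d, starts, axis=1)
        acc += np.minimum(d, cutoff)
    values = acc / e.n_frames
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0
    return DistanceMatrix(residues=residues, values=values, cutoff=cutoff, n_frames=e.n_frames)


def difference_matrix(variant: DistanceMatrix, reference: DistanceMatrix) -> np.ndarray:
    """Elementwise variant − reference distance map (nm).

    Positive entries mean the residue pair sits farther apart in the
    variant ensemble.  Antisymmetric under argument swap.
    """
    if variant.residues != reference.residues:
        raise ValidationError("residue sets differ between matrices")
    if variant.cutoff != reference.cutoff:
        raise ValidationError("cutoffs differ between matrices")
    return variant.values - reference.values


def write_distance_matrix(
    m: DistanceMatrix | np.ndarray,
    path: str | Path,
    residues: Optional[Sequence[int]] = None,
    long_format: bool = False,
) -> None:
    """Write a distance (or difference) matrix as TSV.

    Wide format has residue headers; long format has one
    (res_i, res_j, distance_nm) row per pair.
    """
    if isinstance(m, DistanceMatrix):
        values, res = m.values, m.residues
    else:
        if residues is None:
            raise ValidationError("residues required for a bare array")
        values, res = m, list(residues)
    lines: List[str] = []
    if long_format:
        lines.append("res_i\tres_j\tdistance_nm")
        for i, ri in enumerate(res):
            for j, rj in enumerate(res):
                if j <= i:
                    continue
                lines.append(f"{ri}\t{rj}\t{values[i, j]:.6f}")
    else:
        lines.append("residue\t" + "\t".join(str(r) for r in res))
        for i, ri in enumerate(res):
            lines.append(f"{ri}\t" + "\t".join(f"{v:.6f}" for v in values[i]))
    Path(path).write_text("\n".join(lines) + "\n")
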