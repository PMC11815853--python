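"""Heterogeneous protein-ligand complex representation.

A bound pose is modelled as protein residues (residue level), ligand atoms
and metal ions (atom level).  The geometric quantity everything downstream
consumes is the *minimum distance* between a residue's heavy atoms and each
ligand atom, together with plain point distances for metal-ligand pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Residue", "LigandAtom", "MetalIon", "ComplexGraph", "PairSet",
    "load_protein", "load_ligand_poses", "enumerate_pairs",
    "SCORING_ELEMENTS", "DEFAULT_METALS", "UnsupportedElementError",
]

#: ligand element vocabulary accepted by the scoring heads
SCORING_ELEMENTS = ("H", "B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I")

#: biologically common cations recognised as metal ions by default
DEFAULT_METALS = frozenset({"Zn", "Mg", "Ca", "Mn", "Fe", "Ni", "Cu", "Co", "K", "Na"})

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AA_LETTERS = tuple(sorted(_THREE_TO_ONE.values())) + ("X",)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class UnsupportedElementError(ValueError):
    """Raised when a ligand pose contains elements outside the vocabulary."""


@dataclass
class Residue:
    chain_id: str
    seq_index: int                 # author numbering, metadata only
    aa_code: str                   # one-letter code, "X" for non-standard
    heavy_atom_coords: np.ndarray  # (n_heavy, 3) in Angstrom

    def __post_init__(self):
        self.heavy_atom_coords = np.asarray(self.heavy_atom_coords, dtype=float)
        if self.heavy_atom_coords.ndim != 2 or self.heavy_atom_coords.shape[0] == 0:
            raise ValueError("residue needs at least one heavy atom")
        if self.aa_code not in AA_LETTERS:
            raise ValueError(f"unknown amino-acid code {self.aa_code!r}")


@dataclass
class LigandAtom:
    element: str
    coord: np.ndarray
    atom_index: int

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("ligand atom coordinate not finite")
        if self.element not in SCORING_ELEMENTS:
            raise UnsupportedElementError(f"unsupported ligand element {self.element!r}")


@dataclass
class MetalIon:
    element: str
    coord: np.ndarray
    ion_index: int

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("metal coordinate not finite")


@dataclass
class ComplexGraph:
    residues: list[Residue]
    ligand_atoms: list[LigandAtom]
    metals: list[MetalIon] = field(default_factory=list)
    pose_id: str = "pose"
    protein_id: str | None = None
    ligand_id: str | None = None

    def __post_init__(self):
        if len(self.residues) == 0 or len(self.ligand_atoms) == 0:
            raise ValueError("complex needs at least one residue and one ligand atom")
        if self.protein_id is None:
            self.protein_id = self.pose_id
        if self.ligand_id is None:
            self.ligand_id = self.pose_id

    @property
    def ligand_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.ligand_atoms])

    @property
    def metal_coords(self) -> np.ndarray:
        if not self.metals:
            return np.zeros((0, 3))
        return np.array([m.coord for m in self.metals])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexGraph":
        """Return a copy with a rigid motion applied jointly to all coordinates."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return ComplexGraph(
            residues=[Residue(r.chain_id, r.seq_index, r.aa_code, r.heavy_atom_coords @ R.T + t)
                      for r in self.residues],
            ligand_atoms=[LigandAtom(a.element, R @ a.coord + t, a.atom_index)
                          for a in self.ligand_atoms],
            metals=[MetalIon(m.element, R @ m.coord + t, m.ion_index) for m in self.metals],
            pose_id=self.pose_id, protein_id=self.protein_id, ligand_id=self.ligand_id,
        )


@dataclass
class PairSet:
    """Residue-atom and metal-atom pairs with minimum distances within a cutoff."""

    pl_pairs: list[tuple[int, int, float]]   # (residue i, ligand atom j, d_ij)
    ml_pairs: list[tuple[int, int, float]]   # (metal k, ligand atom j, d_kj)
    cutoff: float

    def __post_init__(self):
        for _, _, d in self.pl_pairs + self.ml_pairs:
            if not (0.0 < d <= self.cutoff):
                raise ValueError(f"pair distance {d} outside (0, {self.cutoff}]")

    def to_tsv(self, path, pose_id: str = "pose"):
        with open(path, "w") as fh:
            fh.write("pose_id\tkind\ti\tj\td\n")
            for i, j, d in self.pl_pairs:
                fh.write(f"{pose_id}\tPL\t{i}\t{j}\t{d:.6f}\n")
            for k, j, d in self.ml_pairs:
                fh.write(f"{pose_id}\tML\t{k}\t{j}\t{d:.6f}\n")


# ---------------------------------------------------------------------------
# structure IO
# ---------------------------------------------------------------------------

def load_protein(path, metal_list=DEFAULT_METALS) -> tuple[list[Residue], list[MetalIon]]:
    """Parse a PDB file into residues and metal ions.

    Alternate locations are resolved to the highest-occupancy conformer,
    waters and non-metal heteroatoms are dropped, protein hydrogens are
    excluded (distances use heavy atoms only) and non-standard amino acids
    are retained with code ``"X"``.
    """
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # noqa: BLE001 - re-raise as a parse error
        raise ValueError(f"could not parse PDB file {path}: {exc}") from exc

    metal_upper = {m.upper(): m.capitalize() for m in metal_list}

    residues: list[Residue] = []
    metals: list[MetalIon] = []
    for start, stop in zip(*_residue_bounds(atoms)):
        sub = atoms[start:stop]
        res_name = sub.res_name[0].upper()
        if res_name in _WATER_NAMES:
            continue
        # polymer records (ATOM) are protein residues; non-standard names map to "X"
        if not sub.hetero[0] or res_name in _THREE_TO_ONE:
            heavy = sub[sub.element != "H"]
            if len(heavy) == 0:
                continue
            residues.append(Residue(
                chain_id=str(sub.chain_id[0]),
                seq_index=int(sub.res_id[0]),
                aa_code=_THREE_TO_ONE.get(res_name, "X"),
                heavy_atom_coords=heavy.coord.astype(float),
            ))
        # heteroatom record: single-atom residues with a recognised metal element
        elif len(sub) == 1 and sub.element[0].upper() in metal_upper:
            metals.append(MetalIon(
                element=metal_upper[sub.element[0].upper()],
                coord=sub.coord[0].astype(float),
                ion_index=len(metals),
            ))
        # other heteroatoms (cofactors, buffers) are dropped

    if not residues:
        raise ValueError(f"no standard protein residues found in {path}")
    return residues, metals


def _residue_bounds(atoms):
    import biotite.structure as struc

    starts = struc.get_residue_starts(atoms)
    stops = np.append(starts[1:], len(atoms))
    return starts, stops


def load_ligand_poses(path, on_unsupported: str = "raise"):
    """Read a multi-record SDF into one ligand-atom list per pose.

    Atom order within each record is preserved and element symbols are
    normalised (``"CL"`` -> ``"Cl"``).  Records whose elements fall outside
    the scoring vocabulary are rejected: with ``on_unsupported="raise"`` an
    :class:`UnsupportedElementError` is raised naming the offending elements;
    with ``"skip"`` the pose is dropped with a warning and scoring continues.
    """
    from rdkit import Chem

    if on_unsupported not in ("raise", "skip"):
        raise ValueError("on_unsupported must be 'raise' or 'skip'")

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    poses: list[list[LigandAtom]] = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unparseable SDF record {idx} in {path}")
        if mol.GetNumConformers() == 0:
            raise ValueError(f"SDF record {idx} has no coordinates")
        conf = mol.GetConformer()
        coords = conf.GetPositions()
        if not conf.Is3D() and np.allclose(coords[:, 2], 0.0):
            raise ValueError(f"SDF record {idx} is 2D-only (all z = 0)")
        symbols = [a.GetSymbol() for a in mol.GetAtoms()]
        bad = sorted({s for s in symbols if s not in SCORING_ELEMENTS})
        if bad:
            msg = f"SDF record {idx} contains unsupported elements {bad}"
            if on_unsupported == "raise":
                raise UnsupportedElementError(msg)
            warnings.warn(msg + "; pose skipped", stacklevel=2)
            continue
        poses.append([LigandAtom(sym, coords[j], j) for j, sym in enumerate(symbols)])
    return poses


# ---------------------------------------------------------------------------
# pair enumeration
# ---------------------------------------------------------------------------

def enumerate_pairs(complex: ComplexGraph, cutoff: float = 9.0,
                    include_hydrogens: bool = True) -> PairSet:
    """All residue-atom and metal-atom pairs with (minimum) distance <= cutoff.

    The residue-atom distance ``d_ij`` is the minimum over the residue's heavy
    atoms of the Euclidean distance to ligand atom ``j``; metal-atom distances
    are plain point-to-point.  An empty result is valid (score contribution 0).
    """
    from scipy.spatial.distance import cdist

    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    lig = complex.ligand_coords
    keep_atom = np.array([include_hydrogens or a.element != "H" for a in complex.ligand_atoms])

    pl_pairs: list[tuple[int, int, float]] = []
    for i, res in enumerate(complex.residues):
        d = cdist(res.heavy_atom_coords, lig).min(axis=0)
        for j in np.nonzero((d <= cutoff) & keep_atom)[0]:
            if d[j] <= 0.0:
                raise ValueError(f"coincident residue/ligand atoms at pair ({i}, {j})")
            pl_pairs.append((i, int(j), float(d[j])))

    ml_pairs: list[tuple[int, int, float]] = []
    met = complex.metal_coords
    if len(met):
        dm = cdist(met, lig)
        for k in range(dm.shape[0]):
            for j in np.nonzero((dm[k] <= cutoff) & keep_atom)[0]:
                if dm[k, j] <= 0.0:
                    raise ValueError(f"coincident metal/ligand atoms at pair ({k}, {j})")
                ml_pairs.append((k, int(j), float(dm[k, j])))

    return PairSet(pl_pairs=pl_pairs, ml_pairs=ml_pairs, cutoff=cutoff)
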