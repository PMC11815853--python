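"""Synthetic complexes, distance samples and screening libraries.

Everything here is a pure function of its parameters and a seed, so the
whole stack can be trained and evaluated without downloads.  Two complex
generators are provided:

* :func:`gen_complex` — geometric toys where a controllable fraction of
  residue-atom pairs falls within the scoring cutoff (placement gives each
  residue either all pairs inside or all pairs outside the cutoff, so the
  expected pair fraction equals the requested fraction exactly);
* :func:`gen_mixture_complex` — "class-labelled" complexes whose ligand
  atoms sit far apart, so each residue forms exactly one pair whose distance
  is drawn from a known per-(amino-acid, element) mixture.  These planted
  mixtures are the ground truth for parameter-recovery and pose-ranking
  checks.
"""

from __future__ import annotations

import numpy as np

from .complex_model import ComplexGraph, LigandAtom, MetalIon, Residue, enumerate_pairs
from .nmdn_core import MixtureDensity, log_density_at, reference_probability

__all__ = [
    "gen_complex", "gen_mixture_distances", "gen_screen_library",
    "make_class_mixtures", "gen_mixture_complex", "gen_pose_system",
    "true_nmdn_score", "gen_affinity_dataset", "write_pdb", "write_sdf",
]

_AA20 = list("ACDEFGHIKLMNPQRSTVWY")
_HEAVY_ELEMENTS = ["C", "N", "O", "S"]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


def _random_unit(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def gen_complex(n_residues: int, n_lig_atoms: int, n_metals: int = 0, seed: int = 0,
                within_fraction: float = 0.7, cutoff: float = 9.0) -> ComplexGraph:
    """Random toy complex with a controllable within-cutoff pair fraction.

    The ligand is a tight blob (radius 1 A) at the origin.  Each residue is
    anchored at a sampled minimum distance from its nearest ligand atom:
    "inside" residues at 2.5-5.5 A (within the cutoff of every ligand atom)
    and "outside" residues beyond cutoff+3 (outside for every atom), so the
    expected fraction of residue-atom pairs inside the cutoff equals
    ``within_fraction``.
    """
    rng = np.random.default_rng(seed)
    lig_coords = rng.uniform(-1.0, 1.0, (n_lig_atoms, 3))
    lig_coords *= 1.0 / max(1.0, np.max(np.linalg.norm(lig_coords, axis=1)))
    ligand_atoms = [
        LigandAtom(rng.choice(_HEAVY_ELEMENTS), lig_coords[j], j)
        for j in range(n_lig_atoms)
    ]

    residues = []
    for i in range(n_residues):
        inside = rng.random() < within_fraction
        m = rng.uniform(2.5, min(5.5, cutoff - 3.5)) if inside else rng.uniform(cutoff + 3.0, cutoff + 7.0)
        anchor = lig_coords[rng.integers(n_lig_atoms)]
        direction = _random_unit(rng)
        base = anchor + m * direction
        n_atoms = int(rng.integers(1, 4))
        coords = [base]
        for _ in range(n_atoms - 1):
            # extra atoms strictly farther from the ligand than the base atom
            coords.append(base + direction * rng.uniform(0.2, 0.8))
        residues.append(Residue(chain_id="A", seq_index=i + 1,
                                aa_code=str(rng.choice(_AA20)),
                                heavy_atom_coords=np.array(coords)))

    metals = []
    for k in range(n_metals):
        m = rng.uniform(2.5, min(5.5, cutoff - 3.5))
        metals.append(MetalIon("Zn", lig_coords[rng.integers(n_lig_atoms)]
                               + m * _random_unit(rng), k))

    return ComplexGraph(residues=residues, ligand_atoms=ligand_atoms, metals=metals,
                        pose_id=f"synthetic-{seed}")


def gen_mixture_distances(class_params: dict[tuple, MixtureDensity], n_per_class: int,
                          seed: int = 0, cutoff: float = 9.0) -> dict[tuple, np.ndarray]:
    """Distance samples per class, drawn from the stated mixtures and
    truncated (by rejection) to (0, cutoff]."""
    rng = np.random.default_rng(seed)
    out = {}
    for key, mix in class_params.items():
        samples: list[float] = []
        while len(samples) < n_per_class:
            comp = rng.choice(mix.n_components, size=n_per_class, p=mix.weights)
            draw = rng.normal(mix.means[comp], mix.sigmas[comp])
            ok = draw[(draw > 0) & (draw <= cutoff)]
            samples.extend(ok.tolist())
        out[key] = np.array(samples[:n_per_class])
    return out


def gen_screen_library(n_ligands: int, active_fraction: float = 0.02,
                       score_separation: float = 0.0, seed: int = 0):
    """Screening table with actives' latent score shifted by ``score_separation``.

    With separation 0 the expected enrichment factor is 1; large separations
    push the EF toward its 1/active_fraction maximum.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_active = int(round(n_ligands * active_fraction))
    is_active = np.zeros(n_ligands, dtype=bool)
    is_active[rng.choice(n_ligands, size=n_active, replace=False)] = True
    score = rng.standard_normal(n_ligands) + score_separation * is_active
    return pd.DataFrame({
        "ligand_id": [f"lig{i:05d}" for i in range(n_ligands)],
        "score": score,
        "is_active": is_active,
    })


# ---------------------------------------------------------------------------
# planted-mixture complexes
# ---------------------------------------------------------------------------

def make_class_mixtures(aa_codes=("A", "G"), elements=("C", "O"),
                        seed: int = 0, n_components: int = 2) -> dict:
    """Random but reproducible 2-component mixtures keyed by (aa, element).

    Component means lie in 2-7 A and sigmas in 0.35-0.8 A, so essentially
    all mass sits inside the 9 A cutoff.
    """
    rng = np.random.default_rng(seed)
    mixtures = {}
    for aa in aa_codes:
        for el in elements:
            w = rng.uniform(0.25, 0.75)
            means = np.sort(rng.uniform(2.0, 7.0, n_components))
            while np.min(np.diff(means, prepend=means[0] - 2.0)[1:]) < 1.0 and n_components > 1:
                means = np.sort(rng.uniform(2.0, 7.0, n_components))
            sigmas = rng.uniform(0.35, 0.8, n_components)
            weights = np.full(n_components, (1 - w) / max(n_components - 1, 1))
            weights[0] = w
            mixtures[(aa, el)] = MixtureDensity(weights, means, sigmas)
    return mixtures


_ATOM_SPACING = 30.0   # ligand atoms far apart: every residue forms exactly one pair


def gen_mixture_complex(class_mixtures: dict, n_res_per_atom: int = 4, seed: int = 0,
                        distance_sampler=None, cutoff: float = 9.0,
                        pose_id: str | None = None) -> ComplexGraph:
    """Complex whose pair distances are draws from the planted class mixtures.

    Ligand atoms (one per element in the classes) are spaced 30 A apart, so
    each residue is within the cutoff of exactly one atom and the pair
    distance is exactly the sampled value.  ``distance_sampler(rng, key)``
    overrides the mixture draw (used to build decoy poses).
    """
    rng = np.random.default_rng(seed)
    aa_codes = sorted({aa for aa, _ in class_mixtures})
    elements = sorted({el for _, el in class_mixtures})

    ligand_atoms = [LigandAtom(el, np.array([j * _ATOM_SPACING, 0.0, 0.0]), j)
                    for j, el in enumerate(elements)]

    def draw(key):
        if distance_sampler is not None:
            return float(distance_sampler(rng, key))
        mix = class_mixtures[key]
        while True:
            comp = int(rng.choice(mix.n_components, p=mix.weights))
            d = rng.normal(mix.means[comp], mix.sigmas[comp])
            if 0.5 < d <= cutoff - 0.2:
                return float(d)

    residues = []
    for j, el in enumerate(elements):
        for r in range(n_res_per_atom):
            aa = aa_codes[r % len(aa_codes)]
            d = draw((aa, el))
            pos = ligand_atoms[j].coord + d * _random_unit(rng)
            residues.append(Residue("A", len(residues) + 1, aa, pos[None, :]))

    return ComplexGraph(residues=residues, ligand_atoms=ligand_atoms,
                        pose_id=pose_id or f"mixture-{seed}")


def gen_pose_system(class_mixtures: dict, n_res_per_atom: int = 4, n_poses: int = 4,
                    seed: int = 0, decoy_range: tuple[float, float] = (1.5, 8.5),
                    cutoff: float = 9.0) -> list[ComplexGraph]:
    """One docking system: pose 0 native-like (mixture-sampled distances),
    the rest decoys with uniform pair distances."""
    poses = [gen_mixture_complex(class_mixtures, n_res_per_atom, seed=seed * 1000,
                                 cutoff=cutoff, pose_id=f"sys{seed}-pose0")]
    lo, hi = decoy_range
    for p in range(1, n_poses):
        poses.append(gen_mixture_complex(
            class_mixtures, n_res_per_atom, seed=seed * 1000 + p, cutoff=cutoff,
            distance_sampler=lambda rng, key: rng.uniform(lo, hi),
            pose_id=f"sys{seed}-pose{p}"))
    return poses


def true_nmdn_score(complex: ComplexGraph, class_mixtures: dict, cutoff: float = 9.0,
                    ref_distance: float | None = None) -> float:
    """Oracle score using the generative mixtures instead of a trained head."""
    if ref_distance is None:
        ref_distance = cutoff
    pairs = enumerate_pairs(complex, cutoff=cutoff)
    total = 0.0
    for i, j, d in pairs.pl_pairs:
        key = (complex.residues[i].aa_code, complex.ligand_atoms[j].element)
        mix = class_mixtures[key]
        log_p = float(log_density_at(mix, d))
        p_ref = float(reference_probability(mix, ref_distance))
        total += log_p - np.log(p_ref)
    return total


def gen_affinity_dataset(n_complexes: int = 60, seed: int = 0,
                         class_mixtures: dict | None = None,
                         n_res_per_atom: int = 4, noise: float = 0.0,
                         start_index: int = 0):
    """Training samples with labels from a planted linear rule.

    pkd* = sum_pairs w(aa, element) * exp(-d / 2) + 0.4 * dG_gas->water
           + 0.25 * dG_oct->water + 4.0, plus optional Gaussian noise.
    The planted coefficients depend only on ``seed``; ``start_index`` selects
    disjoint complex sets under the same rule (held-out splits).  Returns
    (samples, truth) where truth records the planted coefficients.
    """
    from .interaction_core import LigandExtras
    from .training import TrainingSample

    rng = np.random.default_rng(seed)
    if class_mixtures is None:
        class_mixtures = make_class_mixtures(seed=seed)
    keys = sorted(class_mixtures)
    w = {k: rng.uniform(1.0, 4.0) for k in keys}
    c_gw, c_wo, bias = 0.4, 0.25, 4.0

    samples = []
    for offset in range(n_complexes):
        idx = start_index + offset
        cx_rng = np.random.default_rng(seed * 7919 + idx)
        cx = gen_mixture_complex(class_mixtures, n_res_per_atom, seed=seed * 7919 + idx,
                                 pose_id=f"aff-{seed}-{idx}")
        extras = LigandExtras(
            mmff_rmsd=float(cx_rng.uniform(0.0, 2.0)),
            dG_gas_to_water=float(cx_rng.uniform(-8.0, 0.0)),
            dG_oct_to_water=float(cx_rng.uniform(-3.0, 3.0)),
        )
        pairs = enumerate_pairs(cx, cutoff=9.0)
        label = bias + c_gw * extras.dG_gas_to_water + c_wo * extras.dG_oct_to_water
        for i, j, d in pairs.pl_pairs:
            key = (cx.residues[i].aa_code, cx.ligand_atoms[j].element)
            label += w[key] * np.exp(-d / 2.0)
        label += noise * cx_rng.standard_normal()
        samples.append(TrainingSample(complex=cx, extras=extras, pkd=float(label)))
    truth = {"weights": w, "c_gw": c_gw, "c_wo": c_wo, "bias": bias}
    return samples, truth


# ---------------------------------------------------------------------------
# standard-format writers (fixtures exercise the real parsers)
# ---------------------------------------------------------------------------

def write_pdb(path, residues: list[Residue], metals: list[MetalIon] = ()):
    """Write residues/metals as a minimal standard PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_atoms = sum(len(r.heavy_atom_coords) for r in residues) + len(metals)
    arr = struc.AtomArray(n_atoms)
    names = ["CA", "CB", "CG", "CD", "CE", "CZ"]
    idx = 0
    for r in residues:
        for a, coord in enumerate(r.heavy_atom_coords):
            arr.chain_id[idx] = r.chain_id
            arr.res_id[idx] = r.seq_index
            arr.res_name[idx] = _ONE_TO_THREE[r.aa_code]
            arr.atom_name[idx] = names[a % len(names)]
            arr.element[idx] = "C"
            arr.hetero[idx] = False
            arr.coord[idx] = coord
            idx += 1
    for m in metals:
        arr.chain_id[idx] = "Z"
        arr.res_id[idx] = 900 + m.ion_index
        arr.res_name[idx] = m.element.upper()
        arr.atom_name[idx] = m.element.upper()
        arr.element[idx] = m.element.upper()
        arr.hetero[idx] = True
        arr.coord[idx] = m.coord
        idx += 1
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_sdf(path, poses: list[list[LigandAtom]], title: str = "pose"):
    """Write ligand poses (no bonds needed) as a multi-record V2000 SDF."""
    from rdkit import Chem
    from rdkit.Chem import AllChem  # noqa: F401  (registers conformer tooling)
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for p, atoms in enumerate(poses):
        mol = Chem.RWMol()
        for a in atoms:
            mol.AddAtom(Chem.Atom(a.element))
        conf = Chem.Conformer(len(atoms))
        for a in atoms:
            conf.SetAtomPosition(a.atom_index, Point3D(*map(float, a.coord)))
        conf.Set3D(True)
        m = mol.GetMol()
        m.AddConformer(conf)
        m.SetProp("_Name", f"{title}-{p}")
        writer.write(m)
    writer.close()
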