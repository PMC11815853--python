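"""Pairwise interaction module predicting experimental binding affinity (pKd).

Each residue-atom pair within 9 A contributes a scalar computed from the
two embeddings and an RBF expansion of the minimum distance, gated by a
Hadamard product of three branch vectors; metal-atom pairs contribute
analogously (without the ligand-strain RMSD feature).  The predicted pKd is
the sum of all pair contributions plus a linear solvation correction whose
coefficients are read out from the same pair hidden states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, concatenate
from .complex_model import ComplexGraph, PairSet, enumerate_pairs
from .encoders import EmbeddingSet

__all__ = [
    "RBFSpec", "RBFLayer", "LigandExtras", "AffinityPrediction", "InteractionModule",
    "smooth_cutoff", "rbf_expand", "pkd_loss", "screen_loss", "predict_pkd",
    "compute_mmff_rmsd", "load_extras_table",
]


def smooth_cutoff(d, d_star: float = 10.0):
    """Quintic smooth cutoff: phi(0)=1, phi(d)=0 for d >= d*, C1 at both ends.

    phi(d) = 1 - 6x^5 + 15x^4 - 10x^3 with x = d/d*.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    x = np.clip(d / d_star, 0.0, 1.0)
    return 1.0 - 6.0 * x**5 + 15.0 * x**4 - 10.0 * x**3


@dataclass
class RBFSpec:
    """Static description of the radial basis: 64 Gaussians on e^{-d}.

    Centers are initialized equally spaced between e^{-10} and 1; widths to
    a constant making adjacent basis functions overlap at half maximum; the
    smooth cutoff distance d* defaults to 10 A.
    """

    n_basis: int = 64
    d_star: float = 10.0

    def initial_centers(self) -> np.ndarray:
        return np.linspace(np.exp(-10.0), 1.0, self.n_basis)

    def initial_beta(self) -> float:
        spacing = (1.0 - np.exp(-10.0)) / (self.n_basis - 1)
        return float(np.log(2.0) / (spacing / 2.0) ** 2)


class RBFLayer(nn.Module):
    """Learnable radial basis expansion g_k(d) = exp(-beta_k (e^{-d}-mu_k)^2) phi(d)."""

    def __init__(self, spec: RBFSpec = RBFSpec(), trainable: bool = True):
        super().__init__()
        self.spec = spec
        self.centers = Tensor(spec.initial_centers(), requires_grad=trainable)
        # beta kept positive through softplus (softplus ~ identity at this scale)
        self.beta_raw = Tensor(np.full(spec.n_basis, spec.initial_beta()), requires_grad=trainable)

    def expand(self, d) -> Tensor:
        d = np.atleast_1d(np.asarray(d, dtype=float))
        phi = smooth_cutoff(d, self.spec.d_star)
        x = Tensor(np.exp(-d)[:, None])
        diff = x - self.centers
        beta = self.beta_raw.softplus()
        return (-(beta * diff * diff)).exp() * Tensor(phi[:, None])


def rbf_expand(d, layer: RBFLayer | None = None, spec: RBFSpec | None = None) -> np.ndarray:
    """Numpy-facing RBF expansion; builds a fresh layer at init if none given."""
    if layer is None:
        layer = RBFLayer(spec or RBFSpec(), trainable=False)
    return layer.expand(d).data


@dataclass
class LigandExtras:
    """Per-ligand auxiliary features for affinity prediction.

    ``mmff_rmsd`` is the heavy-atom RMSD (A) between the bound pose and its
    MMFF94-optimized geometry (conformational strain proxy); the two transfer
    free energies (kcal/mol) represent the ligand's solvation energetics.
    """

    mmff_rmsd: float = 0.0
    dG_gas_to_water: float = 0.0
    dG_oct_to_water: float = 0.0

    def __post_init__(self):
        if self.mmff_rmsd < 0:
            raise ValueError("mmff_rmsd must be non-negative")


@dataclass
class AffinityPrediction:
    pose_id: str
    pkd: float
    pl_sum: float
    ml_sum: float
    alpha_gw: float
    alpha_wo: float
    solvation_correction: float
    pl_contributions: np.ndarray
    ml_contributions: np.ndarray


class InteractionModule(nn.Module):
    """Pairwise affinity head.

    Branch widths are 128; concatenating the gated hidden state with the
    64-entry RBF expansion of the MMFF-RMSD feature gives the 192-wide input
    of the protein-ligand readout.  Metal-ligand pairs use a 128-wide readout
    (no RMSD branch) and carry no solvation coefficients.
    """

    def __init__(self, d_prot: int, d_lig: int, d_metal: int = 64,
                 hidden_dim: int = 128, rbf_spec: RBFSpec = RBFSpec(),
                 seed: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(seed)
        self.hidden_dim = hidden_dim
        self.rbf_dist = RBFLayer(rbf_spec)
        self.rbf_rmsd = RBFLayer(rbf_spec)
        self.rbf_ml = RBFLayer(rbf_spec)
        self.prot_lin = nn.Linear(d_prot, hidden_dim, rng)
        self.lig_lin = nn.Linear(d_lig, hidden_dim, rng)
        self.dist_lin = nn.Linear(rbf_spec.n_basis, hidden_dim, rng)
        self.metal_lin = nn.Linear(d_metal, hidden_dim, rng)
        self.ml_lig_lin = nn.Linear(d_lig, hidden_dim, rng)
        self.ml_dist_lin = nn.Linear(rbf_spec.n_basis, hidden_dim, rng)
        self.pl_readout = nn.Linear(hidden_dim + rbf_spec.n_basis, 1, rng)
        self.ml_readout = nn.Linear(hidden_dim, 1, rng)
        self.alpha_gw_readout = nn.Linear(hidden_dim, 1, rng)
        self.alpha_wo_readout = nn.Linear(hidden_dim, 1, rng)

    # -- building blocks ------------------------------------------------------
    def gated_pair_hidden(self, h_prot: Tensor, h_lig: Tensor, d: np.ndarray) -> Tensor:
        """Hadamard product of the SSP+linear embedding branches and the RBF branch."""
        a = self.prot_lin(nn.ssp(h_prot))
        b = self.lig_lin(nn.ssp(h_lig))
        c = self.dist_lin(self.rbf_dist.expand(d))
        return a * b * c

    def gated_ml_hidden(self, h_metal: Tensor, h_lig: Tensor, d: np.ndarray) -> Tensor:
        a = self.metal_lin(nn.ssp(h_metal))
        b = self.ml_lig_lin(nn.ssp(h_lig))
        c = self.ml_dist_lin(self.rbf_ml.expand(d))
        return a * b * c

    def pl_contribution(self, hidden: Tensor, mmff_rmsd: float):
        """Per-pair PL contribution plus pairwise solvation coefficients.

        The readout input is the 128-dim hidden state concatenated with the
        64-entry RBF expansion of the RMSD feature (192 total).
        """
        n = hidden.shape[0]
        rmsd_feat = self.rbf_rmsd.expand(np.full(n, float(mmff_rmsd)))
        cat = concatenate([hidden, rmsd_feat], axis=1)
        pl = self.pl_readout(cat).reshape(-1)
        a_gw = self.alpha_gw_readout(hidden).reshape(-1)
        a_wo = self.alpha_wo_readout(hidden).reshape(-1)
        return pl, a_gw, a_wo

    def ml_contribution(self, hidden: Tensor) -> Tensor:
        """Metal-ligand contribution: 128-dim readout, no RMSD concatenation."""
        return self.ml_readout(hidden).reshape(-1)

    # -- full forward ---------------------------------------------------------
    def forward_tensors(self, h_res: Tensor, h_lig: Tensor, h_met: Tensor | None,
                        pairs: PairSet, extras: LigandExtras):
        """Differentiable pKd prediction from embedding tensors and a PairSet."""
        zero = Tensor(np.zeros(1))
        if pairs.pl_pairs:
            ia = np.array([p[0] for p in pairs.pl_pairs])
            jb = np.array([p[1] for p in pairs.pl_pairs])
            d = np.array([p[2] for p in pairs.pl_pairs])
            hidden = self.gated_pair_hidden(h_res[ia], h_lig[jb], d)
            pl_vec, a_gw_vec, a_wo_vec = self.pl_contribution(hidden, extras.mmff_rmsd)
            pl_sum = pl_vec.sum()
            alpha_gw = a_gw_vec.mean()
            alpha_wo = a_wo_vec.mean()
        else:
            warnings.warn("no protein-ligand pairs within cutoff; "
                          "solvation coefficients set to 0", stacklevel=2)
            pl_vec = a_gw_vec = a_wo_vec = zero
            pl_sum = alpha_gw = alpha_wo = Tensor(0.0)
        if pairs.ml_pairs and h_met is not None:
            ka = np.array([p[0] for p in pairs.ml_pairs])
            jb = np.array([p[1] for p in pairs.ml_pairs])
            d = np.array([p[2] for p in pairs.ml_pairs])
            ml_vec = self.ml_contribution(self.gated_ml_hidden(h_met[ka], h_lig[jb], d))
            ml_sum = ml_vec.sum()
        else:
            ml_vec = zero
            ml_sum = Tensor(0.0)
        solv = alpha_gw * extras.dG_gas_to_water + alpha_wo * extras.dG_oct_to_water
        pkd = pl_sum + ml_sum + solv
        return pkd, dict(pl_vec=pl_vec, ml_vec=ml_vec, pl_sum=pl_sum, ml_sum=ml_sum,
                         alpha_gw=alpha_gw, alpha_wo=alpha_wo, solv=solv)


def predict_pkd(complex: ComplexGraph, embeddings: EmbeddingSet, extras: LigandExtras,
                module: InteractionModule, cutoff: float = 9.0,
                include_hydrogens: bool = True,
                pairs: PairSet | None = None) -> AffinityPrediction:
    """Eval-mode pKd prediction.

    pkd = sum PL_ij + sum ML_kj + alpha_gw * dG_gas->water + alpha_wo * dG_oct->water,
    with the alphas averaged over the protein-ligand pairs within the cutoff.
    """
    embeddings.validate(complex)
    if pairs is None:
        pairs = enumerate_pairs(complex, cutoff=cutoff, include_hydrogens=include_hydrogens)
    was_training = module.training
    module.eval()
    h_res = Tensor(embeddings.residue_emb)
    h_lig = Tensor(embeddings.ligand_emb)
    h_met = Tensor(embeddings.metal_emb) if len(complex.metals) else None
    pkd, parts = module.forward_tensors(h_res, h_lig, h_met, pairs, extras)
    if was_training:
        module.train()
    return AffinityPrediction(
        pose_id=complex.pose_id,
        pkd=float(pkd.data),
        pl_sum=float(parts["pl_sum"].data),
        ml_sum=float(parts["ml_sum"].data),
        alpha_gw=float(parts["alpha_gw"].data),
        alpha_wo=float(parts["alpha_wo"].data),
        solvation_correction=float(parts["solv"].data),
        pl_contributions=np.atleast_1d(parts["pl_vec"].data).copy(),
        ml_contributions=np.atleast_1d(parts["ml_vec"].data).copy(),
    )


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def pkd_loss(pred, label) -> float:
    """Mean absolute error between predicted and experimental pKd."""
    pred = np.atleast_1d(np.asarray(pred, dtype=float))
    label = np.atleast_1d(np.asarray(label, dtype=float))
    return float(np.mean(np.abs(pred - label)))


def screen_loss(pred, label, is_binder) -> float:
    """Affinity loss with a weak-binder hinge.

    Binders keep the MAE term.  Weak-binders are only penalised when the
    prediction exceeds the experimental value by more than 1.0 log-units:
    max(pred - label - 1.0, 0).
    """
    pred = np.atleast_1d(np.asarray(pred, dtype=float))
    label = np.atleast_1d(np.asarray(label, dtype=float))
    is_binder = np.atleast_1d(np.asarray(is_binder, dtype=bool))
    terms = np.where(is_binder, np.abs(pred - label),
                     np.maximum(pred - label - 1.0, 0.0))
    return float(np.mean(terms))


# ---------------------------------------------------------------------------
# ligand extras utilities
# ---------------------------------------------------------------------------

def compute_mmff_rmsd(mol) -> float:
    """Heavy-atom best-fit RMSD between a pose and its MMFF94-optimized geometry."""
    from rdkit import Chem
    from rdkit.Chem import AllChem, rdMolAlign

    probe = Chem.Mol(mol)
    Chem.SanitizeMol(probe)
    AllChem.MMFFOptimizeMolecule(probe)
    ref = Chem.RemoveHs(Chem.Mol(mol))
    prb = Chem.RemoveHs(probe)
    return float(rdMolAlign.GetBestRMS(prb, ref))


def load_extras_table(path) -> dict[str, LigandExtras]:
    """Read a ligand extras CSV: ligand_id, mmff_rmsd, dG_gas_to_water, dG_oct_to_water."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"ligand_id", "mmff_rmsd", "dG_gas_to_water", "dG_oct_to_water"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"extras table missing columns {sorted(missing)}")
    return {
        str(row.ligand_id): LigandExtras(float(row.mmff_rmsd),
                                         float(row.dG_gas_to_water),
                                         float(row.dG_oct_to_water))
        for row in df.itertuples()
    }
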