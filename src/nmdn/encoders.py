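"""Residue, ligand-atom and metal embeddings behind a uniform provider contract.

Pretrained encoders (protein language models, molecular message-passing
networks) are *not* bundled: their output is consumed from a keyed array
archive.  A deterministic baseline featurizer — learnable lookup tables plus
a rigid-motion-invariant geometric refinement for ligand atoms — lets the
full stack train and test without any pretrained weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .complex_model import AA_LETTERS, SCORING_ELEMENTS, ComplexGraph
from . import nn

__all__ = [
    "EmbeddingSet", "BaselineFeaturizer", "embed_with_baseline",
    "load_precomputed_embeddings", "ProviderInfo", "register_provider",
    "finetune_flags",
]

_METAL_ELEMENTS = ("Zn", "Mg", "Ca", "Mn", "Fe", "Ni", "Cu", "Co", "K", "Na")


@dataclass
class EmbeddingSet:
    """Embeddings for one complex; row counts must match the entity counts."""

    residue_emb: np.ndarray   # (N_prot, D_prot)
    ligand_emb: np.ndarray    # (N_lig, D_lig)
    metal_emb: np.ndarray     # (N_metal, D_metal)
    provider_id: str = "unknown"

    def validate(self, complex: ComplexGraph) -> "EmbeddingSet":
        n_prot, n_lig, n_met = len(complex.residues), len(complex.ligand_atoms), len(complex.metals)
        if self.residue_emb.shape[0] != n_prot:
            raise ValueError(f"residue embedding rows {self.residue_emb.shape[0]} != {n_prot} residues")
        if self.ligand_emb.shape[0] != n_lig:
            raise ValueError(f"ligand embedding rows {self.ligand_emb.shape[0]} != {n_lig} atoms")
        if self.metal_emb.shape[0] != n_met:
            raise ValueError(f"metal embedding rows {self.metal_emb.shape[0]} != {n_met} metals")
        for name, arr in [("residue", self.residue_emb), ("ligand", self.ligand_emb),
                          ("metal", self.metal_emb)]:
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name} embedding")
        return self


class BaselineFeaturizer(nn.Module):
    """Deterministic stand-in encoder.

    Residue embeddings are a lookup over the one-letter amino-acid alphabet
    (frozen by default, mirroring a pretrained language model that is not
    fine-tuned); ligand-atom embeddings are an element lookup refined by a
    learnable linear map over invariant local geometry (distances to the
    other ligand atoms), and metal embeddings are an element lookup.  Both
    atom-level tables are trainable by default, standing in for encoders
    that are fine-tuned with the rest of the model.
    """

    provider_id = "baseline"

    def __init__(self, dims: tuple[int, int, int] = (64, 64, 64), seed: int = 0,
                 trainable_residue: bool = False, trainable_ligand: bool = True,
                 trainable_metal: bool = True):
        super().__init__()
        d_prot, d_lig, d_metal = dims
        if min(dims) <= 0:
            raise ValueError("embedding dims must be positive")
        self.dims = tuple(dims)
        rng = np.random.default_rng(seed)
        self.aa_table = Tensor(rng.standard_normal((len(AA_LETTERS), d_prot)),
                               requires_grad=trainable_residue)
        self.element_table = Tensor(rng.standard_normal((len(SCORING_ELEMENTS), d_lig)),
                                    requires_grad=trainable_ligand)
        self.geom_weight = Tensor(0.05 * rng.standard_normal((3, d_lig)),
                                  requires_grad=trainable_ligand)
        self.metal_table = Tensor(rng.standard_normal((len(_METAL_ELEMENTS), d_metal)),
                                  requires_grad=trainable_metal)
        self._aa_index = {a: i for i, a in enumerate(AA_LETTERS)}
        self._elem_index = {e: i for i, e in enumerate(SCORING_ELEMENTS)}
        self._metal_index = {m: i for i, m in enumerate(_METAL_ELEMENTS)}

    # geometry features: rigid-invariant, permutation-consistent per atom
    @staticmethod
    def _geometry_features(coords: np.ndarray) -> np.ndarray:
        n = coords.shape[0]
        if n == 1:
            return np.zeros((1, 3))
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        centroid = coords.mean(axis=0)
        d_cen = np.linalg.norm(coords - centroid, axis=1)
        finite = np.where(np.isfinite(dist), dist, 0.0)
        mean_d = finite.sum(1) / (n - 1)
        min_d = dist.min(axis=1)
        return np.column_stack([mean_d, min_d, d_cen])

    # -- tensor-valued forward (used during training so gradients flow) ------
    def residue_rows(self, complex: ComplexGraph) -> Tensor:
        idx = [self._aa_index[r.aa_code] for r in complex.residues]
        return self.aa_table[np.array(idx)]

    def ligand_rows(self, complex: ComplexGraph) -> Tensor:
        idx = []
        for a in complex.ligand_atoms:
            if a.element not in self._elem_index:
                raise ValueError(f"unknown ligand element {a.element!r}")
            idx.append(self._elem_index[a.element])
        geom = self._geometry_features(complex.ligand_coords)
        return self.element_table[np.array(idx)] + Tensor(geom) @ self.geom_weight

    def metal_rows(self, complex: ComplexGraph) -> Tensor:
        if not complex.metals:
            return Tensor(np.zeros((0, self.dims[2])))
        idx = []
        for m in complex.metals:
            if m.element not in self._metal_index:
                raise ValueError(f"unknown metal element {m.element!r}")
            idx.append(self._metal_index[m.element])
        return self.metal_table[np.array(idx)]

    def __call__(self, complex: ComplexGraph) -> EmbeddingSet:
        return EmbeddingSet(
            residue_emb=self.residue_rows(complex).data,
            ligand_emb=self.ligand_rows(complex).data,
            metal_emb=self.metal_rows(complex).data,
            provider_id=self.provider_id,
        ).validate(complex)


def embed_with_baseline(complex: ComplexGraph, dims: tuple[int, int, int] = (64, 64, 64),
                        seed: int = 0) -> EmbeddingSet:
    """One-shot baseline embedding (fresh featurizer, deterministic in seed)."""
    return BaselineFeaturizer(dims=dims, seed=seed)(complex)


def load_precomputed_embeddings(archive, complex: ComplexGraph,
                                provider_id: str = "precomputed") -> EmbeddingSet:
    """Load embeddings from a keyed array archive (NPZ or HDF5).

    Expected keys: ``protein/<protein_id>``, ``ligand/<ligand_id>`` and,
    when metals are present, ``metal/<protein_id>``.  Arrays are validated
    for row count against the complex; any embedding width is accepted.
    """
    path = str(archive)

    def _lookup(store, key):
        if key not in store:
            raise KeyError(f"archive missing key {key!r}")
        return np.asarray(store[key], dtype=float)

    if path.endswith(".npz"):
        with np.load(path) as store:
            return _build_embedding_set(dict(store), complex, provider_id, _lookup)
    import h5py

    with h5py.File(path, "r") as store:
        return _build_embedding_set(store, complex, provider_id,
                                    lambda s, k: _h5_lookup(s, k))


def _h5_lookup(store, key):
    if key not in store:
        raise KeyError(f"archive missing key {key!r}")
    return np.asarray(store[key][()], dtype=float)


def _build_embedding_set(store, complex, provider_id, lookup):
    residue = lookup(store, f"protein/{complex.protein_id}")
    ligand = lookup(store, f"ligand/{complex.ligand_id}")
    if complex.metals:
        metal = lookup(store, f"metal/{complex.protein_id}")
    else:
        metal = np.zeros((0, 1))
    return EmbeddingSet(residue, ligand, metal, provider_id).validate(complex)


# ---------------------------------------------------------------------------
# provider registry and fine-tuning defaults
# ---------------------------------------------------------------------------

@dataclass
class ProviderInfo:
    """Fine-tuning contract of an embedding provider.

    The residue encoder defaults to frozen (protein language models are used
    as fixed feature extractors); ligand and metal encoders default to
    trainable (fine-tuned jointly with the scoring heads).
    """

    name: str
    residue_trainable: bool = False
    ligand_trainable: bool = True
    metal_trainable: bool = True
    extra: dict = field(default_factory=dict)


_REGISTRY: dict[str, ProviderInfo] = {}


def register_provider(info: ProviderInfo) -> ProviderInfo:
    _REGISTRY[info.name] = info
    return info


register_provider(ProviderInfo("baseline"))
register_provider(ProviderInfo("precomputed", ligand_trainable=False, metal_trainable=False))


def finetune_flags(provider: str) -> ProviderInfo:
    """Return the trainability flags for a registered provider."""
    if provider not in _REGISTRY:
        raise KeyError(f"provider {provider!r} not registered")
    return _REGISTRY[provider]
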