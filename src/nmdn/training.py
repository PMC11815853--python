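"""Joint training of the distance-likelihood heads and the affinity head.

The combined objective is ``w_nmdn * (L_PL + L_ML) + w_pkd * L_pkd`` where the
distance terms are summed negative log densities over all pairs within the
training cutoff and the affinity term is the batch MAE (or, in screening
fine-tune mode, the weak-binder hinge objective).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concatenate
from .complex_model import ComplexGraph, PairSet, enumerate_pairs
from .encoders import EmbeddingSet
from .interaction_core import LigandExtras
from .nmdn_core import mdn_nll_tensor

__all__ = ["TrainConfig", "TrainingSample", "LossReport", "combined_loss", "fit",
           "finite_difference_grad", "gradient_check"]

_MODES = ("joint", "screen_finetune")


@dataclass
class TrainConfig:
    """Training hyperparameters.

    The training cutoff (pairs entering the distance loss) and the test
    cutoff / reference distance (pairs entering the score at inference) are
    independent; by default all are 9 A and the reference distance equals
    the test cutoff.
    """

    train_cutoff: float = 9.0
    test_cutoff: float = 9.0
    ref_distance: float | None = None
    lr: float = 1e-4
    batch_size: int = 16
    epochs: int = 30
    seed: int = 0
    w_nmdn: float = 1.0
    w_pkd: float = 1.0
    mode: str = "joint"
    include_hydrogens: bool = True

    def __post_init__(self):
        if self.train_cutoff <= 0 or self.test_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.ref_distance is None:
            self.ref_distance = self.test_cutoff


@dataclass
class TrainingSample:
    """One training record: a pose plus labels and optional fixed embeddings."""

    complex: ComplexGraph
    extras: LigandExtras = field(default_factory=LigandExtras)
    pkd: float | None = None
    is_binder: bool = True
    embeddings: EmbeddingSet | None = None
    _pair_cache: dict = field(default_factory=dict, repr=False)

    def pairs(self, cutoff: float, include_hydrogens: bool = True) -> PairSet:
        key = (round(cutoff, 6), include_hydrogens)
        if key not in self._pair_cache:
            self._pair_cache[key] = enumerate_pairs(
                self.complex, cutoff=cutoff, include_hydrogens=include_hydrogens)
        return self._pair_cache[key]


@dataclass
class LossReport:
    total: float
    nmdn_pl: float
    nmdn_ml: float
    pkd_term: float
    n_pl_pairs: int
    n_ml_pairs: int
    n_labelled: int


def _sample_embedding_tensors(model, sample: TrainingSample):
    """Embedding rows as Tensors; gradients flow into the featurizer tables
    when the sample has no fixed embeddings."""
    if sample.embeddings is not None:
        emb = sample.embeddings.validate(sample.complex)
        h_met = Tensor(emb.metal_emb) if len(sample.complex.metals) else None
        return Tensor(emb.residue_emb), Tensor(emb.ligand_emb), h_met
    f = model.featurizer_
    h_met = f.metal_rows(sample.complex) if sample.complex.metals else None
    return f.residue_rows(sample.complex), f.ligand_rows(sample.complex), h_met


def combined_loss(model, batch: list[TrainingSample], config: TrainConfig):
    """Differentiable combined loss over a batch.

    Returns ``(total, report)`` where ``total`` is an autodiff scalar and the
    report carries the components (which sum exactly to the total under the
    configured weights).
    """
    pl_inputs, pl_dists = [], []
    ml_inputs, ml_dists = [], []
    pkd_terms: list[Tensor] = []

    for sample in batch:
        h_res, h_lig, h_met = _sample_embedding_tensors(model, sample)
        pairs = sample.pairs(config.train_cutoff, config.include_hydrogens)
        if pairs.pl_pairs:
            ia = np.array([p[0] for p in pairs.pl_pairs])
            jb = np.array([p[1] for p in pairs.pl_pairs])
            pl_inputs.append(concatenate([h_res[ia], h_lig[jb]], axis=1))
            pl_dists.append(np.array([p[2] for p in pairs.pl_pairs]))
        if pairs.ml_pairs and h_met is not None:
            ka = np.array([p[0] for p in pairs.ml_pairs])
            jb = np.array([p[1] for p in pairs.ml_pairs])
            ml_inputs.append(concatenate([h_met[ka], h_lig[jb]], axis=1))
            ml_dists.append(np.array([p[2] for p in pairs.ml_pairs]))
        if sample.pkd is not None and config.w_pkd != 0.0:
            test_pairs = sample.pairs(config.test_cutoff, config.include_hydrogens)
            pred, _ = model.interaction_.forward_tensors(
                h_res, h_lig, h_met, test_pairs, sample.extras)
            err = pred - sample.pkd
            if config.mode == "screen_finetune" and not sample.is_binder:
                pkd_terms.append((err - 1.0).relu())   # hinge: max(pred-label-1, 0)
            else:
                pkd_terms.append(err.abs())

    zero = Tensor(0.0)
    if pl_inputs and config.w_nmdn != 0.0:
        loss_pl = mdn_nll_tensor(model.pl_head_, concatenate(pl_inputs, axis=0),
                                 np.concatenate(pl_dists))
    else:
        loss_pl = zero
    if ml_inputs and config.w_nmdn != 0.0 and model.ml_head_ is not None:
        loss_ml = mdn_nll_tensor(model.ml_head_, concatenate(ml_inputs, axis=0),
                                 np.concatenate(ml_dists))
    else:
        loss_ml = zero
    if pkd_terms:
        stacked = pkd_terms[0].reshape(1)
        for t in pkd_terms[1:]:
            stacked = concatenate([stacked, t.reshape(1)], axis=0)
        loss_pkd = stacked.mean()
    else:
        loss_pkd = zero

    total = config.w_nmdn * (loss_pl + loss_ml) + config.w_pkd * loss_pkd
    report = LossReport(
        total=float(total.data),
        nmdn_pl=float(loss_pl.data),
        nmdn_ml=float(loss_ml.data),
        pkd_term=float(loss_pkd.data),
        n_pl_pairs=sum(len(d) for d in pl_dists),
        n_ml_pairs=sum(len(d) for d in ml_dists),
        n_labelled=len(pkd_terms),
    )
    return total, report


def fit(dataset: list[TrainingSample], config: TrainConfig, model=None):
    """Train a model on `dataset`; returns the fitted estimator.

    Deterministic given the seed (single-threaded numpy).  Aborts with a
    diagnostic if the loss diverges to NaN.
    """
    from .estimators import NMDNModel

    if model is None:
        model = NMDNModel(
            train_cutoff=config.train_cutoff, test_cutoff=config.test_cutoff,
            ref_distance=config.ref_distance, lr=config.lr,
            batch_size=config.batch_size, epochs=config.epochs,
            w_nmdn=config.w_nmdn, w_pkd=config.w_pkd, mode=config.mode,
            include_hydrogens=config.include_hydrogens, seed=config.seed,
        )
    return model.fit(dataset)


def finite_difference_grad(loss_fn, param: Tensor, indices, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of ``loss_fn()`` w.r.t. selected
    entries of ``param`` (the independent oracle for the autodiff check)."""
    grads = np.zeros(len(indices))
    flat = param.data.ravel()
    for n, idx in enumerate(indices):
        orig = flat[idx]
        flat[idx] = orig + eps
        hi = loss_fn()
        flat[idx] = orig - eps
        lo = loss_fn()
        flat[idx] = orig
        grads[n] = (hi - lo) / (2 * eps)
    return grads


def gradient_check(model, batch: list[TrainingSample], config: TrainConfig,
                   n_directions: int = 10, eps: float = 1e-5, atol: float = 1e-8,
                   seed: int = 0) -> float:
    """Worst relative disagreement between the autodiff gradient and central
    finite differences of :func:`combined_loss`.

    The comparison is directional: for random unit directions ``v`` over the
    full parameter vector, the projected gradient ``v . g`` is checked
    against ``(L(theta + eps v) - L(theta - eps v)) / (2 eps)``.  Any error
    in any parameter's gradient projects onto a random direction almost
    surely, while the quotient stays well-conditioned (per-entry checks of
    near-zero gradient directions — e.g. biases ahead of batch norm — only
    measure floating-point noise).
    """
    for comp in model._components().values():
        comp.train()
    total, _ = combined_loss(model, batch, config)
    for comp in model._components().values():
        comp.zero_grad()
    total.backward()
    params = [p for p in model._trainable_parameters() if p.grad is not None]

    def loss_value():
        t, _ = combined_loss(model, batch, config)
        return float(t.data)

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_directions):
        vs = [rng.standard_normal(p.data.shape) for p in params]
        norm = np.sqrt(sum(float((v**2).sum()) for v in vs))
        vs = [v / norm for v in vs]
        projected = sum(float((v * p.grad).sum()) for v, p in zip(vs, params))
        originals = [p.data.copy() for p in params]
        for p, v in zip(params, vs):
            p.data = p.data + eps * v
        hi = loss_value()
        for p, o, v in zip(params, originals, vs):
            p.data = o - eps * v
        lo = loss_value()
        for p, o in zip(params, originals):
            p.data = o
        fd = (hi - lo) / (2 * eps)
        rel = abs(fd - projected) / max(abs(fd), abs(projected), atol)
        worst = max(worst, rel)
    return worst


def save_checkpoint(model, path):
    """Single-file archive: component state arrays plus a JSON config blob."""
    state = model._checkpoint_state()
    arrays = state["arrays"]
    meta = json.dumps(state["meta"])
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    from .estimators import NMDNModel

    path = str(path)
    if not path.endswith(".npz"):
        path = path + ".npz"
    with np.load(path) as store:
        meta = json.loads(bytes(store["__meta__"]).decode())
        arrays = {k: store[k] for k in store.files if k != "__meta__"}
    return NMDNModel._from_checkpoint(meta, arrays)
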