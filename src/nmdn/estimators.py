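"""Scikit-learn style estimator bundling the scoring heads.

``NMDNModel`` owns the baseline featurizer, the two distance-likelihood
heads (protein-ligand and metal-ligand) and the pairwise affinity head,
and trains them jointly with Adam on the combined objective.  After
``fit``, ``score_samples`` returns aggregated pose scores and ``predict``
returns pKd estimates; both run the heads in eval mode (deterministic).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .complex_model import ComplexGraph
from .encoders import BaselineFeaturizer, EmbeddingSet
from .interaction_core import (AffinityPrediction, InteractionModule, LigandExtras,
                               RBFSpec, predict_pkd)
from .nmdn_core import NMDNHead, ScoreBreakdown, nmdn_score

__all__ = ["NMDNModel"]


def _as_sample(x, pkd=None):
    from .training import TrainingSample

    if isinstance(x, TrainingSample):
        return x
    if isinstance(x, ComplexGraph):
        return TrainingSample(complex=x, pkd=pkd)
    raise TypeError(f"expected TrainingSample or ComplexGraph, got {type(x)!r}")


class NMDNModel(BaseEstimator):
    """Distance-likelihood pose scorer with a pairwise affinity head.

    Parameters mirror the architecture: embedding dims of the baseline
    featurizer, MLP width/depth and mixture size of the density heads, the
    RBF basis of the affinity head, and the training/test cutoffs.  The
    full-size head width is 4096; the default here is sized for desk-scale
    synthetic data.
    """

    def __init__(self, dims=(64, 64, 64), hidden_dim=64, n_layers=5,
                 n_components=10, dropout=0.1, sigma_min=0.01,
                 interaction_hidden=128, n_basis=64, d_star=10.0,
                 train_cutoff=9.0, test_cutoff=9.0, ref_distance=None,
                 include_hydrogens=True, use_ml_head=True,
                 w_nmdn=1.0, w_pkd=1.0, lr=1e-3, epochs=30, batch_size=16,
                 mode="joint", seed=0):
        self.dims = dims
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.n_components = n_components
        self.dropout = dropout
        self.sigma_min = sigma_min
        self.interaction_hidden = interaction_hidden
        self.n_basis = n_basis
        self.d_star = d_star
        self.train_cutoff = train_cutoff
        self.test_cutoff = test_cutoff
        self.ref_distance = ref_distance
        self.include_hydrogens = include_hydrogens
        self.use_ml_head = use_ml_head
        self.w_nmdn = w_nmdn
        self.w_pkd = w_pkd
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.mode = mode
        self.seed = seed

    # -- construction ---------------------------------------------------------
    def _build(self):
        d_prot, d_lig, d_metal = self.dims
        ss = np.random.SeedSequence(self.seed)
        s_feat, s_pl, s_ml, s_int, s_loop = [int(c.generate_state(1)[0] % (2**31))
                                             for c in ss.spawn(5)]
        self.featurizer_ = BaselineFeaturizer(dims=self.dims, seed=s_feat)
        self.pl_head_ = NMDNHead(d_prot + d_lig, hidden_dim=self.hidden_dim,
                                 n_layers=self.n_layers, n_components=self.n_components,
                                 dropout=self.dropout, sigma_min=self.sigma_min, seed=s_pl)
        self.ml_head_ = (NMDNHead(d_metal + d_lig, hidden_dim=self.hidden_dim,
                                  n_layers=self.n_layers, n_components=self.n_components,
                                  dropout=self.dropout, sigma_min=self.sigma_min, seed=s_ml)
                         if self.use_ml_head else None)
        self.interaction_ = InteractionModule(
            d_prot, d_lig, d_metal, hidden_dim=self.interaction_hidden,
            rbf_spec=RBFSpec(n_basis=self.n_basis, d_star=self.d_star), seed=s_int)
        self._loop_seed = s_loop

    def _is_built(self) -> bool:
        return hasattr(self, "featurizer_")

    def _components(self):
        comps = {"featurizer": self.featurizer_, "pl_head": self.pl_head_,
                 "interaction": self.interaction_}
        if self.ml_head_ is not None:
            comps["ml_head"] = self.ml_head_
        return comps

    def _trainable_parameters(self):
        if self.mode == "screen_finetune":
            # fine-tune the affinity head only; density heads stay frozen
            return self.interaction_.parameters()
        params = (self.featurizer_.parameters() + self.pl_head_.parameters()
                  + self.interaction_.parameters())
        if self.ml_head_ is not None:
            params += self.ml_head_.parameters()
        return params

    # -- training -------------------------------------------------------------
    def fit(self, X, y=None):
        """Train on a list of TrainingSample (or bare ComplexGraph with labels in y)."""
        from .training import TrainConfig, combined_loss

        if y is None:
            samples = [_as_sample(x) for x in X]
        else:
            samples = [_as_sample(x, pkd=float(t)) for x, t in zip(X, y)]
        if not samples:
            raise ValueError("empty training set")
        if not self._is_built():
            self._build()
        config = TrainConfig(
            train_cutoff=self.train_cutoff, test_cutoff=self.test_cutoff,
            ref_distance=self.ref_distance, lr=self.lr, batch_size=self.batch_size,
            epochs=self.epochs, seed=self.seed, w_nmdn=self.w_nmdn,
            w_pkd=self.w_pkd, mode=self.mode,
            include_hydrogens=self.include_hydrogens)
        self.config_ = config

        for m in self._components().values():
            m.train()
        opt = nn.Adam(self._trainable_parameters(), lr=self.lr)
        rng = np.random.default_rng(self._loop_seed)
        self.loss_history_ = []
        n = len(samples)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                batch = [samples[i] for i in order[start:start + self.batch_size]]
                total, report = combined_loss(self, batch, config)
                if not np.isfinite(report.total):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: loss={report.total} "
                        f"(components pl={report.nmdn_pl}, ml={report.nmdn_ml}, "
                        f"pkd={report.pkd_term})")
                opt.zero_grad()
                total.backward()
                opt.step()
                epoch_losses.append(report.total)
            self.loss_history_.append(float(np.mean(epoch_losses)))
        for m in self._components().values():
            m.eval()
        self.n_samples_fit_ = n
        return self

    # -- inference ------------------------------------------------------------
    def _embeddings_for(self, sample) -> EmbeddingSet:
        if sample.embeddings is not None:
            return sample.embeddings
        return self.featurizer_(sample.complex)

    def breakdown(self, x) -> ScoreBreakdown:
        """Full per-pair score breakdown for one pose."""
        sample = _as_sample(x)
        return nmdn_score(
            sample.complex, self._embeddings_for(sample), self.pl_head_,
            ml_head=self.ml_head_, cutoff=self.test_cutoff,
            ref_distance=self.ref_distance, include_hydrogens=self.include_hydrogens)

    def score_samples(self, X) -> np.ndarray:
        """Aggregated NMDN score per pose (higher = more native-like)."""
        return np.array([self.breakdown(x).nmdn_score for x in X])

    def predict_affinity(self, x) -> AffinityPrediction:
        sample = _as_sample(x)
        return predict_pkd(
            sample.complex, self._embeddings_for(sample), sample.extras,
            self.interaction_, cutoff=self.test_cutoff,
            include_hydrogens=self.include_hydrogens)

    def predict(self, X) -> np.ndarray:
        """Predicted pKd per pose."""
        return np.array([self.predict_affinity(x).pkd for x in X])

    # -- persistence ----------------------------------------------------------
    def _checkpoint_state(self):
        arrays = {}
        for name, comp in self._components().items():
            for k, v in comp.state_dict().items():
                arrays[f"{name}.{k}"] = v
        meta = {"params": self.get_params(), "loop_seed": self._loop_seed}
        return {"arrays": arrays, "meta": meta}

    def save(self, path):
        from .training import save_checkpoint

        save_checkpoint(self, path)

    @classmethod
    def _from_checkpoint(cls, meta, arrays):
        model = cls(**{k: (tuple(v) if k == "dims" else v)
                       for k, v in meta["params"].items()})
        model._build()
        model._loop_seed = meta["loop_seed"]
        for name, comp in model._components().items():
            prefix = name + "."
            comp.load_state_dict({k[len(prefix):]: v for k, v in arrays.items()
                                  if k.startswith(prefix)})
            comp.eval()
        return model

    @classmethod
    def load(cls, path) -> "NMDNModel":
        from .training import load_checkpoint

        return load_checkpoint(path)
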