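import numpy as np
import pytest

from nmdn.autodiff import Tensor
from nmdn.complex_model import enumerate_pairs
from nmdn.encoders import embed_with_baseline
from nmdn.interaction_core import (InteractionModule, LigandExtras, RBFLayer,
                                   RBFSpec, load_extras_table, pkd_loss,
                                   predict_pkd, rbf_expand, screen_loss,
                                   smooth_cutoff)
from nmdn.nn import ssp
from nmdn.synthetic_fixtures import gen_complex

from conftest import random_rotation


class TestSmoothCutoff:
    def test_boundary_values(self):
        assert smooth_cutoff(0.0) == pytest.approx(1.0)
        assert smooth_cutoff(10.0) == pytest.approx(0.0)
        assert smooth_cutoff(15.0) == pytest.approx(0.0)

    def test_midpoint(self):
        # 1 - 6/32 + 15/16 - 10/8 = 0.5
        assert smooth_cutoff(5.0, 10.0) == pytest.approx(0.5)

    def test_monotone_and_smooth(self):
        d = np.linspace(0, 12, 500)
        phi = smooth_cutoff(d)
        assert np.all(np.diff(phi) <= 1e-12)
        # C1 at both ends: numerical derivative vanishes
        eps = 1e-5
        assert (smooth_cutoff(eps) - smooth_cutoff(0.0)) / eps == pytest.approx(0, abs=1e-3)
        assert (smooth_cutoff(10.0) - smooth_cutoff(10.0 - eps)) / eps == pytest.approx(0, abs=1e-3)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            smooth_cutoff(-1.0)


class TestRBF:
    def test_length_and_range(self):
        vec = rbf_expand(3.0)
        assert vec.shape == (1, 64)
        assert np.all(vec >= 0) and np.all(vec <= 1)

    def test_zero_beyond_cutoff(self):
        assert np.all(rbf_expand(10.0) == 0.0)
        assert np.all(rbf_expand(12.5) == 0.0)

    def test_peak_location(self):
        # at d = -ln(mu_k), the k-th Gaussian sits at its center: entry = phi(d)
        layer = RBFLayer(RBFSpec(n_basis=8), trainable=False)
        layer.beta_raw.data[:] = 1e6  # very narrow
        mu = layer.centers.data
        for k in (2, 5):
            d = -np.log(mu[k])
            vec = layer.expand(d).data[0]
            assert vec[k] == pytest.approx(smooth_cutoff(d), rel=1e-9)
            mask = np.ones(8, bool)
            mask[k] = False
            assert vec[mask].max() < 1e-6

    def test_center_initialization(self):
        spec = RBFSpec()
        c = spec.initial_centers()
        assert c[0] == pytest.approx(np.exp(-10.0)) and c[-1] == pytest.approx(1.0)
        assert len(c) == 64


def make_module(d_prot=8, d_lig=8, d_metal=8, seed=0):
    return InteractionModule(d_prot, d_lig, d_metal, seed=seed).eval()


class TestPairContributions:
    def test_ssp_zero(self):
        assert float(ssp(Tensor(0.0)).data) == pytest.approx(0.0, abs=1e-15)

    def test_zero_distance_branch_annihilates(self, rng):
        mod = make_module()
        mod.dist_lin.weight.data[:] = 0.0
        mod.dist_lin.bias.data[:] = 0.0
        h = mod.gated_pair_hidden(Tensor(rng.standard_normal((4, 8))),
                                  Tensor(rng.standard_normal((4, 8))),
                                  np.full(4, 3.0))
        assert np.all(h.data == 0.0)

    def test_gated_hidden_composition_oracle(self, rng):
        mod = make_module(seed=3)
        hp = rng.standard_normal((5, 8))
        hl = rng.standard_normal((5, 8))
        d = rng.uniform(1, 8, 5)
        out = mod.gated_pair_hidden(Tensor(hp), Tensor(hl), d).data

        def branch(x, lin):
            act = np.logaddexp(0, x) - np.log(2)
            return act @ lin.weight.data + lin.bias.data

        a = branch(hp, mod.prot_lin)
        b = branch(hl, mod.lig_lin)
        c = mod.rbf_dist.expand(d).data @ mod.dist_lin.weight.data + mod.dist_lin.bias.data
        np.testing.assert_allclose(out, a * b * c, atol=1e-10)

    def test_pl_readout_dimensions_and_oracle(self, rng):
        mod = make_module(seed=1)
        assert mod.pl_readout.weight.shape == (192, 1)   # 128 hidden + 64 RMSD RBF
        assert mod.ml_readout.weight.shape == (128, 1)   # no RMSD concatenation
        hidden = Tensor(rng.standard_normal((3, 128)))
        pl, a_gw, a_wo = mod.pl_contribution(hidden, mmff_rmsd=0.8)
        rmsd_feat = mod.rbf_rmsd.expand(np.full(3, 0.8)).data
        cat = np.concatenate([hidden.data, rmsd_feat], axis=1)
        np.testing.assert_allclose(
            pl.data, (cat @ mod.pl_readout.weight.data + mod.pl_readout.bias.data).ravel(),
            atol=1e-12)
        ml = mod.ml_contribution(hidden)
        np.testing.assert_allclose(
            ml.data,
            (hidden.data @ mod.ml_readout.weight.data + mod.ml_readout.bias.data).ravel(),
            atol=1e-12)

    def test_zero_readout_zero_contribution(self, rng):
        mod = make_module()
        for lin in (mod.pl_readout, mod.ml_readout):
            lin.weight.data[:] = 0.0
            lin.bias.data[:] = 0.0
        hidden = Tensor(rng.standard_normal((3, 128)))
        pl, *_ = mod.pl_contribution(hidden, 0.0)
        assert np.all(pl.data == 0.0)
        assert np.all(mod.ml_contribution(hidden).data == 0.0)


class TestPredictPkd:
    def _setup(self, seed=0, n_metals=1):
        cx = gen_complex(6, 5, n_metals=n_metals, seed=seed)
        emb = embed_with_baseline(cx, dims=(8, 8, 8), seed=0)
        mod = make_module(seed=seed)
        extras = LigandExtras(mmff_rmsd=0.7, dG_gas_to_water=-4.0, dG_oct_to_water=1.5)
        return cx, emb, mod, extras

    def test_zero_params_zero_pkd(self):
        cx, emb, mod, extras = self._setup()
        for lin in (mod.pl_readout, mod.ml_readout, mod.alpha_gw_readout,
                    mod.alpha_wo_readout):
            lin.weight.data[:] = 0.0
            lin.bias.data[:] = 0.0
        pred = predict_pkd(cx, emb, extras, mod)
        assert pred.pkd == pytest.approx(0.0, abs=1e-12)

    def test_decomposition_oracle(self):
        """pkd recomposes exactly from per-pair readouts computed independently."""
        cx, emb, mod, extras = self._setup(seed=2)
        pred = predict_pkd(cx, emb, extras, mod)
        pairs = enumerate_pairs(cx, 9.0)
        pl_vals, gw_vals, wo_vals = [], [], []
        for i, j, d in pairs.pl_pairs:
            hidden = mod.gated_pair_hidden(Tensor(emb.residue_emb[[i]]),
                                           Tensor(emb.ligand_emb[[j]]), np.array([d]))
            pl, a_gw, a_wo = mod.pl_contribution(hidden, extras.mmff_rmsd)
            pl_vals.append(pl.data[0])
            gw_vals.append(a_gw.data[0])
            wo_vals.append(a_wo.data[0])
        ml_vals = []
        for k, j, d in pairs.ml_pairs:
            hidden = mod.gated_ml_hidden(Tensor(emb.metal_emb[[k]]),
                                         Tensor(emb.ligand_emb[[j]]), np.array([d]))
            ml_vals.append(mod.ml_contribution(hidden).data[0])
        expected = (np.sum(pl_vals) + np.sum(ml_vals)
                    + np.mean(gw_vals) * extras.dG_gas_to_water
                    + np.mean(wo_vals) * extras.dG_oct_to_water)
        assert pred.pkd == pytest.approx(expected, abs=1e-8)
        assert pred.alpha_gw == pytest.approx(np.mean(gw_vals), abs=1e-10)
        assert pred.pkd == pytest.approx(pred.pl_sum + pred.ml_sum
                                         + pred.solvation_correction, abs=1e-10)

    def test_single_contribution_shift(self):
        """Adding delta to one PL contribution shifts the total by exactly delta."""
        cx, emb, mod, extras = self._setup(seed=4)
        pred = predict_pkd(cx, emb, extras, mod)
        delta = 0.37
        shifted = pred.pl_contributions.copy()
        shifted[0] += delta
        recomposed = (shifted.sum() + pred.ml_contributions.sum()
                      + pred.solvation_correction)
        assert recomposed == pytest.approx(pred.pkd + delta, abs=1e-10)

    def test_no_pl_pairs_warns_zero_alpha(self):
        cx, emb, mod, extras = self._setup(seed=1, n_metals=0)
        for r in cx.residues:
            r.heavy_atom_coords = r.heavy_atom_coords + 300.0
        with pytest.warns(UserWarning, match="solvation"):
            pred = predict_pkd(cx, emb, extras, mod)
        assert pred.alpha_gw == 0.0 and pred.alpha_wo == 0.0

    def test_rigid_and_permutation_invariance(self, rng):
        cx, emb, mod, extras = self._setup(seed=6)
        base = predict_pkd(cx, emb, extras, mod).pkd
        moved = cx.transformed(random_rotation(rng), rng.uniform(-10, 10, 3))
        emb_m = embed_with_baseline(moved, dims=(8, 8, 8), seed=0)
        assert predict_pkd(moved, emb_m, extras, mod).pkd == pytest.approx(base, abs=1e-8)

        from nmdn.complex_model import ComplexGraph, LigandAtom

        perm = rng.permutation(len(cx.ligand_atoms))
        permuted = ComplexGraph(
            residues=cx.residues,
            ligand_atoms=[LigandAtom(cx.ligand_atoms[p].element,
                                     cx.ligand_atoms[p].coord, n)
                          for n, p in enumerate(perm)],
            metals=cx.metals, pose_id="perm")
        emb_p = embed_with_baseline(permuted, dims=(8, 8, 8), seed=0)
        assert predict_pkd(permuted, emb_p, extras, mod).pkd == pytest.approx(base, abs=1e-8)


class TestLosses:
    def test_pkd_loss_cases(self):
        assert pkd_loss(7.2, 7.2) == 0.0
        assert pkd_loss(6.0, 7.5) == pytest.approx(1.5)
        rng = np.random.default_rng(0)
        p, t = rng.normal(size=20), rng.normal(size=20)
        assert pkd_loss(p, t) == pytest.approx(np.mean(np.abs(p - t)), abs=1e-12)

    def test_screen_loss_cases(self):
        assert screen_loss(6.5, 5.0, False) == pytest.approx(0.5)
        assert screen_loss(5.9, 5.0, False) == 0.0   # inside the +1.0 allowance
        assert screen_loss(6.0, 7.0, True) == pytest.approx(1.0)

    def test_hinge_zero_iff_within_allowance(self):
        preds, labels = np.meshgrid(np.linspace(2, 10, 33), np.linspace(2, 10, 33))
        for p, t in zip(preds.ravel(), labels.ravel()):
            loss = screen_loss(p, t, False)
            assert loss >= 0.0
            if p <= t + 1.0:
                assert loss == 0.0
            else:
                assert loss == pytest.approx(p - t - 1.0)


class TestExtras:
    def test_table_roundtrip(self, tmp_path):
        path = tmp_path / "extras.csv"
        path.write_text("ligand_id,mmff_rmsd,dG_gas_to_water,dG_oct_to_water\n"
                        "lig1,0.5,-4.2,1.1\n")
        table = load_extras_table(path)
        assert table["lig1"].dG_gas_to_water == pytest.approx(-4.2)
        with pytest.raises(ValueError):
            LigandExtras(mmff_rmsd=-0.1)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("ligand_id,mmff_rmsd\nlig1,0.5\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_extras_table(path)

    def test_mmff_rmsd_computation(self):
        from rdkit import Chem
        from rdkit.Chem import AllChem

        from nmdn.interaction_core import compute_mmff_rmsd

        mol = Chem.AddHs(Chem.MolFromSmiles("CCCO"))
        AllChem.EmbedMolecule(mol, randomSeed=3)
        rmsd = compute_mmff_rmsd(mol)
        assert np.isfinite(rmsd) and rmsd >= 0.0


class TestPlantedAffinityRecovery:
    def test_validation_mae_below_threshold(self):
        """Training on a planted pairwise+solvation rule generalises to
        held-out complexes with MAE < 0.2 log-units."""
        from nmdn.estimators import NMDNModel
        from nmdn.synthetic_fixtures import gen_affinity_dataset

        train, _ = gen_affinity_dataset(n_complexes=240, seed=11)
        val, _ = gen_affinity_dataset(n_complexes=30, seed=11, start_index=240)
        model = NMDNModel(dims=(16, 16, 16), hidden_dim=32, n_layers=3,
                          n_components=2, dropout=0.0, w_nmdn=0.0, w_pkd=1.0,
                          lr=2e-3, epochs=150, batch_size=20, seed=3)
        model.fit(train)
        pred = model.predict(val)
        mae = np.mean(np.abs(pred - np.array([s.pkd for s in val])))
        assert mae < 0.2
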