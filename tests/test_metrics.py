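import numpy as np
import pandas as pd
import pytest

from nmdn.screening_metrics import (combined_selection, docking_success,
                                    enrichment_factor, ligand_rmsd,
                                    ranking_powers, select_top_pose)
from nmdn.synthetic_fixtures import gen_screen_library


def library_with_top_hits(n=1000, n_active=20, hits_in_top=4, n_top=10):
    """Deterministic library: exactly `hits_in_top` actives in the first n_top."""
    is_active = np.zeros(n, dtype=bool)
    is_active[:hits_in_top] = True
    is_active[n_top:n_top + (n_active - hits_in_top)] = True
    return pd.DataFrame({
        "ligand_id": [f"l{i}" for i in range(n)],
        "score": np.linspace(100, 1, n),
        "is_active": is_active,
    })


class TestEnrichmentFactor:
    def test_worked_toy(self):
        table = library_with_top_hits()
        assert enrichment_factor(table, 0.01) == pytest.approx(20.0, abs=1e-12)

    def test_all_actives_first_reaches_bound(self):
        n, n_active = 100, 5
        table = pd.DataFrame({
            "ligand_id": [f"l{i}" for i in range(n)],
            "score": np.linspace(10, 1, n),
            "is_active": [i < n_active for i in range(n)],
        })
        ef = enrichment_factor(table, 0.05)
        # brute force: top 5 all active -> (5/5)/(5/100) = 20 = 1/fraction
        assert ef == pytest.approx(1 / 0.05)

    def test_random_scores_mean_near_one(self):
        efs = [enrichment_factor(gen_screen_library(400, 0.05, 0.0, seed=s), 0.05)
               for s in range(300)]
        mean, se = np.mean(efs), np.std(efs, ddof=1) / np.sqrt(len(efs))
        assert abs(mean - 1.0) <= 3 * se + 1e-9

    def test_fpr_mode(self):
        table = library_with_top_hits()
        ef_fpr = enrichment_factor(table, 0.01, mode="fpr")
        # 9 inactives allowed (0.01*980=9.8): walking down, the 4 actives come
        # first, then 16 more actives appear after rank 10
        assert ef_fpr > 0
        with pytest.raises(ValueError):
            enrichment_factor(table, 1.5)

    def test_zero_actives_undefined(self):
        table = gen_screen_library(50, 0.0, 0.0, seed=1)
        with pytest.raises(ValueError, match="zero actives"):
            enrichment_factor(table, 0.1)

    def test_row_order_invariance(self, rng):
        table = library_with_top_hits()
        shuffled = table.sample(frac=1.0, random_state=4).reset_index(drop=True)
        assert enrichment_factor(shuffled, 0.01) == enrichment_factor(table, 0.01)


class TestDockingSuccess:
    def test_single_pose_systems(self):
        table = pd.DataFrame({
            "system_id": ["s1", "s2", "s3"],
            "pose_id": ["p", "p", "p"],
            "score": [1.0, 1.0, 1.0],
            "rmsd": [1.0, 2.5, 0.8],
        })
        report = docking_success(table, threshold=2.0, top_k=1)
        assert report.success_rate == pytest.approx(2 / 3)
        assert report.median_top1_rmsd == pytest.approx(1.0)

    def test_top_k_rescues_second_pose(self):
        table = pd.DataFrame({
            "system_id": ["s"] * 5,
            "pose_id": [f"p{i}" for i in range(5)],
            "score": [9, 8, 7, 6, 5],
            "rmsd": [3.1, 1.2, 4.0, 5.0, 6.0],
        })
        assert docking_success(table, top_k=1).success_rate == 0.0
        assert docking_success(table, top_k=5).success_rate == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_recompute(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(5):
            for p in range(6):
                rows.append((f"s{s}", f"p{p}", rng.normal(), rng.uniform(0.3, 6)))
        table = pd.DataFrame(rows, columns=["system_id", "pose_id", "score", "rmsd"])
        report = docking_success(table, threshold=2.0, top_k=2)
        wins = 0
        for s in range(5):
            sub = table[table.system_id == f"s{s}"]
            top2 = sub.sort_values("score", ascending=False).head(2)
            wins += int((top2.rmsd <= 2.0).any())
        assert report.success_rate == pytest.approx(wins / 5)


class TestRankingPowers:
    def test_perfectly_monotone(self):
        table = pd.DataFrame({
            "target": ["t"] * 10,
            "pred": np.arange(10, dtype=float),
            "label": np.arange(10, dtype=float) ** 3,
        })
        report = ranking_powers(table)
        assert report.mean_spearman == pytest.approx(1.0)

    def test_weighted_average_exact(self):
        # target a: perfect ranking (rho=1, n=10); target b: inverted (rho=-1, n=30)
        a = pd.DataFrame({"target": "a", "pred": np.arange(10.0),
                          "label": np.arange(10.0)})
        b = pd.DataFrame({"target": "b", "pred": np.arange(30.0),
                          "label": -np.arange(30.0)})
        report = ranking_powers(pd.concat([a, b], ignore_index=True))
        assert report.weighted_spearman == pytest.approx((10 * 1 + 30 * -1) / 40)
        assert report.mean_spearman == pytest.approx(0.0, abs=1e-12)

    def test_spearman_equals_rank_pearson_oracle(self, rng):
        from scipy import stats

        pred = rng.normal(size=40)
        label = pred + rng.normal(size=40)
        table = pd.DataFrame({"target": "t", "pred": pred, "label": label})
        report = ranking_powers(table)
        oracle = stats.pearsonr(stats.rankdata(pred), stats.rankdata(label)).statistic
        assert report.per_target.spearman.iloc[0] == pytest.approx(oracle, abs=1e-12)


class TestSelectTopPose:
    def test_highest_wins_and_ties(self):
        assert select_top_pose([("b", 1.0), ("a", 3.0), ("c", 2.0)]) == "a"
        assert select_top_pose([("b", 3.0), ("a", 3.0)]) == "a"

    def test_permutation_invariance(self, rng):
        poses = [(f"p{i}", float(s)) for i, s in enumerate(rng.normal(size=20))]
        ref = select_top_pose(poses)
        for _ in range(5):
            perm = [poses[i] for i in rng.permutation(20)]
            assert select_top_pose(perm) == ref


class TestCombinedSelection:
    def _table(self, n, nmdn, pkd):
        return pd.DataFrame({"ligand_id": [f"l{i}" for i in range(n)],
                             "nmdn": nmdn, "pkd": pkd})

    def test_disjoint_top_sets_no_augmentation(self):
        n = 400
        nmdn = np.zeros(n)
        pkd = np.zeros(n)
        nmdn[[0, 1]] = [10, 9]
        pkd[[2, 3]] = [10, 9]
        selected = combined_selection(self._table(n, nmdn, pkd))
        assert sorted(selected) == ["l0", "l1", "l2", "l3"]

    def test_identical_top_sets_augment_alternately(self):
        n = 400
        nmdn = np.linspace(1, 0, n)   # ranking l0, l1, l2, ...
        pkd = np.linspace(1, 0, n)    # identical ranking
        selected = combined_selection(self._table(n, nmdn, pkd))
        # union of top-2 sets is {l0, l1}; augmentation steps through the
        # stated algorithm: next from nmdn (l2), then next from pkd (l3)
        assert selected == ["l0", "l1", "l2", "l3"]

    @pytest.mark.parametrize("seed", range(6))
    def test_size_always_ceil_of_total_fraction(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(250, 1200))
        table = self._table(n, rng.normal(size=n), rng.normal(size=n))
        selected = combined_selection(table)
        assert len(selected) == len(set(selected)) == int(np.ceil(0.01 * n))

    def test_small_library_minimum_one_per_score(self):
        n = 100   # 0.5% of 100 < 1 -> minimum of 1 ligand per score enforced
        nmdn = np.zeros(n)
        pkd = np.zeros(n)
        nmdn[5] = 1.0
        pkd[7] = 1.0
        selected = combined_selection(self._table(n, nmdn, pkd))
        # each score contributes its single best ligand even though
        # ceil(0.01 * 100) = 1
        assert sorted(selected) == ["l5", "l7"]


class TestLigandRMSD:
    @staticmethod
    def _benzene():
        from rdkit import Chem
        from rdkit.Chem import AllChem

        mol = Chem.MolFromSmiles("c1ccccc1")
        AllChem.EmbedMolecule(mol, randomSeed=11)
        return mol

    def test_identical_poses(self):
        mol = self._benzene()
        assert ligand_rmsd(mol, mol) == pytest.approx(0.0, abs=1e-12)
        assert ligand_rmsd(mol, mol, symmetry_aware=True) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_translation(self):
        from rdkit import Chem
        from rdkit.Geometry import Point3D

        mol = self._benzene()
        moved = Chem.Mol(mol)
        conf = moved.GetConformer()
        for i in range(moved.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, Point3D(p.x + 1.0, p.y, p.z))
        assert ligand_rmsd(mol, moved) == pytest.approx(1.0, abs=1e-9)

    def test_benzene_sixfold_rotation(self):
        """In-plane 60 deg rotation permutes equivalent atoms: RMSD 0 only
        when graph automorphisms are considered."""
        from rdkit import Chem
        from rdkit.Geometry import Point3D

        mol = self._benzene()
        conf = mol.GetConformer()
        coords = conf.GetPositions()
        center = coords.mean(axis=0)
        # rotate atom positions one step around the ring
        rotated = Chem.Mol(mol)
        rconf = rotated.GetConformer()
        n = mol.GetNumAtoms()
        for i in range(n):
            src = coords[(i + 1) % n]
            rconf.SetAtomPosition(i, Point3D(*src))
        plain = ligand_rmsd(mol, rotated)
        symm = ligand_rmsd(mol, rotated, symmetry_aware=True)
        assert plain > 0.5
        assert symm == pytest.approx(0.0, abs=1e-6)
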