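"""Pose-selection and virtual-screening evaluation metrics.

Tabular inputs are plain pandas DataFrames:

* screen tables — one row per ligand with columns ``ligand_id``, one or more
  score columns, and a boolean ``is_active`` (ligand_ids unique);
* pose tables — one row per scored pose with columns ``system_id``,
  ``pose_id``, ``score`` and ``rmsd`` (A to the reference pose, NaN allowed).

Ties in any ranking are broken by stable sort order (first occurrence wins),
with ``pose_id``/``ligand_id`` as the deterministic secondary key where one
exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "enrichment_factor", "docking_success", "DockingReport", "ranking_powers",
    "RankingReport", "select_top_pose", "combined_selection", "ligand_rmsd",
]


def _check_screen_table(table: pd.DataFrame, score_col: str):
    for col in ("ligand_id", score_col, "is_active"):
        if col not in table.columns:
            raise ValueError(f"screen table missing column {col!r}")
    if table["ligand_id"].duplicated().any():
        raise ValueError("ligand_ids must be unique")
    if int(table["is_active"].sum()) == 0:
        raise ValueError("enrichment factor undefined with zero actives")


def enrichment_factor(table: pd.DataFrame, fraction: float = 0.01,
                      mode: str = "top_fraction", score_col: str = "score") -> float:
    """Enrichment factor of actives among the top-scored ligands.

    ``top_fraction`` (default, matching top-x% reporting): the active
    concentration among the ``ceil(fraction * N)`` best-scored ligands
    relative to the library-wide active fraction.  ``fpr``: the true-positive
    rate at the score threshold where the false-positive rate equals
    ``fraction``, divided by ``fraction`` (enrichment over random picking).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if mode not in ("top_fraction", "fpr"):
        raise ValueError("mode must be 'top_fraction' or 'fpr'")
    _check_screen_table(table, score_col)

    ranked = table.sort_values(score_col, ascending=False, kind="mergesort")
    active = ranked["is_active"].to_numpy(dtype=bool)
    n = len(ranked)
    n_active = int(active.sum())

    if mode == "top_fraction":
        n_top = int(np.ceil(fraction * n))
        hits = int(active[:n_top].sum())
        return (hits / n_top) / (n_active / n)

    n_inactive = n - n_active
    if n_inactive == 0:
        raise ValueError("fpr mode needs at least one inactive")
    fp_budget = fraction * n_inactive
    fp = tp = 0
    for is_act in active:
        if is_act:
            tp += 1
        else:
            fp += 1
            if fp > fp_budget:
                break
    return (tp / n_active) / fraction


@dataclass
class DockingReport:
    success_rate: float
    median_top1_rmsd: float
    n_systems: int


def docking_success(table: pd.DataFrame, threshold: float = 2.0,
                    top_k: int = 1) -> DockingReport:
    """Fraction of systems with a pose within ``threshold`` A among the top-k
    scored poses; also reports the median RMSD of the top-1 pose."""
    for col in ("system_id", "pose_id", "score", "rmsd"):
        if col not in table.columns:
            raise ValueError(f"pose table missing column {col!r}")
    valid = table["rmsd"].dropna()
    if (valid < 0).any():
        raise ValueError("rmsd must be non-negative")

    successes, top1_rmsds = [], []
    for _, group in table.groupby("system_id", sort=True):
        ranked = group.sort_values(["score", "pose_id"], ascending=[False, True],
                                   kind="mergesort")
        top = ranked.head(top_k)
        successes.append(bool((top["rmsd"].dropna() <= threshold).any()))
        r1 = ranked.iloc[0]["rmsd"]
        if np.isfinite(r1):
            top1_rmsds.append(float(r1))
    return DockingReport(
        success_rate=float(np.mean(successes)),
        median_top1_rmsd=float(np.median(top1_rmsds)) if top1_rmsds else float("nan"),
        n_systems=len(successes),
    )


@dataclass
class RankingReport:
    per_target: pd.DataFrame        # target, n, pearson, spearman
    pearson: float                  # over the pooled predictions (scoring power)
    mean_spearman: float            # unweighted average across targets
    weighted_spearman: float        # weighted by ligand count per target


def ranking_powers(table: pd.DataFrame, pred_col: str = "pred",
                   label_col: str = "label", target_col: str = "target") -> RankingReport:
    """Scoring/ranking correlations, per target and averaged.

    The weighted average uses the number of ligands per target as weights.
    """
    rows = []
    for target, group in table.groupby(target_col, sort=True):
        n = len(group)
        pear = stats.pearsonr(group[pred_col], group[label_col]).statistic if n > 1 else np.nan
        spear = stats.spearmanr(group[pred_col], group[label_col]).statistic if n > 1 else np.nan
        rows.append((target, n, pear, spear))
    per_target = pd.DataFrame(rows, columns=["target", "n", "pearson", "spearman"])
    weights = per_target["n"].to_numpy(dtype=float)
    spear = per_target["spearman"].to_numpy(dtype=float)
    return RankingReport(
        per_target=per_target,
        pearson=float(stats.pearsonr(table[pred_col], table[label_col]).statistic),
        mean_spearman=float(np.nanmean(spear)),
        weighted_spearman=float(np.nansum(spear * weights) / weights[~np.isnan(spear)].sum()),
    )


def select_top_pose(poses) -> str:
    """Highest-scored pose id; ties resolved to the lexicographically first id.

    `poses` is an iterable of ``(pose_id, score)`` or a DataFrame with
    ``pose_id``/``score`` columns.  Input order never affects the result.
    """
    if isinstance(poses, pd.DataFrame):
        items = list(zip(poses["pose_id"], poses["score"]))
    else:
        items = list(poses)
    if not items:
        raise ValueError("no poses to select from")
    return min(items, key=lambda it: (-it[1], str(it[0])))[0]


def combined_selection(table: pd.DataFrame, score_cols: tuple[str, str] = ("nmdn", "pkd"),
                       total_fraction: float = 0.01,
                       per_score_fraction: float = 0.005) -> list:
    """Merge the per-score top fractions into a fixed-size selection.

    The top ``per_score_fraction`` of ligands under each score are united
    (at least one ligand per score); while the union is smaller than
    ``ceil(total_fraction * N)`` unique ligands, the next-ranked unselected
    ligand is appended from each score alternately, first score first.  The
    selection size equals ``ceil(total_fraction * N)`` except on very small
    libraries, where the one-ligand-per-score minimum can exceed it.
    """
    if table["ligand_id"].duplicated().any():
        raise ValueError("ligand_ids must be unique")
    for col in score_cols:
        if table[col].isna().any():
            raise ValueError(f"score column {col!r} has missing values")
    n = len(table)
    target_count = int(np.ceil(total_fraction * n))
    per_count = max(1, int(np.floor(per_score_fraction * n + 1e-9)))

    rankings = [
        list(table.sort_values([col, "ligand_id"], ascending=[False, True],
                               kind="mergesort")["ligand_id"])
        for col in score_cols
    ]
    selected: list = []
    chosen: set = set()
    for ranking in rankings:
        for lig in ranking[:per_count]:
            if lig not in chosen:
                chosen.add(lig)
                selected.append(lig)
    cursors = [per_count] * len(rankings)
    while len(selected) < target_count:
        for idx, ranking in enumerate(rankings):
            if len(selected) >= target_count:
                break
            while cursors[idx] < n and ranking[cursors[idx]] in chosen:
                cursors[idx] += 1
            if cursors[idx] < n:
                lig = ranking[cursors[idx]]
                chosen.add(lig)
                selected.append(lig)
                cursors[idx] += 1
    return selected


def ligand_rmsd(pose_a, pose_b, symmetry_aware: bool = False) -> float:
    """Heavy-atom RMSD between two poses of the same molecule, without
    superposition (docking convention: both poses share the protein frame).

    Accepts RDKit molecules with conformers; when ``symmetry_aware`` the
    RMSD is minimised over graph automorphisms.
    """
    from rdkit import Chem

    if symmetry_aware:
        from rdkit.Chem import rdMolAlign

        prb = Chem.RemoveHs(Chem.Mol(pose_a))
        ref = Chem.RemoveHs(Chem.Mol(pose_b))
        return float(rdMolAlign.CalcRMS(prb, ref))

    ca = _heavy_coords(pose_a)
    cb = _heavy_coords(pose_b)
    if ca.shape != cb.shape:
        raise ValueError("poses have different heavy-atom counts")
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def _heavy_coords(mol) -> np.ndarray:
    coords = mol.GetConformer().GetPositions()
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() != "H"]
    return coords[heavy]
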