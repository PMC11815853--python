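"""End-to-end pose scoring over externally generated pose files.

Pose generation itself (e.g. a diffusion docking model) is not wrapped:
the contract is one multi-record SDF of candidate poses per protein-ligand
pair, in arbitrary order.  The protocol scores every pose with the
distance-likelihood (NMDN) score, selects the top-1 pose, and computes the
pKd estimate on the selected pose.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .complex_model import ComplexGraph, load_ligand_poses, load_protein
from .interaction_core import LigandExtras
from .screening_metrics import select_top_pose

__all__ = ["ProtocolResult", "run_protocol", "run_protocol_batch", "default_config"]


def default_config() -> dict:
    """Template configuration: 10 sampled poses per pair, 9 A cutoffs."""
    return {
        "n_poses": 10,
        "cutoff": 9.0,
        "ref_distance": 9.0,
        "include_hydrogens": True,
    }


@dataclass
class ProtocolResult:
    pair_id: str
    selected_pose: str | None
    nmdn_score: float
    pkd: float
    failed: bool = False
    per_pose: pd.DataFrame | None = field(default=None, repr=False)
    seconds: float = 0.0


def run_protocol(protein_path, pose_file, model, extras: LigandExtras | None = None,
                 pair_id: str | None = None) -> ProtocolResult:
    """Score all poses of one pair, select the top pose, predict its pKd.

    Poses with unsupported elements are skipped; if every pose is rejected
    the pair is marked failed and the caller can continue with other pairs.
    """
    from .training import TrainingSample

    t0 = time.perf_counter()
    pair_id = pair_id or f"{protein_path}|{pose_file}"
    extras = extras or LigandExtras()
    residues, metals = load_protein(protein_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        atom_lists = load_ligand_poses(pose_file, on_unsupported="skip")
    if not atom_lists:
        return ProtocolResult(pair_id=pair_id, selected_pose=None,
                              nmdn_score=float("nan"), pkd=float("nan"),
                              failed=True, seconds=time.perf_counter() - t0)

    complexes = [
        ComplexGraph(residues=residues, ligand_atoms=atoms, metals=list(metals),
                     pose_id=f"{pair_id}-pose{p}")
        for p, atoms in enumerate(atom_lists)
    ]
    breakdowns = [model.breakdown(cx) for cx in complexes]
    per_pose = pd.DataFrame({
        "pose_id": [b.pose_id for b in breakdowns],
        "nmdn_pl_total": [b.nmdn_pl_total for b in breakdowns],
        "nmdn_ml_total": [b.nmdn_ml_total for b in breakdowns],
        "nmdn_score": [b.nmdn_score for b in breakdowns],
    })
    top_id = select_top_pose(per_pose.rename(columns={"nmdn_score": "score"}))
    top_cx = next(cx for cx in complexes if cx.pose_id == top_id)
    sample = TrainingSample(complex=top_cx, extras=extras)
    affinity = model.predict_affinity(sample)
    top_score = float(per_pose.loc[per_pose.pose_id == top_id, "nmdn_score"].iloc[0])
    return ProtocolResult(pair_id=pair_id, selected_pose=top_id,
                          nmdn_score=top_score, pkd=affinity.pkd,
                          per_pose=per_pose, seconds=time.perf_counter() - t0)


def run_protocol_batch(jobs: list[dict], model, log=print) -> pd.DataFrame:
    """Run the protocol over many pairs; failures do not stop the run.

    Each job is a dict with keys ``protein``, ``poses``, optional ``extras``
    (a LigandExtras) and ``pair_id``.
    """
    rows = []
    for job in jobs:
        res = run_protocol(job["protein"], job["poses"], model,
                           extras=job.get("extras"), pair_id=job.get("pair_id"))
        if log is not None:
            status = "FAILED" if res.failed else f"top={res.selected_pose}"
            log(f"[protocol] {res.pair_id}: {status} ({res.seconds:.2f}s)")
        rows.append({
            "pair_id": res.pair_id, "selected_pose": res.selected_pose,
            "nmdn_score": res.nmdn_score, "pkd": res.pkd, "failed": res.failed,
        })
    return pd.DataFrame(rows)
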