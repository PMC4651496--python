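"""Contact-frequency epitope profiling over a rigid-body docking ensemble.

Given an ensemble of antigen–antibody poses (e.g. 2000 independent rigid-body
docking solutions), an antigen residue is counted as contacting a pose when
at least one of its heavy atoms lies within a distance cutoff (5 Å by
default, inclusive) of any heavy atom of the antibody's complementarity-
determining region (CDR).  The per-residue frequency of that event across the
ensemble profiles the docking-predicted epitope; poses may optionally be
pre-filtered to the best-scoring fraction (lower docking score = better).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import StructureModel, read_all_models, read_structure

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Pose:
    """One rigid-body antigen-antibody pose with an optional docking score."""

    pose_id: str
    structure: StructureModel
    antigen_chain: str
    antibody_chain: str
    score: float | None = None

    def __post_init__(self) -> None:
        for chain_id in (self.antigen_chain, self.antibody_chain):
            if chain_id not in self.structure.chains or not self.structure.chains[chain_id]:
                raise ValueError(f"pose '{self.pose_id}' is missing chain '{chain_id}'")


@dataclass(frozen=True)
class CDRDefinition:
    """Antibody residue numbers constituting the CDR region."""

    residues: frozenset[int]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("CDR definition must be non-empty")

    @classmethod
    def from_ranges(cls, spec: str) -> "CDRDefinition":
        """Parse a range string like ``"26-35,50-58,95-102"`` (inclusive)."""
        residues: set[int] = set()
        for part in spec.split(","):
            part = part.strip()
            if "-" in part:
                lo, hi = part.split("-")
                residues.update(range(int(lo), int(hi) + 1))
            elif part:
                residues.add(int(part))
        return cls(residues=frozenset(residues))


@dataclass(frozen=True)
class ContactProfile:
    """Per-antigen-residue contact counts and frequencies over the kept poses."""

    data: pd.DataFrame  # columns: residue, count, frequency
    n_poses_used: int

    def __post_init__(self) -> None:
        freq = self.data["frequency"].to_numpy()
        count = self.data["count"].to_numpy()
        if np.any(count > self.n_poses_used) or np.any(freq < 0) or np.any(freq > 1):
            raise ValueError("inconsistent contact profile")

    def frequency_of(self, residue: int) -> float:
        row = self.data[self.data["residue"] == residue]
        return float(row["frequency"].iloc[0]) if len(row) else 0.0

    def epitope(self, threshold: float = 0.5, name: str = "docking_epitope"):
        from .nmr_csp import EpitopeSet

        residues = frozenset(
            int(r) for r, f in zip(self.data["residue"], self.data["frequency"])
            if f >= threshold
        )
        if not residues:
            return None
        return EpitopeSet(name=name, provenance="docking", residues=residues)


# ---------------------------------------------------------------------------
# Ensemble I/O
# ---------------------------------------------------------------------------

def read_score_table(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if not {"pose_id", "score"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns pose_id, score")
    return {str(r.pose_id): float(r.score) for r in df.itertuples()}


def write_score_table(scores: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        [{"pose_id": k, "score": f"{v:.6g}"} for k, v in sorted(scores.items())]
    ).to_csv(path, sep="\t", index=False)


def read_pose_ensemble(
    source: str | Path,
    antigen_chain: str,
    antibody_chain: str,
    score_table: str | Path | None = None,
) -> list[Pose]:
    """Load poses from a directory of two-chain PDBs or one multi-model PDB.

    Directory poses are ordered lexicographically by filename (pose_id =
    stem); multi-model poses by model index (pose_id = ``pose_<index>``,
    zero-padded, 1-based).  If a
    score table is given it must cover every pose (all-or-none contract);
    scores for unknown pose ids only raise a warning.
    """
    source = Path(source)
    entries: list[tuple[str, StructureModel]] = []
    if source.is_dir():
        for pdb_path in sorted(source.glob("*.pdb")):
            entries.append((pdb_path.stem, read_structure(pdb_path)))
    else:
        models = read_all_models(source)
        width = max(4, len(str(len(models))))
        entries = [(f"pose_{i + 1:0{width}d}", m) for i, m in enumerate(models)]
    if not entries:
        raise ValueError(f"no poses found in {source}")

    scores: dict[str, float] | None = None
    if score_table is not None:
        scores = read_score_table(score_table)
        pose_ids = {pid for pid, _ in entries}
        missing = sorted(pose_ids - set(scores))
        if missing:
            raise ValueError(
                f"score table covers only part of the ensemble; missing scores "
                f"for {missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
        for unknown in sorted(set(scores) - pose_ids):
            logger.warning("score for unknown pose '%s' ignored", unknown)

    return [
        Pose(
            pose_id=pid,
            structure=model,
            antigen_chain=antigen_chain,
            antibody_chain=antibody_chain,
            score=None if scores is None else scores[pid],
        )
        for pid, model in entries
    ]


# ---------------------------------------------------------------------------
# Contact computation
# ---------------------------------------------------------------------------

def contact_residues(
    pose: Pose, cdr: CDRDefinition, cutoff: float = 5.0
) -> set[int]:
    """Antigen residues with any heavy atom within ``cutoff`` Å (inclusive)
    of any CDR heavy atom.  Hydrogens are ignored on both sides."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ag_coords, ag_res = pose.structure.heavy_atom_arrays(pose.antigen_chain)
    ab_coords, _ = pose.structure.heavy_atom_arrays(
        pose.antibody_chain, residues=set(cdr.residues)
    )
    if len(ab_coords) == 0:
        raise ValueError(
            f"pose '{pose.pose_id}': no CDR residues present in antibody chain "
            f"'{pose.antibody_chain}'"
        )
    tree = cKDTree(ab_coords)
    hits = tree.query_ball_point(ag_coords, r=cutoff)
    return {int(res) for res, h in zip(ag_res, hits) if h}


def contact_frequency(
    ensemble: Sequence[Pose],
    cdr: CDRDefinition,
    cutoff: float = 5.0,
    score_top_fraction: float = 1.0,
) -> ContactProfile:
    """Per-residue contact frequency across the (optionally score-filtered) ensemble.

    With ``score_top_fraction`` < 1, only the best-scoring ceil(fraction * n)
    poses are counted (lower score = better; ties broken by pose id for
    determinism), which requires every pose to carry a score.
    """
    if not ensemble:
        raise ValueError("empty pose ensemble")
    if not 0 < score_top_fraction <= 1:
        raise ValueError("score_top_fraction must be in (0, 1]")
    poses = list(ensemble)
    if score_top_fraction < 1.0:
        if any(p.score is None for p in poses):
            raise ValueError("score filtering requested but poses carry no scores")
        keep = math.ceil(score_top_fraction * len(poses))
        poses = sorted(poses, key=lambda p: (p.score, p.pose_id))[:keep]

    all_residues: set[int] = set()
    for pose in poses:
        _, ag_res = pose.structure.heavy_atom_arrays(pose.antigen_chain)
        all_residues.update(int(r) for r in ag_res)
    counts = {res: 0 for res in sorted(all_residues)}
    for pose in sorted(poses, key=lambda p: p.pose_id):
        for res in contact_residues(pose, cdr, cutoff):
            counts[res] += 1
    n = len(poses)
    data = pd.DataFrame(
        {
            "residue": list(counts),
            "count": list(counts.values()),
            "frequency": [c / n for c in counts.values()],
        }
    )
    return ContactProfile(data=data, n_poses_used=n)


def write_contact_table(profile: ContactProfile, path: str | Path) -> None:
    """TSV report: ``residue  count  frequency`` (frequency to 6 significant digits)."""
    df = profile.data.copy()
    df["frequency"] = df["frequency"].map(lambda v: f"{v:.6g}")
    df.to_csv(path, sep="\t", index=False)
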