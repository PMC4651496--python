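"""Synthetic benchmark data with planted ground truth for every pipeline stage.

The generator emulates the four experimental inputs of the epitope-mapping
workflow on a parvalbumin-sized antigen — HSQC shift tables for a free and
antibody-titrated antigen, ¹⁵N relaxation decay series, a rigid-body docking
pose ensemble over a toy antigen, and a family multiple alignment — each with
a machine-readable manifest of the planted truth (epitope residues,
relaxation rates, per-pose contact sets, conserved columns), so that every
downstream operator can be scored for parameter recovery without any
external data.

All generators are pure functions of a :class:`SimulationConfig`: the same
seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .docking import CDRDefinition, Pose, write_score_table
from .nmr_csp import ShiftTable, TitrationPoint, write_shift_table
from .structure import Atom, Residue, StructureModel, write_multi_model, write_structure
from .conservation import MultipleAlignment, write_alignment

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

#: Default planted epitope (29 residues): the conformational epitope mapped on
#: the antigen (N-terminal residues 7, 8, 11, 12, 15; residues 29-33 and 36 on
#: the AB/CD axis; C-terminal residue 108) extended with residues in the
#: CD-loop-proximal region, around residue 80 and at the C-terminus so that
#: the region breakdown of a default run is 5 (N-terminus), 16 (CD-loop
#: proximal), 5 (around 80) and 3 (C-terminus).
DEFAULT_PLANTED_EPITOPE: frozenset[int] = frozenset(
    {7, 8, 11, 12, 15,
     29, 30, 31, 32, 33, 36, 40, 41, 44,          # AB/CD axis
     52, 54, 55, 57, 58, 60, 61,                  # CD site
     76, 78, 80, 82, 84,                          # around residue 80
     96, 102, 108}                                # C-terminus
)

# internal stream ids so the four generators draw independent randomness
_STREAM_SEQUENCE = 0
_STREAM_SHIFTS = 1
_STREAM_POSES = 2
_STREAM_ALIGNMENT = 3
_STREAM_DECAYS = 4


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults follow the experimental setup being emulated: a 109-residue
    antigen, a 2000-pose docking ensemble, titration points at 40 and 70 µM
    (antigen:antibody 2:1 and 1:1, bound fractions 0.5 and 1.0), a planted
    CSP effect of 0.05 ppm well above the 0.028 ppm significance threshold,
    and per-pose contact probabilities of 0.9 inside / 0.05 outside the
    planted epitope.
    """

    seed: int = 0
    n_residues: int = 109
    planted_epitope: frozenset[int] = DEFAULT_PLANTED_EPITOPE
    disappeared: frozenset[int] = frozenset()
    csp_effect: float = 0.05
    csp_noise_sigma: float = 0.002
    bound_fractions: tuple[float, ...] = (0.5, 1.0)
    concentrations_uM: tuple[float, ...] = (40.0, 70.0)
    molar_ratios: tuple[str, ...] = ("2:1", "1:1")
    n_poses: int = 2000
    p_contact_in: float = 0.9
    p_contact_out: float = 0.05
    n_sequences: int = 6
    substitution_rate: float = 0.2
    gap_rate: float = 0.02
    decay_noise_frac: float = 0.01

    def __post_init__(self) -> None:
        for p in (self.p_contact_in, self.p_contact_out,
                  self.substitution_rate, self.gap_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.csp_effect <= 3 * self.csp_noise_sigma:
            raise ValueError("csp_effect must exceed 3x csp_noise_sigma to be recoverable")
        bad = [r for r in self.planted_epitope | self.disappeared
               if not 1 <= r <= self.n_residues]
        if bad:
            raise ValueError(f"planted residues out of range: {sorted(bad)}")
        if self.n_sequences < 2:
            raise ValueError("need at least 2 sequences for an alignment")
        if not (len(self.bound_fractions) == len(self.concentrations_uM)
                == len(self.molar_ratios)):
            raise ValueError("titration descriptors must have equal length")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthManifest:
    """Planted ground truth written alongside every generated dataset."""

    planted_epitope: list[int] = field(default_factory=list)
    disappeared: list[int] = field(default_factory=list)
    expected_csp: dict[str, dict[int, float]] = field(default_factory=dict)
    relaxation_rates: dict[str, dict[int, dict[str, float]]] = field(default_factory=dict)
    conserved_columns: list[int] = field(default_factory=list)
    pose_contacts: dict[str, list[int]] = field(default_factory=dict)
    cdr_residues: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=str)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            raw = json.load(fh)
        raw["expected_csp"] = {
            k: {int(r): v for r, v in d.items()} for k, d in raw["expected_csp"].items()
        }
        raw["relaxation_rates"] = {
            k: {int(r): v for r, v in d.items()}
            for k, d in raw["relaxation_rates"].items()
        }
        return cls(**raw)


def antigen_sequence(config: SimulationConfig) -> str:
    """Deterministic random amino-acid sequence of the toy antigen."""
    rng = config.rng(_STREAM_SEQUENCE)
    return "".join(rng.choice(list(AA_ORDER), size=config.n_residues))


# ---------------------------------------------------------------------------
# HSQC shift tables
# ---------------------------------------------------------------------------

def simulate_shift_tables(
    config: SimulationConfig,
) -> tuple[ShiftTable, list[TitrationPoint], TruthManifest]:
    """Free and titration-point shift tables with a planted epitope.

    Free amide shifts are drawn uniformly from realistic ranges (δH 7.5-9.5,
    δN 105-130 ppm).  At each titration point the planted residues move by
    ``bound_fraction * csp_effect`` (split 60% into δH and, after the 0.1
    nitrogen weighting, 40% into δN — fast exchange between free and bound
    resonances), and iid Gaussian noise of ``csp_noise_sigma`` is added to
    every bound δH/δN.  Residues in ``config.disappeared`` are dropped from
    every bound table, emulating exchange-broadened peaks.
    """
    seq = antigen_sequence(config)
    rng = config.rng(_STREAM_SHIFTS)
    n = config.n_residues
    residues = np.arange(1, n + 1)
    dH = 7.5 + 2.0 * rng.random(n)
    dN = 105.0 + 25.0 * rng.random(n)
    free = ShiftTable(
        state_label="free",
        data=pd.DataFrame(
            {"residue": residues, "aa": list(seq), "dH": dH, "dN": dN}
        ),
    )

    manifest = TruthManifest(
        planted_epitope=sorted(config.planted_epitope),
        disappeared=sorted(config.disappeared),
    )
    planted = np.isin(residues, sorted(config.planted_epitope))
    points: list[TitrationPoint] = []
    for frac, conc, ratio in zip(
        config.bound_fractions, config.concentrations_uM, config.molar_ratios
    ):
        shift = frac * config.csp_effect
        dH_b = dH + np.where(planted, 0.6 * shift, 0.0)
        dN_b = dN + np.where(planted, 4.0 * shift, 0.0)  # 0.1-weighted: 0.4*shift
        dH_b = dH_b + rng.normal(0.0, config.csp_noise_sigma, n)
        dN_b = dN_b + rng.normal(0.0, config.csp_noise_sigma, n)
        keep = ~np.isin(residues, sorted(config.disappeared))
        label = f"bound_{conc:g}uM"
        table = ShiftTable(
            state_label=label,
            data=pd.DataFrame(
                {
                    "residue": residues[keep],
                    "aa": [seq[i] for i in np.flatnonzero(keep)],
                    "dH": dH_b[keep],
                    "dN": dN_b[keep],
                }
            ),
        )
        points.append(
            TitrationPoint(
                shift_table=table,
                molar_ratio_antigen_to_scfv=ratio,
                antigen_concentration_uM=conc,
            )
        )
        manifest.expected_csp[label] = {
            int(r): float(shift) if p else 0.0 for r, p in zip(residues, planted)
        }
    return free, points, manifest


# ---------------------------------------------------------------------------
# Docking pose ensemble over a toy antigen
# ---------------------------------------------------------------------------

CHAIN_SPACING = 3.8       # Å between consecutive pseudo-Cα positions
CONTACT_OFFSET = 4.0      # Å probe-atom standoff; <= 5 to own Cα, > 5 to neighbours
N_ANTIBODY_RESIDUES = 10
CDR_RESIDUES = frozenset(range(3, 9))  # residues 3-8 of the probe antibody


def toy_antigen(config: SimulationConfig) -> StructureModel:
    """Extended Cα+Cβ pseudo-chain, residue i at x = 3.8·i Å (chain A)."""
    seq = antigen_sequence(config)
    residues = []
    for i in range(1, config.n_residues + 1):
        x = CHAIN_SPACING * i
        name = ONE_TO_THREE[seq[i - 1]]
        atoms = [Atom("CA", "C", (x, 0.0, 0.0), True)]
        if name != "GLY":
            atoms.append(Atom("CB", "C", (x, -1.5, 0.0), True))
        residues.append(Residue(number=i, name=name, atoms=tuple(atoms)))
    return StructureModel(name="toy_antigen", chains={"A": tuple(residues)})


def _antibody_chain(contact_map: Mapping[int, list[float]]) -> tuple[Residue, ...]:
    """Probe antibody: 10 backbone atoms far from the antigen, plus one
    contact atom per touched antigen residue attached to the CDR residues
    round-robin.  ``contact_map`` maps CDR residue -> list of antigen x."""
    residues = []
    for j in range(1, N_ANTIBODY_RESIDUES + 1):
        atoms = [Atom("CA", "C", (CHAIN_SPACING * j, 50.0, 0.0), True)]
        for k, x in enumerate(contact_map.get(j, []), start=1):
            atoms.append(Atom(f"X{k}", "C", (x, CONTACT_OFFSET, 0.0), True))
        residues.append(Residue(number=j, name="GLY", atoms=tuple(atoms)))
    return tuple(residues)


def simulate_pose_ensemble(
    config: SimulationConfig,
) -> tuple[list[Pose], dict[str, float], TruthManifest]:
    """Rigid-pose ensemble in which each antigen residue is contacted
    independently: planted-epitope residues with ``p_contact_in``, others
    with ``p_contact_out``.

    Contacts are realised geometrically — a probe heavy atom is placed
    4.0 Å from the target residue's Cα, which is within the 5 Å criterion
    for that residue only (neighbouring residues are ≥ 5.5 Å away).  Docking
    scores are drawn lower (better) for poses contacting more planted
    residues: score = −(#planted contacts) + N(0, 0.5).
    """
    rng = config.rng(_STREAM_POSES)
    antigen = toy_antigen(config).chains["A"]
    planted = np.isin(np.arange(1, config.n_residues + 1),
                      sorted(config.planted_epitope))
    p = np.where(planted, config.p_contact_in, config.p_contact_out)
    cdr_sorted = sorted(CDR_RESIDUES)

    poses: list[Pose] = []
    scores: dict[str, float] = {}
    manifest = TruthManifest(
        planted_epitope=sorted(config.planted_epitope),
        cdr_residues=cdr_sorted,
    )
    width = max(4, len(str(config.n_poses)))
    for k in range(config.n_poses):
        pose_id = f"pose_{k + 1:0{width}d}"
        contacted = np.flatnonzero(rng.random(config.n_residues) < p) + 1
        contact_map: dict[int, list[float]] = {}
        for idx, res in enumerate(contacted):
            cdr_res = cdr_sorted[idx % len(cdr_sorted)]
            contact_map.setdefault(cdr_res, []).append(CHAIN_SPACING * int(res))
        structure = StructureModel(
            name=pose_id,
            chains={"A": antigen, "B": _antibody_chain(contact_map)},
        )
        n_planted_contacts = int(np.sum(planted[contacted - 1]))
        score = float(-n_planted_contacts + rng.normal(0.0, 0.5))
        poses.append(
            Pose(pose_id=pose_id, structure=structure,
                 antigen_chain="A", antibody_chain="B", score=score)
        )
        scores[pose_id] = score
        manifest.pose_contacts[pose_id] = [int(r) for r in contacted]
    return poses, scores, manifest


def cdr_definition() -> CDRDefinition:
    """CDR of the probe antibody used by the generator."""
    return CDRDefinition(residues=CDR_RESIDUES)


# ---------------------------------------------------------------------------
# Family alignment
# ---------------------------------------------------------------------------

def simulate_alignment(
    config: SimulationConfig,
) -> tuple[MultipleAlignment, TruthManifest]:
    """Family of homologs with the planted epitope columns held invariant.

    The reference (first) sequence is the antigen sequence; each homolog
    mutates every non-conserved site independently with
    ``substitution_rate`` (to a different residue) and deletes it with
    ``gap_rate`` (rendering a gap, so the alignment stays rectangular).
    Planted conserved columns — the planted epitope positions — are copied
    verbatim and never gapped.
    """
    ref = antigen_sequence(config)
    rng = config.rng(_STREAM_ALIGNMENT)
    conserved = sorted(config.planted_epitope)
    conserved_mask = np.isin(np.arange(1, config.n_residues + 1), conserved)
    ids = ["antigen_ref"] + [f"homolog_{i}" for i in range(1, config.n_sequences)]
    seqs = [ref]
    for _ in range(config.n_sequences - 1):
        chars = list(ref)
        for i in range(config.n_residues):
            if conserved_mask[i]:
                continue
            u = rng.random()
            if u < config.gap_rate:
                chars[i] = "-"
            elif u < config.gap_rate + config.substitution_rate:
                alternatives = [a for a in AA_ORDER if a != ref[i]]
                chars[i] = alternatives[rng.integers(len(alternatives))]
        seqs.append("".join(chars))
    aln = MultipleAlignment(ids=tuple(ids), sequences=tuple(seqs))
    manifest = TruthManifest(
        planted_epitope=sorted(config.planted_epitope),
        conserved_columns=conserved,
    )
    return aln, manifest


# ---------------------------------------------------------------------------
# Relaxation decay series
# ---------------------------------------------------------------------------

R1_DELAYS = (0.02, 0.06, 0.12, 0.2, 0.3, 0.45, 0.65, 0.9, 1.2)
R2_DELAYS = (0.004, 0.01, 0.017, 0.026, 0.036, 0.05, 0.07, 0.095)
I0 = 100.0


def default_relaxation_rates(
    config: SimulationConfig,
) -> dict[str, dict[int, dict[str, float]]]:
    """Planted per-residue rates: a freely tumbling ~12 kDa antigen
    (R1 ≈ 1.2-1.8 s⁻¹, R2 ≈ 7-9 s⁻¹) and its ~40 kDa antibody complex, whose
    slower tumbling raises R2 threefold and lowers R1 slightly."""
    rng = config.rng(_STREAM_DECAYS)
    rates: dict[str, dict[int, dict[str, float]]] = {"free": {}, "complex": {}}
    for res in range(1, config.n_residues + 1):
        r1 = float(1.2 + 0.6 * rng.random())
        r2 = float(7.0 + 2.0 * rng.random())
        rates["free"][res] = {"R1": r1, "R2": r2}
        rates["complex"][res] = {"R1": 0.8 * r1, "R2": 3.0 * r2}
    return rates


def simulate_decay_curves(
    config: SimulationConfig,
    rates: dict[str, dict[int, dict[str, float]]] | None = None,
) -> tuple[dict[str, pd.DataFrame], TruthManifest]:
    """Mono-exponential decay series for free and complexed antigen.

    Returns long DataFrames (``residue, delay_s, intensity``) keyed
    ``"free_R1"``, ``"free_R2"``, ``"complex_R1"``, ``"complex_R2"``, with
    iid Gaussian noise of ``decay_noise_frac``·I₀ on every intensity.
    """
    if rates is None:
        rates = default_relaxation_rates(config)
    rng = config.rng(_STREAM_DECAYS + 100)
    sigma = config.decay_noise_frac * I0
    datasets: dict[str, pd.DataFrame] = {}
    for state, per_res in rates.items():
        for mode, delays in (("R1", R1_DELAYS), ("R2", R2_DELAYS)):
            rows = []
            for res in sorted(per_res):
                rate = per_res[res][mode]
                if rate <= 0:
                    raise ValueError(f"non-positive planted rate for residue {res}")
                t = np.asarray(delays)
                y = I0 * np.exp(-rate * t)
                if sigma > 0:
                    y = y + rng.normal(0.0, sigma, len(t))
                    y = np.maximum(y, 1e-3 * I0)  # intensities stay positive
                for d, v in zip(t, y):
                    rows.append({"residue": res, "delay_s": d, "intensity": v})
            datasets[f"{state}_{mode}"] = pd.DataFrame(rows)
    manifest = TruthManifest(relaxation_rates=rates)
    return datasets, manifest


def write_decay_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["intensity"] = out["intensity"].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def write_bundle(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Generate and write every pipeline input plus ``truth.json``.

    Creates shift tables, decay TSVs, the toy antigen PDB, a multi-model pose
    PDB with a score table, an aligned FASTA, a merged truth manifest, and a
    ready-to-run ``pipeline.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    free, points, shift_truth = simulate_shift_tables(config)
    write_shift_table(free, out_dir / "free.tsv")
    titration_entries = []
    for point in points:
        fname = f"{point.shift_table.state_label}.tsv"
        write_shift_table(point.shift_table, out_dir / fname)
        titration_entries.append(
            {
                "shifts": fname,
                "concentration_uM": point.antigen_concentration_uM,
                "ratio": point.molar_ratio_antigen_to_scfv,
            }
        )

    datasets, decay_truth = simulate_decay_curves(config)
    for key, df in datasets.items():
        write_decay_table(df, out_dir / f"decays_{key}.tsv")

    write_structure(toy_antigen(config), out_dir / "antigen.pdb")
    poses, scores, pose_truth = simulate_pose_ensemble(config)
    write_multi_model([p.structure for p in poses], out_dir / "poses.pdb")
    write_score_table(scores, out_dir / "scores.tsv")

    aln, aln_truth = simulate_alignment(config)
    write_alignment(aln, out_dir / "family.afa")

    truth = TruthManifest(
        planted_epitope=sorted(config.planted_epitope),
        disappeared=sorted(config.disappeared),
        expected_csp=shift_truth.expected_csp,
        relaxation_rates=decay_truth.relaxation_rates,
        conserved_columns=aln_truth.conserved_columns,
        pose_contacts=pose_truth.pose_contacts,
        cdr_residues=pose_truth.cdr_residues,
    )
    truth.to_json(out_dir / "truth.json")

    pipeline_cfg = {
        "free_shifts": "free.tsv",
        "titration": titration_entries,
        "decays": {
            "free": {"R1": "decays_free_R1.tsv", "R2": "decays_free_R2.tsv"},
            "complex": {"R1": "decays_complex_R1.tsv", "R2": "decays_complex_R2.tsv"},
        },
        "structure": "antigen.pdb",
        "poses": "poses.pdb",
        "pose_scores": "scores.tsv",
        "antigen_chain": "A",
        "antibody_chain": "B",
        "cdr": sorted(CDR_RESIDUES),
        "alignment": "family.afa",
        "reference_id": "antigen_ref",
    }
    import yaml

    with open(out_dir / "pipeline.yaml", "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=False)
    return out_dir
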