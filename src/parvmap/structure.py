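"""Structure handling: PDB parsing, solvent accessibility, score annotation.

A light residue/atom container is populated from PDB files via gemmi.
Per-residue solvent-accessible surface area (SASA) is computed with the
Shrake–Rupley method (probe sphere rolled over van der Waals spheres,
sampled by a deterministic Fibonacci point set), and residue-level scores
(CSP, contact frequency, epitope membership) are painted into the B-factor
column for visualisation in any molecular viewer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Element-based van der Waals radii (Å) for the heavy atoms of proteins.
VDW_RADII: dict[str, float] = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
DEFAULT_VDW_RADIUS = 1.8

#: Theoretical maximal residue accessibilities (Å², Gly-X-Gly tripeptide
#: reference, Tien et al. 2013) used to normalise residue SASA.
MAX_ASA_TRIPEPTIDE: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

EXPOSED_THRESHOLD = 0.2


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: tuple[float, float, float]
    is_heavy: bool
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass(frozen=True)
class Residue:
    number: int
    name: str  # 3-letter code
    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        if not any(a.is_heavy for a in self.atoms):
            raise ValueError(f"residue {self.number} ({self.name}) has no heavy atom")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass(frozen=True)
class StructureModel:
    """One conformer: chains of residues of atoms, author numbering."""

    name: str
    chains: dict[str, tuple[Residue, ...]]

    def __post_init__(self) -> None:
        for chain_id, residues in self.chains.items():
            numbers = [r.number for r in residues]
            if len(numbers) != len(set(numbers)):
                raise ValueError(f"duplicate residue number in chain {chain_id}")

    def chain(self, chain_id: str) -> tuple[Residue, ...]:
        if chain_id not in self.chains:
            raise KeyError(f"no chain '{chain_id}' in structure {self.name}")
        return self.chains[chain_id]

    def heavy_atom_arrays(
        self, chain_id: str, residues: set[int] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates (N, 3) and parallel residue numbers (N,) of heavy atoms."""
        coords, res_numbers = [], []
        for res in self.chain(chain_id):
            if residues is not None and res.number not in residues:
                continue
            for atom in res.heavy_atoms():
                coords.append(atom.coords)
                res_numbers.append(res.number)
        if not coords:
            return np.empty((0, 3)), np.empty((0,), dtype=int)
        return np.asarray(coords, dtype=float), np.asarray(res_numbers, dtype=int)


def _is_hydrogen(element: str) -> bool:
    return element.upper() in ("H", "D")


def _from_gemmi_model(model: gemmi.Model, name: str) -> StructureModel:
    chains: dict[str, tuple[Residue, ...]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            icode = res.seqid.icode.strip()
            if icode:
                raise ValueError(
                    f"insertion code '{res.seqid.num}{icode}' in chain "
                    f"{chain.name}: author numbering is ambiguous"
                )
            # altloc resolution: per atom name keep the highest-occupancy copy
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            atoms = tuple(
                Atom(
                    name=a.name,
                    element=a.element.name,
                    coords=(a.pos.x, a.pos.y, a.pos.z),
                    is_heavy=not _is_hydrogen(a.element.name),
                    b_factor=a.b_iso,
                )
                for a in best.values()
            )
            residues.append(Residue(number=res.seqid.num, name=res.name, atoms=atoms))
        if residues:
            chains[chain.name] = tuple(residues)
    return StructureModel(name=name, chains=chains)


def read_structure(path: str | Path, model_index: int = 1) -> StructureModel:
    """Read one model of a PDB file (1-based ``model_index``).

    NMR ensembles are reduced to a single conformer; hydrogens are kept but
    flagged non-heavy; alternate locations collapse to the highest-occupancy
    copy; insertion codes are rejected.
    """
    path = Path(path)
    st = gemmi.read_pdb(str(path))
    if model_index < 1 or model_index > len(st):
        raise ValueError(
            f"{path}: model_index {model_index} out of range (1..{len(st)})"
        )
    return _from_gemmi_model(st[model_index - 1], name=path.stem)


def read_all_models(path: str | Path) -> list[StructureModel]:
    """All models of a (possibly multi-model) PDB file, in file order."""
    path = Path(path)
    st = gemmi.read_pdb(str(path))
    return [
        _from_gemmi_model(st[i], name=f"{path.stem}@{i + 1}") for i in range(len(st))
    ]


def _to_gemmi(structure: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.name
    model = gemmi.Model(1)
    for chain_id, residues in structure.chains.items():
        chain = gemmi.Chain(chain_id)
        for res in residues:
            g_res = gemmi.Residue()
            g_res.name = res.name
            g_res.seqid = gemmi.SeqId(res.number, " ")
            for atom in res.atoms:
                g_atom = gemmi.Atom()
                g_atom.name = atom.name
                g_atom.element = gemmi.Element(atom.element)
                g_atom.pos = gemmi.Position(*atom.coords)
                g_atom.occ = 1.0
                g_atom.b_iso = atom.b_factor
                g_res.add_atom(g_atom)
            chain.add_residue(g_res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: StructureModel, path: str | Path) -> None:
    _to_gemmi(structure).write_pdb(str(path))


def write_multi_model(models: Sequence[StructureModel], path: str | Path) -> None:
    """Write several conformers as one multi-model PDB (MODEL/ENDMDL records)."""
    if not models:
        raise ValueError("no models to write")
    st = gemmi.Structure()
    st.name = models[0].name
    for i, model in enumerate(models, start=1):
        single = _to_gemmi(model)
        g_model = single[0]
        g_model.num = i
        st.add_model(g_model)
    st.setup_entities()
    st.write_pdb(str(path))


def annotate_structure(
    structure: StructureModel,
    scores: Mapping[int, float],
    out_path: str | Path,
    default: float = 0.0,
    chain_id: str | None = None,
) -> StructureModel:
    """Write a copy of the structure with residue scores in the B-factor column.

    Every atom of a residue gets the residue's score; residues absent from
    ``scores`` get ``default``.  Scores outside the PDB B-factor field range
    are clamped to [-99.99, 999.99] with a warning.  Score keys that do not
    match any residue (of ``chain_id`` if given, else any chain) are skipped
    with a warning.  Returns the annotated model (also written to disk).
    """
    for res_num, value in scores.items():
        if not math.isfinite(value):
            raise ValueError(f"non-finite score for residue {res_num}")

    present: set[int] = set()
    new_chains: dict[str, tuple[Residue, ...]] = {}
    for cid, residues in structure.chains.items():
        annotate_this = chain_id is None or cid == chain_id
        new_residues = []
        for res in residues:
            value = default
            if annotate_this and res.number in scores:
                value = float(scores[res.number])
                present.add(res.number)
            if not -99.99 <= value <= 999.99:
                clamped = min(max(value, -99.99), 999.99)
                logger.warning(
                    "B-factor %g for residue %d clamped to %g", value, res.number, clamped
                )
                value = clamped
            new_residues.append(
                Residue(
                    number=res.number,
                    name=res.name,
                    atoms=tuple(
                        Atom(a.name, a.element, a.coords, a.is_heavy, b_factor=value)
                        for a in res.atoms
                    ),
                )
            )
        new_chains[cid] = tuple(new_residues)
    for res_num in set(scores) - present:
        logger.warning("score for residue %d matches no structure residue; skipped", res_num)
    annotated = StructureModel(name=structure.name, chains=new_chains)
    write_structure(annotated, out_path)
    return annotated


def read_residue_scores(path: str | Path, chain_id: str | None = None) -> dict[int, float]:
    """Recover per-residue scores from the B-factor column of an annotated PDB."""
    model = read_structure(path)
    scores: dict[int, float] = {}
    for cid, residues in model.chains.items():
        if chain_id is not None and cid != chain_id:
            continue
        for res in residues:
            scores[res.number] = res.atoms[0].b_factor
    return scores


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake-Rupley)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccessibilityRecord:
    """Per-residue SASA, relative accessibility and exposure call."""

    chain_id: str
    residue_number: int
    residue_name: str
    sasa: float
    relative_accessibility: float | None
    exposed: bool | None

    def __post_init__(self) -> None:
        if self.sasa < 0:
            raise ValueError("SASA must be non-negative")


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _vdw_radius(element: str) -> float:
    el = element.upper()
    if el not in VDW_RADII:
        logger.warning("unknown element '%s': using default vdW radius %.2f Å",
                       element, DEFAULT_VDW_RADIUS)
    return VDW_RADII.get(el, DEFAULT_VDW_RADIUS)


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom SASA (Å²) of spheres ``radii`` at ``coords``.

    Each atom's accessible surface is the fraction of ``n_sphere_points``
    test points on its probe-expanded sphere that fall outside every
    neighbouring probe-expanded sphere, times the full sphere area.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.empty(0)
    sphere = fibonacci_sphere(n_sphere_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    sasa = np.empty(n)
    for i in range(n):
        neighbours = [
            j for j in tree.query_ball_point(coords[i], max_reach)
            if j != i
            and np.linalg.norm(coords[j] - coords[i]) < expanded[i] + expanded[j]
        ]
        points = coords[i] + expanded[i] * sphere
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((points - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        sasa[i] = 4.0 * math.pi * expanded[i] ** 2 * accessible.mean()
    return sasa


def compute_sasa(
    structure: StructureModel,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> list[AccessibilityRecord]:
    """Residue-level SASA over all heavy atoms of the structure.

    Relative accessibility divides residue SASA by the theoretical Gly-X-Gly
    maximum for its amino acid type (None for non-standard residues); a
    residue is called exposed when relative accessibility >= 0.2.
    """
    coords, radii, keys = [], [], []
    for chain_id, residues in structure.chains.items():
        for res in residues:
            for atom in res.heavy_atoms():
                coords.append(atom.coords)
                radii.append(_vdw_radius(atom.element))
                keys.append((chain_id, res.number, res.name))
    per_atom = shrake_rupley(
        np.asarray(coords), np.asarray(radii), probe_radius, n_sphere_points
    )
    totals: dict[tuple[str, int, str], float] = {}
    for key, area in zip(keys, per_atom):
        totals[key] = totals.get(key, 0.0) + float(area)
    records = []
    for (chain_id, number, name), area in totals.items():
        max_asa = MAX_ASA_TRIPEPTIDE.get(name)
        rel = area / max_asa if max_asa else None
        records.append(
            AccessibilityRecord(
                chain_id=chain_id,
                residue_number=number,
                residue_name=name,
                sasa=area,
                relative_accessibility=rel,
                exposed=None if rel is None else rel >= EXPOSED_THRESHOLD,
            )
        )
    records.sort(key=lambda r: (r.chain_id, r.residue_number))
    return records


def write_accessibility_table(
    records: Sequence[AccessibilityRecord], path: str | Path
) -> None:
    """TSV report: ``residue  sasa_A2  rel_acc  exposed``."""
    import pandas as pd

    rows = [
        {
            "residue": r.residue_number,
            "sasa_A2": f"{r.sasa:.6g}",
            "rel_acc": "NA" if r.relative_accessibility is None
            else f"{r.relative_accessibility:.6g}",
            "exposed": "NA" if r.exposed is None else int(r.exposed),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
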