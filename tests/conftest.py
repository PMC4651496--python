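"""Shared fixtures: tiny structures, shift tables and synthetic bundles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from parvmap.nmr_csp import ShiftTable
from parvmap.structure import Atom, Residue, StructureModel


def make_shift_table(label: str, rows: list[tuple[int, str, float, float]]) -> ShiftTable:
    return ShiftTable(
        state_label=label,
        data=pd.DataFrame(rows, columns=["residue", "aa", "dH", "dN"]),
    )


def make_structure(
    atoms_by_residue: dict[int, list[tuple[str, str, tuple[float, float, float]]]],
    chain_id: str = "A",
    residue_name: str = "ALA",
) -> StructureModel:
    """Build a single-chain structure from {residue: [(atom, element, xyz)]}."""
    residues = tuple(
        Residue(
            number=num,
            name=residue_name,
            atoms=tuple(
                Atom(name, element, xyz, is_heavy=element.upper() not in ("H", "D"))
                for name, element, xyz in atom_list
            ),
        )
        for num, atom_list in sorted(atoms_by_residue.items())
    )
    return StructureModel(name="toy", chains={chain_id: residues})


def pdb_atom_line(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_seq: int,
    xyz: tuple[float, float, float],
    element: str,
    icode: str = " ",
    altloc: str = " ",
    occ: float = 1.0,
    b: float = 0.0,
) -> str:
    """A correctly column-aligned PDB ATOM record."""
    x, y, z = xyz
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field}{altloc}{res_name:<3s} {chain}"
        f"{res_seq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def free_bound_pair():
    """A 4-residue free table and a bound table with residue 3 disappeared
    and residue 2 perturbed by ΔδH = 0.10, ΔδN = 0.50."""
    free = make_shift_table(
        "free",
        [(1, "A", 8.0, 110.0), (2, "G", 8.5, 112.0), (3, "K", 7.9, 120.0),
         (4, "F", 9.1, 125.0)],
    )
    bound = make_shift_table(
        "bound",
        [(1, "A", 8.0, 110.0), (2, "G", 8.6, 112.5), (4, "F", 9.1, 125.0)],
    )
    return free, bound
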