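"""Clustal-style conservation annotation and epitope/alignment cross-mapping.

Cross-reactive antibody binding to homologous allergens is rationalised by
the conservation of epitope residues across the protein family.  This module
annotates the columns of a multiple alignment with the Clustal consensus
symbols ('*' invariant, ':' strongly conserved, '.' weakly conserved,
' ' otherwise), maps an epitope given in the numbering of one reference
sequence onto alignment columns, and reports overlap with published
IgE-epitope intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import AlignIO

from .nmr_csp import AMINO_ACIDS_1, EpitopeSet

GAP = "-"

#: Clustal "strong" amino-acid groups: a column whose residues all fall in
#: one group (and has no gap) is marked ':'.
STRONG_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in ("STA", "NEQK", "NHQK", "NDEQ", "QHRK",
                           "MILV", "MILF", "HY", "FYW")
)

#: Clustal "weak" groups, marked '.'.
WEAK_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in ("CSA", "ATV", "SAG", "STNK", "STPA", "SGND",
                           "SDEENK", "NDEQHK", "NEQHRK", "FVLIM", "HFY")
)


@dataclass(frozen=True)
class MultipleAlignment:
    """Aligned amino-acid sequences of equal length ('-' gaps), upper case."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in number")
        if len(self.sequences) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        length = len(self.sequences[0])
        for sid, seq in zip(self.ids, self.sequences):
            if len(seq) != length:
                raise ValueError(
                    f"sequence '{sid}' has aligned length {len(seq)}, expected {length}"
                )
            for pos, char in enumerate(seq, start=1):
                if char != GAP and char not in AMINO_ACIDS_1:
                    raise ValueError(
                        f"sequence '{sid}': invalid symbol '{char}' at column {pos}"
                    )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def column(self, index: int) -> tuple[str, ...]:
        """1-based column."""
        return tuple(seq[index - 1] for seq in self.sequences)

    def sequence(self, seq_id: str) -> str:
        try:
            return self.sequences[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"no sequence '{seq_id}' in alignment") from None


_FORMAT_BY_SUFFIX = {
    ".afa": "fasta", ".fasta": "fasta", ".fa": "fasta",
    ".aln": "clustal", ".clustal": "clustal", ".clw": "clustal",
}


def read_alignment(path: str | Path, fmt: str | None = None) -> MultipleAlignment:
    """Read an aligned FASTA or Clustal file (format inferred from suffix).

    Any conservation line in a Clustal file is ignored on input; symbols are
    recomputed by :func:`conservation_symbols`.
    """
    path = Path(path)
    if fmt is None:
        fmt = _FORMAT_BY_SUFFIX.get(path.suffix.lower(), "fasta")
    aln = AlignIO.read(str(path), fmt)
    return MultipleAlignment(
        ids=tuple(rec.id for rec in aln),
        sequences=tuple(str(rec.seq).upper() for rec in aln),
    )


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")


def conservation_symbols(aln: MultipleAlignment) -> str:
    """Clustal consensus line for the alignment.

    Per column: '*' if all residues identical (no gap); ':' if all fall in
    one strong group; '.' if all fall in one weak group; ' ' otherwise.  Any
    gap in a column yields ' '.
    """
    symbols = []
    for col in range(1, aln.length + 1):
        residues = set(aln.column(col))
        if GAP in residues:
            symbols.append(" ")
        elif len(residues) == 1:
            symbols.append("*")
        elif any(residues <= group for group in STRONG_GROUPS):
            symbols.append(":")
        elif any(residues <= group for group in WEAK_GROUPS):
            symbols.append(".")
        else:
            symbols.append(" ")
    return "".join(symbols)


def ungapped_to_column(sequence: str) -> dict[int, int]:
    """Map 1-based ungapped positions of an aligned sequence to 1-based columns."""
    mapping: dict[int, int] = {}
    pos = 0
    for col, char in enumerate(sequence, start=1):
        if char != GAP:
            pos += 1
            mapping[pos] = col
    return mapping


def map_epitope_columns(
    epitope: EpitopeSet, reference_id: str, aln: MultipleAlignment
) -> pd.DataFrame:
    """Locate each epitope residue of the reference sequence in the alignment.

    Returns one row per epitope residue with the alignment column, the
    residue shown by every sequence at that column, the Clustal conservation
    symbol and the fraction of sequences identical to the reference there.
    """
    ref_seq = aln.sequence(reference_id)
    pos_to_col = ungapped_to_column(ref_seq)
    symbols = conservation_symbols(aln)
    rows = []
    for res in epitope.sorted():
        if res not in pos_to_col:
            raise ValueError(
                f"epitope residue {res} is beyond the ungapped length "
                f"({len(pos_to_col)}) of reference '{reference_id}'"
            )
        col = pos_to_col[res]
        column = aln.column(col)
        ref_aa = ref_seq[col - 1]
        identical = sum(1 for c in column if c == ref_aa) / len(column)
        rows.append(
            {
                "residue": res,
                "column": col,
                "ref_aa": ref_aa,
                "per_sequence_residues": "".join(column),
                "symbol": symbols[col - 1],
                "identical_fraction": identical,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Literature epitope intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LiteratureEpitopeSet:
    """Named inclusive residue intervals on a named reference numbering."""

    reference: str
    intervals: tuple[tuple[str, int, int, str], ...]  # (name, start, end, source)

    def __post_init__(self) -> None:
        for name, start, end, _ in self.intervals:
            if start < 1 or start > end:
                raise ValueError(f"bad interval '{name}': [{start}, {end}]")


#: IgE-binding regions of beta-parvalbumins reported by peptide-based epitope
#: mapping studies, in Gad m 1 numbering: the AB/CD-joining axis (28-45,
#: Baltic cod / Atlantic salmon), the C-terminal peptide (95-109, Atlantic
#: cod), the region around residue 80 (carp), and the 30-40 / 50-60 windows
#: recurrently mapped across species.
PACKAGED_LITERATURE_EPITOPES = LiteratureEpitopeSet(
    reference="Gad m 1",
    intervals=(
        ("ab_cd_axis_peptide", 28, 45, "Gad c 1 / Sal s 1 peptide mapping"),
        ("c_terminal_peptide", 95, 109, "Gad m 1 overlapping peptides"),
        ("around_80", 75, 85, "Cyp c 1 mapping"),
        ("pos_30_40", 30, 40, "shared across the three allergens"),
        ("pos_50_60", 50, 60, "Gad m 1 / Gad c 1 only"),
    ),
)


def read_literature_epitopes(path: str | Path, reference: str = "custom") -> LiteratureEpitopeSet:
    """Read intervals from a TSV with columns ``name  start  end  source``."""
    df = pd.read_csv(path, sep="\t")
    return LiteratureEpitopeSet(
        reference=reference,
        intervals=tuple(
            (str(r.name), int(r.start), int(r.end), str(r.source))
            for r in df.itertuples(index=False)
        ),
    )


def epitope_overlap_report(
    epitope: EpitopeSet, literature: LiteratureEpitopeSet
) -> pd.DataFrame:
    """Overlap of an epitope with each literature interval.

    For each interval reports |epitope ∩ interval|, the interval size, and
    the Jaccard index |epitope ∩ interval| / |epitope ∪ interval|.  An empty
    literature set yields an empty report.
    """
    rows = []
    residues = epitope.residues
    for name, start, end, source in literature.intervals:
        interval = set(range(start, end + 1))
        inter = len(residues & interval)
        union = len(residues | interval)
        rows.append(
            {
                "name": name,
                "start": start,
                "end": end,
                "interval_size": len(interval),
                "overlap": inter,
                "jaccard": inter / union if union else 0.0,
                "source": source,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["name", "start", "end", "interval_size", "overlap", "jaccard", "source"],
    )
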