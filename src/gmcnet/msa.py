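"""Alignment post-processing: gap trimming, block selection, anchored windows.

An :class:`Msa` wraps aligned rows with the column bookkeeping that anchored
analyses need — mapping a 1-based ungapped residue position of a reference
row to its 1-based alignment column and back.  All column intervals are
1-based inclusive.

The two reduction steps mirror the standard phylogenetics pipeline: first
drop columns that are almost entirely gaps (trimAl-style, threshold 0.99 or
0.95 for small sets), then keep only conserved blocks of at least five
columns with at most half the rows gapped (Gblocks-style "less stringent"
selection).  Alignment *production* is delegated: supply an externally
aligned FASTA, or call :func:`mafft_align` which shells out to ``mafft``.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .seqio import SequenceRecord, format_fasta, read_fasta

GAP = "-"
FAD_MOTIF_PATTERN = re.compile(r"(?=(G[ACDEFGHIKLMNPQRSTVWY]G[ACDEFGHIKLMNPQRSTVWY]{2}[GAS]))")


class AnchorError(ValueError):
    """An anchored reference position or motif could not be resolved."""


@dataclass
class Msa:
    """Aligned rows (id, aligned string) with position<->column maps."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("aligned rows must all have equal length")
        self._index = {rid: i for i, rid in enumerate(self.ids)}

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> str:
        try:
            return self.rows[self._index[rid]]
        except KeyError:
            raise AnchorError(f"row id not in alignment: {rid!r}") from None

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col`` across rows, gaps included."""
        if not (1 <= col <= self.n_columns):
            raise IndexError(f"column {col} out of range 1..{self.n_columns}")
        return "".join(r[col - 1] for r in self.rows)

    def column_map(self, rid: str) -> list[int]:
        """1-based columns of the residues of row ``rid``, in order."""
        return [c + 1 for c, ch in enumerate(self.row(rid)) if ch != GAP]

    def column_for_position(self, rid: str, pos: int) -> int:
        """Alignment column carrying residue ``pos`` (1-based) of row ``rid``."""
        cmap = self.column_map(rid)
        if not (1 <= pos <= len(cmap)):
            raise AnchorError(
                f"position {pos} out of range 1..{len(cmap)} for row {rid!r}"
            )
        return cmap[pos - 1]

    def position_for_column(self, rid: str, col: int) -> int | None:
        """Inverse lookup; ``None`` when the row is gapped at that column."""
        row = self.row(rid)
        if not (1 <= col <= self.n_columns):
            raise IndexError(f"column {col} out of range 1..{self.n_columns}")
        if row[col - 1] == GAP:
            return None
        return col - row[:col].count(GAP)

    def take_columns(self, columns) -> "Msa":
        """Restrict to 1-based ``columns`` (kept in the given order)."""
        cols = [c - 1 for c in columns]
        return Msa(
            ids=list(self.ids),
            rows=["".join(r[c] for c in cols) for r in self.rows],
        )

    def take_rows(self, ids) -> "Msa":
        return Msa(ids=list(ids), rows=[self.row(r) for r in ids])

    def gap_fraction(self, col: int) -> float:
        column = self.column(col)
        return column.count(GAP) / len(column)

    def top_residue_fraction(self, col: int) -> float:
        """Most-frequent residue count over non-gap rows; 0.0 if all gaps."""
        residues = self.column(col).replace(GAP, "")
        if not residues:
            return 0.0
        return Counter(residues).most_common(1)[0][1] / len(residues)

    def to_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(id=i, residues=r) for i, r in zip(self.ids, self.rows)]


def read_alignment(path) -> Msa:
    records = read_fasta(path)
    return Msa(ids=[r.id for r in records], rows=[r.residues for r in records])


def write_alignment(msa: Msa, path) -> None:
    with open(path, "w") as fh:
        fh.write(format_fasta(msa.to_records()))


def mafft_align(records, method_flags=("--retree", "2")) -> Msa:
    """Align records by shelling out to ``mafft`` (FFT-NS-2 by default)."""
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        infile.write_text(format_fasta(records))
        out = subprocess.run(
            ["mafft", *method_flags, "--anysymbol", str(infile)],
            capture_output=True, text=True, check=True,
        )
        outfile = Path(tmp) / "out.fasta"
        outfile.write_text(out.stdout)
        return read_alignment(outfile)


# ---------------------------------------------------------------------------
# column reduction
# ---------------------------------------------------------------------------

@dataclass
class BlockSelection:
    """Kept alignment columns (sorted, 1-based) and the selection parameters."""

    kept_columns: list[int]
    parameters: dict

    # per-column class for reporting: "conserved", "flank", "rejected"
    column_class: list[str] | None = None


def trim_gap_columns(msa: Msa, max_gap_fraction: float) -> Msa:
    """Drop every column whose gap fraction exceeds ``max_gap_fraction``."""
    if not (0.0 < max_gap_fraction <= 1.0):
        raise ValueError("max_gap_fraction must be in (0, 1]")
    kept = [
        c for c in range(1, msa.n_columns + 1)
        if msa.gap_fraction(c) <= max_gap_fraction
    ]
    return msa.take_columns(kept)


def select_blocks(
    msa: Msa,
    min_block_length: int = 5,
    max_gap_fraction: float = 0.5,
    conservation_threshold: float = 0.50,
    flank_threshold: float = 0.55,
) -> BlockSelection:
    """Gblocks-style conserved-block selection ("less stringent" preset).

    A column is a candidate iff its gap fraction (over all rows) is at most
    ``max_gap_fraction`` — the "with half" gap rule — and its most-frequent
    residue reaches ``conservation_threshold`` of the non-gap rows.  Maximal
    candidate runs are trimmed at both ends until the end columns also reach
    ``flank_threshold``, and runs shorter than ``min_block_length`` are
    rejected.
    """
    if min_block_length < 1:
        raise ValueError("min_block_length must be >= 1")
    for name, value in (
        ("max_gap_fraction", max_gap_fraction),
        ("conservation_threshold", conservation_threshold),
        ("flank_threshold", flank_threshold),
    ):
        if not (0.0 < value <= 1.0):
            raise ValueError(f"{name} must be in (0, 1]")

    n = msa.n_columns
    candidate = [
        msa.gap_fraction(c) <= max_gap_fraction
        and msa.top_residue_fraction(c) >= conservation_threshold
        for c in range(1, n + 1)
    ]
    classes = ["rejected"] * n
    kept: list[int] = []
    c = 0
    while c < n:
        if not candidate[c]:
            c += 1
            continue
        end = c
        while end + 1 < n and candidate[end + 1]:
            end += 1
        lo, hi = c, end
        # flanks of each block must clear the stricter flank threshold
        while lo <= hi and msa.top_residue_fraction(lo + 1) < flank_threshold:
            lo += 1
        while hi >= lo and msa.top_residue_fraction(hi + 1) < flank_threshold:
            hi -= 1
        if hi - lo + 1 >= min_block_length:
            for col in range(lo, hi + 1):
                classes[col] = "conserved"
            classes[lo] = "flank"
            classes[hi] = "flank"
            kept.extend(range(lo + 1, hi + 2))
        c = end + 1
    return BlockSelection(
        kept_columns=kept,
        parameters={
            "min_block_length": min_block_length,
            "max_gap_fraction": max_gap_fraction,
            "conservation_threshold": conservation_threshold,
            "flank_threshold": flank_threshold,
            "gap_denominator": "total_rows",
            "conservation_denominator": "non_gap_rows",
        },
        column_class=classes,
    )


def apply_block_selection(msa: Msa, selection: BlockSelection) -> Msa:
    return msa.take_columns(selection.kept_columns)


def write_block_report(msa: Msa, selection: BlockSelection, path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tclass\tgap_fraction\ttop_residue_fraction\n")
        for c in range(1, msa.n_columns + 1):
            cls = selection.column_class[c - 1] if selection.column_class else ""
            fh.write(
                f"{c}\t{cls}\t{msa.gap_fraction(c):.4f}"
                f"\t{msa.top_residue_fraction(c):.4f}\n"
            )


def column_for_reference_position(msa: Msa, ref_id: str, ref_pos: int) -> int:
    """Alignment column of a 1-based reference residue position."""
    return msa.column_for_position(ref_id, ref_pos)


def window_domain(
    msa: Msa,
    ref_id: str,
    catalytic_asn_pos: int,
    motif_pattern: re.Pattern = FAD_MOTIF_PATTERN,
    start_offset: int = -6,
    end_offset: int = 18,
) -> Msa:
    """Restrict the alignment to an anchored domain window.

    The window runs from ``start_offset`` columns before the first occurrence
    of the FAD-binding motif (GxGxx[GAS]) in the reference row to
    ``end_offset`` columns after the reference's catalytic Asn, clamped to
    the alignment bounds.  This is the CDH-style cut that isolates the
    dehydrogenase (GMC) domain of a multidomain enzyme.
    """
    reference = msa.ungapped(ref_id)
    match = motif_pattern.search(reference)
    if match is None:
        raise AnchorError(f"reference {ref_id!r} lacks the anchor motif")
    motif_pos = match.start() + 1
    if not (1 <= catalytic_asn_pos <= len(reference)):
        raise AnchorError(
            f"catalytic position {catalytic_asn_pos} out of range for {ref_id!r}"
        )
    if reference[catalytic_asn_pos - 1] != "N":
        raise AnchorError(
            f"reference residue at {catalytic_asn_pos} is "
            f"{reference[catalytic_asn_pos - 1]!r}, expected catalytic Asn"
        )
    start_col = msa.column_for_position(ref_id, motif_pos) + start_offset
    end_col = msa.column_for_position(ref_id, catalytic_asn_pos) + end_offset
    start_col = max(1, start_col)
    end_col = min(msa.n_columns, end_col)
    if start_col > end_col:
        raise AnchorError("anchored window is empty")
    return msa.take_columns(range(start_col, end_col + 1))
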