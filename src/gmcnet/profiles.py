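"""Position-frequency analyses: logos, anchored conservation, PTS, Cyt check.

A :class:`PositionFrequencyMatrix` tallies residue counts per position,
either over alignment columns (active-site panels) or over C-terminal
offsets -n..-1 (peroxisomal-targeting-signal logos).  Logo heights use the
information content IC = log2(20) - H(p) in bits, without small-sample
correction.  Gaps never enter the counts: they are tallied separately and
excluded from each position's effective n.

The cytochrome-domain functionality check asks whether a CDH-style
N-terminal heme domain retains its two axial ligands (Met, His) and the
disulfide Cys pair at alignment columns anchored by a characterised
reference (M65/H163/C121/C124 in the classical numbering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msa import GAP, AnchorError, Msa

RESIDUES = list("ACDEFGHIKLMNPQRSTVWY")
_ALPHABET_BITS = np.log2(len(RESIDUES))


@dataclass
class PositionFrequencyMatrix:
    """Residue counts per position with per-position effective n.

    ``counts`` is a residues x positions DataFrame; ``positions`` are
    1-based column indices or negative terminal offsets (-1 = last residue).
    """

    counts: pd.DataFrame  # index: residues; columns: position labels
    gap_counts: pd.Series

    @property
    def positions(self) -> list:
        return list(self.counts.columns)

    @property
    def n_effective(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def frequencies(self) -> pd.DataFrame:
        n = self.n_effective.replace(0, np.nan)
        return (self.counts / n).fillna(0.0)

    def gap_fraction(self) -> pd.Series:
        total = self.n_effective + self.gap_counts
        return (self.gap_counts / total.replace(0, np.nan)).fillna(0.0)

    def information_content(self) -> pd.Series:
        """Per-position IC in bits: log2(20) - Shannon entropy."""
        freqs = self.frequencies()
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
        entropy = -plogp.sum(axis=0)
        ic = pd.Series(_ALPHABET_BITS - entropy, index=self.counts.columns)
        return ic.where(self.n_effective > 0, 0.0)

    def consensus(self) -> str:
        """Modal residue per position ('-' where nothing contributes)."""
        out = []
        for pos in self.counts.columns:
            col = self.counts[pos]
            if col.sum() == 0:
                out.append(GAP)
            else:
                out.append(col.idxmax())
        return "".join(out)

    def to_frame(self) -> pd.DataFrame:
        frame = self.counts.T.copy()
        frame["n_effective"] = self.n_effective
        frame["gap_fraction"] = self.gap_fraction()
        frame["information_content_bits"] = self.information_content()
        return frame


def _empty_counts(positions) -> pd.DataFrame:
    return pd.DataFrame(
        0, index=RESIDUES, columns=list(positions), dtype=int)


def terminal_pfm(records, n_last: int = 10) -> PositionFrequencyMatrix:
    """Counts over the final ``n_last`` residues, aligned at the C-terminus.

    Offset -1 is the last residue.  Records shorter than ``n_last``
    contribute only their available positions; offsets nobody reaches have
    effective n of zero.
    """
    records = list(records)
    if not records:
        raise ValueError("terminal_pfm needs at least one record")
    offsets = list(range(-n_last, 0))
    counts = _empty_counts(offsets)
    gaps = pd.Series(0, index=offsets, dtype=int)
    for rec in records:
        residues = rec.residues
        for offset in offsets:
            if len(residues) + offset >= 0:
                aa = residues[offset]
                if aa in counts.index:
                    counts.loc[aa, offset] += 1
    return PositionFrequencyMatrix(counts=counts, gap_counts=gaps)


def column_pfm(msa: Msa, columns, member_ids=None) -> PositionFrequencyMatrix:
    """Residue counts at the requested alignment columns over members.

    Gaps are excluded from counts and effective n; they are tallied in
    ``gap_counts`` and surface as a per-position gap fraction.
    """
    member_ids = list(member_ids) if member_ids is not None else list(msa.ids)
    columns = list(columns)
    for col in columns:
        if not (1 <= col <= msa.n_columns):
            raise IndexError(f"column {col} out of range 1..{msa.n_columns}")
    counts = _empty_counts(columns)
    gaps = pd.Series(0, index=columns, dtype=int)
    for member in member_ids:
        row = msa.row(member)
        for col in columns:
            aa = row[col - 1]
            if aa == GAP:
                gaps[col] += 1
            elif aa in counts.index:
                counts.loc[aa, col] += 1
    return PositionFrequencyMatrix(counts=counts, gap_counts=gaps)


def conservation_at(
    msa: Msa, ref_id: str, ref_pos: int, member_ids=None,
    residue_class=frozenset(),
) -> float:
    """Fraction of members carrying a ``residue_class`` residue at the
    column anchored by the reference position; gapped members are excluded
    from the denominator."""
    col = msa.column_for_position(ref_id, ref_pos)
    member_ids = list(member_ids) if member_ids is not None else list(msa.ids)
    residue_class = set(residue_class)
    total = 0
    hits = 0
    for member in member_ids:
        aa = msa.row(member)[col - 1]
        if aa == GAP:
            continue
        total += 1
        if aa in residue_class:
            hits += 1
    if total == 0:
        raise ValueError("all members gapped at the anchored column")
    return hits / total


def pts_consensus(records) -> str:
    """Modal C-terminal tripeptide, the peroxisomal targeting signal report."""
    pfm = terminal_pfm(records, n_last=3)
    return pfm.consensus()


# ---------------------------------------------------------------------------
# cytochrome-domain functionality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CytAnchors:
    """Reference residue positions of the heme-domain anchors."""

    ref_id: str
    met: int
    his: int
    cys1: int
    cys2: int


@dataclass
class CytCheck:
    found_met: bool
    found_his: bool
    found_cys1: bool
    found_cys2: bool

    @property
    def functional(self) -> bool:
        return self.found_met and self.found_his and self.found_cys1 and self.found_cys2


def cyt_functionality(msa: Msa, anchors: CytAnchors) -> dict[str, CytCheck]:
    """Per-sequence heme-domain verdict at anchored columns.

    A domain is functional iff the columns anchored by the reference's
    axial Met, axial His and two disulfide Cys residues carry M, H, C and C
    respectively; a gap at any anchored column fails that flag.
    """
    reference = msa.ungapped(anchors.ref_id)
    expected = [("M", anchors.met), ("H", anchors.his),
                ("C", anchors.cys1), ("C", anchors.cys2)]
    cols = []
    for aa, pos in expected:
        if not (1 <= pos <= len(reference)):
            raise AnchorError(
                f"anchor position {pos} out of range for {anchors.ref_id!r}")
        if reference[pos - 1] != aa:
            raise AnchorError(
                f"reference {anchors.ref_id!r} residue {pos} is "
                f"{reference[pos - 1]!r}, expected {aa!r}"
            )
        cols.append(msa.column_for_position(anchors.ref_id, pos))
    out = {}
    for rid, row in zip(msa.ids, msa.rows):
        flags = [row[c - 1] == aa for (aa, _), c in zip(expected, cols)]
        out[rid] = CytCheck(*flags)
    return out


def write_pfm(pfm: PositionFrequencyMatrix, path) -> None:
    pfm.to_frame().to_csv(path, sep="\t", index_label="position")
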