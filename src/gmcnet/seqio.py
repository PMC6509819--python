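"""Sequence store: FASTA/annotation I/O, validity filtering and dereplication.

The data model is intentionally minimal: a :class:`SequenceRecord` is an
identifier plus an uppercase amino-acid string, and an :class:`AnnotationRow`
carries the per-sequence metadata (taxonomy, signal-peptide flag, exon count,
domain coordinates, functional label) that downstream clade profiling
consumes.  Filtering removes records with ambiguous residues (B, J, O, U, X,
Z) or fewer than 450 residues; dereplication collapses near-identical records
at a global-alignment identity threshold (default 0.99), CD-HIT style.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = frozenset("BJOUXZ")


class FastaParseError(ValueError):
    """Raised when a FASTA file violates the expected dialect."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence.

    ``id`` is the FASTA header token up to the first whitespace and must be
    unique within a collection; ``description`` is the remainder of the
    header.  Residues are stored uppercase; positions reported anywhere in
    this package are 1-based inclusive.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        object.__setattr__(self, "residues", self.residues.upper())

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AnnotationRow:
    """Per-sequence annotation joined to records by ``id``.

    ``domain_spans`` are (name, start, end) in 1-based inclusive residue
    coordinates.  Missing values stay ``None`` and are excluded from every
    aggregate denominator downstream.
    """

    id: str
    function_label: str | None = None
    phylum: str | None = None
    order: str | None = None
    signal_flag: bool | None = None
    exon_count: int | None = None
    domain_spans: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self):
        if self.exon_count is not None and self.exon_count < 1:
            raise ValueError(f"exon_count must be >= 1 (id={self.id})")
        for name, start, end in self.domain_spans:
            if not (1 <= start <= end):
                raise ValueError(
                    f"bad domain span {name}:{start}-{end} (id={self.id})"
                )


@dataclass
class DereplicationResult:
    """Greedy identity clustering: representatives plus member assignment."""

    representatives: list[SequenceRecord]
    assignment: dict[str, str]
    threshold: float
    # convention recorded so alternative identity denominators can be compared
    identity_denominator: str = "shorter_sequence"


def read_fasta(path) -> list[SequenceRecord]:
    """Read a protein FASTA file into records, preserving entry order.

    Residues are uppercased.  Duplicate ids or an empty sequence body raise
    :class:`FastaParseError` naming the offending entry.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FastaParseError(f"duplicate sequence id: {entry.id!r}")
        seen.add(entry.id)
        residues = str(entry.seq)
        if not residues:
            raise FastaParseError(f"empty sequence body for id: {entry.id!r}")
        desc = entry.description
        if desc.startswith(entry.id):
            desc = desc[len(entry.id):].strip()
        records.append(SequenceRecord(id=entry.id, residues=residues, description=desc))
    if not records and _file_nonempty(path):
        raise FastaParseError(f"no FASTA entries parsed from {path}")
    return records


def _file_nonempty(path) -> bool:
    try:
        with open(path) as fh:
            return bool(fh.read(1))
    except OSError:
        return False


def write_fasta(records, path, width: int = 60) -> None:
    """Write records as FASTA, bodies wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        fh.write(format_fasta(records, width=width))


def format_fasta(records, width: int = 60) -> str:
    buf = io.StringIO()
    for rec in records:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        buf.write(f">{header}\n")
        for i in range(0, len(rec.residues), width):
            buf.write(rec.residues[i:i + width] + "\n")
    return buf.getvalue()


def filter_valid_records(
    records,
    min_length: int = 450,
    forbidden=AMBIGUOUS_AA,
):
    """Partition records into (kept, removed) by alphabet and length.

    A record is kept iff it contains none of the ``forbidden`` characters and
    has at least ``min_length`` residues.  ``removed`` is a list of
    ``(record, reason)`` with reason ``"invalid_char"`` or ``"too_short"``
    (invalid characters are reported first when both apply).
    """
    forbidden = set(forbidden)
    kept: list[SequenceRecord] = []
    removed: list[tuple[SequenceRecord, str]] = []
    for rec in records:
        if forbidden.intersection(rec.residues):
            removed.append((rec, "invalid_char"))
        elif rec.length < min_length:
            removed.append((rec, "too_short"))
        else:
            kept.append(rec)
    return kept, removed


def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def global_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Global-alignment identity: identical residues / shorter length.

    This is the CD-HIT denominator convention; the alignment itself is a
    BLOSUM62 global alignment (gap open 11, extend 1).
    """
    if a.residues == b.residues:
        return 1.0
    aligner = _global_aligner()
    alignment = aligner.align(a.residues, b.residues)[0]
    matches = sum(
        x == y and x != "-"
        for x, y in zip(alignment[0], alignment[1])
    )
    return matches / min(a.length, b.length)


def dereplicate(records, threshold: float = 0.99) -> DereplicationResult:
    """Greedy incremental clustering at a global identity threshold.

    Records are processed longest-first (ties broken by id); each record
    joins the first existing representative with identity >= ``threshold``,
    otherwise it founds a new representative.  Deterministic for a given
    input set.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(records, key=lambda r: (-r.length, r.id))
    representatives: list[SequenceRecord] = []
    assignment: dict[str, str] = {}
    for rec in ordered:
        home = None
        for rep in representatives:
            if global_identity(rec, rep) >= threshold:
                home = rep
                break
        if home is None:
            representatives.append(rec)
            assignment[rec.id] = rec.id
        else:
            assignment[rec.id] = home.id
    return DereplicationResult(
        representatives=representatives,
        assignment=assignment,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# annotation table (TSV dialect)
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "id", "function_label", "phylum", "order",
    "signal_flag", "exon_count", "domain_spans",
]


def _format_spans(spans) -> str:
    return ";".join(f"{name}:{start}-{end}" for name, start, end in spans)


def _parse_spans(text: str):
    spans = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        name, _, coords = token.rpartition(":")
        start, _, end = coords.partition("-")
        spans.append((name, int(start), int(end)))
    return tuple(spans)


def write_annotations(rows, path) -> None:
    """Write annotation rows as the package's TSV dialect."""
    frame = pd.DataFrame(
        [
            {
                "id": r.id,
                "function_label": r.function_label or "",
                "phylum": r.phylum or "",
                "order": r.order or "",
                "signal_flag": "" if r.signal_flag is None else str(r.signal_flag).lower(),
                "exon_count": "" if r.exon_count is None else r.exon_count,
                "domain_spans": _format_spans(r.domain_spans),
            }
            for r in rows
        ],
        columns=ANNOTATION_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> dict[str, AnnotationRow]:
    """Read the annotation TSV into a mapping id -> AnnotationRow."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows: dict[str, AnnotationRow] = {}
    for _, raw in frame.iterrows():
        flag_text = raw.get("signal_flag", "").strip().lower()
        signal = None if flag_text == "" else flag_text == "true"
        exon_text = raw.get("exon_count", "").strip()
        rows[raw["id"]] = AnnotationRow(
            id=raw["id"],
            function_label=raw.get("function_label", "") or None,
            phylum=raw.get("phylum", "") or None,
            order=raw.get("order", "") or None,
            signal_flag=signal,
            exon_count=int(float(exon_text)) if exon_text else None,
            domain_spans=_parse_spans(raw.get("domain_spans", "")),
        )
    return rows
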