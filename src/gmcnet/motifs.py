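"""GMC validity filter: FAD motifs and the catalytic His/His|His/Asn pair.

A putative GMC oxidoreductase sequence is considered valid when it shows
three properties: (i) the FAD-binding Rossmann motif GxGxxG or one of its
variants GxGxxA / GxGxxS anywhere in the sequence; (ii) a second
FAD-associated motif with consensus hGGpp or hGGGpp (h hydrophobic, p
polar); (iii) the catalytic His/His or His/Asn pair, detected in alignment
space at columns anchored by a characterised reference sequence.  Typical
removal rates on real subfamily clusters are in the 6-20% range.

The two contiguous motifs are scanned on unaligned residues; the catalytic
pair, which is conserved in alignment space rather than at absolute
coordinates, requires an Msa and a reference anchor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .msa import AnchorError, Msa

STANDARD = "ACDEFGHIKLMNPQRSTVWY"
# Zappo-style classes; G deliberately in neither (see report metadata)
HYDROPHOBIC = frozenset("ACFILMVWY")
POLAR = frozenset("DEHKNQRST")

_X = f"[{STANDARD}]"
_H = "[" + "".join(sorted(HYDROPHOBIC)) + "]"
_P = "[" + "".join(sorted(POLAR)) + "]"

# lookahead groups -> overlapping occurrences are all reported
FAD_RE = re.compile(f"(?=(G{_X}G{_X}{_X}[GAS]))")
ASSOC_RE = re.compile(f"(?=({_H}GG{_P}{_P})|({_H}GGG{_P}{_P}))")


@dataclass(frozen=True)
class MotifHit:
    motif_name: str  # fad_gxgxxg | fad_assoc | catalytic_pair
    start: int  # 1-based
    matched_text: str
    variant: str


def find_fad_motif(record) -> list[MotifHit]:
    """All occurrences of the FAD-binding motif G-x-G-x-x-[G|A|S], leftmost first."""
    hits = []
    for m in FAD_RE.finditer(record.residues):
        text = m.group(1)
        hits.append(MotifHit(
            motif_name="fad_gxgxxg",
            start=m.start() + 1,
            matched_text=text,
            variant=f"GxGxx{text[5]}",
        ))
    return hits


def find_assoc_motif(record) -> list[MotifHit]:
    """All occurrences of the FAD-associated motif hGGpp / hGGGpp."""
    hits = []
    for m in ASSOC_RE.finditer(record.residues):
        text = m.group(1) or m.group(2)
        hits.append(MotifHit(
            motif_name="fad_assoc",
            start=m.start() + 1,
            matched_text=text,
            variant="hGGpp" if len(text) == 5 else "hGGGpp",
        ))
    return hits


def find_catalytic_pair(
    msa: Msa,
    reference_anchors: tuple[str, int, int],
    tolerance: int = 0,
) -> dict[str, bool]:
    """Per-row verdict for the catalytic His/His or His/Asn pair.

    The alignment columns carrying the reference's two catalytic residues
    are located; a row passes iff it shows His in the first column and His
    or Asn in the second.  With ``tolerance`` > 0 a window of that many
    columns either side is searched instead of the single column.
    """
    ref_id, pos1, pos2 = reference_anchors
    reference = msa.ungapped(ref_id)
    if reference[pos1 - 1] != "H":
        raise AnchorError(
            f"reference {ref_id!r} residue {pos1} is {reference[pos1 - 1]!r},"
            " expected the catalytic His"
        )
    if reference[pos2 - 1] not in "HN":
        raise AnchorError(
            f"reference {ref_id!r} residue {pos2} is {reference[pos2 - 1]!r},"
            " expected the catalytic His or Asn"
        )
    col1 = msa.column_for_position(ref_id, pos1)
    col2 = msa.column_for_position(ref_id, pos2)

    def window(col):
        lo = max(1, col - tolerance)
        hi = min(msa.n_columns, col + tolerance)
        return range(lo, hi + 1)

    verdict = {}
    for rid, row in zip(msa.ids, msa.rows):
        has_his = any(row[c - 1] == "H" for c in window(col1))
        has_pair = any(row[c - 1] in "HN" for c in window(col2))
        verdict[rid] = has_his and has_pair
    return verdict


@dataclass
class SequenceVerdict:
    has_fad_motif: bool
    has_assoc_motif: bool
    has_catalytic_pair: bool
    fad_hits: list[MotifHit] = field(default_factory=list)
    assoc_hits: list[MotifHit] = field(default_factory=list)

    @property
    def kept(self) -> bool:
        return self.has_fad_motif and self.has_assoc_motif and self.has_catalytic_pair


@dataclass
class FilterReport:
    """Pass/fail of the three-property GMC validity filter per sequence."""

    verdicts: dict[str, SequenceVerdict]
    kept: set[str]
    removed: set[str]
    residue_classes: dict = field(default_factory=lambda: {
        "hydrophobic": "".join(sorted(HYDROPHOBIC)),
        "polar": "".join(sorted(POLAR)),
        "catalytic_detection": "alignment_anchored",
        "motif_detection": "unaligned_contiguous",
    })

    @property
    def removal_fraction(self) -> float:
        total = len(self.kept) + len(self.removed)
        return len(self.removed) / total if total else 0.0

    def property_counts(self) -> dict[str, int]:
        return {
            "missing_fad_motif": sum(
                not v.has_fad_motif for v in self.verdicts.values()),
            "missing_assoc_motif": sum(
                not v.has_assoc_motif for v in self.verdicts.values()),
            "missing_catalytic_pair": sum(
                not v.has_catalytic_pair for v in self.verdicts.values()),
        }


def apply_validity_filter(records, msa: Msa, anchors) -> FilterReport:
    """Keep sequences showing all three GMC validity properties.

    ``records`` must be rows of ``msa`` (their ungapped residues must match);
    ``anchors`` is (reference_id, pos1, pos2) in reference residue
    coordinates.
    """
    records = list(records)
    for rec in records:
        if msa.ungapped(rec.id) != rec.residues:
            raise ValueError(
                f"record {rec.id!r} does not match its alignment row")
    pair = find_catalytic_pair(msa, anchors)
    verdicts: dict[str, SequenceVerdict] = {}
    kept, removed = set(), set()
    for rec in records:
        fad = find_fad_motif(rec)
        assoc = find_assoc_motif(rec)
        v = SequenceVerdict(
            has_fad_motif=bool(fad),
            has_assoc_motif=bool(assoc),
            has_catalytic_pair=pair[rec.id],
            fad_hits=fad,
            assoc_hits=assoc,
        )
        verdicts[rec.id] = v
        (kept if v.kept else removed).add(rec.id)
    return FilterReport(verdicts=verdicts, kept=kept, removed=removed)


def write_filter_report(report: FilterReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("# classes: " + repr(report.residue_classes) + "\n")
        fh.write(
            "id\thas_fad_motif\tfad_variant\tfad_pos"
            "\thas_assoc_motif\tassoc_pos\thas_catalytic_pair\tkept\n"
        )
        for rid in sorted(report.verdicts):
            v = report.verdicts[rid]
            fad_variant = v.fad_hits[0].variant if v.fad_hits else ""
            fad_pos = v.fad_hits[0].start if v.fad_hits else ""
            assoc_pos = v.assoc_hits[0].start if v.assoc_hits else ""
            fh.write(
                f"{rid}\t{v.has_fad_motif}\t{fad_variant}\t{fad_pos}"
                f"\t{v.has_assoc_motif}\t{assoc_pos}"
                f"\t{v.has_catalytic_pair}\t{rid in report.kept}\n"
            )
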