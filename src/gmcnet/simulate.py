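"""Ground-truthed synthetic protein superfamilies.

The generator grows several families from a shared root ancestor: each
family descends along its own random bifurcating (coalescent-shaped,
ultrametric) tree under a 20-state Jukes-Cantor-type substitution process,
with the per-branch substitution probability calibrated in closed form so
that realised within-family and between-family identities hit the
configured targets in expectation.  On top of the neutral backbone the
generator plants the features the analysis pipeline looks for:

* one FAD-binding motif GxGxx[G|A|S] and one FAD-associated hGG(G)pp motif
  at family-fixed positions,
* a catalytic His/His or His/Asn pair,
* an optional N-terminal 18-residue signal peptide (per sequence),
* an optional C-terminal PTS tripeptide (per family, e.g. ARF or SRL),
* an optional 120-residue fused accessory (cytochrome-like) domain with
  M/H/C/C anchor residues, intact ("functional") or broken ("degenerate").

Planted regions are shielded from substitutions and indels; a configurable
fraction of sequences per family is made *invalid* by breaking exactly one
of the three validity properties, with every chance occurrence of the
broken motif disrupted as well, so filter precision/recall against the
truth is exact.  The generator knows its own indel history and therefore
emits the true per-family alignment alongside the sequences.

All outputs are pure functions of the configuration, including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .motifs import ASSOC_RE, FAD_RE
from .msa import GAP, Msa
from .seqio import AnnotationRow, SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA)}

SIGNAL_PEPTIDE = "MKFSTILLAAVAASALAQ"  # 18 aa, G-free: cannot host either motif
ACCESSORY_LENGTH = 120
# anchor positions (1-based) inside the accessory domain: axial Met/His + Cys pair
ACCESSORY_ANCHORS = {"met": 20, "cys1": 60, "cys2": 63, "his": 100}
_BACKGROUND_IDENTITY = 1.0 / len(AA)

PROPERTIES = ("fad_motif", "assoc_motif", "catalytic_pair")


class ConfigError(ValueError):
    """The synthetic configuration is internally inconsistent."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic superfamily.

    ``invalid_fraction`` is converted to a per-family count by
    round-half-to-even of ``fraction * seqs_per_family``.  ``pts_tripeptides``
    and ``accessory_domains`` are per-family tuples padded with ``None``;
    accessory entries are ``None`` / ``"functional"`` / ``"degenerate"``.
    """

    seed: int = 1
    n_families: int = 5
    seqs_per_family: int = 30
    length: int = 550
    within_family_identity: float = 0.70
    between_family_identity: float = 0.25
    invalid_fraction: float = 0.10
    signal_fraction: float = 0.5
    indel_rate: float = 1.0  # expected indels per sequence
    indel_mean_length: float = 2.0
    family_labels: tuple = ("AAO", "AOx", "CDH", "GOx", "POx")
    pts_tripeptides: tuple = ("ARF", "SRL", None, None, None)
    accessory_domains: tuple = (None, None, "functional", "degenerate", None)

    def __post_init__(self):
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        if self.seqs_per_family < 2:
            raise ConfigError("seqs_per_family must be >= 2")
        if self.length < 100:
            raise ConfigError("length must be >= 100")
        for name in ("within_family_identity", "between_family_identity",
                     "invalid_fraction", "signal_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.within_family_identity <= self.between_family_identity:
            raise ConfigError(
                "within_family_identity must exceed between_family_identity")
        if self.between_family_identity <= _BACKGROUND_IDENTITY:
            raise ConfigError(
                f"between_family_identity must exceed the random background "
                f"{_BACKGROUND_IDENTITY:.3f}")

    def label(self, family: int) -> str:
        if family < len(self.family_labels):
            return self.family_labels[family]
        return f"fam{family}"

    def pts(self, family: int):
        return self.pts_tripeptides[family] if family < len(self.pts_tripeptides) else None

    def accessory(self, family: int):
        return (self.accessory_domains[family]
                if family < len(self.accessory_domains) else None)

    @property
    def n_invalid_per_family(self) -> int:
        return int(round(self.invalid_fraction * self.seqs_per_family))


@dataclass
class SequenceTruth:
    """Ground truth for one emitted sequence (positions 1-based, final coords)."""

    id: str
    family: int
    family_label: str
    valid: bool
    broken_property: str | None
    fad_start: int | None
    assoc_start: int | None
    catalytic_positions: tuple[int, int] | None
    signal: bool
    pts: str | None
    # None when the family has no accessory domain; otherwise this
    # sequence's own domain status ("functional" or "degenerate")
    accessory: str | None
    accessory_anchor_positions: dict | None


@dataclass
class FamilyTruth:
    family: int
    label: str
    member_ids: list[str]
    ancestor_core: str
    tree_newick: str
    alignment: Msa
    catalytic_reference: str  # first valid member (sorted by id)
    accessory_reference: str | None = None  # first member with intact anchors


@dataclass
class SyntheticTruth:
    config: SyntheticConfig
    sequences: dict[str, SequenceTruth]
    families: list[FamilyTruth]

    def family_assignment(self) -> dict[str, int]:
        return {sid: s.family for sid, s in self.sequences.items()}

    def invalid_ids(self) -> set[str]:
        return {sid for sid, s in self.sequences.items() if not s.valid}

    def catalytic_anchors(self, family: int) -> tuple[str, int, int]:
        ref = self.families[family].catalytic_reference
        p1, p2 = self.sequences[ref].catalytic_positions
        return ref, p1, p2


@dataclass
class SimulationResult:
    records: list[SequenceRecord]
    annotations: dict[str, AnnotationRow]
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# substitution process (20-state Jukes-Cantor-type)
# ---------------------------------------------------------------------------

def identity_to_distance(identity: float) -> float:
    """Closed-form inverse of expected identity under the JC-type model.

    identity(t) = 1/20 + (19/20) * exp(-t / (19/20)) with t in expected
    substitutions per site.
    """
    if not (_BACKGROUND_IDENTITY < identity <= 1.0):
        raise ConfigError(f"identity {identity} outside ({_BACKGROUND_IDENTITY:.3f}, 1]")
    scale = 1.0 - _BACKGROUND_IDENTITY
    return -scale * np.log((identity - _BACKGROUND_IDENTITY) / scale)


def _substitution_probability(distance: float) -> float:
    scale = 1.0 - _BACKGROUND_IDENTITY
    return scale * (1.0 - np.exp(-distance / scale))


def _evolve(seq: np.ndarray, distance: float, mutable: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """One branch of JC-type evolution; only ``mutable`` sites may change."""
    out = seq.copy()
    q = _substitution_probability(distance)
    hit = (rng.random(seq.size) < q) & mutable
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, len(AA), size=n)) % len(AA)
    return out


def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, len(AA), size=length)


def _decode(seq: np.ndarray) -> str:
    return "".join(AA[i] for i in seq)


# ---------------------------------------------------------------------------
# random ultrametric family trees (Kingman-coalescent shape)
# ---------------------------------------------------------------------------

def _coalescent_tree(n_leaves: int, rng: np.random.Generator):
    """Random ultrametric bifurcating tree: (children, heights, root_id).

    Leaves are 0..n-1 at height 0; internal nodes coalesce pairs at
    exponentially spaced heights.
    """
    children: dict[int, tuple] = {i: () for i in range(n_leaves)}
    heights: dict[int, float] = {i: 0.0 for i in range(n_leaves)}
    lineages = list(range(n_leaves))
    t = 0.0
    nxt = n_leaves
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = lineages[i], lineages[j]
        children[nxt] = (a, b)
        heights[nxt] = t
        lineages = [x for x in lineages if x not in (a, b)]
        lineages.append(nxt)
        nxt += 1
    return children, heights, nxt - 1


def _leaf_sets(children, root):
    sets = {}

    def collect(node):
        if not children[node]:
            sets[node] = {node}
        else:
            a, b = children[node]
            collect(a)
            collect(b)
            sets[node] = sets[a] | sets[b]

    collect(root)
    return sets


def _mean_pair_distance(children, heights, root, n_leaves) -> float:
    sets = _leaf_sets(children, root)
    total = 0.0
    for node, kids in children.items():
        if kids:
            a, b = kids
            total += 2.0 * heights[node] * len(sets[a]) * len(sets[b])
    n_pairs = n_leaves * (n_leaves - 1) / 2
    return total / n_pairs


def _tree_newick(children, heights, root, leaf_names, scale) -> str:
    def render(node):
        if not children[node]:
            return leaf_names[node]
        a, b = children[node]
        la = (heights[node] - heights[a]) * scale
        lb = (heights[node] - heights[b]) * scale
        return f"({render(a)}:{la:.6f},{render(b)}:{lb:.6f})"

    return render(root) + ";"


# ---------------------------------------------------------------------------
# planted features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _PlantedLayout:
    """Family-fixed feature positions in ancestral core coordinates (1-based)."""

    fad_span: tuple[int, int]
    assoc_span: tuple[int, int]
    cat1: int
    cat2: int
    pts_span: tuple[int, int] | None

    def protected_intervals(self, exclude: str | None = None):
        out = []
        if exclude != "fad_motif":
            out.append(self.fad_span)
        if exclude != "assoc_motif":
            out.append(self.assoc_span)
        if exclude != "catalytic_pair":
            out.append((self.cat1, self.cat1))
            out.append((self.cat2, self.cat2))
        if self.pts_span:
            out.append(self.pts_span)
        return out


def _layout(length: int, family: int, pts: str | None) -> _PlantedLayout:
    fad_start = max(2, int(length * 0.05))
    assoc_start = int(length * 0.20)
    cat1 = int(length * 0.80)
    cat2 = int(length * 0.90)
    assoc_is_long = family % 2 == 1
    return _PlantedLayout(
        fad_span=(fad_start, fad_start + 5),
        assoc_span=(assoc_start, assoc_start + (5 if assoc_is_long else 4)),
        cat1=cat1,
        cat2=cat2,
        pts_span=(length - 2, length) if pts else None,
    )


def _plant(seq: np.ndarray, layout: _PlantedLayout, family: int) -> np.ndarray:
    """Write the family's motifs and catalytic pair into a core sequence."""
    out = seq.copy()

    def put(pos, text):
        for k, aa in enumerate(text):
            out[pos - 1 + k] = _AA_INDEX[aa]

    fad_variant = "GAS"[family % 3]
    put(layout.fad_span[0], f"GAGVM{fad_variant}")
    put(layout.assoc_span[0], "MGGGSE" if family % 2 == 1 else "LGGTS")
    put(layout.cat1, "H")
    put(layout.cat2, "N" if family % 2 == 1 else "H")
    return out


def _protected_mask(length: int, layout: _PlantedLayout) -> np.ndarray:
    mutable = np.ones(length, dtype=bool)
    for start, end in layout.protected_intervals():
        mutable[start - 1:end] = False
    return mutable


# ---------------------------------------------------------------------------
# indels
# ---------------------------------------------------------------------------

def _sample_indels(length: int, layout: _PlantedLayout,
                   rate: float, mean_length: float,
                   rng: np.random.Generator):
    """Per-leaf indels outside planted regions.

    Returns (deletions: set of core positions, insertions: {pos: text})
    where an insertion at ``pos`` goes between core positions pos and
    pos+1.  Positions strictly inside a planted span are never split.
    """
    protected = set()
    for start, end in layout.protected_intervals():
        protected.update(range(start, end + 1))
    inside = {p for start, end in layout.protected_intervals()
              for p in range(start, end)}  # insertion here would split a span
    deletions: set[int] = set()
    insertions: dict[int, str] = {}
    n_indels = rng.poisson(rate)
    p_geom = 1.0 / mean_length
    for _ in range(n_indels):
        size = min(int(rng.geometric(p_geom)), 20)
        is_deletion = rng.random() < 0.5
        for _attempt in range(50):
            if is_deletion:
                start = int(rng.integers(2, length - size))
                run = set(range(start, start + size))
                if run & protected or run & deletions:
                    continue
                deletions |= run
                break
            else:
                pos = int(rng.integers(1, length))
                if pos in inside or pos in insertions:
                    continue
                insertions[pos] = _decode(_random_sequence(size, rng))
                break
    return deletions, insertions


# ---------------------------------------------------------------------------
# motif disruption for planted-invalid sequences
# ---------------------------------------------------------------------------

def _disrupt_all(row: list[str], pattern, required_slots, protected_positions):
    """Mutate the row until its ungapped sequence has no ``pattern`` match.

    ``required_slots`` are the offsets within a match whose residue the
    pattern constrains; one unprotected slot per match is set to Pro, which
    belongs to no motif class and so can never create a new match.
    """
    for _round in range(100):
        nongap_cols = [c for c, ch in enumerate(row) if ch != GAP]
        seq = "".join(row[c] for c in nongap_cols)
        match = pattern.search(seq)
        if match is None:
            return
        start = match.start()  # 0-based in ungapped coords
        for slot in required_slots:
            pos1 = start + slot + 1
            if pos1 not in protected_positions and start + slot < len(seq):
                row[nongap_cols[start + slot]] = "P"
                break
        else:
            raise RuntimeError(
                "cannot disrupt motif occurrence overlapping planted features")
    raise RuntimeError("motif disruption did not converge")


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate_superfamily(config: SyntheticConfig) -> SimulationResult:
    """Generate the synthetic superfamily described by ``config``.

    Returns records, an annotation table keyed by id, and the full
    ground truth including per-family true alignments and trees.
    """
    rng = np.random.default_rng(config.seed)
    L = config.length
    t_within = identity_to_distance(config.within_family_identity)
    t_between = identity_to_distance(config.between_family_identity)

    root_core = _random_sequence(L, rng)

    records: list[SequenceRecord] = []
    annotations: dict[str, AnnotationRow] = {}
    seq_truth: dict[str, SequenceTruth] = {}
    families: list[FamilyTruth] = []

    for family in range(config.n_families):
        label = config.label(family)
        pts = config.pts(family)
        accessory = config.accessory(family)
        layout = _layout(L, family, pts)
        mutable = _protected_mask(L, layout)

        # --- family tree, scaled so mean pairwise distance == t_within
        children, heights, root = _coalescent_tree(config.seqs_per_family, rng)
        mean_raw = _mean_pair_distance(children, heights, root,
                                       config.seqs_per_family)
        scale = t_within / mean_raw
        depth = heights[root] * scale
        # root->family branch: cross-family leaf distance b_i + depth_i +
        # b_j + depth_j == t_between when b = t_between/2 - depth
        family_branch = max(0.0, (t_between / 2.0) - depth)

        ancestor = _plant(_evolve(root_core, family_branch, np.ones(L, bool), rng),
                          layout, family)

        # --- evolve down the tree
        node_seqs = {root: ancestor}
        stack = [root]
        while stack:
            node = stack.pop()
            for child in children[node]:
                branch = (heights[node] - heights[child]) * scale
                node_seqs[child] = _evolve(node_seqs[node], branch, mutable, rng)
                stack.append(child)

        leaf_names = {i: f"{label}_{i:03d}" for i in range(config.seqs_per_family)}
        member_ids = [leaf_names[i] for i in range(config.seqs_per_family)]
        newick = _tree_newick(children, heights, root, leaf_names, scale)

        core = {}
        for i in range(config.seqs_per_family):
            seq = node_seqs[i].copy()
            if pts:
                for k, aa in enumerate(pts):
                    seq[L - 3 + k] = _AA_INDEX[aa]
            core[i] = seq

        # --- per-leaf indels
        dels, ins = {}, {}
        for i in range(config.seqs_per_family):
            dels[i], ins[i] = _sample_indels(
                L, layout, config.indel_rate, config.indel_mean_length, rng)

        # --- signal peptides and accessory domain
        signal = rng.random(config.seqs_per_family) < config.signal_fraction
        any_signal = bool(signal.any())
        accessory_rows = None
        acc_status: dict[int, str] = {}
        if accessory is not None:
            anchor_mask = np.ones(ACCESSORY_LENGTH, dtype=bool)
            for pos in ACCESSORY_ANCHORS.values():
                anchor_mask[pos - 1] = False
            domain_ancestor = _random_sequence(ACCESSORY_LENGTH, rng)
            for name, expected in (("met", "M"), ("his", "H"),
                                   ("cys1", "C"), ("cys2", "C")):
                domain_ancestor[ACCESSORY_ANCHORS[name] - 1] = _AA_INDEX[expected]
            accessory_rows = {}
            for i in range(config.seqs_per_family):
                dom = _evolve(domain_ancestor, t_within / 2.0, anchor_mask, rng)
                # a "degenerate" family mixes intact and broken domains so
                # anchored detection stays possible and the truth table is
                # informative: odd-index members lose one anchor residue
                if accessory == "degenerate" and i % 2 == 1:
                    acc_status[i] = "degenerate"
                    name = list(ACCESSORY_ANCHORS)[
                        int(rng.integers(0, len(ACCESSORY_ANCHORS)))]
                    wanted = {"met": "M", "his": "H", "cys1": "C", "cys2": "C"}[name]
                    choices = [a for a in AA if a != wanted]
                    dom[ACCESSORY_ANCHORS[name] - 1] = _AA_INDEX[
                        choices[int(rng.integers(0, len(choices)))]]
                else:
                    acc_status[i] = "functional"
                accessory_rows[i] = _decode(dom)

        # --- true alignment layout: [signal][accessory][core w/ indel columns]
        ins_blocks = []  # (core_pos, owner_leaf, text)
        for pos in range(0, L + 1):
            for i in range(config.seqs_per_family):
                if pos in ins[i]:
                    ins_blocks.append((pos, i, ins[i][pos]))

        col_of_core = {}  # ancestral core position -> 0-based core-block column
        core_cols = []
        cursor = 0
        block_iter = 0
        for pos in range(0, L + 1):
            if pos >= 1:
                col_of_core[pos] = cursor
                core_cols.append(("core", pos, None))
                cursor += 1
            # insertion at pos goes between core positions pos and pos+1
            while (block_iter < len(ins_blocks)
                   and ins_blocks[block_iter][0] == pos):
                _, owner, text = ins_blocks[block_iter]
                core_cols.append(("ins", owner, text))
                cursor += len(text)
                block_iter += 1

        prefix_signal = len(SIGNAL_PEPTIDE) if any_signal else 0
        prefix_accessory = ACCESSORY_LENGTH if accessory is not None else 0

        rows = []
        for i in range(config.seqs_per_family):
            parts = []
            if any_signal:
                parts.append(SIGNAL_PEPTIDE if signal[i] else GAP * len(SIGNAL_PEPTIDE))
            if accessory is not None:
                parts.append(accessory_rows[i])
            decoded = _decode(core[i])
            for kind, a, b in core_cols:
                if kind == "ins":
                    parts.append(b if a == i else GAP * len(b))
                else:
                    parts.append(GAP if a in dels[i] else decoded[a - 1])
            rows.append(list("".join(parts)))

        def final_position(row, core_pos):
            """1-based position of an ancestral core residue in the final sequence."""
            col = prefix_signal + prefix_accessory + col_of_core[core_pos]
            return sum(1 for ch in row[:col + 1] if ch != GAP)

        # --- planted-invalid sequences
        n_invalid = config.n_invalid_per_family
        invalid_leaves = sorted(
            int(x) for x in rng.choice(config.seqs_per_family,
                                       size=n_invalid, replace=False))
        broken = {leaf: PROPERTIES[int(rng.integers(0, len(PROPERTIES)))]
                  for leaf in invalid_leaves}

        for i in range(config.seqs_per_family):
            row = rows[i]
            prop = broken.get(i)
            if prop is None:
                continue
            protected = set()
            for start, end in layout.protected_intervals(exclude=prop):
                for p in range(start, end + 1):
                    protected.add(final_position(row, p))
            if accessory is not None:
                for pos in ACCESSORY_ANCHORS.values():
                    col = prefix_signal + pos - 1
                    protected.add(sum(1 for ch in row[:col + 1] if ch != GAP))
            if prop == "catalytic_pair":
                col = prefix_signal + prefix_accessory + col_of_core[layout.cat1]
                row[col] = "A"
            elif prop == "fad_motif":
                _disrupt_all(row, FAD_RE, (0, 2, 5), protected)
            else:
                _disrupt_all(row, ASSOC_RE, (0, 1), protected)

        # --- emit records, truth, annotations
        alignment = Msa(ids=member_ids, rows=["".join(r) for r in rows])
        phylum = "Ascomycota" if family % 2 == 0 else "Basidiomycota"
        orders = (["Eurotiales", "Helotiales"] if phylum == "Ascomycota"
                  else ["Polyporales", "Agaricales"])

        for i in range(config.seqs_per_family):
            sid = leaf_names[i]
            row = rows[i]
            residues = "".join(ch for ch in row if ch != GAP)
            prop = broken.get(i)
            cat_pos = (final_position(row, layout.cat1),
                       final_position(row, layout.cat2))
            anchor_positions = None
            if accessory is not None:
                anchor_positions = {}
                for name, pos in ACCESSORY_ANCHORS.items():
                    col = prefix_signal + pos - 1
                    anchor_positions[name] = sum(
                        1 for ch in row[:col + 1] if ch != GAP)
            seq_truth[sid] = SequenceTruth(
                id=sid,
                family=family,
                family_label=label,
                valid=prop is None,
                broken_property=prop,
                fad_start=(None if prop == "fad_motif"
                           else final_position(row, layout.fad_span[0])),
                assoc_start=(None if prop == "assoc_motif"
                             else final_position(row, layout.assoc_span[0])),
                catalytic_positions=None if prop == "catalytic_pair" else cat_pos,
                signal=bool(signal[i]),
                pts=pts,
                accessory=acc_status.get(i),
                accessory_anchor_positions=anchor_positions,
            )
            records.append(SequenceRecord(id=sid, residues=residues,
                                          description=f"synthetic {label}"))
            spans = []
            if accessory is not None:
                dstart = (len(SIGNAL_PEPTIDE) if signal[i] else 0) + 1
                spans.append(("Cyt", dstart, dstart + ACCESSORY_LENGTH - 1))
                spans.append(("GMC", dstart + ACCESSORY_LENGTH, len(residues)))
            exon = int(rng.integers(1, 4)) if phylum == "Ascomycota" \
                else int(rng.integers(3, 9))
            annotations[sid] = AnnotationRow(
                id=sid,
                function_label=label if i in _seed_indices(broken, config) else None,
                phylum=phylum,
                order=orders[int(rng.integers(0, 2))],
                signal_flag=bool(signal[i]),
                exon_count=None if rng.random() < 0.05 else exon,
                domain_spans=tuple(spans),
            )

        valid_sorted = [m for m in sorted(member_ids)
                        if seq_truth[m].valid]
        if not valid_sorted:
            raise ConfigError(
                f"family {label!r} has no valid sequences to anchor on; "
                "lower invalid_fraction")
        accessory_reference = None
        if accessory is not None:
            accessory_reference = next(
                m for m in sorted(member_ids)
                if seq_truth[m].accessory == "functional")
        families.append(FamilyTruth(
            family=family,
            label=label,
            member_ids=member_ids,
            ancestor_core=_decode(ancestor),
            tree_newick=newick,
            alignment=alignment,
            catalytic_reference=valid_sorted[0],
            accessory_reference=accessory_reference,
        ))

    truth = SyntheticTruth(config=config, sequences=seq_truth, families=families)
    return SimulationResult(records=records, annotations=annotations, truth=truth)


def _seed_indices(broken: dict, config: SyntheticConfig) -> set[int]:
    """Indices of the annotated 'characterised seed' sequences per family:
    the first two valid leaves."""
    out = []
    for i in range(config.seqs_per_family):
        if i not in broken:
            out.append(i)
        if len(out) == 2:
            break
    return set(out)


# ---------------------------------------------------------------------------
# scoring against truth
# ---------------------------------------------------------------------------

def compare_clusters(clusters, truth: SyntheticTruth) -> float:
    """Adjusted Rand index of a clustering against the planted families.

    ``clusters`` is a list of objects with a ``members`` id set (the
    ClusterAssignment of the network module) or a list of id sets.
    """
    from sklearn.metrics import adjusted_rand_score

    predicted: dict[str, int] = {}
    for k, cluster in enumerate(clusters):
        members = getattr(cluster, "members", cluster)
        for sid in members:
            predicted[sid] = k
    true_map = truth.family_assignment()
    if set(predicted) != set(true_map):
        raise ValueError("clustering and truth cover different id sets")
    ids = sorted(true_map)
    return float(adjusted_rand_score(
        [true_map[i] for i in ids], [predicted[i] for i in ids]))


def compare_filter(report, truth: SyntheticTruth,
                   ids=None) -> tuple[float, float]:
    """Precision and recall of invalidity detection (positive = removed)."""
    universe = set(ids) if ids is not None else set(report.kept) | set(report.removed)
    if not universe <= set(truth.sequences):
        raise ValueError("filter report contains ids unknown to the truth")
    removed = set(report.removed) & universe
    true_invalid = truth.invalid_ids() & universe
    tp = len(removed & true_invalid)
    precision = tp / len(removed) if removed else 1.0
    recall = tp / len(true_invalid) if true_invalid else 1.0
    return precision, recall


def truth_compare(result, truth: SyntheticTruth):
    """Dispatch: clustering -> ARI; filter report -> (precision, recall)."""
    if hasattr(result, "kept") and hasattr(result, "removed"):
        return compare_filter(result, truth)
    return compare_clusters(result, truth)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_truth_json(truth: SyntheticTruth, path) -> None:
    payload = {
        "config": asdict(truth.config),
        "sequences": {sid: asdict(s) for sid, s in truth.sequences.items()},
        "families": [
            {
                "family": f.family,
                "label": f.label,
                "member_ids": f.member_ids,
                "ancestor_core": f.ancestor_core,
                "tree_newick": f.tree_newick,
                "catalytic_reference": f.catalytic_reference,
                "accessory_reference": f.accessory_reference,
            }
            for f in truth.families
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
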