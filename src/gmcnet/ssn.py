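"""Sequence similarity networks for superfamily clustering.

Nodes are sequences, edges are pairwise local-alignment similarities that
pass an E-value stringency expressed as an exponent x (edge kept iff
E <= 10^-x), the "alignment score cut-off" convention of EFI-EST-style
tools.  Sweeping the exponent from permissive to stringent makes a
superfamily break apart into functional subfamilies, read off as connected
components.

Scoring: BLOSUM62 local alignment (gap open 11, extend 1), Karlin-Altschul
bit score S' = (lambda*S - ln K)/ln 2 with the classical ungapped constants
lambda = 0.267, K = 0.041 applied to the gapped score, and
E = m * N * 2^-S' where m is the query length and N the total residue count
of the sequence set.  These are recorded in the network metadata; only the
network-level behaviour (thresholding, components, annotation) is
contractual, not any external tool's exact bit scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
from Bio.Align import PairwiseAligner, substitution_matrices

from .seqio import SequenceRecord

EVALUE_FLOOR = 1e-180  # avoids log underflow; preserves ordering at all sweep exponents


@dataclass(frozen=True)
class ScoringParams:
    """Local-alignment scoring and Karlin-Altschul statistics."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041


@dataclass(frozen=True)
class NetworkEdge:
    """Unordered similarity edge (a < b lexicographically)."""

    a: str
    b: str
    bit_score: float
    evalue: float
    percent_identity: float
    alignment_score: float  # -log10(evalue), the sweep stringency axis

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError("self-loops are not allowed")
        if self.a > self.b:
            raise ValueError("edge endpoints must satisfy a < b")


@dataclass
class SimilarityNetwork:
    nodes: set[str]
    edges: list[NetworkEdge]
    cutoff_exponent: float
    scoring: ScoringParams = field(default_factory=ScoringParams)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for e in self.edges:
            g.add_edge(
                e.a, e.b,
                bit_score=e.bit_score, evalue=e.evalue,
                percent_identity=e.percent_identity,
                alignment_score=e.alignment_score,
            )
        return g


@dataclass
class ClusterAssignment:
    cluster_id: int
    members: set[str]
    label: str = "unannotated"


def _local_aligner(scoring: ScoringParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def edge_from_raw_score(
    a: str, b: str, raw_score: float, query_length: int,
    search_space: float, percent_identity: float,
    scoring: ScoringParams = ScoringParams(),
) -> NetworkEdge:
    """Build an edge from a raw local-alignment score via Karlin-Altschul."""
    bit = (scoring.karlin_lambda * raw_score - math.log(scoring.karlin_k)) / math.log(2)
    evalue = query_length * search_space * 2.0 ** (-bit)
    evalue = max(evalue, EVALUE_FLOOR)
    a, b = (a, b) if a < b else (b, a)
    return NetworkEdge(
        a=a, b=b, bit_score=bit, evalue=evalue,
        percent_identity=percent_identity,
        alignment_score=-math.log10(evalue),
    )


def pairwise_score(
    a: SequenceRecord, b: SequenceRecord,
    scoring: ScoringParams = ScoringParams(),
    search_space: float | None = None,
) -> NetworkEdge:
    """Score one sequence pair: local alignment, bit score, E-value, %identity.

    One alignment is computed per unordered pair, with the longer sequence as
    query (ties broken by id), so the result is symmetric in its arguments by
    construction.  ``search_space`` defaults to the summed length of the two
    sequences; network builders pass the total residue count of the set.
    """
    if a.length == 0 or b.length == 0:
        raise ValueError("cannot score a zero-length sequence")
    if a.id == b.id:
        raise ValueError("self-comparison is not a network edge")
    query, subject = (a, b) if (-a.length, a.id) <= (-b.length, b.id) else (b, a)
    if search_space is None:
        search_space = a.length + b.length
    aligner = _local_aligner(scoring)
    alignment = aligner.align(query.residues, subject.residues)[0]
    top, bottom = str(alignment[0]), str(alignment[1])
    ncols = len(top)
    matches = sum(x == y and x != "-" for x, y in zip(top, bottom))
    pid = 100.0 * matches / ncols if ncols else 0.0
    return edge_from_raw_score(
        a.id, b.id, float(alignment.score), query.length,
        search_space, pid, scoring,
    )


def all_pairs_edges(
    records, scoring: ScoringParams = ScoringParams()
) -> list[NetworkEdge]:
    """Score every unordered pair against the whole-set search space."""
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 records to build a network")
    total_residues = sum(r.length for r in records)
    edges = []
    for i, a in enumerate(records):
        for b in records[i + 1:]:
            edges.append(pairwise_score(a, b, scoring, search_space=total_residues))
    return edges


def threshold_edges(edges, cutoff_exponent: float) -> list[NetworkEdge]:
    return [e for e in edges if e.evalue <= 10.0 ** (-cutoff_exponent)]


def build_network(
    records, cutoff_exponent: float,
    scoring: ScoringParams = ScoringParams(),
    edges: list[NetworkEdge] | None = None,
) -> SimilarityNetwork:
    """All-vs-all network at one E-value stringency; isolated nodes included.

    Precomputed ``edges`` (from :func:`all_pairs_edges`) can be supplied to
    re-threshold without re-aligning.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 records to build a network")
    if edges is None:
        edges = all_pairs_edges(records, scoring)
    return SimilarityNetwork(
        nodes={r.id for r in records},
        edges=threshold_edges(edges, cutoff_exponent),
        cutoff_exponent=cutoff_exponent,
        scoring=scoring,
    )


def connected_components(network: SimilarityNetwork) -> list[ClusterAssignment]:
    """Connected components, numbered by decreasing size then smallest member id."""
    comps = list(nx.connected_components(network.to_networkx()))
    comps.sort(key=lambda c: (-len(c), min(c)))
    return [
        ClusterAssignment(cluster_id=i, members=set(c))
        for i, c in enumerate(comps)
    ]


def sweep_cutoffs(
    network: SimilarityNetwork,
    start_exponent: float = 85,
    end_exponent: float = 140,
    step: float = 5,
) -> list[tuple[float, list[ClusterAssignment]]]:
    """Cluster snapshots along increasingly stringent cut-offs.

    ``network`` must be built at the minimum stringency (``start_exponent``);
    each snapshot keeps only edges passing the tightened cut-off, so edges
    shrink and the component count is non-decreasing along the sweep.
    """
    if start_exponent > end_exponent:
        raise ValueError("start_exponent must be <= end_exponent")
    if step <= 0:
        raise ValueError("step must be positive")
    snapshots = []
    exponent = start_exponent
    while exponent <= end_exponent + 1e-9:
        sub = SimilarityNetwork(
            nodes=set(network.nodes),
            edges=threshold_edges(network.edges, exponent),
            cutoff_exponent=exponent,
            scoring=network.scoring,
        )
        snapshots.append((exponent, connected_components(sub)))
        exponent += step
    return snapshots


def annotate_clusters(clusters, annotations) -> list[ClusterAssignment]:
    """Label clusters from their annotated seed members.

    Label is the sole function among members; several distinct functions are
    joined with an en dash in order of first appearance over members sorted
    by id (e.g. "GOx–GDH"); clusters without any labelled member are
    "unannotated".
    """
    labelled = []
    for cluster in clusters:
        functions: list[str] = []
        for member in sorted(cluster.members):
            ann = annotations.get(member)
            if ann is not None and ann.function_label:
                if ann.function_label not in functions:
                    functions.append(ann.function_label)
        label = "–".join(functions) if functions else "unannotated"
        labelled.append(ClusterAssignment(cluster.cluster_id, set(cluster.members), label))
    return labelled


# ---------------------------------------------------------------------------
# import/export
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ["a", "b", "bit_score", "evalue", "alignment_score", "percent_identity"]


def write_edge_list(network: SimilarityNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for e in sorted(network.edges, key=lambda e: (e.a, e.b)):
            fh.write(
                f"{e.a}\t{e.b}\t{e.bit_score:.6f}\t{e.evalue:.6e}"
                f"\t{e.alignment_score:.6f}\t{e.percent_identity:.6f}\n"
            )


def write_graphml(network: SimilarityNetwork, path, annotations=None) -> None:
    g = network.to_networkx()
    g.graph["cutoff_exponent"] = network.cutoff_exponent
    g.graph["scoring"] = (
        f"{network.scoring.matrix} open={network.scoring.gap_open}"
        f" extend={network.scoring.gap_extend}"
        f" lambda={network.scoring.karlin_lambda} K={network.scoring.karlin_k}"
    )
    if annotations:
        for node in g.nodes:
            ann = annotations.get(node)
            if ann is not None:
                if ann.function_label:
                    g.nodes[node]["function_label"] = ann.function_label
                if ann.phylum:
                    g.nodes[node]["phylum"] = ann.phylum
    nx.write_graphml(g, path)


def read_graphml(path) -> SimilarityNetwork:
    g = nx.read_graphml(path)
    edges = [
        NetworkEdge(
            a=min(u, v), b=max(u, v),
            bit_score=float(d["bit_score"]), evalue=float(d["evalue"]),
            percent_identity=float(d["percent_identity"]),
            alignment_score=float(d["alignment_score"]),
        )
        for u, v, d in g.edges(data=True)
    ]
    return SimilarityNetwork(
        nodes=set(g.nodes),
        edges=edges,
        cutoff_exponent=float(g.graph.get("cutoff_exponent", 0.0)),
    )
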