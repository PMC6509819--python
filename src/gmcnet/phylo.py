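"""Tree handling and clade-level statistics.

Trees come in as plain Newick (leaf labels = sequence ids, branch lengths);
midpoint rooting places the root halfway along the longest leaf-to-leaf
path.  Clades are operationalised as the MRCA-spanning leaf set of
characterised reference sequences, with an explicit-member override for
manually curated clades.  The clade conservation statistic is the mean
percent identity over all sequence pairs of the clade, computed on the
existing cluster alignment without realigning and excluding every column
where one or both sequences of a pair carry a gap.

A neighbor-joining constructor from a distance matrix is provided as
plumbing for desk-scale work; maximum-likelihood inference is consumed as
input, never computed here.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np

from .msa import GAP, Msa

_EPS = 1e-12


def read_newick(source) -> dendropy.Tree:
    """Read a Newick tree from a path or string (underscores kept literal)."""
    text = str(source)
    if "(" in text and ";" in text:
        return dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    return dendropy.Tree.get(path=text, schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path=None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _check_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            raise ValueError("tree has missing branch lengths")
        if edge.length < 0:
            raise ValueError("tree has negative branch lengths")


def _leaf_distances_from(leaf) -> dict:
    """Patristic distance from one leaf to every leaf, by edge traversal."""
    dist = {leaf: 0.0}
    stack = [(leaf, None)]
    while stack:
        node, came_from = stack.pop()
        neighbours = list(node.child_nodes())
        if node.parent_node is not None:
            neighbours.append(node.parent_node)
        for nb in neighbours:
            if nb is came_from:
                continue
            edge_len = node.edge.length if nb is node.parent_node else nb.edge.length
            if nb not in dist:
                dist[nb] = dist[node] + (edge_len or 0.0)
                stack.append((nb, node))
    return dist


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    The two farthest leaves end up equidistant from the root (to 1e-9).
    Ties between equally long paths are broken deterministically by the
    lexicographically smallest (label, label) pair.  When the midpoint falls
    exactly on an existing node, that node becomes the root (no zero-length
    dummy edge is introduced).
    """
    tree = tree.clone(depth=1)
    leaves = sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    _check_branch_lengths(tree)

    best = None  # (distance, labelA, labelB, leafA, leafB)
    for la in leaves:
        dist = _leaf_distances_from(la)
        for lb in leaves:
            if lb.taxon.label <= la.taxon.label:
                continue
            d = dist[lb]
            key = (-d, la.taxon.label, lb.taxon.label)
            if best is None or key < best[0]:
                best = (key, la, lb, d)
    _, leaf_a, leaf_b, diameter = best
    target = diameter / 2.0

    # node path leaf_a .. mrca .. leaf_b
    ancestors_a = [leaf_a]
    node = leaf_a
    while node.parent_node is not None:
        node = node.parent_node
        ancestors_a.append(node)
    seen = {id(n): i for i, n in enumerate(ancestors_a)}
    path_b = [leaf_b]
    node = leaf_b
    while id(node) not in seen:
        node = node.parent_node
        path_b.append(node)
    mrca_index = seen[id(node)]
    path = ancestors_a[:mrca_index + 1] + list(reversed(path_b[:-1]))

    cum = 0.0
    for here, there in zip(path, path[1:]):
        ascending = there is here.parent_node
        edge = here.edge if ascending else there.edge
        length = edge.length or 0.0
        if cum + length >= target - _EPS:
            into_edge = target - cum  # distance from `here` end of the edge
            if into_edge <= _EPS and not here.is_leaf():
                tree.reroot_at_node(here, suppress_unifurcations=True)
            elif length - into_edge <= _EPS and not there.is_leaf():
                tree.reroot_at_node(there, suppress_unifurcations=True)
            else:
                if ascending:  # edge.head_node is `here`
                    length1, length2 = length - into_edge, into_edge
                else:  # edge.head_node is `there`
                    length1, length2 = into_edge, length - into_edge
                tree.reroot_at_edge(edge, length1=length1, length2=length2,
                                    suppress_unifurcations=True)
            break
        cum += length
    return tree


def root_to_leaf_distances(tree: dendropy.Tree) -> dict[str, float]:
    out = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label] = d
    return out


def patristic_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Leaf-pair path distances keyed by sorted label pairs."""
    out = {}
    leaves = list(tree.leaf_node_iter())
    for la in leaves:
        dist = _leaf_distances_from(la)
        for lb in leaves:
            if lb.taxon.label > la.taxon.label:
                out[(la.taxon.label, lb.taxon.label)] = dist[lb]
    return out


def nj_tree(distance_matrix, labels) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative branch-length estimates are clamped to zero.  The result is
    returned as an (arbitrarily rooted) dendropy tree; combine with
    :func:`midpoint_root` for display.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    matrix = np.asarray(distance_matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("distance matrix must be square")
    if matrix.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(matrix), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    skb = nj(DistanceMatrix(matrix, ids=list(labels)))
    newick = io.StringIO()
    skb.write(newick, format="newick")
    tree = dendropy.Tree.get(data=newick.getvalue(), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# clades
# ---------------------------------------------------------------------------

@dataclass
class CladeDefinition:
    name: str
    reference_ids: tuple[str, ...]
    assigned_members: set[str] = field(default_factory=set)


class CladeConflictError(ValueError):
    """Two clades' MRCA-spanned leaf sets overlap."""


def assign_clades(tree: dendropy.Tree, definitions) -> list[CladeDefinition]:
    """Fill each clade with the leaf set of its references' MRCA.

    ``definitions`` maps clade name -> iterable of reference leaf labels, or
    is a list of :class:`CladeDefinition`.  An explicit-member override is
    supported by passing a definition whose ``assigned_members`` is already
    nonempty; it is used verbatim (still checked for disjointness).
    """
    if isinstance(definitions, dict):
        definitions = [
            CladeDefinition(name=k, reference_ids=tuple(v))
            for k, v in definitions.items()
        ]
    # clade = subtree below a node, which presupposes a rooted reading
    tree.is_rooted = True
    labels = set(leaf_labels(tree))
    filled = []
    for definition in definitions:
        if definition.assigned_members:
            members = set(definition.assigned_members)
        else:
            refs = sorted(definition.reference_ids)
            if not refs:
                raise ValueError(f"clade {definition.name!r} has no references")
            missing = [r for r in refs if r not in labels]
            if missing:
                raise ValueError(
                    f"clade {definition.name!r} references absent from tree: {missing}")
            if len(refs) == 1:
                members = {refs[0]}
            else:
                mrca = tree.mrca(taxon_labels=refs)
                members = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        filled.append(CladeDefinition(
            name=definition.name,
            reference_ids=tuple(sorted(definition.reference_ids)),
            assigned_members=members,
        ))
    for a, b in combinations(filled, 2):
        overlap = a.assigned_members & b.assigned_members
        if overlap:
            raise CladeConflictError(
                f"clades {a.name!r} and {b.name!r} overlap on leaves "
                f"{sorted(overlap)}"
            )
    return filled


def pairwise_identity_gap_excluded(row_a: str, row_b: str) -> float:
    """Percent identity of two aligned rows over mutually non-gap columns."""
    a = np.frombuffer(row_a.encode(), dtype="S1")
    b = np.frombuffer(row_b.encode(), dtype="S1")
    gap = GAP.encode()
    both = (a != gap) & (b != gap)
    n = int(both.sum())
    if n == 0:
        raise ValueError("sequence pair shares no mutually non-gap columns")
    return 100.0 * float((a[both] == b[both]).sum()) / n


def mean_percent_identity(msa: Msa, member_ids) -> float:
    """Clade conservation: mean pairwise identity, gap columns excluded.

    For every unordered member pair, identity = identical columns / columns
    where both rows are non-gap (x100); the mean is over all pairs.  The
    alignment is used as supplied, never recomputed.
    """
    member_ids = list(member_ids)
    if len(member_ids) < 2:
        raise ValueError("mean_percent_identity needs at least 2 members")
    rows = {m: msa.row(m) for m in member_ids}
    total = 0.0
    n_pairs = 0
    for a, b in combinations(member_ids, 2):
        try:
            total += pairwise_identity_gap_excluded(rows[a], rows[b])
        except ValueError as exc:
            raise ValueError(f"pair ({a!r}, {b!r}): {exc}") from None
        n_pairs += 1
    return total / n_pairs


@dataclass
class CladeProfile:
    """Per-clade summary mirroring the per-tree property tables."""

    name: str
    size: int
    mean_percent_identity: float
    taxonomy_tally: dict[str, Counter]
    signal_fraction: float | None
    mean_exons: float | None
    single_exon_fraction: float | None
    effective_n: dict[str, int] = field(default_factory=dict)


def clade_profile(msa: Msa, annotations, clade: CladeDefinition) -> CladeProfile:
    """Aggregate clade statistics; unknown annotation values never enter
    denominators, and the effective n per statistic is reported."""
    members = sorted(clade.assigned_members)
    if not members:
        raise ValueError(f"clade {clade.name!r} is empty")
    if len(members) < 2:
        raise ValueError(
            f"clade {clade.name!r} has a single member; profile undefined")
    mpi = mean_percent_identity(msa, members)

    phyla = Counter()
    orders = Counter()
    signals = []
    exons = []
    for m in members:
        ann = annotations.get(m)
        if ann is None:
            continue
        if ann.phylum:
            phyla[ann.phylum] += 1
        if ann.order:
            orders[ann.order] += 1
        if ann.signal_flag is not None:
            signals.append(ann.signal_flag)
        if ann.exon_count is not None:
            exons.append(ann.exon_count)
    return CladeProfile(
        name=clade.name,
        size=len(members),
        mean_percent_identity=mpi,
        taxonomy_tally={"phylum": phyla, "order": orders},
        signal_fraction=(sum(signals) / len(signals)) if signals else None,
        mean_exons=(sum(exons) / len(exons)) if exons else None,
        single_exon_fraction=(
            sum(e == 1 for e in exons) / len(exons)) if exons else None,
        effective_n={
            "signal": len(signals),
            "exons": len(exons),
            "phylum": sum(phyla.values()),
            "order": sum(orders.values()),
        },
    )


def write_profiles(profiles, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "clade\tn\tmean_pct_id\tsignal_fraction\tmean_exons"
            "\tsingle_exon_fraction\tphyla\torders\n"
        )
        for p in profiles:
            phyla = ";".join(f"{k}:{v}" for k, v in sorted(p.taxonomy_tally["phylum"].items()))
            orders = ";".join(f"{k}:{v}" for k, v in sorted(p.taxonomy_tally["order"].items()))
            sig = "" if p.signal_fraction is None else f"{p.signal_fraction:.4f}"
            mex = "" if p.mean_exons is None else f"{p.mean_exons:.4f}"
            sef = "" if p.single_exon_fraction is None else f"{p.single_exon_fraction:.4f}"
            fh.write(
                f"{p.name}\t{p.size}\t{p.mean_percent_identity:.4f}"
                f"\t{sig}\t{mex}\t{sef}\t{phyla}\t{orders}\n"
            )
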