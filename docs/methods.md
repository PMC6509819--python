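# Methods

This note documents the models and numerical choices behind `gmcnet`, in
the order the pipeline runs them.

## Sequence store and dereplication

Sequences with ambiguous residues (B, J, O, U, X, Z) or fewer than 450
residues are removed before any analysis; 450 aa is the conventional lower
bound for a complete GMC fold. Dereplication is greedy incremental
clustering at a global-alignment identity threshold (default 0.99):
records are processed longest-first (ties broken by id), each joins the
first representative it matches at or above the threshold, otherwise it
founds a new one. Identity is counted as identical aligned residues
divided by the length of the shorter sequence — the CD-HIT denominator
convention — on a BLOSUM62 global alignment (gap open 11, extend 1). The
denominator convention is recorded in the result object so alternative
conventions can be compared; with a different denominator the same greedy
order can yield different representative sets.

## Similarity network scoring

The network treats the pairwise stringency as an E-value exponent: an
edge survives cut-off x iff E ≤ 10^(−x). E-values come from the
Karlin–Altschul frame applied to gapped BLOSUM62 local alignments
(gap open 11, extend 1): S′ = (λS − ln K)/ln 2 with the classical
ungapped constants λ = 0.267 and K = 0.041, and E = m·N·2^(−S′) with m the
query length and N the summed residue count of the input set. Applying
ungapped constants to gapped scores slightly overestimates bit scores,
which is acceptable here because only the *ordering* of pairs and their
position relative to the sweep window matter, not agreement with any
external tool's absolute values. One alignment is computed per unordered
pair (longer sequence as query, ties by id), making the score symmetric by
construction. E-values are floored at 1e−180 before taking −log10 so the
stringency axis stays finite; the floor sits well above double underflow
and beyond the deepest sweep exponent used (140). Components are numbered
by decreasing size, then smallest member id. Cluster labels join the
distinct seed function labels with an en dash in order of first appearance
over members sorted by id.

## Validity filter

The two contiguous motifs are scanned on unaligned residues with
exact-class regular expressions reported at every (possibly overlapping)
occurrence: `G x G x x [GAS]` for the Rossmann FAD-binding element and
`h G G p p` / `h G G G p p` for the FAD-associated motif. The residue
classes are a deliberate parameter of the analysis: h = {A,C,F,I,L,M,V,W,Y},
p = {D,E,H,K,N,Q,R,S,T}, with glycine in neither class (it is the motif
scaffold itself). A sequence passes a motif property if the motif occurs
anywhere; no positional restriction is imposed. The catalytic His/His-or-
His/Asn pair is conserved in alignment space, not at absolute coordinates,
so it is detected at the alignment columns carrying the two catalytic
residues of a characterised reference row; the default column tolerance is
0, and a window of ±k columns can be searched for imperfect alignments.
Anchoring fails loudly if the reference lacks His at the first anchor.

## Alignment post-processing

Alignments are consumed from files (or from the bundled `mafft` wrapper);
the package never re-implements an aligner. Gap-column trimming removes a
column when its gap fraction (over all rows) strictly exceeds the
threshold — 0.99 by default, 0.95 recommended for clusters of under ~30
sequences where a single gap is a large fraction. Block selection follows
the Gblocks "less stringent" idea with declared numeric defaults, since
the preset's exact numbers are tool-version dependent: a column is a
candidate iff its gap fraction is ≤ 0.5 ("with half") and its most
frequent residue covers ≥ 0.50 of the non-gap rows; block ends must reach
0.55; candidate runs shorter than 5 columns are rejected. Gap fractions
use all rows as denominator, conservation fractions use non-gap rows; both
conventions are recorded in the selection's parameter block. Domain
windowing restricts the alignment to
[column(FAD motif start) − 6, column(catalytic Asn) + 18], clamped to the
alignment, which isolates the GMC dehydrogenase domain of multidomain
enzymes such as CDH. All column intervals are 1-based inclusive, and all
user-facing residue positions are 1-based ("His103"-style numbering).

## Trees, clades, conservation

Midpoint rooting places the root halfway along the longest leaf-to-leaf
path; ties between equally long paths are broken by the lexicographically
smallest label pair, and a midpoint falling exactly on a node makes that
node the root rather than introducing a zero-length edge. Neighbor
joining (via scikit-bio, negative branch estimates clamped to zero) is
desk-scale plumbing for simulated or small distance matrices; maximum
likelihood trees are consumed as Newick input, never inferred. Clades are
operationalised as the leaf set spanned by the MRCA of named reference
sequences, because published clade boundaries are manual; overlapping
spans raise an error, and an explicit-member override reproduces curated
clades exactly. The conservation statistic is the mean over all member
pairs of percent identity computed only on columns where both rows are
non-gap ("one or both" gapped columns excluded); a pair with no mutually
ungapped column is an error rather than a silent zero. Profile aggregates
(signal fraction, exon statistics, taxonomy tallies) never let unknown
values enter a denominator and report the effective n per statistic.

## Position-frequency matrices

PFMs count residues per alignment column or per C-terminal offset
(−n…−1, with −1 the last residue); sequences shorter than the window
contribute only the offsets they reach. Gaps are excluded from counts and
from the effective n, and reported as a separate gap fraction. Logo
heights use information content IC = log2(20) − H(p) in bits with no
small-sample correction — intended use is hundreds of sequences per clade,
where the correction is negligible; for very small n the IC is optimistic.
The PTS report is the modal residue per offset (consensus tripeptide).
The cytochrome-domain check declares a domain functional iff the anchored
columns of the reference's axial Met, axial His and two disulfide Cys
residues carry M, H, C, C; a gap at an anchored column fails that flag.

## Synthetic superfamily generator

The generator exists to give every pipeline stage a ground truth, not to
imitate real GMC composition. Families descend from a shared random root
ancestor: each family evolves along its own random coalescent-shaped
ultrametric bifurcating tree under a 20-state Jukes–Cantor-type process
(uniform exchangeability), in which expected identity after distance t is
1/20 + (19/20)·exp(−t/(19/20)). This closed form is inverted to calibrate
branch scaling: family trees are rescaled so the mean pairwise leaf
distance equals t(within-identity), and the root-to-family branches are
set so cross-family leaf distance equals t(between-identity). Defaults —
5 families × 30 sequences, length 550, within-family identity 0.70,
between 0.25 — give clear but not trivial network separation: ~70%
identity is typical within a functional GMC subfamily, ~25% is typical
between subfamilies sharing only the fold. Realised within-family
identity runs 2–7 points above target because planted regions are
invariant and identity is convex in distance; the tests assert the
[60, 80]% band rather than the point target.

Planted features: one GxGxx[GAS] motif (variant rotating per family), one
hGGpp or hGGGpp motif (alternating), and a His + His/Asn pair at
family-fixed relative positions, all shielded from substitutions and
indels. Indels are Poisson per sequence (mean 1), geometric length
(mean 2, capped at 20), deletions and insertions equally likely, never
inside or splitting a planted span; the generator tracks them and emits
the true per-family alignment. Optional per-sequence 18-residue signal
peptides (glycine-free, so they can never host either motif), per-family
C-terminal PTS tripeptides, and a 120-residue accessory cytochrome-like
domain with M/H/C/C anchors — intact in a "functional" family, broken in
every odd-indexed member of a "degenerate" family so anchored detection
remains possible and the truth table is informative.

A configured fraction of sequences per family (count =
round-half-to-even of fraction × family size) is made invalid by breaking
exactly one property: the catalytic His is substituted, or every
occurrence of the targeted motif — planted and chance alike, anywhere in
the assembled sequence — is disrupted by mutating one constrained motif
position to proline, which belongs to no motif class and therefore cannot
create new matches. This guarantees the validity filter can achieve exact
precision and recall against the truth, which is what the end-to-end
tests assert.

What the generator does **not** emulate: real amino-acid composition and
exchangeability (substitutions are uniform), rate heterogeneity across
sites, domain-level rearrangements, alignment error (the emitted
alignment is exact), or genomic context (exon counts and taxonomy are
synthesized annotation values only). Passing tests therefore demonstrate
the pipeline's correctness on data whose structure is known, not its
robustness to aligner artefacts or compositional bias in real data.

## Problem sizes and determinism

The test suite and the acceptance script run the generator's default
conditions (150 sequences of ~550–700 aa; 11,175 alignments for the
all-vs-all network, about 1.5 minutes on one core) and hand-sized inputs
elsewhere. All randomness flows from a single integer seed through one
`numpy` generator; identical seeds give byte-identical FASTA output.
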