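# gmcnet

Sequence-space analysis of protein superfamilies, built around the fungal
GMC (glucose–methanol–choline) oxidoreductases: FAD-dependent enzymes such
as aryl-alcohol oxidase (AAO), alcohol oxidase (AOx), cellobiose
dehydrogenase (CDH), glucose oxidase/dehydrogenase (GOx/GDH), pyranose
dehydrogenase (PDH) and pyranose oxidase (POx). The package is for
computational biologists who want to take a large set of putative
superfamily sequences and (1) split it into functional subfamilies, (2)
discard catalytically implausible sequences, and (3) profile the resulting
phylogenetic clades — all with tested, scriptable components rather than a
chain of web tools.

## What it does

**Sequence similarity networks (SSN).** Every sequence pair is scored by
BLOSUM62 local alignment; the raw score S is converted to a bit score
S′ = (λS − ln K)/ln 2 (Karlin–Altschul, λ = 0.267, K = 0.041) and an
expectation value E = m·N·2^(−S′), with m the query length and N the total
residue count of the set. An edge is kept at stringency exponent x iff
E ≤ 10^(−x). Sweeping x from 85 to 140 in steps of 5 makes the superfamily
graph break into connected components; clusters are read off and labelled
from annotated seed sequences (composite labels such as "GOx–GDH" when
seeds of several functions share a component).

**GMC validity filter.** A sequence is kept iff it shows all three of:
the FAD-binding Rossmann motif GxGxxG (or variants GxGxxA/GxGxxS), a
second FAD-associated motif hGGpp/hGGGpp (h hydrophobic, p polar), and the
catalytic His/His or His/Asn pair, detected in alignment space at columns
anchored by a characterised reference.

**Alignment post-processing.** Gap-column trimming (drop columns with
> 99% gaps; > 95% for small sets), Gblocks-style conserved-block selection
(minimum block length 5, gaps "with half"), and anchored domain windowing
(FAD motif − 6 columns … catalytic Asn + 18 columns) for multidomain
enzymes like CDH.

**Clades and profiles.** Newick I/O, midpoint rooting, MRCA-spanning clade
assignment from reference leaves, and per-clade statistics. The clade
conservation statistic is the mean percent sequence identity over all
pairs, computed on the existing alignment and excluding every column where
one or both sequences carry a gap. Position-frequency matrices with
information content IC = log2(20) − H(p) serve as numeric sequence logos,
for C-terminal peroxisomal targeting signals (PTS tripeptides such as ARF
or SRL) and anchored active-site panels; a dedicated check tests
cytochrome-domain functionality (axial Met/His + disulfide Cys pair at
anchored columns).

**Synthetic superfamilies.** `gmcnet.simulate` grows ground-truthed
superfamilies — several families from a shared ancestor, controlled
within/between-family identity, planted motifs, catalytic pairs, signal
peptides, PTS tripeptides, accessory cytochrome-like domains, and a
configurable fraction of deliberately broken sequences — so every pipeline
stage is testable end-to-end with exact expected outcomes.

## Worked example

```python
from gmcnet import (SyntheticConfig, simulate_superfamily, build_network,
                    connected_components, annotate_clusters,
                    apply_validity_filter, mean_percent_identity,
                    terminal_pfm, compare_clusters)

config = SyntheticConfig(seed=1)          # 5 families x 30 sequences, length 550
sim = simulate_superfamily(config)
truth = sim.truth

network = build_network(sim.records, cutoff_exponent=85)
clusters = annotate_clusters(connected_components(network), sim.annotations)
for c in clusters:
    print(f"cluster {c.cluster_id}: {len(c.members):3d} members  label={c.label}")
print("ARI vs planted families:", compare_clusters(clusters, truth))

by_id = {r.id: r for r in sim.records}
family = truth.families[0]                 # the "AAO" family
report = apply_validity_filter(
    [by_id[m] for m in family.member_ids], family.alignment,
    truth.catalytic_anchors(family.family))
print(f"validity filter: kept {len(report.kept)}, removed {len(report.removed)} "
      f"(removal fraction {report.removal_fraction:.2f})")

print(f"mean % identity within {family.label}: "
      f"{mean_percent_identity(family.alignment, family.member_ids):.1f}")

kept = [by_id[m] for m in family.member_ids if truth.sequences[m].valid]
print("C-terminal consensus (PTS):", terminal_pfm(kept, n_last=3).consensus())
```

prints

```
cluster 0:  30 members  label=AAO
cluster 1:  30 members  label=AOx
cluster 2:  30 members  label=CDH
cluster 3:  30 members  label=GOx
cluster 4:  30 members  label=POx
ARI vs planted families: 1.0
validity filter: kept 27, removed 3 (removal fraction 0.10)
mean % identity within AAO: 76.7
C-terminal consensus (PTS): ARF
```

At stringency 10^−85 the network's five components coincide exactly with
the five planted families (adjusted Rand index 1.0); the validity filter
removes precisely the 10% of sequences whose catalytic pair or FAD motifs
were deliberately broken; the within-family conservation lands near the
configured 70% identity target; and the C-terminal logo recovers the
planted ARF targeting signal.

A command-line interface mirrors the library
(`gmcnet simulate | filter | derep | ssn | gmcfilter | msa | clades | logo
| cyt`); run `gmcnet --help` for the full tree.

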