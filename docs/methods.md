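# Methods

## Overview

`diphase` reconstructs the two haplotypes of a diploid genome from long noisy
reads by a correct-then-assemble strategy with two assembly rounds. The key
premise is that heterozygous variation, although far rarer than sequencing
error (≈1% divergence versus 5–15% error), is *correlated across reads from
the same haplotype*, while errors are independent. Every stage exploits this:
correction selects same-haplotype supporting reads before computing a
consensus, and phasing clusters reads by shared SNP alleles before removing
cross-haplotype overlaps from the string graph.

## Haplotype-aware error correction

For each template read, supporting reads (those sharing candidate overlaps)
are aligned to it base-by-base and threaded through a POA graph whose nodes
are `(c, r, b)` triples: template position, consecutive-insertion rank
(`r = 0` for match/mismatch/deletion), and base (`-` for deletion). The
template's trivial self-alignment is included, so every edge's support count
equals the number of alignments traversing it.

*Important in-edges.* For each position's `(c, 0, ·)` node family with total
in-support `S`, an in-edge with support `s_i` is important when

```
s_i ≥  r_l·S                                  S ≤ S_l
       linear(r_l·S_l → r_h·S_h)              S_l < S ≤ S_h
       r_h·S                                  S > S_h
```

with defaults `r_l = 0.5, r_h = 0.2, S_l = 10, S_h = 200`. The rationale: at
low coverage only a near-50% minor branch is credible; at high coverage a 20%
branch already is.

*Important locations* require (1) no template homopolymer run ≥ 3 covering
`c` (homopolymer indel noise mimics branching), (2) at least two important
in-edges whose backward walks close a bubble, (3) a majority of each edge's
reads staying on its bubble path, and (4) substitution-only branches (no
length difference). Condition 4 is enforced structurally: all branch nodes
must be non-insertion, non-deletion nodes.

*Scoring, selection, weighting.* A supporting read scores +1 per important
location where it takes the template's important in-edge and −1 where it
takes a different important in-edge, normalized by the number of such
locations it covers (scores lie in [−1, 1]). Only locations where both
template and supporting read traverse flagged edges count. The score
histogram (bin width 0.1, 3-bin mean smoothing) is scanned for peaks; with
two or more peaks the reads in the highest-score peak (± one bin) are
selected, otherwise the top half (median ties included). Selected scores map
linearly onto `[0.4, 0.8]` as read weights; unselected reads get weight 0.

*Consensus.* Edge weights are the summed weights of selected reads passing
the edge; node `(c, r, b)` pays `P_c = max(0.4^r, 0.3) · W_c` where `W_c` is
the summed weight of reads covering position `c`. Scores propagate in
topological order (ascending packed node code — the packing
`(c << 11) | (r << 3) | b` makes code order a topological order). Because
`P_c` equals the full column weight at `r = 0`, backbone score increments
hover near zero, so a global argmax over all nodes would degenerate; the
terminal is instead the best-scoring node of the **last covered template
column**, and backtracking yields the consensus. Ends without selected-read
coverage are trimmed, and the corrected read's span on the raw read is
recorded. A read with no usable supports is returned unchanged and flagged.

Candidate overlaps are extended to the read ends before POA construction;
without this, seed-derived coordinates stop ~100 bp short of the true overlap
ends and the consensus quality decays at read edges.

## Overlap filters and the string graph

Overlap extension aligns only the flanking segments (shorter flank as a
prefix-anchored query into the longer), advancing while a running score of
+1 per match and −2 per edit improves; the asymmetric penalty is required
because an optimal alignment of two *random* sequences already matches about
half their bases, so ±1 scoring would walk through chimeric flaps. Overlaps
whose residual inner overhang exceeds `min(100, 0.01·l)` (PacBio) or
`min(300, 0.03·l)` (Nanopore) on the read of length `l` carrying it are
removed. A read contained end-to-end inside another (within its own overhang
tolerance) is set aside with all of its overlaps in a side table; per-read
coverage must lie within `[3, 400]`-fold (permissive, configurable).

The string graph has two vertices per read (5'/`B`, 3'/`E`) and an edge pair
per dovetail; dual symmetry (each edge's reverse-complement twin shares its
status) is maintained by every stage. Myers' algorithm (fuzz 500 bp) marks
transitive edges inactive. Identities are computed only for active edges
(edit distance over the inner overlap region) and edges below the six-sigma
MAD threshold `((m₁ − 6·1.253·MAD₁) + 2·(m₂ − 6·1.4826·MAD₂))/3` are removed;
the 1.253 and 1.4826 factors scale mean/median absolute deviation to a
normal-equivalent sigma. Dead ends are repaired by reactivating the
longest-alignment transitive edge above the threshold, then by re-attaching
contained reads — skipping any contained overlap between read pairs already
flagged inconsistent, which would otherwise re-introduce cross-haplotype
junctions. Tips (≤ 3 reads hanging off a junction), spurious links (overlap
length < 30% of the strongest sibling), and — in round 1 only — bubbles are
removed; maximal unbranched paths become contigs (cycles are broken at the
lowest-identity edge). Contig sequences splice each read's unaligned suffix,
with residual inner overhangs subtracted so junctions neither drop nor
duplicate slack.

The SNP-aware best-overlap-graph step ranks each node side's edges by
`s_i = (n_i⁺·w − n_i⁻, l_i)` (`w = 0.5`), where `n⁺/n⁻` count shared
same/different SNP alleles of the edge's read pair. The top edge is a
candidate; a further edge becomes one only if its read is inconsistent with
every current candidate's read *and* its score gap from the top obeys
`max(C, s_i·R1)` (non-negative `s_i`) or `max(C, −s_i·R2)` (negative), with
`C = 4, R1 = 2, R2 = 0.66`. Edges that are candidates from both sides become
best; a side left empty falls back to its top edge. Round 1 runs with all
counts zero, degrading to overlap-length ranking.

## Read grouping and inconsistent overlaps

Corrected reads are mapped to the round-1 contigs by minimizer voting plus
infix edit-distance alignment. Placements with at least half the primary's
votes are all kept (the analogue of mapping with a 0.5 secondary-to-primary
score ratio): in a collapsed or repeat-bearing reference, a read from one
repeat copy must contribute to the pileup of every near-identical instance,
otherwise the divergent sites that distinguish the copies are never seen.
The mapping reference is made non-redundant first (a contig aligning
near-fully into a longer one is dropped for phasing purposes), so each locus
pools the reads of both haplotypes.

A pileup site is heterozygous when coverage lies in `[10, 1000]` and the
second-most-common base count clears the same piecewise rule with
`r_l = 0.4, r_h = 0.2, c_l = 10, c_h = 100`. Reads get allele vectors
`H_r(s) ∈ {0, 1, 2}` and, per template read, the reads sharing ≥ 3
informative sites are clustered: a modified bisecting k-means seeds two
centroids with the most distant read pair (|D| distance, capped random pair
sample of 2000 when large), assigns each read to the closer centroid — or to
a separate far-read subgroup when `|A|/|V_≠| < 0.3` or `|D|/|A| > 0.5`
against both — and iterates to a fixpoint. A group stops dividing at ≤ 3
reads or when internally consistent. The printed consistency rule
`Σ|D(r,C,0,0)| ≤ p₅` reads zero for a *perfectly balanced* group because the
centroid votes cancel; the implementation uses the equivalent minority-vote
form `Σ_s min(v_s⁺, v_s⁻)`, identical for unbalanced sites and continuous
through the degeneracy. Far reads re-enter the combining step as singleton
leaves. Leaves merge back into the template's group `L1` (and then into the
nearest list entry) under the printed `A/S/D` conditions with
`p₆ = 0.66, p₇ = 6, p₈ = 4, p₉ = 0.2`. Each read's alleles are then verified
and corrected from its group centroid; the whole pass runs twice, each round
consuming the previous round's matrix.

In the final round, a query read is inconsistent with the template when both
its group-level and read-level `D`-versus-`A` conditions hold (threshold
`p₈ = 4` by default; a strict threshold of 8 different alleles applies to the
corrected-read pass and a loose threshold of 6 to the raw-read pass when
external raw-read SNP calls are supplied as VCF). The pair's overlaps are
removed only when the reads' directions and 3'-end distances on the contigs
agree with the overlap geometry (tolerance 1000 bp for corrected reads,
`max(2500, 0.05·D_c)` for raw reads) — a repeat-displaced overlap whose reads
sit far apart on the contig is deliberately left alone. With several
placements per read, a single concordant placement pair counts as agreement.
The relation is symmetrized.

## Two sets of contigs

After round-2 simplification, bubbles (two internally disjoint paths between
a shared source and sink, search depth 50) and alternate branches (exactly
two branches; the shorter one linear, dead-ended, and > 30% inconsistent
with the other) are detected. Primary paths traverse one side of each
without breaking; the divergent interiors of the other sides become
alternate contigs, and an independent contig > 30% inconsistent with a
longer one is demoted to alternate. Contigs that merely duplicate a longer
primary without haplotype signal are assembly redundancy and dropped. For
the dual format, adjacent bubbles are phased by minimizing the summed
centroid distance between the out-groups of one bubble and the in-groups of
the next (seeded random choice when they share no informative site); fully
separated haplotype pairs are split across the two sets by the same
> 30%-inconsistency pairing, the longer partner going to haplotype 1. With
no heterozygous evidence at all, the dual output falls back to a single
haplotype set with a warning. The polishing-stage alignment filter (removing
alignments of reads inconsistent with a contig's layout reads) is provided;
polishing itself is external.

## Synthetic data

The simulator draws haplotype 1 uniformly at random, derives haplotype 2 by
Bernoulli(`het_rate`) heterozygous variants (SNPs by default; an
`indel_het_fraction` hook adds 1–50 bp indels, default 0 since phasing uses
SNP alleles only), optionally inserts near-identical repeat copies before
variant sampling, and samples reads uniformly from both haplotypes and
strands with truncated-normal lengths (default mean 5 kb, sd 1.5 kb, min
500 bp) and per-base substitution/insertion/deletion errors (default 10%,
50/25/25 mix). Truth tables record haplotype sequences, het sites
(haplotype-1 coordinates, 0-based half-open), repeat intervals, and per-read
labels. Everything is deterministic per seed.

What the simulator does *not* emulate: non-uniform coverage, chimeric reads,
length-dependent and homopolymer-biased error profiles (a flag enables a
simple homopolymer enrichment), structural variation beyond small indels and
the repeat hook, and quality-score realism. Passing tests therefore
demonstrate the algorithmic behavior of the method under idealized sampling,
not performance on real flow-cell data.

## Study conditions and problem sizes

The standard diploid condition used throughout the tests and the acceptance
script is a 50-kb genome at 1% SNP heterozygosity, 40-fold coverage per
haplotype, 10% read error — the middle of the heterozygosity (0.34–1.48%) and
error (5–15%) ranges of real diploid long-read datasets, at a genome size
that keeps a full pipeline run around five minutes. The repeat scenario uses
a 20-kb homozygous genome with a 2-kb, 2-copy, 0.5%-diverged repeat and
1.2-kb reads, so reads cannot span the repeat. The homozygous control uses a
20-kb genome at zero heterozygosity. Correction caps supports at the 45
longest alignments per template; at 40×/haplotype this leaves ~22
same-haplotype supports, enough for ≥ 99.8% mean consensus accuracy.

## Evaluation conventions

Haplotype-specific k-mer sets are computed exactly from the two simulated
haplotypes (symmetric difference of canonical 18-mer sets) rather than from
parental short reads. Consistency is `Σ max(k_p, k_m) / Σ (k_p + k_m)` over
the 40× longest reads; completeness counts parent-specific k-mers observed
≥ 4 times there (note the end-coverage ramp: positions within ~4L/depth of a
genome end cannot reach 4 occurrences under uniform sampling). Read and
contig accuracy is matches / (matches + mismatches + insertions + deletions)
from an edit-distance alignment's cigar. For contigs, each truth het site
covered by the alignment is attributed to a haplotype; an isolated
single-site deviation whose neighbours agree is counted as a *flip* (a base
error), and *switch events* are transitions of the flip-filtered origin
sequence — the same distinction k-mer-based assembly evaluators draw between
Hamming flips and phase switches.

## Known limitations

- The built-in minimizer overlapper is all-vs-all and intended for ≤ ~10⁴
  reads; external candidate overlaps can be supplied as PAF.
- Round-1 behavior on repeats is seed-sensitive at the margin of copy
  divergence versus corrected-read accuracy: the repeat may already be
  partially resolved in round 1. Round 2 resolves both copies distinctly in
  either case, which is the property the tests pin.
- Indel heterozygosity is simulated but not phased (SNP alleles only).
- Contig base quality is bounded by corrected-read quality (~99.5–99.8%);
  consensus polishing is deliberately out of scope.
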