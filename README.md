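# diphase

Diploid genome assembly from long noisy reads, at desk scale: haplotype-aware
error correction on partial-order alignment (POA) graphs, a fast string-graph
assembler, a read-level SNP caller with centroid-based read grouping for
removing inconsistent overlaps, and generation of two sets of contigs
(primary/alternate or dual assembly) — driven end to end by a built-in
synthetic diploid read simulator with full ground truth.

## The problem

Long noisy reads (PacBio CLR, Nanopore R9/R10) carry 5–15% sequencing error,
well above the 0.3–1.5% divergence between the two haplotypes of a diploid
genome. Standard correct-then-assemble pipelines therefore erase heterozygous
alleles as if they were errors, and overlap graphs are riddled with
*inconsistent overlaps* — overlaps joining reads from different haplotypes or
different copies of a near-identical repeat — which cause haplotype switch
errors and unresolved repeats.

`diphase` addresses both problems:

1. **Haplotype-aware correction.** For each template read a POA graph is
   built from its supporting reads; nodes are keyed by `(c, r, b)` (template
   position, consecutive-insertion rank, base). A heterozygous site shows two
   dominant parallel branches: an in-edge of the position-`c` node family is
   *important* when its support count `s_i` clears a piecewise threshold in
   the family total `S = Σ s_i` (rate `r_l = 0.5` below `S_l = 10`, `r_h = 0.2`
   above `S_h = 200`, linear in between). Each supporting read is scored ±1
   per important location by whether it follows the template's branch,
   normalized by the locations it covers; reads in the top peak of the score
   histogram are selected and their scores mapped linearly onto edge weights
   in `[0.4, 0.8]`. Consensus is the best-scoring path under
   `S_v = max(S_u + W_(u,v) − P_c)` with `P_c = max(0.4^r, 0.3)·W_c`.
2. **Two-round string-graph assembly.** Overlaps are extended to the read
   ends and filtered by residual overhang (`min(100, 0.01·l)` PacBio,
   `min(300, 0.03·l)` Nanopore), containment, and coverage. Myers' algorithm
   marks transitive edges; active-edge identities below
   `((m₁ − 6·1.253·MAD₁) + 2·(m₂ − 6·1.4826·MAD₂))/3` are removed, with
   dead-end repair through reactivated transitive edges and contained reads.
3. **Read grouping and inconsistent-overlap removal.** Corrected reads are
   mapped to the round-1 (haplotype-collapsed) contigs; heterozygous SNP
   sites are called from the pileup and each read gets an allele vector
   `H_r(s) ∈ {0,1,2}`. A divide-then-combine clustering over centroid
   site-set algebra (`V_>`, `V_<`, `A`, `S`, `D`) groups reads by haplotype,
   verifies and corrects alleles (two passes), and flags read pairs whose
   groups differ at enough verified sites; their overlaps are removed when
   read directions and 3'-end distances agree with the contig layout.
4. **Two sets of contigs.** The rebuilt graph separates haplotypes into
   bubbles, alternate branches, or independent contigs; a SNP-aware
   best-overlap-graph rule (`s_i = (n_i⁺·w − n_i⁻, l_i)`) keeps the right
   edges. Output is primary/alternate or a dual assembly whose bubble sides
   are phased by matching allele-group centroids.

## Worked example

```python
from diphase import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1)      # 50-kb genome, 1% het, 10% error, 40x/hap
res = run_pipeline(cfg, outdir="run/")
print(res.report["round1"]["contig_lengths"])   # [49604]
print(len(res.hap1), len(res.hap2))             # 1 1
print(res.report["inconsistent_pairs"])         # 31639
```

The round-1 assembly collapses both haplotypes into a single 49.6-kb contig.
Phasing then calls 516 heterozygous sites, flags 31,639 inconsistent read
pairs (all of them truly cross-haplotype against the simulator's truth
labels), and round 2 separates the graph into one contig per haplotype: on
this run a 49.0-kb and a 47.7-kb contig, each 99.6% identical to its truth
haplotype with zero switch events across 526 and 508 informative het sites —
versus roughly two-thirds heterozygote retention if support selection is
disabled.

The same pipeline is scriptable from the shell:

```
diphase sim      --config cfg.json --out sim/
diphase overlap  --reads sim/reads.fq --platform pacbio --out ovl.paf
diphase correct  --reads sim/reads.fq --paf ovl.paf --out corrected.fa
diphase asm1     --reads corrected.fa --paf retained.paf --out asm1/
diphase phase    --contigs asm1/contigs.fa --reads corrected.fa --paf retained.paf --out phase/
diphase asm2     --reads corrected.fa --paf phase/filtered.paf --inconsistent phase/inconsistent_pairs.tsv --format dual --out asm2/
diphase eval     --reads corrected.fa --truth sim/haplotypes.fa --out eval/
diphase run      --seed 1 --out run/    # everything at once
```

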