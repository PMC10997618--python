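"""Configuration and the end-to-end pipeline driver.

Stages: simulate (or load) reads -> raw-read overlaps -> haplotype-aware
correction -> corrected-read overlaps + filters -> round-1 (haplotype-
collapsed) assembly -> SNP calling / read grouping / inconsistent-overlap
removal -> round-2 assembly emitting primary/alternate and dual contig sets
-> truth-based evaluation. A single global seed is fanned out per stage; runs
are deterministic for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import correct as correct_mod
from . import diploid, evalkit, io, overlap as ovl_mod, phase as phase_mod, sgraph
from .simdata import SimParams, Truth, simulate_diploid_genome, simulate_reads

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sim: SimParams = field(default_factory=SimParams)
    overlap: ovl_mod.OverlapFilterParams = field(
        default_factory=ovl_mod.OverlapFilterParams
    )
    correction: correct_mod.CorrectionParams = field(
        default_factory=correct_mod.CorrectionParams
    )
    snp: phase_mod.SnpCallParams = field(default_factory=phase_mod.SnpCallParams)
    grouping: phase_mod.GroupingParams = field(
        default_factory=phase_mod.GroupingParams
    )
    bog: sgraph.BogParams = field(default_factory=sgraph.BogParams)
    platform: str = "pacbio"
    seed: int = 0
    haplotype_aware: bool = True
    fuzz: int = 500
    tip_max_reads: int = 3
    spur_frac: float = 0.3
    raw_vcf: str | None = None

    def __post_init__(self) -> None:
        self.sim.seed = self.seed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        nested = {
            "sim": SimParams,
            "overlap": ovl_mod.OverlapFilterParams,
            "correction": correct_mod.CorrectionParams,
            "snp": phase_mod.SnpCallParams,
            "grouping": phase_mod.GroupingParams,
            "bog": sgraph.BogParams,
        }
        valid = {f.name for f in dataclasses.fields(cls)}
        for key, val in d.items():
            if key not in valid:
                raise ValueError(f"unknown configuration key: {key!r}")
            if key in nested and isinstance(val, dict):
                sub_valid = {f.name for f in dataclasses.fields(nested[key])}
                bad = set(val) - sub_valid
                if bad:
                    raise ValueError(f"unknown {key} keys: {sorted(bad)}")
                if key == "sim" and "error_mix" in val:
                    val["error_mix"] = tuple(val["error_mix"])
                if key == "correction" and "weight_range" in val:
                    val["weight_range"] = tuple(val["weight_range"])
                kwargs[key] = nested[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def save(self, path) -> None:
        io.write_json(path, self.to_dict())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(io.read_json(path))


@dataclass
class PipelineResult:
    truth: Truth | None
    reads: dict[str, str]
    raw_candidates: list[ovl_mod.Overlap]
    corrected: dict[str, str]
    corrected_records: dict[str, correct_mod.CorrectedRead]
    retained_overlaps: list[ovl_mod.Overlap]
    contigs1: list[sgraph.Contig]
    matrix: phase_mod.AlleleMatrix | None
    inconsistent_pairs: set[tuple[str, str]]
    filtered_overlaps: list[ovl_mod.Overlap]
    primary: list[sgraph.Contig]
    alternates: list[sgraph.Contig]
    hap1: list[sgraph.Contig]
    hap2: list[sgraph.Contig]
    report: dict
    graph1_pairs: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    graph2_pairs: list[tuple[str, str]] = dataclasses.field(default_factory=list)


def _sub_seed(seed: int, idx: int) -> int:
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


def ng50(lengths: list[int], genome_size: int) -> int:
    """Length of the shortest contig such that contigs at least that long
    cover half the (known) genome size."""
    total = 0
    for L in sorted(lengths, reverse=True):
        total += L
        if total >= genome_size / 2:
            return L
    return 0


def _nonredundant(contigs: dict[str, str], min_ident: float = 0.93) -> dict[str, str]:
    """Drop contigs that align near-fully into a longer kept contig."""
    from .evalkit import align_identity

    kept: dict[str, str] = {}
    for name in sorted(contigs, key=lambda n: (-len(contigs[n]), n)):
        seq = contigs[name]
        if any(
            len(seq) <= len(other) and align_identity(seq, other) >= min_ident
            for other in kept.values()
        ):
            continue
        kept[name] = seq
    return kept


def assemble_round(
    overlaps: list[ovl_mod.Overlap],
    reads: dict[str, str],
    contained: dict[str, list[ovl_mod.Overlap]],
    cfg: PipelineConfig,
    snp_evidence: dict | None = None,
    inconsistent: set | None = None,
    pop_bubbles: bool = True,
    prefix: str = "ctg",
) -> tuple[sgraph.StringGraph, list[sgraph.Contig], dict]:
    """One round of string-graph assembly; returns (graph, contigs, counters)."""
    g = sgraph.build_string_graph(overlaps)
    sgraph.mark_transitive(g, cfg.fuzz)
    counters = {"after_transitive": g.status_counts()}
    g, stats = sgraph.identity_filter(g, reads)
    counters["after_identity"] = g.status_counts()
    if stats is not None:
        counters["identity_threshold"] = stats.threshold
    sgraph.repair_dead_ends(g, contained, reads, inconsistent)
    counters["after_repair"] = g.status_counts()
    sgraph.best_overlap_select(
        g, snp_evidence or {}, inconsistent or set(), cfg.bog
    )
    sgraph.simplify_ambiguous(
        g, pop_bubbles=pop_bubbles, tip_max_reads=cfg.tip_max_reads,
        spur_frac=cfg.spur_frac,
    )
    counters["after_simplify"] = g.status_counts()
    contigs = sgraph.extract_contigs(g, reads, prefix=prefix)
    counters["n_contigs"] = len(contigs)
    counters["contig_lengths"] = sorted(
        (len(c.sequence) for c in contigs), reverse=True
    )
    return g, contigs, counters


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | Path | None = None,
    reads: dict[str, str] | None = None,
) -> PipelineResult:
    """Run every stage; ``reads`` bypasses simulation when given."""
    report: dict = {"config_seed": cfg.seed}
    truth = None
    if reads is None:
        haps, truth = simulate_diploid_genome(cfg.sim)
        read_list, truth = simulate_reads(haps, truth, cfg.sim)
        reads = dict(read_list)
        report["sim"] = {
            "genome_length": len(haps[0]),
            "n_het_sites": len(truth.het_sites),
            "n_reads": len(reads),
            "total_bases": sum(len(s) for s in reads.values()),
        }

    # --- correction --------------------------------------------------------
    raw_cands = ovl_mod.find_candidate_overlaps(reads, k=13, w=8, min_shared=4)
    report["raw_candidate_overlaps"] = len(raw_cands)
    corrected_records = correct_mod.correct_all(
        reads, raw_cands, cfg.correction, cfg.haplotype_aware
    )
    corrected = {n: r.sequence for n, r in corrected_records.items() if r.sequence}
    report["corrected_reads"] = len(corrected)

    # --- corrected-read overlaps + filters ---------------------------------
    cands = ovl_mod.find_candidate_overlaps(corrected, k=15, w=10, min_shared=4)
    extended = [ovl_mod.extend_overlap(ov, corrected) for ov in cands]
    filtered = ovl_mod.filter_overhangs(extended, cfg.overlap)
    final, contained, coverage = ovl_mod.remove_contained_and_low_coverage(
        filtered, cfg.overlap
    )
    retained = [ov for ov in final if ov.status == ovl_mod.RETAINED]
    report["overlap_status"] = ovl_mod.status_counts(final)

    # --- round 1: haplotype-collapsed assembly -----------------------------
    g1, contigs1, c1 = assemble_round(
        retained, corrected, contained, cfg, pop_bubbles=True, prefix="ctg"
    )
    report["round1"] = c1

    # --- phasing -----------------------------------------------------------
    # The mapping reference must be non-redundant: a short round-1 contig that
    # is just the other haplotype of a region already covered by a longer
    # contig would split the reads of one locus over two references and hide
    # their shared SNP sites.
    contig_seqs = _nonredundant({c.name: c.sequence for c in contigs1})
    report["phase_reference_contigs"] = len(contig_seqs)
    matrix = None
    pairs: set[tuple[str, str]] = set()
    placements = phase_mod.map_reads_to_contigs(corrected, contig_seqs)
    sites = phase_mod.call_het_sites(contig_seqs, placements, corrected, cfg.snp)
    report["n_het_sites_called"] = len(sites)
    if sites:
        matrix = phase_mod.call_read_alleles(placements, sites, corrected)
        matrix = phase_mod.verify_correct_alleles(
            matrix, cfg.grouping, seed=_sub_seed(cfg.seed, 5)
        )
        if cfg.raw_vcf:
            vcf_sites = io.read_vcf_het_sites(cfg.raw_vcf)
            raw_place = phase_mod.map_reads_to_contigs(reads, contig_seqs, k=13, w=8)
            raw_matrix = phase_mod.call_read_alleles(raw_place, vcf_sites, reads)
            strict, loose = phase_mod.merge_raw_snp_evidence(
                matrix, raw_matrix, cfg.grouping, seed=_sub_seed(cfg.seed, 6)
            )
            kept1, dropped1 = phase_mod.mark_inconsistent_overlaps(
                strict, retained, matrix, cfg.grouping.dist_tol_corrected,
                cfg.grouping,
            )
            kept, dropped2 = phase_mod.mark_inconsistent_overlaps(
                loose, kept1, raw_matrix, None, cfg.grouping, corrected=matrix
            )
            pairs = strict | loose
            dropped = dropped1 + dropped2
        else:
            pairs = phase_mod.find_inconsistent_pairs(
                matrix, cfg.grouping, seed=_sub_seed(cfg.seed, 6)
            )
            kept, dropped = phase_mod.mark_inconsistent_overlaps(
                pairs, retained, matrix, cfg.grouping.dist_tol_corrected,
                cfg.grouping,
            )
        report["inconsistent_pairs"] = len(pairs)
        report["overlaps_removed_inconsistent"] = len(dropped)
    else:
        log.warning("no heterozygous sites called; dual assembly will mirror "
                    "the collapsed assembly")
        kept = retained
    report["overlaps_into_round2"] = len(kept)

    # --- round 2: diploid assembly -----------------------------------------
    evidence = (
        phase_mod.snp_agreement_counts(matrix, kept) if matrix is not None else {}
    )
    g2, _, c2 = assemble_round(
        kept, corrected, contained, cfg, snp_evidence=evidence,
        inconsistent=pairs, pop_bubbles=False, prefix="r2ctg",
    )
    report["round2"] = c2
    primary, alternates, bubbles = diploid.emit_primary_alternate(
        g2, corrected, pairs
    )
    if matrix is None or not pairs:
        # no heterozygous evidence at all: a second haplotype set would only
        # duplicate the collapsed assembly
        log.warning("dual assembly falls back to a single haplotype set")
        hap1, hap2 = [dataclasses.replace(c) for c in primary], []
        for i, c in enumerate(hap1):
            c.name = f"hap1-ctg{i:04d}"
    else:
        hap1, hap2 = diploid.connect_dual_paths(
            g2, corrected, matrix, pairs, seed=_sub_seed(cfg.seed, 7)
        )
    if truth is not None:
        gsize = len(truth.haplotype_sequences[0])
        for key in ("round1", "round2"):
            report[key]["ng50"] = ng50(report[key]["contig_lengths"], gsize)
    report["n_primary"] = len(primary)
    report["n_alternate"] = len(alternates)
    report["n_bubbles"] = len(bubbles)
    report["dual_sizes"] = (
        sum(len(c.sequence) for c in hap1),
        sum(len(c.sequence) for c in hap2),
    )

    def _live_pairs(g: sgraph.StringGraph) -> list[tuple[str, str]]:
        seen = set()
        for e in g.edges.values():
            if e.status in sgraph.LIVE:
                seen.add(tuple(sorted((e.source[0], e.target[0]))))
        return sorted(seen)

    result = PipelineResult(
        truth, reads, raw_cands, corrected, corrected_records, retained,
        contigs1, matrix, pairs, kept, primary, alternates, hap1, hap2, report,
        _live_pairs(g1), _live_pairs(g2),
    )
    if outdir is not None:
        _write_outputs(Path(outdir), cfg, result, g1, g2)
    return result


def _write_outputs(
    outdir: Path, cfg: PipelineConfig, res: PipelineResult,
    g1: sgraph.StringGraph, g2: sgraph.StringGraph,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if res.truth is not None:
        io.write_fasta(outdir / "haplotypes.fa", {
            "hap1": res.truth.haplotype_sequences[0],
            "hap2": res.truth.haplotype_sequences[1],
        })
        io.write_tsv(
            outdir / "truth_het_sites.tsv",
            [
                {"position": p, "hap1_allele": a, "hap2_allele": b}
                for p, a, b in res.truth.het_sites
            ],
            ["position", "hap1_allele", "hap2_allele"],
        )
        io.write_tsv(
            outdir / "truth_read_labels.tsv",
            [
                {"read": n, "haplotype": l.haplotype, "start": l.start,
                 "end": l.end, "strand": l.strand}
                for n, l in sorted(res.truth.read_labels.items())
            ],
            ["read", "haplotype", "start", "end", "strand"],
        )
    io.write_fastq(outdir / "reads.fq", res.reads)
    io.write_fasta(outdir / "corrected.fa", res.corrected)
    io.write_tsv(
        outdir / "corrected_provenance.tsv",
        [
            {"read": n, "raw_start": r.raw_span[0], "raw_end": r.raw_span[1],
             "n_selected": len(r.selected), "flagged": int(r.flagged)}
            for n, r in sorted(res.corrected_records.items())
        ],
        ["read", "raw_start", "raw_end", "n_selected", "flagged"],
    )
    io.write_paf(outdir / "retained_overlaps.paf", res.retained_overlaps)
    io.write_paf(outdir / "round2_overlaps.paf", res.filtered_overlaps)
    io.write_fasta(
        outdir / "asm1_contigs.fa", {c.name: c.sequence for c in res.contigs1}
    )
    io.write_gfa(outdir / "asm1_graph.gfa", g1, res.corrected)
    io.write_gfa(outdir / "asm2_graph.gfa", g2, res.corrected)
    io.write_fasta(
        outdir / "primary.fa", {c.name: c.sequence for c in res.primary}
    )
    io.write_fasta(
        outdir / "alternate.fa", {c.name: c.sequence for c in res.alternates}
    )
    io.write_fasta(outdir / "hap1.fa", {c.name: c.sequence for c in res.hap1})
    io.write_fasta(outdir / "hap2.fa", {c.name: c.sequence for c in res.hap2})
    io.write_tsv(
        outdir / "inconsistent_pairs.tsv",
        [{"read_a": a, "read_b": b} for a, b in sorted(res.inconsistent_pairs)],
        ["read_a", "read_b"],
    )
    cfg.save(outdir / "config.json")
    io.write_json(outdir / "report.json", _jsonable(res.report))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
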