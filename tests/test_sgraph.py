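"""String graph construction, Myers marking, filters, contig extraction."""

import numpy as np
import pytest

from diphase import sgraph
from diphase.overlap import Overlap, RETAINED
from diphase.sgraph import (
    BogParams,
    IdentityStats,
    StringGraph,
    best_overlap_select,
    build_string_graph,
    extract_contigs,
    identity_filter,
    mark_transitive,
    repair_dead_ends,
    simplify_ambiguous,
    transitive_reduction_bruteforce,
)
from diphase.simdata import revcomp


def _chain_reads(rng, genome, starts, length):
    """Reads tiling a genome left to right, plus their pairwise overlaps."""
    reads = {
        f"r{i}": genome[s : s + length] for i, s in enumerate(starts)
    }
    ovs = []
    for i in range(len(starts)):
        for j in range(i + 1, len(starts)):
            si, sj = starts[i], starts[j]
            inter = min(si, sj) + length - max(si, sj)
            if inter <= 0:
                continue
            a, b = f"r{i}", f"r{j}"
            ovs.append(
                Overlap(a, b, "+",
                        max(sj - si, 0), min(length, sj - si + length),
                        max(si - sj, 0), min(length, si - sj + length),
                        length, length, identity=0.99, status=RETAINED)
            )
    return reads, ovs


@pytest.fixture()
def chain3(rng):
    genome = "".join("ACGT"[i] for i in rng.integers(0, 4, size=5000))
    return genome, *_chain_reads(rng, genome, [0, 1000, 2000], 3000)


class TestBuild:
    def test_three_read_chain(self, chain3):
        _, reads, ovs = chain3
        g = build_string_graph(ovs)
        assert len(g.edges) == 6  # 3 overlaps x 2 edges
        assert g.check_dual_symmetry()

    def test_empty_overlaps(self):
        g = build_string_graph([])
        assert g.edges == {}

    def test_non_dovetail_skipped(self):
        contained = Overlap("a", "b", "+", 1000, 3000, 0, 2000, 10000, 2000,
                            status=RETAINED)
        g = build_string_graph([contained])
        assert g.edges == {}


class TestTransitive:
    def test_triangle_marks_long_edge(self, chain3):
        _, reads, ovs = chain3
        g = build_string_graph(ovs)
        mark_transitive(g, fuzz=100)
        # r0->r2 is implied by r0->r1->r2
        e = g.edges[(("r0", "E"), ("r2", "E"))]
        assert e.status == sgraph.TRANSITIVE
        assert g.edges[e.dual_key].status == sgraph.TRANSITIVE
        assert g.edges[(("r0", "E"), ("r1", "E"))].status == sgraph.ACTIVE

    def test_chain_without_shortcut_untouched(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, size=8000))
        reads, ovs = _chain_reads(rng, genome, [0, 2200, 4400], 3000)
        # r0 and r2 do not overlap (gap), only consecutive edges exist
        g = build_string_graph(ovs)
        mark_transitive(g, fuzz=100)
        assert all(e.status == sgraph.ACTIVE for e in g.edges.values())

    def test_matches_bruteforce_on_random_layouts(self, rng):
        """Randomized read layouts: Myers marking equals the brute-force
        two-edge-path reduction."""
        for trial in range(60):
            n = int(rng.integers(4, 14))
            starts = np.sort(rng.integers(0, 8000, size=n))
            length = int(rng.integers(2500, 4000))
            genome = "".join("ACGT"[i] for i in rng.integers(0, 4, size=12000))
            reads, ovs = _chain_reads(rng, genome, starts.tolist(), length)
            g = build_string_graph(ovs)
            oracle = transitive_reduction_bruteforce(g, fuzz=500)
            mark_transitive(g, fuzz=500)
            got = {
                k for k, e in g.edges.items() if e.status == sgraph.TRANSITIVE
            }
            assert got == oracle, trial


class TestIdentityFilter:
    def test_zero_dispersion_removes_nothing(self, chain3):
        _, reads, ovs = chain3
        for ov in ovs:
            ov.identity = 0.95
        g = build_string_graph(ovs)
        g, stats = identity_filter(g, reads)
        assert stats.threshold == pytest.approx(0.95)
        assert all(e.status != sgraph.REMOVED_LOW_QUALITY
                   for e in g.edges.values())

    def test_outlier_edge_removed(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, size=20000))
        reads, ovs = _chain_reads(
            rng, genome, [0, 1500, 3000, 4500, 6000, 7500, 9000, 10500, 12000,
                          13500], 3000
        )
        idents = [0.99] * len(ovs)
        idents[3] = 0.80
        for ov, i in zip(ovs, idents):
            ov.identity = i
        g = build_string_graph(ovs)
        g, stats = identity_filter(g, reads)
        bad = ovs[3]
        key_edges = [e for e in g.edges.values() if e.overlap is bad]
        assert all(e.status == sgraph.REMOVED_LOW_QUALITY for e in key_edges)

    def test_too_few_edges_skips(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, size=5000))
        reads, ovs = _chain_reads(rng, genome, [0, 1500], 3000)
        ovs[0].identity = 0.5
        g = build_string_graph(ovs)
        g, stats = identity_filter(g, reads)
        assert stats is None


class TestDualSymmetryProperty:
    def test_symmetry_after_every_stage(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, size=30000))
        starts = np.sort(rng.integers(0, 26000, size=18)).tolist()
        reads, ovs = _chain_reads(rng, genome, starts, 4000)
        for ov in ovs:
            ov.identity = float(rng.uniform(0.95, 1.0))
        g = build_string_graph(ovs)
        assert g.check_dual_symmetry()
        mark_transitive(g)
        assert g.check_dual_symmetry()
        identity_filter(g, reads)
        assert g.check_dual_symmetry()
        repair_dead_ends(g, {}, reads)
        assert g.check_dual_symmetry()
        simplify_ambiguous(g)
        assert g.check_dual_symmetry()


class TestBog:
    def _graph_two_out(self, rng, evidence, inconsistent):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, size=20000))
        # r0 overlaps both r1 (longer) and r2 (shorter): two out-edges at r0.E
        reads = {"r0": genome[0:4000], "r1": genome[1000:5000],
                 "r2": genome[2000:6000]}
        ovs = [
            Overlap("r0", "r1", "+", 1000, 4000, 0, 3000, 4000, 4000,
                    identity=0.99, status=RETAINED),
            Overlap("r0", "r2", "+", 2000, 4000, 0, 2000, 4000, 4000,
                    identity=0.99, status=RETAINED),
            Overlap("r1", "r2", "+", 1000, 4000, 0, 3000, 4000, 4000,
                    identity=0.99, status=RETAINED),
        ]
        g = build_string_graph(ovs)
        best_overlap_select(g, evidence, inconsistent, BogParams())
        return g

    def test_single_out_edge_is_best(self, chain3):
        _, reads, ovs = chain3
        g = build_string_graph([ovs[0]])
        best_overlap_select(g, {}, set())
        assert all(e.status == sgraph.BEST for e in g.edges.values())

    def test_consistent_runner_up_not_candidate(self, rng):
        # A scores 3.0, B scores 0.0, reads consistent: only A survives at r0.E
        ev = {("r0", "r1"): (6, 0), ("r0", "r2"): (0, 0), ("r1", "r2"): (0, 0)}
        g = self._graph_two_out(rng, ev, set())
        e_b = g.edges[(("r0", "E"), ("r2", "E"))]
        assert e_b.status == sgraph.REMOVED_AMBIGUOUS

    def test_inconsistent_far_score_not_candidate(self, rng):
        # B scores -2.0, inconsistent with A: gap 5 >= max(4, 1.32) -> removed
        ev = {("r0", "r1"): (6, 0), ("r0", "r2"): (0, 2), ("r1", "r2"): (0, 0)}
        g = self._graph_two_out(rng, ev, {("r1", "r2"), ("r0", "r2")})
        e_b = g.edges[(("r0", "E"), ("r2", "E"))]
        assert e_b.status == sgraph.REMOVED_AMBIGUOUS

    def test_inconsistent_close_score_kept(self, rng):
        # B scores 0.5 vs A 3.0: gap 2.5 < 4, B's read inconsistent with A's
        ev = {("r0", "r1"): (6, 0), ("r0", "r2"): (1, 0), ("r1", "r2"): (0, 0)}
        g = self._graph_two_out(rng, ev, {("r1", "r2")})
        e_b = g.edges[(("r0", "E"), ("r2", "E"))]
        assert e_b.status == sgraph.BEST


class TestSimplifyAndExtract:
    def test_linear_chain_unchanged_and_extracted(self, chain3):
        genome, reads, ovs = chain3
        g = build_string_graph(ovs)
        mark_transitive(g, fuzz=100)
        simplify_ambiguous(g)
        contigs = extract_contigs(g, reads)
        assert len(contigs) == 1
        assert contigs[0].sequence in (genome, revcomp(genome))
        assert len(contigs[0].layout) == 3

    def test_contig_length_is_span_of_union(self, chain3):
        genome, reads, ovs = chain3
        g = build_string_graph(ovs)
        mark_transitive(g, fuzz=100)
        contigs = extract_contigs(g, reads)
        assert len(contigs[0].sequence) == 5000

    def test_empty_graph_gives_no_contigs(self):
        g = StringGraph()
        assert extract_contigs(g, {}) == []

    def test_spur_removed(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, size=20000))
        reads, ovs = _chain_reads(
            rng, genome, [0, 3000, 6000, 9000, 12000], 5000
        )
        # attach a short spur read overlapping r1 by only a little
        reads["spur"] = genome[5500:9500]
        ovs.append(Overlap("r1", "spur", "+", 2500, 5000, 0, 2500,
                           5000, 4000, identity=0.99, status=RETAINED))
        g = build_string_graph(ovs)
        mark_transitive(g, fuzz=200)
        simplify_ambiguous(g, tip_max_reads=1)
        contigs = extract_contigs(g, reads)
        main = max(contigs, key=lambda c: len(c.sequence))
        assert len(main.layout) >= 5

    def test_stage_accounting_partitions_edges(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, size=30000))
        starts = np.sort(rng.integers(0, 25000, size=15)).tolist()
        reads, ovs = _chain_reads(rng, genome, starts, 5000)
        for ov in ovs:
            ov.identity = float(rng.uniform(0.97, 1.0))
        g = build_string_graph(ovs)
        total = len(g.edges)
        mark_transitive(g)
        identity_filter(g, reads)
        repair_dead_ends(g, {}, reads)
        simplify_ambiguous(g)
        counts = g.status_counts()
        assert sum(counts.values()) == total
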