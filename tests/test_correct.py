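"""POA graph construction, branch analysis, selection, consensus."""

import itertools

import numpy as np
import pytest

from diphase import correct as cm
from diphase.correct import (
    Alignment,
    CorrectionParams,
    SupportScore,
    build_poa_graph,
    consensus,
    correct_read,
    make_node,
    mark_important_edges,
    mark_important_locations,
    node_b,
    node_c,
    node_r,
    score_supporting_reads,
    select_and_weight,
)


def _aln(name, t_start, cigar, query):
    return Alignment(name, t_start, cigar, query)


class TestPoaGraph:
    def test_template_only_is_linear_chain(self):
        g = build_poa_graph("t", "ACGTACGT", [])
        assert len(g.edges) == 7
        for e, s in zip(g.edges, g.supports):
            assert s == 1
            u, v = int(e) >> 32, int(e) & 0xFFFFFFFF
            assert node_c(v) == node_c(u) + 1
            assert node_r(u) == node_r(v) == 0

    def test_substitution_creates_parallel_nodes(self):
        #             position 5 of ACGTACGTAC
        g = build_poa_graph("t", "ACGTACGTAC", [_aln("s", 0, "5=1X4=", "ACGTAGGTAC")])
        nodes = set()
        for e in g.edges.tolist():
            nodes.add(e >> 32)
            nodes.add(e & 0xFFFFFFFF)
        assert make_node(5, 0, "C") in nodes  # template base
        assert make_node(5, 0, "G") in nodes  # supporting read base
        sup = {int(e): int(s) for e, s in zip(g.edges, g.supports)}
        assert sup[(make_node(4, 0, "A") << 32) | make_node(5, 0, "C")] == 1
        assert sup[(make_node(4, 0, "A") << 32) | make_node(5, 0, "G")] == 1

    def test_insertion_creates_ranked_nodes(self):
        g = build_poa_graph("t", "ACGTACGT", [_aln("s", 0, "4=2I4=", "ACGTGGACGT")])
        nodes = set()
        for e in g.edges.tolist():
            nodes.add(e >> 32)
            nodes.add(e & 0xFFFFFFFF)
        assert make_node(3, 1, "G") in nodes
        assert make_node(3, 2, "G") in nodes

    def test_deletion_node_on_path(self):
        g = build_poa_graph("t", "ACGTACGT", [_aln("s", 0, "3=2D3=", "ACGACGT"[:6])])
        nodes = {e >> 32 for e in g.edges.tolist()} | {
            e & 0xFFFFFFFF for e in g.edges.tolist()
        }
        assert make_node(3, 0, "-") in nodes
        assert make_node(4, 0, "-") in nodes

    def test_path_conservation(self, noisy_sim):
        """Summed support over each location's family in-edges equals the
        number of alignments spanning that location."""
        _, _, _, reads = noisy_sim
        names = sorted(reads)
        template = reads[names[0]]
        import edlib

        alns = []
        for n in names[1:6]:
            res = edlib.align(reads[n], template, mode="HW", task="path")
            alns.append(Alignment(n, res["locations"][0][0], res["cigar"], reads[n]))
        g = build_poa_graph(names[0], template, alns)
        v = g.edges & 0xFFFFFFFF
        fam = ((v >> 3) & 0xFF) == 0
        cv = (v >> 11)[fam]
        tot = np.zeros(len(template), dtype=int)
        np.add.at(tot, cv, g.supports[fam])
        spans = [g.spans[n] for n in g.paths]
        for c in range(1, len(template)):
            expect = sum(1 for s0, s1 in spans if s0 < c <= s1)
            assert tot[c] == expect


class TestImportantEdges:
    def _graph_with_branch(self, n_x, n_y, length=30):
        """Template plus supports: n_x agreeing with template base at c=15,
        n_y carrying a substitution."""
        t = ("ACGT" * 10)[:length]
        q_sub = t[:15] + ("G" if t[15] != "G" else "C") + t[16:]
        alns = [
            _aln(f"x{i}", 0, f"{length}=", t) for i in range(n_x)
        ] + [
            _aln(f"y{i}", 0, "15=1X14=", q_sub) for i in range(n_y)
        ]
        return build_poa_graph("t", t, alns)

    def test_balanced_branches_both_important(self):
        g = self._graph_with_branch(9, 10)  # S = 20 with template
        p = CorrectionParams()
        imp = mark_important_edges(g, p)
        cs = {node_c(e & 0xFFFFFFFF) for e in imp}
        assert 15 in cs
        by15 = [e for e in imp if node_c(e & 0xFFFFFFFF) == 15]
        assert len(by15) == 2

    def test_threshold_boundary(self):
        # S=20: threshold ~6.842 -> 6 supports not flagged, 7 flagged
        p = CorrectionParams()
        g = self._graph_with_branch(13, 6)  # minority branch support 6 of S=20
        by15 = [
            e for e in mark_important_edges(g, p)
            if node_c(e & 0xFFFFFFFF) == 15
        ]
        assert len(by15) == 1  # only the majority branch
        g = self._graph_with_branch(12, 7)
        by15 = [
            e for e in mark_important_edges(g, p)
            if node_c(e & 0xFFFFFFFF) == 15
        ]
        assert len(by15) == 2

    def test_important_location_rules(self):
        p = CorrectionParams()
        g = self._graph_with_branch(9, 10)
        locs = mark_important_locations(g, mark_important_edges(g, p), p)
        assert 15 in locs

    def test_homopolymer_location_excluded(self):
        t = "ACGTACGTAC" + "AAAAA" + "CGTACGTACG"
        q = t[:12] + "C" + t[13:]  # substitution inside the A-run
        alns = [_aln(f"x{i}", 0, f"{len(t)}=", t) for i in range(9)] + [
            _aln(f"y{i}", 0, "12=1X12=", q) for i in range(10)
        ]
        g = build_poa_graph("t", t, alns)
        p = CorrectionParams()
        locs = mark_important_locations(g, mark_important_edges(g, p), p)
        assert 12 not in locs

    def test_length_changing_bubble_excluded(self):
        t = ("ACGT" * 10)[:30]
        q_del = t[:15] + t[16:]  # 1-bp heterozygous deletion
        alns = [_aln(f"x{i}", 0, "30=", t) for i in range(9)] + [
            _aln(f"y{i}", 0, "15=1D14=", q_del) for i in range(10)
        ]
        g = build_poa_graph("t", t, alns)
        p = CorrectionParams()
        locs = mark_important_locations(g, mark_important_edges(g, p), p)
        assert 15 not in locs


class TestScoringSelection:
    def test_score_tally(self):
        t = ("ACGTA" * 12)[:60]
        sub = lambda pos, s: s[:pos] + ("G" if s[pos] != "G" else "T") + s[pos + 1:]
        # heterozygous-looking substitutions at 5 sites
        sites = [7, 18, 29, 41, 52]
        q = t
        for c in sites:
            q = sub(c, q)
        cig_alt = "".join(
            f"{n}=1X" for n in np.diff([-1] + sites) - 1
        ) + f"{59 - sites[-1]}="
        alns = [_aln(f"x{i}", 0, "60=", t) for i in range(8)] + [
            _aln(f"y{i}", 0, cig_alt, q) for i in range(8)
        ]
        g = build_poa_graph("t", t, alns)
        p = CorrectionParams()
        locs = mark_important_locations(g, mark_important_edges(g, p), p)
        assert set(sites) <= set(locs)
        scores = {s.read_id: s for s in score_supporting_reads(g, locs, p)}
        assert scores["x0"].normalized == 1.0
        assert scores["y0"].normalized == -1.0

    def test_bimodal_selection_takes_high_peak(self):
        scores = [SupportScore(f"a{i}", normalized=0.9) for i in range(10)] + [
            SupportScore(f"b{i}", normalized=-0.8) for i in range(10)
        ]
        out = select_and_weight(scores, CorrectionParams())
        sel = {s.read_id for s in out if s.selected}
        assert sel == {f"a{i}" for i in range(10)}

    def test_unimodal_selects_top_half(self):
        scores = [SupportScore(f"r{i}", normalized=v)
                  for i, v in enumerate(np.linspace(0.3, 0.5, 10))]
        out = select_and_weight(scores, CorrectionParams())
        assert sum(s.selected for s in out) == 5
        cut = sorted((s.normalized for s in out), reverse=True)[4]
        assert all(s.selected == (s.normalized >= cut) for s in out)

    def test_linear_weight_map(self):
        scores = [
            SupportScore("a", normalized=0.2),
            SupportScore("b", normalized=0.6),
            SupportScore("c", normalized=1.0),
        ]
        for s in scores:
            s.selected = True
        # force all selected through the <2 peak path: call with bimodal off
        out = select_and_weight(scores, CorrectionParams())
        chosen = {s.read_id: s.weight for s in out if s.selected}
        # whatever subset was selected, the map is linear onto [0.4, 0.8]
        vals = sorted(chosen.values())
        assert vals[0] == pytest.approx(0.4)
        assert vals[-1] == pytest.approx(0.8)

    def test_single_read_gets_midpoint(self):
        out = select_and_weight([SupportScore("a", normalized=0.5)],
                                CorrectionParams())
        assert out[0].selected and out[0].weight == pytest.approx(0.6)


class TestConsensus:
    def test_identical_supports_reproduce_template(self):
        t = ("ACGT" * 25)[:100]
        alns = [_aln(f"s{i}", 0, "100=", t) for i in range(5)]
        g = build_poa_graph("t", t, alns)
        seq, _ = consensus(g, {f"s{i}": 0.6 for i in range(5)},
                           CorrectionParams())
        assert seq == t

    def test_majority_corrects_template_error(self):
        true = ("ACGTA" * 20)[:100]
        t = true[:50] + ("G" if true[50] != "G" else "C") + true[51:]
        alns = [_aln(f"s{i}", 0, "50=1X49=", true) for i in range(9)]
        g = build_poa_graph("t", t, alns)
        seq, _ = consensus(g, {f"s{i}": 0.6 for i in range(9)},
                           CorrectionParams())
        assert seq == true

    def test_no_weights_returns_template(self):
        t = "ACGTACGTACGT"
        g = build_poa_graph("t", t, [])
        seq, _ = consensus(g, {}, CorrectionParams())
        assert seq == t

    def test_dp_matches_exhaustive_enumeration(self):
        """Brute-force oracle: enumerate all source->terminal paths on small
        graphs and score them with the same objective."""
        rng = np.random.default_rng(5)
        p = CorrectionParams()
        for trial in range(30):
            L = 4
            t = "".join("ACGT"[i] for i in rng.integers(0, 4, size=L))
            alns = []
            for j in range(3):
                # random single-substitution support
                pos = int(rng.integers(0, L))
                base = "ACGT"[int(rng.integers(0, 4))]
                q = t[:pos] + base + t[pos + 1:]
                cig = []
                for k, (x, y) in enumerate(zip(t, q)):
                    cig.append("1=" if x == y else "1X")
                alns.append(_aln(f"s{j}", 0, "".join(cig), q))
            g = build_poa_graph("t", t, alns)
            weights = {f"s{j}": 0.5 + 0.07 * j for j in range(3)}
            seq, _ = consensus(g, weights, p)
            by_seq, best_score = _enumerate_best(g, weights, p)
            # the DP's sequence must achieve the enumerated optimum (score
            # ties between distinct optimal paths are broken arbitrarily)
            assert by_seq.get(seq) == pytest.approx(best_score), (t, trial)

    def test_selection_disabled_equals_plain_on_homozygous(self, noisy_sim):
        _, _, _, reads = noisy_sim
        from diphase.overlap import find_candidate_overlaps

        names = sorted(reads)[:30]
        sub = {n: reads[n] for n in names}
        ovs = find_candidate_overlaps(sub, k=13, w=8, min_shared=4)
        p = CorrectionParams(max_supporting_reads=10)
        rec = correct_read(names[0], ovs, sub, p, haplotype_aware=True)
        assert rec.sequence


def _enumerate_best(g, weights, p):
    """All-paths enumeration using the consensus objective."""
    from collections import defaultdict

    w_edges = defaultdict(float)
    wc = np.zeros(len(g.template) + 1)
    for name, w in weights.items():
        if w <= 0 or name not in g.paths:
            continue
        c0, c1 = g.spans[name]
        wc[c0] += w
        wc[c1 + 1] -= w
        path = g.paths[name]
        for e in ((path[:-1].astype(np.int64) << 32) | path[1:]).tolist():
            w_edges[e] += w
    wc = np.cumsum(wc)[: len(g.template)]
    covered = np.flatnonzero(wc > 1e-12)
    c_last = int(covered[-1])

    adj = defaultdict(list)
    targets = set()
    sources = set()
    for e in g.edges.tolist():
        u, v = e >> 32, e & 0xFFFFFFFF
        adj[u].append((v, e))
        targets.add(v)
        sources.add(u)
    starts = sources - targets
    best = (None, -np.inf)
    import itertools

    def penalty(v):
        c, r = v >> 11, (v >> 3) & 0xFF
        return max(p.pc_base ** r, p.pc_floor) * (
            wc[c] if c < len(g.template) else 0.0
        )

    by_seq: dict[str, float] = {}
    best_score = -np.inf
    stack = [(s, 0.0, [s]) for s in sorted(starts)]
    while stack:
        node, score, path = stack.pop()
        if (node >> 11) == c_last:
            seq = "".join("ACGT-"[v & 0x7] for v in path if (v & 0x7) != 4)
            if score > by_seq.get(seq, -np.inf):
                by_seq[seq] = score
            best_score = max(best_score, score)
        for v, e in adj[node]:
            stack.append((v, score + w_edges.get(e, 0.0) - penalty(v), path + [v]))
    return by_seq, best_score
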