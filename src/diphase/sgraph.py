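"""Directed string graph over oriented read ends, and its simplification.

Every non-contained read contributes two vertices, its 5' (``B``) and 3'
(``E``) end; a dovetail overlap contributes a directed edge and its
reverse-complement twin. Simplification proceeds in stages: Myers' transitive
marking, identity thresholding (six-sigma MAD rule), dead-end repair through
reactivated transitive edges and contained reads, SNP-aware best-overlap
selection, and ambiguous-edge removal; maximal linear paths become contigs.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .overlap import Overlap, compute_identity
from .rules import bog_gap_ok, identity_threshold
from .simdata import revcomp

log = logging.getLogger(__name__)

Node = tuple[str, str]  # (read id, 'B' | 'E')

ACTIVE = "active"
TRANSITIVE = "transitive"
REMOVED_LOW_QUALITY = "removed_low_quality"
REACTIVATED = "reactivated"
ADDED_CONTAINED = "added_contained"
REMOVED_AMBIGUOUS = "removed_ambiguous"
BEST = "best"

LIVE = {ACTIVE, REACTIVATED, ADDED_CONTAINED, BEST}


def flip(node: Node) -> Node:
    return (node[0], "B" if node[1] == "E" else "E")


@dataclass
class SgEdge:
    source: Node
    target: Node
    length: int              # unaligned suffix appended when traversing
    overlap: Overlap | None
    aln_len: int
    identity: float | None = None
    status: str = ACTIVE

    @property
    def key(self) -> tuple[Node, Node]:
        return (self.source, self.target)

    @property
    def dual_key(self) -> tuple[Node, Node]:
        return (flip(self.target), flip(self.source))


@dataclass
class IdentityStats:
    m1: float
    m2: float
    mad1: float
    mad2: float
    threshold: float

    @classmethod
    def from_identities(cls, idents: list[float]) -> "IdentityStats":
        x = np.asarray(idents, float)
        return cls(
            float(np.mean(x)), float(np.median(x)),
            float(np.mean(np.abs(x - np.mean(x)))),
            float(np.median(np.abs(x - np.median(x)))),
            identity_threshold(x),
        )


@dataclass
class BogParams:
    w: float = 0.5
    C: float = 4.0
    R1: float = 2.0
    R2: float = 0.66

    def __post_init__(self) -> None:
        if min(self.w, self.C, self.R1, self.R2) <= 0:
            raise ValueError("BOG parameters must be positive")


class StringGraph:
    def __init__(self) -> None:
        self.edges: dict[tuple[Node, Node], SgEdge] = {}
        self.out: dict[Node, dict[Node, SgEdge]] = defaultdict(dict)
        self.inn: dict[Node, dict[Node, SgEdge]] = defaultdict(dict)
        self.reads: set[str] = set()
        self.identity_cutoff: float | None = None

    # -- basic ops ----------------------------------------------------------
    def add_edge(self, e: SgEdge) -> None:
        self.edges[e.key] = e
        self.out[e.source][e.target] = e
        self.inn[e.target][e.source] = e
        self.reads.add(e.source[0])
        self.reads.add(e.target[0])

    def set_status(self, e: SgEdge, status: str, sync_dual: bool = True) -> None:
        e.status = status
        if sync_dual:
            d = self.edges.get(e.dual_key)
            if d is not None:
                d.status = status

    def live_out(self, v: Node) -> list[SgEdge]:
        return [e for e in self.out.get(v, {}).values() if e.status in LIVE]

    def live_in(self, v: Node) -> list[SgEdge]:
        return [e for e in self.inn.get(v, {}).values() if e.status in LIVE]

    def nodes(self) -> list[Node]:
        seen = set()
        for e in self.edges.values():
            seen.add(e.source)
            seen.add(e.target)
        return sorted(seen)

    def status_counts(self) -> dict[str, int]:
        counts: dict[str, int] = defaultdict(int)
        for e in self.edges.values():
            counts[e.status] += 1
        return dict(counts)

    def check_dual_symmetry(self) -> bool:
        return all(
            self.edges.get(e.dual_key) is not None
            and self.edges[e.dual_key].status == e.status
            for e in self.edges.values()
        )


def _edge_pair_for_overlap(ov: Overlap) -> list[SgEdge] | None:
    """Classify a dovetail overlap into its string-graph edge pair."""
    a_left, b_left, a_right, b_right = ov.flanks()
    aln_len = ((ov.a_end - ov.a_start) + (ov.b_end - ov.b_start)) // 2
    b_fwd: Node = (ov.read_b, "E" if ov.strand == "+" else "B")
    b_rev: Node = (ov.read_b, "B" if ov.strand == "+" else "E")
    # residual inner overhangs (tolerated by the filter) are subtracted so a
    # spliced junction neither drops nor duplicates the unaligned slack
    if a_left >= b_left and a_right <= b_right:
        # suffix of a matches prefix of oriented b
        e1 = SgEdge((ov.read_a, "E"), b_fwd, max(b_right - a_right, 0),
                    ov, aln_len, ov.identity)
        e2 = SgEdge(b_rev, (ov.read_a, "B"), max(a_left - b_left, 0),
                    ov, aln_len, ov.identity)
        return [e1, e2]
    if b_left >= a_left and b_right <= a_right:
        e1 = SgEdge(b_fwd, (ov.read_a, "E"), max(a_right - b_right, 0),
                    ov, aln_len, ov.identity)
        e2 = SgEdge((ov.read_a, "B"), b_rev, max(b_left - a_left, 0),
                    ov, aln_len, ov.identity)
        return [e1, e2]
    return None  # containment; not a dovetail


def build_string_graph(overlaps: list[Overlap]) -> StringGraph:
    """Construct the graph from retained dovetail overlaps; non-dovetails are
    skipped with a log message."""
    g = StringGraph()
    for ov in overlaps:
        pair = _edge_pair_for_overlap(ov)
        if pair is None:
            log.debug("skipping non-dovetail overlap %s/%s", ov.read_a, ov.read_b)
            continue
        for e in pair:
            g.add_edge(e)
    return g


# ---------------------------------------------------------------------------
# transitive marking (Myers)


def mark_transitive(g: StringGraph, fuzz: int = 500) -> StringGraph:
    """Mark transitive edges inactive: an edge v->x implied by shorter edges
    v->w->x (within ``fuzz``) does not contribute to contigs."""
    VACANT, INPLAY, ELIMINATED = 0, 1, 2
    mark: dict[Node, int] = defaultdict(int)
    reduce_edge: set[tuple[Node, Node]] = set()
    for v in g.nodes():
        out = sorted(g.live_out(v), key=lambda e: (e.length, e.target))
        if not out:
            continue
        for e in out:
            mark[e.target] = INPLAY
        longest = out[-1].length + fuzz
        for e in out:
            w = e.target
            if mark[w] != INPLAY:
                continue
            for e2 in sorted(g.live_out(w), key=lambda x: (x.length, x.target)):
                if e.length + e2.length > longest:
                    break
                if mark[e2.target] == INPLAY:
                    mark[e2.target] = ELIMINATED
        for e in out:
            if mark[e.target] == ELIMINATED:
                reduce_edge.add(e.key)
            mark[e.target] = VACANT
    for key in reduce_edge:
        g.set_status(g.edges[key], TRANSITIVE)
    return g


def transitive_reduction_bruteforce(g: StringGraph, fuzz: int = 500) -> set[tuple[Node, Node]]:
    """O(V*E) oracle: an edge is transitive iff some two-edge live path joins
    its endpoints with total length within fuzz of the edge length."""
    marked = set()
    for e in g.edges.values():
        if e.status not in LIVE:
            continue
        for mid in list(g.out.get(e.source, {})):
            if mid == e.target:
                continue
            e1 = g.out[e.source][mid]
            e2 = g.out.get(mid, {}).get(e.target)
            if e2 is None or e1.status not in LIVE or e2.status not in LIVE:
                continue
            if abs(e1.length + e2.length - e.length) <= fuzz:
                marked.add(e.key)
                break
    return marked


# ---------------------------------------------------------------------------
# identity filter and dead-end repair


def identity_filter(
    g: StringGraph, reads: dict[str, str] | None = None
) -> tuple[StringGraph, IdentityStats | None]:
    """Compute identities of active edges, derive the six-sigma MAD threshold,
    and remove active edges below it."""
    active = [e for e in g.edges.values() if e.status in LIVE]
    for e in active:
        if e.identity is None:
            if reads is None:
                raise ValueError("reads required to compute edge identities")
            e.identity = compute_identity(e.overlap, reads)
            d = g.edges.get(e.dual_key)
            if d is not None:
                d.identity = e.identity
    # one identity per overlap (the edge pair shares it)
    idents = sorted({(min(e.key, e.dual_key)): e.identity for e in active}.values())
    if len(idents) < 3:
        log.warning("fewer than 3 active edges; identity filter skipped")
        return g, None
    stats = IdentityStats.from_identities(idents)
    g.identity_cutoff = stats.threshold
    for e in active:
        if e.identity < stats.threshold:
            g.set_status(e, REMOVED_LOW_QUALITY)
    return g, stats


def _dead_ends(g: StringGraph) -> list[Node]:
    return [v for v in g.nodes() if not g.live_out(v)]


def repair_dead_ends(
    g: StringGraph,
    contained: dict[str, list[Overlap]],
    reads: dict[str, str] | None = None,
    inconsistent: set[tuple[str, str]] | None = None,
) -> StringGraph:
    """Reconnect paths broken by the identity filter.

    For every dead-end node, the transitive out-edge with the longest
    alignment whose identity clears the threshold is reactivated; remaining
    dead-ends are extended with contained reads from the side table.
    """
    thr = g.identity_cutoff if g.identity_cutoff is not None else -1.0
    for v in _dead_ends(g):
        cands = [e for e in g.out.get(v, {}).values() if e.status == TRANSITIVE]
        best = None
        for e in sorted(cands, key=lambda e: -e.aln_len):
            if e.identity is None and reads is not None and e.overlap is not None:
                e.identity = compute_identity(e.overlap, reads)
            if e.identity is not None and e.identity >= thr:
                best = e
                break
        if best is not None:
            g.set_status(best, REACTIVATED)
    # contained-read extension
    inconsistent = inconsistent or set()
    for v in _dead_ends(g):
        rid = v[0]
        added = False
        for ov in _contained_overlaps_for(contained, rid):
            if (min(ov.read_a, ov.read_b), max(ov.read_a, ov.read_b)) in inconsistent:
                continue  # never bridge with a cross-haplotype overlap
            if reads is not None:
                ident = compute_identity(ov, reads)
                if ident < thr:
                    continue
                ov.identity = ident
            pair = _edge_pair_for_overlap(ov)
            if pair is None:
                continue
            if any(e.source == v for e in pair):  # the pair members are duals
                for e in pair:
                    e.status = ADDED_CONTAINED
                    g.add_edge(e)
                added = True
            if added:
                break
    return g


def _contained_overlaps_for(
    contained: dict[str, list[Overlap]], rid: str
) -> list[Overlap]:
    out = []
    for ovs in contained.values():
        for ov in ovs:
            if rid in (ov.read_a, ov.read_b):
                out.append(ov)
    return sorted(out, key=lambda ov: -(ov.a_end - ov.a_start))


# ---------------------------------------------------------------------------
# best overlap selection


def best_overlap_select(
    g: StringGraph,
    snp_evidence: dict[tuple[str, str], tuple[int, int]],
    inconsistent: set[tuple[str, str]],
    p: BogParams | None = None,
) -> StringGraph:
    """SNP-aware best-overlap-graph pruning.

    Each edge scores ``(n+ * w - n-, overlap length)`` from the per-read-pair
    agreement counts. For each node side the top edge is a candidate; further
    edges become candidates only when their read is inconsistent with every
    current candidate's read and their score gap from the top edge obeys the
    piecewise bound. Edges marked candidate from both sides become best; a
    side left without a best edge falls back to its top edge; everything else
    is removed.
    """
    p = p or BogParams()

    def pair_key(e: SgEdge) -> tuple[str, str]:
        a, b = e.source[0], e.target[0]
        return (a, b) if a <= b else (b, a)

    def score(e: SgEdge) -> tuple[float, int]:
        n_pos, n_neg = snp_evidence.get(pair_key(e), (0, 0))
        return (n_pos * p.w - n_neg, e.aln_len)

    def candidates(edges: list[SgEdge], other_read) -> set[tuple[Node, Node]]:
        if not edges:
            return set()
        ranked = sorted(edges, key=score, reverse=True)
        cand = [ranked[0]]
        s0 = score(ranked[0])[0]
        for e in ranked[1:]:
            si = score(e)[0]
            r = other_read(e)
            if not all(
                tuple(sorted((r, other_read(c)))) in inconsistent for c in cand
            ):
                continue
            if bog_gap_ok(s0, si, p.C, p.R1, p.R2):
                cand.append(e)
        return {e.key for e in cand}

    out_cand: set[tuple[Node, Node]] = set()
    in_cand: set[tuple[Node, Node]] = set()
    for v in g.nodes():
        out_cand |= candidates(g.live_out(v), lambda e: e.target[0])
        in_cand |= candidates(g.live_in(v), lambda e: e.source[0])

    best = out_cand & in_cand
    # dual symmetry
    best |= {g.edges[k].dual_key for k in list(best) if g.edges[k].dual_key in g.edges}
    for v in g.nodes():
        outs = g.live_out(v)
        if outs and not any(e.key in best for e in outs):
            e = max(outs, key=score)
            best.add(e.key)
            best.add(e.dual_key)
        ins = g.live_in(v)
        if ins and not any(e.key in best for e in ins):
            e = max(ins, key=score)
            best.add(e.key)
            best.add(e.dual_key)
    for e in list(g.edges.values()):
        if e.status in LIVE:
            g.set_status(e, BEST if e.key in best else REMOVED_AMBIGUOUS,
                         sync_dual=False)
    return g


# ---------------------------------------------------------------------------
# ambiguous-structure removal and contig extraction


def _linear_walk(g: StringGraph, start: Node, forward: bool) -> list[SgEdge]:
    """Follow the unique live chain from start until a junction or dead end."""
    edges = []
    v = start
    seen = {start}
    while True:
        nxt = g.live_out(v) if forward else g.live_in(v)
        if len(nxt) != 1:
            break
        e = nxt[0]
        w = e.target if forward else e.source
        degree = g.live_in(w) if forward else g.live_out(w)
        edges.append(e)
        if len(degree) != 1 or w in seen:
            break
        seen.add(w)
        v = w
    return edges


def simplify_ambiguous(
    g: StringGraph,
    pop_bubbles: bool = True,
    tip_max_reads: int = 3,
    spur_frac: float = 0.3,
    max_rounds: int = 5,
) -> StringGraph:
    """Remove tips, spurious links, and (round 1 only) pop simple bubbles."""
    from .diploid import detect_bubbles  # shared bubble finder

    for _ in range(max_rounds):
        changed = False
        # tips: short dead-end chains hanging off junctions
        for v in g.nodes():
            if g.live_out(v) or not g.live_in(v):
                continue
            chain = _linear_walk(g, v, forward=False)
            if 0 < len(chain) <= tip_max_reads:
                tail = chain[-1].source
                if len(g.live_out(tail)) > 1:  # tips hang off junctions only
                    for e in chain:
                        g.set_status(e, REMOVED_AMBIGUOUS)
                    changed = True
        # spurious links: far weaker than the strongest sibling
        for v in g.nodes():
            outs = g.live_out(v)
            if len(outs) >= 2:
                m = max(e.aln_len for e in outs)
                for e in outs:
                    if e.aln_len < spur_frac * m:
                        g.set_status(e, REMOVED_AMBIGUOUS)
                        changed = True
        if pop_bubbles:
            for b in detect_bubbles(g):
                weaker = min(
                    (b.path1, b.path2),
                    key=lambda path: (len(path), sum(e.aln_len for e in path)),
                )
                for e in weaker:
                    if e.status in LIVE:
                        g.set_status(e, REMOVED_AMBIGUOUS)
                        changed = True
        if not changed:
            break
    return g


@dataclass
class Contig:
    name: str
    sequence: str
    layout: list[tuple[str, str, int]] = field(default_factory=list)  # read, strand, offset
    path: list[Node] = field(default_factory=list)


def _oriented(reads: dict[str, str], node: Node) -> str:
    seq = reads[node[0]]
    return seq if node[1] == "E" else revcomp(seq)


def extract_contigs(
    g: StringGraph, reads: dict[str, str], prefix: str = "ctg"
) -> list[Contig]:
    """Splice maximal unbranched live paths into contig sequences.

    Each read lands in at most one contig (a path and its reverse-complement
    twin produce a single contig). Cycles are broken at the lowest-identity
    edge. Reads with no live edges become singleton contigs.
    """
    # break cycles first
    for e in _find_cycle_edges(g):
        log.warning("breaking cycle at %s->%s", e.source, e.target)
        g.set_status(e, REMOVED_AMBIGUOUS)

    used_reads: set[str] = set()
    used_edges: set[tuple[Node, Node]] = set()
    contigs: list[Contig] = []

    def emit(path_edges: list[SgEdge]) -> None:
        nodes = [path_edges[0].source] + [e.target for e in path_edges]
        # trim nodes whose reads already sit in another contig (shared
        # junction reads, or the reverse-complement twin of an emitted path)
        lo = 0
        while lo < len(nodes) and nodes[lo][0] in used_reads:
            lo += 1
        hi = len(nodes)
        while hi > lo and nodes[hi - 1][0] in used_reads:
            hi -= 1
        nodes = nodes[lo:hi]
        path_edges = path_edges[lo : hi - 1] if hi - lo >= 2 else []
        if not nodes or any(n[0] in used_reads for n in nodes):
            return
        for n in nodes:
            used_reads.add(n[0])
        seq = _oriented(reads, nodes[0])
        layout = [(nodes[0][0], "+" if nodes[0][1] == "E" else "-", 0)]
        for e, n in zip(path_edges, nodes[1:]):
            offset = len(seq) - (len(reads[n[0]]) - e.length)
            if e.length > 0:
                seq += _oriented(reads, n)[-e.length :]
            layout.append((n[0], "+" if n[1] == "E" else "-", max(offset, 0)))
        contigs.append(Contig(f"{prefix}{len(contigs):04d}", seq, layout, nodes))

    def interior(w: Node) -> bool:
        return len(g.live_in(w)) == 1 and len(g.live_out(w)) == 1

    start_edges = sorted(
        (e for e in g.edges.values() if e.status in LIVE and not interior(e.source)),
        key=lambda e: (e.source, e.target),
    )
    for e0 in start_edges:
        if e0.key in used_edges:
            continue
        chain = [e0]
        used_edges.add(e0.key)
        w = e0.target
        while interior(w):
            e = g.live_out(w)[0]
            if e.key in used_edges:
                break
            chain.append(e)
            used_edges.add(e.key)
            w = e.target
        emit(chain)
    for rid in sorted(g.reads - used_reads):
        used_reads.add(rid)
        contigs.append(Contig(f"{prefix}{len(contigs):04d}", reads[rid], [(rid, "+", 0)],
                              [(rid, "E")]))
    return contigs


def _find_cycle_edges(g: StringGraph) -> list[SgEdge]:
    """Lowest-identity edge of each live cycle."""
    import networkx as nx

    dg = nx.DiGraph()
    for e in g.edges.values():
        if e.status in LIVE:
            dg.add_edge(e.source, e.target)
    out = []
    try:
        while True:
            cyc = nx.find_cycle(dg)
            edges = [g.edges[(u, v)] for u, v, *_ in [(c[0], c[1]) for c in cyc]]
            worst = min(edges, key=lambda e: (e.identity if e.identity is not None else 0.0))
            out.append(worst)
            dg.remove_edge(*worst.key)
            d = worst.dual_key
            if dg.has_edge(*d):
                dg.remove_edge(*d)
    except nx.NetworkXNoCycle:
        pass
    return out
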