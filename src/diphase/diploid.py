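"""Second-round assembly: bubbles, alternate branches, two sets of contigs.

After inconsistent overlaps are removed, the rebuilt string graph separates
haplotypes either into bubble structures (two parallel paths between a shared
source and sink), into alternate branches (a junction whose shorter linear
branch is mostly inconsistent with the other), or into fully independent
contigs. Primary paths traverse one side of every bubble/branch without
breaking; the other sides become alternate contigs. For the dual-assembly
format, paths through adjacent bubbles are connected by matching the allele
centroids of their flanking read groups, and independent contig pairs that
are mutually inconsistent are split across the two haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phase import AlleleMatrix, Centroid, centroid_sets
from .sgraph import LIVE, Contig, Node, SgEdge, StringGraph, extract_contigs

log = logging.getLogger(__name__)


@dataclass
class Bubble:
    source: Node
    sink: Node
    path1: list[SgEdge]
    path2: list[SgEdge]

    def reads(self, which: int) -> list[str]:
        path = self.path1 if which == 1 else self.path2
        out = []
        for e in path:
            if e.source[0] not in out:
                out.append(e.source[0])
            if e.target[0] not in out:
                out.append(e.target[0])
        interior = [r for r in out if r not in (self.source[0], self.sink[0])]
        return interior or out


def _walk_branch(g: StringGraph, e0: SgEdge, cap: int) -> list[SgEdge]:
    """Follow a branch linearly from its first edge until a junction,
    reconvergence point, or the depth cap."""
    chain = [e0]
    v = e0.target
    for _ in range(cap):
        outs = g.live_out(v)
        ins = g.live_in(v)
        if len(ins) != 1 or len(outs) != 1:
            break
        chain.append(outs[0])
        v = outs[0].target
    return chain


def detect_bubbles(g: StringGraph, depth_cap: int = 50) -> list[Bubble]:
    """Simple two-path bubbles: a node with exactly two live out-edges whose
    branches rejoin at a common node with internally disjoint paths."""
    bubbles = []
    seen_pairs = set()
    for v in g.nodes():
        outs = g.live_out(v)
        if len(outs) != 2:
            continue
        b1 = _walk_branch(g, outs[0], depth_cap)
        b2 = _walk_branch(g, outs[1], depth_cap)
        n1 = [e.target for e in b1]
        n2 = [e.target for e in b2]
        common = next((n for n in n1 if n in n2), None)
        if common is None:
            continue
        p1 = b1[: n1.index(common) + 1]
        p2 = b2[: n2.index(common) + 1]
        int1 = {e.target for e in p1[:-1]}
        int2 = {e.target for e in p2[:-1]}
        if int1 & int2:
            continue
        key = (v, common)
        if key in seen_pairs or (tuple(reversed(key)) in seen_pairs):
            continue
        seen_pairs.add(key)
        bubbles.append(Bubble(v, common, p1, p2))
    return bubbles


def detect_alternate_branches(
    g: StringGraph,
    inconsistent: set[tuple[str, str]],
    depth_cap: int = 50,
    min_frac: float = 0.3,
) -> list[tuple[list[SgEdge], list[SgEdge]]]:
    """Two-branch junctions whose shorter, branch-free arm is mostly
    inconsistent with the other arm; returns (shorter, longer) edge lists."""
    out = []
    for v in g.nodes():
        outs = g.live_out(v)
        if len(outs) != 2:  # condition (1): exactly two branches
            continue
        b1 = _walk_branch(g, outs[0], depth_cap)
        b2 = _walk_branch(g, outs[1], depth_cap)
        # skip if they reconverge (that is a bubble)
        if any(e.target in [x.target for x in b2] for e in b1):
            continue
        short, long_ = (b1, b2) if len(b1) <= len(b2) else (b2, b1)
        tail = short[-1].target
        if g.live_out(tail):  # not linear to a dead end: branch continues
            continue
        reads_s = {e.target[0] for e in short} | {short[0].source[0]} - {v[0]}
        reads_l = {e.target[0] for e in long_}
        if not reads_s:
            continue
        n_inc = sum(
            1 for r in reads_s
            if any((min(r, q), max(r, q)) in inconsistent for q in reads_l)
        )
        if n_inc / len(reads_s) > min_frac:
            out.append((short, long_))
    return out


def _mask_edges(g: StringGraph, edges: set[tuple[Node, Node]], tag: str) -> dict:
    saved = {}
    for key in edges:
        e = g.edges.get(key)
        if e is not None and e.status in LIVE:
            saved[key] = e.status
            e.status = tag
    return saved


def _restore(g: StringGraph, saved: dict) -> None:
    for key, st in saved.items():
        g.edges[key].status = st


def _with_duals(g: StringGraph, edges: list[SgEdge]) -> set[tuple[Node, Node]]:
    keys = set()
    for e in edges:
        keys.add(e.key)
        if e.dual_key in g.edges:
            keys.add(e.dual_key)
    return keys


def _interior_contig(
    g: StringGraph, reads: dict[str, str], path: list[SgEdge], name: str
) -> Contig | None:
    """Splice the interior reads of a bubble side / branch into a contig.

    For a bubble side the shared source is excluded and, when the path
    reconverges, the shared sink too; a direct source->sink edge has no
    interior and yields nothing.
    """
    from .sgraph import _oriented

    nodes = [e.target for e in path]
    last = path[-1].target
    if g.live_out(last) or g.live_in(last):  # reconverging side: drop sink
        converges = len(g.live_in(last)) > 1
    else:
        converges = False
    if converges:
        nodes = nodes[:-1]
    if not nodes:
        return None
    seq = _oriented(reads, nodes[0])
    layout = [(nodes[0][0], "+" if nodes[0][1] == "E" else "-", 0)]
    for e, n in zip(path[1:], nodes[1:]):
        offset = len(seq) - (len(reads[n[0]]) - e.length)
        if e.length > 0:
            seq += _oriented(reads, n)[-e.length :]
        layout.append((n[0], "+" if n[1] == "E" else "-", max(offset, 0)))
    return Contig(name, seq, layout, nodes)


def _drop_masked_singletons(
    contigs: list[Contig], masked: set[tuple[Node, Node]]
) -> list[Contig]:
    """Reads whose edges were masked out for this extraction must not leak
    back in as singleton contigs."""
    masked_reads = {k[0][0] for k in masked} | {k[1][0] for k in masked}
    return [
        c for c in contigs
        if not (len(c.layout) == 1 and c.layout[0][0] in masked_reads)
    ]


def _weaker_side(b: Bubble) -> list[SgEdge]:
    span = lambda path: sum(e.length for e in path)
    return min((b.path1, b.path2), key=lambda path: (len(path), span(path)))


def _contig_inconsistency(
    a: Contig, b: Contig, inconsistent: set[tuple[str, str]]
) -> float:
    """Fraction of the first contig's layout reads inconsistent with any read
    of the second contig's layout."""
    reads_b = {r for r, _, _ in b.layout}
    if not a.layout:
        return 0.0
    n = sum(
        1 for r, _, _ in a.layout
        if any((min(r, q), max(r, q)) in inconsistent for q in reads_b)
    )
    return n / len(a.layout)


def emit_primary_alternate(
    g: StringGraph,
    reads: dict[str, str],
    inconsistent: set[tuple[str, str]],
    depth_cap: int = 50,
) -> tuple[list[Contig], list[Contig], list[Bubble]]:
    """Primary contigs traverse one side of each bubble / alternate branch;
    the other sides, and shorter independent contigs that are >30%
    inconsistent with a longer one, become alternates."""
    bubbles = detect_bubbles(g, depth_cap)
    branches = detect_alternate_branches(g, inconsistent, depth_cap)
    alt_keys: set[tuple[Node, Node]] = set()
    for b in bubbles:
        alt_keys |= _with_duals(g, _weaker_side(b))
    for short, _ in branches:
        alt_keys |= _with_duals(g, short)

    saved = _mask_edges(g, alt_keys, "altside")
    primary = _drop_masked_singletons(extract_contigs(g, reads, prefix="pri"),
                                      alt_keys)
    _restore(g, saved)

    # alternate contigs: the divergent interiors of the other sides
    alternates = []
    seen_interiors: set[frozenset] = set()
    alt_paths = [_weaker_side(b) for b in bubbles] + [s for s, _ in branches]
    for i, path in enumerate(alt_paths):
        interior = _interior_contig(g, reads, path, f"alt{len(alternates):04d}")
        if interior is None:
            continue
        key = frozenset(r for r, _, _ in interior.layout)
        if key in seen_interiors:
            continue  # reverse-complement twin of an emitted path
        seen_interiors.add(key)
        alternates.append(interior)

    # independent-contig demotion
    primary.sort(key=lambda c: -len(c.sequence))
    demoted: list[Contig] = []
    kept: list[Contig] = []
    for c in primary:
        if any(
            _contig_inconsistency(c, other, inconsistent) > 0.3 for other in kept
        ):
            demoted.append(c)
        else:
            kept.append(c)
    # contigs that merely duplicate a longer primary without any haplotype
    # signal are assembly redundancy, not alternates; drop them
    kept = _purge_redundant(kept)
    for i, c in enumerate(demoted):
        c.name = f"alt-ctg{i:04d}"
    return kept, alternates + demoted, bubbles


def _group_centroid(m: AlleleMatrix, read_names: list[str]) -> Centroid:
    rows = np.array([m.row[r] for r in read_names if r in m.row], dtype=int)
    if not len(rows):
        rows = np.empty(0, dtype=int)
    return Centroid.of(m.H, rows)


def connect_dual_paths(
    g: StringGraph,
    reads: dict[str, str],
    m: AlleleMatrix | None,
    inconsistent: set[tuple[str, str]],
    seed: int = 0,
    depth_cap: int = 50,
) -> tuple[list[Contig], list[Contig]]:
    """Dual assembly: two parallel contig sets.

    Sides of each bubble are assigned to haplotype 1/2; adjacent bubbles are
    phased by minimizing the summed centroid distance between the out-groups
    of one bubble and the in-groups of the next (random, seeded, when they
    share no informative site). Independent contigs that are mutually
    inconsistent are paired and split across the haplotypes (longer one to
    haplotype 1, matching the convention of placing unpaired sequence there).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    bubbles = detect_bubbles(g, depth_cap)
    assign: dict[int, int] = {}  # bubble index -> side of hap1 (1 or 2)
    prev = None
    for i, b in enumerate(bubbles):
        if prev is None:
            assign[i] = 1
        else:
            pb = bubbles[prev]
            side_prev = assign[prev]
            o1 = pb.reads(side_prev)
            o2 = pb.reads(3 - side_prev)
            best, best_d = None, None
            if m is not None:
                co1, co2 = _group_centroid(m, o1), _group_centroid(m, o2)
                for cand in (1, 2):
                    ci1 = _group_centroid(m, b.reads(cand))
                    ci2 = _group_centroid(m, b.reads(3 - cand))
                    tot_a = 0
                    tot_d = 0
                    for ca, cb in ((co1, ci1), (co2, ci2)):
                        a_m, _, d_m = centroid_sets(ca, cb, 0.0, 1.0)
                        tot_a += int(a_m.sum())
                        tot_d += int(d_m.sum())
                    if tot_a and (best_d is None or tot_d < best_d):
                        best, best_d = cand, tot_d
            if best is None:
                best = int(rng.integers(1, 3))  # no shared informative site
            assign[i] = best
        prev = i

    def extract_hap(which: int) -> list[Contig]:
        excl: set = set()
        for i, b in enumerate(bubbles):
            keep_side = assign[i] if which == 1 else 3 - assign[i]
            excl |= _with_duals(g, b.path2 if keep_side == 1 else b.path1)
        saved = _mask_edges(g, excl, "otherside")
        contigs = _drop_masked_singletons(
            extract_contigs(g, reads, prefix=f"hap{which}-ctg"), excl
        )
        _restore(g, saved)
        return contigs

    hap1 = extract_hap(1)
    hap2 = extract_hap(2)

    # Contigs with identical read layouts in both extractions were not touched
    # by any bubble: either genuinely shared (collapsed homozygous sequence,
    # kept in both sets) or one of a fully separated haplotype pair — those
    # are paired up by the mutual-inconsistency rule and split across the two
    # haplotypes, the longer one going to haplotype 1.
    key = lambda c: frozenset(r for r, _, _ in c.layout)
    in2 = {key(c) for c in hap2}
    shared = sorted(
        (c for c in hap1 if key(c) in in2), key=lambda c: -len(c.sequence)
    )
    taken: dict[frozenset, int] = {}
    for i, c in enumerate(shared):
        if key(c) in taken:
            continue
        for j in range(i + 1, len(shared)):
            other = shared[j]
            if key(other) in taken:
                continue
            if _contig_inconsistency(other, c, inconsistent) > 0.3:
                taken[key(c)] = 1
                taken[key(other)] = 2
                break
    if taken:
        hap1 = [c for c in hap1 if taken.get(key(c), 1) == 1]
        hap2 = [c for c in hap2 if taken.get(key(c), 2) == 2]
    # a short leftover contig whose sequence already sits inside a longer
    # contig of the same set adds no haplotype information; drop it
    hap1 = _purge_redundant(hap1)
    hap2 = _purge_redundant(hap2)
    for i, c in enumerate(hap1):
        c.name = f"hap1-ctg{i:04d}"
    for i, c in enumerate(hap2):
        c.name = f"hap2-ctg{i:04d}"
    return hap1, hap2


def _purge_redundant(contigs: list[Contig], min_ident: float = 0.93) -> list[Contig]:
    from .evalkit import align_identity

    kept: list[Contig] = []
    for c in sorted(contigs, key=lambda c: -len(c.sequence)):
        if any(
            len(c.sequence) <= len(o.sequence)
            and align_identity(c.sequence, o.sequence) >= min_ident
            for o in kept
        ):
            continue
        kept.append(c)
    return kept


def filter_polish_alignments(
    alignments: dict[str, "object"],
    contig_layouts: dict[str, list[tuple[str, str, int]]],
    inconsistent: set[tuple[str, str]],
) -> dict[str, "object"]:
    """Drop read-to-contig alignments of reads inconsistent with any read in
    the contig's layout (the polishing-stage switch-error guard)."""
    out = {}
    for rname, pl in alignments.items():
        layout = contig_layouts.get(getattr(pl, "contig", None), [])
        if any(
            (min(rname, q), max(rname, q)) in inconsistent for q, _, _ in layout
        ):
            continue
        out[rname] = pl
    return out
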