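"""Haplotype-aware error correction on a partial-order alignment graph.

For each template read a POA graph is built from pairwise alignments of its
supporting reads. Nodes are keyed by a triple ``(c, r, b)``: template
position, consecutive-insertion rank (``r = 0`` for match/mismatch/deletion)
and base (``-`` for a deletion). Positions where the graph shows two dominant
parallel branches ("important locations") betray heterozygous alleles rather
than random error; supporting reads are scored +-1 by whether they follow the
template's branch at those positions, reads in the top score peak are
selected, their scores are mapped linearly onto edge weights, and a weighted
dynamic program over the graph emits the consensus. Selecting same-haplotype
supports is what lets correction remove sequencing errors without erasing
heterozygotes.

Internally nodes are packed into integers, ``code = (c << 11) | (r << 3) | b``
with ``b`` in A,C,G,T,- = 0..4 and ``r`` clipped at 255, so paths and edge
tallies are plain numpy arrays.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from .overlap import Overlap
from .rules import piecewise_rate_threshold
from .simdata import revcomp

_B2I = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
_I2B = "ACGT-"
_CIG_RE = re.compile(r"(\d+)([=XID])")
_CIG = {"=": 0, "X": 1, "I": 2, "D": 3}

R_SHIFT, C_SHIFT, R_MASK, B_MASK = 3, 11, 0xFF, 0x7


def node_c(code: int) -> int:
    return code >> C_SHIFT


def node_r(code: int) -> int:
    return (code >> R_SHIFT) & R_MASK


def node_b(code: int) -> str:
    return _I2B[code & B_MASK]


def make_node(c: int, r: int, b: str) -> int:
    return (c << C_SHIFT) | (min(r, 255) << R_SHIFT) | _B2I[b]


@dataclass
class CorrectionParams:
    r_l: float = 0.5
    r_h: float = 0.2
    S_l: float = 10.0
    S_h: float = 200.0
    weight_range: tuple[float, float] = (0.4, 0.8)
    pc_base: float = 0.4
    pc_floor: float = 0.3
    max_supporting_reads: int = 45
    min_homopolymer: int = 3        # run length that counts as a homopolymer
    peak_bin_width: float = 0.1
    bubble_walk_cap: int = 6
    min_support_span: int = 500     # ignore overlaps shorter than this

    def validate(self) -> None:
        if not 0 < self.r_h < self.r_l <= 1:
            raise ValueError("require 0 < r_h < r_l <= 1")
        if not self.S_l < self.S_h:
            raise ValueError("require S_l < S_h")
        lo, hi = self.weight_range
        if not 0 < lo < hi <= 1:
            raise ValueError("weight_range must lie within (0, 1]")


@dataclass
class Alignment:
    """Base-level alignment of a supporting read (oriented to the template
    forward strand) against the template; cigar ops are =, X, I, D with the
    template as the reference."""

    read_id: str
    t_start: int
    cigar: str
    query: str  # oriented query segment covered by the cigar


@dataclass
class SupportScore:
    read_id: str
    raw: int = 0
    n_important: int = 0
    normalized: float = 0.0
    selected: bool = False
    weight: float = 0.0


class PoaGraph:
    """POA graph over integer-packed nodes with per-edge support counts."""

    def __init__(self, template_id: str, template: str):
        self.template_id = template_id
        self.template = template
        self.tcode = np.array([_B2I.get(b, 0) for b in template], dtype=np.int64)
        self.paths: dict[str, np.ndarray] = {}
        self.spans: dict[str, tuple[int, int]] = {}
        # filled by finalize():
        self.edges: np.ndarray | None = None     # int64 (u << 32 | v)
        self.supports: np.ndarray | None = None

    def add_template_path(self) -> None:
        c = np.arange(len(self.template), dtype=np.int64)
        self.paths[self.template_id] = (c << C_SHIFT) | self.tcode
        self.spans[self.template_id] = (0, len(self.template) - 1)

    def add_alignment(self, aln: Alignment) -> None:
        path = _path_from_cigar(aln, self.tcode)
        if path is None or len(path) < 2:
            return
        self.paths[aln.read_id] = path
        self.spans[aln.read_id] = (node_c(int(path[0])), node_c(int(path[-1])))

    def finalize(self) -> None:
        chunks = [((p[:-1].astype(np.int64) << 32) | p[1:]) for p in self.paths.values()]
        alle = np.concatenate(chunks)
        self.edges, self.supports = np.unique(alle, return_counts=True)

    # convenience views -----------------------------------------------------
    def edge_uv(self) -> tuple[np.ndarray, np.ndarray]:
        return self.edges >> 32, self.edges & 0xFFFFFFFF

    def in_edge_table(self) -> dict[int, list[tuple[int, int]]]:
        """node -> list of (source node, support)."""
        u, v = self.edge_uv()
        table: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for uu, vv, ss in zip(u.tolist(), v.tolist(), self.supports.tolist()):
            table[vv].append((uu, ss))
        return table


_Q2CODE = np.zeros(256, dtype=np.int64)
for _b, _i in _B2I.items():
    _Q2CODE[ord(_b)] = _i


def _path_from_cigar(aln: Alignment, tcode: np.ndarray) -> np.ndarray | None:
    """Expand a cigar into the node-code path it traces through the graph
    (fully vectorized over the cigar runs)."""
    if aln.t_start < 0:
        raise ValueError(f"alignment start {aln.t_start} outside template")
    qcode = _Q2CODE[np.frombuffer(aln.query.encode(), dtype=np.uint8)]
    runs = _CIG_RE.findall(aln.cigar)
    # trim leading insertions (no preceding template column to attach to)
    qi0 = 0
    while runs and runs[0][1] == "I":
        qi0 += int(runs.pop(0)[0])
    if not runs:
        return None
    lens = np.array([int(n) for n, _ in runs], dtype=np.int64)
    ops = np.array([_CIG[op] for _, op in runs], dtype=np.int64)  # = X I D
    t_use = np.where(ops != 2, lens, 0)
    q_use = np.where(ops != 3, lens, 0)
    run_c = aln.t_start + np.concatenate([[0], np.cumsum(t_use)[:-1]])
    run_q = qi0 + np.concatenate([[0], np.cumsum(q_use)[:-1]])
    if run_c[-1] + t_use[-1] > len(tcode):
        raise ValueError("alignment exceeds template length")
    n_tot = int(lens.sum())
    rep = np.repeat(np.arange(len(runs)), lens)
    off = np.arange(n_tot) - np.repeat(
        np.concatenate([[0], np.cumsum(lens)[:-1]]), lens
    )
    op_e = ops[rep]
    ins = op_e == 2
    c = np.where(ins, run_c[rep] - 1, run_c[rep] + off)
    r = np.where(ins, np.minimum(off + 1, 255), 0)
    qpos = run_q[rep] + off
    b = np.where(
        op_e == 3, 4, np.where(op_e == 0, tcode[np.minimum(c, len(tcode) - 1)],
                               qcode[np.minimum(qpos, len(qcode) - 1)])
    )
    path = (c << C_SHIFT) | (r << R_SHIFT) | b
    # trim trailing insertions / deletions (uninformative dangling ends)
    while len(path) and (node_r(int(path[-1])) > 0 or (int(path[-1]) & B_MASK) == 4):
        path = path[:-1]
    return path if len(path) else None


def build_poa_graph(
    template_id: str, template: str, alignments: list[Alignment]
) -> PoaGraph:
    """Build the POA graph from template-vs-support alignments, including the
    trivial self-alignment of the template."""
    g = PoaGraph(template_id, template)
    g.add_template_path()
    for aln in alignments:
        try:
            g.add_alignment(aln)
        except ValueError:
            continue  # reject alignments with out-of-range coordinates
    g.finalize()
    return g


# ---------------------------------------------------------------------------
# important edges and locations


def mark_important_edges(g: PoaGraph, p: CorrectionParams) -> set[int]:
    """Flag in-edges of the per-location (c, 0, .) node families whose support
    count clears the piecewise threshold on the family total."""
    u, v = g.edge_uv()
    fam = ((v >> R_SHIFT) & R_MASK) == 0
    cv = (v >> C_SHIFT)[fam]
    s = g.supports[fam]
    total = np.zeros(len(g.template), dtype=float)
    np.add.at(total, cv, s)
    thr = piecewise_rate_threshold(total, p.r_l, p.r_h, p.S_l, p.S_h)
    imp = s >= thr[cv] - 1e-9
    return set(g.edges[fam][imp].tolist())


def _is_homopolymer(template: str, c: int, min_run: int) -> bool:
    b = template[c]
    i = c
    while i > 0 and template[i - 1] == b:
        i -= 1
    j = c
    while j + 1 < len(template) and template[j + 1] == b:
        j += 1
    return j - i + 1 >= min_run


def mark_important_locations(
    g: PoaGraph, important_edges: set[int], p: CorrectionParams
) -> dict[int, list[int]]:
    """Keep locations where the flagged parallel branches form a clean
    substitution bubble.

    A location survives iff (1) the template base at ``c`` is not inside a
    homopolymer run, (2) at least two in-edges of its node family are flagged
    and walking backwards from them closes a bubble, (3) more than half of the
    reads through each flagged in-edge follow that bubble path, and (4) the
    two path sequences differ by substitution only (no length difference).
    Returns ``{c: [edge codes of the important in-edges]}``.
    """
    by_c: dict[int, list[int]] = defaultdict(list)
    for e in important_edges:
        v = e & 0xFFFFFFFF
        by_c[v >> C_SHIFT].append(e)
    in_table = g.in_edge_table()
    support_of = _edge_support_lookup(g)

    def walk_back(start: int) -> tuple[list[int], list[int]]:
        nodes, sups = [start], []
        cur = start
        for _ in range(p.bubble_walk_cap):
            ins = in_table.get(cur)
            if not ins:
                break
            uu, ss = max(ins, key=lambda t: t[1])
            nodes.append(uu)
            sups.append(ss)
            cur = uu
        return nodes, sups

    out: dict[int, list[int]] = {}
    for c, edges in sorted(by_c.items()):
        if len(edges) < 2:
            continue
        if _is_homopolymer(g.template, c, p.min_homopolymer):
            continue
        walks = []
        ok = True
        for e in edges:
            uu, vv = e >> 32, e & 0xFFFFFFFF
            if (vv & B_MASK) == 4 or ((uu >> R_SHIFT) & R_MASK) != 0:
                ok = False  # deletion branch or insertion source: length change
                break
            walks.append((e, *walk_back(uu)))
        if not ok:
            continue
        # find the earliest node of the first walk present in all other walks
        common = None
        others = [set(nodes) for _, nodes, _ in walks[1:]]
        for cand in walks[0][1]:
            if all(cand in o for o in others):
                common = cand
                break
        if common is None:
            continue
        good = True
        for e, nodes, sups in walks:
            stop = nodes.index(common)
            branch = nodes[:stop]  # source-side branch nodes; target v checked above
            if any((n & B_MASK) == 4 or ((n >> R_SHIFT) & R_MASK) != 0 for n in branch):
                good = False  # indel on a branch: condition (4)
                break
            # condition (3): majority of the reads through the flagged in-edge
            # stay on the branch path
            s_e = support_of(e)
            if any(s <= 0.5 * s_e for s in sups[:stop]):
                good = False
                break
        if good:
            out[c] = sorted(edges)
    return out


def _edge_support_lookup(g: PoaGraph):
    table = {int(e): int(s) for e, s in zip(g.edges, g.supports)}
    return lambda e: table.get(int(e), 0)


# ---------------------------------------------------------------------------
# supporting-read scoring, selection, weighting


def _family_entries(path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices (into the path, > 0) and template positions where the path
    enters an (c, 0, .) family node."""
    r0 = ((path >> R_SHIFT) & R_MASK) == 0
    idx = np.flatnonzero(r0)
    idx = idx[idx > 0]
    return idx, (path[idx] >> C_SHIFT)


def score_supporting_reads(
    g: PoaGraph, important: dict[int, list[int]], p: CorrectionParams
) -> list[SupportScore]:
    """+-1 tally over important locations, normalized by the number of
    important locations at which the read takes a flagged branch.

    Only locations where both the template and the supporting read traverse a
    flagged in-edge contribute; +1 when they take the same one, -1 otherwise.
    """
    imp_locs = np.array(sorted(important), dtype=np.int64)
    imp_set = {e for edges in important.values() for e in edges}
    tpath = g.paths[g.template_id]
    tmpl_edge = {}
    for c in imp_locs.tolist():
        e = int((int(tpath[c - 1]) << 32) | int(tpath[c])) if c >= 1 else None
        if e is not None and e in imp_set:
            tmpl_edge[c] = e
    scores = []
    for name, path in g.paths.items():
        if name == g.template_id:
            continue
        sc = SupportScore(name)
        if len(imp_locs):
            idx, cs = _family_entries(path)
            hit = np.isin(cs, imp_locs)
            for i, c in zip(idx[hit].tolist(), cs[hit].tolist()):
                te = tmpl_edge.get(c)
                if te is None:
                    continue
                e = int((int(path[i - 1]) << 32) | int(path[i]))
                if e == te:
                    sc.raw += 1
                    sc.n_important += 1
                elif e in imp_set:
                    sc.raw -= 1
                    sc.n_important += 1
        sc.normalized = sc.raw / sc.n_important if sc.n_important else 0.0
        scores.append(sc)
    return scores


def select_and_weight(
    scores: list[SupportScore], p: CorrectionParams
) -> list[SupportScore]:
    """Select the reads in the highest-score peak of the score histogram (or
    the top half if the histogram is unimodal) and map their scores linearly
    onto the weight range."""
    if not scores:
        return scores
    lo, hi = p.weight_range
    mid = (lo + hi) / 2
    if len(scores) < 2:
        for s in scores:
            s.selected, s.weight = True, mid
        return scores

    vals = np.array([s.normalized for s in scores])
    bw = p.peak_bin_width
    nb = int(round(2 / bw))
    counts, edges = np.histogram(vals, bins=nb, range=(-1, 1 + 1e-12))
    smooth = np.convolve(counts, np.ones(3) / 3, mode="same")
    peaks = [
        i for i in range(nb)
        if smooth[i] > (smooth[i - 1] if i > 0 else -1)
        and smooth[i] > (smooth[i + 1] if i < nb - 1 else -1)
    ]
    if len(peaks) >= 2:
        top = max(peaks)  # highest-score peak
        lo_edge = edges[max(top - 1, 0)]
        hi_edge = edges[min(top + 2, nb)]
        chosen = (vals >= lo_edge - 1e-12) & (vals <= hi_edge + 1e-12)
    else:
        order = np.argsort(-vals, kind="stable")
        half = (len(scores) + 1) // 2
        cut = vals[order[half - 1]]
        chosen = vals >= cut  # include ties at the median
    sel = np.flatnonzero(chosen)
    smin, smax = vals[sel].min(), vals[sel].max()
    for i, s in enumerate(scores):
        s.selected = bool(chosen[i])
        if not s.selected:
            s.weight = 0.0
        elif smax - smin < 1e-12:
            s.weight = mid
        else:
            s.weight = lo + (s.normalized - smin) / (smax - smin) * (hi - lo)
    return scores


# ---------------------------------------------------------------------------
# consensus


def consensus(
    g: PoaGraph, weights: dict[str, float], p: CorrectionParams
) -> tuple[str, tuple[int, int]]:
    """Highest-weight path through the graph by dynamic programming.

    Edge weights are the summed weights of the selected reads passing the
    edge; each node at location ``c`` pays a penalty
    ``max(pc_base**r, pc_floor) * W_c`` with ``W_c`` the summed weight of
    reads covering ``c``. Scores are computed in topological order (ascending
    node code); the best-scoring node of the last covered template column is
    the terminal and backtracking yields the consensus. Returns the sequence
    and its span on the template (inclusive template columns).
    """
    if g.edges is None or not len(g.edges):
        return "", (0, 0)
    L = len(g.template)
    wc = np.zeros(L + 1)
    have_weight = False
    w_edges: dict[int, float] = defaultdict(float)
    for name, w in weights.items():
        if w <= 0 or name not in g.paths:
            continue
        have_weight = True
        c0, c1 = g.spans[name]
        wc[c0] += w
        wc[c1 + 1] -= w
        path = g.paths[name]
        for e in ((path[:-1].astype(np.int64) << 32) | path[1:]).tolist():
            w_edges[e] += w
    if not have_weight:
        return g.template, (0, L - 1)
    wc = np.cumsum(wc)[:L]
    covered = np.flatnonzero(wc > 1e-12)
    c_last, c_first = int(covered[-1]), int(covered[0])

    score: dict[int, float] = {}
    pred: dict[int, int] = {}
    v_arr = g.edges & 0xFFFFFFFF
    # processing edges in ascending target-code order is a topological sweep:
    # v strictly exceeds u on every edge
    order = np.argsort(v_arr, kind="stable")
    u_all = (g.edges >> 32)[order].tolist()
    v_all = v_arr[order].tolist()
    e_all = g.edges[order].tolist()
    for u, v, e in zip(u_all, v_all, e_all):
        c, r = v >> C_SHIFT, (v >> R_SHIFT) & R_MASK
        pen = max(p.pc_base ** r, p.pc_floor) * (wc[c] if c < L else 0.0)
        cand = score.get(u, 0.0) + w_edges.get(e, 0.0) - pen
        if cand > score.get(v, -np.inf):
            score[v] = cand
            pred[v] = u

    terminal, best = None, -np.inf
    for v, s in score.items():
        if (v >> C_SHIFT) == c_last and (s, v) > (best, terminal or -1):
            terminal, best = v, s
    if terminal is None:
        return g.template[c_first : c_last + 1], (c_first, c_last)
    chain = [terminal]
    while chain[-1] in pred:
        chain.append(pred[chain[-1]])
    chain.reverse()
    seq = "".join(_I2B[v & B_MASK] for v in chain if (v & B_MASK) != 4)
    return seq, (node_c(chain[0]), node_c(chain[-1]))


# ---------------------------------------------------------------------------
# the full per-read operation


@dataclass
class CorrectedRead:
    name: str
    sequence: str
    raw_span: tuple[int, int]  # corrected read's span on the raw read, half-open
    selected: list[str] = field(default_factory=list)
    scores: list[SupportScore] = field(default_factory=list)
    flagged: bool = False  # True when returned uncorrected


def align_support(
    template: str, support: str, ov: Overlap, template_is_a: bool, pad: int = 250
) -> Alignment | None:
    """Base-level alignment of the overlap region of a supporting read onto
    the template, oriented to the template's forward strand."""
    if template_is_a:
        t0, t1 = ov.a_start, ov.a_end
        s_seq = support[ov.b_start : ov.b_end]
        name = ov.read_b
    else:
        t0, t1 = ov.b_start, ov.b_end
        s_seq = support[ov.a_start : ov.a_end]
        name = ov.read_a
    if ov.strand == "-":
        s_seq = revcomp(s_seq)
    w0 = max(0, t0 - pad)
    w1 = min(len(template), t1 + pad)
    if w1 - w0 < 50 or not s_seq:
        return None
    res = edlib.align(s_seq, template[w0:w1], mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    start = w0 + res["locations"][0][0]
    return Alignment(name, start, res["cigar"], s_seq)


def correct_read(
    template_name: str,
    overlaps: list[Overlap],
    reads: dict[str, str],
    p: CorrectionParams,
    haplotype_aware: bool = True,
) -> CorrectedRead:
    """Correct one template read: build the POA graph from its supporting
    reads, select likely same-haplotype supports, and emit the weighted
    consensus. With ``haplotype_aware=False`` all supports get equal weight
    (plain weighted-POA consensus)."""
    template = reads[template_name]
    cands = [
        ov for ov in overlaps
        if template_name in (ov.read_a, ov.read_b) and ov.read_a != ov.read_b
    ]
    span = lambda ov: (ov.a_end - ov.a_start) if ov.read_a == template_name else (
        ov.b_end - ov.b_start
    )
    cands = [ov for ov in cands if span(ov) >= p.min_support_span]
    cands.sort(key=span, reverse=True)
    cands = cands[: p.max_supporting_reads]
    # seed-based candidate coordinates stop short of the true overlap ends;
    # extending them keeps POA support coverage up to the template's edges
    from .overlap import extend_overlap

    cands = [extend_overlap(ov, reads) for ov in cands]
    if not cands:
        return CorrectedRead(template_name, template, (0, len(template)), flagged=True)

    alignments = []
    for ov in cands:
        is_a = ov.read_a == template_name
        other = ov.read_b if is_a else ov.read_a
        aln = align_support(template, reads[other], ov, is_a)
        if aln is not None:
            alignments.append(aln)
    if not alignments:
        return CorrectedRead(template_name, template, (0, len(template)), flagged=True)

    g = build_poa_graph(template_name, template, alignments)
    if haplotype_aware:
        imp_edges = mark_important_edges(g, p)
        imp_locs = mark_important_locations(g, imp_edges, p)
        scores = score_supporting_reads(g, imp_locs, p)
        scores = select_and_weight(scores, p)
    else:
        mid = sum(p.weight_range) / 2
        scores = [
            SupportScore(a.read_id, selected=True, weight=mid) for a in alignments
        ]
    weights = {s.read_id: s.weight for s in scores}
    seq, (c0, c1) = consensus(g, weights, p)
    if not seq:
        return CorrectedRead(template_name, template, (0, len(template)), flagged=True)
    return CorrectedRead(
        template_name, seq, (c0, c1 + 1),
        selected=[s.read_id for s in scores if s.selected], scores=scores,
    )


def correct_all(
    reads: dict[str, str],
    overlaps: list[Overlap],
    p: CorrectionParams | None = None,
    haplotype_aware: bool = True,
) -> dict[str, CorrectedRead]:
    """Correct every read, indexing overlaps by read once."""
    p = p or CorrectionParams()
    p.validate()
    by_read: dict[str, list[Overlap]] = defaultdict(list)
    for ov in overlaps:
        by_read[ov.read_a].append(ov)
        by_read[ov.read_b].append(ov)
    return {
        name: correct_read(name, by_read.get(name, []), reads, p, haplotype_aware)
        for name in sorted(reads)
    }
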