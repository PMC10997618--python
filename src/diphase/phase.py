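"""Read-level SNP calling, centroid clustering, and inconsistent overlaps.

Corrected reads are mapped back onto the haplotype-collapsed round-1 contigs;
heterozygous SNP sites are called from the pileup (coverage in a band, second
allele above a piecewise threshold), and each read gets an allele vector
``H_r(s)`` in {0, 1, 2}. Reads are clustered per template with a
divide-then-combine strategy built on centroid algebra (verified-site sets
``V_>``, ``V_<``, ``V_!=`` and the pairwise ``A``/``S``/``D`` site sets),
alleles are verified and corrected against the template's group centroid, and
read pairs whose groups differ at enough verified sites are declared
inconsistent. Their overlaps — when read directions and 3'-end distances on
the contigs agree with the overlap geometry — are removed before the second
round of assembly.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from .overlap import Overlap, minimizer_sketch
from .rules import piecewise_rate_threshold
from .simdata import revcomp

log = logging.getLogger(__name__)

_CIG = {"=": 0, "X": 1, "I": 2, "D": 3}


@dataclass
class SnpCallParams:
    cov_min: int = 10
    cov_max: int = 1000
    r_l: float = 0.4
    r_h: float = 0.2
    c_l: float = 10.0
    c_h: float = 100.0

    def validate(self) -> None:
        if not 0 < self.r_h < self.r_l < 1:
            raise ValueError("require 0 < r_h < r_l < 1")
        if not self.c_l < self.c_h or self.cov_min > self.c_l:
            raise ValueError("require cov_min <= c_l < c_h")


@dataclass
class GroupingParams:
    p2: float = 0.3
    p3: float = 0.5
    p4: float = 0.02
    p5: float = 4.0
    p6: float = 0.66
    p7: float = 6.0
    p8: float = 4.0
    p9: float = 0.2
    min_common_sites: int = 3
    strict_diff: float = 8.0
    loose_diff: float = 6.0
    dist_tol_corrected: float = 1000.0
    dist_tol_raw_abs: float = 2500.0
    dist_tol_raw_frac: float = 0.05
    verify_rounds: int = 2
    max_iter: int = 20
    seed_pair_cap: int = 2000

    def validate(self) -> None:
        if self.strict_diff <= self.loose_diff:
            raise ValueError("strict_diff must exceed loose_diff")


@dataclass
class SnpSite:
    contig: str
    position: int
    allele1: str
    allele2: str
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class Placement:
    read: str
    contig: str
    start: int
    end: int
    strand: str
    cigar: str

    @property
    def three_prime(self) -> int:
        """Contig coordinate of the read's own 3' end."""
        return self.end if self.strand == "+" else self.start


# ---------------------------------------------------------------------------
# read-to-contig mapping


def map_reads_to_contigs(
    reads: dict[str, str],
    contigs: dict[str, str],
    k: int = 15,
    w: int = 10,
    min_votes: int = 5,
    pad: int = 300,
    secondary_ratio: float = 0.5,
    max_placements: int = 4,
) -> dict[str, list[Placement]]:
    """Placements of each read on the contig set (minimizer voting, then
    infix edit-distance alignment), primary first.

    Secondary placements with at least ``secondary_ratio`` of the primary's
    votes are kept: in collapsed or repeat-bearing references a read from one
    repeat copy must contribute to the pileup of every near-identical
    instance, otherwise divergent sites are never seen.
    """
    index: dict[int, list] = defaultdict(list)
    for ci, (cname, cseq) in enumerate(sorted(contigs.items())):
        h, pos, rev = minimizer_sketch(cseq, k, w)
        for hh, pp, vv in zip(h.tolist(), pos.tolist(), rev.tolist()):
            index[hh].append((ci, pp, vv))
    cnames = sorted(contigs)

    placements: dict[str, list[Placement]] = {}
    for rname in sorted(reads):
        rseq = reads[rname]
        h, pos, rev = minimizer_sketch(rseq, k, w)
        votes: dict[tuple[int, int, int], int] = defaultdict(int)
        anchors: dict[tuple[int, int, int], list[tuple[int, int]]] = defaultdict(list)
        for hh, pp, vv in zip(h.tolist(), pos.tolist(), rev.tolist()):
            for ci, cp, cv in index.get(hh, []):
                strand = 1 if cv != vv else 0
                rp = len(rseq) - (pp + k) if strand else pp
                key = (ci, strand, (cp - rp) // 400)
                votes[key] += 1
                anchors[key].append((cp, rp))
        if not votes:
            continue
        ranked = sorted(votes, key=lambda kk: -votes[kk])
        top = votes[ranked[0]]
        if top < min_votes:
            continue
        spans_seen: list[tuple[int, int, int]] = []
        out: list[Placement] = []
        for key in ranked[: 3 * max_placements]:
            if votes[key] < max(min_votes, secondary_ratio * top):
                continue
            ci, strand, _ = key
            cseq = contigs[cnames[ci]]
            cps = [a[0] for a in anchors[key]]
            rps = [a[1] for a in anchors[key]]
            w0 = max(0, min(cp - rp for cp, rp in zip(cps, rps)) - pad)
            w1 = min(
                len(cseq),
                max(cp + (len(rseq) - rp) for cp, rp in zip(cps, rps)) + pad,
            )
            if any(
                c == ci and not (w1 <= s0 or w0 >= s1) for c, s0, s1 in spans_seen
            ):
                continue  # overlaps an already-kept placement window
            query = rseq if strand == 0 else revcomp(rseq)
            res = edlib.align(query, cseq[w0:w1], mode="HW", task="path")
            if res["editDistance"] < 0 or not res.get("cigar"):
                continue
            loc = res["locations"][0]
            spans_seen.append((ci, w0 + loc[0], w0 + loc[1] + 1))
            out.append(
                Placement(
                    rname, cnames[ci], w0 + loc[0], w0 + loc[1] + 1,
                    "+" if strand == 0 else "-", res["cigar"],
                )
            )
            if len(out) >= max_placements:
                break
        if out:
            placements[rname] = out
    return placements


def _walk_runs(cigar: str):
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            yield num, ch
            num = 0


def _covered_bases(pl: Placement, read_seq: str):
    """Yield (contig position array, read base code array) for the =/X runs."""
    q = read_seq if pl.strand == "+" else revcomp(read_seq)
    qcode = np.frombuffer(q.encode(), dtype=np.uint8)
    c, qi = pl.start, 0
    for n, op in _walk_runs(pl.cigar):
        if op in "=X":
            yield np.arange(c, c + n), qcode[qi : qi + n]
            c += n
            qi += n
        elif op == "D":
            c += n
        else:
            qi += n


# ---------------------------------------------------------------------------
# het-site calling and the allele matrix


def call_het_sites(
    contigs: dict[str, str],
    placements: dict[str, list[Placement]],
    reads: dict[str, str],
    p: SnpCallParams | None = None,
) -> list[SnpSite]:
    """Heterozygous SNP sites from the read pileup on each contig (all
    placements of every read contribute)."""
    p = p or SnpCallParams()
    p.validate()
    by_contig: dict[str, list[Placement]] = defaultdict(list)
    for pls in placements.values():
        for pl in pls:
            by_contig[pl.contig].append(pl)
    sites: list[SnpSite] = []
    base_idx = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
    for cname in sorted(by_contig):
        L = len(contigs[cname])
        counts = np.zeros((L, 4), dtype=np.int32)
        for pl in sorted(by_contig[cname], key=lambda q: q.read):
            for cpos, bases in _covered_bases(pl, reads[pl.read]):
                for code, col in base_idx.items():
                    sel = cpos[bases == code]
                    np.add.at(counts[:, col], sel, 1)
        cov = counts.sum(axis=1)
        order = np.argsort(counts, axis=1)
        first = order[:, -1]
        second = order[:, -2]
        n2 = counts[np.arange(L), second]
        thr = piecewise_rate_threshold(cov, p.r_l, p.r_h, p.c_l, p.c_h)
        mask = (cov >= p.cov_min) & (cov <= p.cov_max) & (n2 >= thr - 1e-9)
        for pos in np.flatnonzero(mask).tolist():
            sites.append(
                SnpSite(
                    cname, pos, "ACGT"[first[pos]], "ACGT"[second[pos]],
                    {b: int(counts[pos, j]) for j, b in enumerate("ACGT")},
                )
            )
    return sites


class AlleleMatrix:
    """Per-read SNP allele calls: H[r, s] in {0, 1, 2} (0 = uncovered or
    neither allele), plus read placements used for distance checks."""

    def __init__(
        self,
        names: list[str],
        sites: list[SnpSite],
        H: np.ndarray,
        placements: dict[str, list[Placement]],
    ):
        self.names = names
        self.row = {n: i for i, n in enumerate(names)}
        self.sites = sites
        self.H = H
        self.placements = placements
        self.site_contig = np.array([s.contig for s in sites])
        self.site_pos = np.array([s.position for s in sites])

    def copy(self) -> "AlleleMatrix":
        return AlleleMatrix(self.names, self.sites, self.H.copy(), self.placements)


def call_read_alleles(
    placements: dict[str, Placement],
    sites: list[SnpSite],
    reads: dict[str, str],
) -> AlleleMatrix:
    names = sorted(placements)
    H = np.zeros((len(names), len(sites)), dtype=np.int8)
    by_contig: dict[str, list[int]] = defaultdict(list)
    for j, s in enumerate(sites):
        by_contig[s.contig].append(j)
    pos_arrays = {
        c: (np.array([sites[j].position for j in idx]), np.array(idx))
        for c, idx in by_contig.items()
    }
    a1 = np.frombuffer("".join(s.allele1 for s in sites).encode(), dtype=np.uint8) \
        if sites else np.empty(0, np.uint8)
    a2 = np.frombuffer("".join(s.allele2 for s in sites).encode(), dtype=np.uint8) \
        if sites else np.empty(0, np.uint8)
    for i, name in enumerate(names):
        for pl in placements[name]:
            if pl.contig not in pos_arrays:
                continue
            positions, idx = pos_arrays[pl.contig]
            for cpos, bases in _covered_bases(pl, reads[name]):
                lo = np.searchsorted(positions, cpos[0])
                hi = np.searchsorted(positions, cpos[-1], side="right")
                if lo == hi:
                    continue
                hit_pos = positions[lo:hi]
                hit_idx = idx[lo:hi]
                b = bases[hit_pos - cpos[0]]
                H[i, hit_idx] = np.where(
                    b == a1[hit_idx], 1, np.where(b == a2[hit_idx], 2, 0)
                )
    return AlleleMatrix(names, sites, H, placements)


# ---------------------------------------------------------------------------
# centroid algebra


@dataclass
class Centroid:
    v: np.ndarray  # signed votes per site
    n: np.ndarray  # total votes per site

    @classmethod
    def of(cls, H: np.ndarray, rows: np.ndarray) -> "Centroid":
        sub = H[rows]
        plus = (sub == 1).sum(axis=0)
        minus = (sub == 2).sum(axis=0)
        return cls((plus - minus).astype(np.int64), (plus + minus).astype(np.int64))

    def v_gt(self, p0: float, p1: float) -> np.ndarray:
        return (self.v > 0) & (np.abs(self.v) >= np.maximum(p0 * self.n, p1))

    def v_lt(self, p0: float, p1: float) -> np.ndarray:
        return (self.v < 0) & (np.abs(self.v) >= np.maximum(p0 * self.n, p1))

    def v_ne(self, p0: float, p1: float) -> np.ndarray:
        return self.v_gt(p0, p1) | self.v_lt(p0, p1)


def centroid_sets(
    c1: Centroid, c2: Centroid, p0: float, p1: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Common (A), same-sign (S) and opposite-sign (D) verified site masks."""
    g1, l1 = c1.v_gt(p0, p1), c1.v_lt(p0, p1)
    g2, l2 = c2.v_gt(p0, p1), c2.v_lt(p0, p1)
    a = (g1 | l1) & (g2 | l2)
    s = (l1 & l2) | (g1 & g2)
    d = (l1 & g2) | (g1 & l2)
    return a, s, d


# ---------------------------------------------------------------------------
# divide-then-combine clustering


def _pair_counts(H: np.ndarray):
    """Pairwise |A| and |D| matrices for a read-by-site allele matrix."""
    P = (H == 1).astype(np.float32)
    M = (H == 2).astype(np.float32)
    D = P @ M.T + M @ P.T
    A = (P + M) @ (P + M).T
    return A, D


def divide_group(
    rows: np.ndarray,
    H: np.ndarray,
    p: GroupingParams,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Recursive 3-way bisecting split of a read group.

    Each level seeds two centroids with the most distant read pair, assigns
    each read to the nearer centroid (or to a separate far-read subgroup when
    it matches neither), iterates to a fixpoint, and recurses; far reads
    become singleton leaves. A group stops dividing when it has <= 3 reads or
    is internally consistent (sum |D| / sum |A| <= p4 and sum |D| <= p5).
    """
    out: list[np.ndarray] = []
    stack = [np.asarray(rows)]
    while stack:
        g = stack.pop()
        if len(g) <= 3:
            out.append(g)
            continue
        cen = Centroid.of(H, g)
        P = (H[g] == 1)
        M = (H[g] == 2)
        # internal-consistency stop rule: the summed per-read distance from
        # the centroid equals the minority vote count per site; the explicit
        # min() form also covers the degenerate 50/50 case where votes cancel
        # (v_s = 0) and the naive sum would read zero
        plus = P.sum(0)
        minus = M.sum(0)
        minority = int(np.minimum(plus, minus).sum())
        total = int((plus + minus).sum())
        if minority <= p.p5 and minority <= p.p4 * max(total, 1):
            out.append(g)
            continue
        # seed pair with the largest pairwise distance (capped sample)
        npairs = len(g) * (len(g) - 1) // 2
        if npairs > p.seed_pair_cap:
            ii = rng.integers(0, len(g), size=p.seed_pair_cap)
            jj = rng.integers(0, len(g), size=p.seed_pair_cap)
            keep = ii != jj
            ii, jj = ii[keep], jj[keep]
            Dp = ((P[ii] & M[jj]) | (M[ii] & P[jj])).sum(1)
            k = int(np.argmax(Dp))
            seeds = (int(ii[k]), int(jj[k]))
        else:
            A, D = _pair_counts(H[g])
            seeds = np.unravel_index(np.argmax(D), D.shape)
        assign = None
        c1 = Centroid.of(H, g[[seeds[0]]])
        c2 = Centroid.of(H, g[[seeds[1]]])
        for _ in range(p.max_iter):
            stats = []
            for c in (c1, c2):
                a_i = ((P | M) & (c.v != 0)[None, :]).sum(1).astype(float)
                d_i = ((P & (c.v < 0)[None, :]) | (M & (c.v > 0)[None, :])).sum(1).astype(float)
                stats.append((a_i, d_i))
            tot = (P | M).sum(1).astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                far = np.ones(len(g), bool)
                ratio = []
                for a_i, d_i in stats:
                    cov_frac = np.where(tot > 0, a_i / np.maximum(tot, 1), 0.0)
                    dr = np.where(a_i > 0, d_i / np.maximum(a_i, 1), np.inf)
                    far &= (cov_frac < p.p2) | (dr > p.p3)
                    ratio.append(dr)
            new = np.where(far, 2, np.where(ratio[0] <= ratio[1], 0, 1))
            if assign is not None and np.array_equal(new, assign):
                break
            assign = new
            if (assign == 0).any():
                c1 = Centroid.of(H, g[assign == 0])
            if (assign == 1).any():
                c2 = Centroid.of(H, g[assign == 1])
        g0, g1, gfar = g[assign == 0], g[assign == 1], g[assign == 2]
        if not len(g0) or not len(g1):
            merged = np.concatenate([g0, g1])
            if len(merged):
                out.append(merged)
            for r in gfar:
                out.append(np.array([r]))
            continue
        stack.append(g0)
        stack.append(g1)
        for r in gfar:  # far reads join combining as singleton leaves
            out.append(np.array([r]))
    return [g for g in out if len(g)]


def _sizes(H, rows1, rows2, p0, p1) -> tuple[int, int, int]:
    a, s, d = centroid_sets(Centroid.of(H, rows1), Centroid.of(H, rows2), p0, p1)
    return int(a.sum()), int(s.sum()), int(d.sum())


def combine_subgroups(
    leaves: list[np.ndarray],
    template_row: int,
    H: np.ndarray,
    p: GroupingParams,
) -> list[np.ndarray]:
    """Merge subgroup leaves back into haplotype groups around the template's
    leaf ``L1``; incompatible leaves start new entries of the list."""
    l1_idx = next(i for i, g in enumerate(leaves) if template_row in g)
    L: list[np.ndarray] = [leaves[l1_idx]]
    rest = [g for i, g in enumerate(leaves) if i != l1_idx]
    remaining = []
    for g in rest:
        a, _, d = _sizes(H, g, L[0], p.p6, p.p7)
        a2, _, d2 = _sizes(H, g, L[0], p.p6, p.p7 / 2)
        if d < min(p.p8, a * p.p9) and d2 < a2 * p.p9:
            L[0] = np.concatenate([L[0], g])
        else:
            remaining.append(g)
    remaining.sort(key=lambda g: _sizes(H, L[0], g, p.p6, p.p7)[2])
    for g in remaining:
        best_j, best_s = None, -1
        for j in range(len(L)):
            _, s, _ = _sizes(H, g, L[j], p.p6, 0.0)
            if s > best_s:
                best_j, best_s = j, s
        a, _, d = _sizes(H, g, L[best_j], p.p6, p.p7)
        a0, _, d0 = _sizes(H, g, L[best_j], p.p6, 0.0)
        if d < max(p.p8, a * p.p9) and d0 < a0 * p.p9:
            L[best_j] = np.concatenate([L[best_j], g])
        else:
            L.append(g)
    return L


def _group_for_template(
    m: AlleleMatrix, t_row: int, p: GroupingParams
) -> np.ndarray | None:
    """Rows of the reads sharing >= min_common_sites informative sites with
    the template (template included)."""
    t_sites = m.H[t_row] > 0
    if not t_sites.any():
        return None
    common = ((m.H > 0) & t_sites[None, :]).sum(axis=1)
    rows = np.flatnonzero(common >= p.min_common_sites)
    return rows if len(rows) >= 2 and t_row in rows else None


def verify_correct_alleles(
    m: AlleleMatrix, p: GroupingParams | None = None, seed: int = 0
) -> AlleleMatrix:
    """Two (by default) passes of per-template clustering followed by allele
    correction of the template from its group-L1 centroid."""
    p = p or GroupingParams()
    p.validate()
    for rnd in range(p.verify_rounds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rnd]))
        newH = m.H.copy()
        for t_row in range(len(m.names)):
            rows = _group_for_template(m, t_row, p)
            if rows is None:
                continue
            sub_sites = np.flatnonzero(m.H[t_row] > 0)
            Hs = m.H[:, sub_sites]
            leaves = divide_group(rows, Hs, p, rng)
            L = combine_subgroups(leaves, t_row, Hs, p)
            cen = Centroid.of(Hs, L[0])
            ver = cen.v_ne(p.p6, p.p7)
            covered = Hs[t_row] > 0
            fix = ver & covered
            newH[t_row, sub_sites[fix]] = np.where(cen.v[fix] > 0, 1, 2)
        m = AlleleMatrix(m.names, m.sites, newH, m.placements)
    return m


# ---------------------------------------------------------------------------
# inconsistent overlaps


def _expected_three_prime_distance(ov: Overlap) -> float:
    if ov.strand == "+":
        offset = ov.a_start - ov.b_start
        return abs(ov.a_len - (offset + ov.b_len))
    offset = ov.a_start - (ov.b_len - ov.b_end)
    return abs(ov.a_len - offset)


def _distance_conflict(
    ov: Overlap,
    pas: list[Placement] | None,
    pbs: list[Placement] | None,
    tol: float,
) -> bool:
    """True when every placement pair contradicts the overlap geometry.

    A read may have several placements (repeat copies); the overlap conflicts
    with the contig layout only if no concordant pair exists.
    """
    if not pas or not pbs:
        return False  # no layout evidence, no conflict
    exp = _expected_three_prime_distance(ov)
    saw_pair = False
    for pa in pas:
        for pb in pbs:
            if pa.contig != pb.contig:
                continue
            saw_pair = True
            same = pa.strand == pb.strand
            if (ov.strand == "+") != same:
                continue
            if abs(exp - abs(pa.three_prime - pb.three_prime)) < tol:
                return False
    return saw_pair


def find_inconsistent_pairs(
    m: AlleleMatrix, p: GroupingParams | None = None,
    diff_threshold: float | None = None, seed: int = 0,
) -> set[tuple[str, str]]:
    """Read pairs whose haplotype groups differ at enough verified sites.

    For each template the final clustering is recomputed; a query read r with
    subgroup L_r is inconsistent with the template when both
    ``|D(L_r,L1)| >= max(p8, |A(L_r,L1)|*p9)`` and the read-level condition on
    ``D(r,L1) ∩ A(L_r,L1)`` hold. ``diff_threshold`` overrides p8 (strict=8
    for corrected-read evidence, loose=6 for raw-read evidence). The returned
    relation is symmetrized.
    """
    p = p or GroupingParams()
    p8 = p.p8 if diff_threshold is None else diff_threshold
    rng = np.random.default_rng(np.random.SeedSequence([seed, 999]))
    pairs: set[tuple[str, str]] = set()
    for t_row in range(len(m.names)):
        rows = _group_for_template(m, t_row, p)
        if rows is None:
            continue
        sub_sites = np.flatnonzero(m.H[t_row] > 0)
        Hs = m.H[:, sub_sites]
        leaves = divide_group(rows, Hs, p, rng)
        L = combine_subgroups(leaves, t_row, Hs, p)
        if len(L) < 2:
            continue
        c1 = Centroid.of(Hs, L[0])
        g1, l1 = c1.v_gt(p.p6, p.p7), c1.v_lt(p.p6, p.p7)
        l1_set = set(L[0].tolist())
        for Lr in L[1:]:
            cr = Centroid.of(Hs, Lr)
            a_m, _, d_m = centroid_sets(cr, c1, p.p6, p.p7)
            if d_m.sum() < max(p8, a_m.sum() * p.p9):
                continue
            for r in Lr.tolist():
                if r in l1_set:
                    continue
                rp = Hs[r] == 1
                rm = Hs[r] == 2
                d_r = (rp & l1) | (rm & g1)
                a_r = (rp | rm) & (g1 | l1)
                # read-level check restricted to the group-verified sites
                if (d_r & a_m).sum() >= max(p8, (a_r & a_m).sum() * p.p9):
                    t, q = m.names[t_row], m.names[r]
                    pairs.add((min(t, q), max(t, q)))
    return pairs


def mark_inconsistent_overlaps(
    pairs: set[tuple[str, str]],
    overlaps: list[Overlap],
    m: AlleleMatrix,
    tol: float | None = None,
    p: GroupingParams | None = None,
    corrected: "AlleleMatrix | None" = None,
) -> tuple[list[Overlap], list[Overlap]]:
    """Split overlaps into (kept, inconsistent) using the pair relation plus
    the direction/distance concordance check against the contig layout.

    With ``corrected`` given (raw-read mode) the tolerance is per pair:
    ``max(dist_tol_raw_abs, dist_tol_raw_frac * D_c)`` where ``D_c`` is the
    3'-end distance of the corresponding corrected reads on the contigs.
    """
    p = p or GroupingParams()
    base_tol = p.dist_tol_corrected if tol is None else tol
    kept, dropped = [], []
    for ov in overlaps:
        key = (min(ov.read_a, ov.read_b), max(ov.read_a, ov.read_b))
        tol_ov = base_tol
        if corrected is not None:
            ca = (corrected.placements.get(ov.read_a) or [None])[0]
            cb = (corrected.placements.get(ov.read_b) or [None])[0]
            d_c = (
                abs(ca.three_prime - cb.three_prime)
                if ca is not None and cb is not None and ca.contig == cb.contig
                else 0.0
            )
            tol_ov = max(p.dist_tol_raw_abs, p.dist_tol_raw_frac * d_c)
        if key in pairs and not _distance_conflict(
            ov, m.placements.get(ov.read_a), m.placements.get(ov.read_b), tol_ov
        ):
            dropped.append(ov)
        else:
            kept.append(ov)
    return kept, dropped


def merge_raw_snp_evidence(
    corrected: AlleleMatrix,
    raw: AlleleMatrix | None,
    p: GroupingParams | None = None,
    seed: int = 0,
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Strict corrected-read pass plus (when raw evidence exists) a loose
    raw-read pass; returns (strict pairs, loose pairs).

    Without raw evidence only the corrected pass runs (PacBio CLR mode). The
    raw pass reuses read names, which are preserved by error correction.
    """
    p = p or GroupingParams()
    strict = find_inconsistent_pairs(corrected, p, p.strict_diff, seed)
    loose: set[tuple[str, str]] = set()
    if raw is not None and len(raw.sites):
        loose = find_inconsistent_pairs(raw, p, p.loose_diff, seed)
    return strict, loose


def snp_agreement_counts(
    m: AlleleMatrix, overlaps: list[Overlap]
) -> dict[tuple[str, str], tuple[int, int]]:
    """Per overlapping pair, the number of shared sites with the same (n+)
    and different (n-) alleles — the evidence driving best-overlap scores."""
    out = {}
    for ov in overlaps:
        a, b = ov.read_a, ov.read_b
        ia, ib = m.row.get(a), m.row.get(b)
        if ia is None or ib is None:
            continue
        ha, hb = m.H[ia], m.H[ib]
        both = (ha > 0) & (hb > 0)
        same = int(((ha == hb) & both).sum())
        diff = int(both.sum()) - same
        out[(min(a, b), max(a, b))] = (same, diff)
    return out
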