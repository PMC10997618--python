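"""Candidate overlap detection and the overhang / contained / coverage filters.

Candidate overlaps come either from the built-in minimizer overlapper (desk
scale, all-vs-all) or from an external PAF file. Candidates are then extended
to the read ends by aligning only the flanking segments, and overlaps whose
residual inner overhangs are still long are removed: the threshold is
``min(overhang_abs, overhang_frac * l)`` for the read of length ``l`` carrying
the overhang (100 bp / 1% for PacBio, 300 bp / 3% for Nanopore). Finally,
reads contained in other reads are set aside and per-read coverage bounds are
enforced.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

import edlib
import numpy as np

from .simdata import revcomp

# status values, also serialized into PAF st:Z tags
CANDIDATE = "candidate"
EXTENDED = "extended"
REMOVED_OVERHANG = "removed_overhang"
REMOVED_CONTAINED = "removed_contained"
REMOVED_COVERAGE = "removed_coverage"
RETAINED = "retained"


@dataclass
class Overlap:
    """A pairwise overlap record; coordinates are on each read's forward frame."""

    read_a: str
    read_b: str
    strand: str  # '+' same strand, '-' opposite
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    a_len: int
    b_len: int
    identity: float | None = None
    status: str = CANDIDATE

    def canonical(self) -> "Overlap":
        if self.read_a <= self.read_b:
            return self
        return Overlap(
            self.read_b, self.read_a, self.strand,
            self.b_start, self.b_end, self.a_start, self.a_end,
            self.b_len, self.a_len, self.identity, self.status,
        )

    # --- overhang geometry -------------------------------------------------
    # In the overlap's own left-to-right frame (a forward), the four flanks:
    def flanks(self) -> tuple[int, int, int, int]:
        """(a_left, b_left, a_right, b_right) unaligned flank lengths,
        with b's flanks taken on a's orientation frame."""
        a_left = self.a_start
        a_right = self.a_len - self.a_end
        if self.strand == "+":
            b_left = self.b_start
            b_right = self.b_len - self.b_end
        else:
            b_left = self.b_len - self.b_end
            b_right = self.b_start
        return a_left, b_left, a_right, b_right


@dataclass
class OverlapFilterParams:
    platform: str = "pacbio"  # 'pacbio' or 'ont'
    overhang_abs: int | None = None
    overhang_frac: float | None = None
    min_coverage: float = 3.0
    max_coverage: float = 400.0

    def __post_init__(self) -> None:
        if self.overhang_abs is None:
            self.overhang_abs = 100 if self.platform == "pacbio" else 300
        if self.overhang_frac is None:
            self.overhang_frac = 0.01 if self.platform == "pacbio" else 0.03
        if self.overhang_abs <= 0 or not 0 < self.overhang_frac < 1:
            raise ValueError("invalid overhang parameters")


def overhang_threshold(read_len: int, p: OverlapFilterParams) -> float:
    return min(p.overhang_abs, p.overhang_frac * read_len)


# --------------------------------------------------------------------------
# minimizer sketching


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(len(arr), 255, dtype=np.uint8)
    for b, v in zip(b"ACGT", range(4)):
        code[arr == b] = v
    return code


_MIX = np.uint64(0x9E3779B97F4A7C15)


def _hash64(x: np.ndarray) -> np.ndarray:
    # invertible mix (splitmix-style) for deterministic minimizer ordering
    x = x.astype(np.uint64)
    x = (x ^ (x >> np.uint64(30))) * _MIX
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


def minimizer_sketch(seq: str, k: int, w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical (k,w)-minimizers of a sequence.

    Returns (hash, position, is_reverse) arrays; is_reverse marks positions
    where the canonical k-mer is the reverse complement of the forward k-mer.
    """
    code = _encode(seq)
    n = len(code) - k + 1
    if n <= 0:
        return (np.empty(0, np.uint64), np.empty(0, np.int64), np.empty(0, bool))
    valid = np.ones(n, bool)
    kmers = np.zeros(n, np.uint64)
    rkmers = np.zeros(n, np.uint64)
    for i in range(k):
        c = code[i : i + n]
        valid &= c != 255
        kmers = (kmers << np.uint64(2)) | c.astype(np.uint64)
        rc = np.uint64(3) - c.astype(np.uint64)
        rkmers |= rc << np.uint64(2 * i)
    canon = np.minimum(kmers, rkmers)
    is_rev = rkmers < kmers
    h = _hash64(canon)
    h[~valid] = np.uint64(0xFFFFFFFFFFFFFFFF)
    # sliding window minimum over h
    if n <= w:
        best = np.argmin(h)
        return h[best : best + 1], np.array([best]), is_rev[best : best + 1]
    m = n - w + 1
    idx = np.arange(m)
    window = np.lib.stride_tricks.sliding_window_view(h, w)
    arg = np.argmin(window, axis=1)
    pos = idx + arg
    sel = np.unique(pos)
    return h[sel], sel, is_rev[sel]


def find_candidate_overlaps(
    reads: dict[str, str],
    k: int = 13,
    w: int = 8,
    min_shared: int = 4,
    max_occ: int = 200,
    diag_band: int = 500,
) -> list[Overlap]:
    """All-vs-all candidate overlaps from shared minimizers.

    A pair is reported once (lexicographically smaller read id first) when it
    shares at least ``min_shared`` minimizers on a consistent diagonal band.
    Approximate overlap coordinates are taken from the extreme matched
    minimizer positions; :func:`extend_overlap` refines them.
    """
    if not reads:
        raise ValueError("reads must be non-empty")
    names = sorted(reads)
    if any(len(reads[nm]) < k for nm in names):
        raise ValueError("k exceeds the shortest read length")
    lens = {nm: len(reads[nm]) for nm in names}
    rid = {nm: i for i, nm in enumerate(names)}

    index: dict[int, list] = defaultdict(list)  # hash -> [(rid, pos, rev)]
    sketches = {}
    for nm in names:
        h, p, rv = minimizer_sketch(reads[nm], k, w)
        sketches[nm] = (h, p, rv)
        i = rid[nm]
        for hh, pp, vv in zip(h.tolist(), p.tolist(), rv.tolist()):
            index[hh].append((i, pp, vv))

    # posting arrays per hash, skipping over-represented minimizers
    postings = {
        hh: np.array(lst, dtype=np.int64)
        for hh, lst in index.items()
        if len(lst) <= max_occ
    }

    out: list[Overlap] = []
    for nm in names:
        i = rid[nm]
        h, p, rv = sketches[nm]
        hit_rid, hit_apos, hit_bpos, hit_rel = [], [], [], []
        for hh, pp, vv in zip(h.tolist(), p.tolist(), rv.tolist()):
            post = postings.get(hh)
            if post is None:
                continue
            mask = post[:, 0] > i  # canonical order: only partners with larger id
            if not mask.any():
                continue
            sub = post[mask]
            hit_rid.append(sub[:, 0])
            hit_apos.append(np.full(len(sub), pp))
            hit_bpos.append(sub[:, 1])
            hit_rel.append(sub[:, 2] != vv)  # True -> opposite strand match
        if not hit_rid:
            continue
        rids = np.concatenate(hit_rid)
        apos = np.concatenate(hit_apos)
        bpos = np.concatenate(hit_bpos)
        rel = np.concatenate(hit_rel)
        blen = np.array([lens[names[j]] for j in rids])
        # diagonal on b's oriented frame
        bpos_or = np.where(rel, blen - (bpos + k), bpos)
        diag = apos - bpos_or
        key = (rids * 2 + rel) * (1 << 22) + (diag // diag_band + (1 << 20))
        uniq, inv, counts = np.unique(key, return_inverse=True, return_counts=True)
        for u in np.flatnonzero(counts >= min_shared):
            sel = inv == u
            j = int(rids[sel][0])
            opp = bool(rel[sel][0])
            a0, a1 = int(apos[sel].min()), int(apos[sel].max()) + k
            bo0, bo1 = int(bpos_or[sel].min()), int(bpos_or[sel].max()) + k
            bl = lens[names[j]]
            if opp:
                b0, b1 = bl - bo1, bl - bo0
            else:
                b0, b1 = bo0, bo1
            out.append(
                Overlap(nm, names[j], "-" if opp else "+",
                        a0, a1, b0, b1, lens[nm], bl)
            )
    # merge duplicate pair/strand records (adjacent diagonal bands) keeping the widest span
    best: dict[tuple, Overlap] = {}
    span = lambda o: (o.a_end - o.a_start) + (o.b_end - o.b_start)
    for ov in out:
        kk = (ov.read_a, ov.read_b, ov.strand)
        cur = best.get(kk)
        if cur is None or span(ov) > span(cur):
            best[kk] = ov
    return list(best.values())


# --------------------------------------------------------------------------
# extension to read ends


def _oriented_b(ov: Overlap, seq_b: str) -> str:
    return seq_b if ov.strand == "+" else revcomp(seq_b)


def _extend_side(q: str, t: str) -> tuple[int, int]:
    """Extend an alignment from position 0 of both q and t as far as the
    running score (+1 per match, -2 per edit) keeps improving.

    Returns (q_used, t_used). A clean dovetail flank consumes all of q; an
    unalignable flap (e.g. a chimeric junction) stops the extension at the
    score maximum, leaving the flap as residual overhang. The edit penalty
    must exceed the match reward because the optimal alignment of two random
    sequences already matches about half their bases.
    """
    if not q or not t:
        return 0, 0
    res = edlib.align(q, t, mode="SHW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return 0, 0
    qi = ti = score = 0
    best = (0, 0, 0)
    import re

    for n, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
        n = int(n)
        if op == "=":
            qi += n
            ti += n
            score += n
        elif op == "X":
            qi += n
            ti += n
            score -= 2 * n
        elif op == "I":
            qi += n
            score -= 2 * n
        else:
            ti += n
            score -= 2 * n
        if score > best[0]:
            best = (score, qi, ti)
    return best[1], best[2]


def extend_overlap(ov: Overlap, reads: dict[str, str]) -> Overlap:
    """Extend a candidate overlap toward both read ends.

    Only the flanking segments are aligned (prefix-anchored edit-distance
    extension of the shorter flank into the longer one); the extension stops
    at its score maximum, so unalignable flaps remain as residual overhangs.
    """
    a = reads[ov.read_a]
    b = _oriented_b(ov, reads[ov.read_b])
    # work on b's oriented frame
    if ov.strand == "+":
        b0, b1 = ov.b_start, ov.b_end
    else:
        b0, b1 = ov.b_len - ov.b_end, ov.b_len - ov.b_start
    a0, a1 = ov.a_start, ov.a_end

    if min(a0, b0) > 0:  # left: align reversed flanks, shorter as query
        if a0 <= b0:
            qu, tu = _extend_side(a[:a0][::-1], b[:b0][::-1])
            a0, b0 = a0 - qu, b0 - tu
        else:
            qu, tu = _extend_side(b[:b0][::-1], a[:a0][::-1])
            b0, a0 = b0 - qu, a0 - tu
    ra, rb = ov.a_len - a1, len(b) - b1
    if min(ra, rb) > 0:  # right
        if ra <= rb:
            qu, tu = _extend_side(a[a1:], b[b1:])
            a1, b1 = a1 + qu, b1 + tu
        else:
            qu, tu = _extend_side(b[b1:], a[a1:])
            b1, a1 = b1 + qu, a1 + tu

    if ov.strand == "+":
        nb0, nb1 = b0, b1
    else:
        nb0, nb1 = ov.b_len - b1, ov.b_len - b0
    return replace(ov, a_start=a0, a_end=a1, b_start=nb0, b_end=nb1, status=EXTENDED)


def compute_identity(ov: Overlap, reads: dict[str, str]) -> float:
    """Edit-distance identity of the aligned (inner) overlap region."""
    a = reads[ov.read_a][ov.a_start : ov.a_end]
    b = reads[ov.read_b][ov.b_start : ov.b_end]
    if ov.strand == "-":
        b = revcomp(b)
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


# --------------------------------------------------------------------------
# filters


def filter_overhangs(ovs: list[Overlap], params: OverlapFilterParams) -> list[Overlap]:
    """Remove overlaps whose residual inner overhangs are still long.

    For each side of the overlap the *inner* overhang is the shorter of the
    two flanks (the one that must vanish for a dovetail); it is tested against
    the threshold of the read that carries it.
    """
    out = []
    for ov in ovs:
        a_left, b_left, a_right, b_right = ov.flanks()
        bad = False
        for fa, fb in ((a_left, b_left), (a_right, b_right)):
            if fa <= fb:
                bad |= fa > overhang_threshold(ov.a_len, params)
            else:
                bad |= fb > overhang_threshold(ov.b_len, params)
        out.append(replace(ov, status=REMOVED_OVERHANG if bad else RETAINED))
    return out


def remove_contained_and_low_coverage(
    ovs: list[Overlap], params: OverlapFilterParams
) -> tuple[list[Overlap], dict[str, list[Overlap]], dict[str, float]]:
    """Drop overlaps of contained reads and reads with out-of-range coverage.

    Returns (overlaps with final statuses, contained side table, per-read
    coverage). A read is contained when a retained overlap covers it
    end-to-end within its overhang tolerance inside the other read.
    Overlaps touching contained reads are removed but kept in the side table
    for later dead-end repair.
    """
    live = [ov for ov in ovs if ov.status == RETAINED]
    contained: set[str] = set()
    for ov in live:
        a_left, b_left, a_right, b_right = ov.flanks()
        tol_a = overhang_threshold(ov.a_len, params)
        tol_b = overhang_threshold(ov.b_len, params)
        a_in = a_left <= tol_a and a_right <= tol_a
        b_in = b_left <= tol_b and b_right <= tol_b
        if a_in and b_in:  # near-identical reads: call the shorter contained
            contained.add(ov.read_a if ov.a_len <= ov.b_len else ov.read_b)
        elif a_in:
            contained.add(ov.read_a)
        elif b_in:
            contained.add(ov.read_b)

    side: dict[str, list[Overlap]] = defaultdict(list)
    kept: list[Overlap] = []
    out: list[Overlap] = []
    for ov in ovs:
        if ov.status != RETAINED:
            out.append(ov)
            continue
        if ov.read_a in contained or ov.read_b in contained:
            ov = replace(ov, status=REMOVED_CONTAINED)
            for r in (ov.read_a, ov.read_b):
                if r in contained:
                    side[r].append(ov)
            out.append(ov)
        else:
            kept.append(ov)

    cov: dict[str, float] = defaultdict(float)
    for ov in kept:
        cov[ov.read_a] += (ov.a_end - ov.a_start) / ov.a_len
        cov[ov.read_b] += (ov.b_end - ov.b_start) / ov.b_len
    bad_cov = {
        r for r, c in cov.items() if not params.min_coverage <= c <= params.max_coverage
    }
    for ov in kept:
        if ov.read_a in bad_cov or ov.read_b in bad_cov:
            out.append(replace(ov, status=REMOVED_COVERAGE))
        else:
            out.append(ov)
    return out, dict(side), dict(cov)


def status_counts(ovs: list[Overlap]) -> dict[str, int]:
    counts: dict[str, int] = defaultdict(int)
    for ov in ovs:
        counts[ov.status] += 1
    return dict(counts)
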