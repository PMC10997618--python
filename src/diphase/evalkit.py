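"""Truth-based evaluation: trio binning, k-mer consistency/completeness,
alignment accuracy, and haplotype fidelity of assembled contigs.

At desk scale the haplotype-specific k-mer sets are computed exactly from the
two simulated haplotypes (the symmetric difference of their canonical k-mer
sets) instead of from parental short reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .rules import trio_classify
from .simdata import revcomp


def canonical_kmers(seq: str, k: int) -> set[str]:
    out = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        rc = revcomp(km)
        out.add(km if km <= rc else rc)
    return out


def kmer_multiset(seq: str, k: int) -> dict[str, int]:
    out: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        rc = revcomp(km)
        km = km if km <= rc else rc
        out[km] = out.get(km, 0) + 1
    return out


@dataclass
class TrioKmerSets:
    paternal: set[str]
    maternal: set[str]
    k: int

    def __post_init__(self) -> None:
        if self.paternal & self.maternal:
            raise ValueError("haplotype-specific k-mer sets must be disjoint")
        if not self.paternal or not self.maternal:
            raise ValueError("both k-mer sets must be non-empty")

    @classmethod
    def from_haplotypes(cls, hap1: str, hap2: str, k: int = 18) -> "TrioKmerSets":
        k1 = canonical_kmers(hap1, k)
        k2 = canonical_kmers(hap2, k)
        return cls(k1 - k2, k2 - k1, k)

    def counts_in(self, seq: str) -> tuple[int, int]:
        kp = km = 0
        for i in range(len(seq) - self.k + 1):
            s = seq[i : i + self.k]
            rc = revcomp(s)
            s = s if s <= rc else rc
            if s in self.paternal:
                kp += 1
            elif s in self.maternal:
                km += 1
        return kp, km


def trio_bin_reads(
    reads: dict[str, str], ks: TrioKmerSets
) -> dict[str, str]:
    """Classify each read paternal/maternal/untagged by its haplotype-specific
    k-mer hits."""
    K_p, K_m = len(ks.paternal), len(ks.maternal)
    out = {}
    for name in sorted(reads):
        kp, km = ks.counts_in(reads[name])
        out[name] = trio_classify(kp, km, K_p, K_m)
    return out


def _longest_subset(reads: dict[str, str], depth_cap: float, genome_size: int):
    target = depth_cap * genome_size
    chosen: dict[str, str] = {}
    total = 0
    for name in sorted(reads, key=lambda n: (-len(reads[n]), n)):
        if total >= target:
            break
        chosen[name] = reads[name]
        total += len(reads[name])
    return chosen


def consistency_completeness(
    reads: dict[str, str],
    ks: TrioKmerSets,
    genome_size: int,
    depth_cap: float = 40.0,
    min_occurrence: int = 4,
) -> tuple[float, float]:
    """Consistency = sum max(k_p, k_m) / sum (k_p + k_m) over the depth-capped
    longest reads; completeness = fraction of the parent-specific k-mer
    universe observed at least ``min_occurrence`` times in that subset."""
    subset = _longest_subset(reads, depth_cap, genome_size)
    if not subset:
        raise ValueError("no reads selected for evaluation")
    num = den = 0
    seen: dict[str, int] = {}
    universe = ks.paternal | ks.maternal
    for seq in subset.values():
        kp, km = ks.counts_in(seq)
        num += max(kp, km)
        den += kp + km
        for i in range(len(seq) - ks.k + 1):
            s = seq[i : i + ks.k]
            rc = revcomp(s)
            s = s if s <= rc else rc
            if s in universe:
                seen[s] = seen.get(s, 0) + 1
    consistency = num / den if den else 1.0
    complete = sum(1 for v in seen.values() if v >= min_occurrence) / len(universe)
    return consistency, complete


# ---------------------------------------------------------------------------
# alignment accuracy


def cigar_accuracy(cigar: str) -> float:
    """matches / (matches + mismatches + insertions + deletions) of an
    extended cigar string."""
    import re

    tallies = {"=": 0, "X": 0, "I": 0, "D": 0}
    for n, op in re.findall(r"(\d+)([=XID])", cigar):
        tallies[op] += int(n)
    total = sum(tallies.values())
    return tallies["="] / total if total else 0.0


def read_accuracy(
    reads: dict[str, str],
    truths: tuple[str, str],
    genome_size: int | None = None,
    depth_cap: float = 40.0,
    mask: list[tuple[int, int]] | None = None,
) -> tuple[dict[str, float], float, int]:
    """Per-read and aggregate accuracy of reads against the better-matching
    truth haplotype (edit-distance alignment, cigar scan).

    Aggregation covers the ``depth_cap`` longest reads when ``genome_size`` is
    given. ``mask`` optionally restricts scoring to truth intervals (applied
    to the alignment's matched span on the truth). Returns (per-read,
    aggregate, unaligned count).
    """
    subset = (
        _longest_subset(reads, depth_cap, genome_size) if genome_size else reads
    )
    per: dict[str, float] = {}
    agg_m = agg_t = 0
    unaligned = 0
    for name in sorted(subset):
        seq = subset[name]
        best = None
        for hap in truths:
            for q in (seq, revcomp(seq)):
                res = edlib.align(q, hap, mode="HW", task="path")
                if res["editDistance"] >= 0 and (
                    best is None or res["editDistance"] < best["editDistance"]
                ):
                    best = res
        if best is None or not best.get("cigar"):
            unaligned += 1
            continue
        if mask:
            start = best["locations"][0][0]
            if not any(lo <= start < hi for lo, hi in mask):
                continue
        acc = cigar_accuracy(best["cigar"])
        per[name] = acc
        import re

        for n, op in re.findall(r"(\d+)([=XID])", best["cigar"]):
            agg_t += int(n)
            if op == "=":
                agg_m += int(n)
    return per, (agg_m / agg_t if agg_t else 0.0), unaligned


# ---------------------------------------------------------------------------
# haplotype fidelity of contigs


def align_identity(query: str, target: str) -> float:
    """Identity of the best infix alignment of query (either strand) on target."""
    best = None
    for q in (query, revcomp(query)):
        res = edlib.align(q, target, mode="HW")
        if res["editDistance"] >= 0 and (best is None or res["editDistance"] < best):
            best = res["editDistance"]
    return 1.0 - best / len(query) if best is not None else 0.0


def allele_agreement(
    seq: str,
    source_hap: str,
    het_sites: list[tuple[int, str, str]],
    source_index: int,
) -> tuple[int, int]:
    """(agreeing, informative) het-allele counts of a read against its source
    haplotype.

    The read is aligned to the haplotype it was sampled from; at every truth
    het site inside the alignment, the read base is compared with the source
    allele. Sites showing neither allele (a sequencing error) are not
    informative. Positions are haplotype-1 coordinates, which coincide with
    haplotype-2 coordinates for SNP-only simulations.
    """
    import re

    best = None
    for q in (seq, revcomp(seq)):
        res = edlib.align(q, source_hap, mode="HW", task="path")
        if res["editDistance"] >= 0 and (
            best is None or res["editDistance"] < best[0]["editDistance"]
        ):
            best = (res, q)
    if best is None or not best[0].get("cigar"):
        return 0, 0
    res, q = best
    site_map = {pos: (a1, a2) for pos, a1, a2 in het_sites}
    t_pos, q_pos = res["locations"][0][0], 0
    agree = total = 0
    for n, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
        n = int(n)
        if op in "=X":
            for j in range(n):
                alleles = site_map.get(t_pos + j)
                if alleles is not None:
                    base = q[q_pos + j]
                    if base == alleles[source_index]:
                        agree += 1
                        total += 1
                    elif base == alleles[1 - source_index]:
                        total += 1
            t_pos += n
            q_pos += n
        elif op == "D":
            t_pos += n
        else:
            q_pos += n
    return agree, total


def haplotype_fidelity(
    contig: str,
    hap1: str,
    hap2: str,
    het_sites: list[tuple[int, str, str]],
) -> tuple[float, int, int, int, int]:
    """Identity to the better haplotype plus switch accounting over het sites.

    The contig is aligned to the haplotype it matches best; at every truth het
    site covered by the alignment the contig base is read out and attributed
    to haplotype 1 or 2. An isolated single-site deviation (both neighbours
    agree with each other) is a base error, not a phase change; it is counted
    as a flip, and switch events are transitions of the flip-filtered origin
    sequence. Returns (identity, informative sites, majority-haplotype sites,
    switch events, flips).
    """
    cands = []
    for hap_idx, hap in enumerate((hap1, hap2)):
        for strand, q in enumerate((contig, revcomp(contig))):
            res = edlib.align(q, hap, mode="HW", task="path")
            if res["editDistance"] >= 0:
                cands.append((res["editDistance"], hap_idx, strand, res))
    if not cands:
        return 0.0, 0, 0, 0, 0
    dist, hap_idx, strand, res = min(cands, key=lambda t: t[0])
    identity = 1.0 - dist / len(contig)
    q = contig if strand == 0 else revcomp(contig)
    t_start = res["locations"][0][0]

    # walk the cigar to read the contig base at each het site (hap1 frame for
    # hap_idx 0; project through the site's alleles otherwise)
    import re

    origin: list[int] = []
    site_map = {pos: (a1, a2) for pos, a1, a2 in het_sites}
    t_pos, q_pos = t_start, 0
    for n, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
        n = int(n)
        if op in "=X":
            for j in range(n):
                tp = t_pos + j
                if tp in site_map:
                    a1, a2 = site_map[tp]
                    base = q[q_pos + j]
                    if base == (a1 if hap_idx == 0 else a2):
                        origin.append(hap_idx + 1)
                    elif base == (a2 if hap_idx == 0 else a1):
                        origin.append(2 - hap_idx)
            t_pos += n
            q_pos += n
        elif op == "D":
            t_pos += n
        else:
            q_pos += n
    if not origin:
        return identity, 0, 0, 0, 0
    majority = max(set(origin), key=origin.count)
    filtered = [
        o for i, o in enumerate(origin)
        if not (
            (i == 0 or origin[i - 1] != o)
            and (i == len(origin) - 1 or origin[i + 1] != o)
        )
    ]
    switches = sum(1 for a, b in zip(filtered, filtered[1:]) if a != b)
    flips = len(origin) - len(filtered)
    return identity, len(origin), origin.count(majority), switches, flips
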