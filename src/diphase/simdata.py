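"""Synthetic diploid genomes and long noisy reads with ground truth.

The simulator produces the two ingredients every downstream stage needs for
testing: a pair of haplotype sequences differing by heterozygous variants at a
configurable rate, and reads sampled from both haplotypes with
substitution/insertion/deletion errors, together with truth tables (het sites,
read-to-haplotype labels) in haplotype-1 coordinates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass
class SimParams:
    """Parameters of the diploid read simulation.

    Defaults describe the standard study conditions used throughout the test
    suite: a 50-kb genome at 1% SNP heterozygosity, 40-fold coverage per
    haplotype and a 10% per-base error rate, which is in the middle of the
    5-15% error range typical of PacBio CLR / Nanopore R9 reads.
    """

    genome_length: int = 50_000
    het_rate: float = 0.01
    indel_het_fraction: float = 0.0  # fraction of het variants that are 1-50 bp indels
    depth_per_haplotype: float = 40.0
    read_length_mean: int = 5_000
    read_length_sd: int = 1_500
    read_length_min: int = 500
    error_rate: float = 0.10
    error_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)  # sub, ins, del
    repeat_spec: list[tuple[int, int, float]] | None = None
    homopolymer_bias: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.het_rate <= 0.05:
            raise ValueError(f"het_rate {self.het_rate} outside [0, 0.05]")
        if not 0 <= self.error_rate <= 0.25:
            raise ValueError(f"error_rate {self.error_rate} outside [0, 0.25]")
        if self.depth_per_haplotype <= 0:
            raise ValueError("depth_per_haplotype must be > 0")
        if abs(sum(self.error_mix) - 1.0) > 1e-9:
            raise ValueError("error_mix proportions must sum to 1")
        if self.genome_length < 1000:
            raise ValueError("genome_length < 1000 is too small for overlap structure")


@dataclass
class ReadLabel:
    haplotype: int  # 0 or 1
    start: int      # on its haplotype, 0-based
    end: int        # half-open
    strand: str     # '+' or '-'


@dataclass
class Truth:
    """Ground truth of a simulation, in haplotype-1 0-based half-open coordinates."""

    haplotype_sequences: tuple[str, str] = ("", "")
    het_sites: list[tuple[int, str, str]] = field(default_factory=list)
    indel_sites: list[tuple[int, str, str]] = field(default_factory=list)
    repeat_intervals: list[tuple[int, int]] = field(default_factory=list)
    read_labels: dict[str, ReadLabel] = field(default_factory=dict)
    read_error_positions: dict[str, list[int]] = field(default_factory=dict)

    def hap2_coordinate(self, hap1_pos: int) -> int:
        """Map a haplotype-1 coordinate to haplotype 2 through the indel set."""
        shift = 0
        for pos, a1, a2 in self.indel_sites:
            if pos < hap1_pos:
                shift += len(a2) - len(a1)
        return hap1_pos + shift


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def simulate_diploid_genome(params: SimParams) -> tuple[tuple[str, str], Truth]:
    """Draw haplotype 1, then derive haplotype 2 by sampling heterozygous variants.

    SNP positions are Bernoulli(het_rate) per base; a fraction
    ``indel_het_fraction`` of the variants are 1-50 bp indels instead.
    ``repeat_spec`` entries insert near-identical repeat copies (shared by both
    haplotypes) before variants are drawn, so repeats and heterozygosity
    interact the same way they do in real genomes.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    hap1 = _random_seq(rng, params.genome_length)
    repeat_intervals: list[tuple[int, int]] = []
    if params.repeat_spec:
        hap1, repeat_intervals = _insert_repeats(rng, hap1, params.repeat_spec)
    n = len(hap1)

    is_var = rng.random(n) < params.het_rate
    var_pos = np.flatnonzero(is_var)
    is_indel = rng.random(len(var_pos)) < params.indel_het_fraction

    truth = Truth()
    hap1_str = hap1.tobytes().decode()
    snp_sites: list[tuple[int, str, str]] = []
    indel_sites: list[tuple[int, str, str]] = []
    # build hap2 left to right
    pieces: list[str] = []
    prev = 0
    for pos, indel in zip(var_pos.tolist(), is_indel.tolist()):
        ref = hap1_str[pos]
        pieces.append(hap1_str[prev:pos])
        if indel:
            length = int(rng.integers(1, 51))
            if rng.random() < 0.5:  # insertion in hap2
                ins = _random_seq(rng, length).tobytes().decode()
                pieces.append(ref + ins)
                indel_sites.append((pos, ref, ref + ins))
                prev = pos + 1
            else:  # deletion in hap2
                dele = hap1_str[pos : pos + 1 + length]
                pieces.append(ref)
                indel_sites.append((pos, dele, ref))
                prev = pos + 1 + length
        else:
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[int(rng.integers(0, 3))]
            pieces.append(alt)
            snp_sites.append((pos, ref, alt))
            prev = pos + 1
    pieces.append(hap1_str[prev:])
    hap2_str = "".join(pieces)

    truth.haplotype_sequences = (hap1_str, hap2_str)
    truth.het_sites = snp_sites
    truth.indel_sites = indel_sites
    truth.repeat_intervals = repeat_intervals
    return (hap1_str, hap2_str), truth


def _insert_repeats(
    rng: np.random.Generator, hap: np.ndarray, spec: list[tuple[int, int, float]]
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Insert ``copies`` near-identical copies of a random unit at spread-out
    loci; returns the new sequence and the copy intervals (final coordinates)."""
    intervals: list[tuple[int, int]] = []
    for length, copies, divergence in spec:
        unit = _random_seq(rng, length)
        n = len(hap)
        anchors = np.linspace(n // (copies + 1), n - n // (copies + 1), copies).astype(int)
        segments = []
        prev = 0
        inserted = 0
        for a in anchors:
            copy = unit.copy()
            mut = np.flatnonzero(rng.random(length) < divergence)
            for m in mut:
                choices = BASES[BASES != copy[m]]
                copy[m] = choices[rng.integers(0, len(choices))]
            segments.append(hap[prev:a])
            segments.append(copy)
            intervals.append((a + inserted, a + inserted + length))
            inserted += length
            prev = a
        segments.append(hap[prev:])
        hap = np.concatenate(segments)
    return hap, intervals


def simulate_reads(
    haplotypes: tuple[str, str], truth: Truth, params: SimParams
) -> tuple[list[tuple[str, str]], Truth]:
    """Sample reads uniformly from both haplotypes and strands and inject errors.

    Returns ``(reads, truth)`` where reads is a list of (name, sequence); the
    truth object is updated in place with per-read labels. Read names encode
    nothing: all provenance lives in ``truth.read_labels``.
    """
    if not haplotypes[0]:
        raise ValueError("haplotypes must be non-empty")
    if params.read_length_mean > len(haplotypes[0]):
        raise ValueError("read_length_mean exceeds genome length")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))

    reads: list[tuple[str, str]] = []
    idx = 0
    for h, hap in enumerate(haplotypes):
        n = len(hap)
        target = params.depth_per_haplotype * n
        sampled = 0
        while sampled < target:
            length = int(rng.normal(params.read_length_mean, params.read_length_sd))
            length = max(params.read_length_min, min(length, n))
            start = int(rng.integers(0, n - length + 1))
            frag = hap[start : start + length]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = revcomp(frag)
            seq, _errpos = _inject_errors(rng, frag, params)
            name = f"read{idx:05d}"
            idx += 1
            reads.append((name, seq))
            truth.read_labels[name] = ReadLabel(h, start, start + length, strand)
            sampled += length
    return reads, truth


def _inject_errors(
    rng: np.random.Generator, frag: str, params: SimParams
) -> tuple[str, list[int]]:
    arr = np.frombuffer(frag.encode(), dtype="S1")
    n = len(arr)
    err = rng.random(n) < params.error_rate
    pos = np.flatnonzero(err)
    psub, pins, _pdel = params.error_mix
    kind = rng.random(len(pos))
    out: list[bytes] = []
    errpos: list[int] = []
    prev = 0
    for p, kk in zip(pos.tolist(), kind.tolist()):
        out.append(arr[prev:p].tobytes())
        errpos.append(p)
        base = arr[p]
        if kk < psub:  # substitution
            choices = BASES[BASES != base]
            out.append(choices[rng.integers(0, len(choices))].tobytes())
            prev = p + 1
        elif kk < psub + pins:  # insertion (keep base, add 1+ random)
            nins = 1
            if params.homopolymer_bias and p > 0 and arr[p - 1] == base:
                nins += int(rng.random() < 0.5)
            out.append(base.tobytes())
            out.append(_random_seq(rng, nins).tobytes())
            prev = p + 1
        else:  # deletion
            prev = p + 1
    out.append(arr[prev:].tobytes())
    return b"".join(out).decode(), errpos
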