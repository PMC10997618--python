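"""Readers and writers for the pipeline's interchange formats.

FASTA/FASTQ go through Biopython; PAF records carry the standard 12 columns
plus ``id:f`` (identity) and ``st:Z`` (status) tags; GFA 1.0 S/L lines carry
edge status in ``st:Z``. All TSV tables use 0-based half-open coordinates.
Malformed records raise ``FormatError`` with the offending line number.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .overlap import Overlap
from .phase import SnpSite
from .sgraph import StringGraph


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fastx(path: str | Path) -> dict[str, str]:
    """Read FASTA or FASTQ (by extension); mixed-case bases are upper-cased."""
    path = Path(path)
    fmt = "fastq" if path.suffix in {".fq", ".fastq"} else "fasta"
    out = {}
    for rec in SeqIO.parse(str(path), fmt):
        seq = str(rec.seq)
        if not seq.isupper():
            seq = seq.upper()
        out[rec.id] = seq
    return out


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=n, description="") for n, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(path: str | Path, seqs: dict[str, str], quality: int = 20) -> None:
    recs = []
    for n, s in seqs.items():
        rec = SeqRecord(Seq(s), id=n, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(s)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


# ---------------------------------------------------------------------------
# PAF


def write_paf(path: str | Path, overlaps: list[Overlap]) -> None:
    with open(path, "w") as fh:
        for ov in overlaps:
            n_match = min(ov.a_end - ov.a_start, ov.b_end - ov.b_start)
            cols = [
                ov.read_a, ov.a_len, ov.a_start, ov.a_end, ov.strand,
                ov.read_b, ov.b_len, ov.b_start, ov.b_end,
                n_match, max(ov.a_end - ov.a_start, ov.b_end - ov.b_start), 255,
            ]
            tags = [f"st:Z:{ov.status}"]
            if ov.identity is not None:
                tags.insert(0, f"id:f:{ov.identity:.6f}")
            fh.write("\t".join(map(str, cols + tags)) + "\n")


def read_paf(path: str | Path) -> list[Overlap]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path}:{ln}: PAF needs >= 12 columns")
            try:
                ov = Overlap(
                    read_a=parts[0], a_len=int(parts[1]),
                    a_start=int(parts[2]), a_end=int(parts[3]),
                    strand=parts[4],
                    read_b=parts[5], b_len=int(parts[6]),
                    b_start=int(parts[7]), b_end=int(parts[8]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
            if ov.strand not in "+-":
                raise FormatError(f"{path}:{ln}: bad strand {ov.strand!r}")
            for tag in parts[12:]:
                if tag.startswith("id:f:"):
                    ov.identity = float(tag[5:])
                elif tag.startswith("st:Z:"):
                    ov.status = tag[5:]
            out.append(ov)
    return out


# ---------------------------------------------------------------------------
# GFA 1.0


def write_gfa(path: str | Path, g: StringGraph, reads: dict[str, str]) -> None:
    """S-lines for every read in the graph, L-lines for every edge (status in
    st:Z); only live edges count toward assembly but all are recorded."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for rid in sorted(g.reads):
            seq = reads.get(rid, "*")
            fh.write(f"S\t{rid}\t{seq}\tLN:i:{len(seq) if seq != '*' else 0}\n")
        for (src, dst), e in sorted(g.edges.items()):
            fh.write(
                "L\t{}\t{}\t{}\t{}\t{}M\tst:Z:{}\n".format(
                    src[0], "+" if src[1] == "E" else "-",
                    dst[0], "+" if dst[1] == "E" else "-",
                    e.aln_len, e.status,
                )
            )


def read_gfa(path: str | Path):
    """Parse S/L lines back into (segments, links) tuples."""
    segments: dict[str, str] = {}
    links: list[tuple] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "S":
                if len(parts) < 3:
                    raise FormatError(f"{path}:{ln}: truncated S line")
                segments[parts[1]] = parts[2]
            elif parts[0] == "L":
                if len(parts) < 6:
                    raise FormatError(f"{path}:{ln}: truncated L line")
                status = next(
                    (t[5:] for t in parts[6:] if t.startswith("st:Z:")), None
                )
                links.append((parts[1], parts[2], parts[3], parts[4], parts[5], status))
    return segments, links


# ---------------------------------------------------------------------------
# TSV tables


def write_tsv(path: str | Path, rows: list[dict], columns: list[str]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=columns, delimiter="\t")
        w.writeheader()
        w.writerows(rows)


def read_tsv(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def write_sites_tsv(path: str | Path, sites: list[SnpSite]) -> None:
    rows = [
        {
            "contig": s.contig, "position": s.position,
            "allele1": s.allele1, "allele2": s.allele2,
            "counts": ",".join(f"{b}:{c}" for b, c in sorted(s.counts.items())),
        }
        for s in sites
    ]
    write_tsv(path, rows, ["contig", "position", "allele1", "allele2", "counts"])


# ---------------------------------------------------------------------------
# VCF (heterozygous SNP input)


def read_vcf_het_sites(path: str | Path) -> list[SnpSite]:
    """Heterozygous SNP records from a VCF: biallelic SNPs only; positions are
    converted to 0-based."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            out.append(SnpSite(rec.chrom, rec.pos - 1, ref, alt))
    return out


def write_vcf_het_sites(path: str | Path, sites: list[SnpSite],
                        contig_lengths: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in sorted(contig_lengths.items()):
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(sites, key=lambda s: (s.contig, s.position)):
            fh.write(
                f"{s.contig}\t{s.position + 1}\t.\t{s.allele1}\t{s.allele2}"
                "\t.\tPASS\t.\n"
            )


# ---------------------------------------------------------------------------
# BED (region masks)


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED needs >= 3 columns")
            try:
                out.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# JSON helpers


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
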