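"""Shared fixtures: tiny hand-written SAM/VCF inputs built at test time."""

from __future__ import annotations

import re
from pathlib import Path

import pysam
import pytest

CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def bam_from_sam(sam_text: str, out_dir: Path, name: str = "reads") -> Path:
    """Write SAM text, coordinate-sort into an indexed BAM."""
    sam = out_dir / f"{name}.sam"
    sam.write_text(sam_text)
    bam = out_dir / f"{name}.bam"
    pysam.sort("-o", str(bam), str(sam))
    pysam.index(str(bam))
    return bam


def naive_base_at(pos_1based: int, flag: int, start_1based: int, cigar: str, seq: str):
    """Base aligned at a reference position, by direct CIGAR walk; None if absent."""
    if flag & (0x4 | 0x100 | 0x800):
        return None
    ref = start_1based
    query = 0
    for length, op in CIGAR_RE.findall(cigar):
        length = int(length)
        if op in "M=X":
            if ref <= pos_1based < ref + length:
                return seq[query + (pos_1based - ref)]
            ref += length
            query += length
        elif op in "DN":
            ref += length
        elif op in "IS":
            query += length
    return None


def naive_pileup(bam_path: Path, sites) -> list[tuple[int, int, int]]:
    """Independent brute-force (ref, alt, other) tally over the SAM text.

    No quality filtering, no deduplication, every primary read counted —
    the oracle for counting with all filters disabled.
    """
    text = pysam.view("-h", str(bam_path))
    records = []
    for line in text.splitlines():
        if line.startswith("@"):
            continue
        f = line.split("\t")
        records.append((f[2], int(f[1]), int(f[3]), f[5], f[9]))
    out = []
    for site in sites:
        ref = alt = other = 0
        for chrom, flag, start, cigar, seq in records:
            if chrom != site.chrom:
                continue
            base = naive_base_at(site.pos, flag, start, cigar, seq)
            if base is None:
                continue
            if base == site.ref_allele:
                ref += 1
            elif base == site.alt_allele:
                alt += 1
            else:
                other += 1
        out.append((ref, alt, other))
    return out


# Hand-constructed pileup around chr1:100 (site REF=A, ALT=G), read length 10.
# By-hand tally with defaults (min BQ 10, min MQ 20, dedup by flag, fragments
# counted once): ref=5 (r1,r2,r3,p3/1,p4/1), alt=3 (r4,r5,p1 merged),
# other=2 (r6 'T', r11 'N'), lowMQ=1 (r7), lowBQ=1 (r8), dup=1 (r10),
# mate conflict=2 (p2 pair), merged=1 (p1), raw depth=16; r9 spans the site
# via a deletion and carries no base there.
HAND_SAM = "\n".join(
    [
        "@HD\tVN:1.6\tSO:unsorted",
        "@SQ\tSN:chr1\tLN:10000",
        "r1\t0\tchr1\t96\t60\t10M\t*\t0\t0\tCCCCACCCCC\tIIIIIIIIII",
        "r2\t0\tchr1\t96\t60\t10M\t*\t0\t0\tCCCCACCCCC\tIIIIIIIIII",
        "r3\t0\tchr1\t93\t60\t10M\t*\t0\t0\tCCCCCCCACC\tIIIIIIIIII",
        "r4\t0\tchr1\t96\t60\t10M\t*\t0\t0\tCCCCGCCCCC\tIIIIIIIIII",
        "r5\t0\tchr1\t98\t60\t10M\t*\t0\t0\tCCGCCCCCCC\tIIIIIIIIII",
        "r6\t0\tchr1\t96\t60\t10M\t*\t0\t0\tCCCCTCCCCC\tIIIIIIIIII",
        "r7\t0\tchr1\t96\t5\t10M\t*\t0\t0\tCCCCACCCCC\tIIIIIIIIII",
        "r8\t0\tchr1\t96\t60\t10M\t*\t0\t0\tCCCCACCCCC\tIIII#IIIII",
        "r9\t0\tchr1\t96\t60\t4M2D6M\t*\t0\t0\tCCCCCCCCCC\tIIIIIIIIII",
        "r10\t1024\tchr1\t96\t60\t10M\t*\t0\t0\tCCCCACCCCC\tIIIIIIIIII",
        "r11\t0\tchr1\t96\t60\t10M\t*\t0\t0\tCCCCNCCCCC\tIIIIIIIIII",
        "p1\t99\tchr1\t96\t60\t10M\t=\t98\t12\tCCCCGCCCCC\tIIIIIIIIII",
        "p1\t147\tchr1\t98\t60\t10M\t=\t96\t-12\tCCGCCCCCCC\tIIIIIIIIII",
        "p2\t99\tchr1\t96\t60\t10M\t=\t97\t11\tCCCCACCCCC\tIIIIIIIIII",
        "p2\t147\tchr1\t97\t60\t10M\t=\t96\t-11\tCCCGCCCCCC\tIIIIIIIIII",
        "p3\t99\tchr1\t96\t60\t10M\t=\t300\t214\tCCCCACCCCC\tIIIIIIIIII",
        "p3\t147\tchr1\t300\t60\t10M\t=\t96\t-214\tCCCCCCCCCC\tIIIIIIIIII",
        "p4\t97\tchr1\t96\t60\t10M\t=\t300\t0\tCCCCACCCCC\tIIIIIIIIII",
        "p4\t145\tchr1\t300\t60\t10M\t=\t96\t0\tCCCCCCCCCC\tIIIIIIIIII",
        "",
    ]
)


@pytest.fixture
def hand_bam(tmp_path):
    return bam_from_sam(HAND_SAM, tmp_path, "hand")


SMALL_VCF = "\n".join(
    [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=100000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA001",
        "chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1",
        "chr1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/0",
        "chr1\t300\trs3\tAT\tA\t.\tPASS\t.\tGT\t0/1",
        "chr1\t400\trs4\tG\tC\t.\tPASS\t.\tGT\t1|0",
        "chr1\t500\trs5\tT\tA,C\t.\tPASS\t.\tGT\t0/1",
        "",
    ]
)


@pytest.fixture
def small_vcf(tmp_path):
    path = tmp_path / "small.vcf"
    path.write_text(SMALL_VCF)
    return path
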