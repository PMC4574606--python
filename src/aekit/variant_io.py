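"""Heterozygous-site input/output and positional site filtering.

Allelic expression is measured at bi-allelic heterozygous SNPs (het-SNPs):
the two parental haplotypes are distinguished by the reference and
alternative alleles of the site, and RNA-seq reads carrying each allele are
counted. This module defines the site universe: it loads het-SNPs from VCF,
applies positional blacklists (e.g. low-mappability or simulation-flagged
mapping-bias regions supplied as BED), and writes filtered site lists back
out.

Coordinate conventions: VCF positions are 1-based; BED intervals are 0-based
half-open. Conversion happens exactly once, at the filtering boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

_VALID_BASES = frozenset("ACGT")

__all__ = [
    "HetSite",
    "SiteFilterMask",
    "load_het_sites",
    "read_bed_mask",
    "apply_site_filter",
    "write_sites_vcf",
    "write_sites_tsv",
]


@dataclass(frozen=True)
class HetSite:
    """One bi-allelic heterozygous SNP — the unit of AE measurement.

    Attributes
    ----------
    chrom : str
        Chromosome name, exactly as in the source VCF (no harmonization).
    pos : int
        1-based position.
    ref_allele, alt_allele : str
        Single-nucleotide REF and ALT alleles.
    site_id : str
        Variant identifier; ``"."`` when absent.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    site_id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele not in _VALID_BASES:
            raise ValueError(f"ref allele must be one of A/C/G/T, got {self.ref_allele!r}")
        if self.alt_allele not in _VALID_BASES:
            raise ValueError(f"alt allele must be one of A/C/G/T, got {self.alt_allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def _merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> tuple[tuple[str, int, int], ...]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if start >= end:
            raise ValueError(f"interval start must be < end, got [{start}, {end})")
        if start < 0:
            raise ValueError(f"interval start must be >= 0, got {start}")
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return tuple(merged)


@dataclass(frozen=True)
class SiteFilterMask:
    """A set of genomic intervals (0-based half-open) to exclude from analysis.

    Typical masks mark regions of low mappability or sites with allelic
    mapping bias detected in alignment simulations. Intervals are merged on
    construction so the stored set is non-overlapping.
    """

    intervals: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)
    label: str = "mask"

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", _merge_intervals(self.intervals))

    def contains(self, chrom: str, pos: int) -> bool:
        """True if 1-based position ``pos`` falls inside a mask interval."""
        zero_based = pos - 1
        for c, s, e in self.intervals:
            if c == chrom and s <= zero_based < e:
                return True
        return False


def read_bed_mask(path: str | Path, label: str = "mask") -> SiteFilterMask:
    """Read a BED3+ file into a :class:`SiteFilterMask`."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: expected >= 3 BED columns")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return SiteFilterMask(intervals=tuple(intervals), label=label)


def _is_het(gt: tuple | None) -> bool:
    return gt is not None and tuple(sorted(x for x in gt if x is not None)) == (0, 1)


def load_het_sites(vcf_path: str | Path, sample: str | None = None) -> list[HetSite]:
    """Load bi-allelic het-SNPs from a VCF.

    Parameters
    ----------
    vcf_path
        Plain or bgzip-compressed VCF.
    sample
        If given, only records genotyped heterozygous (0/1, 0|1 or 1|0) for
        this sample are returned; phase is ignored. If None, every
        bi-allelic SNP record is returned as a candidate het site.

    Returns
    -------
    list of HetSite sorted by (chrom, pos). Multi-allelic and indel records
    are skipped with a single summary warning. Duplicate positions raise.
    """
    sites: list[HetSite] = []
    skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        if sample is not None and sample not in list(vcf.header.samples):
            raise ValueError(f"sample {sample!r} not present in {vcf_path}")
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref not in _VALID_BASES
                or alts[0] not in _VALID_BASES
            ):
                skipped += 1
                continue
            if sample is not None:
                gt = rec.samples[sample].get("GT")
                if not _is_het(gt):
                    continue
            sites.append(
                HetSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alts[0],
                    site_id=rec.id or ".",
                )
            )
    if skipped:
        warnings.warn(
            f"skipped {skipped} non-bi-allelic-SNP record(s) in {vcf_path}",
            stacklevel=2,
        )
    sites.sort(key=lambda s: s.key)
    for a, b in zip(sites, sites[1:]):
        if a.key == b.key:
            raise ValueError(f"duplicate site position {a.chrom}:{a.pos} in {vcf_path}")
    return sites


def apply_site_filter(
    sites: Sequence[HetSite], mask: SiteFilterMask
) -> tuple[list[HetSite], list[HetSite]]:
    """Partition ``sites`` into (retained, removed) under ``mask``.

    A site is removed when its position lies inside any mask interval
    (0-based half-open, so a site whose 0-based coordinate equals an
    interval end is retained). Input order is preserved in both outputs and
    the two lists partition the input exactly.
    """
    retained: list[HetSite] = []
    removed: list[HetSite] = []
    for site in sites:
        (removed if mask.contains(site.chrom, site.pos) else retained).append(site)
    return retained, removed


def write_sites_tsv(sites: Sequence[HetSite], path: str | Path) -> None:
    """Write sites as a 5-column TSV (contig, position, variantID, ref, alt)."""
    with open(path, "w") as fh:
        fh.write("contig\tposition\tvariantID\trefAllele\taltAllele\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.site_id}\t{s.ref_allele}\t{s.alt_allele}\n")


def write_sites_vcf(
    sites: Sequence[HetSite],
    path: str | Path,
    sample: str | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write sites as a minimal VCF v4.2; het genotype column when ``sample`` given.

    The written file round-trips through :func:`load_het_sites`.
    """
    chroms: list[str] = []
    for s in sites:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            if contig_lengths and chrom in contig_lengths:
                fh.write(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if sample is not None:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            cols += f"\tFORMAT\t{sample}"
        fh.write(cols + "\n")
        for s in sites:
            row = f"{s.chrom}\t{s.pos}\t{s.site_id}\t{s.ref_allele}\t{s.alt_allele}\t.\tPASS\t."
            if sample is not None:
                row += "\tGT\t0/1"
            fh.write(row + "\n")
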