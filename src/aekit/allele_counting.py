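"""Filtered allele counting at het-SNPs from aligned RNA-seq reads.

The counter walks a list of het-SNPs over a coordinate-sorted, indexed
alignment file and tallies, per site, the reads supporting the reference
allele, the alternative allele, and any other base, after a filtering
cascade designed to keep exactly one high-quality observation per
independent RNA fragment:

1. only primary alignments with an aligned base at the site enter the tally
   (reads spanning the site via a deletion or splice gap carry no base and
   are ignored entirely);
2. mapping-quality threshold (also enforcing unique mapping, together with
   the exclusion of secondary/supplementary records);
3. duplicate removal, with the retained representative chosen at random or
   by base quality — never by mapping score, which would bias towards the
   reference allele;
4. overlapping mates of one fragment are counted once when their base calls
   agree (at the higher of the two base qualities) and discarded when they
   conflict;
5. base-quality threshold on the surviving observation.

Every read that enters the tally is accounted for in exactly one output
bucket, so the per-site counts and filter diagnostics always sum to the raw
depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .variant_io import HetSite

__all__ = [
    "CountingOptions",
    "SiteCounts",
    "count_alleles",
    "resolve_fragment_overlap",
    "select_duplicate_representative",
    "write_counts_table",
    "read_counts_table",
]

_POLICIES = ("random", "by_base_quality")


@dataclass(frozen=True)
class CountingOptions:
    """Read-filtering options for allele counting.

    ``duplicate_detection``: ``"flag"`` trusts the SAM duplicate flag
    (0x400); ``"signature"`` groups fragments by alignment signature
    (chrom, fragment start, mate start, strand) and keeps one representative
    per group under ``duplicate_policy``. Mapping score is never consulted
    when choosing the representative.
    """

    min_base_quality: int = 10
    min_mapping_quality: int = 20
    remove_duplicates: bool = True
    duplicate_policy: str = "random"
    duplicate_detection: str = "flag"
    count_fragments_once: bool = True
    min_depth: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_base_quality < 0 or self.min_mapping_quality < 0:
            raise ValueError("quality thresholds must be >= 0")
        if self.duplicate_policy not in _POLICIES:
            raise ValueError(
                f"duplicate_policy must be one of {_POLICIES}, got "
                f"{self.duplicate_policy!r} (selection by mapping score is "
                "deliberately unsupported: it biases towards the reference allele)"
            )
        if self.duplicate_detection not in ("flag", "signature"):
            raise ValueError("duplicate_detection must be 'flag' or 'signature'")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass(frozen=True)
class SiteCounts:
    """Per-site allele counts plus filtered-read diagnostics.

    Invariant: ``ref_count + alt_count + other_count + low_baseq_dropped +
    low_mapq_dropped + duplicates_dropped + mate_conflicts_dropped +
    overlapping_mates_merged == raw_depth`` — every read with an aligned
    base at the site lands in exactly one bucket. ``improper_pairs`` is a
    diagnostic overlay (reads in non-proper pairs are counted, not
    filtered) and takes no part in the conservation sum.
    """

    site: HetSite
    ref_count: int = 0
    alt_count: int = 0
    other_count: int = 0
    raw_depth: int = 0
    low_baseq_dropped: int = 0
    low_mapq_dropped: int = 0
    duplicates_dropped: int = 0
    mate_conflicts_dropped: int = 0
    overlapping_mates_merged: int = 0
    improper_pairs: int = 0

    @property
    def total_count(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def ref_ratio(self) -> float:
        if self.total_count == 0:
            return float("nan")
        return self.ref_count / self.total_count

    def accounted(self) -> int:
        return (
            self.ref_count
            + self.alt_count
            + self.other_count
            + self.low_baseq_dropped
            + self.low_mapq_dropped
            + self.duplicates_dropped
            + self.mate_conflicts_dropped
            + self.overlapping_mates_merged
        )


def resolve_fragment_overlap(
    base1: str, qual1: int, base2: str, qual2: int
) -> tuple[str, int] | None:
    """Resolve two mate base calls of one fragment at one site.

    Returns the consensus ``(base, quality)`` counted once — at the higher
    of the two qualities — when the calls agree, or None (DISCARD) when
    they conflict: a fragment whose mates disagree at the site carries no
    trustworthy allele observation.
    """
    if base1 == base2:
        return base1, max(qual1, qual2)
    return None


@dataclass
class _ReadObs:
    name: str
    base: str
    baseq: int
    mapq: int
    is_dup: bool
    is_read1: bool
    signature: tuple


@dataclass
class _Fragment:
    reads: list[_ReadObs]

    @property
    def site_base_quality(self) -> int:
        return max(r.baseq for r in self.reads)

    @property
    def signature(self) -> tuple:
        return self.reads[0].signature


def select_duplicate_representative(
    group: Sequence, policy: str, seed: int | None = None, rng=None
):
    """Pick the one retained member of a duplicate group.

    ``policy="random"`` draws uniformly; ``policy="by_base_quality"`` keeps
    the member with the highest base quality at the site (ties broken at
    random). Mapping quality is never consulted — preferring the
    better-mapping read would systematically favour reference-allele reads.
    Members must expose ``site_base_quality``; plain ``(base, quality)``
    tuples are also accepted.
    """
    if len(group) == 0:
        raise ValueError("duplicate group must be non-empty")
    if policy not in _POLICIES:
        raise ValueError(f"unknown duplicate policy {policy!r}")
    if len(group) == 1:
        return group[0]
    if rng is None:
        rng = np.random.default_rng(seed)

    def _qual(m) -> int:
        return m.site_base_quality if hasattr(m, "site_base_quality") else m[1]

    if policy == "random":
        return group[int(rng.integers(len(group)))]
    best = max(_qual(m) for m in group)
    top = [m for m in group if _qual(m) == best]
    return top[int(rng.integers(len(top)))]


def _aligned_base(read: pysam.AlignedSegment, pos0: int) -> tuple[str, int] | None:
    """Base call and quality aligned at 0-based reference position, or None."""
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == pos0:
            seq = read.query_sequence
            quals = read.query_qualities
            return seq[qpos], (quals[qpos] if quals is not None else 0)
        if rpos is not None and rpos > pos0:
            break
    return None


def _fragment_signature(read: pysam.AlignedSegment) -> tuple:
    # Fragment-level signature: both mates of a PCR clone share it.
    self_start = read.reference_start
    mate_start = read.next_reference_start if read.is_paired else -1
    lo, hi = sorted((self_start, mate_start))
    strand = read.is_reverse if not read.is_paired else (
        read.is_reverse if read.is_read1 else not read.is_reverse
    )
    return (read.reference_name, lo, hi, strand)


def _count_site(
    aln: pysam.AlignmentFile, site: HetSite, options: CountingOptions, rng
) -> SiteCounts:
    pos0 = site.pos - 1
    obs: list[_ReadObs] = []
    improper = 0
    for read in aln.fetch(site.chrom, pos0, site.pos):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        hit = _aligned_base(read, pos0)
        if hit is None:
            continue  # deletion or splice gap over the site: no base to assign
        base, qual = hit
        if read.is_paired and not read.is_proper_pair:
            improper += 1
        obs.append(
            _ReadObs(
                name=read.query_name or "",
                base=base,
                baseq=qual,
                mapq=read.mapping_quality,
                is_dup=read.is_duplicate,
                is_read1=not read.is_read2,
                signature=_fragment_signature(read),
            )
        )

    raw_depth = len(obs)
    low_mapq = [r for r in obs if r.mapq < options.min_mapping_quality]
    kept = [r for r in obs if r.mapq >= options.min_mapping_quality]

    # group into fragments by read name
    frag_map: dict[str, list[_ReadObs]] = {}
    order: list[str] = []
    for r in kept:
        if r.name not in frag_map:
            frag_map[r.name] = []
            order.append(r.name)
        frag_map[r.name].append(r)
    fragments = [_Fragment(frag_map[name]) for name in order]

    duplicates_dropped = 0
    if options.remove_duplicates:
        if options.duplicate_detection == "flag":
            retained = []
            for f in fragments:
                if all(r.is_dup for r in f.reads):
                    duplicates_dropped += len(f.reads)
                else:
                    retained.append(f)
            fragments = retained
        else:
            groups: dict[tuple, list[_Fragment]] = {}
            gorder: list[tuple] = []
            for f in fragments:
                sig = f.signature
                if sig not in groups:
                    groups[sig] = []
                    gorder.append(sig)
                groups[sig].append(f)
            retained = []
            for sig in gorder:
                group = groups[sig]
                rep = select_duplicate_representative(
                    group, options.duplicate_policy, rng=rng
                )
                retained.append(rep)
                duplicates_dropped += sum(
                    len(f.reads) for f in group if f is not rep
                )
            fragments = retained

    mate_conflicts = 0
    mates_merged = 0
    candidates: list[tuple[str, int]] = []
    for f in fragments:
        if len(f.reads) >= 2 and options.count_fragments_once:
            # >2 observations per fragment name cannot occur for primary
            # paired alignments; resolve the first two defensively.
            r1, r2 = f.reads[0], f.reads[1]
            res = resolve_fragment_overlap(r1.base, r1.baseq, r2.base, r2.baseq)
            if res is None:
                mate_conflicts += len(f.reads)
            else:
                candidates.append(res)
                mates_merged += len(f.reads) - 1
        else:
            candidates.extend((r.base, r.baseq) for r in f.reads)

    ref = alt = other = low_baseq = 0
    for base, qual in candidates:
        if qual < options.min_base_quality:
            low_baseq += 1
        elif base == site.ref_allele:
            ref += 1
        elif base == site.alt_allele:
            alt += 1
        else:
            other += 1  # includes 'N' calls

    return SiteCounts(
        site=site,
        ref_count=ref,
        alt_count=alt,
        other_count=other,
        raw_depth=raw_depth,
        low_baseq_dropped=low_baseq,
        low_mapq_dropped=len(low_mapq),
        duplicates_dropped=duplicates_dropped,
        mate_conflicts_dropped=mate_conflicts,
        overlapping_mates_merged=mates_merged,
        improper_pairs=improper,
    )


def count_alleles(
    alignments: str | Path | pysam.AlignmentFile,
    sites: Sequence[HetSite],
    options: CountingOptions | None = None,
) -> list[SiteCounts]:
    """Count reference/alternative/other allele reads at each het-SNP.

    ``alignments`` must be coordinate-sorted and indexed. Returns one
    :class:`SiteCounts` per site in input order (zero-coverage sites
    included); when ``options.min_depth > 0``, sites with fewer counted
    ref+alt reads are omitted. Deterministic under ``options.rng_seed``.
    """
    if options is None:
        options = CountingOptions()
    own = not isinstance(alignments, pysam.AlignmentFile)
    aln = pysam.AlignmentFile(str(alignments)) if own else alignments
    try:
        try:
            has_index = aln.check_index()
        except (ValueError, AttributeError) as exc:
            raise ValueError(
                f"alignment file {aln.filename!r} must be coordinate-sorted and indexed"
            ) from exc
        if not has_index:
            raise ValueError(
                f"alignment file {aln.filename!r} must be coordinate-sorted and indexed"
            )
        refs = set(aln.references)
        rng = np.random.default_rng(options.rng_seed)
        out: list[SiteCounts] = []
        for site in sites:
            if site.chrom not in refs:
                raise ValueError(
                    f"chromosome {site.chrom!r} absent from alignment header "
                    f"(header names: {sorted(refs)[:5]}...)"
                )
            sc = _count_site(aln, site, options, rng)
            if options.min_depth > 0 and sc.total_count < options.min_depth:
                continue
            out.append(sc)
        return out
    finally:
        if own:
            aln.close()


_TABLE_COLUMNS = [
    "contig",
    "position",
    "variantID",
    "refAllele",
    "altAllele",
    "refCount",
    "altCount",
    "totalCount",
    "lowMAPQDepth",
    "lowBaseQDepth",
    "rawDepth",
    "otherBases",
    "improperPairs",
    # extra diagnostics beyond the classic counter schema; appended so the
    # leading columns keep the familiar order and meaning
    "duplicatesDropped",
    "mateConflicts",
    "matesMerged",
]


def counts_to_frame(counts: Iterable[SiteCounts]) -> pd.DataFrame:
    rows = [
        {
            "contig": c.site.chrom,
            "position": c.site.pos,
            "variantID": c.site.site_id,
            "refAllele": c.site.ref_allele,
            "altAllele": c.site.alt_allele,
            "refCount": c.ref_count,
            "altCount": c.alt_count,
            "totalCount": c.total_count,
            "lowMAPQDepth": c.low_mapq_dropped,
            "lowBaseQDepth": c.low_baseq_dropped,
            "rawDepth": c.raw_depth,
            "otherBases": c.other_count,
            "improperPairs": c.improper_pairs,
            "duplicatesDropped": c.duplicates_dropped,
            "mateConflicts": c.mate_conflicts_dropped,
            "matesMerged": c.overlapping_mates_merged,
        }
        for c in counts
    ]
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_counts_table(counts: Iterable[SiteCounts], path: str | Path) -> None:
    """Write per-site counts as TSV, one row per site, fixed column order."""
    counts_to_frame(counts).to_csv(path, sep="\t", index=False)


def read_counts_table(path: str | Path) -> list[SiteCounts]:
    """Read a counts TSV written by :func:`write_counts_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "variantID": str})
    out: list[SiteCounts] = []
    for row in df.itertuples(index=False):
        site = HetSite(
            chrom=str(row.contig),
            pos=int(row.position),
            ref_allele=str(row.refAllele),
            alt_allele=str(row.altAllele),
            site_id=str(row.variantID),
        )
        out.append(
            SiteCounts(
                site=site,
                ref_count=int(row.refCount),
                alt_count=int(row.altCount),
                other_count=int(row.otherBases),
                raw_depth=int(row.rawDepth),
                low_baseq_dropped=int(row.lowBaseQDepth),
                low_mapq_dropped=int(row.lowMAPQDepth),
                duplicates_dropped=int(getattr(row, "duplicatesDropped", 0)),
                mate_conflicts_dropped=int(getattr(row, "mateConflicts", 0)),
                overlapping_mates_merged=int(getattr(row, "matesMerged", 0)),
                improper_pairs=int(row.improperPairs),
            )
        )
    return out
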