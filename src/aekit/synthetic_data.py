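"""Synthetic RNA-seq alignments and genotypes with known allelic truth.

Every error source the counting and QC stages must handle is a generative
knob here: per-base sequencing error (substituted uniformly over the three
non-template bases), PCR duplicates (fragments cloned and flag-marked),
overlapping mate pairs (both mates of a fragment covering the site),
genotyping errors (a fraction of nominally heterozygous sites that are
truly homozygous), and reference mapping bias (ALT-carrying fragments
thinned with a retention probability < 1, emulating the lower alignment
success of reads mismatching the reference).

Reads are paired-end, fully matching a synthetic reference except for the
planted allele at each het-SNP; alignment itself is out of scope, so the
emitted BAM is "perfectly aligned" by construction and exercises counting
semantics, not aligner behavior. A counts-level generator
(:func:`simulate_site_counts`) draws per-site allele counts from the same
probability model without materializing reads, for large statistical
calibration experiments.

Identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .allele_counting import SiteCounts
from .variant_io import HetSite, write_sites_vcf

__all__ = [
    "SimConfig",
    "SimSample",
    "CohortSim",
    "simulate_sample",
    "simulate_site_counts",
    "simulate_cohort",
    "simulate_cohort_counts",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Generative settings for one simulated RNA-seq sample.

    Coverage is per-site fragment count: fixed at ``round(coverage_mean)``
    when ``coverage_dispersion`` is None, otherwise negative binomial with
    that mean and size (dispersion) parameter. True reference ratios at het
    sites are ``ratio`` everywhere, or drawn uniformly from
    ``0.5 +/- ratio_spread`` (a simple symmetric overdispersion family), or
    given explicitly per site via ``site_ratios``. ``reference_bias`` is
    the retention probability of an ALT-carrying fragment (1 = unbiased).
    """

    n_sites: int = 100
    coverage_mean: float = 30.0
    coverage_dispersion: float | None = None
    ratio: float = 0.5
    ratio_spread: float = 0.0
    site_ratios: tuple[float, ...] | None = None
    error_rate: float = 0.0
    duplicate_rate: float = 0.0
    mate_overlap_fraction: float = 0.0
    genotype_error_fraction: float = 0.0
    reference_bias: float = 1.0
    read_length: int = 50
    fragment_length_mean: float = 300.0
    fragment_length_sd: float = 30.0
    base_quality: int = 30
    mapping_quality: int = 60
    site_spacing: int = 1000
    chrom: str = "chr1"
    sample_name: str = "SIM"
    seed: int = 0
    genome_seed: int | None = None  # share one reference across a cohort

    def __post_init__(self) -> None:
        for name in (
            "duplicate_rate",
            "mate_overlap_fraction",
            "genotype_error_fraction",
            "reference_bias",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.read_length < 2:
            raise ValueError("read_length must be >= 2")
        if self.fragment_length_mean < 2 * self.read_length:
            raise ValueError(
                "contradictory config: fragment_length_mean must be >= "
                "2 * read_length so non-overlapping mate pairs exist"
            )
        if self.site_ratios is not None and len(self.site_ratios) != self.n_sites:
            raise ValueError("site_ratios must have one entry per site")
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError("ratio must be in [0, 1]")
        if not 0.0 <= self.ratio_spread <= 0.5:
            raise ValueError("ratio_spread must be in [0, 0.5]")


@dataclass(frozen=True)
class SimSample:
    """File bundle and in-memory truth for one simulated sample."""

    bam_path: Path
    vcf_path: Path
    truth_path: Path
    sites: tuple[HetSite, ...]
    truth: pd.DataFrame
    sample_name: str


@dataclass(frozen=True)
class CohortSim:
    """A simulated cohort: per-individual bundles plus eSNP genotype table."""

    samples: Mapping[str, SimSample]
    esnp_table: pd.DataFrame  # columns: individual, gene, genotype
    genes: pd.DataFrame  # columns: gene_id, chrom, start, end (0-based half-open)


def _layout(config: SimConfig) -> tuple[int, np.ndarray]:
    """Genome length and 1-based site positions (deterministic per config)."""
    margin = int(
        config.fragment_length_mean + 4.0 * config.fragment_length_sd
    ) + 2 * config.read_length
    positions = margin + config.site_spacing * np.arange(config.n_sites)
    genome_len = int(positions[-1]) + margin
    return genome_len, positions


def _make_genome_and_sites(
    config: SimConfig,
) -> tuple[np.ndarray, list[HetSite], np.ndarray]:
    genome_len, positions = _layout(config)
    rng = np.random.default_rng(
        config.seed if config.genome_seed is None else config.genome_seed
    )
    genome = _BASES[rng.integers(0, 4, genome_len)]
    sites = []
    for i, pos in enumerate(positions):
        ref = genome[pos - 1].decode()
        alt = rng.choice([b for b in "ACGT" if b != ref])
        sites.append(
            HetSite(
                chrom=config.chrom,
                pos=int(pos),
                ref_allele=ref,
                alt_allele=str(alt),
                site_id=f"snp{i}",
            )
        )
    return genome, sites, positions


def _draw_truth(config: SimConfig, sites: Sequence[HetSite], rng) -> pd.DataFrame:
    records = []
    for i, site in enumerate(sites):
        if rng.random() < config.genotype_error_fraction:
            genotype = "hom_ref" if rng.random() < 0.5 else "hom_alt"
            ratio = 1.0 if genotype == "hom_ref" else 0.0
        else:
            genotype = "het"
            if config.site_ratios is not None:
                ratio = float(config.site_ratios[i])
            elif config.ratio_spread > 0:
                ratio = 0.5 + rng.uniform(-config.ratio_spread, config.ratio_spread)
            else:
                ratio = config.ratio
        records.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "ref": site.ref_allele,
                "alt": site.alt_allele,
                "true_genotype": genotype,
                "true_ref_ratio": ratio,
            }
        )
    return pd.DataFrame(records)


def _coverage(config: SimConfig, rng) -> int:
    if config.coverage_dispersion is None:
        return int(round(config.coverage_mean))
    size = config.coverage_dispersion
    p = size / (size + config.coverage_mean)
    return int(rng.negative_binomial(size, p))


def _site_base(true_base: str, error_rate: float, rng) -> str:
    if error_rate > 0 and rng.random() < error_rate:
        others = [b for b in "ACGT" if b != true_base]
        return others[int(rng.integers(3))]
    return true_base


def simulate_sample(
    config: SimConfig, out_dir: str | Path, prefix: str | None = None
) -> SimSample:
    """Generate one sample: sorted+indexed BAM, het-site VCF, truth TSV.

    Truth columns include, per site: the true genotype and reference ratio,
    ``true_coverage`` (fragments written, clones excluded),
    ``n_fragments_drawn`` (before bias thinning), ``n_bias_dropped``,
    ``n_duplicates`` (clone fragments added) and ``n_overlap_fragments``
    (fragments whose mates both cover the site). Reads in the BAM equal
    ``2 * sum(true_coverage + n_duplicates)`` exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or config.sample_name
    rng = np.random.default_rng(config.seed)
    genome, sites, _ = _make_genome_and_sites(config)
    truth = _draw_truth(config, sites, rng)

    L = config.read_length
    reads: list[tuple] = []  # (pos0, qname, flag, seq, mate_pos0, tlen)
    stats_rows = []
    for i, site in enumerate(sites):
        p0 = site.pos - 1
        ratio = float(truth.loc[i, "true_ref_ratio"])
        n_frags = _coverage(config, rng)
        retained = dup_count = bias_dropped = overlap_count = 0
        for f in range(n_frags):
            is_ref = rng.random() < ratio
            if not is_ref and rng.random() >= config.reference_bias:
                bias_dropped += 1
                continue
            allele = site.ref_allele if is_ref else site.alt_allele
            overlap = rng.random() < config.mate_overlap_fraction
            if overlap:
                d = int(rng.integers(1, max(2, L // 2 + 1)))
                lo = max(0, p0 - L + 1)
                s1 = int(rng.integers(lo, p0 - d + 1))
                s2 = s1 + d
                flen = L + d
                overlap_count += 1
            else:
                flen = max(2 * L, int(round(rng.normal(
                    config.fragment_length_mean, config.fragment_length_sd
                ))))
                if rng.random() < 0.5:
                    s1 = int(rng.integers(max(0, p0 - L + 1), p0 + 1))
                    s2 = s1 + flen - L
                else:
                    s2 = int(rng.integers(max(0, p0 - L + 1), p0 + 1))
                    s1 = max(0, s2 - (flen - L))
                    flen = s2 + L - s1

            def _seq(start: int) -> str:
                chars = genome[start : start + L].tobytes().decode()
                if start <= p0 < start + L:
                    k = p0 - start
                    base = _site_base(allele, config.error_rate, rng)
                    chars = chars[:k] + base + chars[k + 1 :]
                return chars

            qname = f"f{i}_{f}"
            seq1, seq2 = _seq(s1), _seq(s2)
            pair = [
                (s1, qname, 0x1 | 0x2 | 0x20 | 0x40, seq1, s2, flen),
                (s2, qname, 0x1 | 0x2 | 0x10 | 0x80, seq2, s1, -flen),
            ]
            reads.extend(pair)
            retained += 1
            if rng.random() < config.duplicate_rate:
                dupname = qname + "d"
                reads.append((s1, dupname, 0x1 | 0x2 | 0x20 | 0x40 | 0x400, seq1, s2, flen))
                reads.append((s2, dupname, 0x1 | 0x2 | 0x10 | 0x80 | 0x400, seq2, s1, -flen))
                dup_count += 1
        stats_rows.append(
            {
                "true_coverage": retained,
                "n_fragments_drawn": n_frags,
                "n_bias_dropped": bias_dropped,
                "n_duplicates": dup_count,
                "n_overlap_fragments": overlap_count,
            }
        )

    truth = pd.concat([truth, pd.DataFrame(stats_rows)], axis=1)
    reads.sort(key=lambda r: (r[0], r[1], r[2]))

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.chrom, "LN": int(len(genome))}],
        "RG": [{"ID": config.sample_name, "SM": config.sample_name}],
    }
    bam_path = out_dir / f"{prefix}.bam"
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for pos0, qname, flag, seq, mate_pos0, tlen in reads:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos0
            a.mapping_quality = config.mapping_quality
            a.cigarstring = f"{L}M"
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(
                chr(config.base_quality + 33) * L
            )
            a.next_reference_id = 0
            a.next_reference_start = mate_pos0
            a.template_length = tlen
            a.set_tag("RG", config.sample_name)
            bam.write(a)
    pysam.index(str(bam_path))

    vcf_path = out_dir / f"{prefix}.vcf"
    write_sites_vcf(
        sites, vcf_path, sample=config.sample_name,
        contig_lengths={config.chrom: int(len(genome))},
    )
    truth_path = out_dir / f"{prefix}.truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimSample(
        bam_path=bam_path,
        vcf_path=vcf_path,
        truth_path=truth_path,
        sites=tuple(sites),
        truth=truth,
        sample_name=config.sample_name,
    )


def simulate_site_counts(
    config: SimConfig,
) -> tuple[list[SiteCounts], pd.DataFrame]:
    """Draw per-site allele counts from the generative model, without reads.

    Uses the same probability model as :func:`simulate_sample` — allele
    choice at the true ratio, ALT thinning at ``reference_bias``, then
    per-read substitution error uniform over the three non-template bases —
    but skips read geometry, duplicates and mate overlap (which exist only
    at the read level). Fast enough for calibration experiments with tens
    of thousands of sites.
    """
    rng = np.random.default_rng(config.seed)
    _, positions = _layout(config)
    alleles = "ACGT"
    sites = []
    rng_sites = np.random.default_rng(
        config.seed if config.genome_seed is None else config.genome_seed
    )
    for i, pos in enumerate(positions):
        ref, alt = rng_sites.choice(list(alleles), size=2, replace=False)
        sites.append(
            HetSite(config.chrom, int(pos), str(ref), str(alt), site_id=f"snp{i}")
        )
    truth = _draw_truth(config, sites, rng)
    counts = []
    for i, site in enumerate(sites):
        n = _coverage(config, rng)
        ratio = float(truth.loc[i, "true_ref_ratio"])
        n_ref_true = int(rng.binomial(n, ratio))
        n_alt_true = n - n_ref_true
        if config.reference_bias < 1.0:
            n_alt_true = int(rng.binomial(n_alt_true, config.reference_bias))
        ref = alt = other = 0
        for true_base, m in ((site.ref_allele, n_ref_true), (site.alt_allele, n_alt_true)):
            errs = int(rng.binomial(m, config.error_rate)) if config.error_rate else 0
            correct = m - errs
            if true_base == site.ref_allele:
                ref += correct
            else:
                alt += correct
            if errs:
                others = [b for b in alleles if b != true_base]
                targets = rng.integers(0, 3, errs)
                for t in targets:
                    b = others[int(t)]
                    if b == site.ref_allele:
                        ref += 1
                    elif b == site.alt_allele:
                        alt += 1
                    else:
                        other += 1
        counts.append(
            SiteCounts(
                site=site,
                ref_count=ref,
                alt_count=alt,
                other_count=other,
                raw_depth=ref + alt + other,
            )
        )
    truth["true_coverage"] = [c.raw_depth for c in counts]
    return counts, truth


def _assign_cohort(
    n_individuals: int,
    n_egenes: int,
    sites_per_gene: int,
    het_effect: float,
    rng,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Genotype classes (individual x gene) and per-site true ratios."""
    individuals = [f"IND{i:03d}" for i in range(n_individuals)]
    is_het = rng.random((n_individuals, n_egenes)) < 0.5
    n_sites = n_egenes * sites_per_gene
    ratios = np.full((n_individuals, n_sites), 0.5)
    for i in range(n_individuals):
        for g in range(n_egenes):
            if is_het[i, g]:
                signs = rng.choice([-1.0, 1.0], size=sites_per_gene)
                ratios[i, g * sites_per_gene : (g + 1) * sites_per_gene] = (
                    0.5 + signs * het_effect
                )
    return individuals, is_het, ratios


def _gene_table(config: SimConfig, n_egenes: int, sites_per_gene: int) -> pd.DataFrame:
    _, positions = _layout(replace(config, n_sites=n_egenes * sites_per_gene))
    half = config.site_spacing // 2
    rows = []
    for g in range(n_egenes):
        first = int(positions[g * sites_per_gene])
        last = int(positions[(g + 1) * sites_per_gene - 1])
        rows.append(
            {
                "gene_id": f"gene{g}",
                "chrom": config.chrom,
                "start": max(0, first - 1 - half),
                "end": last + half,
            }
        )
    return pd.DataFrame(rows)


def _esnp_frame(individuals, is_het, n_egenes) -> pd.DataFrame:
    rows = [
        {
            "individual": ind,
            "gene": f"gene{g}",
            "genotype": "heterozygous" if is_het[i, g] else "homozygous",
        }
        for i, ind in enumerate(individuals)
        for g in range(n_egenes)
    ]
    return pd.DataFrame(rows)


def simulate_cohort(
    base: SimConfig,
    n_individuals: int,
    n_egenes: int,
    het_effect: float,
    cohort_seed: int,
    out_dir: str | Path,
) -> CohortSim:
    """Simulate a read-level cohort for the eQTL-validation analysis.

    Each individual is assigned heterozygous or homozygous status for each
    eGene's eSNP (probability 0.5 each); het individuals' sites within the
    gene get true reference ratio 0.5 +/- het_effect (sign random per
    site), hom individuals 0.5. ``base.n_sites`` is partitioned evenly
    into ``n_egenes`` genes; all individuals share one synthetic reference
    genome and site list. Deterministic under ``cohort_seed``.
    """
    if not 0.0 <= het_effect < 0.5:
        raise ValueError("het_effect must be in [0, 0.5)")
    sites_per_gene = base.n_sites // n_egenes
    if sites_per_gene < 1:
        raise ValueError("n_sites must be >= n_egenes")
    n_sites = n_egenes * sites_per_gene
    rng = np.random.default_rng(cohort_seed)
    individuals, is_het, ratios = _assign_cohort(
        n_individuals, n_egenes, sites_per_gene, het_effect, rng
    )
    out_dir = Path(out_dir)
    samples: dict[str, SimSample] = {}
    for i, ind in enumerate(individuals):
        cfg = replace(
            base,
            n_sites=n_sites,
            site_ratios=tuple(ratios[i]),
            seed=int(rng.integers(2**31)),
            genome_seed=cohort_seed,
            sample_name=ind,
        )
        samples[ind] = simulate_sample(cfg, out_dir / ind)
    return CohortSim(
        samples=samples,
        esnp_table=_esnp_frame(individuals, is_het, n_egenes),
        genes=_gene_table(base, n_egenes, sites_per_gene),
    )


def simulate_cohort_counts(
    base: SimConfig,
    n_individuals: int,
    n_egenes: int,
    het_effect: float,
    cohort_seed: int,
) -> tuple[dict[str, list[SiteCounts]], pd.DataFrame, pd.DataFrame]:
    """Counts-level cohort (no reads): fast variant of :func:`simulate_cohort`.

    Returns (counts by individual, eSNP genotype table, gene table).
    """
    if not 0.0 <= het_effect < 0.5:
        raise ValueError("het_effect must be in [0, 0.5)")
    sites_per_gene = base.n_sites // n_egenes
    if sites_per_gene < 1:
        raise ValueError("n_sites must be >= n_egenes")
    n_sites = n_egenes * sites_per_gene
    rng = np.random.default_rng(cohort_seed)
    individuals, is_het, ratios = _assign_cohort(
        n_individuals, n_egenes, sites_per_gene, het_effect, rng
    )
    counts_by_individual: dict[str, list[SiteCounts]] = {}
    for i, ind in enumerate(individuals):
        cfg = replace(
            base,
            n_sites=n_sites,
            site_ratios=tuple(ratios[i]),
            seed=int(rng.integers(2**31)),
            genome_seed=cohort_seed,
            sample_name=ind,
        )
        counts_by_individual[ind], _ = simulate_site_counts(cfg)
    return (
        counts_by_individual,
        _esnp_frame(individuals, is_het, n_egenes),
        _gene_table(base, n_egenes, sites_per_gene),
    )
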