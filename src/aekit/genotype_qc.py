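"""Genotype-error detection and per-sample QC from allele-count data.

A homozygous site miscalled as heterozygous shows up in RNA-seq as
monoallelic expression, mimicking strong allelic imbalance. At high
coverage, however, even truly homozygous sites accumulate a few reads of
the "wrong" allele through sequencing and alignment noise, so strict
monoallelicity is the wrong criterion. This module implements a binomial
noise model instead:

* the per-library noise rate ``epsilon`` is estimated from reads carrying
  alleles *other* than the designated REF or ALT — alleles that cannot be
  produced by either true haplotype;
* each site is then tested against the null hypothesis of homozygosity:
  under hom-REF the alternative-allele count n_A is Binomial(n, epsilon),
  and symmetrically under hom-ALT. The two upper-tail probabilities
  P(x >= n_A | RR) and P(x >= n_R | AA) are summed (capped at 1);
* sites where homozygosity cannot be rejected at the configured FDR are
  flagged as possible genotyping errors.

Sample-level metrics (fraction of het-SNPs with both alleles observed,
DNA-RNA heterozygous concordance) detect genotyping-platform problems and
sample contamination or mislabeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .allele_counting import SiteCounts
from .variant_io import HetSite

__all__ = [
    "NoiseEstimate",
    "HomozygosityCall",
    "NoQualifyingSitesError",
    "estimate_noise_rate",
    "homozygosity_test",
    "flag_genotype_errors",
    "both_alleles_observed_fraction",
    "dna_rna_het_concordance",
]

OTHER_ALLELE_EXCLUSION = 0.05  # sites with > 5 % other-allele reads are not used for epsilon


class NoQualifyingSitesError(ValueError):
    """Raised when a QC metric has no qualifying sites and is undefined."""


@dataclass(frozen=True)
class NoiseEstimate:
    """Empirical per-library noise rate.

    ``epsilon`` is the ratio of the summed other-allele reads to half the
    summed reads of the eligible sites: a read drawn from one of the two
    true alleles can err towards either of the two non-template bases that
    are neither REF nor ALT, or towards the opposite designated allele, so
    other-allele reads observe two of the (roughly) equally likely error
    targets and the halved denominator converts the observed fraction into
    a per-allele error rate.
    """

    epsilon: float
    other_allele_reads: int
    total_reads: int
    sites_used: int
    sites_excluded: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")


@dataclass(frozen=True)
class HomozygosityCall:
    site: HetSite
    n_ref: int
    n_alt: int
    p_hom: float
    q_value: float
    flagged: bool


def estimate_noise_rate(counts: Sequence[SiteCounts]) -> NoiseEstimate:
    """Estimate the library noise rate epsilon from other-allele reads.

    Sites where strictly more than 5 % of assigned reads (ref+alt+other)
    carry an other allele are excluded from both sums — large other-allele
    fractions indicate site-specific artifacts rather than uniform noise.
    """
    if len(counts) == 0:
        raise ValueError("cannot estimate noise rate from zero sites")
    other_sum = 0
    total_sum = 0
    used = excluded = 0
    for c in counts:
        site_total = c.ref_count + c.alt_count + c.other_count
        if site_total > 0 and c.other_count / site_total > OTHER_ALLELE_EXCLUSION:
            excluded += 1
            continue
        used += 1
        other_sum += c.other_count
        total_sum += site_total
    if total_sum == 0:
        warnings.warn("no reads at eligible sites; epsilon set to 0", stacklevel=2)
        eps = 0.0
    else:
        eps = other_sum / (total_sum / 2.0)
    return NoiseEstimate(
        epsilon=min(eps, 1.0),
        other_allele_reads=other_sum,
        total_reads=total_sum,
        sites_used=used,
        sites_excluded=excluded,
    )


def homozygosity_test(
    n_ref: int, n_alt: int, epsilon: float, inclusive: bool = True
) -> float:
    """Two-tail binomial test of homozygosity at one site.

    Returns ``min(1, P(x >= n_alt | hom-REF) + P(x >= n_ref | hom-ALT))``
    where each count is Binomial(n, epsilon) under the respective
    homozygous null. A small p rejects homozygosity (the site is a genuine
    het); p near 1 means the data are consistent with one true allele plus
    noise.

    ``inclusive=True`` computes "n or more" tails, i.e. ``P(x >= k) =
    1 - BinCDF(k-1, n, eps)``; ``inclusive=False`` uses the strict
    ``1 - BinCDF(k, n, eps)`` convention instead, for exact replication of
    pipelines written that way.
    """
    if n_ref < 0 or n_alt < 0:
        raise ValueError("allele counts must be non-negative")
    n = n_ref + n_alt
    if n < 1:
        raise ValueError("total count must be >= 1")
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must be in [0, 1)")
    shift = 1 if inclusive else 0
    tail_alt = stats.binom.sf(n_alt - shift, n, epsilon)
    tail_ref = stats.binom.sf(n_ref - shift, n, epsilon)
    return float(min(1.0, tail_alt + tail_ref))


def flag_genotype_errors(
    counts: Sequence[SiteCounts],
    epsilon: float,
    fdr: float = 0.01,
    inclusive: bool = True,
) -> list[HomozygosityCall]:
    """Flag sites whose counts fail to reject homozygosity at the given FDR.

    Benjamini-Hochberg correction is applied across sites; a site is
    flagged when its adjusted homozygosity p-value does NOT attain
    significance — including fully monoallelic low-count sites, where
    homozygosity cannot be rejected and heterozygosity is unsupported.
    Sites with zero ref+alt reads are always flagged. Output order matches
    input order.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must be in (0, 1)")
    p_values = []
    for c in counts:
        if c.total_count == 0:
            p_values.append(1.0)
        else:
            p_values.append(
                homozygosity_test(c.ref_count, c.alt_count, epsilon, inclusive)
            )
    if p_values:
        reject, q_values, _, _ = multipletests(p_values, alpha=fdr, method="fdr_bh")
    else:
        reject, q_values = np.array([], dtype=bool), np.array([])
    return [
        HomozygosityCall(
            site=c.site,
            n_ref=c.ref_count,
            n_alt=c.alt_count,
            p_hom=float(p),
            q_value=float(q),
            flagged=not bool(rej),
        )
        for c, p, q, rej in zip(counts, p_values, q_values, reject)
    ]


def both_alleles_observed_fraction(
    counts: Sequence[SiteCounts], min_depth: int = 8
) -> float:
    """Fraction of het-SNPs (total_count >= min_depth) with reads from both alleles.

    A sensitive genome-wide indicator of genotyping quality: false het
    calls appear monoallelic, so an excess of single-allele sites flags a
    sample with poor genotypes.
    """
    qualifying = [c for c in counts if c.total_count >= min_depth]
    if not qualifying:
        raise NoQualifyingSitesError(
            f"no sites with total_count >= {min_depth}; fraction undefined"
        )
    both = sum(1 for c in qualifying if c.ref_count > 0 and c.alt_count > 0)
    return both / len(qualifying)


def dna_rna_het_concordance(
    counts: Sequence[SiteCounts], min_depth: int = 8, min_minor_reads: int = 1
) -> float:
    """Proportion of DNA-heterozygous sites that look heterozygous in RNA.

    Among sites with total_count >= min_depth, the fraction whose
    lesser-covered allele has at least ``min_minor_reads`` reads. With the
    default of 1 this reduces to :func:`both_alleles_observed_fraction`.
    Low values indicate sample contamination or mislabeling.
    """
    qualifying = [c for c in counts if c.total_count >= min_depth]
    if not qualifying:
        raise NoQualifyingSitesError(
            f"no sites with total_count >= {min_depth}; concordance undefined"
        )
    concordant = sum(
        1 for c in qualifying if min(c.ref_count, c.alt_count) >= min_minor_reads
    )
    return concordant / len(qualifying)
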