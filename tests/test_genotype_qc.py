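"""Noise-rate estimation and the binomial homozygosity test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aekit.allele_counting import SiteCounts
from aekit.genotype_qc import (
    NoQualifyingSitesError,
    both_alleles_observed_fraction,
    dna_rna_het_concordance,
    estimate_noise_rate,
    flag_genotype_errors,
    homozygosity_test,
)
from aekit.synthetic_data import SimConfig, simulate_site_counts
from aekit.variant_io import HetSite


def _counts(triples):
    return [
        SiteCounts(
            site=HetSite("chr1", 100 + i * 10, "A", "G"),
            ref_count=r,
            alt_count=a,
            other_count=o,
            raw_depth=r + a + o,
        )
        for i, (r, a, o) in enumerate(triples)
    ]


def brute_force_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by direct probability-mass summation
    (log-factorial arithmetic, independent of any CDF routine)."""
    if k <= 0:
        return 1.0
    if p == 0.0:
        return 0.0
    total = 0.0
    for x in range(k, n + 1):
        log_pmf = (
            math.lgamma(n + 1)
            - math.lgamma(x + 1)
            - math.lgamma(n - x + 1)
            + x * math.log(p)
            + (n - x) * math.log1p(-p)
        )
        total += math.exp(log_pmf)
    return total


class TestNoiseRate:
    def test_worked_fixture(self):
        """Sites (45,50,5) and (50,48,2): the first sits exactly at the 5 %
        other-allele boundary and is retained (the exclusion is strict),
        giving epsilon = 7 / (200/2) = 0.07."""
        est = estimate_noise_rate(_counts([(45, 50, 5), (50, 48, 2)]))
        assert est.other_allele_reads == 7
        assert est.total_reads == 200
        assert est.epsilon == pytest.approx(0.07)
        assert est.sites_used == 2 and est.sites_excluded == 0

    def test_zero_other_reads(self):
        assert estimate_noise_rate(_counts([(30, 30, 0), (10, 20, 0)])).epsilon == 0.0

    def test_noisy_site_excluded(self):
        """A site with 10 % other-allele reads is excluded from both sums."""
        est = estimate_noise_rate(_counts([(45, 45, 10), (50, 48, 2)]))
        assert est.sites_excluded == 1
        assert est.epsilon == pytest.approx(2 / (100 / 2))

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            estimate_noise_rate([])

    def test_epsilon_recovery_from_generative_model(self):
        """With per-read error e substituted uniformly over the 3 non-template
        bases, other-allele reads occur at rate 2e/3 per read, so the halved
        denominator makes E[epsilon-hat] = 4e/3."""
        e = 0.015
        counts, _ = simulate_site_counts(
            SimConfig(n_sites=2000, coverage_mean=60, error_rate=e, seed=42)
        )
        est = estimate_noise_rate(counts)
        expected = 4 * e / 3
        # binomial MC error on the pooled other-read rate
        total = est.total_reads
        se = math.sqrt((2 * e / 3) * (1 - 2 * e / 3) / total) * 2
        assert abs(est.epsilon - expected) < 3 * se


class TestHomozygosityTest:
    def test_monoallelic_site_p_is_one(self):
        """With n_A = 0 the P(x >= 0) tail is certain: homozygosity is never
        rejected for a monoallelic site."""
        assert homozygosity_test(30, 0, 0.01) == 1.0

    def test_balanced_het_matches_brute_force(self):
        p = homozygosity_test(15, 15, 0.01)
        expected = brute_force_tail(15, 30, 0.01) * 2
        assert p == pytest.approx(expected, rel=1e-12)
        assert p < 1e-15

    def test_zero_noise_limit(self):
        """Under epsilon = 0 any read of each allele is impossible for a
        homozygote, so p = 0 whenever both alleles are seen."""
        assert homozygosity_test(5, 3, 0.0) == 0.0
        assert homozygosity_test(5, 0, 0.0) == 1.0

    def test_exclusive_tail_convention(self):
        """The strict-inequality variant drops the observed count from the
        tail: p(exclusive) < p(inclusive) and matches its own brute force."""
        n_r, n_a, eps = 28, 2, 0.05
        inc = homozygosity_test(n_r, n_a, eps, inclusive=True)
        exc = homozygosity_test(n_r, n_a, eps, inclusive=False)
        assert exc < inc
        expected = brute_force_tail(n_a + 1, 30, eps) + brute_force_tail(n_r + 1, 30, eps)
        assert exc == pytest.approx(min(1.0, expected), rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            homozygosity_test(0, 0, 0.01)
        with pytest.raises(ValueError):
            homozygosity_test(5, 5, 1.0)
        with pytest.raises(ValueError):
            homozygosity_test(-1, 5, 0.01)

    @given(
        n_r=st.integers(0, 100),
        n_a=st.integers(0, 100),
        eps=st.floats(0.0, 0.3, exclude_max=False),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_symmetry_and_bounds(self, n_r, n_a, eps):
        if n_r + n_a == 0:
            return
        p = homozygosity_test(n_r, n_a, eps)
        assert p == homozygosity_test(n_a, n_r, eps)
        assert 0.0 <= p <= 1.0

    @pytest.mark.parametrize("n", [10, 31, 60])
    def test_monotone_in_minor_allele_count(self, n):
        """For fixed n, p_hom is non-increasing as the minor count rises
        from 0 towards n/2: more balanced data reject homozygosity harder."""
        eps = 0.02
        ps = [homozygosity_test(n - k, k, eps) for k in range(n // 2 + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestFlagging:
    def test_strong_het_not_flagged(self):
        calls = flag_genotype_errors(_counts([(50, 45, 0)]), epsilon=0.01, fdr=0.01)
        assert not calls[0].flagged

    def test_monoallelic_low_count_flagged(self):
        calls = flag_genotype_errors(_counts([(8, 0, 0)]), epsilon=0.01, fdr=0.01)
        assert calls[0].flagged and calls[0].p_hom == 1.0

    def test_zero_count_site_flagged(self):
        calls = flag_genotype_errors(_counts([(0, 0, 0)]), epsilon=0.01)
        assert calls[0].flagged

    def test_output_order_matches_input(self):
        counts = _counts([(50, 45, 0), (8, 0, 0), (20, 18, 0)])
        calls = flag_genotype_errors(counts, epsilon=0.01)
        assert [c.site.pos for c in calls] == [c.site.pos for c in counts]
        assert [c.flagged for c in calls] == [False, True, False]


class TestSampleMetrics:
    def test_both_alleles_fraction_direct(self):
        frac = both_alleles_observed_fraction(
            _counts([(10, 5, 0), (8, 0, 0), (0, 7, 0)]), min_depth=1
        )
        assert frac == pytest.approx(1 / 3)

    def test_all_biallelic_gives_one(self):
        assert both_alleles_observed_fraction(_counts([(5, 5, 0), (9, 1, 0)]), 1) == 1.0

    def test_no_qualifying_sites_signaled(self):
        with pytest.raises(NoQualifyingSitesError):
            both_alleles_observed_fraction(_counts([(1, 0, 0)]), min_depth=10)

    def test_concordance_reduces_to_both_alleles_at_one_read(self):
        counts = _counts([(10, 5, 0), (8, 0, 0), (0, 7, 0), (3, 1, 0)])
        assert dna_rna_het_concordance(counts, 1, 1) == both_alleles_observed_fraction(
            counts, 1
        )

    def test_concordance_minor_read_threshold(self):
        frac = dna_rna_het_concordance(
            _counts([(20, 0, 0), (20, 1, 0), (20, 5, 0)]), min_depth=1, min_minor_reads=2
        )
        assert frac == pytest.approx(1 / 3)

    def test_genotype_error_fraction_recovered(self):
        """At high coverage, the fraction of sites with both alleles seen
        approximates 1 - g for injected genotype-error fraction g."""
        g = 0.1
        counts, truth = simulate_site_counts(
            SimConfig(n_sites=3000, coverage_mean=50, genotype_error_fraction=g, seed=9)
        )
        frac = both_alleles_observed_fraction(counts, min_depth=8)
        se = math.sqrt(g * (1 - g) / 3000)
        assert abs(frac - (1 - g)) < 4 * se

    def test_contamination_lowers_concordance(self):
        """A sample whose reads disagree with its nominal genotypes at a
        subset of sites — the signature of contamination or mislabeling —
        shows lower DNA-RNA het concordance than the matched clean sample."""
        clean, _ = simulate_site_counts(
            SimConfig(n_sites=1000, coverage_mean=40, seed=5)
        )
        contaminated, _ = simulate_site_counts(
            SimConfig(
                n_sites=1000, coverage_mean=40, genotype_error_fraction=0.2, seed=5
            )
        )
        c_clean = dna_rna_het_concordance(clean, 8, 2)
        c_mixed = dna_rna_het_concordance(contaminated, 8, 2)
        assert c_mixed < c_clean
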