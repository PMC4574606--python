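# aekit

Data processing and quality control for **allelic expression (AE)** analysis
of RNA-seq data — also known as allele-specific expression or allelic
imbalance analysis.

AE analysis quantifies the relative expression of the two parental
haplotypes of a diploid individual, measured at heterozygous SNPs
(het-SNPs): at each such site, RNA-seq reads carrying the reference (REF)
and alternative (ALT) allele are counted, and imbalance between the two
counts reflects *cis*-regulatory variation, nonsense-mediated decay,
imprinting and other allele-level biology. The measurement is conceptually
simple but error-prone in practice: PCR duplicates, double-counted
overlapping mate pairs, reference mapping bias, and genotyping errors all
mimic or distort allelic imbalance. `aekit` implements the counting and the
QC battery needed to keep those artifacts out of the signal, plus a
simulator that generates alignments with known allelic truth so every stage
can be validated without any external data.

## What it computes

**Units.** At a het-SNP with `n_R` reference and `n_A` alternative reads:

    reference ratio  r = n_R / (n_R + n_A)
    effect size     AE = |0.5 − r|            (0 = balanced, 0.5 = monoallelic)

**Counting** (`allele_counting`). Per-site REF/ALT/other tallies from a
coordinate-sorted, indexed BAM over a het-SNP list, with a filtering
cascade: mapping-quality and base-quality thresholds, exclusion of
secondary/supplementary alignments, duplicate removal (retained read chosen
at random or by base quality — never by mapping score, which favours the
reference allele), and counting each paired-end fragment once when its
mates overlap the site (consistent mate calls merge at the higher base
quality; conflicting calls discard the fragment). Every read at a site is
accounted for in exactly one output column, so counts plus filter
diagnostics always sum to the raw depth.

**Genotype QC** (`genotype_qc`). A homozygous site miscalled heterozygous
appears monoallelic in RNA. The library noise rate ε is estimated from
reads carrying alleles other than REF or ALT:

    ε = Σ other-allele reads / (Σ reads / 2)

excluding sites with >5 % other-allele reads. Each site is then tested
against the null of homozygosity: with `n = n_R + n_A`,

    p_hom = min(1, P(x ≥ n_A | Bin(n, ε)) + P(x ≥ n_R | Bin(n, ε)))

and sites where homozygosity cannot be rejected (Benjamini–Hochberg FDR)
are flagged as putative genotyping errors. Per-sample metrics — the
fraction of het-SNPs with both alleles observed, and DNA–RNA heterozygous
concordance — detect genotyping-platform problems, contamination and
mislabeling.

**AE statistics** (`ae_stats`). Exact two-sided binomial test of each
site's reference count against a null of 0.5 or against the sample-wide
mean reference ratio (the "adjusted null" that absorbs residual reference
mapping bias), BH correction across sites, a minimum effect-size cutoff
(default 0.15) that suppresses depth-driven significance at highly covered
sites, and down-sampling of counts to a fixed total (conventionally 30)
for cross-sample comparability.

**Sample comparison** (`sample_comparison`). Pairwise distance between
samples = (shared sites significant in exactly one) / (shared sites),
embedded with classical (Torgerson) MDS for batch-effect inspection.

**eQTL validation** (`eqtl_validation`). Individuals heterozygous for a
gene's top eQTL SNP should show elevated AE in that gene. Gene-level AE
(median per-site effect size over sites with ≥16 reads) is compared between
eSNP heterozygotes and homozygotes per gene with a Wilcoxon rank-sum test
(BH across genes) — a positive control showing that QC increases
expected-direction calls and suppresses opposite-direction ones.

**Simulator** (`synthetic_data`). Paired-end reads over a synthetic
reference with planted alleles, with generative knobs for sequencing error,
PCR duplicates, mate overlap, genotyping-error sites, reference-bias
thinning of ALT fragments, coverage and overdispersion — emitting an
indexed BAM, a het-site VCF and a ground-truth table. A counts-level
generator draws from the same probability model without materializing reads
for large calibration experiments.

## Worked example

```python
import tempfile
from aekit import (SimConfig, simulate_sample, load_het_sites, count_alleles,
                   CountingOptions, estimate_noise_rate, flag_genotype_errors,
                   analyze_counts)

cfg = SimConfig(n_sites=200, coverage_mean=60, error_rate=0.01,
                duplicate_rate=0.15, mate_overlap_fraction=0.05,
                genotype_error_fraction=0.05, reference_bias=0.9,
                ratio_spread=0.2, seed=7)
with tempfile.TemporaryDirectory() as td:
    sample = simulate_sample(cfg, td)
    sites = load_het_sites(sample.vcf_path, sample="SIM")
    counts = count_alleles(sample.bam_path, sites, CountingOptions())

noise = estimate_noise_rate(counts)
calls = flag_genotype_errors(counts, noise.epsilon, fdr=0.01)
flagged = {c.site.key for c in calls if c.flagged}
kept = [c for c in counts if c.site.key not in flagged]
results = analyze_counts(kept, null_ratio="auto", fdr=0.05,
                         min_effect=0.15, min_depth=30)

print(f"noise rate epsilon = {noise.epsilon:.4f}")
print(f"flagged as putative genotype errors: {len(flagged)}/{len(counts)}")
print(f"adjusted null = {results[0].null_ratio:.4f}")
print(f"significant AE sites: {sum(r.significant for r in results)}/{len(results)}")
```

Output:

```
noise rate epsilon = 0.0121
flagged as putative genotype errors: 14/200
adjusted null = 0.5295
significant AE sites: 33/186
```

The estimated ε (~0.012) reflects the injected 1 % per-base error rate
(other-allele reads arise at rate 2e/3, so E[ε̂] = 4e/3 ≈ 0.013); the 14
flagged sites are dominated by the truly homozygous sites the simulator
planted among the nominal hets; the adjusted null sits above 0.5 because
ALT-carrying fragments were thinned to 90 % retention; and the sites called
significant are those whose overdispersed true ratios clear the joint
q ≤ 0.05 and AE ≥ 0.15 criterion at 60× coverage.

The same pipeline is available from the shell:

```bash
aekit simulate --n-sites 200 --coverage 60 --seed 7 --out-dir sim/
aekit count --bam sim/sample.bam --vcf sim/sample.vcf --sample SIM -o counts.tsv
aekit gtcheck --counts counts.tsv --fdr 0.01 -o gt.tsv
aekit aetest --counts counts.tsv --null auto --min-effect 0.15 -o ae.tsv
```

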