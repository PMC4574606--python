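# Methods

This note documents the models, conventions and numerical choices behind
`aekit`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Site universe

AE is measured at bi-allelic heterozygous SNPs. `variant_io` loads records
from VCF and keeps only single-nucleotide, bi-allelic records; when a
sample is named, only genotypes 0/1, 0|1 or 1|0 qualify. Multi-allelic
records are dropped rather than split, and indels are rejected — indel AE
suffers pervasive alignment artifacts and is out of scope. Phase is
ignored: counting is strictly per-site, and any haplotype-level
aggregation belongs downstream where phasing error can be modeled.

Coordinates: VCF positions are 1-based, BED masks are 0-based half-open;
the conversion happens once, inside `SiteFilterMask.contains` (a site at
1-based position `p` is masked iff `start <= p-1 < end`). Chromosome-name
mismatches between inputs ("chr1" vs "1") raise an error rather than being
silently harmonized: a name mismatch usually signals mixed genome builds.

Blacklists of low-mappability or mapping-biased regions are *consumed*
here, never produced; building them requires mappability tracks or
alignment simulations that are deliberately outside this package.

## Counting semantics

Per site, reads are processed in a fixed cascade, and every read with an
aligned base at the site lands in exactly one output bucket (the
conservation identity `ref + alt + other + lowBQ + lowMQ + dup +
mateConflict + mateMerged = rawDepth` is asserted property-style in the
tests):

1. Secondary and supplementary alignments are excluded outright, and reads
   spanning the site via a deletion or splice gap carry no base and do not
   enter `rawDepth` at all — there is nothing to assign.
2. Mapping-quality threshold (default 20). Together with step 1 this is the
   operational meaning of "uniquely mapping reads only"; most aligners
   assign MAPQ 0–3 to multi-mappers.
3. Duplicate removal (default on). Two detection routes: trust the SAM
   0x400 flag (default — the upstream marker already chose a
   representative), or group fragments by alignment signature (chromosome,
   fragment start, mate start, strand) for unmarked inputs and select one
   representative per group — uniformly at random, or by highest site base
   quality with random tie-breaks. Mapping score is never consulted:
   ALT-carrying reads systematically map slightly worse, so a
   best-mapping-score rule would enrich REF among retained duplicates.
   Selection is seeded and reproducible.
4. Mate-overlap resolution (default on). A fragment whose two mates both
   cover the site is one molecule: consistent base calls are counted once,
   carrying the *higher* of the two base qualities (the better read of the
   same molecule is the better measurement); conflicting calls discard the
   fragment. Because the consensus quality is the maximum, this step runs
   before the base-quality filter.
5. Base-quality threshold (default 10) on the surviving observation, then
   classification as REF, ALT or other (`N` counts as other).

`rawDepth` is defined pre-filtering (all primary reads with an aligned
base), which is what makes the conservation identity checkable; reads in
non-proper pairs are counted normally and surfaced in a diagnostic
`improperPairs` column rather than filtered, since improper pairing is a
library-geometry signal, not evidence against the base call. The output
table mirrors the classic per-site counter schema (contig … improperPairs)
and appends three extra diagnostic columns so the full record round-trips.

## Genotype-error model

The noise rate ε is estimated from reads assigned to neither REF nor ALT:
ε = Σother / (Σtotal / 2), over sites whose other-allele fraction is at
most 5 % (strictly greater is excluded as a site-specific artifact). The
halving reflects that the two "other" bases are two of the roughly
equiprobable error targets, converting the observed other-allele rate into
a per-target rate. Under the generator's error model (per-read error `e`
uniform over the three non-template bases) the estimator's expectation is
4e/3, which the tests verify by recovery.

The homozygosity test treats a nominal het site as hom-REF or hom-ALT plus
noise: `p_hom = min(1, P(x ≥ n_A | Bin(n, ε)) + P(x ≥ n_R | Bin(n, ε)))`.
Tails are inclusive — "n_A or more" is `1 − BinCDF(n_A − 1, n, ε)`, so the
`n_A = 0` tail is exactly 1 and a monoallelic site can never reject
homozygosity. An `inclusive=False` variant (`1 − BinCDF(n_A, n, ε)`) is
exposed for exact replication of pipelines that use the strict convention;
the two differ by one probability mass per tail. The cap at 1 is needed
because both tails overlap when one count is near zero. Sites are flagged
when BH-adjusted significance is *not* attained at the configured FDR
(default 1 %) — including fully monoallelic low-count sites, where
homozygosity cannot be rejected and heterozygosity is unsupported. The
coverage threshold for flagging (≥8 reads by convention) is applied by the
caller after fragment merging, i.e. on counted fragments, since merged
counts are the molecule-level evidence.

Interpretation stays with the user: a flagged site may be a genotyping
error or genuinely monoallelic biology (imprinting, nonsense-mediated
decay); the statistics cannot distinguish them from one sample.

## AE statistics

The imbalance test is the exact binomial test, two-sided by the
minimum-likelihood convention (sum of all outcome probabilities no larger
than the observed one), which reduces to the doubled smaller tail capped at
1 when the null is 0.5. The adjusted null is the unweighted mean of
per-site reference ratios over covered sites — unweighted so a handful of
very deep sites cannot drag the genome-wide estimate; a read-weighted
(pooled) variant is available, and both are exposed because "mean
reference ratio" is ambiguous between the two. Benjamini–Hochberg is used
for FDR control throughout.

The minimum effect-size cutoff (default 0.15) is applied *after* FDR:
significance requires both q ≤ FDR and AE ≥ cutoff. Its purpose is to
break the coupling between read depth and significance — at depth 10 000 an
allelic ratio of 0.53 is overwhelmingly significant but biologically
negligible.

Depth scaling draws the target total (default 30) without replacement from
the pooled REF+ALT reads (hypergeometric); reads are finite physical
observations, and with-replacement sampling would inflate variance at
shallow sites. Sites below the target are skipped and flagged, never
errors. Default analysis thresholds: ≥30 reads for significance testing,
≥8 for QC summaries, ≥16 for gene-level AE — all configurable.

## Sample distances and MDS

The distance between two samples is the number of shared sites significant
in exactly one of them divided by the number of shared sites, where
"shared" means tested (depth and QC passed) in both — otherwise the
denominator is ill-defined. Pairs with no shared sites get NaN and must be
imputed or dropped before embedding. Classical (Torgerson) MDS
double-centers the squared distance matrix and eigendecomposes; negative
eigenvalues — possible because this distance is not guaranteed Euclidean —
are truncated to zero with a warning, the standard practice. The embedding
is verified against R's `cmdscale` in the test suite.

## eQTL validation

Gene-level AE for one individual is the median per-site effect size over
the gene's sites with ≥16 reads. A site inside several overlapping genes
contributes to each — exclusion would silently discard data. The eSNP
genotype dichotomy is heterozygous vs homozygous, pooling both homozygote
classes. Genes with ≥30 measurements per class (configurable) are tested
with the Mann–Whitney/Wilcoxon rank-sum test — exact null for small
classes, normal approximation with tie correction otherwise, as SciPy
implements — with BH across genes; the direction (het > hom expected,
het < hom anomalous) is recorded with every call. Median AE is taken over
unsigned per-site effect sizes; with mixed phasing the signed ratios are
not commensurable at gene level without haplotype information.

## Synthetic data

The generator plants alleles at known sites on a synthetic random
reference and emits "perfectly aligned" paired-end reads (all-match CIGAR),
an indexed BAM, a het-calling VCF (including the injected homozygous
sites), and a truth table. Knobs and their defaults:

| knob | meaning | default |
|---|---|---|
| `coverage_mean` / `coverage_dispersion` | fragments per site; fixed, or negative binomial with this mean/size | 30 / fixed |
| `ratio`, `ratio_spread`, `site_ratios` | true REF ratio at het sites: constant, uniform on 0.5±spread, or explicit | 0.5 |
| `error_rate` | per-read substitution at the site base, uniform over the 3 non-template bases | 0 |
| `duplicate_rate` | probability a fragment is cloned and 0x400-flagged | 0 |
| `mate_overlap_fraction` | fragments whose mates both cover their site | 0 |
| `genotype_error_fraction` | nominal het sites that are truly homozygous (hom-REF/hom-ALT equally) | 0 |
| `reference_bias` | retention probability of an ALT-carrying fragment | 1 |
| `read_length`, `fragment_length_mean/sd` | read/fragment geometry | 50, 300±30 |

Defaults are chosen to be neutral (no artifacts) so each experiment
switches on exactly the error sources it studies; 30× site coverage and
50 bp paired reads are typical of the bulk RNA-seq settings this tool
targets. Reference bias is modeled as post-hoc thinning of ALT fragments
rather than by simulating an aligner: the statistics only see the
consequence (REF excess), and thinning reproduces it with a closed-form
expectation — pooled REF fraction 1/(1+b) at true ratio 0.5 — used in the
recovery tests. Sequencing error is applied at the site base only (the
rest of each read matches the reference exactly); this preserves every
quantity the pipeline measures while keeping reads trivially alignable.
Overdispersion is a symmetric uniform spread of true ratios around 0.5 —
any symmetric family suffices for calibration experiments, and one
parameter keeps it interpretable. PCR clones copy their template's bases
(including its error, as a real PCR duplicate would); identical config and
seed give byte-identical outputs, and a cohort shares one reference genome
via `genome_seed`.

What the generator does **not** emulate: transcript structure and
splicing, expression-level variation across genes, position-dependent
quality, aligner behavior (soft-clipping, multi-mapping), indels, and
haplotype-correlated sites within genes (other than through the shared
true ratio). Passing tests therefore demonstrate the correctness of the
counting and statistical machinery under the stated generative model — not
robustness to alignment artifacts in real data, which is exactly why the
blacklist and bias-adjusted-null mechanisms exist for real inputs.

The counts-level generator (`simulate_site_counts`) draws (REF, ALT,
other) counts from the identical probability model without read geometry;
duplicates and mate overlap do not exist at that level. It is used for
experiments needing tens of thousands of sites.

## Experiment designs and numerical choices

* **Binomial exactness** is checked against direct probability-mass
  summation in log-factorial arithmetic to 1e-12 across the n ≤ 200 grid.
* **Calibration** of the AE test is measured on 10 000 null-true sites at
  deep coverage (negative binomial mean 2000, size 10). Depth matters
  here: an exact discrete test is conservative, with attained size
  undershooting α by up to the p-value jump at the rejection cutoff
  (~0.015 at 100×, <0.003 at 2000×), so a calibration readout is
  informative only where that quantization is well below sampling noise.
  The exact attained sizes under this design are 0.0097, 0.0487 and
  0.0976 at α = 0.01, 0.05, 0.1.
* **Genotype-error recovery** runs at 40× with e = 0.015 and 5 % injected
  homozygous sites; the sensitivity floor asserted is the exact
  enumeration of the flagging probability at a fixed α = FDR level, a
  lower bound on BH flagging since BH rejects no more easily.
* **Two-lab clustering** plants strong (0.30) effects detectable at both
  60× and 300×, and weak (0.06) effects detectable only at 300× and below
  the 0.15 effect cutoff — so q-only significance separates the labs on
  MDS axis 1 and the cutoff removes most of the separation (silhouette by
  lab drops from ~0.8–0.9 to ~0.25).
* **QC benefit at eGenes** uses a 36-individual read-level cohort, 30
  genes × 4 sites at 30×, het effect 0.15, with 15 % duplicates, 8 %
  genotype errors, ALT retention 0.85 and 1 % errors injected; ≥12
  measurements per class are required — the same comparison as at full
  cohort scale, at sizes that keep the whole battery around a minute.

Ties in duplicate selection are broken by seeded RNG; all simulation seeds
derive from a single user seed via `numpy.random.SeedSequence`. Degenerate
inputs are signaled explicitly: QC metrics with no qualifying sites raise
rather than return NaN, zero-coverage sites get p_hom = 1 and are flagged,
and an all-zero distance matrix embeds at the origin.

## Limitations

Beta-binomial/overdispersion inference, haplotype-aggregated gene-level
testing, WASP-style read filtering, personalized-genome alignment and eQTL
mapping are out of scope; the package flags and filters, it does not model
biological overdispersion. The binomial p-values on real data remain
anti-conservative to an unknown degree even after QC — the adjusted null
absorbs mean bias, not site-specific bias — so downstream analyses should
treat significance calls as enrichment rankings rather than calibrated
error rates unless validated per data set.
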