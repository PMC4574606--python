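"""Gene-level AE comparison between eQTL heterozygotes and homozygotes.

Individuals heterozygous for a gene's top eQTL SNP (eSNP) carry one
high- and one low-expressing regulatory haplotype and are therefore
expected to show elevated allelic expression within the gene (eGene),
whereas eSNP homozygotes should be balanced. Comparing gene-level AE
between the two genotype classes is a positive control for an AE pipeline:
QC measures that remove artifactual imbalance should increase the number
of genes significant in the expected direction (het > hom) and decrease
the opposite calls.

Gene-level AE for one individual is the median per-site effect size
(|0.5 - reference ratio|) over the gene's het-SNPs with at least 16 reads.
Classes are compared per gene with a Wilcoxon rank-sum test, BH-corrected
across genes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ae_stats import AEResult

__all__ = [
    "GeneAEMeasure",
    "read_gene_bed",
    "gene_level_ae",
    "attach_esnp_genotypes",
    "compare_het_vs_hom",
    "imbalance_proportion_by_class",
]

GENE_COLUMNS = ("gene_id", "chrom", "start", "end")  # start/end 0-based half-open


@dataclass(frozen=True)
class GeneAEMeasure:
    """Median AE of one gene in one individual.

    ``esnp_genotype`` is "heterozygous" or "homozygous" for the gene's top
    eSNP, or None before annotation.
    """

    gene_id: str
    individual_id: str
    median_ae: float
    n_sites: int
    esnp_genotype: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.median_ae <= 0.5:
            raise ValueError("median AE must be in [0, 0.5]")
        if self.n_sites < 1:
            raise ValueError("a gene measure requires at least one site")


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read gene intervals from BED4 (chrom, start, end, gene_id)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {ln}: expected >= 4 BED columns")
            rows.append(
                {
                    "gene_id": parts[3],
                    "chrom": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                }
            )
    return pd.DataFrame(rows, columns=list(GENE_COLUMNS))


def gene_level_ae(
    results_by_individual: Mapping[str, Sequence[AEResult]],
    genes: pd.DataFrame,
    min_depth: int = 16,
) -> list[GeneAEMeasure]:
    """Median per-gene AE effect size per individual.

    Each site with total_count >= min_depth is intersected against the gene
    intervals (0-based half-open); a site inside several overlapping genes
    contributes to each of them. Genes with no qualifying site in an
    individual are omitted for that individual.
    """
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    gene_rows = list(genes[list(GENE_COLUMNS)].itertuples(index=False))
    measures: list[GeneAEMeasure] = []
    for indiv, results in results_by_individual.items():
        qualifying = [r for r in results if r.total_count >= min_depth]
        for gene_id, chrom, start, end in gene_rows:
            effects = [
                r.effect_size
                for r in qualifying
                if r.site.chrom == chrom and start <= r.site.pos - 1 < end
            ]
            if effects:
                measures.append(
                    GeneAEMeasure(
                        gene_id=str(gene_id),
                        individual_id=str(indiv),
                        median_ae=float(np.median(effects)),
                        n_sites=len(effects),
                    )
                )
    return measures


def attach_esnp_genotypes(
    measures: Sequence[GeneAEMeasure], esnp_table: pd.DataFrame
) -> list[GeneAEMeasure]:
    """Annotate measures with eSNP genotype class from a
    (individual, gene, genotype) table.

    ``genotype`` must be "heterozygous" or "homozygous"; both homozygote
    genotypes of the eSNP pool into the homozygous class. Measures without
    a table entry are dropped (no genotype, no class comparison).
    """
    lookup = {
        (str(row.individual), str(row.gene)): str(row.genotype)
        for row in esnp_table.itertuples(index=False)
    }
    out = []
    for m in measures:
        gt = lookup.get((m.individual_id, m.gene_id))
        if gt is None:
            continue
        if gt not in ("heterozygous", "homozygous"):
            raise ValueError(f"unknown genotype class {gt!r}")
        out.append(replace(m, esnp_genotype=gt))
    return out


def compare_het_vs_hom(
    measures: Sequence[GeneAEMeasure],
    min_per_class: int = 30,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum comparison of AE between genotype classes.

    Only genes with at least ``min_per_class`` AE measurements in each
    class are tested (exact null distribution for small classes, normal
    approximation with tie correction otherwise, as implemented by the
    Mann-Whitney U test). BH correction runs across tested genes. The
    ``direction`` column records "het_gt_hom" (expected, true positive
    under the eQTL model) or "het_lt_hom" (opposite, false positive).
    """
    rows = []
    by_gene: dict[str, dict[str, list[float]]] = {}
    for m in measures:
        if m.esnp_genotype is None:
            raise ValueError("measures must carry esnp_genotype labels")
        by_gene.setdefault(m.gene_id, {"heterozygous": [], "homozygous": []})[
            m.esnp_genotype
        ].append(m.median_ae)
    for gene_id in sorted(by_gene):
        het = by_gene[gene_id]["heterozygous"]
        hom = by_gene[gene_id]["homozygous"]
        if len(het) < min_per_class or len(hom) < min_per_class:
            continue
        if np.ptp(het + hom) == 0:  # all values identical: no test
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(het, hom, alternative="two-sided").pvalue)
        rows.append(
            {
                "gene_id": gene_id,
                "n_het": len(het),
                "n_hom": len(hom),
                "median_het": float(np.median(het)),
                "median_hom": float(np.median(hom)),
                "direction": "het_gt_hom"
                if np.median(het) > np.median(hom)
                else "het_lt_hom",
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "n_het",
            "n_hom",
            "median_het",
            "median_hom",
            "direction",
            "p_value",
        ],
    )
    if len(df):
        reject, q, _, _ = multipletests(df["p_value"], alpha=fdr, method="fdr_bh")
        df["q_value"] = q
        df["significant"] = reject
    else:
        df["q_value"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def imbalance_proportion_by_class(
    measures: Sequence[GeneAEMeasure], threshold: float = 0.25
) -> pd.DataFrame:
    """Per gene, the fraction of individuals in each genotype class with
    median AE above ``threshold``."""
    rows: dict[str, dict[str, list[float]]] = {}
    for m in measures:
        if m.esnp_genotype is None:
            raise ValueError("measures must carry esnp_genotype labels")
        rows.setdefault(m.gene_id, {"heterozygous": [], "homozygous": []})[
            m.esnp_genotype
        ].append(m.median_ae)
    out = []
    for gene_id in sorted(rows):
        rec: dict[str, object] = {"gene_id": gene_id}
        for cls in ("heterozygous", "homozygous"):
            vals = rows[gene_id][cls]
            rec[f"n_{cls}"] = len(vals)
            rec[f"prop_imbalanced_{cls}"] = (
                float(np.mean([v > threshold for v in vals])) if vals else float("nan")
            )
        out.append(rec)
    return pd.DataFrame(out)
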