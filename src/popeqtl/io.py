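"""Readers and writers for the plain-text scan inputs and outputs.

Formats
-------
Genotype TSV: one row per SNP with columns
``snp_id, chrom, pos, allele_minor, allele_major`` followed by one 0/1/2/NA
minor-allele count per sample. Expression TSV: one row per gene with columns
``gene_id, chrom, start, end`` followed by one log2 value per sample.
Population TSV: ``sample_id, population`` with population in {0, 1}.

Coordinates are 1-based inclusive internally; BED input (0-based, half-open)
is converted on read. VCF input is supported through cyvcf2 when installed,
with the minor allele defined on the pooled two-population sample (frequency
ties resolved toward ALT).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model_core import CohortData

__all__ = [
    "read_genotype_tsv",
    "read_expression_tsv",
    "read_population_tsv",
    "read_bed",
    "read_vcf",
    "read_cohort",
]

_GENO_META = ["snp_id", "chrom", "pos", "allele_minor", "allele_major"]
_EXPR_META = ["gene_id", "chrom", "start", "end"]


def read_genotype_tsv(path):
    """Read a genotype TSV into (SNP x sample DataFrame, SNP coordinate table)."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _GENO_META if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: genotype TSV lacks columns {missing}")
    frame = frame.set_index("snp_id")
    coords = frame[_GENO_META[1:]].copy()
    coords["pos"] = coords["pos"].astype(int)
    genotypes = frame.drop(columns=_GENO_META[1:]).astype(float)
    return genotypes, coords


def read_expression_tsv(path):
    """Read an expression TSV into (gene x sample DataFrame, gene coordinate table)."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _EXPR_META if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: expression TSV lacks columns {missing}")
    frame = frame.set_index("gene_id")
    coords = frame[_EXPR_META[1:]].copy()
    coords[["start", "end"]] = coords[["start", "end"]].astype(int)
    expression = frame.drop(columns=_EXPR_META[1:]).astype(float)
    return expression, coords


def read_population_tsv(path):
    """Read the sample -> population map; returns (sample_ids, population array)."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "population"):
        if col not in frame.columns:
            raise ValueError(f"{path}: population TSV lacks column {col!r}")
    return list(frame["sample_id"].astype(str)), frame["population"].to_numpy(dtype=int)


def read_bed(path):
    """Read gene intervals from BED (0-based half-open) as 1-based inclusive."""
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str},
    )
    frame = frame.set_index("gene_id")
    frame["start"] = frame["start"].astype(int) + 1
    frame["end"] = frame["end"].astype(int)
    return frame[["chrom", "start", "end"]]


def read_vcf(path):
    """Read biallelic SNPs from a VCF into (genotype DataFrame, coordinate table).

    Genotypes become minor-allele counts with the minor allele defined by
    pooled frequency across all samples; when REF and ALT are equally
    frequent the ALT allele is taken as minor. Missing calls become NaN.
    Requires cyvcf2 (``pip install popeqtl[vcf]``).
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - depends on optional extra
        raise ImportError("VCF input requires the cyvcf2 package") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        alt_counts = np.asarray(variant.gt_types, dtype=float)
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        counts = np.select(
            [alt_counts == 0, alt_counts == 1, alt_counts == 3],
            [0.0, 1.0, 2.0],
            default=np.nan,
        )
        called = counts[~np.isnan(counts)]
        if called.size == 0:
            continue
        alt_freq = called.sum() / (2 * called.size)
        if alt_freq <= 0.5:
            minor, major, geno = variant.ALT[0], variant.REF, counts
        else:
            minor, major, geno = variant.REF, variant.ALT[0], 2.0 - counts
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        rows.append(geno)
        meta.append((snp_id, str(variant.CHROM), int(variant.POS), minor, major))
    coords = pd.DataFrame(
        meta, columns=["snp_id", "chrom", "pos", "allele_minor", "allele_major"]
    ).set_index("snp_id")
    genotypes = pd.DataFrame(rows, index=coords.index, columns=samples)
    return genotypes, coords


def read_cohort(genotype_path, expression_path, population_path) -> CohortData:
    """Assemble a :class:`CohortData` from the three TSV inputs.

    Sample columns of both matrices are aligned to the order of the
    population file; every sample listed there must be present in both.
    """
    genotypes, snp_coords = read_genotype_tsv(genotype_path)
    expression, gene_coords = read_expression_tsv(expression_path)
    sample_ids, population = read_population_tsv(population_path)
    for name, frame in (("genotype", genotypes), ("expression", expression)):
        absent = [s for s in sample_ids if s not in frame.columns]
        if absent:
            raise ValueError(f"{name} matrix lacks samples {absent[:5]}")
    return CohortData(
        sample_ids=sample_ids,
        population=population,
        genotypes=genotypes[sample_ids],
        expression=expression[sample_ids],
        snp_coords=snp_coords,
        gene_coords=gene_coords,
    )
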