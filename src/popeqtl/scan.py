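"""Chromosome-wide SNP-gene scan: pairing, testing, classification, selection.

Every SNP is paired with every gene on the same chromosome (trans-genome
pairs are out of scope), each pair is tested by the requested methods, and a
pair is called *local* when the SNP lies within 100 kb of the gene body and
*distant* otherwise. Per gene, the significant SNP with the smallest
association p-value is flagged as the putative eQT locus. Benjamini-Hochberg
adjusted p-values are computed across all tested pairs. Untestable pairs
(monomorphic SNPs, rank-deficient designs) are logged with a reason and kept
out of the results.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import (
    CohortData,
    CTWMFit,
    PopEqtlError,
    ctwm_association_test,
    fit_ctwm,
    fit_oneway,
)
from .model_selection import bh_fdr
from .partition_gs import (
    DEFAULT_GS_THRESHOLD,
    DEFAULT_P_THRESHOLD,
    estimate_bd,
    estimate_gs,
    gs_proportion,
)
from .qt_transform import qt_association_test
from .simulator import simulate_genotypes

logger = logging.getLogger("popeqtl.scan")

__all__ = [
    "LOCAL_WINDOW",
    "ScanRecord",
    "classify_locality",
    "pair_within_chromosome",
    "run_scan",
    "select_best_snp",
    "recode_by_upregulated_allele",
    "records_to_frame",
    "write_results",
    "generate_fixture",
]

LOCAL_WINDOW = 100_000
SCAN_METHODS = ("ig", "qt", "ctwm", "gs")


@dataclass
class ScanRecord:
    """Result of testing one same-chromosome SNP-gene pair."""

    gene_id: str
    snp_id: str
    chromosome: str
    snp_pos: int
    gene_start: int
    gene_end: int
    locality: str
    p_values: dict = field(default_factory=dict)   # keys: ig0, ig1, qt, ctwm, gs, bd
    gs: float = float("nan")
    bd: float = float("nan")
    gs_proportion: float = float("nan")
    significant: bool = False
    best_for_gene: bool = False
    esnp: bool = False
    q_value: float = float("nan")


def classify_locality(snp_pos: int, gene_start: int, gene_end: int,
                      window: int = LOCAL_WINDOW) -> str:
    """'local' when the SNP lies within ``window`` bp of the gene body (inclusive)."""
    return "local" if gene_start - window <= snp_pos <= gene_end + window else "distant"


def pair_within_chromosome(cohort: CohortData, local_only: bool = False,
                           window: int = LOCAL_WINDOW):
    """Yield every same-chromosome (gene_id, snp_id) pair in deterministic order.

    Genes are visited sorted by (chromosome, start, id) and SNPs within a
    chromosome by (position, id). With ``local_only`` the pairing is
    restricted to SNPs inside the local window of each gene.
    """
    genes = cohort.gene_coords.loc[
        cohort.gene_coords.assign(_id=cohort.gene_coords.index)
        .sort_values(["chrom", "start", "_id"]).index
    ]
    snps = cohort.snp_coords.loc[
        cohort.snp_coords.assign(_id=cohort.snp_coords.index)
        .sort_values(["chrom", "pos", "_id"]).index
    ]
    by_chrom = {chrom: sub for chrom, sub in snps.groupby("chrom", sort=False)}
    for gene_id, gene in genes.iterrows():
        sub = by_chrom.get(gene["chrom"])
        if sub is None:
            continue
        for snp_id, snp in sub.iterrows():
            if local_only and classify_locality(
                int(snp["pos"]), int(gene["start"]), int(gene["end"]), window
            ) != "local":
                continue
            yield gene_id, snp_id


def _test_pair(y, g, pop, methods) -> tuple[dict, dict]:
    """Apply the requested per-pair tests; returns (p_values, extras)."""
    p_values: dict = {}
    extras: dict = {}
    fit: CTWMFit | None = None
    if "ctwm" in methods or "gs" in methods:
        fit = fit_ctwm(y, g, pop)
    if "ig" in methods:
        mask0 = pop == 0
        p_values["ig0"] = fit_oneway(y[mask0], g[mask0], population=0).p_value
        p_values["ig1"] = fit_oneway(y[~mask0], g[~mask0], population=1).p_value
    if "qt" in methods:
        p_values["qt"] = qt_association_test(y, g, pop).p_value
    if "ctwm" in methods:
        p_values["ctwm"] = ctwm_association_test(fit).p_value
    if "gs" in methods:
        bd, bd_test = estimate_bd(fit)
        gs, gs_test = estimate_gs(fit)
        extras["bd"] = bd
        extras["gs"] = gs
        p_values["bd"] = bd_test.p_value
        if gs_test is not None:
            p_values["gs"] = gs_test.p_value
    return p_values, extras


def run_scan(
    cohort: CohortData,
    methods=("ctwm", "gs"),
    p_threshold: float = DEFAULT_P_THRESHOLD,
    gs_threshold: float = DEFAULT_GS_THRESHOLD,
    primary: str | None = None,
    local_only: bool = False,
) -> list:
    """Test every same-chromosome SNP-gene pair and annotate the results.

    ``primary`` names the method whose p-value drives the significance flag,
    BH adjustment and best-SNP selection (default: 'ctwm' when requested,
    otherwise the first requested method). Returns the list of testable
    :class:`ScanRecord`; untestable pairs are logged with a reason code.
    """
    unknown = [m for m in methods if m not in SCAN_METHODS]
    if unknown:
        raise ValueError(f"unknown scan methods {unknown}; choose from {SCAN_METHODS}")
    if primary is None:
        primary = "ctwm" if "ctwm" in methods else methods[0]
    primary_key = {"ig": "ig0", "gs": "gs"}.get(primary, primary)

    pop = cohort.population
    expr = cohort.expression
    geno = cohort.genotypes
    records: list = []
    n_untestable = 0
    for gene_id, snp_id in pair_within_chromosome(cohort, local_only=local_only):
        y = expr.loc[gene_id].to_numpy(dtype=float)
        g = geno.loc[snp_id].to_numpy(dtype=float)
        try:
            p_values, extras = _test_pair(y, g, pop, methods)
        except PopEqtlError as err:
            n_untestable += 1
            logger.info("untestable pair %s/%s: %s", gene_id, snp_id, err)
            continue
        gene = cohort.gene_coords.loc[gene_id]
        snp = cohort.snp_coords.loc[snp_id]
        rec = ScanRecord(
            gene_id=str(gene_id),
            snp_id=str(snp_id),
            chromosome=str(snp["chrom"]),
            snp_pos=int(snp["pos"]),
            gene_start=int(gene["start"]),
            gene_end=int(gene["end"]),
            locality=classify_locality(int(snp["pos"]), int(gene["start"]), int(gene["end"])),
            p_values=p_values,
            gs=extras.get("gs", float("nan")),
            bd=extras.get("bd", float("nan")),
        )
        if not np.isnan(rec.gs) or not np.isnan(rec.bd):
            rec.gs_proportion = gs_proportion(rec.gs, rec.bd)
        p_primary = p_values.get(primary_key)
        if primary == "ig":
            rec.significant = (
                p_values.get("ig0", 1.0) < p_threshold
                and p_values.get("ig1", 1.0) < p_threshold
            )
        elif p_primary is not None:
            rec.significant = p_primary < p_threshold
        if "gs" in methods and "gs" in p_values:
            rec.esnp = p_values["gs"] < p_threshold and abs(rec.gs) >= gs_threshold
        records.append(rec)

    logger.info("scan complete: %d pairs tested, %d untestable", len(records), n_untestable)

    # BH adjustment across all tested pairs on the primary p-value
    with_p = [r for r in records if primary_key in r.p_values]
    if with_p:
        q = bh_fdr([r.p_values[primary_key] for r in with_p])
        for r, qv in zip(with_p, q):
            r.q_value = float(qv)

    for gene_id in {r.gene_id for r in records}:
        best = select_best_snp(
            [r for r in records if r.gene_id == gene_id], primary_key=primary_key
        )
        if best is not None:
            best.best_for_gene = True
    return records


def select_best_snp(records, primary_key: str = "ctwm"):
    """Pick the significant record with the smallest primary p-value for a gene.

    Ties are broken toward the smaller genomic position, then the
    lexicographically smaller SNP id. Returns None when nothing is significant.
    """
    candidates = [r for r in records if r.significant and primary_key in r.p_values]
    if not candidates:
        return None
    return min(candidates, key=lambda r: (r.p_values[primary_key], r.snp_pos, r.snp_id))


def recode_by_upregulated_allele(genotypes, fit: CTWMFit) -> np.ndarray:
    """Orient minor-allele counts so 2 = homozygous for the upregulated allele.

    The upregulated allele is the minor allele when the fitted homozygote
    contrast (tau_2, or 2 * tau_1 when the minor homozygote class is absent)
    is positive, otherwise the major allele (the coding is flipped to
    2 - count). Heterozygotes always stay 1; missing stays missing. A zero
    contrast is ambiguous: a warning is emitted and the minor allele is used.
    """
    g = np.asarray(genotypes, dtype=float)
    if 2 in fit.tau_classes or fit.baseline == 2:
        contrast = fit.tau(2) - fit.tau(0)
    else:
        contrast = 2.0 * (fit.tau(1) - fit.tau(0))
    if contrast == 0.0:
        warnings.warn("zero homozygote contrast: upregulated allele ambiguous, "
                      "keeping minor-allele orientation", stacklevel=2)
        return g.copy()
    return g.copy() if contrast > 0 else 2.0 - g


def records_to_frame(records) -> pd.DataFrame:
    """Flatten scan records into the output table."""
    rows = []
    for r in records:
        rows.append({
            "gene_id": r.gene_id,
            "snp_id": r.snp_id,
            "chrom": r.chromosome,
            "snp_pos": r.snp_pos,
            "gene_start": r.gene_start,
            "gene_end": r.gene_end,
            "locality": r.locality,
            "p_ig0": r.p_values.get("ig0", float("nan")),
            "p_ig1": r.p_values.get("ig1", float("nan")),
            "p_qt": r.p_values.get("qt", float("nan")),
            "p_ctwm": r.p_values.get("ctwm", float("nan")),
            "p_gs": r.p_values.get("gs", float("nan")),
            "p_bd": r.p_values.get("bd", float("nan")),
            "gs": r.gs,
            "bd": r.bd,
            "gs_proportion": r.gs_proportion,
            "q_value": r.q_value,
            "significant": r.significant,
            "best_for_gene": r.best_for_gene,
            "esnp_flag": r.esnp,
        })
    return pd.DataFrame(rows)


def write_results(records, path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

DEFAULT_FIXTURE_CONFIG = {
    "n0": 60,
    "n1": 90,
    "chrom": "chr1",
    "sigma": 1.0,
    "null_genes": 0,
    "null_snps": 0,
    "null_maf": 0.3,
    "planted": [],  # dicts with p0, d, D, E, locality ('local'/'distant')
}

_GENE_SPACING = 2_000_000
_GENE_LENGTH = 50_000


def generate_fixture(config: dict | None, seed: int, out_dir):
    """Write a synthetic cohort with planted eQTL to TSV files.

    Each ``planted`` entry creates one gene/SNP pair simulated under the
    two-population model at its (p0, d, D, E); ``locality`` places the SNP
    inside the gene ('local') or 500 kb downstream ('distant'). Null genes
    are pure noise and null SNPs are unlinked Hardy-Weinberg draws, so every
    extra pairing is a true negative. A ``manifest.json`` records the ground
    truth. Identical (config, seed) produce identical files.
    """
    cfg = dict(DEFAULT_FIXTURE_CONFIG)
    cfg.update(config or {})
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n0, n1 = int(cfg["n0"]), int(cfg["n1"])
    n = n0 + n1
    samples = [f"s{k:03d}" for k in range(n)]
    population = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    chrom = str(cfg["chrom"])
    sigma = float(cfg["sigma"])

    gene_rows, snp_rows, truth = [], [], []
    expr_data, geno_data = {}, {}
    slot = 0

    for k, spec_entry in enumerate(cfg["planted"]):
        entry = dict(spec_entry)
        gene_id = entry.get("gene_id", f"gene_planted_{k}")
        snp_id = entry.get("snp_id", f"snp_planted_{k}")
        start = 1_000_000 + slot * _GENE_SPACING
        end = start + _GENE_LENGTH
        locality = entry.get("locality", "local")
        pos = start + 10_000 if locality == "local" else end + 500_000
        slot += 1
        p0, d = float(entry["p0"]), float(entry.get("d", 0.0))
        D, E = float(entry.get("D", 0.0)), float(entry.get("E", 0.0))
        g = np.concatenate([
            simulate_genotypes(p0, n0, rng),
            simulate_genotypes(p0 + d, n1, rng),
        ])
        y = np.where(population == 0, D, 0.0) + g * E + sigma * rng.standard_normal(n)
        gene_rows.append((gene_id, chrom, start, end))
        snp_rows.append((snp_id, chrom, pos, "A", "G"))
        expr_data[gene_id] = y
        geno_data[snp_id] = g.astype(float)
        truth.append({
            "gene_id": gene_id, "snp_id": snp_id, "p0": p0, "d": d, "D": D, "E": E,
            "locality": classify_locality(pos, start, end),
        })

    for k in range(int(cfg["null_genes"])):
        gene_id = f"gene_null_{k}"
        start = 1_000_000 + slot * _GENE_SPACING
        slot += 1
        gene_rows.append((gene_id, chrom, start, start + _GENE_LENGTH))
        expr_data[gene_id] = rng.standard_normal(n)
    for k in range(int(cfg["null_snps"])):
        snp_id = f"snp_null_{k}"
        pos = 500_000 + k * 137_000
        snp_rows.append((snp_id, chrom, pos, "A", "G"))
        geno_data[snp_id] = simulate_genotypes(float(cfg["null_maf"]), n, rng).astype(float)

    gene_coords = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end"])
    snp_coords = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos",
                                                 "allele_minor", "allele_major"])
    expression = pd.DataFrame(
        {s: [expr_data[gid][i] for gid in gene_coords["gene_id"]]
         for i, s in enumerate(samples)},
        index=gene_coords["gene_id"],
    )
    genotypes = pd.DataFrame(
        {s: [geno_data[sid][i] for sid in snp_coords["snp_id"]]
         for i, s in enumerate(samples)},
        index=snp_coords["snp_id"],
    )

    paths = {
        "genotypes": out_dir / "genotypes.tsv",
        "expression": out_dir / "expression.tsv",
        "population": out_dir / "population.tsv",
        "manifest": out_dir / "manifest.json",
    }
    pd.concat([snp_coords.set_index("snp_id"), genotypes], axis=1).to_csv(
        paths["genotypes"], sep="\t", index_label="snp_id", na_rep="NA")
    pd.concat([gene_coords.set_index("gene_id"), expression], axis=1).to_csv(
        paths["expression"], sep="\t", index_label="gene_id", float_format="%.6f")
    pd.DataFrame({"sample_id": samples, "population": population}).to_csv(
        paths["population"], sep="\t", index=False)
    manifest = {"seed": int(seed), "config": {k: v for k, v in cfg.items()},
                "planted": truth}
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return paths
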