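"""Cell-mean tabulation and linear-model machinery for two-population eQTL tests.

A biallelic SNP partitions each of two ethnic populations (labelled 0 and 1)
into at most three genotype classes j = 0, 1, 2, the number of minor alleles
carried. Log2 expression of one gene is modelled per population/genotype cell.
Two models are provided:

* the independent-group (IG) one-way ANOVA ``y_ijk = mu_i0 + tau_ij + e_ijk``
  fitted separately within each population, and
* the constrained two-way model (CTWM) ``y_ijk = mu_i0 + tau_j + e_ijk`` in
  which the genotype offsets ``tau_j`` are shared across populations while the
  expression baselines ``mu_i0`` remain population specific (no
  population-by-genotype interaction).

Arbitrary linear hypotheses ``B beta = 0`` on the CTWM coefficients are tested
with the partial F-statistic

    F = (B b)' [B (X'X)^- B']^{-1} (B b) / q / (SSE / v),

where ``q = rank(B)`` and ``v`` is the residual degrees of freedom; the same
machinery drives the association, baseline-difference and genetic-score tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPE_CLASSES = (0, 1, 2)

__all__ = [
    "GENOTYPE_CLASSES",
    "PopEqtlError",
    "NoDataError",
    "SinglePopulationError",
    "NoCommonGenotypeError",
    "NotTestableError",
    "NotIdentifiableError",
    "SaturatedModelError",
    "UntestableContrastError",
    "CohortData",
    "CellMeans",
    "OneWayFit",
    "CTWMFit",
    "TestResult",
    "IGDecision",
    "tabulate_cells",
    "common_genotype",
    "fit_oneway",
    "ig_common_eqtl",
    "fit_ctwm",
    "partial_f_test",
    "ctwm_association_test",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PopEqtlError(Exception):
    """Base class for statistical / data errors raised by this package."""


class NoDataError(PopEqtlError):
    """No usable observations remain (e.g. every genotype call is missing)."""


class SinglePopulationError(PopEqtlError):
    """An operation requiring both populations saw samples from only one."""


class NoCommonGenotypeError(PopEqtlError):
    """No genotype class is observed in both populations."""


class NotTestableError(PopEqtlError):
    """The requested hypothesis has no testable parameters (e.g. monomorphic SNP)."""


class NotIdentifiableError(PopEqtlError):
    """The design matrix is rank deficient; the model parameters are not estimable."""


class SaturatedModelError(PopEqtlError):
    """The model has zero residual degrees of freedom."""


class UntestableContrastError(PopEqtlError):
    """The hypothesis matrix B yields a singular or empty contrast."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    """Paired genotype/expression data for n samples from two populations.

    Parameters
    ----------
    sample_ids
        Sample identifiers, shared by the genotype and expression columns.
    population
        Per-sample population label in {0, 1}.
    genotypes
        SNP x sample matrix of minor-allele counts (0/1/2, NaN = missing),
        indexed by SNP id with columns equal to ``sample_ids``.
    expression
        Gene x sample matrix of log2 expression values, indexed by gene id.
    snp_coords
        Per-SNP table with columns ``chrom``, ``pos`` (1-based),
        ``allele_minor``, ``allele_major``.
    gene_coords
        Per-gene table with columns ``chrom``, ``start``, ``end``
        (1-based inclusive).
    """

    sample_ids: list
    population: np.ndarray
    genotypes: pd.DataFrame
    expression: pd.DataFrame
    snp_coords: pd.DataFrame
    gene_coords: pd.DataFrame

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=int)
        labels = set(np.unique(self.population))
        if not labels <= {0, 1}:
            raise ValueError(f"population labels must be in {{0,1}}, got {sorted(labels)}")
        if len(labels) != 2:
            raise SinglePopulationError("cohort must contain samples from both populations")
        n = len(self.sample_ids)
        if self.population.shape != (n,):
            raise ValueError("population vector does not match sample_ids")
        for name, frame in (("genotypes", self.genotypes), ("expression", self.expression)):
            if list(frame.columns) != list(self.sample_ids):
                raise ValueError(f"{name} columns must equal sample_ids (same order)")
        gvals = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(gvals) | np.isin(gvals, GENOTYPE_CLASSES)
        if not ok.all():
            raise ValueError("genotype entries must be 0, 1, 2 or missing")
        if (self.snp_coords["pos"].to_numpy() <= 0).any():
            raise ValueError("SNP positions must be positive integers")
        if (self.gene_coords[["start", "end"]].to_numpy() <= 0).any():
            raise ValueError("gene coordinates must be positive integers")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class CellMeans:
    """Counts, means and genotype proportions for the 2 x 3 population/genotype grid.

    ``counts[i, j]`` is n_ij, ``means[i, j]`` the cell mean (NaN when the cell
    is empty) and ``proportions[i, j] = n_ij / n_i`` the within-population
    genotype proportion P_ij.
    """

    counts: np.ndarray
    means: np.ndarray
    proportions: np.ndarray

    @property
    def n_per_population(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def observed_classes(self) -> list:
        """Genotype classes observed in at least one population."""
        return [j for j in GENOTYPE_CLASSES if self.counts[:, j].sum() > 0]


@dataclass(frozen=True)
class TestResult:
    """Outcome of an F-test of a linear hypothesis B beta = 0."""

    statistic: float
    df_num: int
    df_den: int
    p_value: float
    estimate: float | np.ndarray | None = None


@dataclass(frozen=True)
class OneWayFit:
    """One-way ANOVA of expression on genotype within a single population."""

    population: int | None
    mu0_hat: float
    tau_hat: np.ndarray          # length 3; NaN for unobserved classes, 0 at baseline
    sse: float
    df_error: int
    f_stat: float
    p_value: float
    counts: np.ndarray           # length 3 genotype counts
    means: np.ndarray            # length 3 cell means (NaN when empty)
    baseline: int

    def as_test_result(self) -> TestResult:
        k = int((self.counts > 0).sum())
        return TestResult(self.f_stat, k - 1, self.df_error, self.p_value,
                          estimate=self.tau_hat)


@dataclass(frozen=True)
class IGDecision:
    """Common-eQTL decision from two per-population one-way ANOVA fits."""

    common: bool
    p_values: tuple
    rule: str
    alpha: float


@dataclass(frozen=True)
class CTWMFit:
    """Least-squares fit of the constrained two-way model.

    ``beta_hat`` holds the retained coefficients in the order
    (mu_00, mu_10, tau_j for each retained genotype class j != baseline).
    Genotype classes unobserved in both populations are dropped; a class
    observed in only one population keeps its shared tau column (this is the
    borrowing of strength the model is built for).
    """

    beta_hat: np.ndarray
    param_names: tuple
    tau_classes: tuple           # genotype classes with a tau column, in beta order
    baseline: int
    design_rank: int
    sse: float
    df_error: int
    xtx_inverse: np.ndarray
    cells: CellMeans
    n_obs: int

    def tau(self, j: int) -> float:
        """Fitted genotype offset tau_j (0 at the baseline class)."""
        if j == self.baseline:
            return 0.0
        if j in self.tau_classes:
            return float(self.beta_hat[2 + self.tau_classes.index(j)])
        raise KeyError(f"genotype class {j} not retained in the fit")

    def mu(self, i: int) -> float:
        """Fitted baseline mean of population i."""
        return float(self.beta_hat[i])

    def fitted_cell_mean(self, i: int, j: int) -> float:
        return self.mu(i) + self.tau(j)

    def population_fitted_mean(self, i: int) -> float:
        """Model-implied mean of population i at its observed genotype proportions."""
        p = self.cells.proportions[i]
        total = self.mu(i)
        for j in self.tau_classes:
            total += p[j] * self.tau(j)
        return total


# ---------------------------------------------------------------------------
# Input cleaning
# ---------------------------------------------------------------------------

def _clean(y, g, pop=None):
    """Coerce vectors to arrays and drop samples with missing genotype."""
    y = np.asarray(y, dtype=float).ravel()
    g = np.asarray(g, dtype=float).ravel()
    if y.shape != g.shape:
        raise ValueError("expression and genotype vectors must share length")
    keep = ~np.isnan(g)
    if pop is not None:
        pop = np.asarray(pop, dtype=int).ravel()
        if pop.shape != y.shape:
            raise ValueError("population vector must share length with y and g")
    if not keep.any():
        raise NoDataError("all genotype calls are missing")
    y = y[keep]
    gi = g[keep].astype(int)
    if not np.isin(gi, GENOTYPE_CLASSES).all():
        raise ValueError("genotype entries must be 0, 1, 2 or missing")
    if pop is None:
        return y, gi, None
    pop = pop[keep]
    if not np.isin(pop, (0, 1)).all():
        raise ValueError("population labels must be 0 or 1")
    return y, gi, pop


# ---------------------------------------------------------------------------
# Cell means and the common genotype
# ---------------------------------------------------------------------------

def tabulate_cells(y, g, pop) -> CellMeans:
    """Tabulate counts, cell means and genotype proportions per population.

    Samples with a missing genotype call are excluded from every count
    (listwise deletion per SNP). Raises :class:`NoDataError` when nothing
    remains and :class:`SinglePopulationError` when a population has no
    samples after exclusion.
    """
    y, gi, pop = _clean(y, g, pop)
    counts = np.bincount(pop * 3 + gi, minlength=6).reshape(2, 3).astype(float)
    n_i = counts.sum(axis=1)
    if (n_i == 0).any():
        raise SinglePopulationError("one population has no genotyped samples")
    sums = np.bincount(pop * 3 + gi, weights=y, minlength=6).reshape(2, 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
        props = counts / n_i[:, None]
    return CellMeans(counts=counts.astype(int), means=means, proportions=props)


def common_genotype(cells: CellMeans) -> int:
    """Most frequent shared genotype class c = argmax_j prod_i P_ij.

    Ties are broken toward the smallest class index. Raises
    :class:`NoCommonGenotypeError` when no class is observed in both
    populations.
    """
    shared = (cells.counts[0] > 0) & (cells.counts[1] > 0)
    if not shared.any():
        raise NoCommonGenotypeError("no genotype class observed in both populations")
    products = cells.proportions[0] * cells.proportions[1]
    products = np.where(shared, products, -np.inf)
    return int(np.argmax(products))


# ---------------------------------------------------------------------------
# IG method: per-population one-way ANOVA
# ---------------------------------------------------------------------------

def fit_oneway(y, g, population: int | None = None) -> OneWayFit:
    """Classic unbalanced one-way ANOVA of expression on genotype class.

    The baseline class is the smallest observed genotype; ``mu0_hat`` is its
    mean and ``tau_hat[j]`` the offset of class j from it. The F-statistic
    tests H0: all tau_j = 0 on (k - 1, n - k) degrees of freedom.
    """
    y, gi, _ = _clean(y, g)
    counts = np.bincount(gi, minlength=3).astype(float)
    classes = [j for j in GENOTYPE_CLASSES if counts[j] > 0]
    k = len(classes)
    if k < 2:
        raise NotTestableError("fewer than two genotype classes observed")
    n = y.size
    df_error = n - k
    if df_error < 1:
        raise SaturatedModelError("one-way model has zero residual degrees of freedom")
    sums = np.bincount(gi, weights=y, minlength=3)
    means = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    grand = y.mean()
    ssb = float(np.sum(counts[classes] * (means[classes] - grand) ** 2))
    sse = float(np.sum((y - means[gi]) ** 2))
    if ssb <= 0.0:
        f_stat, p_value = 0.0, 1.0
    else:
        f_stat = (ssb / (k - 1)) / (sse / df_error)
        p_value = float(stats.f.sf(f_stat, k - 1, df_error))
    baseline = classes[0]
    tau = np.where(counts > 0, means - means[baseline], np.nan)
    return OneWayFit(
        population=population,
        mu0_hat=float(means[baseline]),
        tau_hat=tau,
        sse=sse,
        df_error=df_error,
        f_stat=float(f_stat),
        p_value=p_value,
        counts=counts.astype(int),
        means=means,
        baseline=baseline,
    )


def ig_common_eqtl(
    fit0: OneWayFit,
    fit1: OneWayFit,
    alpha: float = 0.05,
    rule: str = "union-null",
) -> IGDecision:
    """Combine two per-population ANOVA fits into a common-eQTL decision.

    ``rule="union-null"`` (the conventional choice) declares a common eQTL
    only when both per-population tests reject; ``rule="intersection-null"``
    declares a signal when either rejects.
    """
    p0, p1 = fit0.p_value, fit1.p_value
    if rule == "union-null":
        common = (p0 < alpha) and (p1 < alpha)
    elif rule == "intersection-null":
        common = (p0 < alpha) or (p1 < alpha)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return IGDecision(common=common, p_values=(p0, p1), rule=rule, alpha=alpha)


# ---------------------------------------------------------------------------
# CTWM fit
# ---------------------------------------------------------------------------

def fit_ctwm(y, g, pop, baseline: int = 0) -> CTWMFit:
    """Least-squares fit of the constrained two-way model.

    The design has one column per population baseline (indicator of
    population membership) plus one shared genotype-offset column per
    non-baseline genotype class observed in at least one population. Fitted
    values, SSE and every estimable contrast are invariant to the ``baseline``
    relabelling.
    """
    if baseline not in GENOTYPE_CLASSES:
        raise ValueError("baseline must be 0, 1 or 2")
    y, gi, pop = _clean(y, g, pop)
    cells = tabulate_cells(y, gi, pop)  # also enforces both populations present
    tau_classes = tuple(j for j in cells.observed_classes() if j != baseline)

    n = y.size
    p = 2 + len(tau_classes)
    X = np.zeros((n, p))
    X[:, 0] = pop == 0
    X[:, 1] = pop == 1
    for idx, j in enumerate(tau_classes):
        X[:, 2 + idx] = gi == j

    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < p:
        raise NotIdentifiableError("rank-deficient design: model not identifiable")
    df_error = n - p
    if df_error < 1:
        raise SaturatedModelError("constrained two-way model has zero residual df")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    sse = float(max(resid @ resid, 0.0))
    names = ("mu00", "mu10") + tuple(f"tau{j}" for j in tau_classes)
    return CTWMFit(
        beta_hat=beta,
        param_names=names,
        tau_classes=tau_classes,
        baseline=baseline,
        design_rank=p,
        sse=sse,
        df_error=df_error,
        xtx_inverse=xtx_inv,
        cells=cells,
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# Partial F-tests
# ---------------------------------------------------------------------------

def partial_f_test(fit: CTWMFit, B) -> TestResult:
    """Partial F-test of the linear hypothesis B beta = 0 on a CTWM fit.

    ``B`` is a q x p hypothesis matrix (or a length-p vector for q = 1) whose
    columns match ``fit.param_names``. The statistic is the general
    linear-hypothesis quadratic form divided by q = rank(B) and the residual
    mean square SSE / v; p-values come from the exact F(q, v) upper tail.
    """
    B = np.atleast_2d(np.asarray(B, dtype=float))
    p = fit.beta_hat.size
    if B.shape[1] != p:
        raise ValueError(f"hypothesis matrix has {B.shape[1]} columns, fit has {p} parameters")
    q = int(np.linalg.matrix_rank(B))
    if q < 1:
        raise UntestableContrastError("hypothesis matrix is zero")
    if q < B.shape[0]:
        raise ValueError("hypothesis matrix rows must be linearly independent")
    if fit.df_error < 1:
        raise SaturatedModelError("no residual degrees of freedom for the partial F-test")

    bb = B @ fit.beta_hat
    middle = B @ fit.xtx_inverse @ B.T
    if np.linalg.matrix_rank(middle) < q:
        raise UntestableContrastError("B (X'X)^- B' is singular")
    numerator = float(bb @ np.linalg.solve(middle, bb))
    numerator = max(numerator, 0.0)
    s2 = fit.sse / fit.df_error
    estimate = float(bb[0]) if B.shape[0] == 1 else bb
    if numerator == 0.0:
        return TestResult(0.0, q, fit.df_error, 1.0, estimate=estimate)
    if s2 == 0.0:
        # noise-free data with a nonzero contrast: report an infinite statistic
        return TestResult(float("inf"), q, fit.df_error, 0.0, estimate=estimate)
    f_stat = numerator / q / s2
    p_value = float(stats.f.sf(f_stat, q, fit.df_error))
    return TestResult(float(f_stat), q, fit.df_error, p_value, estimate=estimate)


def ctwm_association_test(fit: CTWMFit) -> TestResult:
    """Test H0: every shared genotype offset tau_j = 0 (SNP-expression association)."""
    n_tau = len(fit.tau_classes)
    if n_tau == 0:
        raise NotTestableError("no genotype offsets retained (monomorphic SNP)")
    B = np.zeros((n_tau, fit.beta_hat.size))
    for r in range(n_tau):
        B[r, 2 + r] = 1.0
    return partial_f_test(fit, B)
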