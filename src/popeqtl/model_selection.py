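"""Full/reduced-model F-tests that probe the constrained two-way model's assumptions.

Three nested comparisons justify (or falsify) the modelling choices for a
given SNP-gene pair:

* ``interaction_test`` — saturated cell-means model (free population-by-
  genotype interaction) against the constrained model with shared genotype
  offsets;
* ``baseline_homogeneity_test`` — population-specific baselines against a
  single common baseline;
* ``additivity_test`` — free co-dominant genotype offsets against the
  additive constraint tau_2 = 2 tau_1 (a single slope on minor-allele count).

``interaction_model_association_test`` is the two-way-ANOVA-with-interaction
comparator used in simulations: it tests all genotype-related terms (main
effects plus interactions) jointly. ``bh_fdr`` is the Benjamini-Hochberg
step-up adjustment used at genome scale.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model_core import (
    NotIdentifiableError,
    NotTestableError,
    SaturatedModelError,
    TestResult,
    _clean,
    fit_ctwm,
)

__all__ = [
    "interaction_test",
    "interaction_model_association_test",
    "baseline_homogeneity_test",
    "additivity_test",
    "bh_fdr",
]


def _groups_sse(y, labels):
    """Within-group SSE and residual df for a model with one mean per label."""
    uniq, inv = np.unique(labels, return_inverse=True)
    counts = np.bincount(inv).astype(float)
    means = np.bincount(inv, weights=y) / counts
    sse = float(np.sum((y - means[inv]) ** 2))
    return sse, y.size - uniq.size, uniq.size


def _design_sse(y, X):
    """SSE and residual df of a least-squares fit on an explicit design."""
    xtx = X.T @ X
    rank = int(np.linalg.matrix_rank(xtx))
    if rank < X.shape[1]:
        raise NotIdentifiableError("reduced design is rank deficient")
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    return float(max(resid @ resid, 0.0)), y.size - rank


def _nested_f(sse_full, df_full, sse_reduced, df_reduced, estimate=None) -> TestResult:
    q = df_reduced - df_full
    if q < 1:
        raise NotTestableError("full and reduced models have the same dimension")
    if df_full < 1:
        raise SaturatedModelError("full model has zero residual degrees of freedom")
    numerator = max(sse_reduced - sse_full, 0.0) / q
    if numerator == 0.0:
        return TestResult(0.0, q, df_full, 1.0, estimate=estimate)
    if sse_full == 0.0:
        return TestResult(float("inf"), q, df_full, 0.0, estimate=estimate)
    f_stat = numerator / (sse_full / df_full)
    return TestResult(float(f_stat), q, df_full, float(stats.f.sf(f_stat, q, df_full)),
                      estimate=estimate)


def interaction_test(y, g, pop) -> TestResult:
    """Test the population-by-genotype interaction against the constrained model.

    Full model: one free mean per observed population/genotype cell.
    Reduced model: the constrained two-way model (shared genotype offsets).
    """
    y, gi, pop = _clean(y, g, pop)
    reduced = fit_ctwm(y, gi, pop)
    sse_full, df_full, _ = _groups_sse(y, pop * 3 + gi)
    return _nested_f(sse_full, df_full, reduced.sse, reduced.df_error)


def interaction_model_association_test(y, g, pop) -> TestResult:
    """Joint test of all genotype terms in the two-way model with interaction.

    Full model: free cell means per population/genotype cell. Reduced model:
    population means only. With data from a single population this reduces to
    the classic one-way ANOVA F-test.
    """
    y, gi, pop = _clean(y, g, pop)
    sse_full, df_full, _ = _groups_sse(y, pop * 3 + gi)
    sse_red, df_red, _ = _groups_sse(y, pop)
    return _nested_f(sse_full, df_full, sse_red, df_red)


def baseline_homogeneity_test(y, g, pop) -> TestResult:
    """Test population-specific baselines against a single shared baseline.

    Full model: the constrained two-way model. Reduced model: identical
    baselines (mu_00 = mu_10). Equivalent to the 1-df partial F-test of
    BD = 0 on the full fit.
    """
    y, gi, pop = _clean(y, g, pop)
    full = fit_ctwm(y, gi, pop)
    cols = [np.ones(y.size)]
    for j in full.tau_classes:
        cols.append((gi == j).astype(float))
    sse_red, df_red = _design_sse(y, np.column_stack(cols))
    estimate = full.mu(0) - full.mu(1)
    return _nested_f(full.sse, full.df_error, sse_red, df_red, estimate=estimate)


def additivity_test(y, g, pop) -> TestResult:
    """Test the co-dominant model against the additive constraint tau_2 = 2 tau_1.

    Requires all three genotype classes to be observed overall; the reduced
    model regresses on minor-allele count with population-specific baselines.
    """
    y, gi, pop = _clean(y, g, pop)
    full = fit_ctwm(y, gi, pop)
    if len(full.cells.observed_classes()) < 3:
        raise NotTestableError("additivity test needs all three genotype classes")
    X = np.column_stack([
        (pop == 0).astype(float),
        (pop == 1).astype(float),
        gi.astype(float),
    ])
    sse_red, df_red = _design_sse(y, X)
    return _nested_f(full.sse, full.df_error, sse_red, df_red)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
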