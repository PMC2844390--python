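"""Rank-based inverse normal transformation and the pooled-ANOVA comparator.

The QT strategy sidesteps population structure by forcing the expression
values of each gene, within each population, onto a standard normal scale
before pooling: the value of rank r among n maps to the normal quantile at
(r - 0.5) / n, with ties receiving average ranks. A single one-way ANOVA of
the pooled transformed values on genotype then tests the SNP association.

The transformation removes population-level location differences, but it also
shrinks genotype effects whenever the two populations concentrate on opposite
homozygotes, which is exactly the situation combined-population eQTL scans
care about.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .model_core import OneWayFit, PopEqtlError, TestResult, fit_oneway

__all__ = ["NotTransformableError", "quantile_normalize", "qt_pooled_fit", "qt_association_test"]


class NotTransformableError(PopEqtlError):
    """Too few finite values to rank-transform."""


def quantile_normalize(values) -> np.ndarray:
    """Map one population's expression values to standard normal quantiles.

    The value with (average) rank r among n becomes ``Phi^{-1}((r - 0.5)/n)``;
    output order matches input order. With all values tied every entry maps
    to 0. Requires at least two finite values.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or not np.isfinite(values).all():
        raise NotTransformableError("need >= 2 finite values to transform")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / values.size)


def qt_pooled_fit(y, g, pop) -> OneWayFit:
    """Transform each population separately, pool, and fit a one-way ANOVA on genotype.

    Samples with missing genotype are excluded before ranking so the
    transformation sees exactly the analysed samples. The returned fit's
    ``tau_hat`` is on the transformed (normal-quantile) scale.
    """
    y = np.asarray(y, dtype=float).ravel()
    g = np.asarray(g, dtype=float).ravel()
    pop = np.asarray(pop, dtype=int).ravel()
    if not (y.shape == g.shape == pop.shape):
        raise ValueError("y, g and pop must share length")
    keep = ~np.isnan(g)
    y, g, pop = y[keep], g[keep], pop[keep]
    z = np.empty_like(y)
    for i in np.unique(pop):
        mask = pop == i
        z[mask] = quantile_normalize(y[mask])
    return fit_oneway(z, g)


def qt_association_test(y, g, pop) -> TestResult:
    """SNP-association F-test of the QT comparator."""
    return qt_pooled_fit(y, g, pop).as_test_result()
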