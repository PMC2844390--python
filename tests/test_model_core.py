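import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from popeqtl import (
    NoCommonGenotypeError,
    NoDataError,
    NotIdentifiableError,
    NotTestableError,
    SaturatedModelError,
    SinglePopulationError,
    UntestableContrastError,
    CellMeans,
    common_genotype,
    ctwm_association_test,
    fit_ctwm,
    fit_oneway,
    ig_common_eqtl,
    partial_f_test,
    tabulate_cells,
)
from popeqtl.simulator import SimulationScenario, simulate_dataset

from conftest import random_cohort_vectors


class TestTabulateCells:
    def test_counts_means_proportions(self, balanced_toy):
        cells = tabulate_cells(*balanced_toy)
        assert cells.counts.tolist() == [[2, 2, 0], [2, 2, 0]]
        np.testing.assert_allclose(cells.means[:, :2], [[1, 3], [4, 6]])
        assert np.isnan(cells.means[:, 2]).all()
        np.testing.assert_allclose(cells.proportions, [[0.5, 0.5, 0], [0.5, 0.5, 0]])

    def test_single_class_degenerate(self):
        cells = tabulate_cells([1.0, 2, 3], [0, 0, 0], [0, 0, 1])
        assert cells.counts[:, 0].tolist() == [2, 1]
        np.testing.assert_allclose(cells.proportions[:, 0], [1.0, 1.0])

    def test_missing_genotype_excluded_everywhere(self):
        cells = tabulate_cells([1.0, 2, 3, 4], [0, np.nan, 1, 1], [0, 0, 1, 1])
        assert cells.counts.sum() == 3
        assert cells.counts[0].tolist() == [1, 0, 0]

    def test_all_missing_is_no_data(self):
        with pytest.raises(NoDataError):
            tabulate_cells([1.0, 2], [np.nan, np.nan], [0, 1])

    def test_empty_population_signalled(self):
        with pytest.raises(SinglePopulationError):
            tabulate_cells([1.0, 2, 3], [0, 1, np.nan], [0, 0, 1])


class TestCommonGenotype:
    @pytest.mark.parametrize(
        "p0, p1, expected",
        [
            ([0.49, 0.42, 0.09], [0.25, 0.50, 0.25], 1),
            ([0.6, 0.3, 0.1], [0.6, 0.3, 0.1], 0),
            ([0.5, 0.5, 0.0], [0.5, 0.5, 0.0], 0),  # tie -> smallest class
        ],
    )
    def test_argmax_of_proportion_products(self, p0, p1, expected):
        props = np.array([p0, p1])
        counts = np.rint(props * 100).astype(int)
        cells = CellMeans(counts=counts, means=np.zeros((2, 3)), proportions=props)
        assert common_genotype(cells) == expected

    def test_no_shared_class(self):
        counts = np.array([[5, 0, 0], [0, 0, 5]])
        props = counts / 5
        cells = CellMeans(counts=counts, means=np.zeros((2, 3)), proportions=props)
        with pytest.raises(NoCommonGenotypeError):
            common_genotype(cells)


class TestOneWay:
    def test_hand_worked_anova(self):
        fit = fit_oneway([0.0, 2, 2, 4], [0, 0, 1, 1])
        assert fit.mu0_hat == pytest.approx(1.0)
        assert fit.tau_hat[1] == pytest.approx(2.0)
        assert fit.sse == pytest.approx(4.0)
        assert fit.f_stat == pytest.approx(2.0)
        assert fit.p_value == pytest.approx(0.2929, abs=1e-4)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = rng.integers(0, 3, size=25)
            y = rng.normal(size=25) + 0.4 * g
            if len(np.unique(g)) < 2:
                continue
            fit = fit_oneway(y, g)
            ref = stats.f_oneway(*(y[g == j] for j in np.unique(g)))
            assert fit.f_stat == pytest.approx(ref.statistic, rel=1e-10)
            assert fit.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_constant_response_gives_null_f(self):
        fit = fit_oneway([3.0, 3, 3, 3], [0, 0, 1, 1])
        assert fit.f_stat == 0.0
        assert fit.p_value == 1.0

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=12)
        g = rng.integers(0, 3, size=12)
        perm = rng.permutation(12)
        a, b = fit_oneway(y, g), fit_oneway(y[perm], g[perm])
        assert a.f_stat == pytest.approx(b.f_stat)
        assert a.sse == pytest.approx(b.sse)

    def test_single_class_not_testable(self):
        with pytest.raises(NotTestableError):
            fit_oneway([1.0, 2, 3], [1, 1, 1])

    def test_saturated(self):
        with pytest.raises(SaturatedModelError):
            fit_oneway([1.0, 2], [0, 1])


class TestIGRule:
    def _fits(self, p0, p1):
        base = fit_oneway([0.0, 2, 2, 4], [0, 0, 1, 1])
        from dataclasses import replace

        return replace(base, p_value=p0), replace(base, p_value=p1)

    def test_union_null_requires_both(self):
        f0, f1 = self._fits(0.001, 0.2)
        assert not ig_common_eqtl(f0, f1, alpha=0.05, rule="union-null").common

    def test_intersection_null_accepts_either(self):
        f0, f1 = self._fits(0.001, 0.2)
        assert ig_common_eqtl(f0, f1, alpha=0.05, rule="intersection-null").common

    def test_identical_strong_signal_common_under_both_rules(self):
        f0, f1 = self._fits(0.01, 0.01)
        for rule in ("union-null", "intersection-null"):
            assert ig_common_eqtl(f0, f1, alpha=0.05, rule=rule).common


class TestCTWMFit:
    def test_balanced_toy_parameters(self, balanced_toy):
        fit = fit_ctwm(*balanced_toy)
        np.testing.assert_allclose(fit.beta_hat, [1.0, 4.0, 2.0])
        assert fit.sse == pytest.approx(8.0)
        assert fit.df_error == 5
        assert fit.design_rank == 3

    def test_constant_response(self):
        fit = fit_ctwm([2.0] * 8, [0, 0, 1, 1, 0, 0, 1, 1], [0, 0, 0, 0, 1, 1, 1, 1])
        assert fit.tau(1) == pytest.approx(0.0)
        assert fit.sse == pytest.approx(0.0)

    def test_single_population_rejected(self):
        with pytest.raises(SinglePopulationError):
            fit_ctwm([1.0, 2, 3, 4], [0, 0, 1, 1], [0, 0, 0, 0])

    def test_unidentifiable_design(self):
        # population 1 only carries genotype 2, unseen anywhere else:
        # its baseline and tau_2 are confounded
        y = [0.0, 1, 2, 3, 4, 5]
        g = [0, 0, 1, 1, 2, 2]
        pop = [0, 0, 0, 0, 1, 1]
        with pytest.raises(NotIdentifiableError):
            fit_ctwm(y, g, pop)

    def test_order_invariance(self, balanced_toy):
        y, g, pop = balanced_toy
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(y))
        a, b = fit_ctwm(y, g, pop), fit_ctwm(y[perm], g[perm], pop[perm])
        np.testing.assert_allclose(a.beta_hat, b.beta_hat)
        assert a.sse == pytest.approx(b.sse)

    def test_baseline_relabelling_invariance(self, four_cell_toy):
        y, g, pop = four_cell_toy
        fits = [fit_ctwm(y, g, pop, baseline=b) for b in (0, 1, 2)]
        for fit in fits[1:]:
            assert fit.sse == pytest.approx(fits[0].sse)
            for i in (0, 1):
                for j in (0, 1, 2):
                    assert fit.fitted_cell_mean(i, j) == pytest.approx(
                        fits[0].fitted_cell_mean(i, j)
                    )
            a = ctwm_association_test(fit)
            b = ctwm_association_test(fits[0])
            assert a.statistic == pytest.approx(b.statistic)


class TestPartialF:
    def test_balanced_toy_tau_contrast(self, balanced_toy):
        fit = fit_ctwm(*balanced_toy)
        res = partial_f_test(fit, [0.0, 0.0, 1.0])
        assert res.statistic == pytest.approx(5.0)
        assert (res.df_num, res.df_den) == (1, 5)
        assert res.p_value == pytest.approx(0.0756, abs=1e-4)
        assert res.estimate == pytest.approx(2.0)

    def test_zero_contrast_value(self, balanced_toy):
        fit = fit_ctwm(*balanced_toy)
        res = partial_f_test(fit, [2.0, -1.0, 1.0])  # 2*mu00 - mu10 + tau1 = 0 exactly
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_matrix_untestable(self, balanced_toy):
        fit = fit_ctwm(*balanced_toy)
        with pytest.raises(UntestableContrastError):
            partial_f_test(fit, [0.0, 0.0, 0.0])

    def test_association_equals_single_contrast_when_one_tau(self, balanced_toy):
        fit = fit_ctwm(*balanced_toy)
        a = ctwm_association_test(fit)
        b = partial_f_test(fit, [0.0, 0.0, 1.0])
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_monomorphic_not_testable(self):
        fit = fit_ctwm([1.0, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
        with pytest.raises(NotTestableError):
            ctwm_association_test(fit)


def _sm_design(g, pop, tau_classes):
    cols = [(pop == 0).astype(float), (pop == 1).astype(float)]
    cols += [(g == j).astype(float) for j in tau_classes]
    return np.column_stack(cols)


def test_least_squares_oracle_equivalence():
    """fit_ctwm / partial_f_test agree with statsmodels OLS + f_test to 1e-8."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        y, g, pop = random_cohort_vectors(rng)
        fit = fit_ctwm(y, g, pop)
        X = _sm_design(g, pop, fit.tau_classes)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.beta_hat, ref.params, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(fit.sse, ref.ssr, rtol=1e-8)
        assert fit.df_error == int(ref.df_resid)

        n_tau = len(fit.tau_classes)
        B = np.zeros((n_tau, 2 + n_tau))
        B[:, 2:] = np.eye(n_tau)
        ours = ctwm_association_test(fit)
        theirs = ref.f_test(B)
        np.testing.assert_allclose(ours.statistic, float(theirs.fvalue), rtol=1e-8)
        np.testing.assert_allclose(ours.p_value, float(theirs.pvalue), rtol=1e-8)

        Brand = rng.normal(size=2 + n_tau)
        ours = partial_f_test(fit, Brand)
        theirs = ref.f_test(Brand[None, :])
        np.testing.assert_allclose(ours.statistic, float(theirs.fvalue), rtol=1e-8)


def test_oneway_equals_general_linear_hypothesis_on_one_population():
    """The one-way ANOVA F is the GLH partial F on the single-population design."""
    rng = np.random.default_rng(5)
    g = rng.integers(0, 3, size=40)
    y = rng.normal(size=40) + 0.3 * g
    fit = fit_oneway(y, g)
    classes = sorted(np.unique(g))[1:]
    X = np.column_stack([np.ones(40)] + [(g == j).astype(float) for j in classes])
    ref = sm.OLS(y, X).fit()
    B = np.zeros((len(classes), X.shape[1]))
    B[:, 1:] = np.eye(len(classes))
    theirs = ref.f_test(B)
    assert fit.f_stat == pytest.approx(float(theirs.fvalue), rel=1e-10)


def test_association_p_values_uniform_under_null():
    """With no SNP effect the CTWM association p-values are U(0,1) (KS at 1%)."""
    sc = SimulationScenario(p0=0.3, d=0.1, D=0.5, E=0.0, n0=40, n1=50, seed=11)
    rng_streams = np.random.SeedSequence(sc.seed).spawn(2000)
    pvals = []
    for child in rng_streams:
        y, g, pop = simulate_dataset(sc, np.random.default_rng(child))
        try:
            pvals.append(ctwm_association_test(fit_ctwm(y, g, pop)).p_value)
        except Exception:
            continue
    stat = stats.kstest(pvals, "uniform")
    assert stat.pvalue > 0.01
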