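"""Causal estimators, sensitivity suite, and Steiger directionality.

Independent oracles (normal-equation weighted least squares, the
interpolation definition of the weighted median, direct Q summation,
grid-search density maximisation) are implemented here and the package
implementations are checked against them.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from clockmr.errors import DataError, InsufficientInstrumentsError
from clockmr.estimators import (
    EggerEstimator, IVWEstimator, TraitMeta, WeightedMedianEstimator,
    WeightedModeEstimator, egger, ivw, single_snp_and_loo, steiger,
    wald_ratio, weighted_median, weighted_mode,
)
from conftest import instrument_frame


# ---------------------------------------------------------------------------
# oracles


def wls_oracle(gamma, Gamma, w, intercept=False):
    """Weighted least squares by the normal equations."""
    X = np.column_stack([np.ones_like(gamma), gamma]) if intercept \
        else np.asarray(gamma, float).reshape(-1, 1)
    W = np.diag(w)
    xtwx = X.T @ W @ X
    coef = np.linalg.solve(xtwx, X.T @ W @ np.asarray(Gamma, float))
    resid = Gamma - X @ coef
    rss = float(resid @ W @ resid)
    cov_unit = np.linalg.inv(xtwx)
    return coef, rss, cov_unit


def q_oracle(gamma, Gamma, se_Gamma, theta):
    ratios = Gamma / gamma
    w = gamma ** 2 / se_Gamma ** 2
    return float(np.sum(w * (ratios - theta) ** 2))


def median_oracle(ratios, weights):
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    p = np.cumsum(w) - w / 2
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    j = int(np.searchsorted(p, 0.5))
    frac = (0.5 - p[j - 1]) / (p[j] - p[j - 1])
    return float(r[j - 1] + frac * (r[j] - r[j - 1]))


def _random_fixture(rng, k=None):
    k = k or int(rng.integers(3, 12))
    gamma = rng.normal(0, 0.1, k)
    gamma[gamma == 0] = 0.05
    Gamma = rng.normal(0, 0.05, k)
    se_Gamma = rng.uniform(0.005, 0.05, k)
    se_gamma = rng.uniform(0.002, 0.01, k)
    return instrument_frame(gamma, Gamma, se_Gamma, se_gamma=se_gamma)


# ---------------------------------------------------------------------------


class TestWaldRatio:
    def test_hand_evaluation(self):
        est = wald_ratio(0.1, 0.012, 0.01)
        assert est.beta == pytest.approx(0.12)
        assert est.se == pytest.approx(0.1)

    def test_null_numerator(self):
        assert wald_ratio(0.1, 0.0, 0.01).beta == 0

    def test_zero_gamma_raises(self):
        with pytest.raises(DataError):
            wald_ratio(0.0, 0.01, 0.01)

    def test_second_order_variance_larger(self):
        first = wald_ratio(0.1, 0.05, 0.01)
        second = wald_ratio(0.1, 0.05, 0.01, se_gamma=0.02, second_order=True)
        assert second.se > first.se


class TestIVW:
    FIXTURE = instrument_frame([0.1, 0.2, 0.15], [0.012, 0.020, 0.018],
                               [0.01, 0.01, 0.01])

    def test_worked_example_against_wls_oracle(self):
        est = ivw(self.FIXTURE)
        assert est.beta == pytest.approx(0.0079 / 0.0725, rel=1e-10)
        assert est.beta == pytest.approx(0.1090, abs=5e-5)
        assert est.Q == pytest.approx(0.0717, abs=5e-5)
        assert est.Q_df == 2

    def test_single_instrument_reduces_to_wald(self):
        one = instrument_frame([0.1], [0.012], [0.01])
        est = ivw(one)
        ref = wald_ratio(0.1, 0.012, 0.01)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_homogeneous_ratios_give_zero_q(self):
        hom = instrument_frame([0.1, 0.2, 0.3], [0.01, 0.02, 0.03],
                               [0.01, 0.01, 0.01])
        est = ivw(hom)
        assert est.beta == pytest.approx(0.1)
        assert est.Q == pytest.approx(0.0, abs=1e-20)

    def test_fixed_equals_weighted_mean_of_wald_ratios(self, rng):
        for _ in range(25):
            f = _random_fixture(rng)
            est = ivw(f, mode="fixed")
            theta = f["Gamma"] / f["gamma"]
            w = f["gamma"] ** 2 / f["se_Gamma"] ** 2
            assert est.beta == pytest.approx(np.average(theta, weights=w),
                                             rel=1e-12)
            assert est.se == pytest.approx(np.sqrt(1 / w.sum()), rel=1e-12)

    def test_mre_scales_se_by_dispersion_without_flooring(self):
        fe = ivw(self.FIXTURE, mode="fixed")
        mre = ivw(self.FIXTURE)
        phi = np.sqrt(mre.Q / mre.Q_df)
        assert mre.se == pytest.approx(fe.se * phi, rel=1e-12)
        assert phi < 1  # this fixture is under-dispersed: se shrinks


class TestEgger:
    def test_points_on_line_through_origin(self):
        f = instrument_frame([0.1, 0.2, 0.3, 0.4], [0.05, 0.10, 0.15, 0.20],
                             [0.01, 0.01, 0.01, 0.01])
        est = egger(f)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)
        assert est.beta == pytest.approx(0.5, rel=1e-10)

    def test_shifting_Gamma_moves_only_the_intercept(self, rng):
        # gammas kept positive so no orientation flip interferes with the shift
        f = _random_fixture(rng)
        f["gamma"] = f["gamma"].abs()
        base = egger(f)
        shifted = f.assign(Gamma=f["Gamma"] + 0.05)
        est = egger(shifted)
        assert est.beta == pytest.approx(base.beta, rel=1e-9)
        assert est.intercept == pytest.approx(base.intercept + 0.05, rel=1e-9)

    def test_against_wls_oracle_with_orientation(self, rng):
        for _ in range(25):
            f = _random_fixture(rng)
            flip = np.sign(f["gamma"].to_numpy())
            g = f["gamma"].to_numpy() * flip
            G = f["Gamma"].to_numpy() * flip
            w = 1 / f["se_Gamma"].to_numpy() ** 2
            coef, rss, cov = wls_oracle(g, G, w, intercept=True)
            k = len(f)
            scale = max(rss / (k - 2), 1.0)
            est = egger(f)
            assert est.intercept == pytest.approx(coef[0], rel=1e-9, abs=1e-12)
            assert est.beta == pytest.approx(coef[1], rel=1e-9, abs=1e-12)
            assert est.se == pytest.approx(np.sqrt(scale * cov[1, 1]),
                                           rel=1e-9)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(instrument_frame([0.1, 0.2], [0.01, 0.02], [0.01, 0.01]))

    def test_zero_intercept_constraint_is_fixed_ivw(self, rng):
        # dropping the intercept column of the Egger design reproduces IVW
        f = _random_fixture(rng)
        w = 1 / f["se_Gamma"].to_numpy() ** 2
        coef, _, _ = wls_oracle(f["gamma"].to_numpy(), f["Gamma"].to_numpy(), w)
        assert ivw(f, mode="fixed").beta == pytest.approx(coef[0], rel=1e-12)


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        f = instrument_frame([1.0, 1.0, 1.0], [0.10, 0.12, 0.30],
                             [1.0, 1.0, 1.0])
        assert weighted_median(f, n_boot=0).beta == pytest.approx(0.12)

    def test_interpolation_formula(self):
        # ratios 0.10/0.12/0.30, weights 0.2/0.2/0.6 -> 0.21
        w = np.array([0.2, 0.2, 0.6])
        se_G = 1 / np.sqrt(w)  # gamma = 1 so weight = 1/se_Gamma^2
        f = instrument_frame([1.0, 1.0, 1.0], [0.10, 0.12, 0.30], se_G)
        assert weighted_median(f, n_boot=0).beta == pytest.approx(0.21)
        assert median_oracle([0.10, 0.12, 0.30], w) == pytest.approx(0.21)

    def test_degenerate_identical_ratios(self):
        f = instrument_frame([0.1, 0.2, 0.3], [0.01, 0.02, 0.03],
                             [1e-6, 1e-6, 1e-6], se_gamma=[1e-9] * 3)
        est = weighted_median(f, n_boot=200, random_state=0)
        assert est.beta == pytest.approx(0.1)
        assert est.se < 1e-3  # bootstrap se collapses with the noise

    def test_matches_oracle_on_random_fixtures(self, rng):
        for _ in range(25):
            f = _random_fixture(rng)
            theta = (f["Gamma"] / f["gamma"]).to_numpy()
            w = (f["gamma"] ** 2 / f["se_Gamma"] ** 2).to_numpy()
            assert weighted_median(f, n_boot=0).beta == pytest.approx(
                median_oracle(theta, w), rel=1e-10)

    def test_bootstrap_se_reproducible(self, rng):
        f = _random_fixture(rng)
        a = weighted_median(f, n_boot=300, random_state=11)
        b = weighted_median(f, n_boot=300, random_state=11)
        assert a.se == b.se


class TestWeightedMode:
    def test_identical_ratios(self):
        f = instrument_frame([0.1, 0.2, 0.3], [0.01, 0.02, 0.03],
                             [0.01, 0.01, 0.01])
        assert weighted_mode(f, n_boot=0).beta == pytest.approx(0.1, abs=1e-6)

    def test_majority_cluster_wins(self):
        f = instrument_frame([1, 1, 1, 1], [0.1, 0.1, 0.1, 0.9],
                             [0.05, 0.05, 0.05, 0.05])
        est = weighted_mode(f, n_boot=0)
        assert abs(est.beta - 0.1) < 0.05

    def test_matches_grid_density_oracle(self, rng):
        for _ in range(10):
            f = _random_fixture(rng)
            est = weighted_mode(f, n_boot=0)
            theta = (f["Gamma"] / f["gamma"]).to_numpy()
            w = (f["gamma"] ** 2 / f["se_Gamma"] ** 2).to_numpy()
            w = w / w.sum()
            sd = np.std(theta, ddof=1)
            iqr = np.subtract(*np.percentile(theta, [75, 25]))
            disp = min(sd, iqr / 1.349) if iqr > 0 else sd
            h = 0.9 * disp * len(theta) ** (-1 / 5)
            grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 20001)
            dens = (w[:, None]
                    * np.exp(-0.5 * ((grid[None] - theta[:, None]) / h) ** 2)).sum(0)
            assert est.beta == pytest.approx(grid[np.argmax(dens)], abs=2 * h / 100)

    def test_sharper_bandwidth_stays_on_dominant_cluster(self):
        f = instrument_frame([1] * 7, [0.1, 0.11, 0.09, 0.1, 0.5, 0.51, 0.49],
                             [0.05] * 7)
        wide = weighted_mode(f, bandwidth_phi=1.0, n_boot=0).beta
        narrow = weighted_mode(f, bandwidth_phi=0.5, n_boot=0).beta
        assert abs(wide - 0.1) < 0.05 and abs(narrow - 0.1) < 0.05


class TestEquivariance:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_sign_and_scale_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        f = _random_fixture(rng)
        ests = {
            "ivw": lambda d: ivw(d).beta,
            "egger": lambda d: egger(d).beta,
            "median": lambda d: weighted_median(d, n_boot=0).beta,
        }
        for name, fn in ests.items():
            base = fn(f)
            both = f.assign(gamma=-f["gamma"], Gamma=-f["Gamma"])
            assert fn(both) == pytest.approx(base, rel=1e-9, abs=1e-12), name
            neg = f.assign(Gamma=-f["Gamma"])
            assert fn(neg) == pytest.approx(-base, rel=1e-9, abs=1e-12), name
            c = 3.7
            scaled = f.assign(Gamma=c * f["Gamma"], se_Gamma=c * f["se_Gamma"])
            assert fn(scaled) == pytest.approx(c * base, rel=1e-9), name
        scaled = f.assign(Gamma=2 * f["Gamma"], se_Gamma=2 * f["se_Gamma"])
        assert ivw(scaled).se == pytest.approx(2 * ivw(f).se, rel=1e-9)


class TestSingleSnpAndLOO:
    def test_two_instruments_swap(self):
        f = instrument_frame([0.1, 0.2], [0.012, 0.02], [0.01, 0.01])
        per, loo = single_snp_and_loo(f)
        assert loo.iloc[0]["beta"] == pytest.approx(0.1)   # drop rs0 -> rs1 ratio
        assert loo.iloc[1]["beta"] == pytest.approx(0.12)  # drop rs1 -> rs0 ratio

    def test_homogeneous_ratios_constant_loo(self):
        f = instrument_frame([0.1, 0.2, 0.3], [0.01, 0.02, 0.03],
                             [0.01, 0.01, 0.01])
        _, loo = single_snp_and_loo(f)
        np.testing.assert_allclose(loo["beta"], 0.1)

    def test_loo_matches_rerunning_ivw_on_subsets(self, rng):
        f = _random_fixture(rng, k=4)
        per, loo = single_snp_and_loo(f)
        for i in range(4):
            sub = f.drop(index=i)
            assert loo.iloc[i]["beta"] == pytest.approx(ivw(sub).beta, rel=1e-12)
        for i in range(4):
            assert per.iloc[i]["beta"] == pytest.approx(
                f["Gamma"][i] / f["gamma"][i], rel=1e-12)


class TestSteiger:
    def _frame(self, gamma, Gamma, eaf=0.3):
        k = len(gamma)
        return instrument_frame(gamma, Gamma, [0.01] * k, se_gamma=[0.01] * k,
                                eaf_exposure=[eaf] * k, eaf_outcome=[eaf] * k)

    def test_symmetric_r2_is_undetermined(self):
        f = self._frame([0.1, 0.2], [0.1, 0.2])
        meta = TraitMeta("continuous", 10_000)
        res = steiger(f, meta, meta)
        assert res.direction is None
        assert res.pvalue == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0)

    def test_mediation_chain_direction_and_retention(self):
        # outcome effects attenuated by theta=0.3: less outcome variance
        f = self._frame([0.1, 0.2, 0.15], [0.03, 0.06, 0.045])
        res = steiger(f, TraitMeta("continuous", 30_000),
                      TraitMeta("continuous", 30_000))
        assert res.direction == "exposure_to_outcome"
        assert res.retained == ["rs0", "rs1", "rs2"]
        assert res.pvalue < 0.05

    def test_reverse_snp_removed_by_filtering(self):
        f = self._frame([0.1, 0.2, 0.01], [0.03, 0.06, 0.2])
        res = steiger(f, TraitMeta("continuous", 30_000),
                      TraitMeta("continuous", 30_000))
        assert "rs2" not in res.retained
        assert set(res.retained) == {"rs0", "rs1"}

    def test_binary_outcome_uses_case_fraction(self):
        f = self._frame([0.1, 0.2, 0.15], [0.1, 0.2, 0.15])
        res = steiger(f, TraitMeta("continuous", 30_000),
                      TraitMeta("binary", 100_000, ncase=10_000, ncontrol=90_000))
        # same betas but observed-scale pseudo-r2 shrinks by K(1-K)
        assert (res.r2_outcome < res.r2_exposure).all()
        liab = steiger(f, TraitMeta("continuous", 30_000),
                       TraitMeta("binary", 100_000, ncase=10_000,
                                 ncontrol=90_000), binary_scale="liability")
        assert not np.allclose(liab.r2_outcome, res.r2_outcome)

    def test_missing_eaf_raises(self):
        f = instrument_frame([0.1], [0.1], [0.01])
        with pytest.raises(DataError):
            steiger(f, TraitMeta("continuous", 1000), TraitMeta("continuous", 1000))
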