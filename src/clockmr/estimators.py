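"""Causal-effect estimators and sensitivity analyses for two-sample MR.

Given k harmonised instruments with SNP-exposure effects gamma_j (se
se_gamma_j) and SNP-outcome effects Gamma_j (se se_Gamma_j), the per-SNP
Wald ratio theta_j = Gamma_j / gamma_j estimates the causal effect. The
estimators combine the ratios under different assumptions:

* IVW — weighted regression of Gamma on gamma through the origin with
  weights 1/se_Gamma^2; unbiased when all instruments are valid. The
  multiplicative random-effects variant inflates the standard error by
  the residual dispersion to absorb heterogeneity.
* MR-Egger — the same regression with a free intercept; the intercept
  estimates average directional pleiotropy and the slope remains
  consistent under the InSIDE assumption.
* Weighted median — consistent when instruments carrying at least half
  of the weight are valid.
* Weighted mode — consistent when the largest group of instruments with
  the same ratio is valid (zero modal pleiotropy assumption).

The estimators are written in the scikit-learn idiom: parameterised
constructors, ``fit`` on a harmonised-instrument table, fitted attributes
with trailing underscores, and ``get_params``/``set_params`` inherited
from :class:`sklearn.base.BaseEstimator`. Module-level functions are thin
wrappers returning an :class:`MREstimate`.

The Steiger directionality test and single-SNP / leave-one-out analyses
live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from clockmr.errors import DataError, InsufficientInstrumentsError

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MREstimate:
    """One method's causal-effect estimate on the log-OR (or trait) scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    Q: float | None = None
    Q_df: int | None = None
    Q_p: float | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def to_dict(self) -> dict:
        return {
            "method": self.method, "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pvalue": self.pvalue, "n_snps": self.n_snps,
            "intercept": self.intercept, "intercept_se": self.intercept_se,
            "intercept_p": self.intercept_p,
            "Q": self.Q, "Q_df": self.Q_df, "Q_p": self.Q_p,
        }


@dataclass
class SteigerResult:
    """Directionality diagnostics comparing variance explained per trait."""

    r2_exposure: np.ndarray
    r2_outcome: np.ndarray
    rsids: list[str]
    direction: str | None  # "exposure_to_outcome", "outcome_to_exposure", None
    statistic: float
    pvalue: float
    retained: list[str]


def _extract(instruments) -> pd.DataFrame:
    """Accept a harmonised table (optionally with exclusions) or an array-like."""
    if isinstance(instruments, pd.DataFrame):
        df = instruments
        if "excluded" in df.columns:
            df = df[~df["excluded"].astype(bool)]
        need = ["gamma", "se_gamma", "Gamma", "se_Gamma"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise DataError(f"instrument table lacks columns {missing}")
        if "rsid" not in df.columns:
            df = df.assign(rsid=[f"snp{i}" for i in range(len(df))])
        return df.reset_index(drop=True)
    raise DataError("instruments must be a harmonised DataFrame")


def _check_k(k: int, minimum: int, method: str) -> None:
    if k < minimum:
        raise InsufficientInstrumentsError(
            f"{method} requires at least {minimum} instruments, got {k}")


# ---------------------------------------------------------------------------
# Wald ratio


def wald_ratio(gamma: float, Gamma: float, se_Gamma: float,
               se_gamma: float | None = None,
               second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate theta = Gamma / gamma.

    The first-order delta-method standard error se_Gamma/|gamma| ignores
    the uncertainty in gamma (the tooling convention); pass
    ``second_order=True`` to add the gamma contribution.
    """
    if gamma == 0:
        raise DataError("wald ratio undefined for gamma = 0")
    theta = Gamma / gamma
    var = (se_Gamma / gamma) ** 2
    if second_order:
        if se_gamma is None:
            raise DataError("second-order wald ratio needs se_gamma")
        var += (Gamma ** 2 * se_gamma ** 2) / gamma ** 4
    se = float(np.sqrt(var))
    p = 2 * stats.norm.sf(abs(theta / se)) if se > 0 else (1.0 if theta == 0 else 0.0)
    return MREstimate("wald", float(theta), se, theta - Z95 * se,
                      theta + Z95 * se, float(p), 1)


# ---------------------------------------------------------------------------
# scikit-learn style estimator classes


class _BaseMR(BaseEstimator):
    """Shared fit plumbing for the MR estimator classes."""

    _method = "base"
    _min_snps = 2

    def fit(self, instruments):
        df = _extract(instruments)
        _check_k(len(df), self._min_snps, self._method)
        g = df["gamma"].to_numpy(float)
        if np.any(g == 0):
            raise DataError("instruments with gamma = 0 cannot be used")
        self._fit(
            g,
            df["se_gamma"].to_numpy(float),
            df["Gamma"].to_numpy(float),
            df["se_Gamma"].to_numpy(float),
        )
        self.n_snps_ = len(df)
        self.rsids_ = list(df["rsid"])
        return self

    def _fit(self, gamma, se_gamma, Gamma, se_Gamma):  # pragma: no cover
        raise NotImplementedError

    @property
    def result_(self) -> MREstimate:
        return MREstimate(
            method=self._method, beta=self.beta_, se=self.se_,
            ci_low=self.ci_low_, ci_high=self.ci_high_, pvalue=self.pvalue_,
            n_snps=self.n_snps_,
            intercept=getattr(self, "intercept_", None),
            intercept_se=getattr(self, "intercept_se_", None),
            intercept_p=getattr(self, "intercept_pvalue_", None),
            Q=getattr(self, "q_", None),
            Q_df=getattr(self, "q_df_", None),
            Q_p=getattr(self, "q_pvalue_", None),
        )


class IVWEstimator(_BaseMR):
    """Inverse-variance-weighted regression through the origin.

    Parameters
    ----------
    mode : {"multiplicative_random", "fixed"}
        Fixed-effect uses the theoretical weights directly; the
        multiplicative random-effects default scales the standard error by
        the residual standard deviation phi = sqrt(Q / (k - 1)).
    floor_dispersion : bool
        If True, phi is floored at 1 so the random-effects se can never
        undercut the fixed-effect se. Off by default, matching the
        common tooling convention for this variant.
    """

    _method = "ivw_mre"
    _min_snps = 1

    def __init__(self, mode: str = "multiplicative_random",
                 floor_dispersion: bool = False):
        self.mode = mode
        self.floor_dispersion = floor_dispersion

    def _fit(self, gamma, se_gamma, Gamma, se_Gamma):
        self._method = "ivw_fe" if self.mode == "fixed" else "ivw_mre"
        k = len(gamma)
        w = 1.0 / se_Gamma ** 2
        swg2 = float(np.sum(w * gamma ** 2))
        beta = float(np.sum(w * gamma * Gamma) / swg2)
        se_fe = float(np.sqrt(1.0 / swg2))

        if k >= 2:
            resid = Gamma - beta * gamma
            q = float(np.sum(w * resid ** 2))
            q_df = k - 1
            phi = np.sqrt(q / q_df)
            self.q_, self.q_df_ = q, q_df
            self.q_pvalue_ = float(stats.chi2.sf(q, q_df))
        else:
            phi = 1.0
            self.q_ = self.q_df_ = self.q_pvalue_ = None

        if self.mode == "fixed" or k < 2:
            se = se_fe
        else:
            if self.floor_dispersion:
                phi = max(1.0, phi)
            se = se_fe * float(phi)

        self.beta_, self.se_ = beta, se
        self.dispersion_ = float(phi)
        if se > 0:
            self.pvalue_ = float(2 * stats.norm.sf(abs(beta / se)))
        else:
            self.pvalue_ = 1.0 if beta == 0 else 0.0
        self.ci_low_ = beta - Z95 * se
        self.ci_high_ = beta + Z95 * se


class EggerEstimator(_BaseMR):
    """MR-Egger: weighted regression of Gamma on gamma with an intercept.

    Instruments are oriented so every gamma_j is non-negative before
    fitting (pairs with gamma_j < 0 are sign-flipped), as the method's
    original description requires. The residual dispersion is floored at
    1 when scaling the standard errors, and inference uses the
    t-distribution with k - 2 degrees of freedom.
    """

    _method = "egger"
    _min_snps = 3

    def __init__(self, floor_dispersion: bool = True):
        self.floor_dispersion = floor_dispersion

    def _fit(self, gamma, se_gamma, Gamma, se_Gamma):
        import statsmodels.api as sm

        flip = np.sign(gamma)
        flip[flip == 0] = 1.0
        g = gamma * flip
        G = Gamma * flip
        k = len(g)
        w = 1.0 / se_Gamma ** 2
        X = sm.add_constant(g)
        fit = sm.WLS(G, X, weights=w).fit()
        scale = float(fit.scale)  # residual variance (phi^2), df k - 2
        factor = 1.0
        if self.floor_dispersion and scale < 1.0:
            factor = np.sqrt(1.0 / scale)  # undo the scale, re-apply unit variance
        intercept, slope = fit.params
        se_int, se_slope = fit.bse * factor

        tq = float(stats.t.ppf(0.975, k - 2))
        self.beta_, self.se_ = float(slope), float(se_slope)
        self.pvalue_ = float(2 * stats.t.sf(abs(slope / se_slope), k - 2))
        self.ci_low_ = float(slope - tq * se_slope)
        self.ci_high_ = float(slope + tq * se_slope)
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(se_int)
        self.intercept_pvalue_ = float(2 * stats.t.sf(abs(intercept / se_int), k - 2))
        self.dispersion_ = float(np.sqrt(max(scale, 1.0) if self.floor_dispersion
                                         else scale))
        resid = G - intercept - slope * g
        self.q_ = float(np.sum(w * resid ** 2))
        self.q_df_ = k - 2
        self.q_pvalue_ = float(stats.chi2.sf(self.q_, self.q_df_))


def _ratio_weights(gamma, Gamma, se_Gamma):
    theta = Gamma / gamma
    w = gamma ** 2 / se_Gamma ** 2  # 1 / delta-method variance of theta_j
    return theta, w


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    t = theta[order]
    wn = w[order] / w.sum()
    p = np.cumsum(wn) - wn / 2
    return float(np.interp(0.5, p, t))


class WeightedMedianEstimator(_BaseMR):
    """Weighted median of the Wald ratios.

    The estimate interpolates the inverse-variance-weighted cumulative
    distribution of ordered ratios at the 50th percentile; the standard
    error comes from a parametric bootstrap resampling (gamma_j, Gamma_j)
    from their normal sampling distributions.
    """

    _method = "weighted_median"
    _min_snps = 3

    def __init__(self, n_boot: int = 1000, random_state: int | None = None):
        self.n_boot = n_boot
        self.random_state = random_state

    def _point(self, gamma, Gamma, se_Gamma):
        theta, w = _ratio_weights(gamma, Gamma, se_Gamma)
        return _weighted_median(theta, w)

    def _fit(self, gamma, se_gamma, Gamma, se_Gamma):
        beta = self._point(gamma, Gamma, se_Gamma)
        se = _bootstrap_se(self._point, gamma, se_gamma, Gamma, se_Gamma,
                           self.n_boot, self.random_state)
        _finalise_boot(self, beta, se)


class WeightedModeEstimator(_BaseMR):
    """Mode-based estimate: the maximiser of a weighted kernel density
    of the Wald ratios.

    The Gaussian-kernel bandwidth is ``bandwidth_phi`` times a
    dispersion-based default (0.9 min(sd, iqr/1.349) k^(-1/5)); smaller
    phi sharpens the density around the dominant cluster of ratios.
    """

    _method = "weighted_mode"
    _min_snps = 3

    def __init__(self, bandwidth_phi: float = 1.0, n_boot: int = 1000,
                 random_state: int | None = None, grid_size: int = 2048):
        self.bandwidth_phi = bandwidth_phi
        self.n_boot = n_boot
        self.random_state = random_state
        self.grid_size = grid_size

    def _point(self, gamma, Gamma, se_Gamma):
        theta, w = _ratio_weights(gamma, Gamma, se_Gamma)
        wn = w / w.sum()
        sd = np.std(theta, ddof=1)
        iqr = np.subtract(*np.percentile(theta, [75, 25]))
        disp = min(sd, iqr / 1.349) if iqr > 0 else sd
        if disp <= 0:
            return float(theta[0])
        h = self.bandwidth_phi * 0.9 * disp * len(theta) ** (-1 / 5)
        grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h,
                           self.grid_size)
        dens = (wn[:, None] * np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / h) ** 2)).sum(axis=0)
        return float(grid[int(np.argmax(dens))])

    def _fit(self, gamma, se_gamma, Gamma, se_Gamma):
        beta = self._point(gamma, Gamma, se_Gamma)
        se = _bootstrap_se(self._point, gamma, se_gamma, Gamma, se_Gamma,
                           self.n_boot, self.random_state)
        _finalise_boot(self, beta, se)


def _bootstrap_se(point_fn, gamma, se_gamma, Gamma, se_Gamma,
                  n_boot: int, random_state) -> float:
    """Parametric bootstrap se for ratio-based estimators.

    Draws (gamma*, Gamma*) from N(gamma, se_gamma), N(Gamma, se_Gamma)
    per instrument; returns nan when n_boot = 0 (point estimate only).
    """
    if n_boot <= 0:
        return float("nan")
    rng = np.random.default_rng(random_state)
    k = len(gamma)
    est = np.empty(n_boot)
    g_draw = rng.normal(gamma, se_gamma, size=(n_boot, k))
    G_draw = rng.normal(Gamma, se_Gamma, size=(n_boot, k))
    g_draw[g_draw == 0] = np.finfo(float).tiny
    for b in range(n_boot):
        est[b] = point_fn(g_draw[b], G_draw[b], se_Gamma)
    return float(np.std(est, ddof=1))


def _finalise_boot(obj, beta: float, se: float) -> None:
    obj.beta_, obj.se_ = float(beta), float(se)
    if np.isnan(se) or se == 0:
        obj.pvalue_ = float("nan") if np.isnan(se) else (1.0 if beta == 0 else 0.0)
        obj.ci_low_ = obj.ci_high_ = float("nan") if np.isnan(se) else beta
    else:
        obj.pvalue_ = float(2 * stats.norm.sf(abs(beta / se)))
        obj.ci_low_ = beta - Z95 * se
        obj.ci_high_ = beta + Z95 * se


# ---------------------------------------------------------------------------
# functional wrappers


def ivw(instruments, mode: str = "multiplicative_random",
        floor_dispersion: bool = False) -> MREstimate:
    """Inverse-variance-weighted estimate (reduces to the Wald ratio at k=1)."""
    return IVWEstimator(mode=mode, floor_dispersion=floor_dispersion).fit(
        instruments).result_


def egger(instruments, floor_dispersion: bool = True) -> MREstimate:
    return EggerEstimator(floor_dispersion=floor_dispersion).fit(
        instruments).result_


def weighted_median(instruments, n_boot: int = 1000,
                    random_state: int | None = None) -> MREstimate:
    return WeightedMedianEstimator(n_boot=n_boot, random_state=random_state).fit(
        instruments).result_


def weighted_mode(instruments, bandwidth_phi: float = 1.0, n_boot: int = 1000,
                  random_state: int | None = None) -> MREstimate:
    return WeightedModeEstimator(bandwidth_phi=bandwidth_phi, n_boot=n_boot,
                                 random_state=random_state).fit(
        instruments).result_


def single_snp_and_loo(instruments, mode: str = "multiplicative_random"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP Wald ratios and leave-one-out IVW estimates.

    Returns (per_snp, loo) DataFrames. Diagnoses whether a pooled effect
    is driven by a single instrument.
    """
    df = _extract(instruments)
    _check_k(len(df), 2, "leave-one-out")
    per_rows, loo_rows = [], []
    for i, row in df.iterrows():
        est = wald_ratio(row["gamma"], row["Gamma"], row["se_Gamma"])
        per_rows.append({"rsid": row["rsid"], "beta": est.beta, "se": est.se,
                         "ci_low": est.ci_low, "ci_high": est.ci_high,
                         "pvalue": est.pvalue})
        rest = df.drop(index=i)
        e = ivw(rest, mode=mode)
        loo_rows.append({"rsid_omitted": row["rsid"], "beta": e.beta,
                         "se": e.se, "ci_low": e.ci_low, "ci_high": e.ci_high,
                         "pvalue": e.pvalue, "n_snps": e.n_snps})
    return pd.DataFrame(per_rows), pd.DataFrame(loo_rows)


# ---------------------------------------------------------------------------
# Steiger directionality


@dataclass
class TraitMeta:
    """Per-trait metadata needed by the Steiger test."""

    trait_type: str  # "continuous" or "binary"
    n: float
    ncase: float | None = None
    ncontrol: float | None = None

    @property
    def case_fraction(self) -> float | None:
        if self.ncase is None or self.ncontrol is None:
            return None
        return self.ncase / (self.ncase + self.ncontrol)


def _r2_continuous(beta, se, maf, n):
    var_g = 2 * maf * (1 - maf)
    return (var_g * beta ** 2) / (var_g * beta ** 2 + n * var_g * se ** 2)


def _r2_binary_observed(beta, maf, k_case):
    # variance explained on the observed 0/1 scale from a log-OR:
    # slope on the probability scale is approximately beta * K(1-K) per
    # allele, so the explained share of the K(1-K) outcome variance is
    # 2 maf (1-maf) beta^2 K (1-K)
    return 2 * maf * (1 - maf) * beta ** 2 * k_case * (1 - k_case)


def _r2_binary_liability(beta, maf, k_case):
    z = stats.norm.pdf(stats.norm.ppf(k_case))
    return _r2_binary_observed(beta, maf, k_case) * k_case * (1 - k_case) / z ** 2


def steiger(instruments, exposure_meta: TraitMeta, outcome_meta: TraitMeta,
            binary_scale: str = "observed") -> SteigerResult:
    """MR Steiger test of directionality with per-SNP filtering.

    Compares the variance each instrument explains in the exposure versus
    the outcome. The causal direction exposure -> outcome is supported
    when the instruments collectively explain more exposure than outcome
    variance; the test statistic compares the two aggregate correlations
    with a two-sample z-test on the Fisher (atanh) scale. Filtering
    retains instruments with r2_exposure > r2_outcome.

    Binary outcomes use an observed-scale pseudo-r2 derived from the
    log-OR, allele frequency, and case fraction (``binary_scale="observed"``,
    the default) or its liability-scale transformation
    (``binary_scale="liability"``).
    """
    df = _extract(instruments)
    missing = df["rsid"][df["eaf_exposure"].isna()].tolist() \
        if "eaf_exposure" in df.columns else []
    if "eaf_exposure" not in df.columns or missing:
        raise DataError(f"eaf required for Steiger; missing for {missing or 'all'}")

    maf_x = np.minimum(df["eaf_exposure"], 1 - df["eaf_exposure"]).to_numpy(float)
    eaf_y = df["eaf_outcome"].fillna(df["eaf_exposure"]).to_numpy(float)
    maf_y = np.minimum(eaf_y, 1 - eaf_y)
    g = df["gamma"].to_numpy(float)
    seg = df["se_gamma"].to_numpy(float)
    G = df["Gamma"].to_numpy(float)
    seG = df["se_Gamma"].to_numpy(float)

    r2_x = _r2_continuous(g, seg, maf_x, exposure_meta.n)
    if outcome_meta.trait_type == "binary":
        k_case = outcome_meta.case_fraction
        if k_case is None:
            raise DataError("binary outcome needs ncase/ncontrol for Steiger")
        fn = _r2_binary_liability if binary_scale == "liability" else _r2_binary_observed
        r2_y = fn(G, maf_y, k_case)
    else:
        r2_y = _r2_continuous(G, seG, maf_y, outcome_meta.n)

    tot_x = float(np.clip(np.sum(r2_x), 0, 1 - 1e-12))
    tot_y = float(np.clip(np.sum(r2_y), 0, 1 - 1e-12))
    r_x, r_y = np.sqrt(tot_x), np.sqrt(tot_y)
    denom = np.sqrt(1 / (exposure_meta.n - 3) + 1 / (outcome_meta.n - 3))
    z = (np.arctanh(r_x) - np.arctanh(r_y)) / denom
    if tot_x > tot_y:
        direction = "exposure_to_outcome"
    elif tot_y > tot_x:
        direction = "outcome_to_exposure"
    else:
        direction = None
    pvalue = float(2 * stats.norm.sf(abs(z)))
    retained = df["rsid"][r2_x > r2_y].tolist()
    return SteigerResult(
        r2_exposure=np.asarray(r2_x), r2_outcome=np.asarray(r2_y),
        rsids=list(df["rsid"]), direction=direction,
        statistic=float(z), pvalue=pvalue, retained=retained,
    )
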