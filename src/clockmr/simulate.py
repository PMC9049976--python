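"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of the real inputs: a
continuous exposure (epigenetic age acceleration in years, unit-variance
trait) instrumented by a handful of genome-wide-significant SNPs that
together explain 0.5-4.5% of trait variance, and a binary outcome
(cancer) on the log-odds scale with a small case fraction. True per-SNP
exposure effects gamma_j are scaled so that

    sum_j 2 p_j (1 - p_j) gamma_j^2 = target_r2_total,

true outcome effects are Gamma_j = theta gamma_j + alpha_j with alpha_j
drawn from one of four horizontal-pleiotropy models (none, balanced,
directional, correlated through a shared heritable confounder), and
observed effects add normal noise with the standard errors implied by
sample size and allele frequency:

    se(gamma_hat) = 1 / sqrt(2 p (1 - p) n_x)
    se(Gamma_hat) = 1 / sqrt(2 p (1 - p) n_y K (1 - K))   (binary outcome)

the latter being the logistic-score approximation with case fraction K.
Optional LD blocks append correlated satellite SNPs (with the matching
pairwise r2 reference) to exercise clumping and proxy lookup, and
optional reverse-causal SNPs (explaining more outcome than exposure
variance) exercise the Steiger direction test. A single seed governs the
whole draw through independently spawned substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from clockmr.errors import ConfigError
from clockmr.instruments import LDReference
from clockmr.sumstats import SummaryDataset
from clockmr import studies


@dataclass
class SimulationConfig:
    """Generative model for one synthetic two-sample dataset."""

    n_snps: int
    target_r2_total: float
    seed: int
    exposure_n: int = studies.EXPOSURE_N
    outcome_ncase: Optional[int] = None
    outcome_ncontrol: Optional[int] = None
    outcome_n: Optional[int] = None  # continuous outcome if ncase/ncontrol unset
    theta: float = 0.0  # causal log-OR (binary) or effect (continuous) per year
    maf_range: tuple[float, float] = (0.05, 0.5)
    pleiotropy: str = "none"  # none | balanced | directional | correlated
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_fraction: float = 1.0  # share of instruments carrying pleiotropy
    confounder_effect: float = 0.0  # q_c in the correlated model
    positive_gamma: bool = False  # orient true exposure effects >= 0
    share_concentration: float = 30.0  # Dirichlet concentration of r2 shares
    ld_block_size: int = 1  # satellites per lead SNP (1 = no LD structure)
    ld_within_r2: float = 0.0
    n_reverse_snps: int = 0
    reverse_r2_exposure: float = 0.0015
    reverse_r2_outcome: float = 0.01
    exposure_name: str = "synthetic exposure"
    outcome_name: str = "synthetic outcome"

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        if not (0 < self.target_r2_total < 1):
            raise ConfigError("target_r2_total must lie in (0, 1)")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if self.pleiotropy not in ("none", "balanced", "directional", "correlated"):
            raise ConfigError(f"unknown pleiotropy model {self.pleiotropy!r}")
        if not (0 <= self.pleiotropy_fraction <= 1):
            raise ConfigError("pleiotropy_fraction must lie in [0, 1]")
        binary = self.outcome_ncase is not None and self.outcome_ncontrol is not None
        if not binary and self.outcome_n is None:
            raise ConfigError("set outcome_ncase/outcome_ncontrol or outcome_n")
        if self.target_r2_total / self.n_snps > 0.5:
            raise ConfigError(
                f"target_r2_total={self.target_r2_total} infeasible for "
                f"{self.n_snps} SNP(s)")

    @property
    def outcome_is_binary(self) -> bool:
        return self.outcome_ncase is not None and self.outcome_ncontrol is not None

    @property
    def outcome_total_n(self) -> float:
        if self.outcome_is_binary:
            return float(self.outcome_ncase + self.outcome_ncontrol)
        return float(self.outcome_n)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


@dataclass
class TruthRecord:
    """Everything the generator knew: the target of recovery tests."""

    config: SimulationConfig
    theta: float
    table: pd.DataFrame  # rsid, maf, gamma_true, Gamma_true, alpha_pleio,
    #                      r2_exposure, r2_outcome, is_reverse, block

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


_ALLELES = np.array(["A", "C"])  # non-palindromic pair so harmonisation is exact


def _se_exposure(maf, n):
    return 1.0 / np.sqrt(2 * maf * (1 - maf) * n)


def _se_outcome(maf, cfg: SimulationConfig):
    if cfg.outcome_is_binary:
        n = cfg.outcome_total_n
        k = cfg.outcome_ncase / n
        return 1.0 / np.sqrt(2 * maf * (1 - maf) * n * k * (1 - k))
    return 1.0 / np.sqrt(2 * maf * (1 - maf) * cfg.outcome_n)


def simulate_two_sample(config: SimulationConfig
                        ) -> tuple[SummaryDataset, SummaryDataset, LDReference, TruthRecord]:
    """Draw one synthetic exposure/outcome pair with its LD reference."""
    ss = np.random.SeedSequence(config.seed)
    rng_eff, rng_pleio, rng_noise_x, rng_noise_y, rng_rev = (
        np.random.default_rng(s) for s in ss.spawn(5))

    n_lead = config.n_snps
    maf = rng_eff.uniform(*config.maf_range, size=n_lead)
    var_g = 2 * maf * (1 - maf)

    # instruments emulate post-selection genome-wide-significant SNPs: their
    # variance-explained shares are drawn from a concentrated Dirichlet, so
    # no instrument carries a near-zero effect (matching the tight F ranges
    # such selected instruments show in practice)
    shares = rng_eff.dirichlet(np.full(n_lead, config.share_concentration))
    signs = np.ones(n_lead) if config.positive_gamma \
        else rng_eff.choice([-1.0, 1.0], size=n_lead)
    raw = signs * np.sqrt(shares / var_g)
    u = np.zeros(n_lead)
    if config.pleiotropy == "correlated":
        u = rng_pleio.normal(0.0, config.pleiotropy_sd or 1.0, size=n_lead)
        raw = raw + u
    scale = np.sqrt(config.target_r2_total / np.sum(var_g * raw ** 2))
    gamma = raw * scale
    u = u * scale

    if config.pleiotropy == "none":
        alpha = np.zeros(n_lead)
    elif config.pleiotropy == "balanced":
        alpha = rng_pleio.normal(0.0, config.pleiotropy_sd, size=n_lead)
    elif config.pleiotropy == "directional":
        alpha = rng_pleio.normal(config.pleiotropy_mean, config.pleiotropy_sd,
                                 size=n_lead)
    else:  # correlated: pleiotropy proportional to the shared component
        alpha = config.confounder_effect * u
    if config.pleiotropy != "none" and config.pleiotropy_fraction < 1.0:
        m = int(round(config.pleiotropy_fraction * n_lead))
        carriers = rng_pleio.choice(n_lead, size=m, replace=False)
        mask = np.zeros(n_lead, dtype=bool)
        mask[carriers] = True
        alpha = np.where(mask, alpha, 0.0)

    Gamma = config.theta * gamma + alpha
    rsids = [f"rs{i + 1}" for i in range(n_lead)]
    block = list(range(n_lead))
    is_reverse = [False] * n_lead

    # reverse-causal SNPs: effect originates in the outcome trait
    if config.n_reverse_snps:
        m = config.n_reverse_snps
        maf_r = rng_rev.uniform(*config.maf_range, size=m)
        var_r = 2 * maf_r * (1 - maf_r)
        k_term = 1.0
        if config.outcome_is_binary:
            k = config.outcome_ncase / config.outcome_total_n
            k_term = k * (1 - k)
        G_r = rng_rev.choice([-1, 1], size=m) * np.sqrt(
            config.reverse_r2_outcome / (var_r * k_term))
        g_r = np.sign(G_r) * np.sqrt(config.reverse_r2_exposure / var_r)
        maf = np.concatenate([maf, maf_r])
        gamma = np.concatenate([gamma, g_r])
        Gamma = np.concatenate([Gamma, G_r])
        alpha = np.concatenate([alpha, np.zeros(m)])
        rsids += [f"rs_rev{i + 1}" for i in range(m)]
        block += list(range(n_lead, n_lead + m))
        is_reverse += [True] * m

    # LD satellites around each lead SNP
    ld = LDReference()
    if config.ld_block_size > 1:
        r = np.sqrt(config.ld_within_r2)
        sat_maf, sat_gamma, sat_Gamma, sat_alpha = [], [], [], []
        sat_rsids, sat_block = [], []
        for i, lead in enumerate(list(rsids)):
            for s in range(1, config.ld_block_size):
                sid = f"{lead}_sat{s}"
                sat_rsids.append(sid)
                sat_maf.append(maf[i])
                sat_gamma.append(r * gamma[i])
                sat_Gamma.append(r * Gamma[i])
                sat_alpha.append(0.0)
                sat_block.append(block[i])
                ld.set_r2(lead, sid, config.ld_within_r2)
            sats = [f"{lead}_sat{s}" for s in range(1, config.ld_block_size)]
            for a_i in range(len(sats)):
                for b_i in range(a_i + 1, len(sats)):
                    ld.set_r2(sats[a_i], sats[b_i], config.ld_within_r2)
        maf = np.concatenate([maf, sat_maf])
        gamma = np.concatenate([gamma, sat_gamma])
        Gamma = np.concatenate([Gamma, sat_Gamma])
        alpha = np.concatenate([alpha, sat_alpha])
        rsids += sat_rsids
        block += sat_block
        is_reverse += [False] * len(sat_rsids)

    maf = np.asarray(maf)
    var_g = 2 * maf * (1 - maf)
    se_x = _se_exposure(maf, config.exposure_n)
    se_y = _se_outcome(maf, config)
    gamma_hat = gamma + rng_noise_x.normal(0.0, se_x)
    Gamma_hat = Gamma + rng_noise_y.normal(0.0, se_y)

    from scipy import stats as _st
    tiny = np.finfo(float).tiny
    p_x = np.maximum(2 * _st.norm.sf(np.abs(gamma_hat / se_x)), tiny)
    p_y = np.maximum(2 * _st.norm.sf(np.abs(Gamma_hat / se_y)), tiny)

    k_term = 1.0
    if config.outcome_is_binary:
        k = config.outcome_ncase / config.outcome_total_n
        k_term = k * (1 - k)
    r2_x_true = var_g * gamma ** 2
    r2_y_true = var_g * Gamma ** 2 * (k_term if config.outcome_is_binary else 1.0)

    n_all = len(rsids)
    common = {
        "rsid": rsids,
        "chrom": ["1"] * n_all,
        "pos": np.arange(1, n_all + 1) * 100_000,
        "effect_allele": [_ALLELES[0]] * n_all,
        "other_allele": [_ALLELES[1]] * n_all,
        "eaf": maf,  # effect allele is the minor allele by construction
    }
    exposure = SummaryDataset(
        config.exposure_name, "continuous",
        pd.DataFrame({**common, "beta": gamma_hat, "se": se_x, "pvalue": p_x,
                      "n": float(config.exposure_n)}),
        provenance="clockmr synthetic generator")
    out_cols = {**common, "beta": Gamma_hat, "se": se_y, "pvalue": p_y,
                "n": config.outcome_total_n}
    if config.outcome_is_binary:
        out_cols["ncase"] = float(config.outcome_ncase)
        out_cols["ncontrol"] = float(config.outcome_ncontrol)
    outcome = SummaryDataset(
        config.outcome_name,
        "binary" if config.outcome_is_binary else "continuous",
        pd.DataFrame(out_cols),
        provenance="clockmr synthetic generator")

    truth = TruthRecord(
        config=config, theta=config.theta,
        table=pd.DataFrame({
            "rsid": rsids, "maf": maf, "gamma_true": gamma,
            "Gamma_true": Gamma, "alpha_pleio": alpha,
            "r2_exposure": r2_x_true, "r2_outcome": r2_y_true,
            "is_reverse": is_reverse, "block": block,
        }))
    return exposure, outcome, ld, truth


def simulated_instruments(exposure: SummaryDataset, outcome: SummaryDataset
                          ) -> pd.DataFrame:
    """Fast path from a simulated pair to an instrument table.

    The generator emits both datasets on the same effect allele, so the
    harmonisation step is the identity; this merge skips it for tight
    replicate loops. Use :func:`clockmr.sumstats.harmonise` for anything
    not produced by the generator.
    """
    e = exposure.table[["rsid", "beta", "se", "eaf"]].rename(
        columns={"beta": "gamma", "se": "se_gamma", "eaf": "eaf_exposure"})
    o = outcome.table[["rsid", "beta", "se", "eaf"]].rename(
        columns={"beta": "Gamma", "se": "se_Gamma", "eaf": "eaf_outcome"})
    return e.merge(o, on="rsid")


def scenario_presets(seed: int = 0, cancer: str = "colorectal",
                     theta: float = 0.0) -> dict[str, SimulationConfig]:
    """Named configurations mirroring the study's exposure instruments.

    One preset per clock, each with the clock's instrument count and
    total variance explained, the exposure GWAS sample size, and the
    pooled case/control totals of the chosen cancer meta-analysis
    (colorectal by default, which pools GECCO and FinnGen). Two extra
    presets exercise directionality logic: ``mediation-chain`` (a
    continuous downstream outcome, all instruments valid) and
    ``reverse-adversarial`` (two planted reverse-causal SNPs).
    """
    ncase, ncontrol = studies.meta_totals(cancer)
    presets = {}
    for clock, label in [("HannumAge", "hannum-like"),
                         ("IntrinsicHorvathAge", "horvath-like"),
                         ("PhenoAge", "phenoage-like"),
                         ("GrimAge", "grimage-like")]:
        presets[label] = SimulationConfig(
            n_snps=studies.CLOCK_N_SNPS[clock],
            target_r2_total=studies.CLOCK_R2[clock],
            seed=seed, exposure_n=studies.EXPOSURE_N,
            outcome_ncase=ncase, outcome_ncontrol=ncontrol, theta=theta,
            exposure_name=f"{label} exposure", outcome_name=f"{cancer} (synthetic)")
    presets["mediation-chain"] = SimulationConfig(
        n_snps=10, target_r2_total=0.02, seed=seed,
        exposure_n=studies.EXPOSURE_N, outcome_n=100_000, theta=0.3,
        exposure_name="mediation exposure", outcome_name="mediation outcome")
    presets["reverse-adversarial"] = SimulationConfig(
        n_snps=10, target_r2_total=0.02, seed=seed,
        exposure_n=studies.EXPOSURE_N, outcome_n=100_000, theta=0.3,
        n_reverse_snps=2,
        exposure_name="adversarial exposure", outcome_name="adversarial outcome")
    return presets
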