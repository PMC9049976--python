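"""Orchestration of the full MR study design.

`run_pair` takes one exposure and one outcome GWAS through the whole
instrument workflow (significance selection, LD clumping, proxy
substitution, harmonisation, strength diagnostics) and runs the main IVW
analysis plus the sensitivity suite. `run_bidirectional` analyses both
causal directions with Steiger directionality testing and a
Steiger-filtered re-run. `run_study` executes a declarative
:class:`AnalysisPlan` — every exposure against every outcome source,
fixed-effect meta-analysis over configured per-outcome study groups
(with overlap exclusions such as colorectal dropping UK Biobank), and
Benjamini-Hochberg FDR over the main-analysis family. Negative-control
and risk-factor outcomes are ordinary plan entries handled by the same
machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from clockmr.errors import ConfigError, DataError, InsufficientInstrumentsError
from clockmr.sumstats import SummaryDataset, harmonise, read_sumstats, retained
from clockmr.instruments import (
    LDReference, build_instrument_set, clump, select_significant,
    substitute_proxies,
)
from clockmr.estimators import (
    MREstimate, SteigerResult, TraitMeta, egger, ivw, single_snp_and_loo,
    steiger, weighted_median, weighted_mode,
)
from clockmr.meta import MetaResult, bh_fdr, meta_fixed

logger = logging.getLogger(__name__)


@dataclass
class Settings:
    """Thresholds and seeds shared by all pipeline stages."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    proxy_r2: float = 0.8
    palindromic_maf: float = 0.3
    fdr_alpha: float = 0.05
    fdr_family_size: int = 20
    ivw_mode: str = "multiplicative_random"
    n_boot: int = 1000
    seed: int = 0
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median", "weighted_mode")


@dataclass
class PairResult:
    """Everything one exposure/outcome analysis produced."""

    exposure: str
    outcome: str
    estimates: list[MREstimate] = field(default_factory=list)
    harmonised: Optional[pd.DataFrame] = None
    per_snp: Optional[pd.DataFrame] = None
    loo: Optional[pd.DataFrame] = None
    stage_counts: dict = field(default_factory=dict)
    proxies: dict = field(default_factory=dict)
    weak_instruments: list[str] = field(default_factory=list)
    r2_total: float = float("nan")
    skip_reason: Optional[str] = None

    @property
    def main(self) -> Optional[MREstimate]:
        for est in self.estimates:
            if est.method.startswith("ivw") or est.method == "wald":
                return est
        return None


def _derive_meta(ds: SummaryDataset) -> TraitMeta:
    t = ds.table
    n = float(np.nanmedian(t["n"])) if t["n"].notna().any() else float("nan")
    ncase = float(np.nanmedian(t["ncase"])) if t["ncase"].notna().any() else None
    nctrl = float(np.nanmedian(t["ncontrol"])) if t["ncontrol"].notna().any() else None
    return TraitMeta(ds.trait_type, n, ncase, nctrl)


def _run_estimators(insts: pd.DataFrame, settings: Settings) -> list[MREstimate]:
    k = len(insts)
    out: list[MREstimate] = []
    out.append(ivw(insts, mode=settings.ivw_mode))
    if k >= 3:
        if "egger" in settings.methods:
            out.append(egger(insts))
        if "weighted_median" in settings.methods:
            out.append(weighted_median(insts, n_boot=settings.n_boot,
                                       random_state=settings.seed))
        if "weighted_mode" in settings.methods:
            out.append(weighted_mode(insts, n_boot=settings.n_boot,
                                     random_state=settings.seed))
    return out


def run_pair(exposure: SummaryDataset, outcome: SummaryDataset,
             ld: LDReference, settings: Settings | None = None) -> PairResult:
    """Full instrument workflow and estimator suite for one trait pair."""
    settings = settings or Settings()
    res = PairResult(exposure=exposure.trait_name, outcome=outcome.trait_name)
    counts = res.stage_counts

    sig = select_significant(exposure, settings.p_threshold)
    counts["significant"] = len(sig)
    if len(sig) == 0:
        res.skip_reason = "no genome-wide-significant instruments"
        return res

    clumped = clump(sig, ld, settings.clump_r2)
    counts["clumped"] = len(clumped)

    out_rsids = set(outcome.rsids)
    missing = [r for r in clumped if r not in out_rsids]
    counts["missing_from_outcome"] = len(missing)
    proxies = substitute_proxies(missing, outcome, ld, settings.proxy_r2)
    # a proxy is usable only if the exposure GWAS also contains it
    exp_rsids = set(exposure.rsids)
    usable = {k: v for k, v in proxies.items() if v in exp_rsids}
    res.proxies = usable
    counts["proxied"] = len(usable)
    instrument_rsids = [r for r in clumped if r in out_rsids] + list(usable.values())
    counts["dropped_unproxied"] = len(missing) - len(usable)
    if not instrument_rsids:
        res.skip_reason = "no instruments present in outcome (no proxies found)"
        return res

    harm = harmonise(exposure.subset(instrument_rsids),
                     outcome.subset(instrument_rsids),
                     settings.palindromic_maf)
    res.harmonised = harm
    kept = retained(harm)
    counts["harmonised_retained"] = len(kept)
    counts["harmonised_excluded"] = int(harm["excluded"].sum())
    if kept.empty:
        res.skip_reason = "all instruments excluded during harmonisation"
        return res

    try:
        iset = build_instrument_set(exposure.subset(list(kept["rsid"])))
        res.weak_instruments = iset.weak()
        res.r2_total = iset.r2_total
    except DataError:
        logger.info("instrument strength unavailable (missing eaf or n)")

    res.estimates = _run_estimators(kept, settings)
    if len(kept) >= 2:
        res.per_snp, res.loo = single_snp_and_loo(kept, mode=settings.ivw_mode)
    return res


@dataclass
class BidirectionalResult:
    forward: PairResult
    reverse: PairResult
    steiger_forward: Optional[SteigerResult]
    steiger_reverse: Optional[SteigerResult]
    forward_filtered: Optional[PairResult]
    reverse_filtered: Optional[PairResult]


def _steiger_and_filter(pair: PairResult, exposure: SummaryDataset,
                        outcome: SummaryDataset, settings: Settings
                        ) -> tuple[Optional[SteigerResult], Optional[PairResult]]:
    if pair.skip_reason or pair.harmonised is None:
        return None, None
    kept = retained(pair.harmonised)
    try:
        st = steiger(kept, _derive_meta(exposure), _derive_meta(outcome))
    except DataError as err:
        logger.info("Steiger unavailable: %s", err)
        return None, None
    filtered = kept[kept["rsid"].isin(set(st.retained))]
    fres = PairResult(exposure=pair.exposure, outcome=pair.outcome,
                      harmonised=filtered,
                      stage_counts={"steiger_retained": len(filtered)})
    if filtered.empty:
        fres.skip_reason = "no instruments survive Steiger filtering"
    else:
        fres.estimates = _run_estimators(filtered, settings)
    return st, fres


def run_bidirectional(trait_a: SummaryDataset, trait_b: SummaryDataset,
                      ld: LDReference, settings: Settings | None = None
                      ) -> BidirectionalResult:
    """A->B and B->A analyses with Steiger tests and filtered re-runs."""
    settings = settings or Settings()
    fwd = run_pair(trait_a, trait_b, ld, settings)
    rev = run_pair(trait_b, trait_a, ld, settings)
    st_f, fwd_filt = _steiger_and_filter(fwd, trait_a, trait_b, settings)
    st_r, rev_filt = _steiger_and_filter(rev, trait_b, trait_a, settings)
    return BidirectionalResult(fwd, rev, st_f, st_r, fwd_filt, rev_filt)


# ---------------------------------------------------------------------------
# study plans


@dataclass
class OutcomeSpec:
    name: str  # outcome trait, e.g. "colorectal"
    source: str  # study source, e.g. "GECCO"
    path: str
    trait_type: str = "binary"
    column_map: dict = field(default_factory=dict)


@dataclass
class ExposureSpec:
    name: str
    path: str
    column_map: dict = field(default_factory=dict)


@dataclass
class AnalysisPlan:
    """Declarative description of a full study run."""

    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    meta_groups: dict[str, list[str]] = field(default_factory=dict)
    negative_controls: list[str] = field(default_factory=list)
    risk_factors: list[str] = field(default_factory=list)
    ld_path: Optional[str] = None
    settings: Settings = field(default_factory=Settings)

    def __post_init__(self) -> None:
        declared = {(o.name, o.source) for o in self.outcomes}
        names = {o.name for o in self.outcomes}
        for name, sources in self.meta_groups.items():
            if name not in names:
                raise ConfigError(f"meta group {name!r} references an undeclared outcome")
            for s in sources:
                if (name, s) not in declared:
                    raise ConfigError(
                        f"meta group {name!r} references undeclared source {s!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisPlan":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            exposures=[ExposureSpec(**e) for e in d.get("exposures", [])],
            outcomes=[OutcomeSpec(**o) for o in d.get("outcomes", [])],
            meta_groups=d.get("meta_groups", {}),
            negative_controls=d.get("negative_controls", []),
            risk_factors=d.get("risk_factors", []),
            ld_path=d.get("ld_path"),
            settings=Settings(**d.get("settings", {})),
        )

    def to_yaml(self, path) -> None:
        d = {
            "exposures": [asdict(e) for e in self.exposures],
            "outcomes": [asdict(o) for o in self.outcomes],
            "meta_groups": self.meta_groups,
            "negative_controls": self.negative_controls,
            "risk_factors": self.risk_factors,
            "ld_path": self.ld_path,
            "settings": {**asdict(self.settings),
                         "methods": list(self.settings.methods)},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class AnalysisReport:
    """All tables a study run produces."""

    per_study: pd.DataFrame  # exposure, outcome, source, method, estimate cols
    pooled: pd.DataFrame  # per (exposure, outcome) meta rows with q-values
    forest: pd.DataFrame  # long format: OR scale with CIs, p, q
    pair_results: dict = field(default_factory=dict)
    failures: list[dict] = field(default_factory=list)

    def consistent_pooling(self) -> bool:
        """Re-derive every pooled row from the per-study rows it echoes."""
        for _, row in self.pooled.iterrows():
            res = meta_fixed(row["study_betas"], row["study_ses"])
            if not np.isclose(res.beta, row["beta"], atol=1e-12):
                return False
        return True


def run_study(plan: AnalysisPlan) -> AnalysisReport:
    """Execute a full analysis plan; failures are collected, not raised."""
    settings = plan.settings
    ld = (LDReference.from_long_format(plan.ld_path)
          if plan.ld_path else LDReference())

    exposures = {
        e.name: read_sumstats(e.path, trait_name=e.name,
                              trait_type="continuous", column_map=e.column_map)
        for e in plan.exposures}
    outcomes = [
        (o, read_sumstats(o.path, trait_name=f"{o.name} ({o.source})",
                          trait_type=o.trait_type, column_map=o.column_map))
        for o in plan.outcomes]

    rows = []
    pair_results = {}
    failures = []
    for exp_name, exp_ds in exposures.items():
        for spec, out_ds in outcomes:
            try:
                pr = run_pair(exp_ds, out_ds, ld, settings)
            except (DataError, InsufficientInstrumentsError) as err:
                failures.append({"exposure": exp_name, "outcome": spec.name,
                                 "source": spec.source, "error": str(err)})
                continue
            pair_results[(exp_name, spec.name, spec.source)] = pr
            if pr.skip_reason:
                failures.append({"exposure": exp_name, "outcome": spec.name,
                                 "source": spec.source, "error": pr.skip_reason})
                continue
            for est in pr.estimates:
                rows.append({"exposure": exp_name, "outcome": spec.name,
                             "source": spec.source, **est.to_dict()})
    per_study = pd.DataFrame(rows)

    # fixed-effect meta over configured groups (default: all sources present)
    pooled_rows = []
    if not per_study.empty:
        main = per_study[per_study["method"].str.startswith(("ivw", "wald"))]
        for (exp_name, out_name), grp in main.groupby(["exposure", "outcome"]):
            sources = plan.meta_groups.get(out_name, sorted(grp["source"]))
            sub = grp[grp["source"].isin(sources)]
            if sub.empty:
                continue
            res = meta_fixed(sub["beta"].to_numpy(), sub["se"].to_numpy())
            pooled_rows.append({
                "exposure": exp_name, "outcome": out_name,
                "sources": list(sub["source"]), "beta": res.beta, "se": res.se,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "pvalue": res.pvalue, "k_studies": res.k, "I2": res.I2,
                "I2_ci_low": res.I2_ci_low, "I2_ci_high": res.I2_ci_high,
                "Q": res.Q, "Q_df": res.Q_df, "Q_p": res.Q_p,
                "study_betas": res.study_betas, "study_ses": res.study_ses,
            })
    pooled = pd.DataFrame(pooled_rows)

    # BH-FDR over the main family (negative controls / risk factors excluded)
    if not pooled.empty:
        extra = set(plan.negative_controls) | set(plan.risk_factors)
        in_family = ~pooled["outcome"].isin(extra)
        q = np.full(len(pooled), np.nan)
        flag = np.zeros(len(pooled), dtype=bool)
        if in_family.any():
            qv, fl = bh_fdr(pooled.loc[in_family, "pvalue"].to_numpy(),
                            m=settings.fdr_family_size, alpha=settings.fdr_alpha)
            q[in_family.to_numpy()] = qv
            flag[in_family.to_numpy()] = fl
        pooled["q_value"] = q
        pooled["fdr_discovery"] = flag

    forest_rows = []
    for _, row in pooled.iterrows():
        forest_rows.append({
            "exposure": row["exposure"], "outcome": row["outcome"],
            "method": "ivw_meta", "or": float(np.exp(row["beta"])),
            "ci_low": float(np.exp(row["ci_low"])),
            "ci_high": float(np.exp(row["ci_high"])),
            "pvalue": row["pvalue"], "q_value": row["q_value"],
        })
    forest = pd.DataFrame(forest_rows)

    return AnalysisReport(per_study=per_study, pooled=pooled, forest=forest,
                          pair_results=pair_results, failures=failures)
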