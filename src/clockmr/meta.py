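"""Fixed-effect meta-analysis, per-SNP GWAS meta-analysis, and FDR control.

MR estimates obtained from several outcome GWAS of the same cancer (UK
Biobank, FinnGen, consortium data) are pooled with inverse-variance
fixed-effect meta-analysis. Between-study heterogeneity is summarised by
Cochran's Q and I-squared with a test-based confidence interval on the
ln(H) scale. The per-SNP variant pools whole outcome GWAS row by row,
producing a meta-analysed summary dataset that feeds single-SNP MR.
Multiplicity over the main analysis family is controlled with the
Benjamini-Hochberg step-up procedure at a configured family size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from clockmr.errors import DataError
from clockmr.sumstats import SummaryDataset, harmonise

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MetaResult:
    """Fixed-effect pooled estimate with heterogeneity diagnostics."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    k: int
    I2: float
    I2_ci_low: float | None
    I2_ci_high: float | None
    Q: float
    Q_df: int
    Q_p: float
    study_betas: list[float] = field(default_factory=list)
    study_ses: list[float] = field(default_factory=list)


def _i2_ci(Q: float, k: int) -> tuple[float | None, float | None]:
    """Test-based CI for I2 on the ln(H) scale (Higgins & Thompson).

    Returns (None, None) for k <= 2, where the se of ln(H) is undefined
    and the interval is conventionally reported as unavailable.
    """
    if k <= 2:
        return None, None
    if Q > k:
        se_ln_h = (np.log(Q) - np.log(k - 1)) / (2 * (np.sqrt(2 * Q) - np.sqrt(2 * k - 3)))
    else:
        se_ln_h = np.sqrt(1 / (2 * (k - 2)) * (1 - 1 / (3 * (k - 2) ** 2)))
    ln_h = 0.5 * max(0.0, np.log(Q / (k - 1)))
    lo_h = np.exp(max(0.0, ln_h - Z95 * se_ln_h))
    hi_h = np.exp(max(0.0, ln_h + Z95 * se_ln_h))
    to_i2 = lambda h: float(100 * (h ** 2 - 1) / h ** 2) if h > 1 else 0.0
    return to_i2(lo_h), to_i2(hi_h)


def meta_fixed(betas, ses) -> MetaResult:
    """Inverse-variance fixed-effect pooling of per-study estimates.

    All inputs must be on a common (log-OR) scale. With a single study
    the pooled estimate is that study's. I2 = max(0, (Q - df) / Q) * 100.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise DataError("meta_fixed needs at least one study")
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise DataError("study standard errors must be positive and finite")
    w = 1.0 / s ** 2
    pooled = float(np.sum(w * b) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    k = int(b.size)
    if k >= 2:
        Q = float(np.sum(w * (b - pooled) ** 2))
        q_df = k - 1
        q_p = float(stats.chi2.sf(Q, q_df))
        I2 = float(max(0.0, (Q - q_df) / Q) * 100) if Q > 0 else 0.0
    else:
        Q, q_df, q_p, I2 = 0.0, 0, 1.0, 0.0
    lo, hi = _i2_ci(Q, k)
    p = float(2 * stats.norm.sf(abs(pooled / se)))
    return MetaResult(
        beta=pooled, se=se, ci_low=pooled - Z95 * se, ci_high=pooled + Z95 * se,
        pvalue=p, k=k, I2=I2, I2_ci_low=lo, I2_ci_high=hi,
        Q=Q, Q_df=q_df, Q_p=q_p,
        study_betas=list(map(float, b)), study_ses=list(map(float, s)),
    )


def meta_per_snp(datasets: list[SummaryDataset],
                 palindromic_maf_threshold: float = 0.3) -> SummaryDataset:
    """Per-variant fixed-effect meta-analysis of whole outcome GWAS.

    Datasets after the first are allele-aligned against the first with
    :func:`~clockmr.sumstats.harmonise`; variants whose alleles cannot be
    reconciled in some dataset are dropped from the pooled output (and
    logged). Sample sizes
    are summed. The result uses the first dataset's alleles and eaf and
    can be fed straight back into the pipeline as an outcome.
    """
    if not datasets:
        raise DataError("meta_per_snp needs at least one dataset")
    first = datasets[0]
    if len(datasets) == 1:
        return first
    ref = first.table.set_index("rsid")

    # per-rsid lists of (beta, se); counts
    contrib: dict[str, list[tuple[float, float]]] = {
        r: [(row["beta"], row["se"])] for r, row in ref.iterrows()}
    n_sum = {r: (row["n"] if pd.notna(row["n"]) else 0.0) for r, row in ref.iterrows()}
    ncase_sum = {r: (row["ncase"] if pd.notna(row["ncase"]) else 0.0)
                 for r, row in ref.iterrows()}
    nctrl_sum = {r: (row["ncontrol"] if pd.notna(row["ncontrol"]) else 0.0)
                 for r, row in ref.iterrows()}

    dropped: set[str] = set()
    for ds in datasets[1:]:
        harm = harmonise(first, ds, palindromic_maf_threshold)
        ds_idx = ds.table.set_index("rsid")
        for _, row in harm.iterrows():
            if row["excluded"]:
                dropped.add(row["rsid"])
                continue
            r = row["rsid"]
            contrib[r].append((row["Gamma"], row["se_Gamma"]))
            extra = ds_idx.loc[r]
            for key, store in (("n", n_sum), ("ncase", ncase_sum),
                               ("ncontrol", nctrl_sum)):
                if pd.notna(extra[key]):
                    store[r] += float(extra[key])

    if dropped:
        import logging
        logging.getLogger(__name__).info(
            "meta_per_snp: dropped %d rsid(s) with irreconcilable alleles: %s",
            len(dropped), sorted(dropped))
    rows = []
    for r, pairs in contrib.items():
        if r in dropped:
            continue
        b = np.array([p[0] for p in pairs])
        s = np.array([p[1] for p in pairs])
        w = 1.0 / s ** 2
        pooled = float(np.sum(w * b) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
        p = float(2 * stats.norm.sf(abs(pooled / se)))
        base = ref.loc[r]
        rows.append({
            "rsid": r, "chrom": base["chrom"], "pos": base["pos"],
            "effect_allele": base["effect_allele"],
            "other_allele": base["other_allele"],
            "eaf": base["eaf"], "beta": pooled, "se": se,
            "pvalue": max(p, np.finfo(float).tiny),
            "n": n_sum[r] or np.nan,
            "ncase": ncase_sum[r] or np.nan,
            "ncontrol": nctrl_sum[r] or np.nan,
        })
    name = first.trait_name + " (meta)"
    prov = " + ".join(d.provenance or d.trait_name for d in datasets)
    return SummaryDataset(name, first.trait_type, pd.DataFrame(rows), prov)


def bh_fdr(pvalues, m: int | None = None, alpha: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and discovery flags.

    ``m`` is the configured family size (defaults to the number of
    p-values supplied); using a fixed family keeps partial runs
    comparable to the full design. Returns (q_values, discovery_flags)
    in the input order, with q_i = min_{j >= i} m p_(j) / j capped at 1
    and discoveries flagged at q < alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p <= 0) | np.any(p > 1) or not np.all(np.isfinite(p))):
        raise DataError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise DataError(f"family size m={m} smaller than the {p.size} p-values supplied")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q, q < alpha
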