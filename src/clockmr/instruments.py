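"""Instrument selection and strength diagnostics.

Instruments are SNPs robustly associated with the exposure. Selection
follows the standard recipe: keep genome-wide-significant variants
(p < 5e-8), prune them to approximate independence by greedy LD clumping
(pairwise r-squared below 0.001, most significant SNP kept per cluster),
and, when an instrument is missing from the outcome GWAS, substitute a
strongly correlated proxy (r-squared above 0.8). Instrument strength is
summarised by the per-SNP variance explained

    r2 = 2 b^2 p(1-p) / (2 b^2 p(1-p) + 2 N p(1-p) se^2)

(p the minor-allele frequency) and the F-statistic
F = r2 (N-2) / (1 - r2); F > 10 is the conventional weak-instrument bar.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from clockmr.errors import DataError
from clockmr.sumstats import SummaryDataset

logger = logging.getLogger(__name__)


class LDReference:
    """Pairwise r-squared lookup over a set of rsids.

    Backed by a dict keyed on sorted rsid pairs. Absent pairs are treated
    as independent (r2 = 0) with a one-time warning, since local
    references are typically sparse.
    """

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        self._warned = False
        for (a, b), v in (pairs or {}).items():
            self.set_r2(a, b, v)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise DataError(f"r2({a},{b}) = {r2} outside [0, 1]")
        if a == b and r2 != 1.0:
            raise DataError(f"diagonal r2({a},{a}) must be 1")
        if a != b:
            self._r2[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        val = self._r2.get(self._key(a, b))
        if val is None:
            if not self._warned:
                warnings.warn(
                    f"LD pair ({a}, {b}) absent from reference; treating absent "
                    "pairs as r2 = 0 (independent)",
                    stacklevel=2,
                )
                self._warned = True
            return 0.0
        return val

    def known(self, a: str, b: str) -> bool:
        return a == b or self._key(a, b) in self._r2

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_long_format(cls, path, sep: str = "\t") -> "LDReference":
        """Read (rsid_a, rsid_b, r2) rows from delimited text."""
        df = pd.read_csv(path, sep=sep)
        cols = {c.lower(): c for c in df.columns}
        ref = cls()
        for _, row in df.iterrows():
            ref.set_r2(str(row[cols["rsid_a"]]), str(row[cols["rsid_b"]]),
                       float(row[cols["r2"]]))
        return ref

    @classmethod
    def from_matrix(cls, matrix: pd.DataFrame) -> "LDReference":
        """Build from a square r2 matrix with rsids as index and columns."""
        m = matrix.to_numpy(dtype=float)
        if not np.allclose(m, m.T, atol=1e-8):
            raise DataError("LD matrix is not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise DataError("LD matrix diagonal must be 1")
        ref = cls()
        ids = [str(i) for i in matrix.index]
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                ref.set_r2(a, ids[j], m[i, j])
        return ref

    def to_long_format(self, path, sep: str = "\t") -> None:
        rows = [{"rsid_a": a, "rsid_b": b, "r2": v}
                for (a, b), v in sorted(self._r2.items())]
        pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"]).to_csv(
            path, sep=sep, index=False)


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure with strength diagnostics."""

    trait_name: str
    table: pd.DataFrame  # variant rows plus r2_j, F_j columns
    r2_total: float = 0.0
    f_median: float = float("nan")
    f_min: float = float("nan")
    f_max: float = float("nan")

    @property
    def rsids(self) -> list[str]:
        return list(self.table["rsid"])

    def weak(self) -> list[str]:
        """rsids of instruments failing the conventional F > 10 bar."""
        return list(self.table.loc[self.table["F_j"] <= 10, "rsid"])


def select_significant(dataset: SummaryDataset, p_threshold: float = 5e-8) -> SummaryDataset:
    """Keep variants with p-value strictly below the significance threshold."""
    keep = dataset.table[dataset.table["pvalue"] < p_threshold]
    if keep.empty:
        logger.info("select_significant: no variants below p < %g in %s",
                    p_threshold, dataset.trait_name)
    return SummaryDataset(dataset.trait_name, dataset.trait_type, keep,
                          dataset.provenance)


def _clump_order(df: pd.DataFrame) -> pd.DataFrame:
    # ascending p; ties by larger |beta/se|, then lexicographic rsid
    z = (df["beta"] / df["se"]).abs()
    return df.assign(_z=z).sort_values(
        ["pvalue", "_z", "rsid"], ascending=[True, False, True]
    ).drop(columns="_z")


def clump(candidates: SummaryDataset, ld: LDReference,
          r2_threshold: float = 0.001) -> list[str]:
    """Greedy LD clumping: accept variants in order of significance.

    Candidates are visited by ascending p-value (ties: larger |z|, then
    rsid); a candidate is accepted iff its r2 with every already-accepted
    variant is strictly below ``r2_threshold``. Deterministic in the input
    and invariant to row order.
    """
    accepted: list[str] = []
    for _, row in _clump_order(candidates.table).iterrows():
        rsid = row["rsid"]
        if all(ld.r2(rsid, kept) < r2_threshold for kept in accepted):
            accepted.append(rsid)
    return accepted


def substitute_proxies(missing: list[str], outcome: SummaryDataset,
                       ld: LDReference, r2_min: float = 0.8) -> dict[str, str]:
    """Map missing instruments to their best available LD proxy.

    For each missing rsid, the outcome variant with maximal r2 subject to
    r2 strictly greater than ``r2_min`` is chosen; ties are broken by
    smaller outcome p-value, then lexicographic rsid. Instruments with no
    admissible proxy get no mapping.
    """
    out = outcome.table.set_index("rsid")
    mapping: dict[str, str] = {}
    for rsid in missing:
        best = None
        for cand in out.index:
            r2 = ld.r2(rsid, cand)
            if r2 <= r2_min:
                continue
            key = (-r2, out.loc[cand, "pvalue"], cand)
            if best is None or key < best[0]:
                best = (key, cand)
        if best is not None:
            mapping[rsid] = best[1]
        else:
            logger.info("no LD proxy (r2 > %g) found for %s", r2_min, rsid)
    return mapping


def instrument_strength(snp, n: float | None = None) -> tuple[float, float]:
    """Per-SNP variance explained and F-statistic.

    ``snp`` is any object with ``beta``, ``se``, ``eaf`` attributes (a
    :class:`~clockmr.sumstats.VariantAssociation` or a table row); sample
    size is taken from ``snp.n`` unless overridden. MAF is
    min(eaf, 1 - eaf). Raises :class:`DataError` when eaf or n is missing.
    """
    beta, se, eaf = snp.beta, snp.se, snp.eaf
    n = n if n is not None else getattr(snp, "n", None)
    if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)):
        raise DataError(f"{snp.rsid}: eaf required for instrument strength")
    if n is None or (isinstance(n, float) and np.isnan(n)):
        raise DataError(f"{snp.rsid}: sample size required for instrument strength")
    if not (0 < eaf < 1):
        raise DataError(f"{snp.rsid}: eaf must lie in (0, 1)")
    maf = min(eaf, 1 - eaf)
    var_g = 2 * maf * (1 - maf)
    r2 = (var_g * beta ** 2) / (var_g * beta ** 2 + n * var_g * se ** 2)
    f = r2 * (n - 2) / (1 - r2)
    return float(r2), float(f)


def build_instrument_set(selected: SummaryDataset, rsids: list[str] | None = None,
                         n: float | None = None) -> InstrumentSet:
    """Assemble an :class:`InstrumentSet` with per-SNP r2 and F columns."""
    df = selected.table
    if rsids is not None:
        df = df[df["rsid"].isin(set(rsids))]
    df = df.reset_index(drop=True).copy()
    strengths = [instrument_strength(row, n=n) for row in df.itertuples()]
    df["r2_j"] = [s[0] for s in strengths]
    df["F_j"] = [s[1] for s in strengths]
    fs = df["F_j"].to_numpy()
    weak = df.loc[df["F_j"] <= 10, "rsid"].tolist()
    if weak:
        logger.warning("weak instruments (F <= 10): %s", weak)
    return InstrumentSet(
        trait_name=selected.trait_name,
        table=df,
        r2_total=float(df["r2_j"].sum()),
        f_median=float(np.median(fs)) if len(fs) else float("nan"),
        f_min=float(fs.min()) if len(fs) else float("nan"),
        f_max=float(fs.max()) if len(fs) else float("nan"),
    )
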