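"""GWAS summary-statistic containers, I/O, and allele harmonisation.

Two-sample MR combines per-variant effect estimates from an exposure GWAS
with those from an outcome GWAS. Before any estimator can run, both sets
of associations must refer to the same effect allele at every variant.
This module provides the data model (:class:`VariantAssociation`,
:class:`SummaryDataset`), delimited-text readers/writers with a
column-name mapping for the many GWAS file dialects, and
:func:`harmonise`, which aligns effect alleles between two datasets,
resolving strand flips where possible and excluding palindromic variants
whose orientation cannot be established from allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from clockmr.errors import ConfigError, DataError

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order used by readers/writers
CANONICAL_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n", "ncase", "ncontrol",
]

MANDATORY_COLUMNS = ["rsid", "effect_allele", "other_allele", "beta", "se", "pvalue"]

#: fixed output column order for harmonised instrument tables
HARMONISED_COLUMNS = [
    "rsid", "effect_allele", "other_allele",
    "gamma", "se_gamma", "Gamma", "se_Gamma",
    "eaf_exposure", "eaf_outcome",
    "palindromic", "flipped", "excluded", "exclusion_reason",
]


@dataclass
class VariantAssociation:
    """One variant's per-allele association with one trait.

    ``beta`` is in trait units for continuous traits and is the log odds
    ratio for binary traits. ``eaf`` is the effect-allele frequency.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None
    ncase: float | None = None
    ncontrol: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0 or not np.isfinite(self.se):
            raise DataError(f"{self.rsid}: se must be positive, got {self.se}")
        if self.effect_allele == self.other_allele:
            raise DataError(f"{self.rsid}: effect and other allele are identical")
        if not (0 < self.pvalue <= 1):
            raise DataError(f"{self.rsid}: pvalue must lie in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise DataError(f"{self.rsid}: eaf must lie in (0, 1), got {self.eaf}")
        if self.ncase is not None and self.ncontrol is not None and self.n is not None:
            if abs(self.ncase + self.ncontrol - self.n) > 0.5:
                raise DataError(f"{self.rsid}: ncase + ncontrol != n")


@dataclass
class SummaryDataset:
    """A validated GWAS summary-statistics table for one trait.

    Wraps a :class:`pandas.DataFrame` with the canonical columns; rsids
    are unique. ``trait_type`` is ``"continuous"`` or ``"binary"``.
    """

    trait_name: str
    trait_type: str
    table: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigError(f"unknown trait_type {self.trait_type!r}")
        df = self.table.copy()
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[CANONICAL_COLUMNS].reset_index(drop=True)
        df["rsid"] = df["rsid"].astype(str)
        df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
        df["other_allele"] = df["other_allele"].astype(str).str.upper()
        for col in ("eaf", "beta", "se", "pvalue", "n", "ncase", "ncontrol"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        dup = df["rsid"][df["rsid"].duplicated()]
        if len(dup):
            raise DataError(f"duplicate rsid(s): {sorted(set(dup))}")
        self._validate_rows(df)
        self.table = df

    @staticmethod
    def _validate_rows(df: pd.DataFrame) -> None:
        bad: dict[int, str] = {}
        se_bad = ~(df["se"] > 0)
        p_bad = ~((df["pvalue"] > 0) & (df["pvalue"] <= 1))
        allele_bad = df["effect_allele"] == df["other_allele"]
        eaf = df["eaf"]
        eaf_bad = eaf.notna() & ~((eaf > 0) & (eaf < 1))
        nc, nco, n = df["ncase"], df["ncontrol"], df["n"]
        count_bad = nc.notna() & nco.notna() & n.notna() & ((nc + nco - n).abs() > 0.5)
        for mask, msg in [
            (se_bad, "se must be > 0"),
            (p_bad, "pvalue must lie in (0, 1]"),
            (allele_bad, "effect_allele equals other_allele"),
            (eaf_bad, "eaf must lie in (0, 1)"),
            (count_bad, "ncase + ncontrol != n"),
        ]:
            for idx in df.index[mask]:
                bad.setdefault(int(idx) + 1, msg)  # 1-based data row number
        if bad:
            details = "; ".join(f"row {r}: {m}" for r, m in sorted(bad.items()))
            raise DataError(f"invalid rows in summary statistics: {details}")

    @property
    def rsids(self) -> pd.Index:
        return pd.Index(self.table["rsid"])

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, rsids: Iterable[str]) -> "SummaryDataset":
        keep = self.table[self.table["rsid"].isin(set(rsids))]
        return SummaryDataset(self.trait_name, self.trait_type, keep, self.provenance)

    def variants(self) -> list[VariantAssociation]:
        out = []
        for _, row in self.table.iterrows():
            out.append(VariantAssociation(
                rsid=row["rsid"], effect_allele=row["effect_allele"],
                other_allele=row["other_allele"], beta=row["beta"], se=row["se"],
                pvalue=row["pvalue"],
                chrom=None if pd.isna(row["chrom"]) else str(row["chrom"]),
                pos=None if pd.isna(row["pos"]) else int(row["pos"]),
                eaf=None if pd.isna(row["eaf"]) else float(row["eaf"]),
                n=None if pd.isna(row["n"]) else float(row["n"]),
                ncase=None if pd.isna(row["ncase"]) else float(row["ncase"]),
                ncontrol=None if pd.isna(row["ncontrol"]) else float(row["ncontrol"]),
            ))
        return out


def read_sumstats(
    path,
    trait_name: str = "",
    trait_type: str = "continuous",
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
    provenance: str = "",
) -> SummaryDataset:
    """Read delimited-text summary statistics into a :class:`SummaryDataset`.

    ``column_map`` maps canonical names to the file's header names, e.g.
    ``{"beta": "BETA", "se": "standard_error"}``; unmapped canonical names
    are looked up verbatim (case-insensitively). The delimiter is sniffed
    from the header (tab or comma) unless ``sep`` is given.

    Raises :class:`ConfigError` if a mandatory column is absent and
    :class:`DataError` for invalid rows (named by 1-based data row number)
    or duplicate rsids.
    """
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    raw = pd.read_csv(path, sep=sep)
    lower = {c.lower(): c for c in raw.columns}
    column_map = dict(column_map or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif src.lower() in lower:
            rename[lower[src.lower()]] = canon
        elif canon in MANDATORY_COLUMNS:
            raise ConfigError(f"{path}: mandatory column {canon!r} (file name {src!r}) not found")
    df = raw.rename(columns=rename)
    df = df[[c for c in CANONICAL_COLUMNS if c in df.columns]]
    name = trait_name or str(path)
    return SummaryDataset(name, trait_type, df, provenance or str(path))


def write_sumstats(dataset: SummaryDataset, path, sep: str = "\t") -> None:
    """Write a dataset as delimited text in the canonical column order."""
    df = dataset.table.copy()
    # drop all-missing optional columns so round-trips stay tidy
    keep = [c for c in CANONICAL_COLUMNS
            if c in MANDATORY_COLUMNS or df[c].notna().any()]
    df[keep].to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# harmonisation


def _is_snp(a: str, b: str) -> bool:
    return a in COMPLEMENT and b in COMPLEMENT


def _is_palindromic(a: str, b: str) -> bool:
    return _is_snp(a, b) and COMPLEMENT[a] == b


def harmonise(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindromic_maf_threshold: float = 0.3,
) -> pd.DataFrame:
    """Align outcome effect alleles to the exposure's at shared variants.

    Returns a DataFrame in the fixed :data:`HARMONISED_COLUMNS` order with
    one row per shared rsid: exposure effect ``gamma``, outcome effect
    ``Gamma`` (oriented to the exposure effect allele), and exclusion
    bookkeeping.

    Rules, applied per variant:

    * identical allele pairs: copy the outcome effect;
    * swapped allele pairs: negate the outcome beta, take 1 - eaf, flag
      ``flipped``;
    * strand-complement (or swapped complement) pairs at non-palindromic
      SNPs: complement and proceed as above;
    * palindromic SNPs (A/T, C/G): allele labels carry no strand
      information, so orientation is inferred from allele frequency —
      requires MAF strictly below ``palindromic_maf_threshold`` in *both*
      datasets; otherwise excluded (``palindromic_high_maf``). Missing
      eaf on either side makes the orientation indeterminate and the
      variant is excluded with reason ``strand_mismatch``;
    * anything else is excluded with reason ``allele_mismatch``.
    """
    exp = exposure.table.set_index("rsid")
    out = outcome.table.set_index("rsid")
    shared = [r for r in exp.index if r in out.index]
    if not shared:
        raise DataError(
            f"no shared rsids between {exposure.trait_name!r} and {outcome.trait_name!r}"
        )

    rows = []
    for rsid in shared:
        e = exp.loc[rsid]
        o = out.loc[rsid]
        ea_x, oa_x = e["effect_allele"], e["other_allele"]
        ea_y, oa_y = o["effect_allele"], o["other_allele"]
        eaf_x = e["eaf"] if pd.notna(e["eaf"]) else None
        eaf_y = o["eaf"] if pd.notna(o["eaf"]) else None
        pal = _is_palindromic(ea_x, oa_x)

        flipped = False
        excluded = False
        reason = "none"
        beta_y = o["beta"]

        if pal:
            # labels are strand-ambiguous: decide by frequency alone
            if {ea_y, oa_y} != {ea_x, oa_x}:
                excluded, reason = True, "allele_mismatch"
            elif eaf_x is None or eaf_y is None:
                excluded, reason = True, "strand_mismatch"
            else:
                maf_x = min(eaf_x, 1 - eaf_x)
                maf_y = min(eaf_y, 1 - eaf_y)
                if maf_x >= palindromic_maf_threshold or maf_y >= palindromic_maf_threshold:
                    excluded, reason = True, "palindromic_high_maf"
                elif (eaf_x < 0.5) == (eaf_y < 0.5):
                    pass  # same minor allele on the effect side: already aligned
                else:
                    flipped = True
                    beta_y = -beta_y
                    eaf_y = 1 - eaf_y
        else:
            pair = (ea_y, oa_y)
            if pair == (ea_x, oa_x):
                pass
            elif pair == (oa_x, ea_x):
                flipped, beta_y = True, -beta_y
                eaf_y = None if eaf_y is None else 1 - eaf_y
            elif _is_snp(ea_x, oa_x) and _is_snp(ea_y, oa_y):
                comp = (COMPLEMENT[ea_y], COMPLEMENT[oa_y])
                if comp == (ea_x, oa_x):
                    pass
                elif comp == (oa_x, ea_x):
                    flipped, beta_y = True, -beta_y
                    eaf_y = None if eaf_y is None else 1 - eaf_y
                else:
                    excluded, reason = True, "allele_mismatch"
            else:
                excluded, reason = True, "allele_mismatch"

        rows.append({
            "rsid": rsid,
            "effect_allele": ea_x,
            "other_allele": oa_x,
            "gamma": e["beta"],
            "se_gamma": e["se"],
            "Gamma": beta_y,
            "se_Gamma": o["se"],
            "eaf_exposure": np.nan if eaf_x is None else eaf_x,
            "eaf_outcome": np.nan if eaf_y is None else eaf_y,
            "palindromic": pal,
            "flipped": flipped,
            "excluded": excluded,
            "exclusion_reason": reason,
        })

    df = pd.DataFrame(rows, columns=HARMONISED_COLUMNS)
    n_excl = int(df["excluded"].sum())
    if n_excl:
        logger.info("harmonise: excluded %d of %d shared variants", n_excl, len(df))
    return df


def retained(harmonised: pd.DataFrame) -> pd.DataFrame:
    """The non-excluded rows of a harmonised table."""
    return harmonised[~harmonised["excluded"]].reset_index(drop=True)


def write_harmonised(harmonised: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a harmonised instrument table in the fixed column order."""
    harmonised[HARMONISED_COLUMNS].to_csv(path, sep=sep, index=False)
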