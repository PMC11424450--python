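"""GWAS/eQTL summary-statistic tables and allele harmonization.

The raw material of two-sample Mendelian randomization is a pair of
per-SNP association tables — one for the exposure (gene expression),
one for the outcome (disease risk). Before any estimator can combine
them, the two tables must refer to the same effect allele at every
shared SNP; :func:`harmonize` performs that alignment, resolving
strand flips and dropping ambiguous palindromic variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "snp", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]
#: columns that must be present and valid in every record
MANDATORY_COLUMNS = [
    "snp", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pvalue",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
VALID_ALLELES = frozenset("ACGT")
PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))


@dataclass
class LoadReport:
    """Per-file account of rows kept and rows dropped at read time."""

    n_read: int = 0
    n_kept: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class AssociationTable:
    """Validated per-SNP summary statistics for a single trait.

    ``df`` holds one row per biallelic SNV with the canonical columns
    ``snp, chrom, pos, effect_allele, other_allele, eaf, beta, se,
    pvalue, n``. ``beta`` is the additive effect per copy of
    ``effect_allele`` (log-odds for case/control traits), ``se`` its
    standard error. Positions are 1-based.
    """

    df: pd.DataFrame
    trait_label: str = ""
    trait_type: str = "quantitative"
    case_fraction: float | None = None
    load_report: LoadReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "case_control":
            if self.case_fraction is None or not 0 < self.case_fraction < 1:
                raise ValueError("case_control trait requires case_fraction in (0,1)")
        if self.df["snp"].duplicated().any():
            dups = self.df["snp"][self.df["snp"].duplicated()].tolist()
            raise ValueError(f"duplicate snp ids in table: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask_or_ids) -> "AssociationTable":
        """New table restricted to a boolean mask or an iterable of snp ids."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray)) and getattr(
            mask_or_ids, "dtype", None
        ) == bool:
            df = self.df[mask_or_ids]
        else:
            ids = set(mask_or_ids)
            df = self.df[self.df["snp"].isin(ids)]
        return AssociationTable(
            df.reset_index(drop=True),
            trait_label=self.trait_label,
            trait_type=self.trait_type,
            case_fraction=self.case_fraction,
        )


@dataclass
class HarmonizedSet:
    """Allele-aligned exposure/outcome effects for a set of instruments.

    All four effect vectors share length ``J`` and, by construction,
    refer to the same effect allele within each SNP. ``dropped`` lists
    ``(snp_id, reason)`` pairs removed during harmonization.
    """

    snp_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_exp = np.asarray(self.beta_exp, dtype=float)
        self.se_exp = np.asarray(self.se_exp, dtype=float)
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        lengths = {
            len(self.snp_ids), self.beta_exp.size, self.se_exp.size,
            self.beta_out.size, self.se_out.size,
        }
        if len(lengths) != 1:
            raise ValueError("harmonized vectors have mismatched lengths")
        if self.n_snp >= 1 and (np.any(self.se_exp <= 0) or np.any(self.se_out <= 0)):
            raise ValueError("standard errors must be positive")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def subset(self, idx) -> "HarmonizedSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HarmonizedSet(
            [self.snp_ids[i] for i in idx],
            self.beta_exp[idx], self.se_exp[idx],
            self.beta_out[idx], self.se_out[idx],
        )


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    dropped: list[tuple[str, str]] = []
    keep = np.ones(len(df), dtype=bool)

    def drop(mask: pd.Series, reason: str) -> None:
        nonlocal keep
        mask = mask.fillna(False).to_numpy(dtype=bool) & keep
        for s in df.loc[mask, "snp"]:
            dropped.append((str(s), reason))
        keep &= ~mask

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    drop(~(ea.isin(VALID_ALLELES) & oa.isin(VALID_ALLELES)),
         "non-SNV or invalid allele")
    drop(ea == oa, "identical alleles")
    for col in ("beta", "se", "pvalue", "pos"):
        drop(df[col].isna(), f"missing {col}")
    drop(df["se"] <= 0, "nonpositive se")
    drop((df["pvalue"] <= 0) | (df["pvalue"] > 1), "pvalue outside (0,1]")
    eaf_bad = df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1))
    drop(eaf_bad, "eaf outside (0,1)")
    n_bad = df["n"].notna() & (df["n"] <= 0)
    drop(n_bad, "nonpositive n")

    out = df[keep].copy()
    out["effect_allele"] = ea[keep]
    out["other_allele"] = oa[keep]
    return out, dropped


def read_summary_stats(
    path,
    column_map: dict[str, str] | None = None,
    trait_type: str = "quantitative",
    trait_label: str = "",
    case_fraction: float | None = None,
    sep: str | None = None,
) -> AssociationTable:
    """Read a TSV/CSV of summary statistics into a validated table.

    ``column_map`` maps file headers to canonical field names; headers
    already canonical pass through. Rows violating record invariants
    are dropped and counted in the table's ``load_report``. Missing
    mandatory columns and empty files raise.
    """
    df = pd.read_csv(path, sep=sep if sep is not None else r"[\t,]",
                     engine="python")
    if df.empty:
        raise ValueError(f"empty summary-statistics file: {path}")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    for c in ("eaf", "n"):
        if c not in df.columns:
            df[c] = np.nan
    df = df[CANONICAL_COLUMNS]
    df["chrom"] = df["chrom"].astype(str)
    df["snp"] = df["snp"].astype(str)

    n_read = len(df)
    df, dropped = _validate_rows(df)
    report = LoadReport(n_read=n_read, n_kept=len(df), dropped=dropped)
    if dropped:
        logger.info("read %s: kept %d/%d rows (%d dropped)",
                    path, report.n_kept, report.n_read, len(dropped))
    return AssociationTable(
        df.reset_index(drop=True), trait_label=trait_label,
        trait_type=trait_type, case_fraction=case_fraction,
        load_report=report,
    )


def write_summary_stats(table: AssociationTable, path) -> None:
    """Write a table back to canonical tab-separated text."""
    table.df.to_csv(path, sep="\t", index=False)


def is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in PALINDROMIC_PAIRS


def harmonize(
    exposure: AssociationTable,
    outcome: AssociationTable,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effect alleles to the exposure's and pair effects.

    For each SNP shared by both tables:

    * identical allele pairs are kept as-is;
    * swapped alleles flip the sign of the outcome beta (and mirror its
      allele frequency);
    * alleles matching only after strand complement are complemented
      and then aligned;
    * palindromic SNPs (A/T, C/G) are strand-ambiguous: they are
      dropped when either trait's effect-allele frequency is missing or
      within ``palindrome_eaf_window`` of 0.5, and otherwise aligned so
      the minor/major sides of the frequencies agree;
    * irreconcilable allele pairs are dropped with a reason.

    Raises if the tables share no SNPs.
    """
    edf = exposure.df.set_index("snp")
    odf = outcome.df.set_index("snp")
    shared = [s for s in exposure.df["snp"] if s in odf.index]
    if not shared:
        raise ValueError("no shared instruments between exposure and outcome")

    ids, be, se_e, bo, se_o = [], [], [], [], []
    dropped: list[tuple[str, str]] = []
    for snp in shared:
        ex, ou = edf.loc[snp], odf.loc[snp]
        ea1, oa1 = ex["effect_allele"], ex["other_allele"]
        ea2, oa2 = ou["effect_allele"], ou["other_allele"]
        beta_out, eaf_out = float(ou["beta"]), ou["eaf"]

        flip = None
        if (ea2, oa2) == (ea1, oa1):
            flip = False
        elif (ea2, oa2) == (oa1, ea1):
            flip = True
        else:
            cea2, coa2 = COMPLEMENT[ea2], COMPLEMENT[oa2]
            if (cea2, coa2) == (ea1, oa1):
                flip = False
            elif (cea2, coa2) == (oa1, ea1):
                flip = True
        if flip is None:
            dropped.append((snp, "incompatible alleles"))
            continue

        if is_palindromic(ea1, oa1):
            eaf_exp = ex["eaf"]
            w = palindrome_eaf_window
            if (
                pd.isna(eaf_exp) or pd.isna(eaf_out)
                or abs(eaf_exp - 0.5) < w or abs(eaf_out - 0.5) < w
            ):
                dropped.append((snp, "palindromic, ambiguous frequency"))
                continue
            # trust the frequencies, not the printed strand: after the
            # nominal alignment the minor-allele sides must agree
            eaf_aligned = 1.0 - eaf_out if flip else eaf_out
            if (eaf_exp - 0.5) * (eaf_aligned - 0.5) < 0:
                flip = not flip

        if flip:
            beta_out = -beta_out
        ids.append(snp)
        be.append(float(ex["beta"]))
        se_e.append(float(ex["se"]))
        bo.append(beta_out)
        se_o.append(float(ou["se"]))

    if dropped:
        logger.info("harmonize: dropped %d of %d shared SNPs",
                    len(dropped), len(shared))
    return HarmonizedSet(ids, np.array(be), np.array(se_e),
                         np.array(bo), np.array(se_o), dropped=dropped)
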