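"""Instrument selection for cis-eQTL Mendelian randomization.

Candidate instruments for a gene are its cis-eQTL SNPs, filtered in a
fixed order: cis-window restriction around the gene body, significance
filtering under Benjamini-Hochberg FDR control (or a raw genome-wide
p-value threshold in reverse-MR mode), greedy LD clumping against a
reference correlation matrix, and exclusion of weak instruments by the
per-SNP F-statistic. The order is part of the protocol: changing it
changes the selected set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .sumstats import AssociationTable

logger = logging.getLogger(__name__)


@dataclass
class GeneRegion:
    """A gene's genomic footprint (1-based, inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


@dataclass
class LDMatrix:
    """Pairwise LD correlations (r, not r²) for a panel of SNPs."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise ValueError("LD matrix shape does not match snp id count")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValueError("LD entries outside [-1, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def r2(self, a: str, b: str) -> float | None:
        """Squared correlation of a SNP pair, or None if either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r[ia, ib] ** 2)


def read_ld_matrix(path) -> LDMatrix:
    """Read a square TSV whose header row and first column are SNP ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LDMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep="\t")


@dataclass
class SelectionConfig:
    """Thresholds governing instrument selection.

    Defaults follow the screening protocol: cis window of 5 kb around
    the gene, FDR < 0.05 for eQTL significance, clumping at r² = 0.1
    within a 10,000 kb window, and F > 10 for instrument strength.
    Reverse-MR mode replaces the FDR filter with a raw genome-wide
    threshold (5e-8) and clumps at r² = 0.001.
    """

    cis_window_bp: int = 5000
    fdr_threshold: float = 0.05
    clump_r2: float = 0.1
    clump_window_kb: int = 10_000
    f_min: float = 10.0
    pvalue_threshold: float | None = None
    reverse_clump_r2: float = 0.001
    strict_ld: bool = False

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "clump_r2", "clump_window_kb", "f_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def reverse(self) -> "SelectionConfig":
        """The reverse-MR variant of this configuration."""
        return SelectionConfig(
            cis_window_bp=self.cis_window_bp,
            fdr_threshold=self.fdr_threshold,
            clump_r2=self.reverse_clump_r2,
            clump_window_kb=self.clump_window_kb,
            f_min=self.f_min,
            pvalue_threshold=self.pvalue_threshold or 5e-8,
            reverse_clump_r2=self.reverse_clump_r2,
            strict_ld=self.strict_ld,
        )


def filter_cis(table: AssociationTable, region: GeneRegion,
               window_bp: int = 5000) -> AssociationTable:
    """Keep SNPs within ``window_bp`` of the gene body, inclusive."""
    if window_bp < 0:
        raise ValueError("window_bp must be nonnegative")
    df = table.df
    mask = (
        (df["chrom"] == region.chrom)
        & (df["pos"] >= region.start - window_bp)
        & (df["pos"] <= region.end + window_bp)
    )
    return table.subset(mask.to_numpy())


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_significance(table: AssociationTable,
                        cfg: SelectionConfig) -> AssociationTable:
    """Retain significant associations.

    Forward mode (``pvalue_threshold`` unset): BH-adjusted p strictly
    below ``fdr_threshold``, the correction applied within this table.
    Reverse mode: raw p strictly below ``pvalue_threshold``.
    """
    if len(table) == 0:
        raise ValueError("cannot filter an empty table")
    p = table.df["pvalue"].to_numpy(dtype=float)
    if cfg.pvalue_threshold is None:
        keep = benjamini_hochberg(p) < cfg.fdr_threshold
    else:
        keep = p < cfg.pvalue_threshold
    return table.subset(keep)


def clump(table: AssociationTable, ld: LDMatrix, r2_threshold: float = 0.1,
          window_kb: int = 10_000, strict: bool = False) -> AssociationTable:
    """Greedy LD clumping: keep index SNPs, prune their LD partners.

    Repeatedly takes the unclaimed SNP with the smallest p-value as an
    index (ties broken by position, then snp id) and removes unclaimed
    SNPs on the same chromosome within ``window_kb`` kilobases whose r²
    with the index exceeds ``r2_threshold``. Pairs absent from the LD
    matrix are treated as unlinked (r² = 0) with a logged warning, or
    raise when ``strict``. Output is sorted by (chrom, position).
    """
    df = table.df.reset_index(drop=True)
    order = df.sort_values(
        by=["pvalue", "pos", "snp"], kind="mergesort"
    ).index.to_numpy()
    claimed = np.zeros(len(df), dtype=bool)
    index_rows: list[int] = []
    warned_missing = False
    window_bp = window_kb * 1000

    pos = df["pos"].to_numpy()
    chrom = df["chrom"].to_numpy()
    snps = df["snp"].to_numpy()
    for i in order:
        if claimed[i]:
            continue
        index_rows.append(i)
        claimed[i] = True
        near = (
            ~claimed
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_bp)
        )
        for j in np.flatnonzero(near):
            r2 = ld.r2(snps[i], snps[j])
            if r2 is None:
                if strict:
                    raise ValueError(
                        f"SNP pair ({snps[i]}, {snps[j]}) missing from LD matrix"
                    )
                if not warned_missing:
                    logger.warning(
                        "clump: SNP pairs missing from LD matrix treated as r2=0"
                    )
                    warned_missing = True
                continue
            if r2 > r2_threshold:
                claimed[j] = True
    kept = df.loc[sorted(index_rows, key=lambda i: (chrom[i], pos[i]))]
    return AssociationTable(
        kept.reset_index(drop=True), trait_label=table.trait_label,
        trait_type=table.trait_type, case_fraction=table.case_fraction,
    )


def f_statistic(beta: float, se: float) -> float:
    """Single-SNP instrument-strength F-statistic, (beta/se)²."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def filter_f(table: AssociationTable, f_min: float = 10.0) -> AssociationTable:
    """Keep SNPs with F strictly above ``f_min`` (F = f_min is excluded)."""
    df = table.df
    f = (df["beta"] / df["se"]) ** 2
    return table.subset((f > f_min).to_numpy())


def select_instruments(
    table: AssociationTable,
    ld: LDMatrix,
    cfg: SelectionConfig,
    region: GeneRegion | None = None,
) -> AssociationTable:
    """Full selection pipeline: cis → significance → clump → F-filter.

    The stage order is fixed by the protocol. ``region`` may be omitted
    in reverse-MR mode, where instruments are genome-wide.
    """
    if region is not None:
        table = filter_cis(table, region, cfg.cis_window_bp)
    if len(table) == 0:
        return table
    table = filter_significance(table, cfg)
    if len(table) == 0:
        return table
    table = clump(table, ld, cfg.clump_r2, cfg.clump_window_kb,
                  strict=cfg.strict_ld)
    return filter_f(table, cfg.f_min)
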