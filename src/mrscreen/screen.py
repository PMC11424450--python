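"""End-to-end causal gene screen.

Per candidate gene: instrument selection from its cis-eQTLs,
harmonization against the disease GWAS, IVW (the screening estimator)
with MR-Egger / weighted-median companions and full sensitivity
diagnostics, Benjamini-Hochberg correction of IVW p-values across genes
within each cohort, replication with direction consistency, reverse MR
with disease loci as instruments, and Bayesian colocalization of
survivors. A gene is a candidate when it is replicated with consistent
direction, shows no reverse causation (reverse p >= 0.05 in both
cohorts) and colocalizes (PP.H4 > 0.80).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coloc import (ColocPriors, ColocResult, coloc_abf, declare_colocalized,
                    region_pair_from_tables)
from .estimators import EggerResult, MRResult, ivw, mr_egger, wald_ratio, \
    weighted_median
from .selection import GeneRegion, LDMatrix, SelectionConfig, \
    benjamini_hochberg, select_instruments
from .sensitivity import LeaveOneOutTable, PressoResult, QResult, cochran_q, \
    leave_one_out, mr_presso
from .simulate import GeneData
from .sumstats import AssociationTable, HarmonizedSet, harmonize

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Thresholds and options for the end-to-end screen."""

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    coloc_priors: ColocPriors = field(default_factory=ColocPriors)
    coloc_window_bp: int = 500_000
    pp_h4_threshold: float = 0.80
    alpha: float = 0.05
    ivw_random_effects: bool = False
    wm_n_boot: int = 1000
    presso_n_sim: int = 1000
    seed: int = 0


@dataclass
class CohortFit:
    """All per-cohort MR output for one gene."""

    ivw: MRResult
    egger: EggerResult | None = None
    weighted_median: MRResult | None = None
    q: QResult | None = None
    presso: PressoResult | None = None
    loo: LeaveOneOutTable | None = None
    n_instruments: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def sensitivity_flagged(self) -> bool:
        """Significant Egger intercept or PRESSO global test."""
        flag = False
        if self.egger is not None:
            flag |= self.egger.intercept_pvalue < 0.05
        if self.presso is not None:
            flag |= self.presso.global_pvalue < 0.05
        return flag


@dataclass
class ScreenResult:
    """One gene's passage through every screening gate."""

    gene_id: str
    discovery: CohortFit | None = None
    validation: CohortFit | None = None
    discovery_adj_p: float | None = None
    validation_adj_p: float | None = None
    replicated: bool = False
    direction_consistent: bool = False
    reverse_p_discovery: float | None = None
    reverse_p_validation: float | None = None
    coloc: ColocResult | None = None
    candidate: bool = False
    status: str = "ok"


def fit_cohort(h: HarmonizedSet, cfg: ScreenConfig) -> CohortFit:
    """All estimators and diagnostics a harmonized set supports."""
    j = h.n_snp
    primary = wald_ratio(h) if j == 1 else ivw(h, cfg.ivw_random_effects)
    if j > 1:  # report under the screening estimator's name
        primary = dataclasses.replace(primary, method="ivw")
    fit = CohortFit(ivw=primary, n_instruments=j, dropped=list(h.dropped))
    if j >= 3:
        fit.egger = mr_egger(h)
        fit.weighted_median = weighted_median(h, n_boot=cfg.wm_n_boot,
                                              seed=cfg.seed)
    if j >= 2:
        fit.q = cochran_q(h)
        fit.loo = leave_one_out(h, alpha=cfg.alpha)
    if j >= 4:
        fit.presso = mr_presso(h, n_sim=cfg.presso_n_sim, seed=cfg.seed,
                               alpha=cfg.alpha)
    return fit


def run_reverse_mr(
    disease_table: AssociationTable,
    expression_outcome: AssociationTable,
    ld: LDMatrix,
    cfg: ScreenConfig,
) -> CohortFit | None:
    """MR with disease as exposure and gene expression as outcome.

    Instruments are genome-wide significant disease loci (p < 5e-8,
    clumped at r² = 0.001); the estimation engine is identical to the
    forward analysis with the roles swapped. Returns None when no
    instrument survives selection.
    """
    instruments = select_instruments(disease_table, ld,
                                     cfg.selection.reverse())
    if len(instruments) == 0:
        return None
    h = harmonize(instruments, expression_outcome)
    if h.n_snp == 0:
        return None
    return fit_cohort(h, cfg)


def run_mr_screen(
    genes: list[GeneData],
    outcome_discovery: AssociationTable,
    outcome_validation: AssociationTable,
    ld: LDMatrix,
    cfg: ScreenConfig | None = None,
    reverse_exposure_discovery: AssociationTable | None = None,
    reverse_exposure_validation: AssociationTable | None = None,
    expression_outcomes: dict[str, AssociationTable] | None = None,
    reverse_ld: LDMatrix | None = None,
) -> list[ScreenResult]:
    """Screen every gene through discovery, replication, reverse MR
    and colocalization.

    B-H correction of IVW p-values is applied across genes within each
    cohort separately, over the genes that produced an estimate. The
    reverse-MR and colocalization gates are evaluated only where their
    inputs are supplied; a gene cannot become a candidate without them.
    """
    if cfg is None:
        cfg = ScreenConfig()
    results: list[ScreenResult] = []
    for gene in genes:
        res = ScreenResult(gene_id=gene.gene_id)
        instruments = select_instruments(gene.exposure, ld, cfg.selection,
                                         region=gene.region)
        if len(instruments) == 0:
            res.status = "no instruments"
            results.append(res)
            continue
        for label, outcome in (("discovery", outcome_discovery),
                               ("validation", outcome_validation)):
            try:
                h = harmonize(instruments, outcome)
            except ValueError:
                h = None
            if h is None or h.n_snp == 0:
                res.status = f"no shared instruments ({label})"
                break
            setattr(res, label, fit_cohort(h, cfg))
        if res.discovery is None or res.validation is None:
            results.append(res)
            continue
        logger.info("%s: %d instruments, ivw_disc=%.3f (p=%.2g)",
                    gene.gene_id, res.discovery.n_instruments,
                    res.discovery.ivw.estimate, res.discovery.ivw.pvalue)
        results.append(res)

    # B-H across genes, per cohort
    fitted = [r for r in results if r.discovery is not None]
    if fitted:
        adj_d = benjamini_hochberg([r.discovery.ivw.pvalue for r in fitted])
        adj_v = benjamini_hochberg([r.validation.ivw.pvalue for r in fitted])
        for r, ad, av in zip(fitted, adj_d, adj_v):
            r.discovery_adj_p = float(ad)
            r.validation_adj_p = float(av)
            r.replicated = ad < cfg.alpha and av < cfg.alpha
            r.direction_consistent = (
                np.sign(r.discovery.ivw.estimate)
                == np.sign(r.validation.ivw.estimate)
            )

    have_reverse = (reverse_exposure_discovery is not None
                    and reverse_exposure_validation is not None
                    and expression_outcomes is not None)
    genes_by_id = {g.gene_id: g for g in genes}
    for r in fitted:
        if not (r.replicated and r.direction_consistent):
            continue
        if have_reverse and r.gene_id in expression_outcomes:
            expr_out = expression_outcomes[r.gene_id]
            rld = reverse_ld if reverse_ld is not None else ld
            rev_d = run_reverse_mr(reverse_exposure_discovery, expr_out,
                                   rld, cfg)
            rev_v = run_reverse_mr(reverse_exposure_validation, expr_out,
                                   rld, cfg)
            r.reverse_p_discovery = rev_d.ivw.pvalue if rev_d else None
            r.reverse_p_validation = rev_v.ivw.pvalue if rev_v else None
        gene = genes_by_id[r.gene_id]
        try:
            reg1, reg2 = region_pair_from_tables(
                gene.exposure, outcome_discovery, gene.region,
                window_bp=cfg.coloc_window_bp)
            r.coloc = coloc_abf(reg1, reg2, cfg.coloc_priors)
        except ValueError as exc:
            logger.warning("%s: colocalization skipped (%s)", r.gene_id, exc)

        reverse_clear = (
            r.reverse_p_discovery is not None
            and r.reverse_p_validation is not None
            and r.reverse_p_discovery >= cfg.alpha
            and r.reverse_p_validation >= cfg.alpha
        )
        r.candidate = bool(
            r.replicated and r.direction_consistent and reverse_clear
            and r.coloc is not None
            and declare_colocalized(r.coloc, cfg.pp_h4_threshold)
        )
    return results


def _fit_row(fit: CohortFit | None, prefix: str) -> dict:
    if fit is None:
        return {}
    row = {
        f"{prefix}_nsnp": fit.n_instruments,
        f"{prefix}_beta": fit.ivw.estimate,
        f"{prefix}_se": fit.ivw.se,
        f"{prefix}_p": fit.ivw.pvalue,
        f"{prefix}_q_p": fit.q.pvalue if fit.q else np.nan,
        f"{prefix}_egger_intercept": fit.egger.intercept if fit.egger else np.nan,
        f"{prefix}_egger_intercept_p":
            fit.egger.intercept_pvalue if fit.egger else np.nan,
        f"{prefix}_presso_global_p":
            fit.presso.global_pvalue if fit.presso else np.nan,
        f"{prefix}_presso_outliers":
            ";".join(fit.presso.outliers) if fit.presso else "",
        f"{prefix}_sensitivity_flagged": fit.sensitivity_flagged,
    }
    return row


def results_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Master table of the screen, one row per gene."""
    rows = []
    for r in results:
        row = {"gene": r.gene_id, "status": r.status}
        row.update(_fit_row(r.discovery, "disc"))
        row.update(_fit_row(r.validation, "valid"))
        row.update({
            "disc_adj_p": r.discovery_adj_p,
            "valid_adj_p": r.validation_adj_p,
            "replicated": r.replicated,
            "direction_consistent": r.direction_consistent,
            "reverse_p_disc": r.reverse_p_discovery,
            "reverse_p_valid": r.reverse_p_validation,
        })
        if r.coloc is not None:
            row.update({k: v for k, v in r.coloc.pp.items()})
            row["coloc_nsnps"] = r.coloc.n_snps
            row["top_shared_snp"] = r.coloc.top_shared_snp
            row["colocalized"] = declare_colocalized(r.coloc)
        row["candidate"] = r.candidate
        rows.append(row)
    return pd.DataFrame(rows)


def mr_results_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Long-format estimates: one row per gene × cohort × method."""
    rows = []
    for r in results:
        for cohort in ("discovery", "validation"):
            fit: CohortFit | None = getattr(r, cohort)
            if fit is None:
                continue
            ests: list[MRResult] = [fit.ivw]
            if fit.egger:
                ests.append(fit.egger.slope)
            if fit.weighted_median:
                ests.append(fit.weighted_median)
            for e in ests:
                rows.append({
                    "gene": r.gene_id, "cohort": cohort, "method": e.method,
                    "nsnp": e.n_snp, "beta": e.estimate, "se": e.se,
                    "ci_low": e.ci_low, "ci_high": e.ci_high,
                    "pvalue": e.pvalue,
                })
    return pd.DataFrame(rows)


def generate_report(results: list[ScreenResult], out_dir,
                    cfg: ScreenConfig | None = None,
                    seed: int | None = None) -> dict[str, Path]:
    """Write the master screen TSV, per-method estimates, the
    colocalization table, per-gene leave-one-out tables and a
    run-metadata JSON. Returns the paths written."""
    if not results:
        raise ValueError("no results to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    master = results_frame(results)
    paths["screen"] = out / "screen_results.tsv"
    master.to_csv(paths["screen"], sep="\t", index=False)

    mr_tbl = mr_results_frame(results)
    paths["mr"] = out / "mr_estimates.tsv"
    mr_tbl.to_csv(paths["mr"], sep="\t", index=False)

    coloc_rows = []
    for r in results:
        if r.coloc is None:
            continue
        row = {"gene": r.gene_id, "nsnps": r.coloc.n_snps}
        row.update(r.coloc.pp)
        row["top_shared_snp"] = r.coloc.top_shared_snp
        row["colocalized"] = declare_colocalized(
            r.coloc, cfg.pp_h4_threshold if cfg else 0.80)
        coloc_rows.append(row)
    paths["coloc"] = out / "colocalization.tsv"
    pd.DataFrame(coloc_rows).to_csv(paths["coloc"], sep="\t", index=False)

    loo_rows = []
    for r in results:
        for cohort in ("discovery", "validation"):
            fit = getattr(r, cohort)
            if fit is not None and fit.loo is not None:
                t = fit.loo.rows.copy()
                t.insert(0, "cohort", cohort)
                t.insert(0, "gene", r.gene_id)
                loo_rows.append(t)
    paths["loo"] = out / "leave_one_out.tsv"
    (pd.concat(loo_rows, ignore_index=True) if loo_rows
     else pd.DataFrame()).to_csv(paths["loo"], sep="\t", index=False)

    meta = {
        "package": "mrscreen",
        "version": __version__,
        "n_genes": len(results),
        "n_candidates": int(sum(r.candidate for r in results)),
        "seed": seed,
    }
    if cfg is not None:
        cfg_json = json.dumps(dataclasses.asdict(cfg), sort_keys=True,
                              default=str)
        meta["config"] = json.loads(cfg_json)
        meta["config_sha256"] = hashlib.sha256(
            cfg_json.encode()).hexdigest()
    paths["meta"] = out / "run_metadata.json"
    paths["meta"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    logger.info("report written to %s (%d genes, %d candidates)",
                out, len(results), meta["n_candidates"])
    return paths
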