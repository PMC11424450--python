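"""Ground-truthed synthetic inputs for every analysis stage.

Summary statistics are simulated directly from their asymptotic
sampling distributions (never via individual-level genotypes): a true
per-SNP exposure effect sized by the variance it explains, a true
outcome effect θ·b plus optional pleiotropy, and observed estimates
drawn around the truth with standard errors 1/sqrt(2·maf(1−maf)·n)
(scaled by the case fraction for case/control traits). Regional
z-scores for colocalization are drawn multivariate normal with the LD
matrix as covariance. Expression matrices carry spiked fold-changes,
correlated gene pairs built from a shared latent factor, and one
shifted gene set.

Default sample sizes mirror the study conditions the pipeline targets:
a blood cis-eQTL exposure of n = 31,684, a disease outcome GWAS of
12,366 cases / 33,609 controls, and a replication GWAS of 5,931 cases
/ 405,386 controls. Per-SNP expression variance explained is drawn
log-uniformly over one decade either side of its configured center,
emulating the highly skewed strength distribution of real cis-eQTLs.

Every simulator is a pure function of its config (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import RegionStats
from .expression import ExpressionMatrix
from .selection import GeneRegion, LDMatrix
from .sumstats import AssociationTable, HarmonizedSet

EQTL_N = 31_684
UC_DISCOVERY_CASES, UC_DISCOVERY_CONTROLS = 12_366, 33_609
UC_VALIDATION_CASES, UC_VALIDATION_CONTROLS = 5_931, 405_386

#: ordered, non-complementary allele pairs (no palindromes, so synthetic
#: tables never lose SNPs to strand ambiguity)
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                 ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Named substream of the global generator for a given seed."""
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])


def _se_beta(maf: np.ndarray, n: int, case_fraction: float | None) -> np.ndarray:
    """Asymptotic se of a per-allele GWAS beta at allele frequency maf."""
    eff = n if case_fraction is None else n * case_fraction * (1 - case_fraction)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * eff)


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    # clamp away from zero: huge z-scores underflow norm.sf, but a
    # summary-statistic p-value must stay in (0, 1]
    p = np.minimum(2 * stats.norm.sf(np.abs(z)), 1.0)
    return np.maximum(p, np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# instruments for MR


@dataclass
class MRSimConfig:
    """Scenario for a single exposure-outcome instrument set.

    ``theta`` is the true causal effect of exposure on outcome.
    ``exposure_h2_per_snp`` centers the log-uniform distribution of
    per-SNP expression variance explained, which spans
    ``h2_spread_decades`` decades either side (0 gives equal-strength
    instruments, useful for isolating single-SNP effects). Pleiotropy
    adds a direct
    SNP-outcome effect α to a fraction ``pleiotropy_frac`` of
    instruments: none, balanced (zero-mean) or directional.
    ``n_outliers`` instruments have their observed outcome beta
    displaced by ``outlier_shift_se`` outcome standard errors.
    """

    j_snps: int = 50
    theta: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_h2_per_snp: float = 0.003
    h2_spread_decades: float = 1.0
    n_exposure: int = EQTL_N
    n_outcome: int = UC_DISCOVERY_CASES + UC_DISCOVERY_CONTROLS
    outcome_case_fraction: float | None = UC_DISCOVERY_CASES / (
        UC_DISCOVERY_CASES + UC_DISCOVERY_CONTROLS)
    pleiotropy: str = "none"
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_frac: float = 1.0
    n_outliers: int = 0
    outlier_shift_se: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.j_snps < 1:
            raise ValueError("j_snps must be >= 1")
        if min(self.n_exposure, self.n_outcome) < 100:
            raise ValueError("sample sizes must be >= 100")
        if not 0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        if not 0 <= self.pleiotropy_frac <= 1:
            raise ValueError("pleiotropy_frac must lie in [0, 1]")
        if self.n_outliers > self.j_snps:
            raise ValueError("more outliers than SNPs")
        if self.h2_spread_decades < 0:
            raise ValueError("h2_spread_decades must be nonnegative")


@dataclass
class MRSimTruth:
    theta: float
    beta_exposure_true: np.ndarray
    alpha: np.ndarray
    outlier_ids: list[str]
    snp_ids: list[str]


def _draw_instrument_effects(cfg: MRSimConfig, rng: np.random.Generator):
    j = cfg.j_snps
    maf = rng.uniform(*cfg.maf_range, size=j)
    # per-SNP variance explained, log-uniform around the configured center
    d = cfg.h2_spread_decades
    h2 = cfg.exposure_h2_per_snp * 10.0 ** rng.uniform(-d, d, size=j)
    # instruments are coded to the exposure-increasing allele (b > 0), the
    # orientation against which directional pleiotropy is defined
    b = np.sqrt(h2 / (2 * maf * (1 - maf)))

    alpha = np.zeros(j)
    if cfg.pleiotropy != "none" and cfg.pleiotropy_frac > 0:
        k = int(round(cfg.pleiotropy_frac * j))
        which = rng.choice(j, size=k, replace=False)
        mean = cfg.pleiotropy_mean if cfg.pleiotropy == "directional" else 0.0
        alpha[which] = rng.normal(mean, cfg.pleiotropy_sd, size=k)

    se_exp = _se_beta(maf, cfg.n_exposure, None)
    se_out = _se_beta(maf, cfg.n_outcome, cfg.outcome_case_fraction)
    beta_exp_obs = rng.normal(b, se_exp)
    beta_out_obs = rng.normal(cfg.theta * b + alpha, se_out)

    outlier_idx = np.array([], dtype=int)
    if cfg.n_outliers > 0:
        outlier_idx = rng.choice(j, size=cfg.n_outliers, replace=False)
        beta_out_obs[outlier_idx] += cfg.outlier_shift_se * se_out[outlier_idx]
    return maf, b, alpha, se_exp, se_out, beta_exp_obs, beta_out_obs, outlier_idx


def simulate_harmonized(cfg: MRSimConfig) -> tuple[HarmonizedSet, MRSimTruth]:
    """Directly simulate an allele-aligned instrument set (fast path).

    Identical draws to :func:`simulate_instruments`; harmonizing the
    tables that function emits recovers this set exactly.
    """
    rng = _rng(cfg.seed, 1)
    (_, b, alpha, se_exp, se_out,
     be_obs, bo_obs, outlier_idx) = _draw_instrument_effects(cfg, rng)
    ids = [f"rs{i + 1}" for i in range(cfg.j_snps)]
    truth = MRSimTruth(cfg.theta, b, alpha,
                       [ids[i] for i in outlier_idx], ids)
    return HarmonizedSet(ids, be_obs, se_exp, bo_obs, se_out), truth


def simulate_instruments(
    cfg: MRSimConfig,
) -> tuple[AssociationTable, AssociationTable, MRSimTruth]:
    """Simulate exposure and outcome summary-statistic tables.

    The outcome table's allele order is randomly swapped per SNP (with
    the beta sign and frequency mirrored) so harmonization is always
    exercised downstream.
    """
    rng = _rng(cfg.seed, 1)
    (maf, b, alpha, se_exp, se_out,
     be_obs, bo_obs, outlier_idx) = _draw_instrument_effects(cfg, rng)
    j = cfg.j_snps
    ids = [f"rs{i + 1}" for i in range(j)]
    pairs = [_ALLELE_PAIRS[k] for k in rng.integers(len(_ALLELE_PAIRS), size=j)]
    ea = np.array([p[0] for p in pairs])
    oa = np.array([p[1] for p in pairs])
    pos = 1_000_000 + 10_000 * np.arange(j)

    def table(beta, se, n, trait_type, cf, label, swap):
        beta = np.where(swap, -beta, beta)
        eaf = np.where(swap, 1 - maf, maf)
        df = pd.DataFrame({
            "snp": ids, "chrom": "1", "pos": pos,
            "effect_allele": np.where(swap, oa, ea),
            "other_allele": np.where(swap, ea, oa),
            "eaf": eaf, "beta": beta, "se": se,
            "pvalue": _two_sided_p(beta / se), "n": n,
        })
        return AssociationTable(df, trait_label=label, trait_type=trait_type,
                                case_fraction=cf)

    no_swap = np.zeros(j, dtype=bool)
    swap = rng.random(j) < 0.5
    exposure = table(be_obs, se_exp, cfg.n_exposure, "quantitative", None,
                     "exposure", no_swap)
    if cfg.outcome_case_fraction is None:
        outcome = table(bo_obs, se_out, cfg.n_outcome, "quantitative", None,
                        "outcome", swap)
    else:
        outcome = table(bo_obs, se_out, cfg.n_outcome, "case_control",
                        cfg.outcome_case_fraction, "outcome", swap)
    truth = MRSimTruth(cfg.theta, b, alpha, [ids[i] for i in outlier_idx], ids)
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# LD and colocalization regions


def simulate_ld_matrix(m: int, block: int, rho: float, seed: int = 0,
                       snp_ids: list[str] | None = None) -> LDMatrix:
    """Block-diagonal constant-correlation LD (positive semidefinite)."""
    if not 1 <= block <= m:
        raise ValueError("require 1 <= block <= m")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    r = np.eye(m)
    for start in range(0, m, block):
        stop = min(start + block, m)
        r[start:stop, start:stop] = rho
    np.fill_diagonal(r, 1.0)
    if snp_ids is None:
        snp_ids = [f"rs{i + 1}" for i in range(m)]
    return LDMatrix(snp_ids, r)


@dataclass
class ColocSimConfig:
    """Scenario for a two-trait regional colocalization experiment.

    ``scenario`` fixes which traits carry a causal variant and whether
    it is shared: h0 (neither), h1/h2 (one trait), h3 (both, distinct
    variants in different LD blocks), h4 (both, shared variant).
    ``causal_z`` is the expected Wald statistic at the causal SNP.
    """

    m_snps: int = 100
    scenario: str = "h4"
    causal_z: float = 8.0
    ld_block_size: int = 5
    ld_rho: float = 0.1
    n1: int = EQTL_N
    n2: int = UC_DISCOVERY_CASES + UC_DISCOVERY_CONTROLS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("h0", "h1", "h2", "h3", "h4"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 1 <= self.ld_block_size <= self.m_snps:
            raise ValueError("require m_snps >= ld_block_size >= 1")
        if self.causal_z <= 0:
            raise ValueError("causal_z must be positive")


def simulate_coloc_region(
    cfg: ColocSimConfig,
) -> tuple[RegionStats, RegionStats, dict]:
    """Simulate aligned regional z-scores for two traits.

    z-vectors are multivariate normal with the LD matrix as covariance
    and mean causal_z · (LD column of the causal SNP) for each trait
    carrying a signal. Trait 1 is quantitative (the eQTL side), trait 2
    case/control (the disease side).
    """
    rng = _rng(cfg.seed, 3)
    m = cfg.m_snps
    ld = simulate_ld_matrix(m, cfg.ld_block_size, cfg.ld_rho)
    chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(m))

    n_blocks = max(m // cfg.ld_block_size, 1)
    c1 = c2 = None
    if cfg.scenario in ("h1", "h3", "h4"):
        b1 = int(rng.integers(n_blocks))
        c1 = b1 * cfg.ld_block_size + cfg.ld_block_size // 2
    if cfg.scenario in ("h2", "h3"):
        while True:
            b2 = int(rng.integers(n_blocks))
            c2 = b2 * cfg.ld_block_size + cfg.ld_block_size // 2
            if cfg.scenario == "h2" or c2 != c1:
                break
    if cfg.scenario == "h4":
        c2 = c1

    def draw(causal):
        mean = cfg.causal_z * ld.r[:, causal] if causal is not None else 0.0
        return mean + chol @ rng.standard_normal(m)

    z1, z2 = draw(c1), draw(c2)
    cf2 = UC_DISCOVERY_CASES / (UC_DISCOVERY_CASES + UC_DISCOVERY_CONTROLS)
    r1 = RegionStats(list(ld.snp_ids), z1, np.full(m, 1.0 / cfg.n1),
                     trait_type="quantitative", n=np.full(m, cfg.n1))
    r2 = RegionStats(list(ld.snp_ids), z2, np.full(m, 1.0 / cfg.n2),
                     trait_type="case_control", case_fraction=cf2,
                     n=np.full(m, cfg.n2))
    truth = {
        "scenario": cfg.scenario,
        "causal_trait1": ld.snp_ids[c1] if c1 is not None else None,
        "causal_trait2": ld.snp_ids[c2] if c2 is not None else None,
        "ld": ld,
    }
    return r1, r2, truth


# ---------------------------------------------------------------------------
# expression matrices


@dataclass
class ExprSimConfig:
    """Scenario for a two-group expression matrix on the log2 scale.

    ``n_spiked`` genes get ``spike_log2fc`` added to the case group;
    ``corr_pairs`` lists (gene index i, gene index j, target r) pairs
    built from a shared latent factor; one gene set of
    ``enriched_set_size`` genes gets ``enrichment_shift`` added to the
    case group. Defaults mirror a blood case/control cohort of 58 vs 95
    samples.
    """

    g_genes: int = 500
    s_per_group: tuple[int, int] = (58, 95)
    n_spiked: int = 0
    spike_log2fc: float = 2.0
    noise_sd: float = 0.5
    corr_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    enriched_set_size: int = 0
    enrichment_shift: float = 0.0
    seed: int = 0
    baseline_mean: float = 5.0

    def __post_init__(self) -> None:
        if self.n_spiked > self.g_genes:
            raise ValueError("n_spiked exceeds g_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for i, j_, r in self.corr_pairs:
            if not 0 < abs(r) <= 1:
                raise ValueError("target correlations must have 0 < |r| <= 1")
            if i == j_ or max(i, j_) >= self.g_genes:
                raise ValueError("invalid correlation pair indices")


def simulate_expression(cfg: ExprSimConfig) -> tuple[ExpressionMatrix, dict]:
    """Simulate a genes × samples log2 expression matrix with truth."""
    rng = _rng(cfg.seed, 4)
    na, nb = cfg.s_per_group
    s = na + nb
    values = cfg.baseline_mean + cfg.noise_sd * rng.standard_normal(
        (cfg.g_genes, s))

    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.g_genes)]
    sample_ids = [f"S{k + 1:03d}" for k in range(s)]
    groups = ["case"] * na + ["control"] * nb
    case = np.arange(s) < na

    reserved: set[int] = set()
    for i, j_, r in cfg.corr_pairs:
        shared = rng.standard_normal(s)
        u = rng.standard_normal(s)
        values[i] = cfg.baseline_mean + cfg.noise_sd * shared
        values[j_] = cfg.baseline_mean + cfg.noise_sd * (
            np.sign(r) * abs(r) * shared + np.sqrt(1 - r**2) * u)
        reserved.update((i, j_))

    free = np.array([i for i in range(cfg.g_genes) if i not in reserved])
    spiked = rng.choice(free, size=cfg.n_spiked, replace=False) \
        if cfg.n_spiked else np.array([], dtype=int)
    values[np.ix_(spiked, np.flatnonzero(case))] += cfg.spike_log2fc

    enriched = np.array([], dtype=int)
    if cfg.enriched_set_size:
        pool = np.array([i for i in free if i not in set(spiked)])
        enriched = rng.choice(pool, size=cfg.enriched_set_size, replace=False)
        values[np.ix_(enriched, np.flatnonzero(case))] += cfg.enrichment_shift

    truth = {
        "spiked_genes": [gene_ids[i] for i in sorted(spiked)],
        "corr_pairs": [(gene_ids[i], gene_ids[j_], r)
                       for i, j_, r in cfg.corr_pairs],
        "enriched_set": [gene_ids[i] for i in sorted(enriched)],
    }
    return ExpressionMatrix(gene_ids, sample_ids, values, groups), truth


# ---------------------------------------------------------------------------
# end-to-end screening panel


@dataclass
class ScreenSimConfig:
    """A multi-gene screening panel with known causal genes.

    Each gene gets a regional block of cis-SNPs with two causal eQTL
    variants (a strong primary and a weaker secondary, in different LD
    blocks). Genes listed in ``causal_genes`` affect the outcome with
    effect ``theta`` entirely through their expression, so their
    regional exposure and outcome signals share causal variants (the
    colocalizing case); all other genes are eQTL-only. A separate set
    of genome-wide significant disease loci (with null effects on every
    gene's expression) feeds reverse MR.
    """

    n_genes: int = 20
    causal_genes: tuple[int, ...] = (0,)
    theta: float = 0.4
    m_per_gene: int = 60
    ld_block_size: int = 5
    ld_rho: float = 0.6
    maf_range: tuple[float, float] = (0.1, 0.5)
    primary_h2: float = 0.04
    secondary_h2: float = 0.01
    n_exposure: int = EQTL_N
    n_out_discovery: int = UC_DISCOVERY_CASES + UC_DISCOVERY_CONTROLS
    cf_discovery: float = UC_DISCOVERY_CASES / (
        UC_DISCOVERY_CASES + UC_DISCOVERY_CONTROLS)
    n_out_validation: int = UC_VALIDATION_CASES + UC_VALIDATION_CONTROLS
    cf_validation: float = UC_VALIDATION_CASES / (
        UC_VALIDATION_CASES + UC_VALIDATION_CONTROLS)
    n_reverse_snps: int = 30
    reverse_z_range: tuple[float, float] = (8.0, 25.0)
    seed: int = 0


@dataclass
class GeneData:
    gene_id: str
    region: GeneRegion
    exposure: AssociationTable


@dataclass
class ScreenPanel:
    """Everything the end-to-end screen consumes, plus ground truth."""

    genes: list[GeneData]
    outcome_discovery: AssociationTable
    outcome_validation: AssociationTable
    ld: LDMatrix
    reverse_exposure_discovery: AssociationTable
    reverse_exposure_validation: AssociationTable
    expression_outcomes: dict[str, AssociationTable]
    reverse_ld: LDMatrix
    truth: dict


def simulate_screen_panel(cfg: ScreenSimConfig) -> ScreenPanel:
    rng = _rng(cfg.seed, 5)
    m, bs = cfg.m_per_gene, cfg.ld_block_size
    n_blocks = m // bs
    neff_disc = cfg.n_out_discovery * cfg.cf_discovery * (1 - cfg.cf_discovery)
    neff_valid = cfg.n_out_validation * cfg.cf_validation * (1 - cfg.cf_validation)

    genes: list[GeneData] = []
    out_frames_disc, out_frames_valid = [], []
    ld_ids: list[str] = []
    ld_blocks: list[np.ndarray] = []
    truth_genes = {}

    for g in range(cfg.n_genes):
        gene_id = f"GENE{g + 1:02d}"
        chrom = str(g + 1)
        region = GeneRegion(gene_id, chrom, 1_000_000, 1_050_000)
        ids = [f"{gene_id.lower()}_rs{i + 1}" for i in range(m)]
        pos = np.linspace(region.start - 4000, region.end + 4000, m).astype(int)
        ld = simulate_ld_matrix(m, bs, cfg.ld_rho, snp_ids=ids)
        chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(m))

        maf = rng.uniform(*cfg.maf_range, size=m)
        se_exp = _se_beta(maf, cfg.n_exposure, None)
        se_od = 1.0 / np.sqrt(2 * maf * (1 - maf) * neff_disc)
        se_ov = 1.0 / np.sqrt(2 * maf * (1 - maf) * neff_valid)

        b1, b2 = rng.choice(n_blocks, size=2, replace=False)
        c1, c2 = b1 * bs + bs // 2, b2 * bs + bs // 2
        beta_causal = np.zeros(m)
        beta_causal[c1] = np.sqrt(cfg.primary_h2 / (2 * maf[c1] * (1 - maf[c1])))
        beta_causal[c2] = np.sqrt(cfg.secondary_h2 / (2 * maf[c2] * (1 - maf[c2])))
        # marginal (LD-convolved) standardized effects
        z_exp_true = (ld.r @ (beta_causal / se_exp))
        beta_exp_marg = z_exp_true * se_exp

        is_causal = g in cfg.causal_genes
        theta_g = cfg.theta if is_causal else 0.0
        beta_out_marg = theta_g * beta_exp_marg

        z_exp = z_exp_true + chol @ rng.standard_normal(m)
        z_od = beta_out_marg / se_od + chol @ rng.standard_normal(m)
        z_ov = beta_out_marg / se_ov + chol @ rng.standard_normal(m)

        pairs = [_ALLELE_PAIRS[k]
                 for k in rng.integers(len(_ALLELE_PAIRS), size=m)]
        ea = np.array([p[0] for p in pairs])
        oa = np.array([p[1] for p in pairs])

        def frame(z, se, n):
            beta = z * se
            return pd.DataFrame({
                "snp": ids, "chrom": chrom, "pos": pos,
                "effect_allele": ea, "other_allele": oa,
                "eaf": maf, "beta": beta, "se": se,
                "pvalue": _two_sided_p(z), "n": n,
            })

        genes.append(GeneData(gene_id, region, AssociationTable(
            frame(z_exp, se_exp, cfg.n_exposure),
            trait_label=f"{gene_id} expression")))
        out_frames_disc.append(frame(z_od, se_od, cfg.n_out_discovery))
        out_frames_valid.append(frame(z_ov, se_ov, cfg.n_out_validation))
        ld_ids.extend(ids)
        ld_blocks.append(ld.r)
        truth_genes[gene_id] = {
            "theta": theta_g,
            "causal_snps": [ids[c1], ids[c2]],
        }

    big_r = np.zeros((len(ld_ids), len(ld_ids)))
    ofs = 0
    for blockmat in ld_blocks:
        k = blockmat.shape[0]
        big_r[ofs:ofs + k, ofs:ofs + k] = blockmat
        ofs += k
    ld_all = LDMatrix(ld_ids, big_r)

    outcome_discovery = AssociationTable(
        pd.concat(out_frames_disc, ignore_index=True),
        trait_label="disease (discovery)", trait_type="case_control",
        case_fraction=cfg.cf_discovery)
    outcome_validation = AssociationTable(
        pd.concat(out_frames_valid, ignore_index=True),
        trait_label="disease (validation)", trait_type="case_control",
        case_fraction=cfg.cf_validation)

    # --- reverse MR: genome-wide disease loci, null on expression -------
    k = cfg.n_reverse_snps
    rev_ids = [f"uc_rs{i + 1}" for i in range(k)]
    rev_pos = 1_000_000 + 1_000_000 * np.arange(k)
    rev_maf = rng.uniform(*cfg.maf_range, size=k)
    rev_se_d = 1.0 / np.sqrt(2 * rev_maf * (1 - rev_maf) * neff_disc)
    rev_se_v = 1.0 / np.sqrt(2 * rev_maf * (1 - rev_maf) * neff_valid)
    z_true_d = rng.uniform(*cfg.reverse_z_range, size=k) \
        * rng.choice([-1.0, 1.0], size=k)
    rev_beta_true = z_true_d * rev_se_d
    rev_pairs = [_ALLELE_PAIRS[j] for j in rng.integers(len(_ALLELE_PAIRS),
                                                        size=k)]
    rev_ea = np.array([p[0] for p in rev_pairs])
    rev_oa = np.array([p[1] for p in rev_pairs])

    def rev_frame(beta, se, n):
        return pd.DataFrame({
            "snp": rev_ids, "chrom": "23", "pos": rev_pos,
            "effect_allele": rev_ea, "other_allele": rev_oa,
            "eaf": rev_maf, "beta": beta, "se": se,
            "pvalue": _two_sided_p(beta / se), "n": n,
        })

    rev_disc = AssociationTable(
        rev_frame(rng.normal(rev_beta_true, rev_se_d), rev_se_d,
                  cfg.n_out_discovery),
        trait_label="disease (discovery)", trait_type="case_control",
        case_fraction=cfg.cf_discovery)
    rev_valid = AssociationTable(
        rev_frame(rng.normal(rev_beta_true, rev_se_v), rev_se_v,
                  cfg.n_out_validation),
        trait_label="disease (validation)", trait_type="case_control",
        case_fraction=cfg.cf_validation)
    rev_ld = LDMatrix(rev_ids, np.eye(k))

    se_expr = 1.0 / np.sqrt(2 * rev_maf * (1 - rev_maf) * cfg.n_exposure)
    expression_outcomes = {}
    for g in range(cfg.n_genes):
        gene_id = f"GENE{g + 1:02d}"
        expression_outcomes[gene_id] = AssociationTable(
            rev_frame(rng.normal(0.0, se_expr), se_expr, cfg.n_exposure),
            trait_label=f"{gene_id} expression")

    truth = {"theta": cfg.theta,
             "causal_genes": [f"GENE{g + 1:02d}" for g in cfg.causal_genes],
             "genes": truth_genes}
    return ScreenPanel(genes, outcome_discovery, outcome_validation, ld_all,
                       rev_disc, rev_valid, expression_outcomes, rev_ld, truth)
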