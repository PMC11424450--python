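"""Transcriptomic characterization of screened genes.

Once a gene survives MR and colocalization, its expression behaviour is
profiled in case/control expression matrices: group differential
expression with Benjamini-Hochberg control, co-expression with marker
genes, median-split grouping by target-gene expression, and pre-ranked
gene-set enrichment over the resulting ranking.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .selection import benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with a two-level group factor.

    ``values`` is log2-scale expression (raw counts are transformed as
    log2(count+1) on construction when ``scale='counts'``).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: list[str]
    scale: str = "log2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g, s = len(self.gene_ids), len(self.sample_ids)
        if self.values.shape != (g, s):
            raise ValueError("values shape does not match gene/sample ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != s:
            raise ValueError("duplicate sample ids")
        if len(self.groups) != s:
            raise ValueError("one group label per sample required")
        if self.scale == "counts":
            self.values = np.log2(self.values + 1.0)
            self.scale = "log2"
        elif self.scale != "log2":
            raise ValueError(f"unknown scale {self.scale!r}")
        self._gene_index = {g_: i for i, g_ in enumerate(self.gene_ids)}

    def gene(self, gene_id: str) -> np.ndarray:
        if gene_id not in self._gene_index:
            raise KeyError(f"gene {gene_id!r} not in matrix")
        return self.values[self._gene_index[gene_id]]

    def group_levels(self) -> list[str]:
        """The two factor levels, in order of first appearance."""
        return list(dict.fromkeys(self.groups))


@dataclass
class DEGRecord:
    gene_id: str
    log2fc: float
    pvalue: float
    adj_pvalue: float
    significant: bool


@dataclass
class CorrelationResult:
    gene_a: str
    gene_b: str
    r: float | None
    pvalue: float | None
    n: int
    reason: str | None = None


@dataclass
class GSEARecord:
    set_name: str
    es: float
    nes: float
    pvalue: float
    fdr: float
    leading_edge: list[str] = field(default_factory=list)


def read_expression_tsv(expr_path, groups_path) -> ExpressionMatrix:
    """Read a genes×samples TSV plus a two-column sample/group TSV."""
    df = pd.read_csv(expr_path, sep="\t", index_col=0)
    ann = pd.read_csv(groups_path, sep="\t")
    ann = ann.set_index(ann.columns[0])[ann.columns[1]]
    groups = [str(ann[s]) for s in df.columns]
    return ExpressionMatrix(list(df.index), list(df.columns),
                            df.to_numpy(dtype=float), groups)


def write_expression_tsv(x: ExpressionMatrix, expr_path, groups_path) -> None:
    pd.DataFrame(x.values, index=x.gene_ids, columns=x.sample_ids).to_csv(
        expr_path, sep="\t")
    pd.DataFrame({"sample": x.sample_ids, "group": x.groups}).to_csv(
        groups_path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def differential_expression(
    x: ExpressionMatrix,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    group_a: str | None = None,
    group_b: str | None = None,
    test: str = "welch",
) -> list[DEGRecord]:
    """Two-group differential expression on the log2 scale.

    log2FC is mean(group A) − mean(group B); p-values come from a
    two-sided Welch (unequal-variance) t-test per gene, or a
    Mann-Whitney rank test when ``test='ranksum'``. Adjusted p-values
    are Benjamini-Hochberg across all genes. A gene is significant when
    adj p < ``alpha`` and |log2FC| > ``fc_threshold``. Genes constant
    in both groups get p = 1.
    """
    levels = x.group_levels()
    if group_a is None or group_b is None:
        if len(levels) != 2:
            raise ValueError("expression matrix must have exactly two groups")
        group_a, group_b = levels
    ga = np.asarray([g == group_a for g in x.groups])
    gb = np.asarray([g == group_b for g in x.groups])
    if ga.sum() < 2 or gb.sum() < 2:
        raise ValueError("each group needs >=2 samples")

    a, b = x.values[:, ga], x.values[:, gb]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    if test == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    elif test == "ranksum":
        p = np.array([
            stats.mannwhitneyu(a[i], b[i], alternative="two-sided").pvalue
            for i in range(a.shape[0])
        ])
    else:
        raise ValueError(f"unknown test {test!r}")
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
    if degenerate.any():
        logger.info("differential_expression: %d zero-variance genes set p=1",
                    int(degenerate.sum()))
    adj = benjamini_hochberg(p)
    sig = (adj < alpha) & (np.abs(lfc) > fc_threshold)
    return [
        DEGRecord(g, float(lfc[i]), float(p[i]), float(adj[i]), bool(sig[i]))
        for i, g in enumerate(x.gene_ids)
    ]


def gene_correlation(x: ExpressionMatrix, gene_a: str,
                     gene_bs: list[str]) -> list[CorrelationResult]:
    """Pearson correlation of one gene with each of a list of genes.

    p-values use the exact t transform with S−2 degrees of freedom.
    Zero-variance genes yield a missing correlation with a reason.
    """
    va = x.gene(gene_a)
    n = len(x.sample_ids)
    if n < 3:
        raise ValueError("correlation requires >=3 samples")
    out = []
    for gb in gene_bs:
        vb = x.gene(gb)
        if va.std() == 0 or vb.std() == 0:
            out.append(CorrelationResult(gene_a, gb, None, None, n,
                                         reason="zero variance"))
            continue
        r, p = stats.pearsonr(va, vb)
        out.append(CorrelationResult(gene_a, gb, float(r), float(p), n))
    return out


def split_by_expression(x: ExpressionMatrix, gene: str) -> list[str]:
    """Median split: per-sample 'high'/'low' labels by a gene's expression.

    Samples at or above the median go to 'high' (exact-median ties go
    high, so an all-constant gene yields all-'high' with a warning).
    """
    if len(x.sample_ids) < 4:
        raise ValueError("median split requires >=4 samples")
    v = x.gene(gene)
    med = float(np.median(v))
    labels = ["high" if val >= med else "low" for val in v]
    if "low" not in labels or "high" not in labels:
        logger.warning("split_by_expression: degenerate split for %s", gene)
    return labels


def _running_es(in_set: np.ndarray, scores: np.ndarray,
                weight: float) -> tuple[float, int]:
    """Enrichment score and extremum index of the GSEA running sum."""
    hit = np.abs(scores) ** weight * in_set
    total_hit = hit.sum()
    g = scores.size
    n_set = int(in_set.sum())
    if total_hit == 0:
        hit = in_set / max(n_set, 1)
    else:
        hit = hit / total_hit
    miss = (~in_set.astype(bool)).astype(float) / (g - n_set)
    running = np.cumsum(hit - miss)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx


def gsea_preranked(
    ranking: "pd.Series | list[tuple[str, float]]",
    gene_sets: dict[str, list[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
) -> list[GSEARecord]:
    """Pre-ranked gene-set enrichment with gene-draw permutation nulls.

    ``ranking`` maps genes to real scores, sorted descending. Hits add
    |score|^weight (normalized by the in-set total) to a running sum,
    misses subtract 1/(G − set size); ES is the running-sum value of
    largest magnitude. The null redraws same-size gene sets at random
    (exhaustively enumerated instead when the number of possible draws
    is at most ``n_perm``); p counts null ES at least as extreme with
    matching sign, NES divides ES by the mean |null ES| of matching
    sign, and FDR uses the sign-stratified NES ratio. Sets smaller than
    ``min_size`` or not smaller than the ranking are skipped.
    """
    if isinstance(ranking, pd.Series):
        genes = list(ranking.index)
        scores = ranking.to_numpy(dtype=float)
    else:
        genes = [g for g, _ in ranking]
        scores = np.array([s for _, s in ranking], dtype=float)
    if np.any(np.diff(scores) > 0):
        raise ValueError("ranking scores must be sorted descending")
    g = len(genes)
    gene_pos = {gname: i for i, gname in enumerate(genes)}

    analyzed: list[tuple[str, float, int, np.ndarray]] = []
    null_es: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for name, members in gene_sets.items():
        in_ranking = [m for m in members if m in gene_pos]
        k = len(in_ranking)
        if k < min_size or k >= g:
            logger.info("gsea: skipping %s (size %d outside bounds)", name, k)
            continue
        in_set = np.zeros(g)
        for m in in_ranking:
            in_set[gene_pos[m]] = 1.0
        es, idx = _running_es(in_set, scores, weight)
        analyzed.append((name, es, idx, in_set))

        n_comb = math.comb(g, k)
        if n_comb <= n_perm:
            draws = itertools.combinations(range(g), k)
            es_null = np.empty(n_comb)
            for d, combo in enumerate(draws):
                mask = np.zeros(g)
                mask[list(combo)] = 1.0
                es_null[d], _ = _running_es(mask, scores, weight)
        else:
            es_null = np.empty(n_perm)
            for d in range(n_perm):
                mask = np.zeros(g)
                mask[rng.choice(g, size=k, replace=False)] = 1.0
                es_null[d], _ = _running_es(mask, scores, weight)
        null_es[name] = es_null

    # sign-matched empirical p and NES
    records: list[GSEARecord] = []
    all_nes_null: list[np.ndarray] = []
    nes_obs: dict[str, float] = {}
    for name, es, idx, in_set in analyzed:
        es_null = null_es[name]
        same_sign = es_null[np.sign(es_null) == np.sign(es)] if es != 0 else es_null
        exhaustive = es_null.size == math.comb(g, int(in_set.sum()))
        n_extreme = int(np.sum(np.abs(same_sign) >= abs(es)))
        if exhaustive:
            p = n_extreme / es_null.size
        else:
            p = (1 + n_extreme) / (es_null.size + 1)
        mean_abs = np.mean(np.abs(same_sign)) if same_sign.size else np.nan
        nes = es / mean_abs if mean_abs and np.isfinite(mean_abs) else 0.0
        nes_obs[name] = nes
        with np.errstate(invalid="ignore", divide="ignore"):
            pos = es_null[es_null > 0]
            neg = es_null[es_null < 0]
            nes_null = np.concatenate([
                pos / pos.mean() if pos.size else pos,
                neg / np.abs(neg).mean() if neg.size else neg,
            ])
        all_nes_null.append(nes_null)
        records.append(GSEARecord(name, float(es), float(nes), float(p), 1.0,
                                  _leading_edge(in_set, genes, idx, es)))

    if records:
        pooled = np.concatenate(all_nes_null) if all_nes_null else np.array([])
        obs = np.array([r.nes for r in records])
        for rec in records:
            rec.fdr = _nes_fdr(rec.nes, pooled, obs)
    return records


def _leading_edge(in_set: np.ndarray, genes: list[str], idx: int,
                  es: float) -> list[str]:
    members = np.flatnonzero(in_set)
    if es >= 0:
        chosen = members[members <= idx]
    else:
        chosen = members[members >= idx]
    return [genes[i] for i in chosen]


def _nes_fdr(nes: float, pooled_null: np.ndarray, obs: np.ndarray) -> float:
    if nes == 0 or pooled_null.size == 0:
        return 1.0
    if nes > 0:
        null_pos = pooled_null[pooled_null > 0]
        obs_pos = obs[obs > 0]
        num = np.mean(null_pos >= nes) if null_pos.size else 0.0
        den = np.mean(obs_pos >= nes) if obs_pos.size else 1.0
    else:
        null_neg = pooled_null[pooled_null < 0]
        obs_neg = obs[obs < 0]
        num = np.mean(null_neg <= nes) if null_neg.size else 0.0
        den = np.mean(obs_neg <= nes) if obs_neg.size else 1.0
    if den == 0:
        return 1.0
    return float(min(1.0, num / den))
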