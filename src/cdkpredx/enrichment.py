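"""Per-gene two-group differential ranking, Benjamini–Hochberg
adjustment and pre-ranked gene-set enrichment.

Genes are ranked by a signed significance score,
``-log10(p) * sign(log2 fold change)``, from an unequal-variance
(Welch) two-sample t-test on log2 expression. Pre-ranked enrichment
uses the classic weighted Kolmogorov–Smirnov running sum (hit
increments proportional to |rank score|, weighting exponent 1),
gene-label permutations for the null, a sign-matched normalized
enrichment score (NES = ES / mean |null ES| of the same sign) and a
sign-matched permutation p-value, with BH adjustment across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix
from .signatures import GeneSetCollection

__all__ = [
    "differential_ranking",
    "bh_adjust",
    "select_deg",
    "preranked_gsea",
    "enrichment_score",
]

_P_FLOOR = np.finfo(float).tiny


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_ranking(
    expr: ExpressionMatrix, groups: pd.Series
) -> pd.DataFrame:
    """Welch t-test per gene between two groups of samples.

    ``groups`` is a per-sample binary (0/1) Series; the log2 fold
    change is mean(group 1) - mean(group 0). Returns a frame indexed by
    gene with columns log2_fold_change, p_value, adjusted_p,
    rank_score.
    """
    g = pd.to_numeric(groups.reindex(expr.values.columns), errors="coerce")
    if g.isna().any():
        raise ValueError("groups must cover every sample in the matrix")
    mask1 = (g == 1).to_numpy()
    mask0 = (g == 0).to_numpy()
    if mask1.sum() < 2 or mask0.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    x1 = expr.values.values[:, mask1]
    x0 = expr.values.values[:, mask0]
    lfc = x1.mean(axis=1) - x0.mean(axis=1)
    res = sps.ttest_ind(x1, x0, axis=1, equal_var=False)
    p = np.nan_to_num(np.asarray(res.pvalue, dtype=float), nan=1.0)
    p_floored = np.maximum(p, _P_FLOOR)
    rank_score = -np.log10(p_floored) * np.sign(lfc)
    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": p,
            "adjusted_p": bh_adjust(p),
            "rank_score": rank_score,
        },
        index=expr.values.index,
    )


def select_deg(
    ranked: pd.DataFrame, padj_cut: float = 0.05, lfc_cut: float = 0.5
) -> list[str]:
    """Differentially expressed genes: adjusted p < cut and |LFC|
    strictly above the fold-change cut."""
    keep = (ranked["adjusted_p"] < padj_cut) & (ranked["log2_fold_change"].abs() > lfc_cut)
    return ranked.index[keep].tolist()


def enrichment_score(ranked_scores: pd.Series, set_genes) -> float:
    """Signed maximal deviation of the weighted running sum for one set.

    ``ranked_scores`` must be sorted in decreasing order; hit steps are
    proportional to |score|, miss steps uniform.
    """
    scores = ranked_scores.to_numpy(dtype=float)
    hit = ranked_scores.index.isin(set(set_genes))
    n_hit = int(hit.sum())
    n_miss = scores.size - n_hit
    if n_hit == 0 or n_miss == 0:
        raise ValueError("set must hit a strict, non-empty subset of the ranking")
    w = np.abs(scores) * hit
    total_w = w.sum()
    if total_w == 0:
        # degenerate all-zero weights: fall back to unweighted steps
        w = hit.astype(float)
        total_w = w.sum()
    running = np.cumsum(w / total_w - (~hit) / n_miss)
    return float(running[np.argmax(np.abs(running))])


def _null_es_for_size(
    abs_scores: np.ndarray, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES distribution for sets of size ``k`` under gene-label
    permutation, evaluated only at hit positions (O(k) per draw)."""
    n = abs_scores.size
    positions = np.empty((n_perm, k), dtype=np.int64)
    for i in range(n_perm):
        positions[i] = rng.choice(n, size=k, replace=False)
    positions.sort(axis=1)
    w = abs_scores[positions]
    cum = np.cumsum(w, axis=1)
    total = cum[:, -1:]
    zero_w = total[:, 0] == 0
    if zero_w.any():  # unweighted fallback mirrors enrichment_score
        cum[zero_w] = np.arange(1, k + 1)
        total[zero_w] = k
    idx = np.arange(k)
    miss_before = (positions - idx) / (n - k)
    top = cum / total - miss_before
    bottom = np.concatenate([np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) / total - miss_before
    top_max = top.max(axis=1)
    bottom_min = bottom.min(axis=1)
    return np.where(np.abs(top_max) >= np.abs(bottom_min), top_max, bottom_min)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per set: es, nes, p_value, adjusted_p, size
    n_perm: int
    seed: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_perm={self.n_perm}\tseed={self.seed}\n")
            self.table.to_csv(fh, sep="\t", index_label="gene_set")


def preranked_gsea(
    ranking: pd.DataFrame | pd.Series,
    sets: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 500,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Pre-ranked gene-set enrichment with a gene-label permutation null.

    ``ranking`` is either the frame from :func:`differential_ranking`
    or a per-gene Series of rank scores. Sets whose intersection with
    the ranking falls outside [min_size, max_size] are dropped from the
    result. Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if isinstance(ranking, pd.DataFrame):
        scores = ranking["rank_score"]
    else:
        scores = ranking
    if scores.index.has_duplicates:
        raise ValueError("ranking contains duplicate genes")
    scores = scores.sort_values(ascending=False, kind="mergesort")
    abs_scores = np.abs(scores.to_numpy(dtype=float))
    universe = set(scores.index)

    sizes: dict[str, int] = {}
    for gs in sets:
        k = len(universe.intersection(gs.genes))
        if min_size <= k <= max_size and k < len(universe):
            sizes[gs.name] = k
    rng = np.random.default_rng(seed)
    null_by_size = {
        k: _null_es_for_size(abs_scores, k, n_perm, rng) for k in sorted(set(sizes.values()))
    }

    rows = []
    for name, k in sizes.items():
        es = enrichment_score(scores, sets[name].genes)
        null = null_by_size[k]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.nan
        else:
            extreme = (np.abs(same_sign) >= abs(es)).sum()
            p = (1.0 + extreme) / (1.0 + same_sign.size)
            mean_mag = np.abs(same_sign).mean()
            nes = es / mean_mag if mean_mag > 0 else np.nan
        rows.append({"gene_set": name, "es": es, "nes": nes, "p_value": p, "size": k})
    table = pd.DataFrame(rows).set_index("gene_set") if rows else pd.DataFrame(
        columns=["es", "nes", "p_value", "size"]
    )
    if len(table):
        table["adjusted_p"] = bh_adjust(table["p_value"].to_numpy())
        table = table[["es", "nes", "p_value", "adjusted_p", "size"]]
    return EnrichmentResult(table=table, n_perm=n_perm, seed=seed)
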