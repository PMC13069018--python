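"""Bulk RNA-seq preprocessing: low-count filtering, gene-length scaling,
TMM between-sample normalization, TPM computation and distance-based
sample QC.

The normalization pipeline produces the log2 TMM-TPM matrix that every
downstream scoring step consumes:

1. drop genes whose total raw count across samples is at or below a
   threshold (default 10);
2. divide each gene's counts by its length after rescaling lengths to
   their per-gene geometric mean across samples (a no-op when lengths
   are per-gene constants);
3. estimate trimmed-mean-of-M-values (TMM) scaling factors on the
   length-scaled matrix and form effective library sizes;
4. convert to transcripts-per-million against the effective library
   size and take log2 with a pseudocount.

Sample outliers are then flagged from the per-sample median Euclidean
distance to all other samples, using a Tukey-style fence of
P75 + 3*IQR on the median distances.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "NormalizationResult",
    "OutlierReport",
    "FilterResult",
    "filter_low_count_genes",
    "length_scale_counts",
    "tmm_factors",
    "log2_tmm_tpm",
    "detect_outlier_samples",
    "filter_samples_by_mapping_qc",
]


class EmptyMatrixError(ValueError):
    """Raised when an operation would leave no genes (or samples)."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} ids: {dups[:5]}")


@dataclass
class CountMatrix:
    """Gene-level counts (genes x samples) with gene lengths in bases.

    ``lengths`` is either a per-gene Series or a genes x samples
    DataFrame (per-sample effective lengths, as produced by
    transcript-abundance estimators).
    """

    counts: pd.DataFrame
    lengths: pd.Series | pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if isinstance(self.lengths, pd.DataFrame):
            if not self.lengths.index.equals(self.counts.index) or not self.lengths.columns.equals(
                self.counts.columns
            ):
                raise ValueError("per-sample lengths must share the count matrix axes")
        else:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                missing = self.lengths.index[self.lengths.isna()].tolist()
                raise ValueError(f"lengths missing for genes: {missing[:5]}")
        if (np.asarray(self.lengths) <= 0).any():
            raise ValueError("gene lengths must be strictly positive")

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    def subset_genes(self, genes: pd.Index) -> "CountMatrix":
        lengths = self.lengths.loc[genes]
        return CountMatrix(self.counts.loc[genes], lengths)

    def to_tsv(self, counts_path, lengths_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        if lengths_path is not None:
            if isinstance(self.lengths, pd.DataFrame):
                self.lengths.to_csv(lengths_path, sep="\t", index_label="gene_id")
            else:
                self.lengths.rename("length").to_csv(lengths_path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, counts_path, lengths_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0)
        if lengths.shape[1] == 1:
            lengths = lengths.iloc[:, 0]
        return cls(counts, lengths)


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, genes x samples."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if not np.isfinite(self.values.values).all():
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


class FilterResult(NamedTuple):
    counts: CountMatrix
    removed_gene_ids: list[str]


@dataclass
class NormalizationResult:
    expression: ExpressionMatrix
    tmm_factors: pd.Series
    effective_library_sizes: pd.Series
    filtered_gene_ids: list[str]
    tpm: pd.DataFrame = field(repr=False, default=None)


@dataclass
class OutlierReport:
    median_distances: pd.Series
    threshold: float
    flagged_sample_ids: list[str]

    def to_json(self, path) -> None:
        payload = {
            "threshold": self.threshold,
            "median_distances": {k: float(v) for k, v in self.median_distances.items()},
            "flagged_sample_ids": list(self.flagged_sample_ids),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def filter_low_count_genes(counts: CountMatrix, max_total: int = 10) -> FilterResult:
    """Drop genes whose total raw count across all samples is <= ``max_total``."""
    totals = counts.counts.sum(axis=1)
    keep = totals > max_total
    if not keep.any():
        raise EmptyMatrixError(
            f"no genes with total count > {max_total}; refusing to return an empty matrix"
        )
    removed = counts.counts.index[~keep].tolist()
    return FilterResult(counts.subset_genes(counts.counts.index[keep]), removed)


def length_scale_counts(counts: CountMatrix) -> pd.DataFrame:
    """Divide counts by gene lengths rescaled to their per-gene geometric mean.

    With per-gene constant lengths the rescaled length is 1 for every
    sample and the output equals the input counts. With per-sample
    lengths L[g,s], the scaled value is C[g,s] / (L[g,s] / geomean_s L[g,.]).
    """
    if isinstance(counts.lengths, pd.DataFrame):
        logl = np.log(counts.lengths.values)
        norm_lengths = np.exp(logl - logl.mean(axis=1, keepdims=True))
        return counts.counts / norm_lengths
    return counts.counts.copy()


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Single-pair TMM factor (log2 scale returned as linear 2**f).

    Genes with a zero in either library drop out of the pair. M-values
    are doubly trimmed (``trim_m`` each tail by rank) together with an
    A-value trim (``trim_a`` each tail); the factor is the
    inverse-variance weighted mean of surviving M-values, with the
    asymptotic binomial (delta-method) variance as weight denominator.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    keep = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, v = m[keep], a[keep], v[keep]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    trimmed = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not trimmed.any():
        return 1.0
    f = np.nansum(m[trimmed] / v[trimmed]) / np.nansum(1.0 / v[trimmed])
    return float(2.0**f)


def tmm_factors(
    scaled_counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, rescaled to geometric mean 1.

    The reference library is the sample whose upper-quartile count
    fraction is closest to the mean of those fractions across samples.
    """
    values = np.asarray(scaled_counts, dtype=float)
    if values.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = values.sum(axis=0)
    if (lib <= 0).any():
        bad = scaled_counts.columns[lib <= 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    f75 = np.quantile(values, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(values[:, j], values[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(values.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=scaled_counts.columns, name="tmm_factor")


def log2_tmm_tpm(
    counts: CountMatrix,
    low_count_max: int | None = 10,
    pseudocount: float = 1.0,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationResult:
    """Full normalization pipeline: filter, length-scale, TMM, TPM, log2.

    Effective library sizes are the length-scaled column sums times the
    TMM factors; TPM columns therefore sum to 1e6 / factor before the
    log transform, and each log2 column is invariant to uniform scaling
    of that sample's counts.
    """
    removed: list[str] = []
    if low_count_max is not None:
        counts, removed = filter_low_count_genes(counts, low_count_max)
    scaled = length_scale_counts(counts)
    if scaled.shape[1] >= 2:
        factors = tmm_factors(scaled, trim_m=trim_m, trim_a=trim_a)
    else:
        factors = pd.Series(1.0, index=scaled.columns, name="tmm_factor")
    effective = scaled.sum(axis=0) * factors
    tpm = scaled.div(effective, axis=1) * 1e6
    expr = ExpressionMatrix(np.log2(tpm + pseudocount))
    return NormalizationResult(
        expression=expr,
        tmm_factors=factors,
        effective_library_sizes=effective.rename("effective_library_size"),
        filtered_gene_ids=removed,
        tpm=tpm,
    )


def detect_outlier_samples(expr: ExpressionMatrix) -> OutlierReport:
    """Flag samples whose median Euclidean distance to all other samples
    strictly exceeds P75 + 3*IQR of the per-sample median distances."""
    n = expr.values.shape[1]
    if n < 4:
        raise ValueError(f"outlier detection needs >= 4 samples, got {n}")
    dmat = squareform(pdist(expr.values.values.T, metric="euclidean"))
    np.fill_diagonal(dmat, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(dmat, axis=1)
    q25, q75 = np.quantile(med, [0.25, 0.75])
    threshold = float(q75 + 3.0 * (q75 - q25))
    medians = pd.Series(med, index=expr.values.columns, name="median_distance")
    flagged = medians.index[medians > threshold].tolist()
    return OutlierReport(medians, threshold, flagged)


def filter_samples_by_mapping_qc(
    qc_table: pd.DataFrame, min_unique_pct: float = 75.0
) -> list[str]:
    """Pass-through alignment QC: given a per-sample table with a
    ``pct_uniquely_mapped`` column, return the ids failing the cutoff.

    Alignment itself is upstream of this package; the rule is applied
    to externally supplied metadata only.
    """
    if "pct_uniquely_mapped" not in qc_table.columns:
        raise ValueError("qc table needs a 'pct_uniquely_mapped' column")
    bad = qc_table.index[qc_table["pct_uniquely_mapped"] < min_unique_pct]
    return bad.tolist()
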