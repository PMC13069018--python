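"""Metagene scoring, cohort-quantile dichotomization and the CDKPredX
three-module classifier.

A metagene score is the unweighted mean log2 expression of a gene
set's members present in the matrix, one score per sample. Scores are
dichotomized at cohort quantiles (median or lower quartile, linear
interpolation), with ties resolved as ``score >= threshold -> high``.

CDKPredX combines three modules — proliferation (Pr), ER signaling
(Er) and immune activity (Im) — and labels a sample positive when Pr
is high (at or above the cohort lower quartile), Er is high (at or
above the median) and Im is low (below the median). The permissive
lower-quartile gate on Pr means roughly 75% of samples pass it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "MissingGenesError",
    "CDKPredXResult",
    "read_gmt",
    "write_gmt",
    "metagene_score",
    "dichotomize",
    "classify_cdkpredx",
    "apply_to_external_cohort",
]

HIGH = "high"
LOW = "low"


class MissingGenesError(KeyError):
    """Too few of a gene set's members are present in the matrix."""

    def __init__(self, set_name: str, missing: list[str], present: int, total: int):
        self.set_name = set_name
        self.missing = missing
        super().__init__(
            f"gene set '{set_name}': only {present}/{total} genes present; "
            f"missing: {', '.join(missing[:10])}"
            + ("..." if len(missing) > 10 else "")
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"gene set '{self.name}' is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set '{self.name}' contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)
    source: str = ""

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise ValueError(f"duplicate gene set name '{gs.name}'")
        self.sets[gs.name] = gs

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a standard GMT file: name <tab> description <tab> genes..."""
    coll = GeneSetCollection(source=str(path))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (needs >= 3 fields)")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            coll.add(GeneSet(name, tuple(genes), desc))
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description or "na", *gs.genes]) + "\n")


def metagene_score(
    expr: ExpressionMatrix, gene_set: GeneSet, min_fraction_present: float = 0.5
) -> pd.Series:
    """Unweighted mean log2 expression over the set genes present in the
    matrix; errors (naming the absentees) if fewer than
    ``min_fraction_present`` of the set's genes are found."""
    present = [g for g in gene_set.genes if g in expr.values.index]
    missing = [g for g in gene_set.genes if g not in expr.values.index]
    if len(present) == 0 or len(present) < min_fraction_present * len(gene_set):
        raise MissingGenesError(gene_set.name, missing, len(present), len(gene_set))
    score = expr.values.loc[present].mean(axis=0)
    score.name = gene_set.name
    return score


_QUANTILE_BY_RULE = {"median": 0.5, "lower_quartile": 0.25}


def dichotomize(scores: pd.Series, rule: str = "median") -> tuple[pd.Series, float]:
    """Split scores into high/low at a cohort quantile.

    Returns (calls, threshold); high iff score >= threshold. An
    all-identical input degenerates to every sample high (warned).
    """
    if rule not in _QUANTILE_BY_RULE:
        raise ValueError(f"unknown rule '{rule}'; expected one of {sorted(_QUANTILE_BY_RULE)}")
    if len(scores) < 2:
        raise ValueError("dichotomization needs at least 2 samples")
    if not np.isfinite(scores.values).all():
        raise ValueError("scores must be finite")
    threshold = float(np.quantile(scores.values, _QUANTILE_BY_RULE[rule]))
    calls = pd.Series(np.where(scores.values >= threshold, HIGH, LOW), index=scores.index)
    if scores.nunique() == 1:
        warnings.warn("all scores identical; every sample called high", stacklevel=2)
    return calls, threshold


@dataclass
class CDKPredXResult:
    """Per-sample module scores, calls and the positive/negative label."""

    table: pd.DataFrame  # sample_id index; pr/er/im scores & calls, label
    thresholds: dict[str, float]
    cohort: str = "derivation"

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    @property
    def positive_fraction(self) -> float:
        return float((self.table["label"] == "positive").mean())

    def to_tsv(self, path, thresholds_path=None) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")
        if thresholds_path is not None:
            with open(thresholds_path, "w") as fh:
                json.dump({"cohort": self.cohort, **self.thresholds}, fh, indent=2, sort_keys=True)


def _classify(
    expr: ExpressionMatrix,
    modules: GeneSetCollection,
    cohort: str,
    min_fraction_present: float,
    fixed_thresholds: dict[str, float] | None = None,
) -> CDKPredXResult:
    for name in ("Pr", "Er", "Im"):
        if name not in modules:
            raise KeyError(f"module gene set '{name}' missing from collection")
    pr = metagene_score(expr, modules["Pr"], min_fraction_present)
    er = metagene_score(expr, modules["Er"], min_fraction_present)
    im = metagene_score(expr, modules["Im"], min_fraction_present)
    if fixed_thresholds is None:
        pr_call, pr_thr = dichotomize(pr, "lower_quartile")
        er_call, er_thr = dichotomize(er, "median")
        im_call, im_thr = dichotomize(im, "median")
    else:
        pr_thr = fixed_thresholds["pr_q1"]
        er_thr = fixed_thresholds["er_median"]
        im_thr = fixed_thresholds["im_median"]
        pr_call = pd.Series(np.where(pr.values >= pr_thr, HIGH, LOW), index=pr.index)
        er_call = pd.Series(np.where(er.values >= er_thr, HIGH, LOW), index=er.index)
        im_call = pd.Series(np.where(im.values >= im_thr, HIGH, LOW), index=im.index)
    positive = (pr_call == HIGH) & (er_call == HIGH) & (im_call == LOW)
    table = pd.DataFrame(
        {
            "pr_score": pr,
            "er_score": er,
            "im_score": im,
            "pr_call": pr_call,
            "er_call": er_call,
            "im_call": im_call,
            "label": np.where(positive, "positive", "negative"),
        }
    )
    thresholds = {"pr_q1": float(pr_thr), "er_median": float(er_thr), "im_median": float(im_thr)}
    return CDKPredXResult(table, thresholds, cohort)


def classify_cdkpredx(
    expr: ExpressionMatrix,
    modules: GeneSetCollection,
    cohort: str = "derivation",
    min_fraction_present: float = 0.5,
) -> CDKPredXResult:
    """Score the Pr/Er/Im modules, dichotomize at (Q1, median, median)
    derived within this cohort, and label positive = high Pr & high Er
    & low Im."""
    return _classify(expr, modules, cohort, min_fraction_present)


def apply_to_external_cohort(
    expr: ExpressionMatrix,
    modules: GeneSetCollection,
    cohort: str,
    mode: str = "requantile",
    reference_thresholds: dict[str, float] | None = None,
    min_fraction_present: float = 0.5,
) -> CDKPredXResult:
    """Apply the classifier to a validation cohort.

    ``mode='requantile'`` (default) re-derives the same quantile levels
    (Q1, median, median) inside the external cohort, giving
    cross-platform comparability. ``mode='absolute'`` transfers the
    derivation cohort's absolute thresholds, which must be supplied.
    """
    if mode == "requantile":
        return _classify(expr, modules, cohort, min_fraction_present)
    if mode == "absolute":
        if reference_thresholds is None:
            raise ValueError("absolute mode requires reference_thresholds")
        return _classify(expr, modules, cohort, min_fraction_present, reference_thresholds)
    raise ValueError(f"unknown mode '{mode}'")
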