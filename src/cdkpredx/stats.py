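"""Contingency-table and regression statistics for two-arm trial
endpoints, plus small clinical formulas (CCCA, easTILs%, SUVmax ratio)
and reconstruction of integer counts from printed percentages.

Conventions
-----------
A 2x2 ``ContingencyTable`` has rows = treatment (first row the
exposure of interest, e.g. CDK4/6 inhibitor + endocrine therapy),
columns = responder / non-responder, so the Wald odds ratio is
(a*d)/(b*c). Treatment-by-biomarker interaction is tested in a
logistic model endpoint ~ arm + biomarker + arm:biomarker; the
interaction p-value comes from a likelihood-ratio test by default
(Wald available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "InteractionResult",
    "SeparationError",
    "AmbiguousReconstructionError",
    "reconstruct_count",
    "reconstruct_split",
    "odds_ratio_wald",
    "fisher_exact",
    "logistic_interaction",
    "ccca_call",
    "eastils_percent",
    "suv_ratio",
    "read_clinical",
    "ARM_CHEMO_FIRST",
    "ARM_CDK_FIRST",
]

# Arm A received paclitaxel first, arm B palbociclib + endocrine
# therapy first; at the 12-week endpoint arm B is the CDK4/6i exposure.
ARM_CHEMO_FIRST = "A"
ARM_CDK_FIRST = "B"

CLINICAL_COLUMNS = [
    "sample_id",
    "arm",
    "orr12",
    "orr24",
    "pcr",
    "rcb_class",
    "ki67_baseline",
    "ki67_week12",
    "suv_baseline",
    "suv_week12",
]


class SeparationError(RuntimeError):
    """Logistic MLE does not exist (empty or pure arm x biomarker cells)."""


class AmbiguousReconstructionError(ValueError):
    def __init__(self, message: str, solutions: list):
        super().__init__(f"{message}; candidates: {solutions}")
        self.solutions = solutions


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a/b = row-1 responders/non, c/d = row-2 responders/non."""

    a: int
    b: int
    c: int
    d: int
    stratum: str = ""

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("table is empty")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    n: int
    stratum: str = ""

    def as_row(self) -> dict:
        return {
            "stratum": self.stratum,
            "estimate": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_value,
            "method": self.method,
            "n": self.n,
        }


@dataclass
class InteractionResult:
    strata: list[AssociationResult]
    statistic: float
    p_value: float
    method: str
    coefficients: dict[str, float]
    n: int


def reconstruct_count(rate_percent: float, n: int) -> int:
    """The unique integer r with 100*r/n within 0.05 of a one-decimal
    printed percentage; errors when none or several exist."""
    if not 0.0 <= rate_percent <= 100.0:
        raise ValueError("rate must be in [0, 100]")
    if n <= 0:
        raise ValueError("n must be positive")
    sols = [r for r in range(n + 1) if abs(100.0 * r / n - rate_percent) < 0.05]
    if not sols:
        raise ValueError(f"no integer r with 100*r/{n} rounding to {rate_percent}")
    if len(sols) > 1:
        raise AmbiguousReconstructionError(
            f"rate {rate_percent}% of {n} is ambiguous", sols
        )
    return sols[0]


def reconstruct_split(
    rate1_percent: float, rate2_percent: float, total: int
) -> tuple[int, int, int, int]:
    """Given two printed percentages whose group sizes sum to ``total``,
    recover the unique (r1, n1, r2, n2); errors on none or many."""
    sols = []
    for n1 in range(1, total):
        n2 = total - n1
        try:
            r1 = reconstruct_count(rate1_percent, n1)
            r2 = reconstruct_count(rate2_percent, n2)
        except ValueError:
            continue
        sols.append((r1, n1, r2, n2))
    if not sols:
        raise ValueError(
            f"no split of {total} consistent with rates {rate1_percent}%, {rate2_percent}%"
        )
    if len(sols) > 1:
        raise AmbiguousReconstructionError(
            f"rates ({rate1_percent}%, {rate2_percent}%) over total {total} are ambiguous", sols
        )
    return sols[0]


def _z975(alpha: float) -> float:
    return float(sps.norm.ppf(1.0 - alpha / 2.0))


def odds_ratio_wald(
    table: ContingencyTable, alpha: float = 0.05, continuity: str = "none"
) -> AssociationResult:
    """Cross-product odds ratio with Wald CI and two-sided Wald p.

    A zero cell is an error unless ``continuity='haldane'`` (adds 0.5
    to every cell).
    """
    a, b, c, d = (float(x) for x in table.cells)
    if continuity == "haldane":
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    elif continuity == "none":
        if min(a, b, c, d) == 0:
            raise ValueError(
                "zero cell in 2x2 table; use continuity='haldane' for a +0.5 correction"
            )
    else:
        raise ValueError(f"unknown continuity '{continuity}'")
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = _z975(alpha)
    log_or = math.log(or_)
    p = 2.0 * float(sps.norm.sf(abs(log_or) / se))
    return AssociationResult(
        odds_ratio=or_,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p_value=p,
        method="wald",
        n=int(sum(table.cells)),
        stratum=table.stratum,
    )


def fisher_exact(table: ContingencyTable) -> AssociationResult:
    """Two-sided Fisher exact test (hypergeometric-probability summation)
    with the sample (cross-product) odds ratio, tolerating zero cells."""
    arr = table.as_array()
    or_, p = sps.fisher_exact(arr, alternative="two-sided")
    return AssociationResult(
        odds_ratio=float(or_),
        ci_low=float("nan"),
        ci_high=float("nan"),
        p_value=float(p),
        method="fisher",
        n=int(sum(table.cells)),
        stratum=table.stratum,
    )


def _stratum_table(y: np.ndarray, exposed: np.ndarray, name: str) -> ContingencyTable:
    return ContingencyTable(
        a=int(((y == 1) & exposed).sum()),
        b=int(((y == 0) & exposed).sum()),
        c=int(((y == 1) & ~exposed).sum()),
        d=int(((y == 0) & ~exposed).sum()),
        stratum=name,
    )


def logistic_interaction(
    clinical: pd.DataFrame,
    biomarker: pd.Series,
    endpoint: str = "orr12",
    method: str = "lrt",
    alpha: float = 0.05,
) -> InteractionResult:
    """Fit endpoint ~ arm + biomarker + arm:biomarker by ML and test the
    interaction term.

    ``clinical`` needs ``arm`` in {A, B} indexed by sample id;
    ``biomarker`` is a per-sample binary (1 = biomarker-positive).
    Complete cases only. Per-stratum treatment odds ratios with Wald
    CIs (Haldane correction on zero cells) are reported alongside.
    """
    if method not in ("lrt", "wald"):
        raise ValueError("method must be 'lrt' or 'wald'")
    df = pd.DataFrame(
        {
            "y": pd.to_numeric(clinical[endpoint], errors="coerce"),
            "arm": clinical["arm"],
            "bio": pd.to_numeric(biomarker.reindex(clinical.index), errors="coerce"),
        }
    ).dropna()
    df["cdk"] = (df["arm"] == ARM_CDK_FIRST).astype(float)
    y = df["y"].to_numpy()
    if len(df) == 0 or y.sum() == 0 or y.sum() == len(y):
        raise SeparationError("endpoint has no events or no non-events after listwise deletion")

    # cell counts of the saturated arm x biomarker design
    cells: dict[tuple[int, int], tuple[int, int]] = {}
    for cdk in (0, 1):
        for bio in (0, 1):
            sub = df[(df["cdk"] == cdk) & (df["bio"] == bio)]
            cells[(cdk, bio)] = (int(sub["y"].sum()), int(len(sub) - sub["y"].sum()))
    empty = [cell for cell, (r, nr) in cells.items() if r + nr == 0]
    if empty:
        raise SeparationError(
            f"empty arm x biomarker cells (cdk, biomarker): {empty}; "
            "the interaction term is not identifiable"
        )
    pure = [cell for cell, (r, nr) in cells.items() if r == 0 or nr == 0]

    # The full model saturates the four cells, so its sup-log-likelihood
    # is available in closed form from the cell rates even when a pure
    # cell pushes the MLE itself to infinity (0*log(0) := 0).
    def _cell_ll(r: int, nr: int) -> float:
        n = r + nr
        ll = 0.0
        if r:
            ll += r * math.log(r / n)
        if nr:
            ll += nr * math.log(nr / n)
        return ll

    llf_full = sum(_cell_ll(r, nr) for r, nr in cells.values())
    reduced = sm.Logit(y, sm.add_constant(df[["cdk", "bio"]])).fit(
        disp=0, warn_convergence=False
    )
    if not reduced.mle_retvals.get("converged", True):
        raise SeparationError("additive model failed to converge")
    lrt_stat = 2.0 * (llf_full - reduced.llf)
    lrt_p = float(sps.chi2.sf(lrt_stat, df=1))

    if pure:
        if method == "wald":
            raise SeparationError(
                f"pure arm x biomarker cells (cdk, biomarker): {pure}; "
                "finite MLE required for the Wald interaction test"
            )
        wald_p = float("nan")
        coefficients = {}
    else:
        X_full = sm.add_constant(
            pd.DataFrame(
                {"cdk": df["cdk"], "bio": df["bio"], "cdk_bio": df["cdk"] * df["bio"]}
            )
        )
        full = sm.Logit(y, X_full).fit(disp=0)
        wald_z = float(full.params["cdk_bio"] / full.bse["cdk_bio"])
        wald_p = 2.0 * float(sps.norm.sf(abs(wald_z)))
        coefficients = {k: float(v) for k, v in full.params.items()}

    strata = []
    for bio, name in ((1.0, "biomarker_positive"), (0.0, "biomarker_negative")):
        mask = df["bio"] == bio
        tab = _stratum_table(y[mask.to_numpy()], (df["cdk"] == 1.0)[mask].to_numpy(), name)
        cont = "haldane" if min(tab.cells) == 0 else "none"
        strata.append(odds_ratio_wald(tab, alpha=alpha, continuity=cont))

    if method == "lrt":
        statistic, p = lrt_stat, lrt_p
    else:
        statistic, p = wald_z, wald_p
    return InteractionResult(
        strata=strata,
        statistic=float(statistic),
        p_value=float(p),
        method=method,
        coefficients=coefficients,
        n=len(df),
    )


def ccca_call(ki67_percent: float, cutoff: float = 2.7) -> bool:
    """Complete cell cycle arrest: Ki67 at or below 2.7%."""
    if not 0.0 <= ki67_percent <= 100.0:
        raise ValueError("Ki67 must be a percentage in [0, 100]")
    return ki67_percent <= cutoff


def eastils_percent(til_cell_area: float, stroma_area: float) -> float:
    """Digital stromal-TIL surrogate: 100 * TIL cell area / stroma area
    (areas in identical units)."""
    if stroma_area <= 0:
        raise ValueError("stroma area must be positive")
    if til_cell_area < 0:
        raise ValueError("TIL cell area must be non-negative")
    return 100.0 * til_cell_area / stroma_area


def suv_ratio(baseline: float, week12: float) -> tuple[float, float]:
    """SUVmax week-12 / baseline ratio and the relative decrease in %."""
    if baseline <= 0:
        raise ValueError("baseline SUVmax must be positive")
    if week12 < 0:
        raise ValueError("week-12 SUVmax must be non-negative")
    ratio = week12 / baseline
    return ratio, 100.0 * (1.0 - ratio)


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical CSV (sample_id, arm, endpoints, Ki67, SUVmax)
    and validate the schema; returns a frame indexed by sample_id."""
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    bad_arm = ~df["arm"].isin([ARM_CHEMO_FIRST, ARM_CDK_FIRST])
    if bad_arm.any():
        raise ValueError(f"arm must be A or B; offending rows: {df.index[bad_arm].tolist()[:5]}")
    for col in ("orr12", "orr24", "pcr"):
        vals = df[col].dropna().unique()
        if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
            raise ValueError(f"column '{col}' must be binary (0/1) or missing")
    return df.set_index("sample_id")
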