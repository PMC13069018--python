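"""End-to-end pipeline: simulate (or load) -> normalize -> QC ->
classify -> associate -> enrich, driven by a YAML config, with a run
manifest recording seed, thresholds and per-stage sample/gene
accounting (a CONSORT-style retained/excluded ledger).

Identical config + seed produce byte-identical manifests; logs go to
standard error, results only to files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as enr
from . import expression as ex
from . import signatures as sig
from . import stats as st
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger("cdkpredx")

ALL_STAGES = ("simulate", "normalize", "qc", "classify", "associate", "gsea")

_THRESHOLD_DEFAULTS = {
    "low_count_max": 10,
    "pseudocount": 1.0,
    "trim_m": 0.30,
    "trim_a": 0.05,
    "min_fraction_present": 0.5,
    "gsea_min_size": 10,
    "gsea_max_size": 500,
    "gsea_n_perm": 1000,
    "endpoint": "orr12",
}

_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}
_INPUT_KEYS = {"counts", "lengths", "gene_sets", "clinical"}
_TOP_KEYS = {"simulation", "inputs", "stages", "thresholds", "outdir", "seed", "log_level"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    inputs: dict | None = None
    stages: tuple[str, ...] = ALL_STAGES
    thresholds: dict = field(default_factory=lambda: dict(_THRESHOLD_DEFAULTS))
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of a simulation block or input paths is required")
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        merged = dict(_THRESHOLD_DEFAULTS)
        merged.update(self.thresholds)
        self.thresholds = merged


def validate_config(path) -> PipelineConfig:
    """Parse and fully validate a YAML config, collecting every error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"unknown key '{key}'")
    has_sim = "simulation" in raw
    has_inputs = "inputs" in raw
    if has_sim == has_inputs:
        errors.append("exactly one of 'simulation' or 'inputs' must be present")
    sim = None
    if has_sim:
        sim_raw = raw.get("simulation") or {}
        bad = [k for k in sim_raw if k not in _SIM_KEYS]
        if bad:
            errors.append(f"unknown simulation keys: {bad}")
        else:
            for key in ("module_sizes", "module_state_rates", "response_coefficients"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            if "seed" not in sim_raw:
                sim_raw["seed"] = int(raw.get("seed", 0))
            try:
                sim = SimulationConfig(**sim_raw)
            except (TypeError, ValueError) as exc:
                errors.append(f"simulation block: {exc}")
    inputs = None
    if has_inputs:
        inputs = raw.get("inputs") or {}
        bad = [k for k in inputs if k not in _INPUT_KEYS]
        if bad:
            errors.append(f"unknown input keys: {bad}")
        for key in sorted(_INPUT_KEYS):
            if key not in inputs:
                errors.append(f"inputs missing '{key}'")
            elif not Path(inputs[key]).exists():
                errors.append(f"input file not found: {inputs[key]}")
    if "outdir" not in raw:
        errors.append("missing required key 'outdir'")
    thresholds = raw.get("thresholds", {})
    if not isinstance(thresholds, dict):
        errors.append("'thresholds' must be a mapping")
        thresholds = {}
    else:
        bad = [k for k in thresholds if k not in _THRESHOLD_DEFAULTS]
        if bad:
            errors.append(f"unknown threshold keys: {bad}")
    stages = tuple(raw.get("stages", ALL_STAGES))
    bad = [s for s in stages if s not in ALL_STAGES]
    if bad:
        errors.append(f"unknown stages: {bad}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return PipelineConfig(
        outdir=str(raw["outdir"]),
        seed=int(raw.get("seed", 0)),
        simulation=sim,
        inputs=inputs,
        stages=stages,
        thresholds=thresholds,
        log_level=str(raw.get("log_level", "INFO")),
    )


def _load_inputs(inputs: dict):
    counts = ex.CountMatrix.from_tsv(inputs["counts"], inputs["lengths"])
    gene_sets = sig.read_gmt(inputs["gene_sets"])
    clinical = st.read_clinical(inputs["clinical"])
    return counts, gene_sets, clinical


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in fixed order and return the manifest.

    Every intermediate artifact is written under ``config.outdir``; the
    manifest ledger accounts for every input sample as retained or
    excluded-with-reason.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s [%(levelname)s] %(message)s",
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest: dict = {
        "package_version": version("cdkpredx"),
        "seed": config.seed,
        "thresholds": thr,
        "stages": {},
        "sample_ledger": {},
        "artifacts": {},
    }

    # --- acquire inputs -------------------------------------------------
    stage = "simulate"
    try:
        if config.simulation is not None:
            log.info("[simulate] drawing synthetic cohort (seed=%d)", config.simulation.seed)
            cohort = simulate_cohort(config.simulation)
            paths = cohort.write(outdir / "cohort")
            manifest["artifacts"].update(
                {k: str(Path(v).relative_to(outdir)) for k, v in paths.items()}
            )
            counts, gene_sets, clinical = cohort.counts, cohort.gene_sets, cohort.clinical
        else:
            log.info("[load] reading input matrices")
            counts, gene_sets, clinical = _load_inputs(config.inputs)
        missing = [s for s in clinical.index if s not in counts.sample_ids]
        if missing:
            raise ValueError(f"clinical samples absent from count matrix: {missing[:5]}")
        manifest["stages"][stage] = {
            "n_samples": len(counts.sample_ids),
            "n_genes": len(counts.gene_ids),
        }
        ledger = {s: "retained" for s in counts.sample_ids}
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, exc) from exc

    if "classify" in config.stages:
        for name in ("Pr", "Er", "Im"):
            if name not in gene_sets:
                raise PipelineError(
                    "classify", KeyError(f"gene set '{name}' required for classification")
                )

    expr = None
    norm = None
    if "normalize" in config.stages:
        stage = "normalize"
        try:
            log.info("[normalize] low-count filter + length scaling + TMM + log2-TPM")
            norm = ex.log2_tmm_tpm(
                counts,
                low_count_max=thr["low_count_max"],
                pseudocount=thr["pseudocount"],
                trim_m=thr["trim_m"],
                trim_a=thr["trim_a"],
            )
            expr = norm.expression
            expr.to_tsv(outdir / "expression.tsv")
            pd.DataFrame(
                {
                    "tmm_factor": norm.tmm_factors,
                    "effective_library_size": norm.effective_library_sizes,
                }
            ).to_csv(outdir / "normalization.tsv", sep="\t", index_label="sample_id")
            manifest["artifacts"]["expression"] = "expression.tsv"
            manifest["artifacts"]["normalization"] = "normalization.tsv"
            manifest["stages"][stage] = {
                "n_genes_in": len(counts.gene_ids),
                "n_genes_removed_low_count": len(norm.filtered_gene_ids),
                "n_genes_out": len(expr.gene_ids),
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

    if "qc" in config.stages:
        stage = "qc"
        try:
            if expr is None:
                raise ValueError("qc requires the normalize stage")
            report = ex.detect_outlier_samples(expr)
            report.to_json(outdir / "outliers.json")
            manifest["artifacts"]["outliers"] = "outliers.json"
            for s in report.flagged_sample_ids:
                ledger[s] = "excluded: expression outlier"
            keep = [s for s in expr.sample_ids if s not in report.flagged_sample_ids]
            expr = ex.ExpressionMatrix(expr.values[keep])
            clinical = clinical.loc[[s for s in clinical.index if s in keep]]
            manifest["stages"][stage] = {
                "threshold": report.threshold,
                "n_flagged": len(report.flagged_sample_ids),
                "n_retained": len(keep),
            }
            log.info("[qc] flagged %d outlier samples", len(report.flagged_sample_ids))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

    result = None
    if "classify" in config.stages:
        stage = "classify"
        try:
            if expr is None:
                raise ValueError("classify requires the normalize stage")
            result = sig.classify_cdkpredx(
                expr, gene_sets, min_fraction_present=thr["min_fraction_present"]
            )
            result.to_tsv(outdir / "cdkpredx.tsv", outdir / "cdkpredx_thresholds.json")
            manifest["artifacts"]["cdkpredx"] = "cdkpredx.tsv"
            manifest["stages"][stage] = {
                "n_classified": len(result.table),
                "n_positive": int((result.table["label"] == "positive").sum()),
                "thresholds": result.thresholds,
            }
            log.info("[classify] %d/%d positive",
                     manifest["stages"][stage]["n_positive"], len(result.table))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

    if "associate" in config.stages:
        stage = "associate"
        try:
            if result is None:
                raise ValueError("associate requires the classify stage")
            biomarker = (result.labels == "positive").astype(int)
            inter = st.logistic_interaction(
                clinical, biomarker, endpoint=thr["endpoint"], method="lrt"
            )
            rows = [s.as_row() for s in inter.strata]
            rows.append(
                {
                    "stratum": "interaction",
                    "estimate": float("nan"),
                    "ci_low": float("nan"),
                    "ci_high": float("nan"),
                    "p": inter.p_value,
                    "method": inter.method,
                    "n": inter.n,
                }
            )
            assoc = pd.DataFrame(rows)
            assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)
            with open(outdir / "associations.json", "w") as fh:
                json.dump(rows, fh, indent=2, sort_keys=True)
            manifest["artifacts"]["associations"] = "associations.tsv"
            manifest["stages"][stage] = {
                "endpoint": thr["endpoint"],
                "interaction_p": inter.p_value,
                "n": inter.n,
            }
            log.info("[associate] interaction p = %.4f (n=%d)", inter.p_value, inter.n)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

    if "gsea" in config.stages:
        stage = "gsea"
        try:
            if expr is None:
                raise ValueError("gsea requires the normalize stage")
            groups = pd.to_numeric(clinical[thr["endpoint"]], errors="coerce").dropna()
            expr_sub = ex.ExpressionMatrix(expr.values[groups.index.tolist()])
            ranked = enr.differential_ranking(expr_sub, groups)
            ranked.to_csv(outdir / "ranking.tsv", sep="\t", index_label="gene_id")
            gsea = enr.preranked_gsea(
                ranked,
                gene_sets,
                min_size=thr["gsea_min_size"],
                max_size=thr["gsea_max_size"],
                n_perm=thr["gsea_n_perm"],
                seed=config.seed,
            )
            gsea.to_tsv(outdir / "gsea.tsv")
            manifest["artifacts"]["ranking"] = "ranking.tsv"
            manifest["artifacts"]["gsea"] = "gsea.tsv"
            manifest["stages"][stage] = {
                "n_genes_ranked": len(ranked),
                "n_sets_tested": len(gsea.table),
                "n_perm": gsea.n_perm,
            }
            log.info("[gsea] tested %d sets", len(gsea.table))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

    manifest["sample_ledger"] = ledger
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run complete; manifest written to %s", outdir / "manifest.json")
    return manifest
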