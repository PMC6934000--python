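"""End-to-end orchestration: cohort → summaries → costing → CEA → DSA.

``run_full_analysis`` reproduces the full analysis from either a cohort CSV
or a synthetic-cohort configuration and writes a report bundle: cohort and
cost summaries, per-measure CEA tables, cost-effectiveness-plane and tornado
coordinates, a machine-readable ``results.json`` duplicating every reported
number, and a run manifest (config echo, hash, seed, version).  A printed-
values mode instead reproduces the published comparison table directly from
the printed per-strategy values and deltas, for the case where no eye-level
data are available.

Runs are deterministic: a fixed seed and config produce a byte-identical
bundle (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, calibration, cea, costing, sensitivity, synthetic, tree as tree_mod
from .cohort import ControlThresholds, read_cohort, summarize_cohort, write_cohort
from .tree import STRATEGY_FREE, STRATEGY_NONFREE, EffectMeasure

__all__ = ["RunConfig", "PipelineError", "run_full_analysis"]

log = logging.getLogger("glaucoma_cea")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """One analysis run.  Exactly one of ``cohort_path`` / ``synthetic_config``
    must be given, unless ``table4_mode`` is set (printed-values reproduction
    needs no cohort)."""

    out_dir: str | Path = "results"
    cohort_path: str | Path | None = None
    synthetic_config: synthetic.CohortConfig | str | Path | None = None
    prices_path: str | Path | None = None  # None -> bundled default price list
    thresholds: ControlThresholds = field(default_factory=ControlThresholds)
    policy: cea.ThresholdPolicy = field(default_factory=cea.ThresholdPolicy)
    effect_measures: tuple[EffectMeasure, ...] = (
        EffectMeasure.ST,
        EffectMeasure.TMS,
        EffectMeasure.NIBUT,
    )
    perturbation_range: tuple[float, float] = (-0.30, 0.30)
    reimbursement_rate: float = calibration.REIMBURSEMENT_RATE
    seed: int | None = None  # overrides the synthetic config's seed
    table4_mode: bool = False

    def validate(self) -> None:
        sources = sum(x is not None for x in (self.cohort_path, self.synthetic_config))
        if self.table4_mode:
            if sources:
                raise PipelineError(
                    "config: table4_mode takes no cohort or synthetic config"
                )
            return
        if sources != 1:
            raise PipelineError(
                "config: exactly one of cohort_path / synthetic_config is required"
            )


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name}: {exc}") from exc
            return False

    return _Ctx()


def _write_json(path: Path, payload) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _config_manifest(config: RunConfig) -> dict:
    echo = {
        "out_dir": str(config.out_dir),
        "cohort_path": str(config.cohort_path) if config.cohort_path else None,
        "synthetic_config": (
            config.synthetic_config.to_dict()
            if isinstance(config.synthetic_config, synthetic.CohortConfig)
            else (str(config.synthetic_config) if config.synthetic_config else None)
        ),
        "prices_path": str(config.prices_path) if config.prices_path else None,
        "thresholds": dataclasses.asdict(config.thresholds),
        "policy": dataclasses.asdict(config.policy),
        "effect_measures": [m.value for m in config.effect_measures],
        "perturbation_range": list(config.perturbation_range),
        "reimbursement_rate": config.reimbursement_rate,
        "seed": config.seed,
        "table4_mode": config.table4_mode,
    }
    digest = hashlib.sha256(json.dumps(echo, sort_keys=True).encode()).hexdigest()
    return {"version": __version__, "config": echo, "config_sha256": digest}


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns results as a dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"mode": "table4" if config.table4_mode else "cohort"}

    if config.table4_mode:
        with _stage("cea"):
            comparisons = calibration.printed_comparisons(policy=config.policy)
            rows = cea.results_to_rows([comparisons[m] for m in ("ST", "TMS", "NIBUT")])
            for row, measure in zip(rows, ("ST", "TMS", "NIBUT")):
                row["effect_measure"] = measure
            pd.DataFrame(rows).to_csv(out / "cea.csv", index=False)
            plane = cea.ce_plane(list(comparisons.values()), config.policy)
            pd.DataFrame(plane["points"]).to_csv(out / "ce_plane.csv", index=False)
            results["cea"] = {m: comparisons[m].to_dict() for m in comparisons}
            results["ce_plane"] = plane
        _write_json(out / "results.json", results)
        _write_json(out / "manifest.json", _config_manifest(config))
        return results

    with _stage("cohort"):
        if config.synthetic_config is not None:
            cfg = config.synthetic_config
            if not isinstance(cfg, synthetic.CohortConfig):
                cfg = synthetic.load_config(cfg)
            if config.seed is not None:
                cfg = dataclasses.replace(cfg, seed=config.seed)
            records = synthetic.generate_cohort(cfg)
            write_cohort(records, out / "cohort.csv")
            results["synthetic_seed"] = cfg.seed
        else:
            records = read_cohort(config.cohort_path)
        results["n_eyes"] = len(records)

    with _stage("summarize"):
        summary = summarize_cohort(records, config.thresholds)
        _write_json(out / "cohort_summary.json", summary.to_dict())
        results["cohort_summary"] = summary.to_dict()

    with _stage("costing"):
        prices = (
            costing.read_price_list(config.prices_path)
            if config.prices_path
            else costing.default_price_list()
        )
        cost_summary = costing.summarize_costs(records, prices)
        _write_json(out / "cost_summary.json", cost_summary.to_dict())
        results["cost_summary"] = cost_summary.to_dict()
        overall = cost_summary.glaucoma_overall
        tears = cost_summary.dry_eye
        split = costing.split_payment(
            overall.median if overall else 0.0,
            tears.median if tears else 0.0,
            config.reimbursement_rate,
        )
        results["payment_split_at_medians"] = dataclasses.asdict(split)

    spec = sensitivity.ComparisonSpec(reference=STRATEGY_NONFREE, comparator=STRATEGY_FREE)
    results["cea"] = {}
    results["tornado"] = {}
    plane_results = []
    for measure in config.effect_measures:
        with _stage(f"cea[{measure.value}]"):
            model = tree_mod.build_tree_from_cohort(
                records, config.thresholds, prices, effect_measure=measure
            )
            tree_mod.save_tree(model, out / f"tree_{measure.value}.json")
            values = {v.strategy: v for v in tree_mod.rollback(model)}
            result = cea.icer(
                values[STRATEGY_NONFREE], values[STRATEGY_FREE], policy=config.policy
            )
            results["cea"][measure.value] = result.to_dict()
            plane_results.append(result)
        with _stage(f"tornado[{measure.value}]"):
            if result.icer is None:
                warnings.warn(
                    f"{measure.value}: zero effect difference, tornado skipped", stacklevel=2
                )
                results["tornado"][measure.value] = None
                continue
            entries = sensitivity.tornado(
                model, spec, relative_range=config.perturbation_range
            )
            frame = pd.DataFrame(
                {
                    "parameter_id": [e.parameter_id for e in entries],
                    "icer_low": [e.icer_low for e in entries],
                    "icer_high": [e.icer_high for e in entries],
                    "base": [e.base_icer for e in entries],
                    "width": [e.width for e in entries],
                }
            )
            frame.to_csv(out / f"tornado_{measure.value}.csv", index=False)
            results["tornado"][measure.value] = frame.to_dict(orient="records")

    with _stage("cea"):
        rows = cea.results_to_rows(plane_results)
        for row, measure in zip(rows, config.effect_measures):
            row["effect_measure"] = measure.value
        pd.DataFrame(rows).to_csv(out / "cea.csv", index=False)
        plane = cea.ce_plane(plane_results, config.policy)
        pd.DataFrame(plane["points"]).to_csv(out / "ce_plane.csv", index=False)
        results["ce_plane"] = plane

    _write_json(out / "results.json", results)
    _write_json(out / "manifest.json", _config_manifest(config))
    return results
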