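"""End-to-end pipeline: preparation -> screening -> selection -> heterogeneity.

A single :class:`PipelineConfig` declares the cohort (a CSV file or a
synthetic specification), the outcome columns per timepoint, optional row
strata (e.g. sex-stratified reruns), and all stage settings.  The pipeline
runs the identical stage sequence for every (timepoint x outcome x stratum)
cell:

1. complete-case filter and near-zero-variance removal;
2. optional screening of a large candidate block (brain features) by
   adjusted regression with BH-FDR;
3. the three-step covariate-selection procedure (honest causal forests over
   random covariate orders and seed ensembles), gated on ATE significance
   and a significantly positive heterogeneity index;
4. for cells whose gates passed: the GATE tertile test, low- vs high-risk
   covariate profiling, and partial-dependence classification of each final
   covariate as risk / protective / flat.

Cells beyond the first outcome play the role of specificity analyses: a
cell is flagged ``pattern_failed`` when its high-minus-low GATE contrast is
not significant or the group ATEs are not monotone.  Everything is
deterministic given the config's seeds; reports carry no timestamps so a
rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import synthetic
from .estimands import aipw_scores, bh_fdr
from .forest import ForestParams, fit_nuisance
from .heterogeneity import compare_risk_groups, gate_test, partial_dependence
from .prep import complete_case_filter, drop_near_zero_variance, screen_features
from .selection import SelectionConfig, three_step_select
from .synthetic import CohortSpec, CohortTable, ModifierTerm


class OutcomeModel(BaseModel):
    """Generating model for one synthetic outcome column."""

    baseline_coefs: dict[str, float] = Field(default_factory=dict)
    tau_intercept: float = 0.0
    modifier_terms: list[ModifierTerm] = Field(default_factory=list)
    noise_sd: float = 1.0
    site_sd: float = 0.0


class SyntheticInput(BaseModel):
    spec: CohortSpec
    outcomes: dict[str, OutcomeModel]


class ScreeningSettings(BaseModel):
    enabled: bool = True
    candidate_prefix: str = "brain__"
    adjustment_prefixes: list[str] = Field(default_factory=lambda: ["environment__", "prs__"])
    alpha: float = Field(default=0.05, gt=0, lt=1)


class SelectionSettings(BaseModel):
    order_seeds: tuple[int, int, int] = (1, 2, 3)
    forest_seeds: tuple[tuple[int, ...], ...] = ((11, 12, 13), (21, 22, 23), (31, 32, 33))
    num_trees: int = 500
    min_node_size: int = 5
    mtry: Optional[int] = None
    nuisance_trees: int = 200
    ate_alpha: float = 0.05
    heterogeneity_alpha: float = 0.05
    apply_gates: bool = True
    empty_intersection_policy: str = "stop"

    def to_config(self, nuisance_seed: int = 0) -> SelectionConfig:
        return SelectionConfig(
            order_seeds=self.order_seeds,
            forest_seeds=self.forest_seeds,
            forest_params=ForestParams(
                num_trees=self.num_trees, min_node_size=self.min_node_size, mtry=self.mtry
            ),
            nuisance_trees=self.nuisance_trees,
            nuisance_seed=nuisance_seed,
            ate_alpha=self.ate_alpha,
            heterogeneity_alpha=self.heterogeneity_alpha,
            apply_gates=self.apply_gates,
            empty_intersection_policy=self.empty_intersection_policy,
        )


class Stratum(BaseModel):
    column: str
    value: float


class PipelineConfig(BaseModel):
    input_csv: Optional[str] = None
    synthetic: Optional[SyntheticInput] = None
    treatment: str = "treatment"
    cluster: str = "cluster"
    outcomes: dict[str, list[str]]  # timepoint -> outcome columns
    strata: dict[str, Optional[Stratum]] = Field(default_factory=lambda: {"all": None})
    min_stratum_size: int = 200
    screening: ScreeningSettings = ScreeningSettings()
    selection: SelectionSettings = SelectionSettings()
    gate_groups: int = 3
    pdp_points: int = 100
    pdp_rho_threshold: float = 0.5
    pdp_eps: float = 0.05
    output_dir: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            k: _jsonable(v)
            for k, v in dataclasses.asdict(obj).items()
            if k not in ("forest", "in_sample")
        }
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj, key=str)] if isinstance(obj, set) else [
            _jsonable(v) for v in obj
        ]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def load_cohort_frame(config: PipelineConfig) -> pd.DataFrame:
    if (config.input_csv is None) == (config.synthetic is None):
        raise ValueError("config must declare exactly one of input_csv / synthetic")
    if config.input_csv is not None:
        return pd.read_csv(config.input_csv)
    syn = config.synthetic
    frame, _ = synthetic.generate_cohort_frame(
        syn.spec,
        {
            name: synthetic.OutcomeSpec(
                baseline_coefs=om.baseline_coefs,
                tau_intercept=om.tau_intercept,
                modifier_terms=om.modifier_terms,
                noise_sd=om.noise_sd,
                site_sd=om.site_sd,
            )
            for name, om in syn.outcomes.items()
        },
    )
    return frame


def _run_cell(
    frame: pd.DataFrame,
    config: PipelineConfig,
    timepoint: str,
    outcome: str,
    stratum_name: str,
    stratum: Stratum | None,
) -> dict:
    cell: dict[str, Any] = {
        "timepoint": timepoint,
        "outcome": outcome,
        "stratum": stratum_name,
    }
    sub = frame
    if stratum is not None:
        sub = frame[frame[stratum.column] == stratum.value]
        if len(sub) < config.min_stratum_size:
            cell["skipped"] = f"stratum below minimum size ({len(sub)} < {config.min_stratum_size})"
            return cell

    reserved = {config.treatment, config.cluster} | {
        c for cols in config.outcomes.values() for c in cols
    }
    covariates = [c for c in sub.columns if c not in reserved]
    if stratum is not None:
        covariates = [c for c in covariates if c != stratum.column]
    table = CohortTable.from_frame(
        sub, treatment=config.treatment, outcome=outcome,
        cluster=config.cluster, covariates=covariates,
    )
    table, n_removed = complete_case_filter(table)
    table, dropped = drop_near_zero_variance(table)
    cell["n"] = table.n
    cell["n_removed_incomplete"] = n_removed
    cell["dropped_near_zero_variance"] = dropped

    if config.screening.enabled:
        candidates = [
            c for c in table.covariate_names if c.startswith(config.screening.candidate_prefix)
        ]
        if candidates:
            adjustment = [
                c
                for c in table.covariate_names
                if any(c.startswith(p) for p in config.screening.adjustment_prefixes)
            ]
            screen = screen_features(table, candidates, adjustment, alpha=config.screening.alpha)
            keep = [c for c in table.covariate_names if c not in candidates] + screen.selected
            keep = [c for c in table.covariate_names if c in set(keep)]
            table = table.select_covariates(keep)
            cell["screening"] = {
                "n_candidates": len(candidates),
                "n_selected": len(screen.selected),
                "selected": screen.selected,
            }

    sel_config = config.selection.to_config(nuisance_seed=config.seed)
    trace = three_step_select(table, config=sel_config)
    cell["selection"] = {
        "stop_reason": trace.stop_reason,
        "final_covariates": trace.final_covariates,
        "stages": [
            {
                "stage": st.stage,
                "covariates": st.covariates,
                "gates_passed": st.gates_passed,
                "intersection": sorted(st.intersection) if st.intersection is not None else None,
                "iterations": [
                    {
                        "iteration_id": it.iteration_id,
                        "order_seed": it.order_seed,
                        "forest_seeds": list(it.forest_seeds),
                        "retained": sorted(it.retained),
                        "ate": _jsonable(it.eval.ate),
                        "calibration": _jsonable(it.eval.calibration),
                        "importance": _jsonable(it.importance_table()),
                    }
                    for it in st.iterations
                ],
            }
            for st in trace.stages
        ],
    }

    if not trace.completed:
        cell["specificity"] = {"pattern_failed": True, "reason": trace.stop_reason}
        return cell

    # headline model: Random Iteration 1 of the final stage
    final_it = trace.final_models()[0]
    final_table = table.select_covariates(final_it.covariate_order)
    nuisance = fit_nuisance(
        final_table, n_estimators=sel_config.nuisance_trees, seed=sel_config.nuisance_seed
    )
    scores = aipw_scores(final_table, nuisance, final_it.forest.oob_tau)
    gate = gate_test(scores, final_it.forest.oob_tau, n_groups=config.gate_groups)
    cell["gate"] = {
        "group_ates": {k: _jsonable(v) for k, v in gate.group_ates.items()},
        "contrasts": _jsonable(gate.contrasts),
        "monotonic": gate.monotonic,
        "no_ranking_signal": gate.no_ranking_signal,
    }
    profile = compare_risk_groups(final_table, gate, trace.final_covariates)
    cell["profile"] = _jsonable(profile.contrasts)
    cell["pdp"] = []
    for name in trace.final_covariates:
        curve = partial_dependence(
            final_it.forest, final_table, name,
            n_points=config.pdp_points,
            rho_threshold=config.pdp_rho_threshold, eps=config.pdp_eps,
        )
        cell["pdp"].append(
            {
                "covariate": name,
                "trend": curve.trend,
                "trend_stat": curve.trend_stat,
                "grid": _jsonable(curve.grid),
                "percentiles": _jsonable(curve.percentiles),
                "simulated_ite": _jsonable(curve.simulated_ite),
            }
        )

    headline = gate.headline
    failed = headline is None or not np.isfinite(headline.fdr_q) or headline.fdr_q >= 0.05
    failed = failed or not gate.monotonic
    reasons = []
    if headline is None or not np.isfinite(headline.fdr_q) or headline.fdr_q >= 0.05:
        reasons.append("high-minus-low GATE contrast not significant")
    if not gate.monotonic:
        reasons.append("group ATEs not monotone")
    cell["specificity"] = {"pattern_failed": bool(failed), "reason": "; ".join(reasons) or "ok"}
    return cell


def _apply_fdr_families(cells: list[dict]) -> None:
    """BH-FDR across cells for the headline ATE / model fit / heterogeneity tests.

    The family is one pipeline run: the last-reached stage's Random
    Iteration 1 results of every non-skipped cell.
    """
    idx = []
    p_ate, p_alpha, p_beta = [], [], []
    for i, cell in enumerate(cells):
        stages = cell.get("selection", {}).get("stages")
        if not stages:
            continue
        it1 = stages[-1]["iterations"][0]
        idx.append(i)
        p_ate.append(it1["ate"]["p_value"])
        p_alpha.append(it1["calibration"]["p_alpha"])
        p_beta.append(it1["calibration"]["p_beta"])
    if not idx:
        return
    q_ate = bh_fdr([p if p is not None else np.nan for p in p_ate])
    q_alpha = bh_fdr([p if p is not None else np.nan for p in p_alpha])
    q_beta = bh_fdr([p if p is not None else np.nan for p in p_beta])
    for k, i in enumerate(idx):
        it1 = cells[i]["selection"]["stages"][-1]["iterations"][0]
        it1["ate"]["fdr_q"] = _jsonable(q_ate[k])
        it1["calibration"]["fdr_q_alpha"] = _jsonable(q_alpha[k])
        it1["calibration"]["fdr_q_beta"] = _jsonable(q_beta[k])


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every (timepoint x outcome x stratum) cell and assemble the report."""
    frame = load_cohort_frame(config)
    cells = []
    for timepoint, outcome_cols in config.outcomes.items():
        for outcome in outcome_cols:
            for stratum_name, stratum in config.strata.items():
                try:
                    cell = _run_cell(frame, config, timepoint, outcome, stratum_name, stratum)
                except Exception as exc:  # cell failures must not stop the run
                    cell = {
                        "timepoint": timepoint,
                        "outcome": outcome,
                        "stratum": stratum_name,
                        "error": f"{type(exc).__name__}: {exc}",
                    }
                cells.append(cell)
    _apply_fdr_families(cells)
    report = {
        # output_dir is a location, not an analysis input: keep it out of the
        # report so reruns writing elsewhere stay byte-identical
        "config": json.loads(config.model_dump_json(exclude={"output_dir"})),
        "cells": cells,
        "specificity_summary": [
            {
                "timepoint": c["timepoint"],
                "outcome": c["outcome"],
                "stratum": c["stratum"],
                "pattern_failed": c.get("specificity", {}).get("pattern_failed"),
                "reason": c.get("specificity", {}).get("reason"),
            }
            for c in cells
            if "specificity" in c
        ],
    }
    if config.output_dir:
        write_report(report, config.output_dir)
    return report


def write_report(report: dict, output_dir) -> None:
    """Write report.json, a Markdown summary, and per-cell CSV tables."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
    lines = ["# Pipeline report", ""]
    rows = []
    for cell in report["cells"]:
        tag = f"{cell['timepoint']}/{cell['outcome']}/{cell['stratum']}"
        if "error" in cell:
            lines.append(f"- **{tag}**: error — {cell['error']}")
            continue
        if "skipped" in cell:
            lines.append(f"- **{tag}**: skipped — {cell['skipped']}")
            continue
        sel = cell["selection"]
        it1 = sel["stages"][-1]["iterations"][0]
        ate = it1["ate"]
        cal = it1["calibration"]
        lines.append(
            f"- **{tag}** (n={cell['n']}): {sel['stop_reason']}; "
            f"ATE={ate['estimate']:.3f} (p={ate['p_value']:.3g}), "
            f"heterogeneity index={cal['heterogeneity_index'] if cal['heterogeneity_index'] is not None else 'NA'}"
        )
        if cell.get("gate"):
            mono = "monotone" if cell["gate"]["monotonic"] else "non-monotone"
            lines.append(f"    - GATE: {mono}; group ATEs "
                         + ", ".join(f"{k}={v['estimate']:.3f}" for k, v in cell["gate"]["group_ates"].items()))
        if cell.get("pdp"):
            trends = ", ".join(f"{p['covariate']}:{p['trend']}" for p in cell["pdp"])
            lines.append(f"    - PDP trends: {trends}")
        # per-cell CSV artifacts
        stem = tag.replace("/", "_")
        imp = pd.DataFrame(
            it1["importance"], columns=["covariate", "importance", "retained"]
        )
        imp.to_csv(out / f"{stem}_importance.csv", index=False)
        if cell.get("gate"):
            gate_rows = [
                {"group": k, "ate": v["estimate"], "se": v["se"], "p": v["p_value"]}
                for k, v in cell["gate"]["group_ates"].items()
            ]
            pd.DataFrame(gate_rows).to_csv(out / f"{stem}_gate.csv", index=False)
        if cell.get("profile"):
            pd.DataFrame(cell["profile"]).to_csv(out / f"{stem}_profile.csv", index=False)
        if cell.get("pdp"):
            pdp_rows = []
            for p in cell["pdp"]:
                for pct, val, ite in zip(p["percentiles"], p["grid"], p["simulated_ite"]):
                    pdp_rows.append(
                        {"covariate": p["covariate"], "percentile": pct, "value": val, "ite": ite}
                    )
            pd.DataFrame(pdp_rows).to_csv(out / f"{stem}_pdp.csv", index=False)
    lines.append("")
    lines.append("## Specificity summary")
    for row in report["specificity_summary"]:
        status = "pattern FAILED" if row["pattern_failed"] else "pattern held"
        lines.append(
            f"- {row['timepoint']}/{row['outcome']}/{row['stratum']}: {status} ({row['reason']})"
        )
    (out / "summary.md").write_text("\n".join(lines) + "\n")
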