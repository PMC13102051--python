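"""Three-step covariate selection over randomized orders and seed ensembles.

The procedure fits a sequence of progressively sparser causal-forest models:

* **First model** — all covariates.  Three *random iterations* shuffle the
  covariate order with different order seeds; each iteration merges three
  forests grown with different seeds into one big forest and retains the
  covariates whose split-frequency importance exceeds the mean importance.
* The **intersection** of the retained sets across the three iterations is
  the second covariate set; the **second model** repeats the procedure on
  it, yielding the final covariate set.
* The **final model** is fitted once per iteration on the final set, and
  its ATE and calibration results are the headline output.

A stage is only entered if the previous one passed its significance gates
(ATE significant AND heterogeneity index significantly positive); when the
first model already shows no significant variation among individuals, the
procedure stops — there is no heterogeneity to localize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .estimands import (
    AteResult,
    CalibrationResult,
    aipw_scores,
    average_treatment_effect,
    calibration_test,
)
from .forest import (
    CausalForest,
    ForestParams,
    NuisanceFits,
    fit_causal_forest,
    fit_nuisance,
    merge_forests,
    variable_importance,
)
from .synthetic import CohortTable


@dataclass(frozen=True)
class SelectionConfig:
    order_seeds: tuple[int, int, int] = (1, 2, 3)
    forest_seeds: tuple[tuple[int, ...], ...] = ((11, 12, 13), (21, 22, 23), (31, 32, 33))
    forest_params: ForestParams = ForestParams()
    nuisance_trees: int = 200
    nuisance_seed: int = 0
    ate_alpha: float = 0.05
    heterogeneity_alpha: float = 0.05
    apply_gates: bool = True
    empty_intersection_policy: str = "stop"  # or "topk"
    topk: int = 10


@dataclass
class ModelEval:
    """ATE + calibration of one merged forest."""

    ate: AteResult
    calibration: CalibrationResult

    def passes_gates(self, config: SelectionConfig) -> bool:
        if self.ate.degenerate or self.calibration.degenerate:
            return False
        return (
            self.ate.p_value < config.ate_alpha
            and self.calibration.p_beta < config.heterogeneity_alpha
        )


@dataclass
class IterationResult:
    iteration_id: int
    order_seed: int
    forest_seeds: tuple[int, ...]
    covariate_order: list[str]
    importance: np.ndarray  # aligned with covariate_order
    retained: set[str]
    eval: ModelEval
    forest: CausalForest = field(repr=False)

    def importance_table(self) -> list[tuple[str, float, bool]]:
        return [
            (name, float(imp), name in self.retained)
            for name, imp in zip(self.covariate_order, self.importance)
        ]


@dataclass
class StageResult:
    stage: str  # "first" | "second" | "final"
    covariates: list[str]
    iterations: list[IterationResult]
    intersection: set[str] | None
    gates_passed: bool


@dataclass
class SelectionTrace:
    stages: list[StageResult]
    final_covariates: list[str] | None
    stop_reason: str  # "completed" | "heterogeneity not significant (<stage>)" | "empty intersection"

    @property
    def completed(self) -> bool:
        return self.stop_reason == "completed"

    def covariate_sets(self) -> list[set[str]]:
        return [set(s.covariates) for s in self.stages]

    def final_models(self) -> list[IterationResult]:
        if not self.stages or self.stages[-1].stage != "final":
            return []
        return self.stages[-1].iterations


def retained_above_mean(names: Sequence[str], importance: np.ndarray) -> set[str]:
    """Covariates with importance strictly above the mean importance."""
    importance = np.asarray(importance, dtype=float)
    return {n for n, v in zip(names, importance) if v > importance.mean()}


def run_random_iteration(
    table: CohortTable,
    covariates: Sequence[str],
    order_seed: int,
    forest_seeds: Sequence[int],
    nuisance: NuisanceFits,
    params: ForestParams = ForestParams(),
    iteration_id: int = 1,
) -> IterationResult:
    """One random iteration: shuffle order, fit a 3-seed ensemble, rank covariates."""
    if len(set(forest_seeds)) < len(forest_seeds):
        warnings.warn("duplicate forest seeds in a seed ensemble")
    order = list(np.array(covariates)[np.random.default_rng(order_seed).permutation(len(covariates))])
    sub = table.select_covariates(order)
    forests = [fit_causal_forest(sub, nuisance, params, seed=s) for s in forest_seeds]
    merged = merge_forests(forests, sub)
    importance = variable_importance(merged)
    retained = retained_above_mean(order, importance)
    scores = aipw_scores(sub, nuisance, merged.oob_tau)
    eval_ = ModelEval(
        ate=average_treatment_effect(scores),
        calibration=calibration_test(sub, nuisance, merged.oob_tau),
    )
    return IterationResult(
        iteration_id=iteration_id,
        order_seed=order_seed,
        forest_seeds=tuple(forest_seeds),
        covariate_order=order,
        importance=importance,
        retained=retained,
        eval=eval_,
        forest=merged,
    )


def intersect_retained(results: Sequence[IterationResult]) -> set[str]:
    """Exact intersection of the retained sets across iterations."""
    sets = [r.retained for r in results]
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def _run_stage(
    table: CohortTable,
    covariates: Sequence[str],
    config: SelectionConfig,
    stage: str,
) -> StageResult:
    sub = table.select_covariates(list(covariates))
    nuisance = fit_nuisance(
        sub, n_estimators=config.nuisance_trees, seed=config.nuisance_seed
    )
    iterations = [
        run_random_iteration(
            table,
            covariates,
            order_seed=config.order_seeds[k],
            forest_seeds=config.forest_seeds[k],
            nuisance=nuisance,
            params=config.forest_params,
            iteration_id=k + 1,
        )
        for k in range(len(config.order_seeds))
    ]
    intersection = intersect_retained(iterations) if stage != "final" else None
    # gate on Random Iteration 1, the headline model
    gates = (not config.apply_gates) or iterations[0].eval.passes_gates(config)
    return StageResult(
        stage=stage,
        covariates=list(covariates),
        iterations=iterations,
        intersection=intersection,
        gates_passed=gates,
    )


def _fallback_topk(stage: StageResult, k: int) -> set[str]:
    mean_imp = {}
    for it in stage.iterations:
        for name, imp, _ in it.importance_table():
            mean_imp[name] = mean_imp.get(name, 0.0) + imp / len(stage.iterations)
    ranked = sorted(mean_imp, key=lambda n: (-mean_imp[n], n))
    return set(ranked[:k])


def three_step_select(
    table: CohortTable,
    covariates: Sequence[str] | None = None,
    config: SelectionConfig = SelectionConfig(),
) -> SelectionTrace:
    """Run the full first -> second -> final model sequence.

    Returns a trace of every stage; stops early (with a reason, never an
    exception) when a significance gate fails or an intersection is empty
    under the "stop" policy.
    """
    if covariates is None:
        covariates = list(table.covariate_names)
    if len(covariates) < 4:
        raise ValueError("need at least 4 covariates for the three-step procedure")

    stages: list[StageResult] = []
    current = list(covariates)
    for stage_name in ("first", "second"):
        stage = _run_stage(table, current, config, stage_name)
        stages.append(stage)
        if not stage.gates_passed:
            return SelectionTrace(
                stages=stages,
                final_covariates=None,
                stop_reason=f"heterogeneity not significant ({stage_name})",
            )
        nxt = stage.intersection
        if not nxt:
            if config.empty_intersection_policy == "topk":
                nxt = _fallback_topk(stage, config.topk)
            else:
                return SelectionTrace(
                    stages=stages, final_covariates=None, stop_reason="empty intersection"
                )
        # preserve the original covariate order for reproducibility
        current = [c for c in current if c in nxt]

    final_stage = _run_stage(table, current, config, "final")
    stages.append(final_stage)
    return SelectionTrace(stages=stages, final_covariates=current, stop_reason="completed")
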