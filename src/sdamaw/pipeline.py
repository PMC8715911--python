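"""End-to-end method development: screen -> split -> RFE -> fit -> refine -> evaluate.

This module wires the individual stages into the `develop` workflow: metric
screening on initial visits, a reach-level stratified 80/20 split, recursive
feature elimination on the calibration set, fitting the vote model,
discretizing the selected metrics into field categories, generating the
crosswalk table, applying single indicators, and reporting accuracy and
repeatability on calibration and validation reaches. Options mirror the
development design grid: with/without geospatial metrics, with/without
direct measures of water presence, regional or subregionally stratified
models, forest or single-tree classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classifiers import (
    ClassifierModel,
    DEFAULT_TAU,
    fit_classifier,
    threshold_sweep,
    vote_threshold_classify,
)
from .core_data import MetricTable, PredictedClass, Reach, StreamflowClass
from .evaluation import (
    DEFAULT_CONVENTION,
    PerformanceReport,
    ScoringConvention,
    accuracy_measures,
    repeatability,
)
from .model_selection import RfeTrace, SplitAssignment, rfe_select, stratified_split
from .refinement import (
    CrosswalkTable,
    DiscretizationRule,
    apply_single_indicators,
    build_crosswalk_table,
    partial_dependence_discretize,
)
from .screening import screen_metrics, passed_metrics

__all__ = ["RunConfig", "DevelopmentResult", "develop_method"]


@dataclass
class RunConfig:
    """Options for one development run (one cell of the design grid)."""

    include_geospatial: bool = False
    include_direct_water: bool = False
    stratify_by_subregion: bool = False
    model_kind: str = "forest"  # "forest" | "single_tree"
    tau: float = DEFAULT_TAU
    convention: ScoringConvention = field(default_factory=ScoringConvention)
    split_fraction: float = 0.8
    n_trees_final: int = 1500
    n_trees_screening: int = 500
    n_trees_rfe: int = 500
    rfe_cv_splits: int = 5
    rfe_tolerance: float = 0.01
    max_model_size: int = 20
    #: crosswalk enumeration is only feasible for small categorical models
    max_crosswalk_metrics: int = 8
    discretize_max_cuts: int = 2
    discretize_min_jump: float = 0.05


@dataclass
class DevelopmentResult:
    """Everything produced by one development run."""

    config: RunConfig
    seed: int
    split: SplitAssignment
    screening: dict
    screened_metrics: list
    rfe_trace: RfeTrace
    selected_metrics: tuple
    model: ClassifierModel
    discretization_rules: dict
    crosswalk: Optional[CrosswalkTable]
    votes: pd.DataFrame  # per (reach_id, visit_index): v_E, v_I, v_P
    predictions: pd.Series  # per (reach_id, visit_index) final PredictedClass
    report_calibration: PerformanceReport
    report_validation: PerformanceReport
    sweep: pd.DataFrame

    def summary(self) -> dict:
        rep, rep_n = self.report_calibration.repeatability, self.report_calibration.repeatability_n
        return {
            "n_screened": len(self.screened_metrics),
            "selected_size": self.rfe_trace.selected_size,
            "selected_metrics": list(self.selected_metrics),
            "calibration": self.report_calibration.to_dict(),
            "validation": self.report_validation.to_dict(),
            "repeatability": {"value": rep, "n": rep_n},
        }


def _classify_rows(
    model: ClassifierModel,
    raw_rows: pd.DataFrame,
    model_rows: pd.DataFrame,
    tau: float,
    fish: Optional[pd.Series],
    algal: Optional[pd.Series],
    rules: Mapping[str, DiscretizationRule],
    crosswalk: Optional[CrosswalkTable],
) -> tuple:
    """Vote, threshold-classify and apply single indicators to metric rows.

    ``raw_rows`` hold the original metric values (used to derive the field
    categories); ``model_rows`` what the model consumes (ordinal codes for a
    categorical model, the raw values otherwise). When a crosswalk is
    available the final outcome is its lookup of the discretized row (the
    published-method path); otherwise the model votes are used directly.
    """
    votes = model.predict_votes(model_rows)
    preds = []
    for k, idx in enumerate(raw_rows.index):
        f = bool(fish.loc[idx]) if fish is not None else False
        a = bool(algal.loc[idx]) if algal is not None else False
        if crosswalk is not None:
            combo = {
                m: str(rules[m].apply(raw_rows.loc[idx, m])) for m in model.metric_names
            }
            combo["fish_present"] = f
            combo["algal_cover_ge10"] = a
            preds.append(crosswalk.lookup(combo))
        else:
            base = vote_threshold_classify(votes[k], tau=tau)
            preds.append(apply_single_indicators(base, f, a))
    return votes, preds


def develop_method(
    table: MetricTable,
    reaches: Sequence[Reach],
    config: Optional[RunConfig] = None,
    seed: int = 0,
    fish_present: Optional[pd.Series] = None,
    algal_cover_ge10: Optional[pd.Series] = None,
) -> DevelopmentResult:
    """Run the full development pipeline on a metric table.

    ``table`` holds all visits (initial + revisits); fitting and selection
    use calibration initial visits only. ``fish_present`` and
    ``algal_cover_ge10`` are optional per-visit single-indicator flags.
    Subregionally stratified runs fit one model per subregion on the shared
    screened metric set and pool the predictions.
    """
    config = config or RunConfig()
    truth = {r.reach_id: r.true_class for r in reaches}
    table = table.select_metrics(
        include_geospatial=config.include_geospatial,
        include_direct_water=config.include_direct_water,
    )
    flow_state = _flow_state_from_table(table)

    if config.stratify_by_subregion:
        return _develop_stratified(
            table, reaches, config, seed, fish_present, algal_cover_ge10, flow_state
        )

    # 1. screening on all initial visits
    screening = screen_metrics(
        table, truth, flow_state, seed=seed, n_trees=config.n_trees_screening
    )
    screened = passed_metrics(screening)
    if not screened:
        raise ValueError("no metric passed screening")

    # 2. reach-level stratified split
    split = stratified_split(reaches, fraction=config.split_fraction, seed=seed)
    cal_table = table.subset_columns(screened).subset_reaches(split.calibration)
    cal_first = cal_table.initial_visits().data.dropna(axis=0)
    cal_truth = [truth[r] for r in cal_first.index.get_level_values(0)]

    # 3. recursive feature elimination on calibration initial visits
    trace = rfe_select(
        cal_first,
        cal_truth,
        seed=seed,
        n_trees=config.n_trees_rfe,
        cv_splits=config.rfe_cv_splits,
        tolerance=config.rfe_tolerance,
        max_size=config.max_model_size,
    )
    selected = trace.selected_metrics

    # 4. final model on the selected metrics
    model = fit_classifier(
        cal_first[list(selected)],
        cal_truth,
        kind=config.model_kind,
        seed=seed,
        n_trees=config.n_trees_final,
    )

    # 5. discretize selected metrics and build the crosswalk, when small enough
    rules = {}
    crosswalk = None
    if len(selected) <= config.max_crosswalk_metrics:
        for m in selected:
            rules[m] = partial_dependence_discretize(
                model,
                cal_first[list(selected)],
                m,
                min_jump=config.discretize_min_jump,
                max_cuts=config.discretize_max_cuts,
            )
        levels = {m: tuple(rules[m].labels) for m in selected}
        cat_cal = pd.DataFrame(
            {m: rules[m].codes(cal_first[m].to_numpy()) for m in selected},
            index=cal_first.index,
            dtype=float,
        )
        cat_model = fit_classifier(
            cat_cal, cal_truth, kind=config.model_kind, seed=seed,
            n_trees=config.n_trees_final,
        )
        crosswalk = build_crosswalk_table(cat_model, levels, tau=config.tau)
        model_for_rows: ClassifierModel = cat_model
        rows_transform = lambda rows: pd.DataFrame(
            {m: rules[m].codes(rows[m].to_numpy()) for m in selected},
            index=rows.index,
            dtype=float,
        )
    else:
        model_for_rows = model
        rows_transform = lambda rows: rows[list(selected)]

    # 6. classify every complete visit row
    all_rows = table.data[list(selected)].dropna(axis=0)
    votes_arr, preds = _classify_rows(
        model_for_rows,
        all_rows,
        rows_transform(all_rows),
        config.tau,
        fish_present,
        algal_cover_ge10,
        rules,
        crosswalk,
    )
    votes = pd.DataFrame(votes_arr, index=all_rows.index, columns=["v_E", "v_I", "v_P"])
    predictions = pd.Series(preds, index=all_rows.index, name="classification")

    return _finalize(
        table, reaches, config, seed, split, screening, screened, trace, selected,
        model, rules, crosswalk, votes, predictions, flow_state, truth,
    )


def _flow_state_from_table(table: MetricTable) -> dict:
    """Flow state per row from a direct surface-flow column when present,
    else 'flowing' (the state only matters for direct-water generators and
    the restricted accuracy measures)."""
    for candidate in ("pctsurfaceflow", "h2o_direct_1"):
        if candidate in table.data.columns:
            col = table.data[candidate]
            return {
                idx: ("flowing" if v > 0 else "dry") for idx, v in col.items()
            }
    return {idx: "flowing" for idx in table.data.index}


def _finalize(
    table, reaches, config, seed, split, screening, screened, trace, selected,
    model, rules, crosswalk, votes, predictions, flow_state, truth,
) -> DevelopmentResult:
    rep_by_reach = {}
    for rid, group in predictions.groupby(level=0):
        rep_by_reach[rid] = [group.loc[(rid, vi)] for vi in sorted(
            group.index.get_level_values(1))]
    rep, rep_n = repeatability(rep_by_reach)

    def report_for(reach_ids):
        mask = [
            (rid in set(reach_ids)) and (vi == 1)
            for rid, vi in predictions.index
        ]
        idx = predictions.index[mask]
        if len(idx) == 0:
            raise ValueError("no rows to evaluate")
        return accuracy_measures(
            predictions.loc[idx].tolist(),
            [truth[rid] for rid, _ in idx],
            [flow_state[key] for key in idx],
            convention=config.convention,
        )

    report_cal = report_for(split.calibration)
    report_val = report_for(split.validation)
    report_cal.repeatability, report_cal.repeatability_n = rep, rep_n

    first_mask = votes.index.get_level_values(1) == 1
    sweep = threshold_sweep(votes.loc[first_mask].to_numpy())

    return DevelopmentResult(
        config=config,
        seed=seed,
        split=split,
        screening=screening,
        screened_metrics=screened,
        rfe_trace=trace,
        selected_metrics=tuple(selected),
        model=model,
        discretization_rules=rules,
        crosswalk=crosswalk,
        votes=votes,
        predictions=predictions,
        report_calibration=report_cal,
        report_validation=report_val,
        sweep=sweep,
    )


def _develop_stratified(
    table, reaches, config, seed, fish_present, algal_cover_ge10, flow_state
) -> DevelopmentResult:
    """One model per subregion; screening, split and RFE run within subregion.

    Predictions and reports are pooled across subregions; the returned model,
    trace and crosswalk are those of the largest subregion (kept for
    inspection — the pooled predictions are the stratified result).
    """
    from .core_data import SUBREGIONS

    sub_of = {r.reach_id: r.subregion for r in reaches}
    results = {}
    for sub in SUBREGIONS:
        sub_reaches = [r for r in reaches if r.subregion == sub]
        if not sub_reaches:
            continue
        sub_table = table.subset_reaches([r.reach_id for r in sub_reaches])
        sub_cfg = RunConfig(**{**config.__dict__, "stratify_by_subregion": False})
        results[sub] = develop_method(
            sub_table, sub_reaches, sub_cfg, seed=seed,
            fish_present=fish_present, algal_cover_ge10=algal_cover_ge10,
        )
    if not results:
        raise ValueError("no reaches supplied")
    votes = pd.concat([r.votes for r in results.values()]).sort_index()
    predictions = pd.concat([r.predictions for r in results.values()]).sort_index()
    split = SplitAssignment(
        assignment={
            rid: grp
            for r in results.values()
            for rid, grp in r.split.assignment.items()
        },
        seed=seed,
        fraction=config.split_fraction,
    )
    largest = max(results.values(), key=lambda r: len(r.votes))
    truth = {r.reach_id: r.true_class for r in reaches}
    merged = _finalize(
        table, reaches, config, seed, split, largest.screening,
        largest.screened_metrics, largest.rfe_trace, largest.selected_metrics,
        largest.model, largest.discretization_rules, largest.crosswalk,
        votes, predictions, flow_state, truth,
    )
    return merged
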