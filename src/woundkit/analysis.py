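"""End-to-end analysis pipeline.

normalize → orient → step-artifact QC → replicate combination →
replicate-distance QC → per-replicate regression → condition medians →
pairwise Mann–Whitney comparison with multiple-testing correction.

The pipeline never mutates the loaded experiment: corrections produce new
normalized series (originals stay on ``.base``), exclusions only remove
replicates from the velocity analysis, and every flag/decision is recorded
in the QC log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataio import LoadedExperiment, TimeSeries
from .errors import GridError, ValidationError
from .preprocessing import NormalizedSeries, normalize, orient
from .qc import (
    ArtifactPolicy,
    StepArtifact,
    detect_step_artifacts,
    correct_artifact,
    fit_kde,
    replicate_distances,
    resolve_decisions,
    shared_time_grid,
)
from .stats import (
    ConditionResult,
    PairwiseComparison,
    ReplicateFit,
    compare_conditions,
    condition_velocity,
    fit_replicate,
)


@dataclass(frozen=True)
class AnalysisConfig:
    artifact_alpha: float = 0.05
    kernel: str = "gaussian"
    bandwidth: float | str = "auto"
    pool_deltas: bool = True  # fit the KDE on the condition's pooled deltas
    k_mad: float = 3.0
    distance_metric: str = "euclidean"
    policy: str = "accept_all"  # accept_all | reject_all | ask
    decisions: dict[str, str] | None = None
    correction: str = "benjamini_hochberg"
    alpha: float = 0.05
    test_mode: str = "auto"
    r2_threshold: float | None = None  # optional replicate filter, off by default
    selection: tuple[str, ...] | None = None
    run_step_qc: bool = True
    run_replicate_qc: bool = True


@dataclass(frozen=True)
class QCLogEntry:
    flag_id: str
    kind: str  # step_artifact | replicate_outlier
    condition: str
    detail: str
    action: str
    provenance: str


@dataclass
class PipelineResult:
    loaded: LoadedExperiment
    config: AnalysisConfig
    normalized: dict[tuple[str, str], NormalizedSeries]  # (well, label) -> series
    combined: dict[str, list[NormalizedSeries]]  # condition -> per-well trajectory
    qc_log: list[QCLogEntry]
    excluded_replicates: list[tuple[str, str]]  # (condition, well)
    condition_results: list[ConditionResult]
    comparisons: list[PairwiseComparison]


def combine_well_series(series: list[NormalizedSeries]) -> NormalizedSeries:
    """Pointwise mean of normalized values on the common time grid.

    With a single series this is the identity; with several (imaging
    positions, modalities) it is the conventional per-well average.
    """
    if len(series) == 1:
        return series[0]
    idx = shared_time_grid(series)
    if len(idx[0]) < 3:
        raise GridError("fewer than 3 shared time points across well series")
    grid = series[0].time[idx[0]]
    mean = np.mean([s.normalized[ix] for s, ix in zip(series, idx)], axis=0)
    base = TimeSeries(
        well=series[0].well,
        source_label="combined",
        time=grid,
        area=np.maximum(mean, 1e-9),
    )
    return NormalizedSeries(
        base=base,
        time=grid.copy(),
        normalized=mean,
        expected_trend=series[0].expected_trend,
    )


def run_pipeline(loaded: LoadedExperiment, config: AnalysisConfig = AnalysisConfig()) -> PipelineResult:
    loaded.validate()
    exp = loaded.experiment
    qc_log: list[QCLogEntry] = []

    # --- normalization + orientation, grouped by condition -----------------
    normalized: dict[tuple[str, str], NormalizedSeries] = {}
    cond_of_series: dict[tuple[str, str], str] = {}
    for s in loaded.series:
        cond = exp.condition_of(s.well)
        ns = orient(normalize(s), cond.assay_kind)
        key = (s.well.name, s.source_label)
        normalized[key] = ns
        cond_of_series[key] = cond.name

    # --- stage 1: step-artifact QC -----------------------------------------
    if config.run_step_qc:
        policy = ArtifactPolicy(alpha=config.artifact_alpha)
        flags_by_id: dict[str, tuple[tuple[str, str], StepArtifact]] = {}
        for cond in exp.conditions:
            keys = [k for k, cn in cond_of_series.items() if cn == cond.name]
            pooled = np.concatenate([normalized[k].deltas for k in keys])
            for key in keys:
                pts = pooled if config.pool_deltas else normalized[key].deltas
                if len(pts) < 2:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    kde = fit_kde(pts, kernel=config.kernel, bandwidth=config.bandwidth)
                for art in detect_step_artifacts(normalized[key], kde, policy):
                    flags_by_id[art.flag_id] = (key, art)
        file_dec = {
            k: v for k, v in (config.decisions or {}).items() if k in flags_by_id
        }
        decisions = resolve_decisions(
            list(flags_by_id), policy=config.policy, decisions=file_dec
        )
        for dec in decisions:
            key, art = flags_by_id[dec.flag_id]
            if dec.action == "accept":
                normalized[key] = correct_artifact(normalized[key], art)
            qc_log.append(
                QCLogEntry(
                    flag_id=dec.flag_id,
                    kind="step_artifact",
                    condition=cond_of_series[key],
                    detail=(
                        f"delta={art.delta_value:.6g} density={art.density_at_delta:.6g} "
                        f"reason={art.reason}"
                    ),
                    action=dec.action,
                    provenance=dec.provenance,
                )
            )

    # --- combine multi-series wells into one replicate trajectory ----------
    combined: dict[str, list[NormalizedSeries]] = {}
    for cond in exp.conditions:
        per_well: list[NormalizedSeries] = []
        for well in cond.wells:
            series = [
                ns
                for (wn, _lbl), ns in sorted(normalized.items())
                if wn == well.name
            ]
            per_well.append(combine_well_series(series))
        combined[cond.name] = per_well

    # --- stage 2: replicate-distance QC -------------------------------------
    excluded: list[tuple[str, str]] = []
    if config.run_replicate_qc:
        reports = {}
        for cond in exp.conditions:
            if len(combined[cond.name]) < 2:
                continue
            reports[cond.name] = replicate_distances(
                combined[cond.name],
                metric=config.distance_metric,
                k_mad=config.k_mad,
                condition_name=cond.name,
            )
        all_ids = [fid for rep in reports.values() for fid in rep.flag_ids()]
        file_dec = {
            k: v for k, v in (config.decisions or {}).items() if k in all_ids
        }
        decisions = resolve_decisions(
            all_ids, policy=config.policy, decisions=file_dec
        )
        dec_by_id = {d.flag_id: d for d in decisions}
        for cname, rep in reports.items():
            for well_name in rep.flagged:
                fid = f"replicate:{cname}:{well_name}"
                dec = dec_by_id[fid]
                if dec.action == "accept":
                    excluded.append((cname, well_name))
                i = rep.replicate_ids.index(well_name)
                qc_log.append(
                    QCLogEntry(
                        flag_id=fid,
                        kind="replicate_outlier",
                        condition=cname,
                        detail=f"mean_distance={rep.mean_distance[i]:.6g}",
                        action=dec.action,
                        provenance=dec.provenance,
                    )
                )

    # --- regression and condition medians -----------------------------------
    condition_results: list[ConditionResult] = []
    excluded_set = set(excluded)
    for cond in exp.conditions:
        fits: list[ReplicateFit] = []
        for ns in combined[cond.name]:
            if (cond.name, ns.well.name) in excluded_set:
                continue
            fit = fit_replicate(ns)
            if config.r2_threshold is not None and fit.r_squared < config.r2_threshold:
                continue
            fits.append(fit)
        if not fits:
            raise ValidationError(
                f"condition {cond.name!r} has no replicates left after QC"
            )
        condition_results.append(condition_velocity(cond.name, fits))

    # --- pairwise comparisons ------------------------------------------------
    selection = list(config.selection) if config.selection else [
        c.name for c in exp.conditions
    ]
    comparisons: list[PairwiseComparison] = []
    if len(selection) >= 2:
        comparisons = compare_conditions(
            condition_results,
            selection=selection,
            method=config.correction,
            alpha=config.alpha,
            mode=config.test_mode,
        )

    return PipelineResult(
        loaded=loaded,
        config=config,
        normalized=normalized,
        combined=combined,
        qc_log=qc_log,
        excluded_replicates=excluded,
        condition_results=condition_results,
        comparisons=comparisons,
    )


__all__ = [
    "AnalysisConfig",
    "QCLogEntry",
    "PipelineResult",
    "combine_well_series",
    "run_pipeline",
]
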