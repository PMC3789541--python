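"""Synthetic wound-healing experiments with known ground truth.

The generator emulates the data that arrives downstream of image
processing: per-well area-versus-time trajectories on a shared acquisition
grid.  The mean model is linear — area(t) = A0·(1 + (s/100)·t) for true
velocity s in percent of the t0 area per time unit — because the analysis
fits a line; additive Gaussian measurement noise is truncated below at a
small positive floor since areas are positive by definition.  Optional
against-trend spikes emulate segmentation glitches, and optional divergent
replicates (slope offset) emulate a failed well.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawn keys indexed by (condition, replicate), so adding a condition never
perturbs the draws of the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataio import LoadedExperiment, TimeSeries, export_experiment_xml, write_well_file
from .errors import ConflictError, ValidationError
from .plate import Condition, Experiment, PlateFormat, WellAddress

# hourly imaging over 8 h: long enough to estimate velocity, short enough
# that a -10 %/h wound is still open at the last frame
DEFAULT_TIME_GRID = tuple(float(t) for t in range(0, 9))
DEFAULT_BASELINE_AREA = 1.0e5  # µm²-scale wound area


@dataclass(frozen=True)
class SimCondition:
    name: str
    true_slope: float  # % of t0 area per time unit
    n_replicates: int = 3
    assay_kind: str = "open_area"


@dataclass(frozen=True)
class ArtifactSpec:
    """Against-trend spike injection: each series carries one spike with
    probability ``rate``; its magnitude (percent units) is uniform in
    [magnitude_lo, magnitude_hi]."""

    rate: float = 0.0
    magnitude_lo: float = 10.0
    magnitude_hi: float = 20.0


@dataclass(frozen=True)
class DivergentSpec:
    """The last ``count`` replicates of each condition get true_slope +
    slope_offset, emulating technically failed wells."""

    count: int = 0
    slope_offset: float = 0.0


@dataclass(frozen=True)
class SimSpec:
    conditions: tuple[SimCondition, ...]
    plate: PlateFormat = field(default_factory=lambda: PlateFormat(8, 12, "96-well"))
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    baseline_area: float = DEFAULT_BASELINE_AREA
    noise_sd: float = 2.0  # percent of t0 area
    artifacts: ArtifactSpec = ArtifactSpec()
    divergent: DivergentSpec = DivergentSpec()
    seed: int = 0

    def validate(self) -> None:
        if len(self.time_grid) < 3:
            raise ValidationError("time grid needs at least 3 points")
        if np.any(np.diff(self.time_grid) <= 0):
            raise ValidationError("time grid must be strictly increasing")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if not self.conditions:
            raise ValidationError("at least one condition required")
        for c in self.conditions:
            if c.n_replicates < 1:
                raise ValidationError(f"condition {c.name!r} needs >= 1 replicate")
        total = sum(c.n_replicates for c in self.conditions)
        if total > self.plate.capacity:
            raise ValidationError(
                f"{total} replicates exceed plate capacity {self.plate.capacity}"
            )


@dataclass(frozen=True)
class InjectedArtifact:
    well_name: str
    source_label: str
    step_index: int  # against-trend step in the delta vector
    magnitude: float  # percent units


@dataclass
class GroundTruth:
    true_slopes: dict[str, float]  # condition -> nominal slope
    replicate_slopes: dict[str, float]  # well name -> generating slope
    artifacts: list[InjectedArtifact]
    divergent_wells: list[str]


@dataclass
class SimulationResult:
    loaded: LoadedExperiment
    truth: GroundTruth


def _well_sequence(plate: PlateFormat):
    for r in range(1, plate.rows + 1):
        for c in range(1, plate.columns + 1):
            yield WellAddress(r, c)


def simulate_experiment(spec: SimSpec) -> SimulationResult:
    """Generate a complete :class:`LoadedExperiment` plus its ground truth."""
    spec.validate()
    t = np.asarray(spec.time_grid, dtype=float)
    a0 = spec.baseline_area
    wells_iter = _well_sequence(spec.plate)
    conditions: list[Condition] = []
    series: list[TimeSeries] = []
    truth = GroundTruth(
        true_slopes={}, replicate_slopes={}, artifacts=[], divergent_wells=[]
    )
    for ci, sc in enumerate(spec.conditions):
        wells = [next(wells_iter) for _ in range(sc.n_replicates)]
        conditions.append(
            Condition(
                name=sc.name,
                assay_kind=sc.assay_kind,
                wells=list(wells),
                extra_metadata={"true_slope": repr(sc.true_slope)},
            )
        )
        truth.true_slopes[sc.name] = sc.true_slope
        for ri, well in enumerate(wells):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=spec.seed, spawn_key=(ci, ri))
            )
            slope = sc.true_slope
            divergent = ri >= sc.n_replicates - spec.divergent.count
            if divergent:
                slope = slope + spec.divergent.slope_offset
                truth.divergent_wells.append(well.name)
            truth.replicate_slopes[well.name] = slope
            area = a0 * (1.0 + slope / 100.0 * t)
            if spec.noise_sd > 0:
                area = area + rng.normal(0.0, spec.noise_sd * a0 / 100.0, size=len(t))
            area = np.maximum(area, 1e-6 * a0)
            if spec.artifacts.rate > 0 and rng.random() < spec.artifacts.rate:
                # spike one interior point against the expected trend
                point = int(rng.integers(1, len(t) - 1))
                mag = float(
                    rng.uniform(spec.artifacts.magnitude_lo, spec.artifacts.magnitude_hi)
                )
                sign = 1.0 if sc.assay_kind == "open_area" else -1.0
                area = area.copy()
                area[point] += sign * mag * a0 / 100.0
                area = np.maximum(area, 1e-6 * a0)
                truth.artifacts.append(
                    InjectedArtifact(
                        well_name=well.name,
                        source_label="sim",
                        step_index=point - 1,
                        magnitude=mag,
                    )
                )
            series.append(
                TimeSeries(well=well, source_label="sim", time=t.copy(), area=area)
            )
    experiment = Experiment(
        identifier=f"sim-{spec.seed}",
        project="synthetic",
        date="2026-01-01",
        plate=spec.plate,
        conditions=conditions,
    )
    loaded = LoadedExperiment(experiment=experiment, series=series)
    loaded.validate()
    return SimulationResult(loaded=loaded, truth=truth)


def write_fixture_files(
    result: SimulationResult | LoadedExperiment,
    directory: str | Path,
    overwrite: bool = False,
) -> list[Path]:
    """One TSV per (well, source_label), the experiment XML and, when ground
    truth is available, a truth TSV.  Reading the tree back reproduces the
    experiment exactly."""
    if isinstance(result, SimulationResult):
        loaded, truth = result.loaded, result.truth
    else:
        loaded, truth = result, None
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _target(name: str) -> Path:
        p = directory / name
        if p.exists() and not overwrite:
            raise ConflictError(f"refusing to overwrite {p}")
        written.append(p)
        return p

    for s in loaded.series:
        write_well_file(s, _target(f"{s.well.name}_{s.source_label}.tsv"))
    _target("experiment.xml").write_bytes(export_experiment_xml(loaded))
    if truth is not None:
        lines = ["kind\twell\tdetail\tvalue"]
        for well, slope in sorted(truth.replicate_slopes.items()):
            lines.append(f"replicate_slope\t{well}\t\t{repr(slope)}")
        for art in truth.artifacts:
            lines.append(
                f"artifact\t{art.well_name}\tstep={art.step_index}\t{repr(art.magnitude)}"
            )
        for well in truth.divergent_wells:
            lines.append(f"divergent\t{well}\t\t")
        _target("ground_truth.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return written


def spec_from_json(path_or_text: str | Path) -> SimSpec:
    """Load a :class:`SimSpec` from the JSON dialect used by the CLI."""
    text = (
        Path(path_or_text).read_text(encoding="utf-8")
        if isinstance(path_or_text, Path) or str(path_or_text).endswith(".json")
        else str(path_or_text)
    )
    obj = json.loads(text)
    plate = obj.get("plate", {})
    return SimSpec(
        conditions=tuple(
            SimCondition(
                name=c["name"],
                true_slope=float(c["true_slope"]),
                n_replicates=int(c.get("n_replicates", 3)),
                assay_kind=c.get("assay_kind", "open_area"),
            )
            for c in obj["conditions"]
        ),
        plate=PlateFormat(
            rows=int(plate.get("rows", 8)),
            columns=int(plate.get("columns", 12)),
            label=plate.get("label", "96-well"),
        ),
        time_grid=tuple(float(t) for t in obj.get("time_grid", DEFAULT_TIME_GRID)),
        baseline_area=float(obj.get("baseline_area", DEFAULT_BASELINE_AREA)),
        noise_sd=float(obj.get("noise_sd", 2.0)),
        artifacts=ArtifactSpec(**obj.get("artifacts", {})),
        divergent=DivergentSpec(**obj.get("divergent", {})),
        seed=int(obj.get("seed", 0)),
    )


__all__ = [
    "SimCondition",
    "ArtifactSpec",
    "DivergentSpec",
    "SimSpec",
    "InjectedArtifact",
    "GroundTruth",
    "SimulationResult",
    "simulate_experiment",
    "write_fixture_files",
    "spec_from_json",
    "DEFAULT_TIME_GRID",
]
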