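"""Per-well data files and whole-experiment XML exchange.

Instruments and image-analysis tools export one tab-separated text file per
well (several per well when multiple imaging positions, modalities or
segmentation algorithms are used), two columns: time and cell-free /
cell-covered area.  A :class:`LoadedExperiment` bundles those trajectories
with the plate set-up and round-trips through a single XML document so an
entire experiment can be archived or exchanged losslessly.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from .errors import ConflictError, FormatError, ValidationError
from .plate import (
    Experiment,
    WellAddress,
    element_to_experiment,
    experiment_to_element,
    parse_and_validate,
)


@dataclass
class TimeSeries:
    """One replicate trajectory: strictly increasing times, positive areas."""

    well: WellAddress
    source_label: str
    time: np.ndarray
    area: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.time.ndim != 1 or self.area.ndim != 1:
            raise ValidationError("time and area must be 1-D")
        if len(self.time) != len(self.area):
            raise ValidationError("time and area must have equal length")
        if len(self.time) < 2:
            raise ValidationError("a time series needs at least 2 points")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")
        if np.any(self.time < 0):
            raise ValidationError("time values must be nonnegative")
        if np.any(self.area <= 0):
            raise ValidationError("area values must be positive")

    @property
    def n_points(self) -> int:
        return len(self.time)

    def equals(self, other: "TimeSeries") -> bool:
        return (
            self.well == other.well
            and self.source_label == other.source_label
            and np.array_equal(self.time, other.time)
            and np.array_equal(self.area, other.area)
        )


@dataclass
class LoadedExperiment:
    experiment: Experiment
    series: list[TimeSeries] = field(default_factory=list)

    def series_for_well(self, well: WellAddress) -> list[TimeSeries]:
        return [s for s in self.series if s.well == well]

    def validate(self) -> None:
        self.experiment.validate()
        assigned = set(self.experiment.assigned_wells())
        for s in self.series:
            if s.well not in assigned:
                raise ValidationError(
                    f"series for well {s.well.name} but that well is unassigned"
                )
        covered = {s.well for s in self.series}
        missing = sorted(w.name for w in assigned - covered)
        if missing:
            raise ValidationError(f"assigned wells without data: {missing}")


def read_well_file(
    source: str | Path | _io.TextIOBase,
    well: WellAddress,
    source_label: str = "default",
) -> TimeSeries:
    """Parse a two-column tab-separated (time, area) file.

    One optional header row — the first row with any non-numeric field — is
    skipped.  Rows are sorted by time; duplicate times, nonpositive areas and
    locale decimal commas are format errors, not guesses.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
        name = str(source)
    else:
        text = source.read()
        name = getattr(source, "name", "<stream>")
    rows: list[tuple[float, float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{name}:{lineno}: expected two tab-separated columns")
        t_txt, a_txt = fields[0].strip(), fields[1].strip()
        try:
            if "," in t_txt or "," in a_txt:
                raise ValueError("decimal comma")
            t, a = float(t_txt), float(a_txt)
        except ValueError:
            if not rows and lineno == _first_content_line(text):
                continue  # single header row
            raise FormatError(
                f"{name}:{lineno}: non-numeric value in {line!r}"
            ) from None
        rows.append((t, a))
    if len(rows) < 2:
        raise FormatError(f"{name}: fewer than 2 data rows")
    rows.sort(key=lambda r: r[0])
    times = [r[0] for r in rows]
    if len(set(times)) != len(times):
        dup = sorted({t for t in times if times.count(t) > 1})
        raise FormatError(f"{name}: duplicate time values {dup}")
    areas = [r[1] for r in rows]
    if any(a <= 0 for a in areas):
        raise FormatError(f"{name}: nonpositive area value")
    if any(t < 0 for t in times):
        raise FormatError(f"{name}: negative time value")
    return TimeSeries(well=well, source_label=source_label, time=np.array(times), area=np.array(areas))


def _first_content_line(text: str) -> int:
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if raw.strip():
            return lineno
    return 1


def write_well_file(ts: TimeSeries, path: str | Path) -> None:
    """Serialize a series in the same dialect ``read_well_file`` parses."""
    lines = ["time\tarea"]
    lines += [f"{float(t)!r}\t{float(a)!r}" for t, a in zip(ts.time, ts.area)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def attach_series(loaded: LoadedExperiment, ts: TimeSeries) -> LoadedExperiment:
    """Append one trajectory; (well, source_label) pairs are unique."""
    if loaded.experiment.condition_of(ts.well) is None:
        raise ValidationError(
            f"well {ts.well.name} is not assigned to any condition"
        )
    for s in loaded.series:
        if s.well == ts.well and s.source_label == ts.source_label:
            raise ConflictError(
                f"well {ts.well.name} already has a series labeled "
                f"{ts.source_label!r}"
            )
    loaded.series.append(ts)
    return loaded


# ---------------------------------------------------------------------------
# Whole-experiment XML
# ---------------------------------------------------------------------------

def export_experiment_xml(loaded: LoadedExperiment) -> bytes:
    """Set-up template plus a data section; floats rendered round-trip exact."""
    loaded.validate()
    root = experiment_to_element(loaded.experiment)
    data = etree.SubElement(root, "data")
    for s in loaded.series:
        se = etree.SubElement(
            data, "series", well=s.well.name, source_label=s.source_label
        )
        for t, a in zip(s.time, s.area):
            etree.SubElement(se, "point", time=repr(float(t)), area=repr(float(a)))
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def import_experiment_xml(doc: bytes | str) -> LoadedExperiment:
    root = parse_and_validate(doc)
    experiment = element_to_experiment(root)
    experiment.validate()
    data = root.find("data")
    series: list[TimeSeries] = []
    if data is not None:
        assigned = set(experiment.assigned_wells())
        for se in data.iterfind("series"):
            well = WellAddress.parse(se.get("well"))
            if well not in assigned:
                raise ValidationError(
                    f"series for unknown/unassigned well {well.name}"
                )
            points = [(float(p.get("time")), float(p.get("area"))) for p in se.iterfind("point")]
            series.append(
                TimeSeries(
                    well=well,
                    source_label=se.get("source_label"),
                    time=np.array([p[0] for p in points]),
                    area=np.array([p[1] for p in points]),
                )
            )
    loaded = LoadedExperiment(experiment=experiment, series=series)
    loaded.validate()
    return loaded


__all__ = [
    "TimeSeries",
    "LoadedExperiment",
    "read_well_file",
    "write_well_file",
    "attach_series",
    "export_experiment_xml",
    "import_experiment_xml",
]
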