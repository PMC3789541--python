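"""Multi-well plate experiment model.

An :class:`Experiment` maps biological conditions (cell line, treatment,
dose, assay kind, free metadata) onto technical-replicate wells of a
user-definable plate.  Set-up templates — everything except measurement
data — round-trip through a versioned XML format whose schema ships with
the package and is enforced on import.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field

from lxml import etree

from .errors import AddressError, ConflictError, SchemaError, ValidationError

SCHEMA_VERSION = "1.0"
ASSAY_KINDS = ("open_area", "covered_area")

_WELL_RE = re.compile(r"^([A-Z])([1-9][0-9]*)$")


@dataclass(frozen=True)
class PlateFormat:
    """Plate geometry; rows are lettered A.. (max 26), columns numbered from 1."""

    rows: int
    columns: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (isinstance(self.rows, int) and isinstance(self.columns, int)):
            raise ValidationError("plate rows/columns must be integers")
        if self.rows < 1 or self.columns < 1:
            raise ValidationError(
                f"plate dimensions must be >= 1, got {self.rows}x{self.columns}"
            )
        if self.rows > 26:
            raise ValidationError("at most 26 rows (A..Z) are supported")

    @property
    def capacity(self) -> int:
        return self.rows * self.columns

    def __contains__(self, well: "WellAddress") -> bool:
        return 1 <= well.row <= self.rows and 1 <= well.column <= self.columns


@dataclass(frozen=True, order=True)
class WellAddress:
    """1-based (row, column) position; canonical text form is e.g. ``A1``."""

    row: int
    column: int

    def __post_init__(self) -> None:
        if self.row < 1 or self.column < 1:
            raise ValidationError(f"well indices are 1-based, got ({self.row}, {self.column})")
        if self.row > 26:
            raise ValidationError("row letters beyond Z are not supported")

    @property
    def name(self) -> str:
        return f"{chr(ord('A') + self.row - 1)}{self.column}"

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        m = _WELL_RE.match(text.strip())
        if m is None:
            raise ValidationError(f"not a well address: {text!r}")
        return cls(row=ord(m.group(1)) - ord("A") + 1, column=int(m.group(2)))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


@dataclass
class Condition:
    """One biological condition and the technical-replicate wells carrying it."""

    name: str
    cell_line: str = ""
    treatment: str = ""
    dose: float = 0.0
    dose_unit: str = ""
    assay_kind: str = "open_area"
    extra_metadata: dict[str, str] = field(default_factory=dict)
    wells: list[WellAddress] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("condition name must be non-empty")
        if self.assay_kind not in ASSAY_KINDS:
            raise ValidationError(
                f"assay_kind must be one of {ASSAY_KINDS}, got {self.assay_kind!r}"
            )
        if self.dose < 0:
            raise ValidationError("dose must be nonnegative")


@dataclass
class Experiment:
    identifier: str
    plate: PlateFormat
    project: str = ""
    date: str = ""
    conditions: list[Condition] = field(default_factory=list)
    time_unit: str = "hours"
    area_unit: str = "µm²"

    def condition(self, name: str) -> Condition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise LookupError(f"no condition named {name!r}")

    def condition_of(self, well: WellAddress) -> Condition | None:
        for c in self.conditions:
            if well in c.wells:
                return c
        return None

    def assigned_wells(self) -> list[WellAddress]:
        return [w for c in self.conditions for w in c.wells]

    def validate(self) -> None:
        """Raise :class:`ValidationError` naming the first violated invariant."""
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate condition names: {dup}")
        seen: dict[WellAddress, str] = {}
        for c in self.conditions:
            if not c.wells:
                raise ValidationError(f"condition {c.name!r} has no wells assigned")
            for w in c.wells:
                if w not in self.plate:
                    raise AddressError(
                        f"well {w.name} of condition {c.name!r} is off the "
                        f"{self.plate.rows}x{self.plate.columns} plate"
                    )
                if w in seen:
                    raise ValidationError(
                        f"well {w.name} assigned to both {seen[w]!r} and {c.name!r}"
                    )
                seen[w] = c.name


def create_plate(rows: int, columns: int, label: str = "") -> PlateFormat:
    """Create a plate format; dimensions must be positive counts."""
    return PlateFormat(rows=rows, columns=columns, label=label)


def assign_wells(
    experiment: Experiment, condition_name: str, wells: list[WellAddress]
) -> Experiment:
    """Extend a condition's replicate wells.

    Re-assigning a well to the condition that already owns it is a no-op
    (idempotent); assigning it to a different condition is a conflict.
    """
    cond = experiment.condition(condition_name)
    for w in wells:
        if w not in experiment.plate:
            raise AddressError(
                f"well {w.name} is off the {experiment.plate.rows}x"
                f"{experiment.plate.columns} plate"
            )
        owner = experiment.condition_of(w)
        if owner is not None and owner.name != condition_name:
            raise ConflictError(
                f"well {w.name} already belongs to condition {owner.name!r}"
            )
    for w in wells:
        if w not in cond.wells:
            cond.wells.append(w)
    return experiment


# ---------------------------------------------------------------------------
# XML template exchange
# ---------------------------------------------------------------------------

def _load_schema() -> etree.XMLSchema:
    src = importlib.resources.files("woundkit.schema").joinpath("experiment-1.0.xsd")
    with importlib.resources.as_file(src) as path:
        return etree.XMLSchema(etree.parse(str(path)))


_SCHEMA: etree.XMLSchema | None = None


def get_schema() -> etree.XMLSchema:
    global _SCHEMA
    if _SCHEMA is None:
        _SCHEMA = _load_schema()
    return _SCHEMA


def experiment_to_element(experiment: Experiment) -> etree._Element:
    root = etree.Element(
        "experiment",
        schema_version=SCHEMA_VERSION,
        identifier=experiment.identifier,
        project=experiment.project,
        date=experiment.date,
        time_unit=experiment.time_unit,
        area_unit=experiment.area_unit,
    )
    etree.SubElement(
        root,
        "plate",
        rows=str(experiment.plate.rows),
        columns=str(experiment.plate.columns),
        label=experiment.plate.label,
    )
    conds = etree.SubElement(root, "conditions")
    for c in experiment.conditions:
        ce = etree.SubElement(
            conds,
            "condition",
            name=c.name,
            cell_line=c.cell_line,
            treatment=c.treatment,
            dose=repr(float(c.dose)),
            dose_unit=c.dose_unit,
            assay_kind=c.assay_kind,
        )
        if c.extra_metadata:
            me = etree.SubElement(ce, "metadata")
            for k, v in c.extra_metadata.items():
                entry = etree.SubElement(me, "entry", key=k)
                entry.text = v
        we = etree.SubElement(ce, "wells")
        for w in c.wells:
            etree.SubElement(we, "well").text = w.name
    return root


def export_setup_template(experiment: Experiment) -> bytes:
    """Serialize the set-up (no measurement data) as schema-valid XML."""
    experiment.validate()
    root = experiment_to_element(experiment)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def element_to_experiment(root: etree._Element) -> Experiment:
    plate_el = root.find("plate")
    plate = PlateFormat(
        rows=int(plate_el.get("rows")),
        columns=int(plate_el.get("columns")),
        label=plate_el.get("label") or "",
    )
    conditions = []
    for ce in root.find("conditions").iterfind("condition"):
        meta = {}
        me = ce.find("metadata")
        if me is not None:
            for entry in me.iterfind("entry"):
                meta[entry.get("key")] = entry.text or ""
        wells = [WellAddress.parse(w.text) for w in ce.find("wells").iterfind("well")]
        conditions.append(
            Condition(
                name=ce.get("name"),
                cell_line=ce.get("cell_line") or "",
                treatment=ce.get("treatment") or "",
                dose=float(ce.get("dose") or 0.0),
                dose_unit=ce.get("dose_unit") or "",
                assay_kind=ce.get("assay_kind"),
                extra_metadata=meta,
                wells=wells,
            )
        )
    exp = Experiment(
        identifier=root.get("identifier"),
        project=root.get("project") or "",
        date=root.get("date") or "",
        plate=plate,
        conditions=conditions,
        time_unit=root.get("time_unit") or "hours",
        area_unit=root.get("area_unit") or "µm²",
    )
    return exp


def parse_and_validate(doc: bytes | str) -> etree._Element:
    data = doc.encode("utf-8") if isinstance(doc, str) else doc
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise SchemaError(f"malformed XML: {exc}") from exc
    schema = get_schema()
    if not schema.validate(root):
        err = schema.error_log.last_error
        raise SchemaError(
            f"schema violation at line {err.line}: {err.message}"
        )
    return root


def import_setup_template(doc: bytes | str) -> Experiment:
    """Parse, schema-validate and reconstruct an :class:`Experiment`."""
    root = parse_and_validate(doc)
    exp = element_to_experiment(root)
    exp.validate()
    return exp


# ---------------------------------------------------------------------------
# Laboratory set-up sheet
# ---------------------------------------------------------------------------

def render_setup_sheet(experiment: Experiment) -> str:
    """Plain-text plate grid with per-well condition labels plus a legend.

    The content contract is the grid and metadata legend; the markdown-ish
    plain text is the default renderer.
    """
    experiment.validate()
    plate = experiment.plate
    owner = {w: c.name for c in experiment.conditions for w in c.wells}
    width = max([len(n) for n in owner.values()] + [3])
    lines = [
        f"# Set-up sheet: {experiment.identifier}",
        f"Project: {experiment.project}   Date: {experiment.date}",
        f"Plate: {plate.label or f'{plate.rows}x{plate.columns}'} "
        f"({plate.rows} rows x {plate.columns} columns)",
        "",
    ]
    header = "    " + " ".join(f"{c:>{width}}" for c in range(1, plate.columns + 1))
    lines.append(header)
    for r in range(1, plate.rows + 1):
        cells = []
        for c in range(1, plate.columns + 1):
            name = owner.get(WellAddress(r, c), ".")
            cells.append(f"{name:>{width}}")
        lines.append(f"  {chr(ord('A') + r - 1)} " + " ".join(cells))
    lines.append("")
    lines.append("## Conditions")
    for c in experiment.conditions:
        wells = ",".join(w.name for w in c.wells)
        lines.append(
            f"- {c.name}: cell_line={c.cell_line!r} treatment={c.treatment!r} "
            f"dose={c.dose} {c.dose_unit} assay={c.assay_kind} wells=[{wells}]"
        )
        for k, v in c.extra_metadata.items():
            lines.append(f"    {k}: {v}")
    return "\n".join(lines) + "\n"


__all__ = [
    "ASSAY_KINDS",
    "SCHEMA_VERSION",
    "PlateFormat",
    "WellAddress",
    "Condition",
    "Experiment",
    "create_plate",
    "assign_wells",
    "export_setup_template",
    "import_setup_template",
    "render_setup_sheet",
]
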