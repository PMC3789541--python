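"""Structured analysis reports.

The report is a *view* over pipeline outputs — every number it shows equals
the corresponding pipeline value; nothing is recomputed.  Markdown is the
canonical, byte-stable rendering; HTML wraps the same content; PDF is an
optional renderer behind a capability check (matplotlib backend).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import __version__ as _version
from .analysis import PipelineResult
from .errors import CapabilityError, ValidationError

FORMATS = ("markdown", "html", "pdf")


def fmt_sig(x: float, digits: int = 4) -> str:
    """Fixed significant digits; plain notation down to 1e-4."""
    return f"{float(x):.{digits}g}"


def fmt_p(p: float) -> str:
    """p-values: 3 significant digits, scientific below 0.001."""
    p = float(p)
    return f"{p:.2e}" if p < 1e-3 else f"{p:.3g}"


@dataclass
class AnalysisReport:
    """Assembled report content, already ordered deterministically
    (conditions by name, wells row-major within a condition)."""

    result: PipelineResult
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.result.condition_results is None:
            raise ValidationError("report assembly requires pipeline results")


def build_report(result: PipelineResult, seed: int | None = None) -> AnalysisReport:
    """Assemble a report; raises if a pipeline section is missing."""
    for name in ("loaded", "normalized", "qc_log", "condition_results", "comparisons"):
        if getattr(result, name, None) is None:
            raise ValidationError(f"cannot assemble report: missing section {name!r}")
    return AnalysisReport(result=result, seed=seed)


def _render_markdown(report: AnalysisReport) -> str:
    res = report.result
    exp = res.loaded.experiment
    lines: list[str] = []
    lines.append(f"# Analysis report: {exp.identifier}")
    lines.append("")
    lines.append("## Experimental design")
    lines.append(
        f"- Plate: {exp.plate.label or ''} ({exp.plate.rows} rows x "
        f"{exp.plate.columns} columns)"
    )
    lines.append(f"- Project: {exp.project}   Date: {exp.date}")
    lines.append(f"- Units: time in {exp.time_unit}, area in {exp.area_unit}")
    for c in sorted(exp.conditions, key=lambda c: c.name):
        wells = ",".join(w.name for w in sorted(c.wells))
        lines.append(
            f"- Condition {c.name}: cell_line={c.cell_line!r} "
            f"treatment={c.treatment!r} dose={c.dose} {c.dose_unit} "
            f"assay={c.assay_kind} wells=[{wells}]"
        )
    lines.append("")
    lines.append("## Acquired data")
    lines.append(f"- Series: {len(res.loaded.series)}")
    for s in sorted(res.loaded.series, key=lambda s: (s.well, s.source_label)):
        lines.append(
            f"- {s.well.name}/{s.source_label}: {s.n_points} points, "
            f"t in [{fmt_sig(s.time[0])}, {fmt_sig(s.time[-1])}]"
        )
    lines.append("")
    lines.append("## Quality control")
    lines.append(f"- Flags: {len(res.qc_log)}")
    for e in sorted(res.qc_log, key=lambda e: e.flag_id):
        lines.append(
            f"- {e.flag_id} [{e.kind}, condition {e.condition}] {e.detail} -> "
            f"{e.action} ({e.provenance})"
        )
    if res.excluded_replicates:
        excl = ", ".join(f"{c}:{w}" for c, w in sorted(res.excluded_replicates))
        lines.append(f"- Excluded replicates: {excl}")
    lines.append("")
    lines.append("## Results")
    lines.append("")
    lines.append("| condition | well | slope (%/time) | intercept (%) | R² | n |")
    lines.append("|---|---|---|---|---|---|")
    for cr in sorted(res.condition_results, key=lambda r: r.condition):
        for f in cr.fits:
            lines.append(
                f"| {cr.condition} | {f.well_name} | {fmt_sig(f.slope)} | "
                f"{fmt_sig(f.intercept)} | {fmt_sig(f.r_squared)} | {f.n_points} |"
            )
    lines.append("")
    lines.append("| condition | median velocity (%/time) | replicates |")
    lines.append("|---|---|---|")
    for cr in sorted(res.condition_results, key=lambda r: r.condition):
        lines.append(
            f"| {cr.condition} | {fmt_sig(cr.median_velocity)} | {len(cr.fits)} |"
        )
    lines.append("")
    lines.append("## Statistical evaluation")
    if res.comparisons:
        lines.append("| pair | U | p | p adjusted | method | significant |")
        lines.append("|---|---|---|---|---|---|")
        for cmp in sorted(
            res.comparisons, key=lambda c: (c.condition_a, c.condition_b)
        ):
            lines.append(
                f"| {cmp.condition_a} vs {cmp.condition_b} | "
                f"{fmt_sig(cmp.u_statistic)} | {fmt_p(cmp.p_raw)} | "
                f"{fmt_p(cmp.p_adjusted)} | {cmp.method} | "
                f"{'yes' if cmp.significant else 'no'} |"
            )
    else:
        lines.append("- No pairwise comparisons (fewer than 2 conditions selected).")
    lines.append("")
    lines.append("## Provenance")
    lines.append(f"- woundkit {_version}")
    cfg = res.config
    lines.append(
        f"- Config: alpha={cfg.artifact_alpha} kernel={cfg.kernel} "
        f"bandwidth={cfg.bandwidth} pool_deltas={cfg.pool_deltas} "
        f"k_mad={cfg.k_mad} metric={cfg.distance_metric} policy={cfg.policy} "
        f"correction={cfg.correction} sig_alpha={cfg.alpha} "
        f"test_mode={cfg.test_mode} r2_threshold={cfg.r2_threshold}"
    )
    if report.seed is not None:
        lines.append(f"- Seed: {report.seed}")
    return "\n".join(lines) + "\n"


def _render_html(report: AnalysisReport) -> str:
    md = _render_markdown(report)
    body = md.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    return (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
        "<title>woundkit report</title></head>\n"
        f"<body><pre>\n{body}</pre></body></html>\n"
    )


def _render_pdf(report: AnalysisReport) -> bytes:
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        from matplotlib.backends.backend_pdf import PdfPages
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover - env without matplotlib
        raise CapabilityError(
            "PDF rendering requires matplotlib; install woundkit[pdf] or "
            "use the markdown/html formats"
        ) from exc
    import io

    md_lines = _render_markdown(report).splitlines()
    buf = io.BytesIO()
    per_page = 55
    with PdfPages(buf) as pdf:
        for start in range(0, len(md_lines), per_page):
            fig = plt.figure(figsize=(8.27, 11.69))
            fig.text(
                0.05,
                0.97,
                "\n".join(md_lines[start : start + per_page]),
                va="top",
                family="monospace",
                fontsize=7,
            )
            pdf.savefig(fig)
            plt.close(fig)
    return buf.getvalue()


def render_report(report: AnalysisReport, format: str = "markdown") -> str | bytes:
    """Render the report; markdown is canonical and byte-stable."""
    if format == "markdown":
        return _render_markdown(report)
    if format == "html":
        return _render_html(report)
    if format == "pdf":
        return _render_pdf(report)
    raise ValidationError(f"unsupported format {format!r}; choose from {FORMATS}")


__all__ = [
    "AnalysisReport",
    "build_report",
    "render_report",
    "fmt_sig",
    "fmt_p",
    "FORMATS",
]
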