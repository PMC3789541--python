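# Methods

This note documents the models, defaults and numerical choices behind
`woundkit`, what the synthetic-data generator does and does not emulate,
and the known limitations of the quality-control rules.

## Data model and units

An experiment is a plate (rows lettered A–Z, columns numbered from 1, so
at most 26 rows) of biological conditions, each owning one or more wells
as technical replicates; a well owns one or more time series (imaging
positions, modalities, or segmentation algorithms, distinguished by a
`source_label`). Time series require strictly increasing, nonnegative
times and strictly positive areas with at least two points. Times default
to hours and areas to µm², but units are metadata only — nothing in the
analysis depends on them.

Normalized values are percentages of the t₀ area (`a(0) = 100` exactly,
enforced after the division so floating-point rounding cannot move the
anchor). Normalization is scale-invariant by construction and keeps the
raw areas untouched on the series' `base` — QC corrections never destroy
data.

Orientation does not flip signs. An `open_area` assay (wound healing:
cell-free area shrinks) expects a decreasing trajectory and treats
positive per-step deltas as the artifact direction; `covered_area`
(exclusion zone read as covered area) is the mirror image. Keeping slopes
signed means a reported velocity of −10 %/h is directly interpretable as
the cell-free area losing 10 % of its starting value per hour.

## Step-artifact detection

The reference distribution for per-step deltas is a KDE fitted, by
default, on the deltas **pooled across all replicates of the condition**:
with the 3–6 replicates typical of plate assays, a per-replicate density
(8–24 deltas) is too unstable. Per-replicate fitting remains available
(`pool_deltas=False`).

- Kernels: Gaussian (default) and Epanechnikov; density is the standard
  `(1/nh) Σ K((x−xᵢ)/h)`.
- Bandwidth: Silverman's rule `h = 0.9·min(sd, IQR/1.34)·n^(−1/5)`; when
  the deltas have zero spread (noiseless data) it falls back to
  `1e−3·max(1, |mean|)` with a warning.
- The central 1−α interval is obtained by trapezoid quadrature of the
  density on a 4001-point grid spanning the data ±8 bandwidths, with the
  CDF renormalized so far-tail quadrature loss (≲1e−6) cannot bias the
  quantiles.

A step is flagged only when its delta is (a) against the expected trend
and (b) beyond the against-trend end of the central 1−α mass (α = 0.05
default). Coupling direction with extremity avoids flagging the ordinary
large with-trend steps of a fast-closing wound. Setting
`require_against_trend=False` switches to a pure two-tailed density rule
(flags reported as `low_density_tail`).

The suggested correction replaces the point terminating the flagged step
by time-weighted linear interpolation between its neighbours; a flagged
terminal step drops the last point. Correction is idempotent per step
(re-correcting warns and is a no-op) and only ever touches the flagged
point. Because the artifact criterion requires an against-trend delta, a
corrected single-point glitch cannot re-flag; a *level shift* (several
consecutive displaced points) is corrected point-by-point and may leave
residual flags — by design, since a level shift genuinely violates the
single-glitch model.

Detectability has a floor: a spike is only visible when its magnitude
exceeds the per-step trend plus the KDE's upper-tail width, and the
pooled spike mass must stay below α/2 or the spikes inflate the density's
own tail and mask themselves (at 6 replicates × 8 steps, one spike is
already ~2 % of the pool). QC of heavily corrupted data should use longer
acquisitions or per-replicate review.

## Replicate screening

Replicates of a condition are compared on the **exact intersection** of
their time grids (matching within 1e−9 relative; at least 3 shared
points). No interpolation is performed by default — aligning by
interpolation would invent data — so mixed-grid experiments must either
share acquisition times or opt into alignment upstream.

The default metric is Euclidean distance on normalized values (Manhattan
ships as a second registered plugin). Each replicate's mean distance to
the others is screened against `median + k·MAD` with k = 3, where the MAD
is the **normal-consistent** median absolute deviation (×1.4826), the
standard robust-outlier convention: k is then in σ-equivalents. With the
raw MAD, k = 3 corresponds to only ≈2σ and good replicates are falsely
excluded in several percent of conditions.

Known limitation: with ≥5 concordant replicates the rule still carries an
intrinsic ~2–3 % chance of flagging one good replicate alongside a true
outlier, because the MAD estimated from ~5 values is itself noisy and
Euclidean distance spreads are right-skewed. With triplicates plus one
failed well — the most common design — a concordant replicate
structurally cannot exceed the cutoff. k is configurable for labs that
prefer a more conservative screen at high replicate counts.

Every flag (step or replicate) carries a stable identifier
(`step:<well>:<label>:<index>`, `replicate:<condition>:<well>`) and must
be resolved before analysis: a TSV decision file overrides the blanket
policy (`accept_all`, `reject_all`); under `ask`, unresolved flags abort
with a listing. Accepted replicate flags exclude the well from velocity
estimation only; the data remain in the archive and the report.

## Velocity and comparison

Wells with several series are averaged pointwise (mean of normalized
values on the common grid) into one replicate trajectory before
regression — the conventional combination, replaceable via the plugin
registry. OLS needs ≥3 points after QC; R² = 1 − SSres/SStot with the
zero-variance convention R² = 1 for an exactly flat perfect fit (0
otherwise), and clipping to [0, 1] against rounding. No R² filter is
applied by default; `r2_threshold` enables one.

The condition velocity is the median replicate slope (mean of the central
pair at even counts). Pairwise comparisons run a two-sided Mann–Whitney U
test on the replicate slope lists: U from midrank sums; exact p by full
enumeration of all C(n_a+n_b, n_a) group assignments when requested or
when (auto) the pooled sample is ≤12 and tie-free — enumeration is
instant at these sizes and exactness matters at plate-scale n; otherwise
the tie-corrected normal approximation with continuity correction,
`p = min(1, 2·(1−Φ(|z|)))`. Two-sided testing is the default and only
mode: directional hypotheses in a screening context invite sign
mistakes.

Multiplicity is corrected over the pairs actually tested (C(k,2) for k
selected conditions), not all pairs on the plate: the user's selection
defines the family. Bonferroni (`min(1, m·p)`) and Benjamini–Hochberg
(step-up `q₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j`) are provided; both clip to (0, 1].

## Plugin registry

Five slots — distance metric, statistical test, KDE kernel, outlier rule,
multiple-testing correction — hold name-keyed implementations with
registered defaults; duplicates are conflicts, and an entry-point group
(`woundkit.plugins`, names `slot.impl`) lets third-party packages
register without code changes.

## Synthetic data

The generator emulates data *downstream of image processing*: per-well
area-versus-time tables. The mean model is linear,
`A(t) = A₀·(1 + (s/100)·t)` for true velocity `s` in %/time-unit, because
the estimator fits a line; defaults are a 96-well plate, hourly imaging
over 8 h (long enough to estimate a slope, short enough that a −10 %/h
wound has not closed — a closed wound hits the positivity floor and the
linear model no longer applies), A₀ = 1e5 (µm²-scale wound), Gaussian
noise of 2 % of A₀ truncated below at a small positive floor, no
artifacts and no divergent replicates unless requested. Artifacts add one
against-trend spike to a single interior sample of a series with
probability `rate`, magnitude uniform in [lo, hi] percent — producing the
spike-then-compensation delta signature of a segmentation glitch.
Divergent replicates offset the generating slope of the last `count`
replicates per condition.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawn keys indexed by (condition, replicate),
so extending an experiment never perturbs existing draws and identical
specs produce byte-identical fixture trees.

What the generator does **not** emulate: curvature of real closure
kinetics (a logistic phase as the wound closes; the linear fit then
underestimates late-phase velocity — a known property of slope-based
analysis, visible as reduced R²), spatial correlation between imaging
positions of one well, heteroscedastic segmentation noise, drift, or
plate-position effects. Passing recovery tests therefore demonstrates
correctness of the estimator and QC under the stated noise model, not
robustness to every failure mode of real microscopy.

Test problem sizes: artifact-recovery operating characteristics are
measured on 85 simulated six-replicate conditions (≈510 replicates,
hourly imaging over 24 h of a −2 %/h condition, 1 % noise, spike
magnitudes 5–10× the noise SD — a slow-migration overnight time-lapse,
where spikes of that size are unambiguous); replicate-outlier recovery on
200 triplicate+1 runs; parameter recovery on 500 six-replicate runs at
2 % noise.

## Reporting

The report is a pure view: every number equals the pipeline output it
mirrors (slopes and velocities at 4 significant digits, p-values at 3,
scientific below 1e−3; full precision lives in the TSVs). Ordering is
deterministic (conditions by name, wells row-major), so the canonical
markdown rendering is byte-stable and diffable. HTML wraps the same
content; PDF is an optional matplotlib-backed renderer behind a
capability check.

## Exchange format

The XML schema (versioned, `schema_version="1.0"`, XSD shipped in the
package and enforced on import) carries the plate, conditions with all
metadata and well assignments, and — in the full-experiment form — every
series as (time, area) points rendered with shortest round-trip float
representation, so export→import is value-exact and re-analysis of an
imported experiment reproduces the original bit-for-bit under the same
configuration. Set-up templates are the same document without the data
section. Per-well input files are two tab-separated columns (time, area);
one optional header row is tolerated, rows are sorted by time, duplicate
times and nonpositive areas are rejected, and decimal commas are a format
error rather than a locale guess.
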