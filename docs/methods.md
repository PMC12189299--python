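# Methods

This note documents the models, numerical choices, and limitations behind
`extractopt`, in the order the pipeline runs.

## Box-Behnken design and coding

The design generator supports exactly the three-factor Box-Behnken layout:
12 edge-midpoint runs — every permutation of (±1, ±1, 0) — followed by
`n_center ≥ 1` center replicates. Run ordering is fixed in the canonical
block order (the X1-X2 block, then X1-X3, then X2-X3, centers last) so that
row indices align with the packaged study tables; run-order randomization
is deliberately not modeled, since the reproduced study reports none.
Coding is affine, `x = (X − center)/half_range`, three-level factors only.
Central-composite and higher-factor designs are out of scope.

The coded model matrix of this design has useful structure that the test
suite asserts directly: linear columns are balanced (eight ±1 entries, zero
sum) and interaction columns are mutually orthogonal and orthogonal to the
linear block. This near-orthogonality is why each interaction coefficient
equals a simple four-point contrast `(y₊₊ − y₊₋ − y₋₊ + y₋₋)/4`.

## Quadratic fit

The full ten-term second-order polynomial is always fit — no term
selection. The published equations for two of the samples omit a
pure-quadratic term; that is treated as a display choice (a coefficient
rounding to 0.00), not as a reduced model, and this package always reports
all ten coefficients so near-zero terms stay visible.

Fitting is OLS on the coded regressors. Uncoded (physical-unit) regressors
span three orders of magnitude once squared (e.g., temperature² ≈ 6400
against a ±1 interaction column), so the coded basis is the numerically
sane one; the uncoded coefficient vector is then obtained by the exact
affine change of variables, and the round trip is verified to machine
precision. When replicate-level data are available, fitting on run means is
exactly equivalent to fitting all replicates under balanced replication
(the model-matrix rows are simply repeated), which is why the published
mean ± SD tables suffice to recover the coefficients.

Display rounding of coefficients is half-away-from-zero to two decimals,
matching the convention of the published equations; numeric comparisons in
tests use an absolute tolerance of 0.01, never string equality.

## ANOVA, lack of fit, pure error

Per-term sums of squares are partial (drop-one): SS(term) =
SSE(model without the term) − SSE(full model), computed by explicit reduced
refits on the coded basis. The source study does not state its SS
convention; drop-one partial SS is the common default of RSM software and
is well defined on this near-orthogonal design. F tests use the residual
mean square at the granularity of the data supplied; no multiplicity
correction is applied across terms (none is applied in the reproduced
tables either).

Two granularities are supported, following the data handed in:

* run means only — a 15-observation ANOVA with 5 residual df;
* replicate information present (raw replicates, or mean ± SD with n ≥ 2) —
  the replicate-level table, in which term SS scale by the replicate count,
  pure error enters as Σᵢ (nᵢ−1)sᵢ² (exact from summaries), lack of fit is
  the replicate-weighted SS of (run mean − fitted), and the residual is
  their sum.

Adjusted R² is 1 − (1−R²)(n−1)/(n−p) with p = 10. If every replicate in a
run is identical (zero pure error), the lack-of-fit F degenerates; it is
reported as +inf (p = 0) when misfit remains and 0 (p = 1) otherwise,
rather than raising.

A calibration property is enforced by simulation: generating 2000 studies
from a quadratic truth with Gaussian noise, the 5 % lack-of-fit test
rejects at 4.8 % — within the ±2-point band treated as acceptable.

Known limitation: the published ANOVA tables are not fully reproducible
from the published run means (their Total SS and pure-error cells imply
unrounded replicate data that were not deposited, and not every printed
R² is consistent with its own printed Residual/Total pair at printed
precision). Only formula-level internal consistency on the stalk-sample
column and property-level correctness of this implementation are asserted.

## Desirability optimization

Each response is optimized separately with the linear larger-is-better
desirability `d = (y − y_min)/(y_max − y_min)` clipped to [0, 1], anchored
at the prediction range over the search grid; the exponent is 1 (no
weighting is described in the reproduced study). A geometric-mean composite
is provided for multi-response use but is not part of the reproduction.

The optimizer evaluates a dense grid (default steps 0.5 % ethanol, 0.5 min,
0.25 °C — comfortably below the 2.5-unit resolution at which the study
reports optima) and polishes the best grid point with bounded L-BFGS-B.
For a quadratic on a box this is effectively exhaustive: the test suite
compares it against enumeration on a 10× finer grid. Plateau ties are all
reported; the lexicographically first setting is the canonical answer.
Interior optima inherit the uncertainty of the fitted coefficients, so
agreement with published interior values is only expected to the reporting
resolution (±2.5 units); corner optima are exact and are asserted exactly.

## Hyperspectral chain

Calibration is the standard push-broom correction
I = (I_raw − I_dark)/(I_white − I_dark); white/dark references may be
per-band vectors or full frames (both occur in practice depending on the
scanner software). Corrected reflectance is never clipped — values outside
[0, 1.2] trigger a logged warning only — and any band where the references
coincide raises an error naming the bands.

Segmentation computes PC1 scores of the mean-centered pixel spectra via
SVD and thresholds the score image with Otsu's criterion (the study names
no threshold rule; Otsu is the parameter-free default for a bimodal
foreground/background histogram). Both polarities of the split are
considered and the minority side is kept by default, since the sample
typically covers less than half the frame; the caller can force either
side.

The Savitzky-Golay first derivative uses the study's parameters (7-point
window, 2nd-degree polynomial) and emits only the valid interior — three
bands are dropped at each edge rather than fabricating edge values that
would propagate into the downstream PCA. The derivative is per band index
by default; wavelength scaling (÷8 nm on the default axis) is available
and only changes the overall scale on a uniform grid. The operator is
linear, so it commutes with pixel averaging (asserted to 1e-10), and is
exact on polynomial spectra up to the fitting degree.

Spectral PCA mean-centers only — no unit-variance scaling, as derivative
spectra share one scale and the study names none. Components come from the
SVD, with signs fixed (largest-magnitude loading positive) so results are
deterministic.

## Group statistics

Kruskal-Wallis uses the tie-corrected H. With the n = 3 per group typical
of the reproduced tables, the chi-square approximation is poor, so the
p-value is computed by exact enumeration of the permutation null whenever
the arrangement count is ≤ 200 000 (1680 for three triplicate groups); the
asymptotic value is available behind a flag, and is what large simulations
use. Dunn's post hoc test is z-based on pooled mean ranks with the usual
tie term; Bonferroni adjustment is the default (most conservative common
choice), with Holm and none as alternatives. Compact letters use the
insert-and-absorb algorithm; exhaustive enumeration in the test suite
confirms letter-count minimality on all patterns up to four groups and on
sampled five-group patterns.

A structural fact worth knowing: rank statistics saturate. With three
groups of ten, an adjacent pair's Dunn z cannot exceed ≈2.54 no matter how
far the groups are separated, so "all pairwise p < 0.001" is attainable
only in the two-group case; the tests encode exactly that. Likewise,
published significance letters derived from n = 3 summaries cannot be
certified without the raw replicates and are not treated as binding.

Percent change is 100·(treated − reference)/reference, rendered
half-away-from-zero to one decimal.

## Synthetic data

The BBD simulator draws y = truth(X) + N(0, σ) per replicate, i.i.d. —
the reproduced study reports only mean ± SD per run, so no
heteroscedasticity model is inferable, and Gaussian noise at σ ≈ 2
response units with triplicate runs mirrors the published SD range (1-8).
All randomness flows through one explicit seed; identical spec + seed is
bit-identical.

The cube simulator emulates the SWIR camera geometry (935-1719 nm at 8 nm,
99 bands) with three smooth synthetic endmembers: a dark flat background, a
bread-crumb spectrum with broad water/starch absorptions, and a mold
spectrum that differs from crumb through Gaussian absorption features
centered at 1150 and 1350 nm with ≈30 nm width — the bands where spoilage
manifests in derivative spectra. Scenes are an elliptical "slice" on
background with a seeded random subset of bread pixels switched to mold at
times with positive mold fraction (default: 10 % at the last acquisition
only). Cubes are delivered as *raw* intensities with matching white/dark
references so the calibration step is genuinely exercised, and noise
(default σ = 0.025 reflectance, ≈SNR 20 at crumb albedo) is added on the
reflectance scale. Default spatial size is 64×64: large enough for stable
segmentation and mean spectra, small enough that the full simulated
storage series runs in seconds.

These endmembers are geometric stand-ins, not measured bread spectra.
Passing tests therefore demonstrate that the pipeline recovers structure it
is designed to recover (masks, band localization, storage-time separation)
under controlled conditions; they say nothing about scattering artifacts,
moisture gradients, specular highlights, or instrument drift in real
acquisitions, and the variance percentages of a PCA on real camera data
are not reproducible from simulation.

## Fixtures and I/O

The published design, response, optimum, ANOVA, and group tables ship as
UTF-8 CSV inside the package, with cells held verbatim in "mean ± sd
letter" notation; a dedicated parser splits them, and loading then
re-serializing any fixture is byte-identical. Cube I/O offers a minimal
ENVI subset (text header + BSQ float32 raw) and a portable .npz archive
that also carries the reference frames, so no binary fixtures are needed
anywhere in the repository — all cubes used by tests are generated at run
time.

One discrepancy in the published tables is handled openly rather than
papered over: refitting the printed C2 TPC means reproduces the printed
predicted column only to ±2 at one run (the authors fitted unrounded
means, and ±0.5 rounding of 15 means can propagate more than one unit
through the hat matrix). The corresponding check is left failing for that
sample rather than loosening the tolerance for the seven branches that do
meet it.
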