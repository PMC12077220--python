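# Methods

`snowmotility` re-implements, as a tested pipeline, the motility-analysis
chain used to characterize the swimming behaviour of snow algae across
temperature: synthetic microswimmer data generation, spot detection and
track linking, per-track motility metrics with motile/non-motile
classification, thermal performance curve (TPC) fitting with bootstrap
confidence intervals, dispersal estimation, phototaxis assay scoring, and
cross-species statistics. This note records the models, the parameter
choices that matter, and the design decisions taken where the design was
genuinely open.

## Synthetic microswimmer recordings

The simulator emulates the tracking assay's conditions: 10-second
recordings at 30 frames/s of a mixed population in a 20 µm-deep counting
chamber. The shallow chamber justifies a 2-D projection; z-motion is not
modelled. Positions are sampled at t = 0 … duration inclusive, so a
noiseless swimmer's summed path length is exactly speed × duration.

Three cell categories:

- **Motile** — constant per-cell speed (drawn from a Gaussian, clipped at
  0) with a heading that diffuses rotationally (`turn_rate_sd_rad_s`,
  default 1.5 rad·s^-1/2) and drifts at a constant angular rate
  (`loop_bias_rad_s`, default 1 rad/s). The two parameters together
  reproduce the loop-and-straight-line, quasi-helical paths of biciliate
  swimmers.
- **Drifting** — advection at a constant drift velocity (default
  2 µm/s) plus Brownian positional jitter; emulates passive transport by
  residual flow in the chamber.
- **Stationary** — Brownian jitter only. The per-frame jitter default is
  0.05 µm ≈ sqrt(2D/fps) for a ~6 µm cell in near-freezing water
  (D ≈ 0.04 µm²/s). This matters: jitter accumulates into path length, and
  an unphysically large value would push non-motile cells across the
  motility threshold.

Walls are reflective (billiard bounce, heading component flipped);
detections are dropped i.i.d. with probability `detection_dropout_p` so the
tracker's gap closing is exercised; everything is bit-reproducible for a
fixed seed. The deciliated-control generator emits only drifting and
stationary cells (the cilia-removed population used to calibrate the
classification threshold).

What the generator does *not* emulate: cell–cell interactions, 3-D
helices, chemo-/gravi-taxis, out-of-focus blur, and detection artifacts
(debris). Passing tests therefore demonstrate the correctness of the
analysis chain under the stated motion model, not detector robustness on
real video.

## Detection and linking

Detection is per-frame difference-of-Gaussians filtering (σ₁ =
diameter/(2√2), σ₂ = √2·σ₁) with local maxima above a quality threshold
and separable 3-point quadratic sub-pixel refinement; quality is the raw
DoG response, so published threshold values from other software's
normalized quality scales are treated as dataset-specific.

Linking is the two-stage linear-assignment formulation: (1) frame-to-frame
one-to-one assignment minimizing summed squared distances with a
non-linking alternative cost equal to the squared link radius (default
30 px); (2) track-segment gap closing, linking segment ends to later
segment starts within 50 px and 30 frames by minimum-cost assignment, then
merging chains. Both stages are solved exactly with a rectangular
assignment solver; a link at exactly the cutoff distance is accepted.
Linking is deterministic for a fixed input ordering (the solver's fixed
row-scan order breaks cost ties by lowest spot index). Tracks spanning
fewer than 75 frames (span = last − first + 1, so closed gaps count) are
removed. Distances across a closed gap contribute a straight-line segment
to path length, consistent with computing metrics on retained spots only.

## Motility metrics and classification

Per track: total distance (sum of consecutive-spot Euclidean steps),
maximum distance (largest displacement from the track's *first* spot — the
TrackMate track-feature convention; a max-over-all-pairs alternative is
available via `max_distance_mode="any"`), confinement ratio (max/total; 0
when the total is 0), mean path speed (total distance / elapsed time), and
dispersal (mean speed × confinement ratio, an effective net-displacement
rate). Elapsed time uses first/last timestamps.

Cells are motile when total distance ≥ 100 µm per 10 s recording —
equivalently a mean speed of 10 µm/s; the boundary is inclusive (a
measure-zero choice, documented). For other durations the threshold
rescales as 10 µm/s × duration. Threshold calibration from
deciliated-control tracks offers `fixed` (100 µm), `quantile` (default
99th percentile of control total distances), and `valley` (minimum-density
point between the two main KDE modes of log10 total distance; requires ≥
30 tracks). Replicate summaries average per-track means over the motile
subpopulation only — each cell weighted once; pooling all displacements
instead would weight long tracks more.

Dispersal converts to field-relevant units as µm/s × 86 400 s/d × 10⁻⁶
m/µm; reported values are truncated (not rounded) to two decimals, with
the scaled value first rounded at the 1e-6 level so binary representation
error cannot flip the truncated digit.

## Thermal performance curves

Two TPC parameterizations are fitted, plus a Weibull curve for model
comparison:

- **Pawar** (Sharpe–Schoolfield-type), with Boltzmann constant
  k = 8.62e-5 eV/K and standardization temperature t_ref = 1 °C:

      rate(T) = r_tref · exp(−e/k · (1/(T+273.15) − 1/(t_ref+273.15)))
                / (1 + e/(e_h−e) · exp(e_h/k · (1/(T_opt+273.15) − 1/(T+273.15))))

  This parameterization places the curve's maximum exactly at the T_opt
  parameter (verified numerically), which is therefore reported directly
  and cross-checked against a dense-grid argmax.
- **Thomas2**: rate(T) = a·exp(b·T) − (c + d·exp(e·T)) — exponential rise
  minus exponentially accelerating inactivation; a is the rate at 0 °C
  when c, d are small. Negative values are floored at 0 for reporting;
  fitting uses the raw value.
- **Weibull**: the standard 4-parameter skewed peak whose maximum a is
  attained at topt; participates only in AIC comparison.

Fitting is weighted nonlinear least squares on per-temperature means with
weights 1/sd as published (1/sd² and unweighted available). Internally
e_h > e is enforced by the reparameterization e_h = e + exp(φ), and the
Thomas2 inactivation offset is constrained c ≥ 0 with b, e bounded away
from zero — without these the optimizer can reach a degenerate
quasi-linear solution with no thermal optimum. Start values come from an
a-priori grid (T_opt over observed temperatures; e ∈ {0.3, 0.6, 1.0} eV,
e_h ∈ {2, 4, 8} eV; Thomas2 additionally a data-driven log-linear
regression of the rising flank); the six best starts by weighted SSE are
refined with a bounded trust-region solver using analytic Jacobians.
T_opt/R_max are read off a 0.01 °C grid over the observed range ± 2 °C.
AIC is computed from the weighted RSS with k = #parameters + 1; lowest AIC
wins, exact ties go to fewer parameters. Both models have a long, nearly
flat cost valley (exponential scale/shape trade-offs), so the optimizer's
termination status on the iteration cap is not used as a convergence
signal; convergence is judged on the bootstrap refit success rate (< 50%
flags `converged=False`).

**Bootstrap confidence intervals.** 95% percentile intervals for T_opt and
R_max from refitting perturbed datasets. The default scheme is a
parametric residual bootstrap: each fitted value is perturbed by Gaussian
noise at the point's known sampling scale sd/√n, de-biased by the c4(n)
normal-sd constant (an n = 3 replicate sd underestimates the true scale by
~11%); each replicate is refitted from the point estimate *and* the best
grid start, so replicates whose optimum hops basins are not pinned to the
point estimate. Two alternatives motivated this design and remain
available: resampling weighted residuals globally (the textbook recipe)
is invalid under 1/sd weights because weighted residuals are then not
exchangeable — their variance grows with sd — and its intervals undercover
badly; resampling standardized empirical residuals fails differently,
because with barely more points than parameters the residuals are
overfit-shrunken and carry almost no degrees of freedom. Simulation on the
study design ({0, 2.5, 5, 10, 15, 20, 25, 30} °C, n = 3, 10% CV) puts the
default scheme's T_opt coverage at 90% (Pawar truth) and 95% (Thomas2
truth). Within-temperature resampling is also available but is degenerate
when each temperature contributes a single mean row.

**Synthetic TPC datasets.** Replicate mean speeds are folded-normal around
the true curve with a relative CV component plus a 0.5 µm/s absolute floor
(apparent speeds are positive magnitudes, and tracking jitter gives even
non-moving populations sub-µm/s apparent speeds — this keeps every sd
strictly positive, as 1/sd weighting requires). Temperatures where the
true rate is non-positive contribute no row: a fully inactivated
population has no motile cells and hence no mean motile speed, exactly as
in the tracking assay. This matters for Thomas2, whose raw value plunges
exponentially past the collapse and can never reconcile with clipped
near-zero observations.

Study-condition truths used in the recovery tests: a cryophilic-like
Pawar curve (r_tref = 30 µm/s, e = 0.6 eV, e_h = 4 eV, T_opt = 8 °C) and a
warmer Thomas2 curve (a = 40 µm/s, b = 0.08 °C⁻¹, c = 5 µm/s, d = 0.35,
e = 0.26 °C⁻¹; T_opt = 19.8 °C, R_max ≈ 130 µm/s) whose declining flank is
sampled by the design — model identification is only meaningful when the
data contain the feature that distinguishes the models.

## Phototaxis assay

The index is the fraction of background-subtracted cell-signal intensity
in the light-facing half of the dish: difference image clipped at zero,
restricted to the dish mask, halves split by the sign of the projection of
pixel position (about the mask centroid) onto the light axis, dividing-line
pixels counted as front. The published mean-intensity × area product
reduces to this sum ratio when "intensity" is the half/whole mean (the
areas cancel); the literal product form is available behind a flag and is
identical by construction. A dish with zero total difference intensity is
flagged undefined rather than scored 0.5. Replicate indices are tested
against the 0.5 null with a two-sided one-sample t-test; across a species
battery p-values are Holm-adjusted by default (conservative,
assumption-free; any statsmodels method name is accepted).

The dish simulator places Gaussian cell blobs in a vignetted dish with a
given expected front-half intensity fraction; blob centres keep a 3σ band
away from the dividing line so each cell's mass lands in its assigned
half, and the image side is kept even so the two halves are
pixel-symmetric and an unbiased dish scores exactly 0.5.

## Cross-species statistics

Trait correlations (R_max vs T_opt, cell width, aspect ratio; dispersal vs
temperature) are OLS fits with exact t-based small-sample inference and a
95% CI for the slope; the swimming-vs-photosynthesis T_opt comparison is
the CI criterion (consistent with slope 1 iff the 95% CI contains 1).
The stability of control swimming speed over time is summarized as
per-replicate OLS slopes pooled with a t-interval — a deliberate,
transparent reduction of the random-slope mixed model used for
benchmarking, which is an off-the-shelf fit adding no bespoke value here.
Ramp-rate comparisons of TPC parameters use Welch's two-sample t-test (no
equal-variance assumption).

`run_pipeline` chains simulate → (re-)link → metrics → per-temperature
summaries → TPC fits → AIC selection, with all randomness derived from one
seed and a provenance record (package version, config echo, seed) in the
output directory; two runs with the same config produce byte-identical
outputs.

## Problem sizes in the test suite

The suite exercises the chain at desk scale, chosen as the smallest sizes
at which the statistical checks are stable: tracking recovery on 25-cell
populations at 5% dropout across three seeds; metric-oracle equality on
120 tracks; TPC point recovery on 100 simulated experiments per model;
CI coverage on 60 (Pawar) + 40 (Thomas2) experiments at n_boot = 200
(pooled — per-model binomial noise at these sizes is unreliable near the
band edges); AIC identification on 50 experiments at 5% CV; motile-fraction
recovery on 30 runs × 3 fractions with 200-cell populations. Bootstrap
defaults in the library remain n_boot = 1000.

## Known limitations

- The DoG detector's quality scale is the raw filter response; thresholds
  are not transferable from other implementations.
- No track splitting/merging; crossing cells in dense fields can swap
  identities (the assay's recovery guarantees hold only for separations
  beyond twice the link radius).
- The Thomas2 raw form cannot represent post-collapse zero plateaus;
  datasets should omit fully inactivated temperatures (the generator and
  pipeline do).
- Percentile bootstrap intervals are approximate for strongly asymmetric
  T_opt distributions near the edge of the sampled range.
- The phototaxis index assumes registered image pairs; no alignment is
  performed.
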