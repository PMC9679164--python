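# Methods

This note documents the models, default parameters and numerical choices
behind `photoprf`, and what the synthetic-data experiments do and do not
show about real data.

## Silent substitution

A three-primary display driving four receptor classes (L, M, S, rod) is
linear once the per-channel gamma non-linearity is removed, so receptor
excitations are `e = M g(v)` with `M` the 4x3 excitation matrix
(`M[r,c] = Σ_λ SPD_c(λ) S_r(λ) Δλ · attenuation_c`, Riemann sum on a common
wavelength grid; spectra are linearly interpolated onto the overlap region at
the finest tabulated step, 390–780 nm at 1 nm by default) and `g(v) = v^γ`
the per-channel gamma model. All silencing algebra runs in this linearized
space. Making gamma explicit matters: a pair solved under one gamma and
displayed under another leaks contrast into the "silenced" class, which is
exactly what `validate_pair` quantifies (and what explains residual rod
contrast of nominally cone-selective stimuli on a real, imperfectly
calibrated screen).

*Cone-isolating pairs.* With the blue channel frozen, the rod row of `M`
defines a one-dimensional null direction in the (R, G) plane:
`d ∝ (M_rod,G, −M_rod,R, 0)`. Modulating along `d` changes L/M excitation
but leaves rod excitation unchanged to machine precision (the rod-row inner
product cancels exactly in floating point). The step size is solved so that
the *mean of the L and M Michelson contrasts* equals the request.
Restricting to red–green shifts the stimulus toward long wavelengths, where
rod sensitivity — and therefore calibration error — is smallest.

*Rod-isolating pairs.* The 1-D null space of the L and M rows (their cross
product) silences both cone classes simultaneously; the induced S-cone
contrast is reported but not constrained, since three primaries cannot
silence three classes. Degenerate geometry (proportional rows) raises an
error rather than returning a meaningless direction.

*One-sided vs bidirectional modulation.* The default pair holds the
background (mid-grey, drive 0.5 per channel unless configured otherwise)
fixed and modulates one-sided toward the target. Michelson contrast
`|Δe| / (2 e_bg + Δe)` is then mildly non-linear in the step, so the step is
found by bracketed root-finding (`brentq`, tolerance ~1e-15; achieved
contrast error < 1e-12). In bidirectional mode the pair straddles the
background symmetrically and contrast `|Δe| / (2 e_bg)` is *exactly* linear
in the step — this is the mode in which "double the contrast = double the
drive delta" holds identically on a linear-gamma display. Gamut violations
report the limiting channel.

*Receptor sensitivities.* The built-in receptor set is generated from a
parametric photopigment template — a Gaussian in log wavelength (SD 0.08,
FWHM ≈ 100 nm at 540 nm) — at standard peak wavelengths (L 566, M 541,
S 441, rod 497 nm). This is a synthetic approximation of standard-observer
fundamentals: entirely adequate for the solver algebra and for all tests
here (which only require four independent broadband curves), but a physical
calibration must substitute measured fundamentals and measured primary
spectra via the two-column text reader.

## Stimulus protocol

One run is 348 frames at TR = 1 s: three 20-s baselines (start, mid-point —
placed after half of the stimulation frames — and end) embedded around 288 s
of simultaneous ring and wedge stimulation. The ring completes 6 cycles of
48 s with logarithmic eccentricity scaling; its centre is log-spaced from
0.5 deg to the value at which the outer edge reaches exactly 8.6 deg, with
annulus width 0.5 x centre eccentricity (constant duty cycle on a log axis).
The wedge is 20 deg wide and advances 10 deg per frame (8 cycles of 36 s),
half-open in angle to avoid double counting at the wrap. Apertures are
binary masks on a square pixel grid (default 4 px/deg for stimulus export;
the analysis pipeline uses 2 px/deg, which changes predicted time courses by
well under the noise level while cutting the forward-model cost fourfold).
The checkerboard carrier is not modelled: the pRF forward model depends only
on the apertures.

## pRF model and two-stage fitting

The forward model is a symmetric bivariate Gaussian in visual space. Frame
drive is the aperture-mask overlap normalized by the Gaussian's total mass
on the grid, convolved with a canonical double-gamma HRF (peak 6 s,
undershoot 16 s, ratio 1:6, peak-normalized, 32-s support). Amplitude and
baseline are not part of the forward model; they are estimated per fit.

*Coarse stage.* The data are smoothed along the cortical sheet with a
Gaussian kernel of FWHM 5 mm on geodesic (graph) distances, truncated at
3 sigma, then correlated against a precomputed prediction bank over a polar
grid: 12 log-spaced eccentricities (0.5–9 deg) x 24 angles plus the origin,
crossed with 8 log-spaced sigmas (0.18–9 deg); the grid deliberately extends
slightly beyond the stimulated field. The argmax of the Pearson correlation
wins; ties break to the first grid index; zero-variance series are flagged
unfit.

*Fine stage.* Vertices whose coarse R² exceeds 0.05 are refined against the
*unsmoothed* series by Nelder–Mead over (x, y, log σ), with amplitude and
baseline profiled out exactly by linear least squares at every objective
evaluation. This minimizes the identical residual sum of squares as a
five-parameter simplex while guaranteeing σ > 0 and converging in fewer
evaluations. An explicit initial simplex with 0.5-deg position steps and a
0.25 log-σ step is supplied: the library default perturbs a coordinate that
starts at exactly zero by only 2.5e-4, which can freeze a pRF on a grid
axis (observed as a vertex stuck at x = 0 on noiseless data). If the
optimizer fails to improve on its start, the start is returned and flagged.

*R² bookkeeping.* R² is the squared Pearson correlation between model and
data throughout. Fine-fitted vertices are scored against the unsmoothed
series; vertices that never pass the coarse gate keep their coarse
(smoothed-series) R² — the two-stage convention. This matters for weak
maps: scoring coarse picks against independent unsmoothed noise would
discard almost everything and make retention statistics incomparable
between strong and weak maps.

After fitting, x, y and σ can be smoothed along the surface (FWHM 3 mm,
fitted vertices only), and positions are converted to eccentricity and
polar angle (0 deg = right horizontal meridian, counter-clockwise positive,
range (−180, 180]). Vertices are excluded from analysis at R² ≤ 0.03 — a
deliberately permissive threshold (two-tailed p = 0.0012 at n = 348 via the
t transform of a correlation) chosen to retain weak emerging signals; 0.05
(p ≈ 3e-5) is the stricter alternative, and conclusions on the synthetic
cohort are unchanged between the two.

## Rod–cone map correspondence

Given paired polar angles (rod θ, cone φ) from vertices that survive the R²
threshold in *both* maps:

* **Orthogonal regression** (total least squares via the first principal
  axis of the centred cloud): slope β = 1 and intercept = 0 indicate
  correspondence. TLS is used because both angle estimates carry comparable
  noise; ordinary least squares would attenuate the slope.
* **Akaike weights** compare three models of φ: the identity line (k = 1,
  noise variance only), a horizontal line at the mean of φ, and a vertical
  line at the mean of θ (k = 2 each: level + variance), with
  `AIC = n ln(RSS/n) + 2k` and weights from `exp(−ΔAIC/2)`. Zero RSS is
  floored at 1e-9·n.
* **Fisher–Lee circular correlation** with a seeded permutation test
  (`p = (1 + #{|CC_perm| ≥ |CC_obs|}) / (n_perm + 1)`).
* A **normative envelope** from control results: the 95% coverage ellipse of
  (β, intercept) at the χ²(2) radius plus the empirical 2.5–97.5 percentile
  CC_FL range; patients are classified inside/outside per index. Samples
  with fewer than three surviving pairs carry NaN statistics and classify as
  outside (no structure to analyse).

*Why the AIC residuals are unwrapped.* Angles live on a circle, so wrapping
residuals to (−180, 180] looks natural — but it destroys the comparison's
power. For an unstructured cone map, the wrapped difference φ − θ against a
well-spread rod map is (near-)uniform with variance 180²/3, the *same*
maximal variance the horizontal model faces, so under the null the identity
model ties in expectation and wins on chance fluctuations alone (~10% of
null datasets in our simulations, independent of sample size). Treating the
angles linearly — the convention in which such regressions report intercepts
far outside (−180, 180] — makes the null identity residual variance the
*sum* of both maps' variances, roughly double the horizontal model's, so
noise reliably loses; a true correspondence still wins overwhelmingly
because its residuals are small for all but the few vertices whose noisy
estimates straddle the ±180 boundary. The wrapped variant remains available
(`wrap=True`) with this caveat documented. For linear position estimates
(x, y, eccentricity) the analogous analysis uses plain Pearson correlation
and unwrapped residuals throughout.

## Synthetic cortex and study conditions

`make_ground_truth` builds two rectangular lattice patches (one per
hemisphere, 4-connected, 2.5-mm spacing) with a complex-log-style template:
log eccentricity (0.5–8.6 deg) along one sheet axis, polar angle spanning
the contralateral hemifield along the other, σ = 0.5 + 0.2 x eccentricity,
and 0.05-deg positional jitter so the truth never sits on a search grid.
Because the spacing is fixed, patch *area* grows with vertex count — as in
cortex, where V1–V3 extend over many centimetres and a 5-mm smoothing kernel
couples only a small neighbourhood. This matters for the null experiments:
if the lattice were instead densified inside a fixed small patch, all
surviving noise vertices would fall within a kernel or two of each other and
the correspondence statistics would see a handful of effectively independent
observations, inflating chance structure.

`simulate_bold` produces `responsive` data (truth-driven prediction scaled
to unit amplitude plus noise with SD 1/tSNR) or `silent` data (noise only;
the model for an untreated cone condition). Noise is white Gaussian by
default with an optional AR(1) filter (ρ = 0.3, variance-renormalized) to
emulate BOLD autocorrelation; tSNR is signal amplitude over noise SD. The
noise stream depends only on the seed and shape, so paired conditions share
it exactly (verified by reconstructing the clean signal as responsive minus
silent). Default study conditions: tSNR 50 for responsive maps and ~320
vertices per sheet in the multi-dataset experiments — large enough that a
silent map's few-percent of threshold-surviving null vertices (typically
10–20) give the model comparison a real sample, while keeping a 50-dataset
experiment within minutes on one CPU. An optional per-frame horizontal
aperture-jitter transform is available to probe gaze-instability effects but
is not part of any default.

What the synthetic experiments show: that the *pipeline* recovers known
ground truth, separates responsive from silent conditions, and that noise
does not fabricate rod–cone correspondence under realistic-scale sampling.
What they do not show: behaviour under physiological noise spectra, real
cortical folding and magnification, nystagmus-driven aperture uncertainty,
or the foveal fitting bias of any particular fitting package — real silent
maps may cluster their spurious estimates rather than spreading them, which
would only strengthen the horizontal model and the null separation.

## Staircase psychophysics

Both forced-choice tasks (4AFC square localization, guess 0.25; ridge
motion discrimination, 2-alternative, guess 0.5 — a "nothing visible" report
counts as incorrect) run 1-up/1-down over 21 contrast levels, level 1 the
highest contrast, starting at level 1. Stopping: ≥ 14 reversals (square) or
≥ 8 (ridge), or ceiling once more than 8 correct responses accumulate at the
lowest contrast. The threshold estimate is the mean of the last six reversal
levels (the estimator is not dictated by the procedure; last-six is standard
practice and discards the descent from the start), converted to mean L+M
Michelson contrast through the level table — by default geometric from 0.52
to 0.16, anchored at the extreme thresholds observed across staircases; a
physical calibration would replace it with measured per-level contrasts.
Group comparison uses the 95% t prediction interval
`mean ± t_{0.975,n−1} s √(1 + 1/n)` of untreated thresholds; only a
threshold strictly below the interval counts as improved cone function.

*A characterized bias.* The staircase converges to the 50%-correct point:
with the stopping rule relaxed to 200 reversals, a simulated Weibull
observer of slope β = 3 shows zero mean bias. Under the clinical protocol,
however, the same shallow observer (whose P(correct) changes by only ~0.04
per level) retains a ≈1.4-level bias toward the start side, because 14
reversals cannot erase the descent from the brightest level when the
restoring force near threshold is weak. Steeper observers (β ≈ 6, i.e.
near-threshold discrimination is decisive) equilibrate within the clinical
rule and their mean thresholds land within 0.1 level of the 50% point over
500 runs. Real threshold estimates from short staircases on shallow
psychometric functions should therefore be read as slightly conservative
(biased toward higher contrast).

## Numerical choices and degenerate inputs

* Pearson correlations are computed on z-scored series; zero-variance
  series are flagged rather than propagated as NaN surprises.
* pRFs with effectively no mass on the aperture grid (sum < 1e-12) produce
  zero drive instead of a 0/0.
* Surface smoothing ignores NaN sources and renormalizes weights; an
  isolated vertex smooths with itself.
* The Fisher–Lee denominator is permutation-invariant, so the permutation
  test recomputes only the numerator; a map with all angles equal yields NaN
  (flagged degenerate).
* All experiment-level randomness flows from a single seed expanded via a
  root generator; derived seeds stay below 2^31.

## Known limitations

* The flat-sheet cortex and white-noise default understate spatial and
  temporal correlations of real BOLD data; the AR(1) option narrows but does
  not close this gap.
* The template receptor sensitivities are not measured fundamentals; solver
  *exactness* is unaffected (it is linear algebra on whatever curves are
  supplied), but absolute contrast values on a physical display are only as
  good as the supplied spectra.
* S-cone silencing is impossible with three primaries and two constraints;
  rod-isolating pairs report, but cannot remove, S-cone contrast.
* No gaze/nystagmus model is applied by default; the aperture-jitter hook
  exists for sensitivity analyses only.
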