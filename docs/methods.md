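# Methods

This note records the models, numerical choices and simulation
conditions behind `geminirec`, and what the package's synthetic
benchmarks do and do not establish about real data.

## Growth model

Particles are assumed to grow by constant-rate addition of subunits onto
their facets, preserving shape. Volume is then linear in time and the
radius follows `r(t) = (K t + A)^{1/3}`; `K` (radius-units³/h) is the
volumetric rate and `A` the cubed radius at `t = 0`. The model ignores
nucleation kinetics and any late-stage drift of the assembly energy
(e.g. from defect accumulation); real growth curves deviate mildly from
linearity near the end of long recordings, which is one reason fits are
reported with R² rather than assumed perfect.

**Fitting.** All fits are performed on the linearized scale — cubed
radius, or the volume index `area^{3/2}` which is proportional to it —
by ordinary least squares of the linearized value against time; R² is
reported on that scale. A nonlinear fit on the radius scale would weight
the noisy early samples differently but has no closed form; the
linearized fit matches how growth curves are usually summarised for this
kind of recorder and is exact under the model. A non-positive fitted
slope marks the fit `degenerate` instead of raising, since constant-size
objects are a legitimate QC outcome. Fitted intercepts may come out
slightly negative under noise even when the true `A` is ≈ 0; they are
accepted (a hard `A ≥ 0` constraint would bias the estimator), and a
negative `A` simply means extrapolated nucleation after `t = 0`.

**Calibration.** With exactly two timestamps the 2×2 linear system on
cubed radii is solved exactly; with more, least squares. Stamps whose
radii do not increase with time invalidate the particle
(`InconsistentStampsError`) rather than being silently dropped: such a
pattern means mis-called bands, and decoding from them would be
meaningless. Decoded times before `t = 0` are returned and flagged
`pre-window`, never clamped — the dark core genuinely predates the first
stamp.

**Numerical conditioning.** The inverse map `(r³ − A)/K` loses relative
precision when `A/K ≫ t` (cancellation in `r³ − A`); round-trip accuracy
is therefore guaranteed relative to the natural timescale `t + A/K`, not
to `t` alone. In every realistic protocol (`A/K` of order hours) this is
indistinguishable from machine precision.

## Reporter kinetics

Cytoplasmic reporter level is modelled as a piecewise first-order
response per stimulus event: after `on + τ_d` the concentration rises
toward the event amplitude with time constant `τ_on`, after `off + τ_d`
it decays with `τ_off`; events superpose additively on a basal level.
Defaults: `τ_d = 2 h` (transcription/translation/transport lag of the
reporter, matching the observed delay of induced signals), `τ_on =
0.5 h`, `τ_off = 1 h`. The decay constant is deliberately of order an
hour: the growing particle itself takes up cytoplasmic reporter and
accelerates its clearance. "Boost" kinetics (destabilized reporter and
transcript) set `τ_on = τ_off = 0.1 h`. These are single-stage effective
constants, not a mechanistic transcription model; the recorder literature
reports delays and turnover qualitatively, so the constants are exposed
as configuration rather than asserted as biology.

The delay enters decoding as a pure shift: decoded event times are
reported raw by default, with `raw − τ_d` available when a protocol sets
the delay. Both are kept because whether a reported onset should be
stimulus time or transcription time depends on the question being asked.

## Geometry and rendering

The midplane cross-section of an octahedral particle growing by uniform
facet addition is a square; the simulator draws particles as nested
square (diamond) level sets, with the layer coordinate of a pixel equal
to the L1 distance from the centre in the particle's rotated frame. The
level-set geometry makes rendering exactly invertible: a profile sampled
along an edge-normal ray, rescaled by `|cos α| + |sin α|` for the ray
angle `α` in the particle frame, reproduces the radial record. Optics
are a Gaussian PSF (applied in image space — note this blurs *geometric*
distance, so its effect on the layer coordinate along an edge-normal ray
is √2 larger), Poisson shot noise (photons per intensity unit), Gaussian
read noise and a constant background. All stochastic rendering requires
an explicit seed and is bit-reproducible.

Not modelled: 3D volumetric imaging, cell bodies, photobleaching,
out-of-plane particle motion, and the reaction–diffusion kinetics of dye
penetration through tissue. Timestamp pulses are drawn as top-hats
*centred* on the administration time (default width 0.5 h) so that the
band's intensity maximum coincides with the injection time it proxies;
in real tissue the labelling kernel is asymmetric and the peak can lag
injection by a diffusion time.

## Band calling

Profiles are extracted with sub-pixel bilinear sampling, averaged over a
configurable width perpendicular to the ray, optionally filtered with a
zero-phase Butterworth low-pass (order 3, cutoff 0.2× Nyquist by
default — zero phase because a causal filter would shift band positions
and bias every decoded time), and baseline-subtracted (10th percentile
of out-of-band samples). The maximum filter-induced deviation is
recorded so distortion can be checked.

Band onsets use the tangent-at-50% construction: the onset radius is the
intercept with the baseline of the tangent taken where the rising flank
crosses half of the peak height. The tangent slope is estimated as the
steepest adjacent-sample slope within a 5-sample window centred on the
crossing; this reproduces the analytic intercept of a Gaussian-integral
edge (`onset = ℓ₀ − 1.2533 σ`) within 5% for edge widths of 2–10
samples, while still landing within one sample on an ideal sharp step.
The onset estimator is *biased* by −1.2533 σ_PSF on a blurred step —
but because timestamp bands are called with the same estimator, the bias
largely cancels in calibration, and the residual error is second order.
Peaks are plain prominence-filtered local maxima (default prominence:
10% of the channel's dynamic range). Flank selection takes the most
prominent band by default, with ties broken toward smaller radius.

## Detection and tracking

Detection: local-mean adaptive threshold (margin 2% of the frame's
dynamic range) OR'd with a Sobel gradient mask, hole filling, small-object
removal, Euclidean distance transform, minimum-separation maxima as
centres, watershed assignment, then intensity-weighted centroids, areas,
mean intensities, and a radius estimate (largest extent above 50% of
peak-over-background). Regions whose peak does not exceed the frame
median by 5 robust (MAD) standard deviations are rejected, which keeps
blank noisy frames empty.

Tracking processes frames in reverse chronological order — every
particle exists and is largest in the last frame, so track ends in
processing order correspond to nucleation in forward time. Links
minimize a linear-sum-assignment cost
`d/d_max + w_A·|ΔA|/max(A) + w_I·|ΔI|/max(I)` with `w_A = w_I = 1` and
`d_max = 30 px`; all three terms live on [0, 1], so the defaults weight
them equally — the weights are exposed because no principled values
exist without a motion/noise model. Links beyond `d_max` are forbidden.
There is no gap closing by default (a missed detection ends the track;
an optional 1-frame bridge exists behind a flag): the QC philosophy is
to flag and exclude suspect tracks (`short`, `gaps`,
`non_monotone_area`) rather than repair them.

## Benchmark scenarios and their calibration

The canonical conditions (module `geminirec.scenarios`):

* **Growth fits** — 35 particles, 48 h at 0.5-h sampling. `K` is
  log-normal with mean 0.3 µm³/h and CV 20% (particles reach ≈ 2.4 µm
  radius in 48 h, matching the few-micron particles such recorders
  produce; the CV is a configuration choice, not a measured value).
  Noise: subunit addition as a Poisson counting process with an
  effective lattice volume of (30 nm)³ per cage — ≈ 5×10⁵ subunits per
  mature particle, so shot noise is sub-percent — plus 2% multiplicative
  area measurement error, which dominates.
* **Early window** — stamps at 0 and 11 h, induction 8 h before the
  first stamp (dark core), signal onsets at 2–8 h, 250 particles per
  group. Band-localization jitter is Gaussian in radius with σ_r chosen
  so the *total* decoded timing s.d. — including the contribution of
  jittered timestamp bands, propagated by the delta method — equals
  0.75 h at the window midpoint. Calibrating only the signal band's
  contribution would understate the decoded spread by ~23%.
* **Late window** — the same σ_r applied to a protocol whose stamps sit
  at 48 and 84 h after induction (signals 6–30 h into the window):
  identical optics, pure geometry-driven degradation, group s.d. ≈ 2–3 h.
* **Band counting** — 11 switches among three dyes every 2 h from age
  6 h, K = 8000 px³/h, PSF σ = 20% of the mean inter-band spacing,
  SNR ≥ 20.
* **Resolution scan** — two stimulus pulses (0.1 h each) at descending
  separations, first event 2 h after nucleation where radial growth is
  fast (24 px/h at r = 144 px), PSF σ = 0.8 px ≈ 20% of the geometric
  inter-band spacing at the 15-min separation — the same PSF convention
  as the band-counting scenario. With Boost kinetics all of 60/45/30/15
  min resolve; with default kinetics 1 h resolves and 15 min merges.

Problem sizes (35 trajectories, 250 particles/group, single-particle
renders at 256–384 px) are the package's standard desk-scale settings;
they complete in seconds and give Monte-Carlo margins comfortably inside
the tolerances the tests assert.

**What passing these benchmarks shows — and does not.** The simulations
validate the *decoding machinery*: that the pipeline recovers what the
generative model wrote, at the stated noise levels. They inherit the
generative model's idealizations — perfectly octahedral particles, a
single jitter scale for all bands, no tracking failures, no spectral
bleed-through, no biological variability in reporter induction. Absolute
in-tissue accuracies, dose–response dynamic range, and nucleation-timing
statistics depend on noise sources the model does not parameterize and
are out of scope.

## Reproducibility

Every stochastic entry point takes a seed; identical seeds give
bit-identical images and tables. CLI runs write a JSON manifest with the
SHA-256 of the canonicalized configuration. Images are stored as
multipage TIFF with channel names in the embedded JSON description
(byte-deterministic, unlike OME-XML which stamps a per-file UUID);
tables as CSV; reports as JSON. Unknown configuration keys are rejected
with their field path rather than ignored.
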