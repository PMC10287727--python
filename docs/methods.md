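# Methods

`chronoplex` re-implements, as a tested library, the computational stages of a
diurnal choroid-plexus (ChP) / cerebrospinal-fluid (CSF) study: fiber-photometry
statistics around the light-dark transition, an extended-depth-of-field imaging
pipeline for multi-day explant movies, circadian period estimation, and
TEM junction quantification.  The raw recordings behind those analyses are not
publicly deposited, so every stage ships with a synthetic-data generator whose
ground truth is known exactly; the test suite and `scripts/acceptance.py` score
each stage as a parameter-recovery problem.

## Photometry

**Model.** A recording is modelled as

    F(t) = α + β·exp(−γ·t^δ) + s(t) + ε(t)

where the stretched-exponential (Kohlrausch) term is photobleaching plus
autofluorescence baseline (α offset, β bleachable amplitude, γ > 0 rate,
0 < δ ≤ 2 stretching exponent), `s(t)` is the diurnal reporter component and
ε is additive Gaussian noise.  `s(t)` is a logistic sigmoid that rises to a
plateau before lights-off, holds through the dark phase, and relaxes over 3 h
after lights-on, repeated every 24 h.  The sigmoid's 10–90% rise spans
`rise_width_min` (default 120 min) and its onset (10% point) sits
`onset_offset_min` before lights-off.  The true shape of the pre-dark rise is
not known; the logistic is a modelling choice made because it gives a
closed-form time for any fractional crossing (the 20% crossing is
`t_half − τ·ln 4` with τ = rise/​(2 ln 9)), which is the ground truth the
anticipation statistic is scored against.

**Preprocessing.** Raw 5-Hz traces are median-filtered in 10-min bins (one
sample at each bin centre; empty bins interpolated).  For first-24-h analyses
a stretched-exponential fit is subtracted; multi-day analyses skip the
correction.  ΔF/F0 is computed relative to the first hour: F0 is the mean of
the *raw* signal over that hour, and the corrected trace is re-centred on its
own first-hour mean so ΔF/F0 averages zero there.

**Fitting the bleach model.** Stretched exponentials are ill-conditioned in
(γ, δ); the fit is multi-started over δ ∈ {0.3, 0.5, 0.7, 1.0} and
γ ∈ {0.01, 0.1, 1}, keeping the lowest residual sum of squares.  When a
recording carries a diurnal transient, a whole-trace least-squares fit
absorbs a substantial fraction of the plateau (we measured ≈20% of the
amplitude and a ~22-min bias on the 20%-crossing time).  Reweighting schemes
(asymmetric least squares, residual peak-stripping) do not rescue this
because the transient occupies more than half of a 24-h window.  The default
preprocessing therefore uses a *light-phase-anchored* fit: since the light
schedule is known, samples from 3 h before lights-off to 3 h after the
following lights-on are excluded and the decay is extrapolated through the
gap.  On synthetic traces this leaves a baseline error below 1e-3 at the
crossing and an anticipation bias of about 2 min (well under one 10-min
bin).  The plain whole-trace fit remains available and is what the
parameter-recovery tests exercise on transient-free traces.

**Diurnal statistics.**
* *Peak response*: mean ΔF/F0 over the clock window 20:30–21:30 (half-open),
  first occurrence in the recording.
* *Classification*: wild-type recordings define an envelope [min, max] of
  peak responses (pooled across experiments); reporter peaks above it are
  `strong`, inside (boundary inclusive) `wild_type_like`, below `dropping`.
* *Anticipation*: for strong responders, the first time ΔF/F0 stays at or
  above 20% of the peak for ≥3 consecutive bins (a sustained-crossing rule
  guarding against noise spikes; an instantaneous rule is available), with
  the crossing refined below bin resolution by linear interpolation between
  the bracketing bins; reported as minutes before lights-off (19:00 by
  default; housing is 12:12 with lights off at 7 p.m.).
* *Daily modulation amplitude*: per complete 24-h window, the 5th–95th
  inter-percentile range of ΔF/F0 — a robust stand-in for peak-to-trough that
  tolerates residual bleach tails and single-bin outliers.

**Synthetic cohorts.** Strong responders use plateau amplitude 0.3 a.u. over
a baseline of ≈1.5 a.u. and 20%-crossing offsets drawn around 67 min before
lights-off (SD 15 min).  Wild-type surrogates are *not* noise-flat: a new
sample always falls outside the min-max envelope of n iid samples with
probability 2/(n+1), so a meaningful envelope requires the wild-type peaks to
spread more than flat-reporter peaks — which is also what real recordings
show (animal-to-animal diurnal autofluorescence variation).  Wild-type
surrogates therefore receive diurnal modulation amplitudes evenly spanning
±0.05 a.u.; flat reporters (amplitude 0) then sit well inside the envelope
and strong/dropping traces (±0.2 ΔF/F0) far outside it.  Dropping recordings
are modelled as a negative-going transient on the reporter time course
(cannula displacement / handling-stress phenotypes), which survives bleach
correction the same way the positive transient does.

## Explant imaging (focus projection + registration)

**Pipeline.** Per timepoint: average the repeated stacks → bin 2×2 in XY →
quantise each plane to 256 gray levels (per-plane min-max) → Shannon entropy
(bits) of the gray-level histogram in a 10×10-px sliding window (reflective
padding; for the even width the window spans 4 px before and 5 px after the
centre) → per-pixel argmax over z (ties to the lowest z) → Gaussian smoothing
of the index map with σ = width/2 = 10 px, clamped to [0, Z−1] → projection
through the original stack with linear interpolation between the bracketing
planes.  The focused video is high-pass filtered (frame minus its 50-px
Gaussian background — registration only, never quantification), registered
to the mean frame rigidly (subpixel phase correlation; rotation by bounded
scalar search on the phase-correlation error), then affinely (6 parameters,
derivative-free minimisation of the mean squared difference, centre-anchored
parametrisation; falls back to the rigid result if the optimum is worse than
identity), then nonrigidly with a classic intensity demons scheme — update
`u = (f − m∘s)·∇f / (‖∇f‖² + (f − m∘s)²)`, accumulated field smoothed with
σ_reg = 2 px after every iteration, 60 iterations per level over a 3-level
pyramid.  Finally: centre-50% crop, rescale between the 1st and 99th
intensity percentiles computed jointly over the whole movie (per-frame
scaling would erase the slow fluorescence change the experiment measures;
a per-frame mode exists), clip to [0, 1], and average each frame to a
mean-intensity trace.

"Width" of the entropy filter is read as the side of the square window and
"width" of the Gaussian as 2σ; both are configuration parameters, since the
protocol names sizes without defining them.

**Synthetic movies.** A band-limited texture (white noise smoothed at
texture_scale = 2 px) lies on a smooth focal surface `z*(x, y, t)` (low-order
polynomial; default a gentle dome spanning ≈±2.5 planes across the field,
drifting 1 plane over the movie — a flattened explant).  Each plane z holds
the texture blurred with σ = 2·|z − z*| px, scaled by a ~24-h sinusoidal
modulation (depth 0.3) and slow bleaching, warped by a smooth nonrigid field
(≤2 px) plus linear drift (0.5 px/frame), with additive noise (SD 0.002) and
256-level digitisation at the end.  The digitisation matters: histogram
entropy discriminates depth only while acquisition noise stays below the
gray-level step — precisely the regime of averaged 8-bit camera data — and
continuous-valued synthetic images with visible noise would make every window
saturate near log2(window area).  What the generator does *not* model:
optical PSF physics, Poisson noise, the isosbestic channel, shading, or
tissue deformation with intensity changes coupled to depth; passing tests
show the pipeline recovers this geometry, not that it handles every
real-tissue pathology.

## Period estimation

**Chi-square periodogram** (Sokolove–Bushell).  For each candidate period P
(16–32 h in 0.1-h steps) the evenly sampled trace is folded into
K = round(P/Δt) phase bins and

    Qp = Σ_h n_h (M_h − M)² / (Σ_i (x_i − M)² / N)

with column means M_h over n_h samples — the count-weighted between-column
sum of squares over the mean total variance, χ²(K−1) under the null, and
Qp ≤ N always.  A linear trend is removed first (damped luminometry baselines
drift); the scan needs ≥3 full cycles of the longest candidate.  Because
~160 candidates are tested, the significance flag uses a Bonferroni-corrected
level α/n_candidates; the peak is chosen by maximising Qp minus its critical
value, since raw Qp values at different K are not comparable.  The
goodness-of-fit percentage is 100·Qp/N — the fraction of trace variance
explained by the folded waveform at the peak (white noise ≈15%, a clean
rhythm >90%); wells below 80% are excluded by the standard gate, mirroring
the inclusion rule used with commercial luminometry software whose exact
formula is unpublished.

**Cosinor.**  Least-squares fit of `m + a·cos(2πt/P) + b·sin(2πt/P)` at a
fixed period (default 24 h); amplitude √(a²+b²), acrophase atan2(b, a)
mapped to hours, p-value from the F-test of the harmonic terms against the
intercept-only model.  This is the rhythm test used for designs with few
timepoints and replicates; it replaces (and is not) the published
nonparametric rhythm-detection tool.

**Synthetic wells.** Damped cosine, baseline 100 counts, amplitude 50,
damping 0.1/day, noise SD 5–10 counts, sampled in 60-s bins 10×/hour for
7 days — amplitude-to-noise ≥3, matching healthy explant wells.

## TEM junction quantification

Inputs are calibrated annotations in μm.  Vesicles within 2 μm of the
lateral membrane polyline (exact point-to-segment distance, via shapely)
are peri-junctional.  Each is localised by projecting onto the polyline and
taking normalised arc length from the basal end: 0 = basal, 1 = apical.
The printed "(apical−basal)/apical" description of this ratio is internally
inconsistent with its stated endpoints; the arc-length position reproduces
the stated 0/1 scale exactly and is what is implemented.  Whether the
distances should be straight-line or along-membrane is unstated;
along-polyline arc length is the implemented interpretation.  Junction width
is the arithmetic mean of exactly 10 inter-membrane gap measurements;
per-animal width is the mean of the per-junction means (10 junctions per
animal in the standard design).

Synthetic junctions place vesicles at arc-length ratios drawn from a Beta
distribution with mean `apical_bias` (concentration 8; a bias of exactly 0
or 1 is treated as zero-variance), offset perpendicular to the membrane
within the zone; gaps are Gaussian around 15 nm (SD 4 nm), matching tight
junction dimensions.

## Numerical choices and conventions

* All clock windows are half-open `[lo, hi)`; clock mapping is
  `clock = (start_clock + t) mod 24` with recordings starting at 13:00 by
  default so the first lights-off falls 6 h in.
* Argmax ties break to the lowest z; interpolation is bilinear for warps and
  linear along z; padding is reflective throughout.
* All randomness flows through `numpy.random.default_rng(seed)`; fixed seeds
  give bit-identical outputs, which the end-to-end determinism check
  (identical SHA-256 checksums on re-run) relies on.
* Registration transforms are estimated on high-passed frames and applied to
  unfiltered frames.
* Problem sizes in tests and the acceptance script (e.g. T=8, Z=20, 128×128
  movies; 12-animal cohorts; 200-replicate null calibrations) are desk-scale
  choices that keep each stage's recovery measurable in seconds to minutes
  on one CPU.

## Known limitations

* The sigmoid waveform and its 3-h post-lights-on relaxation are modelling
  choices; real secretory dynamics may be asymmetric or multi-phasic.
* The light-anchored bleach fit assumes a known 12:12 schedule; free-running
  (DD) recordings would need the margin widened or the plain fit.
* The demons implementation is a minimal diffusion-regularised scheme — no
  symmetric forces, no diffeomorphic guarantees.
* The entropy focus measure degrades when acquisition noise exceeds roughly
  one gray level of the 256-level quantisation; heavily photon-starved
  movies would need a variance- or gradient-based focus measure instead.
* The chi-square periodogram assumes even sampling; gaps are not handled.
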