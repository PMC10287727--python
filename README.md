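# chronoplex

Analysis toolkit for diurnal choroid-plexus (ChP) / cerebrospinal-fluid (CSF)
experiments.  The choroid plexus secretes CSF and its cargo — including the
thyroid-hormone carrier transthyretin (TTR) — on a daily schedule, and the
experiments this package supports track that schedule with four very
different readouts:

* **Fiber photometry** of a fluorescent CSF reporter in freely moving mice:
  traces are median-binned (10 min), corrected for photobleaching with a
  stretched-exponential (Kohlrausch) model `α + β·exp(−γ·t^δ)`, normalised to
  ΔF/F0 relative to the first hour, and summarised by the peak response over
  the 8:30–9:30 p.m. clock window, classification against the wild-type
  autofluorescence envelope (strong / wild-type-like / dropping), the time
  each strong responder first sustains 20% of its peak, and the resulting
  anticipation of lights-off in minutes.
* **Multi-day explant imaging**: 4-D movies (t, z, y, x) whose in-focus
  surface drifts over days are reduced to an all-in-focus video via a local
  Shannon-entropy focus measure (10-px window, 256 gray levels), a smoothed
  per-pixel focus index map, and interpolated projection; the video is then
  registered (rigid → affine → demons nonrigid, against the mean frame),
  cropped, rescaled between its 1st and 99th intensity percentiles, and
  reduced to a mean-intensity trace.
* **Explant luminometry**: circadian period estimation with the
  Sokolove–Bushell chi-square periodogram
  `Qp = Σ_h n_h (M_h − M)² / (σ̂²)` referred to χ²(K−1), with a
  variance-explained goodness-of-fit gate (≥80%) and a cosinor
  (harmonic-regression) rhythm test.
* **TEM junction annotations**: vesicle counts in the 2-μm peri-junctional
  zone, apical-basal localisation as normalised arc length along the lateral
  membrane (1 = apical, 0 = basal), and tight-junction width as the mean of
  10 inter-membrane gap measurements, aggregated per animal.

Because the underlying raw recordings are not publicly deposited, the package
ships a first-class synthetic-data module (`chronoplex.synthdata`) that
generates every input type with exact ground truth, and the entire pipeline
is validated as a parameter-recovery problem.  See `docs/methods.md` for the
models, parameter defaults, and design rationale.

## Worked example

`examples/photometry_diurnal_stats.py` builds a small synthetic cohort and
runs the full photometry analysis:

```
wild-type envelope (n=5): [-0.033, +0.031] ΔF/F0
      animal  peak ΔF/F0           class  t20 clock lead (min)  true lead
  reporter_0       0.200          strong      18.06         57         56
  reporter_1       0.200          strong      18.19         49         48
  reporter_2       0.201          strong      17.87         68         68
  dropping_0      -0.200        dropping          -          -          -
```

Each reporter's peak ΔF/F0 (mean over 8:30–9:30 p.m.) lies far above the
wild-type envelope, so all three are strong responders; their 20%-of-peak
crossings land at clock 17.9–18.2, i.e. 49–68 minutes *before* lights-off
(7 p.m.), within a few minutes of the generator's true crossing times — the
secretory rise anticipates the dark phase rather than reacting to it.  The
recording with a declining signal falls below the envelope and is classified
`dropping`, with no anticipation time defined.

The other examples follow the same pattern: `focus_projection_timelapse.py`
(focus-map recovery and the normalised intensity trace of a synthetic
explant movie), `luminometry_period.py` (periods of damped wells, all
estimated within 0.1 h and passing the 80% goodness gate), and
`junction_vesicles.py` (apical-skewed vesicle ratios and ~16-nm junction
widths).

A thin CLI wraps the same functions:
`chronoplex simulate|photometry|focus|rhythm|em|report` (see `--help`).

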