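"""Fiber-photometry preprocessing and diurnal statistics.

The pipeline for each recording is: median binning (10-min bins) →
stretched-exponential photobleach fit and subtraction (first-24-h analyses
only) → ΔF/F0 normalisation relative to the first hour → diurnal statistics:
the peak response over the 8:30–9:30 p.m. clock window, classification of
reporter recordings against the wild-type autofluorescence envelope, the
clock time at which strong responders first sustain 20% of their peak, the
resulting anticipation of lights-off in minutes, and per-24-h-cycle
modulation amplitudes for multi-day recordings.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .datatypes import BleachFit, DiurnalSummary, NormalizedTrace, PhotometryTrace, WTEnvelope

DELTA_STARTS = (0.3, 0.5, 0.7, 1.0)


def bin_median(trace: PhotometryTrace, bin_min: float = 10.0) -> PhotometryTrace:
    """Median-filter a raw trace into fixed-width bins.

    One output sample per bin, placed at the bin centre, holding the median
    of the raw samples falling in the bin; empty interior bins are linearly
    interpolated from their neighbours.
    """
    if trace.time_h.size == 0:
        raise ValueError("cannot bin an empty trace")
    if bin_min <= 0:
        raise ValueError("bin_min must be positive")
    bin_h = bin_min / 60.0
    n_bins = int(math.ceil((trace.time_h[-1] - trace.time_h[0] + 1e-12) / bin_h))
    n_bins = max(n_bins, 1)
    idx = np.minimum(((trace.time_h - trace.time_h[0]) / bin_h).astype(int), n_bins - 1)
    centers = trace.time_h[0] + (np.arange(n_bins) + 0.5) * bin_h

    med = np.full(n_bins, np.nan)
    order = np.argsort(idx, kind="stable")
    sorted_idx = idx[order]
    sorted_val = trace.value[order]
    starts = np.searchsorted(sorted_idx, np.arange(n_bins), side="left")
    ends = np.searchsorted(sorted_idx, np.arange(n_bins), side="right")
    for b in range(n_bins):
        if ends[b] > starts[b]:
            med[b] = np.median(sorted_val[starts[b]:ends[b]])
    filled = np.isfinite(med)
    if not filled.any():
        raise ValueError("all bins are empty")
    if not filled.all():
        med = np.interp(centers, centers[filled], med[filled])
    return PhotometryTrace(
        time_h=centers, value=med, animal_id=trace.animal_id, genotype=trace.genotype,
        light_schedule=trace.light_schedule, start_clock_h=trace.start_clock_h,
        lights_off_clock_h=trace.lights_off_clock_h,
    )


def _stretched_exp(t: np.ndarray, alpha: float, beta: float, gamma: float, delta: float) -> np.ndarray:
    return alpha + beta * np.exp(-gamma * np.power(np.maximum(t, 0.0), delta))


def fit_stretched_exponential(trace: PhotometryTrace, min_duration_h: float = 6.0) -> BleachFit:
    """Least-squares fit of the Kohlrausch photobleach model α+βe^(−γt^δ).

    Stretched exponentials are ill-conditioned in (γ, δ), so the fit is
    multi-started over a δ grid and the lowest-RSS solution is kept.
    """
    t, y = trace.time_h, trace.value
    if trace.duration_h < min_duration_h:
        raise ValueError(f"recording shorter than the {min_duration_h} h identifiability floor")
    if not np.all(np.isfinite(y)):
        raise ValueError("trace contains non-finite values")

    span = float(y.max() - y.min())
    alpha0 = float(y.min())
    beta0 = max(span, 1e-6 * max(abs(y).max(), 1.0))
    lb = [-np.inf, -np.inf, 1e-9, 1e-3]
    ub = [np.inf, np.inf, np.inf, 2.0]

    best: Optional[BleachFit] = None
    for delta0 in DELTA_STARTS:
        for gamma0 in (0.01, 0.1, 1.0):
            x0 = [alpha0, beta0, gamma0, delta0]
            try:
                res = least_squares(
                    lambda p: _stretched_exp(t, *p) - y, x0, bounds=(lb, ub),
                    method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
                )
            except Exception:
                continue
            if not np.all(np.isfinite(res.x)):
                continue
            rss = float(np.sum(res.fun**2))
            if best is None or rss < best.rss:
                best = BleachFit(*map(float, res.x), rss=rss, converged=bool(res.success))
    if best is None:
        return BleachFit(alpha=float(np.mean(y)), beta=0.0, gamma=1.0, delta=1.0,
                         rss=float(np.sum((y - y.mean()) ** 2)), converged=False)
    return best


def fit_bleach_light_anchored(trace: PhotometryTrace, margin_pre_h: float = 3.0,
                              margin_post_h: float = 3.0, min_points: int = 12) -> BleachFit:
    """Bleach fit anchored on light-phase samples away from the dark-phase transient.

    Reporter recordings carry a secretory transient that rises before
    lights-off, holds through the dark phase, and relaxes after lights-on; a
    least-squares bleach fit over the whole trace partially absorbs it.  The
    light schedule is known, so the fit here excludes the clock interval
    from ``margin_pre_h`` before lights-off to ``margin_post_h`` after the
    following lights-on (lights-on = lights-off + 12 h under 12:12) and
    extrapolates the Kohlrausch decay through the excluded window.  Falls
    back to the full-trace fit when fewer than ``min_points`` samples remain.
    """
    clock = trace.clock_h
    excl_start = (trace.lights_off_clock_h - margin_pre_h) % 24.0
    excl_len = margin_pre_h + 12.0 + margin_post_h
    rel = (clock - excl_start) % 24.0
    mask = rel >= excl_len
    if mask.sum() < min_points:
        return fit_stretched_exponential(trace)
    sub = PhotometryTrace(
        time_h=trace.time_h[mask], value=trace.value[mask], animal_id=trace.animal_id,
        genotype=trace.genotype, light_schedule=trace.light_schedule,
        start_clock_h=trace.start_clock_h, lights_off_clock_h=trace.lights_off_clock_h,
    )
    return fit_stretched_exponential(sub)


def correct_photobleach(trace: PhotometryTrace, fit: BleachFit) -> PhotometryTrace:
    """Subtract the fitted photobleach curve.

    Policy: applied only to first-24-h analysis windows; multi-day analyses
    skip the correction (the caller chooses, and ``compute_dff`` records the
    flag on its output).
    """
    if not fit.converged:
        raise ValueError("photobleach fit did not converge; refusing to correct")
    return trace.with_values(trace.value - fit.model(trace.time_h))


def compute_dff(corrected: PhotometryTrace, raw: PhotometryTrace, baseline_h: float = 1.0,
                corrected_flag: Optional[bool] = None) -> NormalizedTrace:
    """ΔF/F0 relative to the first ``baseline_h`` hours.

    F0 is the mean of the *raw* (pre-correction) signal over the baseline
    window; the numerator is the corrected trace re-centred on its own
    baseline-window mean, so the first hour of ΔF/F0 averages zero.
    """
    if corrected.time_h.shape != raw.time_h.shape or not np.allclose(corrected.time_h, raw.time_h):
        raise ValueError("corrected and raw traces must share a time grid")
    base = corrected.time_h <= corrected.time_h[0] + baseline_h
    if not base.any():
        raise ValueError("baseline window contains no samples")
    f0 = float(np.mean(raw.value[base]))
    if f0 <= 0:
        raise ValueError(f"baseline F0 = {f0:.4g} is not positive; corrupt baseline")
    dff = (corrected.value - float(np.mean(corrected.value[base]))) / f0
    if corrected_flag is None:
        corrected_flag = not np.array_equal(corrected.value, raw.value)
    return NormalizedTrace(
        time_h=corrected.time_h, dff=dff, f0=f0, corrected=corrected_flag,
        start_clock_h=corrected.start_clock_h, lights_off_clock_h=corrected.lights_off_clock_h,
        animal_id=corrected.animal_id, genotype=corrected.genotype,
    )


def _first_window_mask(norm: NormalizedTrace, window_clock_h: Tuple[float, float]) -> np.ndarray:
    """Samples in the first occurrence of the half-open clock window [lo, hi)."""
    lo, hi = window_clock_h
    t_lo = (lo - norm.start_clock_h) % 24.0
    width = (hi - lo) % 24.0
    return (norm.time_h >= t_lo) & (norm.time_h < t_lo + width)


def peak_response(norm: NormalizedTrace, window_clock_h: Tuple[float, float] = (20.5, 21.5)) -> float:
    """Mean ΔF/F0 over the (first) 8:30–9:30 p.m. clock window."""
    mask = _first_window_mask(norm, window_clock_h)
    if not mask.any():
        raise ValueError(f"trace does not cover the clock window {window_clock_h}")
    return float(np.mean(norm.dff[mask]))


def wt_envelope(wt_peaks: Sequence[float]) -> WTEnvelope:
    """Envelope spanned by the wild-type peak responses (pooled across experiments)."""
    peaks = np.asarray(list(wt_peaks), dtype=float)
    if peaks.size == 0:
        raise ValueError("need at least one wild-type peak response")
    return WTEnvelope(lo=float(peaks.min()), hi=float(peaks.max()), n_wt=int(peaks.size))


def classify_responders(reporter_peaks: Sequence[float], wt_env: WTEnvelope) -> List[str]:
    """Classify reporter peak responses against the wild-type envelope.

    Above the envelope → ``strong``; within (inclusive) → ``wild_type_like``;
    below → ``dropping``.  Boundary ties fall inside the envelope.
    """
    out = []
    for p in reporter_peaks:
        if p > wt_env.hi:
            out.append("strong")
        elif p < wt_env.lo:
            out.append("dropping")
        else:
            out.append("wild_type_like")
    return out


def time_to_fraction_of_peak(
    norm: NormalizedTrace,
    peak: float,
    fraction: float = 0.2,
    lights_off_clock_h: Optional[float] = None,
    sustained_bins: int = 3,
    window_clock_h: Tuple[float, float] = (20.5, 21.5),
) -> Tuple[Optional[float], Optional[float]]:
    """First sustained crossing of ``fraction * peak`` and its lead on lights-off.

    The crossing is *sustained*: ΔF/F0 must stay at or above the threshold
    for at least ``sustained_bins`` consecutive samples (guards against noise
    spikes; set ``sustained_bins=1`` for an instantaneous rule).  Returns
    ``(t_clock_h, anticipation_min)``; anticipation is positive when the
    crossing precedes lights-off.  Returns ``(None, None)`` when no crossing
    occurs before the end of the peak window.
    """
    if peak <= 0:
        raise ValueError("peak must be positive")
    if lights_off_clock_h is None:
        lights_off_clock_h = norm.lights_off_clock_h
    lo, hi = window_clock_h
    t_end = (lo - norm.start_clock_h) % 24.0 + (hi - lo) % 24.0
    search = norm.time_h < t_end
    thr = fraction * peak
    above = (norm.dff >= thr) & search
    run = 0
    for i in np.nonzero(search)[0]:
        run = run + 1 if above[i] else 0
        if run >= sustained_bins:
            j = i - sustained_bins + 1
            t_cross = float(norm.time_h[j])
            # refine to the sub-bin crossing point by linear interpolation
            if j > 0 and norm.dff[j - 1] < thr < norm.dff[j]:
                f = (thr - norm.dff[j - 1]) / (norm.dff[j] - norm.dff[j - 1])
                t_cross = float(norm.time_h[j - 1] + f * (norm.time_h[j] - norm.time_h[j - 1]))
            t_clock = (norm.start_clock_h + t_cross) % 24.0
            t_off = (lights_off_clock_h - norm.start_clock_h) % 24.0
            return t_clock, (t_off - t_cross) * 60.0
    return None, None


def daily_modulation_amplitude(norm: NormalizedTrace, p_lo: float = 5.0, p_hi: float = 95.0) -> List[float]:
    """Per-24-h-cycle modulation amplitude of a multi-day ΔF/F0 trace.

    Amplitude = 5th–95th inter-percentile range of ΔF/F0 within each complete
    24-h window from recording start (robust to residual bleach tails and
    single-bin spikes).  Multi-day traces should be normalised without bleach
    correction.  Returns an empty list for recordings shorter than 24 h.
    """
    out: List[float] = []
    t0 = norm.time_h[0]
    k = 0
    while True:
        mask = (norm.time_h >= t0 + 24.0 * k) & (norm.time_h < t0 + 24.0 * (k + 1))
        # require the window to be essentially complete
        if not mask.any() or norm.time_h[mask][-1] - (t0 + 24.0 * k) < 23.0:
            break
        vals = norm.dff[mask]
        out.append(float(np.percentile(vals, p_hi) - np.percentile(vals, p_lo)))
        k += 1
    return out


def summarize_recording(
    norm: NormalizedTrace,
    wt_env: Optional[WTEnvelope] = None,
    fraction: float = 0.2,
    window_clock_h: Tuple[float, float] = (20.5, 21.5),
    sustained_bins: int = 3,
) -> DiurnalSummary:
    """Full per-animal diurnal summary (peak, class, t20, anticipation, amplitudes)."""
    peak = peak_response(norm, window_clock_h)
    cls = classify_responders([peak], wt_env)[0] if wt_env is not None else None
    t20 = anticipation = None
    if cls == "strong" and peak > 0:
        t20, anticipation = time_to_fraction_of_peak(
            norm, peak, fraction=fraction, sustained_bins=sustained_bins, window_clock_h=window_clock_h
        )
    amps = daily_modulation_amplitude(norm) if norm.time_h[-1] - norm.time_h[0] >= 24.0 else []
    return DiurnalSummary(
        animal_id=norm.animal_id, peak_response=peak, responder_class=cls,
        t20_clock_h=t20, anticipation_min=anticipation, daily_amplitudes=amps,
    )


def preprocess(trace: PhotometryTrace, bin_min: float = 10.0, correct_bleach: bool = True,
               baseline_h: float = 1.0, anchor_light_phase: bool = True) -> NormalizedTrace:
    """Convenience composition: bin → (fit → correct) → ΔF/F0.

    The bleach fit defaults to light-phase-anchored mode
    (:func:`fit_bleach_light_anchored`) because reporter recordings carry a
    positive dark-phase transient that a whole-trace least-squares fit would
    partially absorb; pass ``anchor_light_phase=False`` for the plain fit.
    """
    binned = bin_median(trace, bin_min=bin_min)
    if correct_bleach:
        if anchor_light_phase:
            fit = fit_bleach_light_anchored(binned)
        else:
            fit = fit_stretched_exponential(binned)
        corrected = correct_photobleach(binned, fit)
    else:
        corrected = binned
    return compute_dff(corrected, binned, baseline_h=baseline_h, corrected_flag=correct_bleach)
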