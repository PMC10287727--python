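"""Diurnal statistics of CSF reporter photometry.

Builds a small synthetic cohort (strong responders whose signal rises before
lights-off, wild-type animals spanning the autofluorescence envelope, one
recording with a declining signal), preprocesses each trace (10-min median
bins, stretched-exponential photobleach correction, ΔF/F0 relative to the
first hour) and prints the peak response over the 8:30-9:30 p.m. window, the
responder class and, for strong responders, how many minutes before
lights-off (7 p.m.) the trace first sustains 20% of its peak.
"""

import numpy as np

from chronoplex import photometry as ph
from chronoplex import synthdata as sd

rng = np.random.default_rng(0)

wt_norm = [
    ph.preprocess(sd.gen_photometry(sd.PhotometrySimParams(
        signal_amplitude=float(a), noise_sd=0.01, seed=int(rng.integers(2**31))))[0])
    for a in sd.wildtype_modulation_amplitudes(5, rng)
]
env = ph.wt_envelope([ph.peak_response(n) for n in wt_norm])
print(f"wild-type envelope (n={env.n_wt}): [{env.lo:+.3f}, {env.hi:+.3f}] ΔF/F0")

recordings = []
for i in range(3):  # strong responders with known anticipation offsets
    offs = float(rng.normal(67.0, 15.0))
    tr, gt = sd.gen_photometry(sd.PhotometrySimParams(
        onset_offset_min=sd.onset_for_t20_offset(offs), noise_sd=0.01,
        seed=int(rng.integers(2**31))))
    recordings.append((f"reporter_{i}", tr, gt.anticipation_min))
tr, _ = sd.gen_dropping_photometry(sd.PhotometrySimParams(
    signal_amplitude=0.0, noise_sd=0.01, seed=int(rng.integers(2**31))), 0.3)
recordings.append(("dropping_0", tr, None))

print(f"{'animal':>12} {'peak ΔF/F0':>11} {'class':>15} {'t20 clock':>10} {'lead (min)':>10} {'true lead':>10}")
for name, tr, true_ant in recordings:
    summary = ph.summarize_recording(ph.preprocess(tr), env)
    t20 = f"{summary.t20_clock_h:.2f}" if summary.t20_clock_h is not None else "-"
    ant = f"{summary.anticipation_min:.0f}" if summary.anticipation_min is not None else "-"
    true = f"{true_ant:.0f}" if true_ant is not None else "-"
    print(f"{name:>12} {summary.peak_response:>11.3f} {summary.responder_class:>15} "
          f"{t20:>10} {ant:>10} {true:>10}")

print("\nA positive lead means the 20%-of-peak crossing precedes lights-off —")
print("the secretory rise anticipates the dark phase rather than reacting to it.")
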