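"""Circadian period of explant luminometry wells.

Generates damped bioluminescence rhythms (60-s bins, 10 per hour, 7 days)
at known periods, estimates each well's period with the chi-square
periodogram, applies the ≥80% goodness-of-fit inclusion gate, and
cross-checks rhythmicity with a 24-h cosinor fit.
"""

from chronoplex import rhythm as rh
from chronoplex import synthdata as sd

print(f"{'well':>6} {'true P (h)':>10} {'est P (h)':>10} {'Qp':>8} {'fit %':>6} {'kept':>5}")
for i, period in enumerate((23.5, 23.8, 24.5)):
    tr = sd.gen_luminometry(period, damping=0.1, noise_sd=10.0, duration_days=7,
                            seed=10 + i, well_id=f"A{i+1}")
    est = rh.chi_square_periodogram(tr)
    kept = "yes" if rh.passes_goodness_gate(est) else "no"
    print(f"{tr.well_id:>6} {period:>10.1f} {est.period_h:>10.1f} {est.qp:>8.0f} "
          f"{est.goodness_of_fit_pct:>6.1f} {kept:>5}")

tr = sd.gen_luminometry(23.8, damping=0.1, noise_sd=10.0, duration_days=7, seed=10)
amp, acro, p = rh.harmonic_rhythm_test(tr, period_h=24.0)
print(f"\ncosinor at 24 h: amplitude = {amp:.1f} counts, acrophase = {acro:.1f} h, p = {p:.2e}")
print("Estimated periods just under 24 h with near-100% goodness of fit mark")
print("wells with a healthy intrinsic clock; noisy or arrhythmic wells fall")
print("below the 80% gate and are excluded from period averages.")
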