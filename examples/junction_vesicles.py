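"""Peri-junctional vesicle localisation and tight-junction width from TEM annotations.

Generates annotated epithelial junctions (apical-to-basal membrane polyline,
vesicle positions with a known apical bias, 10 inter-membrane gap
measurements per junction), counts vesicles in the 2-μm peri-junctional
zone, summarises their apical-basal positions (1 = apical, 0 = basal), and
aggregates junction widths per animal.
"""

import numpy as np

from chronoplex import synthdata as sd
from chronoplex import ultrastructure as us

junctions = []
for a in range(3):
    for i in range(10):
        ann, _ = sd.gen_junction(sd.JunctionSimParams(
            n_vesicles=30, apical_bias=0.65, membrane_gap_um=0.016,
            seed=100 * a + i))
        ann.animal_id = f"mouse_{a}"
        junctions.append(ann)

all_ratios = []
for j in junctions[:3]:
    stats = us.vesicle_stats(j, zone_width_um=2.0)
    all_ratios.extend(stats.ratios)
    print(f"{j.image_id}: {stats.n_in_zone} vesicles in the 2-μm zone, "
          f"mean apical-basal ratio {stats.ratios.mean():.2f}")

ratios = np.concatenate([us.vesicle_stats(j).ratios for j in junctions])
print(f"\ncohort: {ratios.size} vesicles, mean ratio {ratios.mean():.3f} "
      f"(generator bias 0.65 — vesicles skew apical, consistent with "
      f"apical-directed transcytosis)")

widths = us.aggregate_junctions(junctions)
for animal, w in widths.items():
    print(f"{animal}: mean junction width {w * 1000:.1f} nm (10 junctions x 10 gaps)")
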