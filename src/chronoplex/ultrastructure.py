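"""Peri-junctional vesicle and tight-junction quantification from TEM annotations.

Inputs are calibrated point/polyline annotations (micrometres) of epithelial
junctions: the lateral membrane polyline from the apical to the basal
terminus, vesicle centre coordinates, and 10 inter-membrane distance
measurements per tight junction.  The module counts vesicles inside the
2-μm peri-junctional zone, localises each along the apical-basal axis as a
normalised arc-length ratio (1 = apical, 0 = basal), and averages membrane
gaps into per-junction and per-animal width estimates.

Geometry (point-to-polyline distance, arc-length projection) is delegated to
shapely; distances use exact point-to-segment projection, not vertex-only
distance.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Sequence

import numpy as np
from shapely.geometry import LineString, Point

from .datatypes import JunctionAnnotation, VesicleStats


def _polyline(j: JunctionAnnotation) -> LineString:
    return LineString(j.lateral_polyline)


def count_perijunctional_vesicles(j: JunctionAnnotation, zone_width_um: float = 2.0) -> int:
    """Number of vesicles within ``zone_width_um`` of the lateral membrane polyline."""
    if zone_width_um <= 0:
        raise ValueError("zone width must be positive")
    line = _polyline(j)
    return int(sum(line.distance(Point(v)) <= zone_width_um for v in j.vesicles))


def apical_basal_ratio(vesicle, j: JunctionAnnotation, zone_width_um: float = 2.0) -> float:
    """Normalised arc-length position of a vesicle along the junction.

    The vesicle is projected onto its nearest point on the polyline; the
    ratio is the arc length from the *basal* end to that point divided by the
    total arc length, so the apical terminus maps to exactly 1 and the basal
    terminus to exactly 0.
    """
    line = _polyline(j)
    pt = Point(np.asarray(vesicle, dtype=float))
    if line.distance(pt) > zone_width_um:
        raise ValueError("vesicle lies outside the peri-junctional zone")
    s_from_apical = line.project(pt)  # polyline is ordered apical -> basal
    return float(1.0 - s_from_apical / line.length)


def vesicle_stats(j: JunctionAnnotation, zone_width_um: float = 2.0) -> VesicleStats:
    """Zone count plus apical-basal ratios of all in-zone vesicles."""
    line = _polyline(j)
    ratios = [
        1.0 - line.project(Point(v)) / line.length
        for v in j.vesicles
        if line.distance(Point(v)) <= zone_width_um
    ]
    return VesicleStats(n_in_zone=len(ratios), ratios=np.asarray(ratios))


def junction_width(gap_measurements_um: Sequence[float]) -> float:
    """Junction width: arithmetic mean of the 10 inter-membrane distances."""
    gaps = np.asarray(list(gap_measurements_um), dtype=float)
    if gaps.size != 10:
        raise ValueError(f"expected exactly 10 gap measurements, got {gaps.size}")
    if not np.all(np.isfinite(gaps)) or np.any(gaps <= 0):
        raise ValueError("gap measurements must be finite and positive")
    return float(gaps.mean())


def aggregate_junctions(junctions: Iterable[JunctionAnnotation]) -> Dict[str, float]:
    """Per-animal mean junction width: the average of the per-junction averages."""
    per_animal: Dict[str, List[float]] = defaultdict(list)
    for j in junctions:
        per_animal[j.animal_id].append(junction_width(j.gap_measurements_um))
    return {animal: float(np.mean(widths)) for animal, widths in sorted(per_animal.items())}
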