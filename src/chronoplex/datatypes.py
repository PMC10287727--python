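"""Shared data containers for the diurnal choroid-plexus/CSF analysis pipeline.

All time axes are in hours since recording start.  Traces additionally carry
the wall-clock hour at which the recording started so that clock-referenced
windows (the 8:30–9:30 p.m. peak window, lights-off at 7 p.m.) can be mapped
onto recording time: ``clock_h = (start_clock_h + time_h) mod 24``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


@dataclass
class PhotometryTrace:
    """Single-channel fiber-photometry fluorescence trace.

    Parameters
    ----------
    time_h : array
        Sample times in hours since recording start, strictly increasing.
    value : array
        Fluorescence in arbitrary units.
    start_clock_h : float
        Wall-clock hour (0-24) of the first sample.
    lights_off_clock_h : float
        Clock hour of the dark-phase onset (default 19.0, i.e. 7 p.m.).
    genotype : str
        ``"reporter"`` or ``"wild_type"``.
    light_schedule : str
        ``"LD"`` (12:12 light-dark) or ``"DD"`` (constant darkness).
    """

    time_h: np.ndarray
    value: np.ndarray
    animal_id: str = "animal"
    genotype: str = "reporter"
    light_schedule: str = "LD"
    start_clock_h: float = 13.0
    lights_off_clock_h: float = 19.0

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_h.shape != self.value.shape:
            raise ValueError("time_h and value must have identical shapes")
        if self.time_h.size and np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time_h must be strictly increasing")

    @property
    def clock_h(self) -> np.ndarray:
        """Wall-clock hour of each sample."""
        return (self.start_clock_h + self.time_h) % 24.0

    @property
    def duration_h(self) -> float:
        return float(self.time_h[-1] - self.time_h[0]) if self.time_h.size else 0.0

    def with_values(self, value: np.ndarray) -> "PhotometryTrace":
        return replace(self, value=np.asarray(value, dtype=float))


@dataclass
class BleachFit:
    """Stretched-exponential photobleach model ``f(t) = alpha + beta*exp(-gamma*t**delta)``."""

    alpha: float
    beta: float
    gamma: float
    delta: float
    rss: float
    converged: bool

    def model(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.alpha + self.beta * np.exp(-self.gamma * np.power(np.maximum(t, 0.0), self.delta))


@dataclass
class NormalizedTrace:
    """Baseline-normalized trace: dff(t) = (F(t) - <F>_first_hour) / F0."""

    time_h: np.ndarray
    dff: np.ndarray
    f0: float
    corrected: bool
    start_clock_h: float = 13.0
    lights_off_clock_h: float = 19.0
    animal_id: str = "animal"
    genotype: str = "reporter"

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)

    @property
    def clock_h(self) -> np.ndarray:
        return (self.start_clock_h + self.time_h) % 24.0


@dataclass
class WTEnvelope:
    """Range of wild-type peak responses used to classify reporter recordings."""

    lo: float
    hi: float
    n_wt: int

    def __post_init__(self) -> None:
        if self.n_wt < 1:
            raise ValueError("wild-type envelope requires at least one recording")
        if self.lo > self.hi:
            raise ValueError("envelope lo must not exceed hi")


@dataclass
class DiurnalSummary:
    """Per-animal diurnal statistics around the first lights-off transition."""

    animal_id: str
    peak_response: float
    responder_class: Optional[str] = None  # strong | wild_type_like | dropping
    t20_clock_h: Optional[float] = None
    anticipation_min: Optional[float] = None
    daily_amplitudes: list = field(default_factory=list)


@dataclass
class LuminometryTrace:
    """Bioluminescence counts in 60-s bins acquired 10 times per hour."""

    time_h: np.ndarray
    counts: np.ndarray
    well_id: str = "well"

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)


@dataclass
class PeriodEstimate:
    """Result of a chi-square periodogram scan."""

    period_h: float
    qp: float
    p_value: float
    goodness_of_fit_pct: float
    significant: bool
    periods_h: Optional[np.ndarray] = None
    qp_values: Optional[np.ndarray] = None
    critical_values: Optional[np.ndarray] = None


@dataclass
class VolumetricTimelapse:
    """4-D intensity array ordered (t, z, y, x)."""

    data: np.ndarray
    frame_interval_min: float = 30.0
    pixel_um: float = 1.0
    n_repeats_averaged: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("timelapse data must be 4-D (t, z, y, x)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("timelapse contains non-finite intensities")

    @property
    def shape(self):
        return self.data.shape

    @property
    def time_h(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) * self.frame_interval_min / 60.0


@dataclass
class FocusIndexMap:
    """Per-pixel in-focus z index (fractional after smoothing)."""

    index: np.ndarray
    raw_index: np.ndarray

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=float)
        self.raw_index = np.asarray(self.raw_index)


@dataclass
class RigidTransform:
    dy: float
    dx: float
    theta_deg: float


@dataclass
class RegistrationChain:
    """Per-frame transforms mapping each frame onto the mean-frame reference."""

    rigid: list = field(default_factory=list)          # RigidTransform per frame
    affine: list = field(default_factory=list)         # 3x3 matrices per frame
    displacement: list = field(default_factory=list)   # (2, Y, X) fields per frame
    reference: str = "mean_frame"


@dataclass
class ExplantTrace:
    """Normalized mean-intensity trace extracted from a registered explant movie."""

    time_h: np.ndarray
    mean_norm_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.mean_norm_intensity = np.asarray(self.mean_norm_intensity, dtype=float)


@dataclass
class JunctionAnnotation:
    """Annotated epithelial junction from a TEM image, coordinates in micrometres.

    The lateral membrane polyline is ordered from the apical to the basal
    terminus; vesicle positions are 2-D points; ``gap_measurements_um`` holds
    the 10 inter-membrane distances used for the junction-width estimate.
    """

    apical_point: tuple
    basal_point: tuple
    lateral_polyline: np.ndarray
    vesicles: np.ndarray
    gap_measurements_um: np.ndarray = field(default_factory=lambda: np.array([]))
    image_id: str = "image"
    animal_id: str = "animal"

    def __post_init__(self) -> None:
        self.lateral_polyline = np.asarray(self.lateral_polyline, dtype=float).reshape(-1, 2)
        self.vesicles = np.asarray(self.vesicles, dtype=float).reshape(-1, 2)
        self.gap_measurements_um = np.asarray(self.gap_measurements_um, dtype=float)
        if self.lateral_polyline.shape[0] < 2:
            raise ValueError("lateral polyline needs at least two vertices")
        if not np.allclose(self.lateral_polyline[0], self.apical_point):
            raise ValueError("polyline must start at the apical point")
        if not np.allclose(self.lateral_polyline[-1], self.basal_point):
            raise ValueError("polyline must end at the basal point")
        seg = np.diff(self.lateral_polyline, axis=0)
        if not np.hypot(seg[:, 0], seg[:, 1]).sum() > 0:
            raise ValueError("polyline arc length must be positive")


@dataclass
class VesicleStats:
    n_in_zone: int
    ratios: np.ndarray

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.n_in_zone != self.ratios.size:
            raise ValueError("n_in_zone must equal the number of ratios")
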