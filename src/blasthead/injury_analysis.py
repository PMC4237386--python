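"""Response metrics and injury-severity classification for gauge traces.

Two printed criteria drive the classification:

* the Ward intracranial-pressure contusion index — peak ICP below
  173 kPa: minor or no injury; 173-235 kPa: minor contusion or cortex
  hemorrhage; above 235 kPa: serious cerebral contusion;
* the Zhang von Mises axonal thresholds — 6.0 / 7.8 / 10.0 kPa for
  25% / 50% / 80% probability of mild TBI.

Alongside the plain peak, the peak-to-peak pressure excursion within a
1 ms window is extracted (the largest positive-to-negative swing whose
extremes both fall inside one window), since the sharp compression-to-
tension transition is itself a candidate damage mechanism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from blasthead.gauges import GaugeTrace

__all__ = [
    "GaugeMetrics",
    "SeverityLabel",
    "AxonalRiskBand",
    "peak_metrics",
    "ward_classify",
    "zhang_axonal_classify",
    "attenuation_percent",
    "WARD_MINOR_KPA",
    "WARD_SERIOUS_KPA",
    "ZHANG_THRESHOLDS_KPA",
]

WARD_MINOR_KPA = 173.0
WARD_SERIOUS_KPA = 235.0
ZHANG_THRESHOLDS_KPA = (6.0, 7.8, 10.0)  # 25%, 50%, 80% probability


class SeverityLabel(IntEnum):
    """Ordered contusion severity from the ICP criterion."""

    NO_OR_MINOR_INJURY = 0
    MINOR_CONTUSION_OR_CORTEX_HEMORRHAGE = 1
    SERIOUS_CONTUSION = 2


class AxonalRiskBand(IntEnum):
    """Ordered mild-TBI probability band from the von Mises criterion."""

    BELOW_25PCT = 0
    P25_TO_50PCT = 1
    P50_TO_80PCT = 2
    ABOVE_80PCT = 3


@dataclass(frozen=True)
class GaugeMetrics:
    """Scalar response metrics extracted from one gauge trace."""

    label: str
    peak_positive: float  # Pa
    peak_negative: float  # Pa (signed minimum)
    peak_to_peak_1ms: float  # Pa
    time_of_peak: float  # s
    peak_von_mises: float | None = None  # Pa


def peak_metrics(trace: GaugeTrace, window: float = 1.0e-3) -> GaugeMetrics:
    """Extract peak and windowed peak-to-peak metrics from a trace.

    ``peak_to_peak_1ms`` is the maximum over all contiguous windows of
    length at most ``window`` of (window max - window min): both
    extremes must fall inside a single window.  The trace baseline is
    the meta ``ambient_pa`` if present (absolute traces), else zero.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    dt = trace.dt
    if window < 2.0 * dt:
        raise ValueError("window must cover at least two sampling intervals")
    p = trace.pressure - float(trace.meta.get("ambient_pa", 0.0))
    # +1e-9 guards the floor against dt round-off from uniform grids
    w = min(int(math.floor(window / dt + 1e-9)) + 1, p.size)
    wins = sliding_window_view(p, w)
    p2p = float(np.max(wins.max(axis=1) - wins.min(axis=1)))
    i_pk = int(np.argmax(p))
    vm = float(np.max(trace.von_mises)) if trace.von_mises is not None else None
    return GaugeMetrics(
        label=trace.label,
        peak_positive=float(p[i_pk]),
        peak_negative=float(np.min(p)),
        peak_to_peak_1ms=p2p,
        time_of_peak=float(trace.time[i_pk]),
        peak_von_mises=vm,
    )


def _check_level(value: float, what: str) -> float:
    v = float(value)
    if math.isnan(v) or v < 0:
        raise ValueError(f"{what} must be finite and non-negative, got {value!r}")
    return v


def ward_classify(peak_positive: float, unit: str = "kPa") -> SeverityLabel:
    """Contusion severity from peak positive intracranial pressure.

    Thresholds 173 and 235 kPa; both boundary values fall in the middle
    band (the criterion reads "below 173" and "more than 235").  Meant
    for brain gauges only — the index was stated for cerebral contusion
    and does not transfer to the spinal cord.
    """
    v = _check_level(peak_positive, "peak pressure")
    kpa = v / 1000.0 if unit.lower() == "pa" else v
    if kpa < WARD_MINOR_KPA:
        return SeverityLabel.NO_OR_MINOR_INJURY
    if kpa <= WARD_SERIOUS_KPA:
        return SeverityLabel.MINOR_CONTUSION_OR_CORTEX_HEMORRHAGE
    return SeverityLabel.SERIOUS_CONTUSION


def zhang_axonal_classify(peak_von_mises: float, unit: str = "kPa") -> AxonalRiskBand:
    """Mild-TBI probability band from peak von Mises stress.

    Threshold values (6.0, 7.8, 10.0 kPa) are tolerances, so each enters
    the higher band.
    """
    v = _check_level(peak_von_mises, "peak von Mises stress")
    kpa = v / 1000.0 if unit.lower() == "pa" else v
    t25, t50, t80 = ZHANG_THRESHOLDS_KPA
    if kpa < t25:
        return AxonalRiskBand.BELOW_25PCT
    if kpa < t50:
        return AxonalRiskBand.P25_TO_50PCT
    if kpa < t80:
        return AxonalRiskBand.P50_TO_80PCT
    return AxonalRiskBand.ABOVE_80PCT


def attenuation_percent(proximal_peak: float, distal_peak: float) -> int:
    """Proximal-to-distal attenuation, rounded to the nearest percent.

    ``100 * (1 - distal/proximal)``; e.g. 201 kPa -> 138 kPa gives 31%.
    """
    if not (proximal_peak > 0) or math.isnan(distal_peak):
        raise ValueError("proximal peak must be positive and both peaks finite")
    return int(round(attenuation_fraction(proximal_peak, distal_peak) * 100.0))


def attenuation_fraction(proximal_peak: float, distal_peak: float) -> float:
    """Full-precision attenuation fraction ``1 - distal/proximal``."""
    if not (proximal_peak > 0):
        raise ValueError("proximal peak must be positive")
    return 1.0 - distal_peak / proximal_peak
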