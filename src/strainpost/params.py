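"""Peak systolic strain, GLS, and derived strain rate.

Peak systolic strain is the strain extremum that characterises systolic
shortening of one segment.  Two selection rules coexist in practice and
can disagree on pathological curves:

``window_min``
    the most negative sample between the first QRS onset and aortic valve
    closure (AVC) — even when the curve is exclusively positive, in which
    case the least positive sample is returned.

``echopac_75``
    the rule applied by GE's EchoPAC: with N the most negative and P the
    most positive sample in the same window, the positive peak P is
    selected when it exceeds 75 % of |N|; otherwise N is selected.  A
    window with no negative samples yields P.

The rules diverge exactly on curves with a prominent positive systolic
peak, the signature of left-bundle-branch-block-type dyssynchrony (early
systolic stretch of basal segments, erratic septal motion after the septal
flash).

Global Longitudinal Strain (GLS) is the arithmetic mean of the 18
segmental peak values of the left ventricle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import TraceDataError, UsageError
from .io import Quantity, SegmentModel, StrainTrace
from .phases import EventTiming


class PeakRule(str, Enum):
    WINDOW_MIN = "window_min"  # most negative sample in [QRS1, AVC]
    ECHOPAC_75 = "echopac_75"  # positive peak if it exceeds 75% of |negative peak|


#: fraction of |negative peak| the positive peak must exceed under ECHOPAC_75
POSITIVE_PEAK_FRACTION = 0.75

#: more than this many excluded segments flags the study's GLS as unreliable
MAX_EXCLUDED_SEGMENTS = 2


@dataclass(frozen=True)
class SegmentPeak:
    """Peak systolic strain of one segment."""

    segment: str
    value: float  # strain, %
    time: float  # ms
    rule: PeakRule


@dataclass(frozen=True)
class GlsResult:
    """Per-segment peaks and their arithmetic mean."""

    peaks: list[SegmentPeak]
    gls: float  # %
    rule: PeakRule
    n_segments: int
    excluded: tuple[str, ...] = ()
    qc_flag: bool = False  #: True when more than MAX_EXCLUDED_SEGMENTS were dropped
    phased: bool = True  #: False when peaks were taken over the whole trace

    def format_report(self) -> str:
        """Stable ``key: value`` terminal report."""
        lines = [f"rule: {self.rule.value}"]
        if not self.phased:
            lines.append("window: unphased (whole trace; no ECG / valve events)")
        for p in self.peaks:
            lines.append(f"peak[{p.segment}]: {p.value:.2f} % @ {p.time:.0f} ms")
        lines.append(f"n_segments: {self.n_segments}")
        if self.excluded:
            lines.append(f"excluded: {', '.join(self.excluded)}")
        if self.qc_flag:
            lines.append("qc_flag: more than 2 segments excluded")
        lines.append(f"GLS: {self.gls:.2f} %")
        return "\n".join(lines)


def _systolic_window(
    time: np.ndarray, events: EventTiming | None
) -> tuple[int, int]:
    """Index range (inclusive) of the peak-search window.

    With events, the window spans QRS onset to AVC, the sample nearest each
    boundary included; without events (unphased mode) it is the whole trace.
    """
    if events is None:
        return 0, time.size - 1
    i0 = int(np.argmin(np.abs(time - events.qrs1)))
    i1 = int(np.argmin(np.abs(time - events.avc)))
    if i1 <= i0:
        raise TraceDataError(
            f"systolic window [{events.qrs1:g}, {events.avc:g}] ms contains "
            "fewer than two samples"
        )
    return i0, i1


def peak_window_min(
    time: np.ndarray,
    curve: np.ndarray,
    events: EventTiming | None,
    segment: str = "",
) -> SegmentPeak:
    """Peak systolic strain as the window minimum (most negative sample).

    Ties are broken by the earliest time.  On exclusively positive curves
    the least positive sample is returned — the rule never switches sign.
    """
    time = np.asarray(time, dtype=float)
    curve = np.asarray(curve, dtype=float)
    i0, i1 = _systolic_window(time, events)
    window = curve[i0 : i1 + 1]
    k = int(np.argmin(window))  # argmin takes the first occurrence: earliest tie
    return SegmentPeak(
        segment=segment,
        value=float(window[k]),
        time=float(time[i0 + k]),
        rule=PeakRule.WINDOW_MIN,
    )


def peak_echopac(
    time: np.ndarray,
    curve: np.ndarray,
    events: EventTiming | None,
    segment: str = "",
) -> SegmentPeak:
    """Peak systolic strain under the EchoPAC 75 % positive-peak rule."""
    time = np.asarray(time, dtype=float)
    curve = np.asarray(curve, dtype=float)
    i0, i1 = _systolic_window(time, events)
    window = curve[i0 : i1 + 1]
    kn = int(np.argmin(window))
    kp = int(np.argmax(window))
    n_val, p_val = float(window[kn]), float(window[kp])
    if n_val >= 0:  # no negative samples in the window
        k = kp
    elif p_val > POSITIVE_PEAK_FRACTION * abs(n_val):
        k = kp
    else:
        k = kn
    return SegmentPeak(
        segment=segment,
        value=float(window[k]),
        time=float(time[i0 + k]),
        rule=PeakRule.ECHOPAC_75,
    )


_PEAK_FUNCS = {
    PeakRule.WINDOW_MIN: peak_window_min,
    PeakRule.ECHOPAC_75: peak_echopac,
}


def segment_peak(
    time: np.ndarray,
    curve: np.ndarray,
    events: EventTiming | None,
    rule: PeakRule | str = PeakRule.WINDOW_MIN,
    segment: str = "",
) -> SegmentPeak:
    """Dispatch to the requested peak-selection rule."""
    return _PEAK_FUNCS[PeakRule(rule)](time, curve, events, segment)


def compute_gls(
    trace: StrainTrace,
    events: EventTiming | None,
    rule: PeakRule | str = PeakRule.WINDOW_MIN,
    exclude: tuple[str, ...] = (),
) -> GlsResult:
    """Global Longitudinal Strain of an 18-segment LV strain trace.

    Parameters
    ----------
    trace
        Merged 18-segment LV strain trace (``segment_model == AHA18``).
    events
        Valve events / ECG landmarks defining the systolic window; ``None``
        computes *unphased* peaks over the whole trace (for simulated
        inputs shipped without an ECG).
    rule
        Peak-selection rule applied to every segment.
    exclude
        Segment labels to drop (inadequate tracking).  Excluding more than
        two segments sets the quality-control flag on the result.

    Raises
    ------
    UsageError
        If the trace is not an 18-segment strain trace, or an excluded
        label is not among its segments.
    """
    rule = PeakRule(rule)
    if trace.segment_model is not SegmentModel.AHA18:
        raise UsageError("GLS is defined on the 18-segment LV model")
    if trace.quantity is not Quantity.STRAIN:
        raise UsageError("GLS is computed from strain, not strain-rate, curves")
    unknown = [s for s in exclude if s not in trace.segments]
    if unknown:
        raise UsageError(f"excluded labels not in trace: {', '.join(sorted(unknown))}")
    used = [s for s in trace.labels if s not in exclude]
    if not used:
        raise UsageError("all segments excluded")
    qc = len(exclude) > MAX_EXCLUDED_SEGMENTS
    if qc:
        warnings.warn(
            f"{len(exclude)} segments excluded (> {MAX_EXCLUDED_SEGMENTS}): "
            "GLS flagged as unreliable",
            stacklevel=2,
        )
    peaks = [
        segment_peak(trace.time, trace.segments[s], events, rule, segment=s)
        for s in used
    ]
    return GlsResult(
        peaks=peaks,
        gls=float(np.mean([p.value for p in peaks])),
        rule=rule,
        n_segments=len(used),
        excluded=tuple(exclude),
        qc_flag=qc,
        phased=events is not None,
    )


def strain_rate_from_strain(trace: StrainTrace) -> StrainTrace:
    """Differentiate strain curves to strain rate.

    Central divided differences on the (possibly non-uniform) time grid,
    one-sided at the ends; strain is converted from % to fractional and
    time from ms to s, so the result is in 1/s.  No smoothing is applied.
    """
    if trace.quantity is not Quantity.STRAIN:
        raise UsageError("input trace must hold strain, not strain rate")
    if trace.n_samples < 3:
        raise TraceDataError("need at least 3 samples to differentiate")
    t_s = trace.time / 1000.0
    rates = {
        label: np.gradient(values / 100.0, t_s)
        for label, values in trace.segments.items()
    }
    return StrainTrace(
        time=trace.time,
        segments=rates,
        chamber=trace.chamber,
        view=trace.view,
        quantity=Quantity.STRAIN_RATE,
        segment_model=trace.segment_model,
    )
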