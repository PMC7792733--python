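"""Synthetic phase-structured strain cycles and paired GLS sets.

Real strain traces come out of proprietary speckle-tracking software; to
exercise every stage of the pipeline without clinical exports, this module
builds curves whose ground truth is known by construction:

* :func:`generate_strain_cycle` produces per-segment longitudinal strain
  of one cardiac cycle — zero at the first QRS onset, an optional positive
  early-systolic bulge (the "stretch" pattern of left-bundle-branch-block
  dyssynchrony), monotone descent to a prescribed peak inside the ejection
  phase, recovery through isovolumic relaxation and early filling, a small
  atrial-contraction deflection, and return to ≈ 0 at the second QRS —
  plus a schematic ECG with impulse-like QRS complexes and a P-wave bump.
* :func:`generate_paired_gls` draws paired measurement series with a
  prescribed systematic bias and within-pair spread, the ground truth for
  the agreement battery.

Curves are chains of cosine-eased (half-cosine) segments joined at the
phase boundaries: smooth, monotone between nodes, and with extrema exactly
at the nodes, so the prescribed peak *is* the sample-grid minimum whenever
the noise is off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UsageError
from .io import (
    Chamber,
    EcgTrace,
    Quantity,
    SegmentModel,
    StrainTrace,
    View,
    aha18_labels,
)
from .phases import EventTiming

#: a plausible resting-heart-rate cycle used as the default event set:
#: RR 850 ms, EMC 30 ms, IVC 50 ms, ejection 300 ms, IVR 80 ms,
#: early filling 240 ms, atrial phase 150 ms
DEFAULT_EVENTS = EventTiming(
    qrs1=0.0, mvc=30.0, avo=80.0, avc=380.0, mvo=460.0, p_onset=700.0, qrs2=850.0
)

#: healthy-range segmental peak strains (%), mildly heterogeneous across
#: the 18 LV segments
DEFAULT_PEAKS = tuple(-22.0 + 1.5 * np.cos(2 * np.pi * k / 18) for k in range(18))


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Ground-truth description of one synthetic strain study.

    Parameters
    ----------
    events
        Valve events and ECG landmarks of the simulated cycle, ms.
    peaks
        Target peak systolic strain per segment, % (18 values for an LV
        study, 6 for a single-view chamber).
    early_stretch
        Amplitude (%) of a positive bulge during EMC/IVC, peaking at
        aortic valve opening — 0 disables it; positive values emulate the
        dyssynchronous early-stretch morphology.
    post_systolic_offset
        Amount (%) by which the curve has already recovered at aortic
        valve closure relative to the peak (0 keeps the peak held until
        AVC).
    noise_sd
        SD of additive white Gaussian noise, %.
    sample_interval
        Sampling step, ms (speckle-tracking frame rates of 50-90 Hz
        correspond to 11-20 ms).
    seed
        Seed for the noise generator; equal seeds give identical traces.
    """

    events: EventTiming = DEFAULT_EVENTS
    peaks: tuple[float, ...] = DEFAULT_PEAKS
    early_stretch: float = 0.0
    post_systolic_offset: float = 0.0
    noise_sd: float = 0.0
    sample_interval: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise UsageError("sample_interval must be positive")
        if self.noise_sd < 0:
            raise UsageError("noise_sd must be non-negative")
        if not all(np.isfinite(self.peaks)):
            raise UsageError("target peaks must be finite")
        if len(self.peaks) not in (6, 18):
            raise UsageError("peaks must list 6 or 18 segments")
        if self.early_stretch < 0:
            raise UsageError("early_stretch must be non-negative")
        if self.post_systolic_offset < 0:
            raise UsageError(
                "post_systolic_offset must be non-negative (the curve cannot "
                "undershoot its target peak at aortic valve closure)"
            )
        if self.early_stretch > 0 and any(p >= 0 for p in self.peaks):
            raise UsageError(
                "positive target peaks cannot be combined with an early "
                "stretch bulge; the bulge would not dominate the curve"
            )


def _cosine_chain(t: np.ndarray, nodes: list[tuple[float, float]]) -> np.ndarray:
    """Evaluate a chain of cosine-eased segments through ``nodes`` at ``t``."""
    out = np.empty_like(t)
    times = [p[0] for p in nodes]
    values = [p[1] for p in nodes]
    out[t <= times[0]] = values[0]
    out[t >= times[-1]] = values[-1]
    for (t0, v0), (t1, v1) in zip(nodes[:-1], nodes[1:]):
        mask = (t >= t0) & (t < t1)
        if t1 > t0:
            u = (t[mask] - t0) / (t1 - t0)
            out[mask] = v0 + (v1 - v0) * (1 - np.cos(np.pi * u)) / 2
    return out


def _snap(t_target: float, grid: np.ndarray) -> float:
    return float(grid[np.argmin(np.abs(grid - t_target))])


def _segment_nodes(
    spec: SyntheticStudySpec, peak: float, grid: np.ndarray
) -> list[tuple[float, float]]:
    e = spec.events
    # the peak node is snapped onto the sample grid so the prescribed value
    # is exactly attained by a sample
    t_peak = _snap(e.avo + 0.75 * (e.avc - e.avo), grid)
    t_mid_a = _snap((e.p_onset + e.qrs2) / 2, grid)
    nodes = [(e.qrs1, 0.0)]
    if spec.early_stretch > 0:
        nodes.append((e.avo, spec.early_stretch))
    nodes += [
        (t_peak, peak),
        (e.avc, peak + spec.post_systolic_offset),
        (e.mvo, peak * 0.55),
        (e.p_onset, peak * 0.10),
        (t_mid_a, peak * 0.16),  # small atrial-contraction deflection
        (e.qrs2, 0.0),
    ]
    return nodes


def _synthetic_ecg(t: np.ndarray, events: EventTiming) -> np.ndarray:
    """Schematic ECG: narrow QRS impulses at both QRS onsets, a broad P bump."""
    ecg = np.zeros_like(t)

    def add(center: float, width: float, amp: float) -> None:
        mask = np.abs(t - center) < width
        ecg[mask] += amp * np.cos(np.pi * (t[mask] - center) / (2 * width)) ** 2

    for t_qrs in (events.qrs1, events.qrs2):
        add(t_qrs, 15.0, 1.0)
    add(events.p_onset + 40.0, 40.0, 0.25)
    return ecg


def generate_strain_cycle(
    spec: SyntheticStudySpec,
    chamber: Chamber = Chamber.LV,
    view: View = View.NONE,
) -> tuple[StrainTrace, EcgTrace, EventTiming]:
    """Build one synthetic strain study with known per-segment peaks.

    Returns the strain trace, a co-registered schematic ECG, and the event
    set used (identical to ``spec.events``).  With ``noise_sd = 0`` the
    most negative sample of every segment between the first QRS onset and
    aortic valve closure equals the prescribed target peak exactly.
    """
    e = spec.events
    n = int(np.floor((e.qrs2 - e.qrs1) / spec.sample_interval)) + 1
    t = e.qrs1 + spec.sample_interval * np.arange(n)
    rng = np.random.default_rng(spec.seed)

    if len(spec.peaks) == 18:
        labels = aha18_labels()
        model = SegmentModel.AHA18
    else:
        labels = [f"{level}_{wall}" for wall in ("free_wall", "septal") for level in ("basal", "mid", "apical")]
        model = SegmentModel.SIX

    segments: dict[str, np.ndarray] = {}
    for label, peak in zip(labels, spec.peaks):
        curve = _cosine_chain(t, _segment_nodes(spec, peak, t))
        if spec.noise_sd > 0:
            curve = curve + rng.normal(0.0, spec.noise_sd, size=t.size)
        segments[label] = curve

    trace = StrainTrace(
        time=t,
        segments=segments,
        chamber=chamber,
        view=view,
        quantity=Quantity.STRAIN,
        segment_model=model,
    )
    ecg = EcgTrace(time=t, amplitude=_synthetic_ecg(t, e), source_view=View.A4C)
    return trace, ecg, e


def generate_view_traces(
    spec: SyntheticStudySpec,
) -> tuple[dict[View, StrainTrace], EcgTrace]:
    """Split one 18-segment synthetic study into three per-view 6-segment
    traces (the shape of real per-view exports), sharing the event set.

    The views are generated on the same beat, so :func:`~strainpost.io.align_views`
    reassembles them without time rescaling.
    """
    if len(spec.peaks) != 18:
        raise UsageError("per-view export needs an 18-segment spec")
    full, ecg, _ = generate_strain_cycle(spec)
    out: dict[View, StrainTrace] = {}
    for view in (View.A4C, View.A3C, View.A2C):
        labels = aha18_labels(view)
        out[view] = StrainTrace(
            time=full.time,
            segments={lab: full.segments[lab] for lab in labels},
            chamber=Chamber.LV,
            view=view,
            quantity=Quantity.STRAIN,
            segment_model=SegmentModel.SIX,
        )
    return out, ecg


def generate_paired_gls(
    n: int,
    mu: float = -15.0,
    spread: float = 5.0,
    bias: float = 0.0,
    sd_diff: float = 0.5,
    seed: int = 0,
) -> "PairedMeasurements":
    """Draw paired GLS-like measurements with known bias and spread.

    ``a_i ~ Normal(mu, spread)`` is the reference method;
    ``b_i = a_i − bias + Normal(0, sd_diff)`` the candidate, so the
    expected Bland-Altman bias of a − b is exactly ``bias`` and the
    expected dispersion 1.96·``sd_diff``.
    """
    from .io import PairedMeasurements

    if n < 3:
        raise UsageError("need n >= 3 pairs")
    if spread < 0 or sd_diff < 0:
        raise UsageError("spread and sd_diff must be non-negative")
    rng = np.random.default_rng(seed)
    a = mu + spread * rng.standard_normal(n)
    b = a - bias + sd_diff * rng.standard_normal(n)
    labels = [f"S{i + 1:04d}" for i in range(n)]
    return PairedMeasurements(
        labels=labels, a=a, b=b, name_a="reference", name_b="candidate"
    )
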