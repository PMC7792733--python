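"""Figure rendering: multi-panel curve displays, Q-Q, equality-line and
Bland-Altman plots.

All functions draw onto matplotlib axes/figures and return the figure so
callers can save or embed it.  Segment colors use a fixed 18-color palette
(tab20 minus the two grays) so re-runs are visually identical.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .agreement import AgreementReport, QQData, bland_altman_points
from .io import EcgTrace, PairedMeasurements, StrainTrace
from .phases import EventTiming

#: valve events drawn as labeled vertical markers on curve panels
_MARKED_EVENTS = ("mvc", "avo", "avc", "mvo")

_PALETTE = [c for i, c in enumerate(plt.get_cmap("tab20").colors) if i not in (14, 15)]


def _draw_event_markers(ax, events: EventTiming) -> None:
    for name in _MARKED_EVENTS:
        t = getattr(events, name)
        ax.axvline(t, color="0.35", lw=0.8, ls="--")
        ax.text(
            t, 1.01, name.upper(), transform=ax.get_xaxis_transform(),
            ha="center", va="bottom", fontsize=7, color="0.25",
        )


def plot_trace_panel(ax, trace: StrainTrace, events: EventTiming | None = None) -> None:
    """One panel of segment curves with optional valve-event markers."""
    for i, (label, values) in enumerate(trace.segments.items()):
        ax.plot(trace.time, values, lw=1.0, color=_PALETTE[i % len(_PALETTE)], label=label)
    unit = "%" if trace.quantity.value == "strain" else "1/s"
    ax.set_ylabel(f"{trace.chamber.value} {trace.quantity.value} ({unit})")
    ax.axhline(0, color="0.8", lw=0.6)
    if events is not None:
        _draw_event_markers(ax, events)


def plot_study(
    panels: list[StrainTrace],
    ecg: EcgTrace | None,
    events: EventTiming | None,
    title: str = "",
):
    """Stacked display of curve panels plus, when present, the ECG."""
    n = len(panels) + (1 if ecg is not None else 0)
    fig, axes = plt.subplots(n, 1, sharex=True, figsize=(9, 2.6 * n), squeeze=False)
    axes = axes.ravel()
    for ax, trace in zip(axes, panels):
        plot_trace_panel(ax, trace, events)
    if ecg is not None:
        ax = axes[-1]
        ax.plot(ecg.time, ecg.amplitude, color="k", lw=0.9)
        ax.set_ylabel("ECG (a.u.)")
        if events is not None:
            _draw_event_markers(ax, events)
    axes[-1].set_xlabel("time (ms)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def plot_qq(qq: QQData, title: str = "Normal Q-Q plot"):
    """Q-Q plot with the quartile-anchored reference line in red."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(qq.theoretical, qq.ordered, "o", ms=4, mfc="none", color="k")
    xs = np.array([qq.theoretical[0], qq.theoretical[-1]])
    ax.plot(xs, qq.intercept + qq.slope * xs, color="red", lw=1.2)
    ax.set_xlabel("theoretical quantiles")
    ax.set_ylabel("sample quantiles")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_equality(pairs: PairedMeasurements):
    """Paired measurements against the line of equality."""
    fig, ax = plt.subplots(figsize=(4.8, 4.8))
    ax.plot(pairs.a, pairs.b, "o", ms=4, mfc="none", color="k")
    lo = min(pairs.a.min(), pairs.b.min())
    hi = max(pairs.a.max(), pairs.b.max())
    pad = 0.05 * (hi - lo if hi > lo else 1.0)
    ax.plot([lo - pad, hi + pad], [lo - pad, hi + pad], color="red", lw=1.0)
    ax.set_xlabel(f"{pairs.name_a} GLS (%)")
    ax.set_ylabel(f"{pairs.name_b} GLS (%)")
    ax.set_title("line of equality")
    fig.tight_layout()
    return fig


def plot_bland_altman(pairs: PairedMeasurements, report: AgreementReport):
    """Bland-Altman plot: differences vs means, bias and limits of agreement."""
    pts = bland_altman_points(pairs)
    ba = report.bland_altman
    fig, ax = plt.subplots(figsize=(5.5, 4.2))
    ax.plot(pts[:, 0], pts[:, 1], "o", ms=4, mfc="none", color="k")
    ax.axhline(ba.bias, color="b", lw=1.0, label=f"bias {ba.bias:+.2f}")
    for y, lab in ((ba.loa_low, "LoA low"), (ba.loa_high, "LoA high")):
        ax.axhline(y, color="r", lw=0.9, ls="--", label=f"{lab} {y:+.2f}")
    ax.set_xlabel(f"mean of {pairs.name_a} and {pairs.name_b} (%)")
    ax.set_ylabel(f"{pairs.name_a} − {pairs.name_b} (%)")
    ax.legend(fontsize=8)
    ax.set_title("Bland-Altman")
    fig.tight_layout()
    return fig
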