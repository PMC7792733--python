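"""End-to-end study processing: the program flow behind the CLI.

A *study directory* holds one exam's trace exports under a simple naming
convention, ``<chamber>_<view>_<quantity>.txt`` in lower case::

    lv_a4c_strain.txt    lv_a3c_strain.txt    lv_a2c_strain.txt
    rv_a4c_strain.txt    la_a4c_strain.txt    lv_a4c_strain_rate.txt ...

An 18-segment left-ventricle trace may instead be supplied as a single
``lv_strain.txt`` / ``lv_strain_rate.txt`` (the shape of simulated exports
that come without per-view files or ECG).  The co-registered ECG rides as
an ``ecg`` column of the 4-chamber LV file, whose recording is the study's
time standard.

Six *view options* select what is displayed and computed:

1. LV strain + LV strain rate + ECG
2. LV strain + LA strain + ECG
3. LV strain + LA strain rate + ECG
4. LV strain + RV strain + ECG
5. LV strain + LV strain rate derived from the strain curves + ECG
6. LV strain + LV strain rate, no ECG ("test" mode for simulated input;
   no phase segmentation — peaks are computed over the whole trace and
   flagged unphased)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError
from .io import (
    Chamber,
    EcgTrace,
    Quantity,
    StrainTrace,
    View,
    align_views,
    read_trace_export,
)
from .params import GlsResult, PeakRule, compute_gls, strain_rate_from_strain
from .phases import CyclePhases, EventTiming, segment_phases, validate_landmarks

#: panel composition per view option: (chamber, quantity) pairs; the
#: DERIVED marker means the strain-rate panel is differentiated from the
#: strain curves rather than read from an export
DERIVED = "derived"

VIEW_OPTIONS: dict[int, dict] = {
    1: {"panels": [(Chamber.LV, Quantity.STRAIN), (Chamber.LV, Quantity.STRAIN_RATE)], "ecg": True},
    2: {"panels": [(Chamber.LV, Quantity.STRAIN), (Chamber.LA, Quantity.STRAIN)], "ecg": True},
    3: {"panels": [(Chamber.LV, Quantity.STRAIN), (Chamber.LA, Quantity.STRAIN_RATE)], "ecg": True},
    4: {"panels": [(Chamber.LV, Quantity.STRAIN), (Chamber.RV, Quantity.STRAIN)], "ecg": True},
    5: {"panels": [(Chamber.LV, Quantity.STRAIN), (Chamber.LV, DERIVED)], "ecg": True},
    6: {"panels": [(Chamber.LV, Quantity.STRAIN), (Chamber.LV, Quantity.STRAIN_RATE)], "ecg": False},
}


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs of one processing run."""

    traces_dir: Path
    exam_id: str
    view_option: int = 1
    rule: PeakRule = PeakRule.WINDOW_MIN
    valve_events: dict[str, float] | None = None  # mvc/avo/avc/mvo, ms
    landmarks: dict[str, float] | None = None  # qrs1/p_onset/qrs2, ms
    out_dir: Path | None = None


@dataclass(frozen=True)
class PipelineResult:
    exam_id: str
    panels: list[StrainTrace]
    ecg: EcgTrace | None
    events: EventTiming | None
    phases: CyclePhases | None
    gls: GlsResult
    report: str
    figure_path: Path | None = None


def load_timing_file(path: str | Path) -> dict[str, float]:
    """Read a ``key: value`` (YAML mapping) timing file, values in ms."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a key: value mapping of times in ms")
    return {str(k).lower(): float(v) for k, v in raw.items()}


def _find_trace(
    traces_dir: Path, chamber: Chamber, quantity: Quantity
) -> tuple[StrainTrace, EcgTrace | None]:
    """Load one chamber/quantity, merging per-view files when present."""
    stem = f"{chamber.value.lower()}_{{view}}_{quantity.value}.txt"
    view_files = {
        v: traces_dir / stem.format(view=v.value.lower())
        for v in (View.A4C, View.A3C, View.A2C)
    }
    if all(p.exists() for p in view_files.values()):
        traces, ecg = [], None
        for v, p in view_files.items():
            tr, e = read_trace_export(p)
            traces.append(tr)
            if v is View.A4C and e is not None:
                ecg = e
        return align_views(traces, reference=View.A4C), ecg
    single = traces_dir / f"{chamber.value.lower()}_{quantity.value}.txt"
    if single.exists():
        return read_trace_export(single)
    a4c = view_files[View.A4C]
    if a4c.exists():  # single-view chamber (RV, LA): the 4-chamber file alone
        return read_trace_export(a4c)
    raise ConfigError(
        f"no {chamber.value} {quantity.value} export found in {traces_dir} "
        f"(looked for {a4c.name} / 3-view set / {single.name})"
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute read → align → landmark validation → phase segmentation →
    peak/GLS computation → report/figure for one study.

    Returns the assembled result; ``result.report`` is the stable
    terminal report (phase start times and computed parameters).
    """
    opt = VIEW_OPTIONS.get(config.view_option)
    if opt is None:
        raise ConfigError(f"view option must be 1-6, got {config.view_option}")
    traces_dir = Path(config.traces_dir)

    panels: list[StrainTrace] = []
    ecg: EcgTrace | None = None
    lv_strain: StrainTrace | None = None
    for chamber, quantity in opt["panels"]:
        if quantity == DERIVED:
            if lv_strain is None:
                raise ConfigError("derived strain rate requires the LV strain panel")
            panels.append(strain_rate_from_strain(lv_strain))
            continue
        trace, trace_ecg = _find_trace(traces_dir, chamber, quantity)
        if chamber is Chamber.LV and quantity is Quantity.STRAIN:
            lv_strain = trace
        if trace_ecg is not None and ecg is None:
            ecg = trace_ecg
        panels.append(trace)
    assert lv_strain is not None  # every option's first panel is LV strain

    events: EventTiming | None = None
    phases: CyclePhases | None = None
    if opt["ecg"]:
        if ecg is None:
            raise ConfigError(
                f"view option {config.view_option} requires an ECG column in the "
                "4-chamber LV export (only option 6 runs without ECG)"
            )
        if not config.valve_events or not config.landmarks:
            raise ConfigError(
                "valve events (mvc, avo, avc, mvo) and ECG landmarks "
                "(qrs1, p_onset, qrs2) are required for phased processing"
            )
        missing = {"mvc", "avo", "avc", "mvo"} - set(config.valve_events)
        if missing:
            raise ConfigError(f"valve events missing: {', '.join(sorted(missing))}")
        lm = {k: config.landmarks[k] for k in ("qrs1", "p_onset", "qrs2")}
        validate_landmarks(ecg, **lm)
        events = EventTiming(**lm, **{k: config.valve_events[k] for k in ("mvc", "avo", "avc", "mvo")})
        phases = segment_phases(events)

    gls = compute_gls(lv_strain, events, rule=config.rule)

    lines = [f"exam: {config.exam_id}", f"view_option: {config.view_option}"]
    if phases is not None:
        lines += ["", phases.format_report()]
    lines += ["", gls.format_report()]
    report = "\n".join(lines)

    figure_path = None
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{config.exam_id}_report.txt").write_text(report + "\n")
        from .viz import plot_study  # deferred: matplotlib import is slow

        fig = plot_study(panels, ecg, events, title=config.exam_id)
        figure_path = out / f"{config.exam_id}_curves.png"
        fig.savefig(figure_path, dpi=120)
        import matplotlib.pyplot as plt

        plt.close(fig)
    return PipelineResult(
        exam_id=config.exam_id,
        panels=panels,
        ecg=ecg,
        events=events,
        phases=phases,
        gls=gls,
        report=report,
        figure_path=figure_path,
    )


def validate_fixture(
    variant: str = "printed", out_dir: str | Path | None = None
) -> "AgreementReport":
    """Run the agreement battery on the packaged 48-subject GLS fixture.

    Optionally renders the Q-Q, equality-line and Bland-Altman figures
    into ``out_dir``.
    """
    from .agreement import compare_methods
    from .io import load_gls_validation_pairs

    pairs = load_gls_validation_pairs(variant)
    report = compare_methods(pairs)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "agreement_report.txt").write_text(report.format_report() + "\n")
        import matplotlib.pyplot as plt

        from .viz import plot_bland_altman, plot_equality, plot_qq

        figs = {
            "qq_reference.png": plot_qq(report.normal_a.qq, "Q-Q: reference method"),
            "qq_candidate.png": plot_qq(report.normal_b.qq, "Q-Q: candidate method"),
            "equality.png": plot_equality(pairs),
            "bland_altman.png": plot_bland_altman(pairs, report),
        }
        if report.normal_diff is not None:
            figs["qq_differences.png"] = plot_qq(
                report.normal_diff.qq, "Q-Q: paired differences"
            )
        for name, fig in figs.items():
            fig.savefig(out / name, dpi=120)
            plt.close(fig)
    return report
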