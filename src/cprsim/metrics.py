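"""Per-scenario resuscitation performance metrics and cohort summaries.

Mines the three scenario log streams for the performance variables a
debriefing needs: median cardiac output during the arrest, no-flow time
and no-flow-time fraction, time to ROSC, time to first adrenaline and to
first defibrillation, indicated / non-indicated shock counts, the mean
inter-shock interval and its mean absolute deviation from the guideline
2-minute cycle, and pre-intubation ventilation count and frequency.

The assessment window runs from scenario start (t = 0) to the ROSC event,
or to the last event record when no ROSC occurred (a censored scenario).
Metrics that are undefined for a scenario (no shocks, no ROSC, ...) are
``None``; cohort summaries exclude them pairwise.

Cohort dispersion uses the population standard deviation (divisor ``n``):
the cohort is treated as the complete set of assessed teams, not a sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields as dataclass_fields
from importlib import resources
from pathlib import Path

import numpy as np

from .engine import GuidelineConfig, Marker
from .log_io import (
    Drug,
    DrugLog,
    EventCode,
    EventLog,
    PhysioLog,
    format_mmss,
    parse_defib_detail,
)


@dataclass(frozen=True)
class MetricsReport:
    """The per-scenario performance variables (times in seconds)."""

    median_cardiac_output: float | None = None
    mean_cardiac_output: float | None = None
    no_flow_time: float | None = None
    no_flow_time_fraction: float | None = None
    time_to_rosc: float | None = None
    time_to_first_epinephrine: float | None = None
    time_to_intubation: float | None = None
    time_to_first_defib: float | None = None
    n_indicated_defibs: int = 0
    n_non_indicated_defibs: int = 0
    fraction_indicated: float | None = None
    mean_defib_interval: float | None = None
    mean_abs_dev_from_target_interval: float | None = None
    n_ventilations_pre_intubation: int = 0
    vent_frequency_pre_intubation: float | None = None


#: fields printed as mm:ss in human-readable reports
TIME_FIELDS = frozenset({
    "no_flow_time", "time_to_rosc", "time_to_first_epinephrine",
    "time_to_intubation", "time_to_first_defib", "mean_defib_interval",
    "mean_abs_dev_from_target_interval",
})
#: fields printed with two decimals
FRACTION_FIELDS = frozenset({"no_flow_time_fraction", "fraction_indicated"})
_INT_FIELDS = frozenset({"n_indicated_defibs", "n_non_indicated_defibs",
                         "n_ventilations_pre_intubation"})


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class CohortSummary:
    """Mean, population SD and n per metric over a cohort of scenarios."""

    stats: dict[str, MetricSummary]
    n_reports: int


# ---------------------------------------------------------------------------
# sub-extractors

def assessment_window(event_log: EventLog) -> tuple[int, int]:
    """(0, end): end is the ROSC time, else the last record (censored)."""
    records = event_log.records
    if not records:
        raise ValueError("empty event log")
    for r in records:
        if r.code is EventCode.ROSC:
            return 0, r.time
    return 0, records[-1].time


def no_flow_metrics(event_log: EventLog) -> tuple[float, float]:
    """Total no-flow seconds within the window, and their fraction of it.

    Compressions cover half-open intervals [CC_ON, CC_OFF); a final CC_ON
    without CC_OFF runs to the window end.
    """
    _, end = assessment_window(event_log)
    if end <= 0:
        raise ValueError("assessment window has zero length")
    flow = 0.0
    on_since: int | None = None
    for r in event_log:
        if r.code is EventCode.CC_ON:
            if on_since is None:
                on_since = r.time
        elif r.code is EventCode.CC_OFF:
            if on_since is None:
                raise ValueError(f"CC_OFF at {r.time}s without matching CC_ON")
            flow += max(0, min(r.time, end) - on_since)
            on_since = None
    if on_since is not None:
        flow += max(0, end - on_since)
    nft = end - flow
    return nft, nft / end


def defibrillation_metrics(event_log: EventLog, cfg: GuidelineConfig | None = None):
    """First-shock time, counts by class, and inter-shock interval stats.

    Intervals are consecutive differences over *all* recorded shocks
    (indicated and non-indicated); mean interval = (t_last - t_first)/(n-1)
    for n >= 2; the mean absolute deviation is taken from the guideline
    target interval.  ``None`` where fewer shocks exist than needed.
    """
    cfg = cfg or GuidelineConfig()
    times, classes = [], []
    for r in event_log:
        if r.code is EventCode.DEFIB:
            _, cls = parse_defib_detail(r.detail)
            times.append(r.time)
            classes.append(cls)
    n_ind = sum(1 for c in classes if c == "indicated")
    n_non = len(classes) - n_ind
    t_first = times[0] if times else None
    frac = n_ind / (n_ind + n_non) if times else None
    if len(times) >= 2:
        diffs = np.diff(times)
        mean_interval = (times[-1] - times[0]) / (len(times) - 1)
        mad = float(np.mean(np.abs(diffs - cfg.target_shock_interval)))
    else:
        mean_interval = None
        mad = None
    return t_first, n_ind, n_non, frac, mean_interval, mad


def drug_and_marker_times(event_log: EventLog,
                          drug_log: DrugLog) -> tuple[float | None, float | None]:
    """Earliest adrenaline time (first-dose marker, else drug log) and
    earliest intubation marker time; ``None`` when absent."""
    t_epi = None
    t_intubation = None
    for r in event_log:
        if r.code is EventCode.MARKER:
            if r.detail == Marker.EPI_1.value and t_epi is None:
                t_epi = r.time
            elif r.detail == Marker.INTUBATION.value and t_intubation is None:
                t_intubation = r.time
    if t_epi is None:
        for d in drug_log:
            if d.drug is Drug.ADRENALINE:
                t_epi = d.time
                break
    return t_epi, t_intubation


def ventilation_metrics(event_log: EventLog, t_intubation: float | None,
                        window_end: float) -> tuple[int, float | None]:
    """Ventilations strictly before intubation (or window end) and their
    mean frequency (min^-1) over that denominator."""
    cutoff = t_intubation if t_intubation is not None else window_end
    count = sum(1 for r in event_log
                if r.code is EventCode.VENT and r.time < cutoff)
    if cutoff <= 0:
        return count, None
    return count, count / (cutoff / 60.0)


def median_cardiac_output(physio_log: PhysioLog, window_end: float) -> float:
    """Median of cardiac-output samples at time <= window end (L/min)."""
    values = [s.cardiac_output for s in physio_log if s.time <= window_end]
    if not values:
        raise ValueError("no physio samples inside the assessment window")
    return float(np.median(values))


# ---------------------------------------------------------------------------
# assembly

def compute_metrics(event_log: EventLog, physio_log: PhysioLog, drug_log: DrugLog,
                    cfg: GuidelineConfig | None = None) -> MetricsReport:
    """Assemble the full per-scenario report from the three log streams."""
    cfg = cfg or GuidelineConfig()
    _, end = assessment_window(event_log)

    rosc = next((r.time for r in event_log if r.code is EventCode.ROSC), None)
    nft, nft_frac = no_flow_metrics(event_log)
    t_first, n_ind, n_non, frac, mean_int, mad = defibrillation_metrics(event_log, cfg)
    t_epi, t_intub = drug_and_marker_times(event_log, drug_log)
    n_vent, vent_freq = ventilation_metrics(event_log, t_intub, end)

    co_values = [s.cardiac_output for s in physio_log if s.time <= end]
    median_co = float(np.median(co_values)) if co_values else None
    mean_co = float(np.mean(co_values)) if co_values else None

    return MetricsReport(
        median_cardiac_output=median_co,
        mean_cardiac_output=mean_co,
        no_flow_time=nft,
        no_flow_time_fraction=nft_frac,
        time_to_rosc=rosc,
        time_to_first_epinephrine=t_epi,
        time_to_intubation=t_intub,
        time_to_first_defib=t_first,
        n_indicated_defibs=n_ind,
        n_non_indicated_defibs=n_non,
        fraction_indicated=frac,
        mean_defib_interval=mean_int,
        mean_abs_dev_from_target_interval=mad,
        n_ventilations_pre_intubation=n_vent,
        vent_frequency_pre_intubation=vent_freq,
    )


def summarize(reports: list[MetricsReport]) -> CohortSummary:
    """Cohort mean and population SD per metric; ``None`` excluded pairwise."""
    if not reports:
        raise ValueError("cannot summarize an empty cohort")
    stats: dict[str, MetricSummary] = {}
    for f in dataclass_fields(MetricsReport):
        values = [getattr(r, f.name) for r in reports if getattr(r, f.name) is not None]
        if not values:
            continue
        arr = np.asarray(values, dtype=float)
        stats[f.name] = MetricSummary(mean=float(arr.mean()),
                                      sd=float(arr.std(ddof=0)),
                                      n=len(values))
    return CohortSummary(stats=stats, n_reports=len(reports))


# ---------------------------------------------------------------------------
# report / summary serialization

def _field_to_str(name: str, value) -> str:
    if value is None:
        return "NA"
    if name in _INT_FIELDS:
        return str(int(value))
    return repr(float(value))  # shortest exact representation: round-trips


def report_to_dict(report: MetricsReport) -> dict[str, object]:
    """Flat dict with raw values plus mm:ss renderings of the time fields."""
    out: dict[str, object] = {}
    for f in dataclass_fields(MetricsReport):
        value = getattr(report, f.name)
        out[f.name] = value
        if f.name in TIME_FIELDS:
            out[f.name + "_mmss"] = None if value is None else format_mmss(value)
    return out


def write_report(report: MetricsReport, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report_to_dict(report), indent=2) + "\n",
                        encoding="utf-8")
        return
    lines = []
    for key, value in report_to_dict(report).items():
        if key.endswith("_mmss"):
            lines.append(f"{key}\t{'NA' if value is None else value}")
        else:
            lines.append(f"{key}\t{_field_to_str(key, value)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_report(path: str | Path) -> MetricsReport:
    """Read a flat report back (tsv or json); ``*_mmss`` keys are derived
    and ignored."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if text.lstrip().startswith("{"):
        raw = json.loads(text)
        data = {k: v for k, v in raw.items() if not k.endswith("_mmss")}
    else:
        data = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            if "\t" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key<TAB>value'")
            key, value = line.split("\t", 1)
            if key.endswith("_mmss"):
                continue
            data[key] = None if value == "NA" else value
    known = {f.name for f in dataclass_fields(MetricsReport)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ValueError(f"unknown report field {key!r} in {path}")
        if value is None:
            kwargs[key] = None
        elif key in _INT_FIELDS:
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    return MetricsReport(**kwargs)


_SUMMARY_LABELS = {
    "median_cardiac_output": "median cardiac output (L/min)",
    "mean_cardiac_output": "mean cardiac output (L/min)",
    "no_flow_time": "no-flow time (min:sec)",
    "no_flow_time_fraction": "no-flow-time fraction",
    "time_to_rosc": "time until ROSC (min:sec)",
    "time_to_first_epinephrine": "time until first epinephrine (min:sec)",
    "time_to_intubation": "time until intubation (min:sec)",
    "time_to_first_defib": "time until first defibrillation (min:sec)",
    "n_indicated_defibs": "indicated defibrillations (n)",
    "n_non_indicated_defibs": "non-indicated defibrillations (n)",
    "fraction_indicated": "fraction of indicated defibrillations",
    "mean_defib_interval": "mean interval of defibrillations (min:sec)",
    "mean_abs_dev_from_target_interval":
        "mean deviation of defibrillation interval from target (min:sec)",
    "n_ventilations_pre_intubation": "ventilations before intubation (n)",
    "vent_frequency_pre_intubation": "ventilation frequency before intubation (min^-1)",
}


def format_stat(name: str, stat: MetricSummary) -> str:
    """Render ``mean ± sd`` at the field's printed precision."""
    if name in TIME_FIELDS:
        return f"{format_mmss(stat.mean)} ± {format_mmss(stat.sd)}"
    if name in FRACTION_FIELDS:
        return f"{stat.mean:.2f} ± {stat.sd:.2f}"
    return f"{stat.mean:.1f} ± {stat.sd:.1f}"


def format_summary(summary: CohortSummary) -> str:
    """Human-readable cohort table, one metric per line."""
    lines = [f"cohort of {summary.n_reports} scenarios"]
    for name, stat in summary.stats.items():
        label = _SUMMARY_LABELS.get(name, name)
        lines.append(f"{label}\t{format_stat(name, stat)}\t(n={stat.n})")
    return "\n".join(lines)


def write_summary(summary: CohortSummary, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "json":
        payload = {
            "n_reports": summary.n_reports,
            "metrics": {name: {"mean": s.mean, "sd": s.sd, "n": s.n}
                        for name, s in summary.stats.items()},
        }
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
        return
    lines = ["metric\tmean\tsd\tn\tformatted"]
    for name, s in summary.stats.items():
        lines.append(f"{name}\t{s.mean:g}\t{s.sd:g}\t{s.n}\t{format_stat(name, s)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# benchmark cohort

def load_reference_cohort() -> list[MetricsReport]:
    """Benchmark cohort: per-scenario results of five professional
    prehospital teams (one emergency physician plus two paramedics each)
    resuscitating a simulated coarse-VF patient under 2005 ERC guidelines.

    Shipped as a packaged table; fields the table does not carry (no-flow
    seconds, mean CO, intubation time) are ``None``.
    """
    path = resources.files("cprsim") / "fixtures" / "reference_cohort.tsv"
    lines = path.read_text(encoding="utf-8").strip().splitlines()
    header = lines[0].split("\t")
    reports = []
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        n_ind = int(row["n_indicated_defibs"])
        n_non = int(row["n_non_indicated_defibs"])
        reports.append(MetricsReport(
            median_cardiac_output=float(row["median_cardiac_output"]),
            no_flow_time_fraction=float(row["no_flow_time_fraction"]),
            time_to_rosc=float(row["time_to_rosc"]),
            time_to_first_epinephrine=float(row["time_to_first_epinephrine"]),
            time_to_first_defib=float(row["time_to_first_defib"]),
            n_indicated_defibs=n_ind,
            n_non_indicated_defibs=n_non,
            fraction_indicated=n_ind / (n_ind + n_non) if n_ind + n_non else None,
            mean_defib_interval=float(row["mean_defib_interval"]),
            mean_abs_dev_from_target_interval=float(row["mean_abs_dev_from_target_interval"]),
            n_ventilations_pre_intubation=int(row["n_ventilations_pre_intubation"]),
            vent_frequency_pre_intubation=float(row["vent_frequency_pre_intubation"]),
        ))
    return reports
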