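"""The three scenario log streams and their plain-text dialect.

A scenario run produces three tab-separated UTF-8 files — ``event.tsv``,
``physio.tsv`` and ``drug.tsv`` — holding, respectively, the discrete
scenario events (state entries, rhythm changes, shocks, markers,
compression on/off edges, ventilations), the periodically sampled vital
signs, and the administered drugs.  Timestamps are integer seconds elapsed
from scenario start; there are no wall-clock dates, so fixtures are
deterministic and diffable.

Compression edges (``CC_ON``/``CC_OFF``) and ventilations are first-class
event records here: without them the performance metrics (no-flow time,
ventilation counts) could not be recovered from the files alone.

Reading back a written log reproduces the in-memory records exactly; this
round-trip identity is a contract and is property-tested.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

EVENT_FILENAME = "event.tsv"
PHYSIO_FILENAME = "physio.tsv"
DRUG_FILENAME = "drug.tsv"

_EVENT_HEADER = ["time", "code", "detail"]
_PHYSIO_HEADER = ["time", "hr", "sbp", "dbp", "cardiac_output", "spo2"]
_DRUG_HEADER = ["time", "drug", "dose"]

_DEFIB_DETAIL_RE = re.compile(r"^(\d+(?:\.\d+)?)J (indicated|non_indicated)$")


class LogFormatError(ValueError):
    """A log file violates the dialect; carries the offending line number."""

    def __init__(self, path: object, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


class EventCode(str, Enum):
    STATE = "STATE"          # scenario state entry; detail = state name
    RHYTHM = "RHYTHM"        # rhythm change; detail = rhythm name
    DEFIB = "DEFIB"          # recorded shock; detail = "<energy>J <classification>"
    MARKER = "MARKER"        # observer marker click; detail = marker name
    VENT = "VENT"            # sensed bag-mask ventilation
    CC_ON = "CC_ON"          # chest compressions start
    CC_OFF = "CC_OFF"        # chest compressions stop
    ROSC = "ROSC"            # return of spontaneous circulation
    WARN = "WARN"            # engine warning (ignored/over-cap shock, ...)


class Drug(str, Enum):
    ADRENALINE = "adrenaline"
    ATROPINE = "atropine"
    AMIODARONE = "amiodarone"


@dataclass(frozen=True)
class EventRecord:
    time: int
    code: EventCode
    detail: str = ""


@dataclass(frozen=True)
class PhysioSample:
    """One vital-signs sample: HR (min^-1), SBP/DBP (mmHg), CO (L/min), SpO2 (%)."""

    time: int
    hr: float
    sbp: float
    dbp: float
    cardiac_output: float
    spo2: float


@dataclass(frozen=True)
class DrugRecord:
    time: int
    drug: Drug
    dose: str


@dataclass
class EventLog:
    records: list[EventRecord] = field(default_factory=list)

    def __iter__(self) -> Iterator[EventRecord]:
        return iter(self.records)

    def validate(self) -> None:
        _check_sorted((r.time for r in self.records), "event log")


@dataclass
class PhysioLog:
    samples: list[PhysioSample] = field(default_factory=list)

    def __iter__(self) -> Iterator[PhysioSample]:
        return iter(self.samples)

    def validate(self) -> None:
        _check_sorted((s.time for s in self.samples), "physio log")


@dataclass
class DrugLog:
    records: list[DrugRecord] = field(default_factory=list)

    def __iter__(self) -> Iterator[DrugRecord]:
        return iter(self.records)

    def validate(self) -> None:
        _check_sorted((r.time for r in self.records), "drug log")


def _check_sorted(times, label: str) -> None:
    prev = None
    for t in times:
        if t < 0:
            raise ValueError(f"{label}: negative time {t}")
        if prev is not None and t < prev:
            raise ValueError(f"{label}: times not non-decreasing ({prev} -> {t})")
        prev = t


def parse_defib_detail(detail: str) -> tuple[float, str]:
    """Split a DEFIB payload like ``"150J indicated"`` into (energy, class)."""
    m = _DEFIB_DETAIL_RE.match(detail)
    if m is None:
        raise ValueError(f"unparseable DEFIB detail: {detail!r}")
    return float(m.group(1)), m.group(2)


def format_defib_detail(energy: float, classification: str) -> str:
    return f"{energy:g}J {classification}"


def _fmt_num(value: float) -> str:
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))  # shortest exact representation: round-trips


# ---------------------------------------------------------------------------
# writers

def write_event_log(log: EventLog, path: str | Path) -> None:
    log.validate()
    _write_tsv(path, _EVENT_HEADER,
               ([r.time, r.code.value, r.detail] for r in log.records))


def write_physio_log(log: PhysioLog, path: str | Path) -> None:
    log.validate()
    _write_tsv(path, _PHYSIO_HEADER,
               ([s.time, _fmt_num(s.hr), _fmt_num(s.sbp), _fmt_num(s.dbp),
                 _fmt_num(s.cardiac_output), _fmt_num(s.spo2)] for s in log.samples))


def write_drug_log(log: DrugLog, path: str | Path) -> None:
    log.validate()
    _write_tsv(path, _DRUG_HEADER,
               ([r.time, r.drug.value, r.dose] for r in log.records))


def write_logs(event: EventLog, physio: PhysioLog, drug: DrugLog,
               directory: str | Path) -> tuple[Path, Path, Path]:
    """Write the three streams into *directory*; returns the three paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = (directory / EVENT_FILENAME, directory / PHYSIO_FILENAME,
             directory / DRUG_FILENAME)
    write_event_log(event, paths[0])
    write_physio_log(physio, paths[1])
    write_drug_log(drug, paths[2])
    return paths


def _write_tsv(path: str | Path, header: list[str], rows) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


# ---------------------------------------------------------------------------
# readers

def read_event_log(path: str | Path) -> EventLog:
    records = []
    for lineno, row in _read_tsv(path, _EVENT_HEADER):
        t = _parse_time(path, lineno, row[0])
        try:
            code = EventCode(row[1])
        except ValueError:
            raise LogFormatError(path, lineno, f"unknown event code {row[1]!r}") from None
        detail = row[2]
        if code is EventCode.DEFIB:
            try:
                parse_defib_detail(detail)
            except ValueError as exc:
                raise LogFormatError(path, lineno, str(exc)) from None
        records.append(EventRecord(t, code, detail))
    log = EventLog(records)
    _validate_read(log, path)
    return log


def read_physio_log(path: str | Path) -> PhysioLog:
    samples = []
    for lineno, row in _read_tsv(path, _PHYSIO_HEADER):
        t = _parse_time(path, lineno, row[0])
        try:
            vals = [float(x) for x in row[1:]]
        except ValueError:
            raise LogFormatError(path, lineno, f"unparseable numeric field in {row!r}") from None
        samples.append(PhysioSample(t, *vals))
    log = PhysioLog(samples)
    _validate_read(log, path)
    return log


def read_drug_log(path: str | Path) -> DrugLog:
    records = []
    for lineno, row in _read_tsv(path, _DRUG_HEADER):
        t = _parse_time(path, lineno, row[0])
        try:
            drug = Drug(row[1])
        except ValueError:
            raise LogFormatError(path, lineno, f"unknown drug {row[1]!r}") from None
        records.append(DrugRecord(t, drug, row[2]))
    log = DrugLog(records)
    _validate_read(log, path)
    return log


def read_logs(directory: str | Path) -> tuple[EventLog, PhysioLog, DrugLog]:
    directory = Path(directory)
    for name in (EVENT_FILENAME, PHYSIO_FILENAME, DRUG_FILENAME):
        if not (directory / name).exists():
            raise FileNotFoundError(f"missing log file: {directory / name}")
    return (read_event_log(directory / EVENT_FILENAME),
            read_physio_log(directory / PHYSIO_FILENAME),
            read_drug_log(directory / DRUG_FILENAME))


def _read_tsv(path: str | Path, header: list[str]):
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            first = next(reader)
        except StopIteration:
            raise LogFormatError(path, 1, "missing header") from None
        if first != header:
            raise LogFormatError(path, 1, f"bad header {first!r}, expected {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise LogFormatError(path, lineno,
                                     f"expected {len(header)} fields, got {len(row)}")
            yield lineno, row


def _parse_time(path, lineno: int, text: str) -> int:
    try:
        t = int(text)
    except ValueError:
        raise LogFormatError(path, lineno, f"unparseable time {text!r}") from None
    if t < 0:
        raise LogFormatError(path, lineno, f"negative time {t}")
    return t


def _validate_read(log, path) -> None:
    # re-raise monotonicity violations with the offending line number
    times = [getattr(r, "time") for r in log]
    for i in range(1, len(times)):
        if times[i] < times[i - 1]:
            raise LogFormatError(path, i + 2, f"time goes backwards ({times[i-1]} -> {times[i]})")


# ---------------------------------------------------------------------------
# mm:ss utilities

_MMSS_RE = re.compile(r"^(\d+):([0-5]\d)$")


def parse_mmss(text: str) -> int:
    """``"M:SS"`` / ``"MM:SS"`` -> whole seconds (``"18:09"`` -> 1089)."""
    m = _MMSS_RE.match(text.strip())
    if m is None:
        raise ValueError(f"not a mm:ss time: {text!r}")
    return int(m.group(1)) * 60 + int(m.group(2))


def format_mmss(seconds: float) -> str:
    """Whole or fractional seconds -> zero-padded ``"MM:SS"`` (nearest second)."""
    if seconds < 0:
        raise ValueError(f"negative duration: {seconds}")
    total = round(seconds)
    return f"{total // 60:02d}:{total % 60:02d}"
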