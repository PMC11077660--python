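"""Shared signal data model, CSV persistence and configuration loading.

Every signal in the toolkit — raw sEMG in volts, ankle angles in degrees,
optical densities, hemoglobin concentration changes — travels as a
:class:`Trace`: a uniformly sampled, labeled time-series.  Event annotations
(ground-truth swing onsets, switch activations, task blocks) travel as an
:class:`EventList`.  Both round-trip through a human-inspectable CSV dialect:
UTF-8, metadata as leading ``# key=value`` comment lines, then a single
``value`` column.
"""

from __future__ import annotations

import dataclasses
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

__all__ = [
    "Trace",
    "Event",
    "EventList",
    "RunConfig",
    "read_trace_csv",
    "write_trace_csv",
    "read_events_csv",
    "write_events_csv",
    "load_config",
    "log",
]


def log(msg: str) -> None:
    """Timestamped log line to standard error."""
    ts = time.strftime("%Y-%m-%dT%H:%M:%S")
    print(f"[{ts}] cifes: {msg}", file=sys.stderr)


@dataclass
class Trace:
    """A uniformly sampled, labeled time-series.

    The time of sample ``i`` is ``start_time + i / sampling_rate``.

    Parameters
    ----------
    label : str
        What the signal is (e.g. ``"rf_semg"``, ``"ankle_left"``).
    sampling_rate : float
        Samples per second, strictly positive.
    values : ndarray
        The samples; must be finite.
    units : str
        Physical units, e.g. ``"V"``, ``"deg"``, ``"deg/s"``, ``"OD"``,
        ``"umol/L"``.
    start_time : float
        Time of the first sample in seconds.
    """

    label: str
    sampling_rate: float
    values: np.ndarray
    units: str = ""
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("Trace values must be one-dimensional")
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError(f"Trace {self.label!r} contains non-finite samples")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Duration in seconds (n samples / rate)."""
        return self.values.size / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.values.size) / self.sampling_rate

    def with_values(self, values: np.ndarray, *, label: str | None = None,
                    units: str | None = None) -> "Trace":
        """Copy of this trace with new samples (same clock)."""
        return Trace(
            label=self.label if label is None else label,
            sampling_rate=self.sampling_rate,
            values=np.asarray(values, dtype=float),
            units=self.units if units is None else units,
            start_time=self.start_time,
        )


@dataclass(frozen=True)
class Event:
    onset: float
    offset: float
    tag: str = ""

    def __post_init__(self) -> None:
        if self.offset < self.onset:
            raise ValueError(f"event offset {self.offset} precedes onset {self.onset}")


@dataclass
class EventList:
    """Ordered (onset, offset, tag) annotations, sorted by onset."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events], dtype=float)

    def add(self, onset: float, offset: float, tag: str = "") -> None:
        self.events.append(Event(onset, offset, tag))
        self.events.sort(key=lambda e: e.onset)


# ---------------------------------------------------------------------------
# CSV persistence

_TRACE_FIELDS = ("label", "sampling_rate", "units", "start_time")
_FLOAT_FMT = "%.10g"


def write_trace_csv(trace: Trace, path: str | Path) -> None:
    """Write a trace in the ``# key=value`` + single-column CSV dialect."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# label={trace.label}\n")
        fh.write(f"# sampling_rate={_FLOAT_FMT % trace.sampling_rate}\n")
        fh.write(f"# units={trace.units}\n")
        fh.write(f"# start_time={_FLOAT_FMT % trace.start_time}\n")
        fh.write("value\n")
        for v in trace.values:
            fh.write((_FLOAT_FMT % v) + "\n")


def read_trace_csv(path: str | Path) -> Trace:
    """Read a trace written by :func:`write_trace_csv`.

    Raises
    ------
    ValueError
        On a missing/malformed header field (named in the message) or a
        non-numeric sample (with its row number).
    FileNotFoundError
        If the file does not exist.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    values: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            kv = line.lstrip("#").strip()
            if "=" not in kv:
                raise ValueError(f"{path}: malformed metadata line {i + 1}: {line!r}")
            key, _, val = kv.partition("=")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    for fld in ("label", "sampling_rate"):
        if fld not in meta:
            raise ValueError(f"{path}: header missing required field {fld!r}")
    if body_start >= len(lines) or lines[body_start].strip() != "value":
        raise ValueError(f"{path}: header missing 'value' column declaration")
    for row, line in enumerate(lines[body_start + 1:], start=body_start + 2):
        s = line.strip()
        if not s:
            continue
        try:
            values.append(float(s))
        except ValueError:
            raise ValueError(f"{path}: non-numeric sample at row {row}: {s!r}") from None
    try:
        rate = float(meta["sampling_rate"])
    except ValueError:
        raise ValueError(f"{path}: malformed header field 'sampling_rate'") from None
    return Trace(
        label=meta["label"],
        sampling_rate=rate,
        values=np.array(values, dtype=float),
        units=meta.get("units", ""),
        start_time=float(meta.get("start_time", 0.0)),
    )


def write_events_csv(events: EventList, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("onset,offset,tag\n")
        for e in events:
            fh.write(f"{_FLOAT_FMT % e.onset},{_FLOAT_FMT % e.offset},{e.tag}\n")


def read_events_csv(path: str | Path) -> EventList:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "onset,offset,tag":
        raise ValueError(f"{path}: expected header 'onset,offset,tag'")
    ev = []
    for row, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",", 2)
        if len(parts) != 3:
            raise ValueError(f"{path}: malformed event at row {row}: {line!r}")
        try:
            ev.append(Event(float(parts[0]), float(parts[1]), parts[2]))
        except ValueError as exc:
            raise ValueError(f"{path}: bad event at row {row}: {exc}") from None
    return EventList(ev)


# ---------------------------------------------------------------------------
# Run configuration

#: Registry of known configuration sections -> {key: default}.  Modules
#: register their config dataclasses at import time via
#: :func:`register_config_section`.
_CONFIG_SECTIONS: dict[str, dict[str, object]] = {}


def register_config_section(name: str, cls: type) -> type:
    """Register a config dataclass so ``load_config`` can validate its keys."""
    _CONFIG_SECTIONS[name] = {f.name: f for f in dataclasses.fields(cls)}
    _CONFIG_SECTIONS[name + "__cls"] = cls  # type: ignore[assignment]
    return cls


@dataclass
class RunConfig:
    """Seed plus one parameter mapping per module section.

    Unknown sections or keys are rejected at load time with the list of
    valid alternatives, so typos fail loudly instead of silently taking
    defaults.
    """

    seed: int = 0
    sections: dict[str, object] = field(default_factory=dict)

    def section(self, name: str):
        """Config object for *name*, default-constructed if never set."""
        if name not in self.sections:
            cls = _CONFIG_SECTIONS.get(name + "__cls")
            if cls is None:
                raise KeyError(f"unknown config section {name!r}")
            self.sections[name] = cls()
        return self.sections[name]


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration, apply overrides, fill defaults.

    The file is a mapping ``{seed: int, <section>: {key: value}, ...}``.
    Overrides are a flat mapping of either ``seed`` or ``section.key``
    (dotted) entries and win over file values.
    """
    # modules must be imported so their sections are registered
    from cifes import control, emg, fnirs, kinematics, patient, stim, switching  # noqa: F401

    raw: dict = {}
    if path is not None:
        with Path(path).open("r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        raw = loaded or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: top level must be a mapping")
    for key, val in (overrides or {}).items():
        if key == "seed":
            raw["seed"] = val
        elif "." in key:
            sec, _, k = key.partition(".")
            raw.setdefault(sec, {})[k] = val
        else:
            raise ValueError(f"override {key!r} must be 'seed' or 'section.key'")

    cfg = RunConfig()
    valid_sections = sorted(k for k in _CONFIG_SECTIONS if not k.endswith("__cls"))
    for sec, content in raw.items():
        if sec == "seed":
            cfg.seed = int(content)
            if cfg.seed < 0:
                raise ValueError("seed must be non-negative")
            continue
        if sec + "__cls" not in _CONFIG_SECTIONS:
            raise ValueError(
                f"unknown config section {sec!r}; valid sections: "
                f"{', '.join(['seed'] + valid_sections)}")
        cls = _CONFIG_SECTIONS[sec + "__cls"]
        fields = _CONFIG_SECTIONS[sec]
        if content is None:
            content = {}
        unknown = set(content) - set(fields)
        if unknown:
            raise ValueError(
                f"unknown key(s) {sorted(unknown)} in section {sec!r}; "
                f"valid keys: {sorted(fields)}")
        cfg.sections[sec] = cls(**content)
    log(f"config loaded: seed={cfg.seed} sections={sorted(cfg.sections)}")
    return cfg
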