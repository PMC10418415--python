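"""Compound registry, plate maps, and well-trace I/O.

Everything downstream of the raw recordings consumes the types defined
here: :class:`CompoundRecord` (one row of the reference-compound table),
:class:`PlateEntry`/:class:`PlateMap` (well metadata), and :class:`Trace`
(one well's uniformly sampled fluorescence signal).

All on-disk formats are plain CSV with a required header:

* registry:  ``name,category,cmax_nM,dose1_nM,dose2_nM,dose3_nM,dose4_nM``
* plate map: ``well_id,cell_line,compound,dose_index,phase``
* traces:    ``time_s`` followed by one column per well recording, the
  column named ``<well_id>:<phase>`` (a well is recorded twice, before
  and after dosing, so the phase is part of the column name).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DMSO",
    "RiskLabel",
    "CellLine",
    "Phase",
    "CompoundRecord",
    "PlateEntry",
    "PlateMap",
    "Trace",
    "RegistryError",
    "TraceFormatError",
    "load_registry",
    "write_registry",
    "read_platemap",
    "write_platemap",
    "read_traces",
    "write_traces",
]

#: Vehicle-control pseudo-compound name used in plate maps.
DMSO = "DMSO"

_TIME_COLUMN = "time_s"
_UNIFORM_TOL = 1e-9
_TRACE_DECIMALS = 6


class RegistryError(ValueError):
    """Raised when a registry or plate-map file violates its contract."""


class TraceFormatError(ValueError):
    """Raised when a trace file violates its contract."""


class RiskLabel(str, enum.Enum):
    """CiPA TdP risk category."""

    HIGH = "high"
    INTERMEDIATE = "intermediate"
    LOW = "low"

    @classmethod
    def parse(cls, text: str) -> "RiskLabel":
        key = str(text).strip().lower()
        aliases = {
            "high": cls.HIGH,
            "intermediate": cls.INTERMEDIATE,
            "mid": cls.INTERMEDIATE,
            "low": cls.LOW,
        }
        if key not in aliases:
            raise RegistryError(f"unknown risk category: {text!r}")
        return aliases[key]


class CellLine(str, enum.Enum):
    CONTROL = "control"
    PROGERIA = "progeria"


class Phase(str, enum.Enum):
    PRE = "pre"
    POST = "post"


@dataclass(frozen=True)
class CompoundRecord:
    """One reference compound: name, risk category, Cmax and dose grid (nM)."""

    name: str
    risk_label: RiskLabel
    cmax: float
    doses: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if not self.name:
            raise RegistryError("compound name must be non-empty")
        if len(self.doses) != 4:
            raise RegistryError(
                f"{self.name}: expected exactly 4 doses, got {len(self.doses)}"
            )
        if self.cmax <= 0 or any(d <= 0 for d in self.doses):
            raise RegistryError(f"{self.name}: all concentrations must be > 0")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise RegistryError(
                f"{self.name}: doses must be strictly increasing, got {self.doses}"
            )


@dataclass(frozen=True)
class PlateEntry:
    """Metadata for one well: cell line, treatment, and recording phase."""

    well_id: str
    cell_line: CellLine
    compound: str
    dose_index: int | None
    phase: Phase

    def __post_init__(self) -> None:
        if self.compound == DMSO:
            if self.dose_index is not None:
                raise RegistryError(
                    f"{self.well_id}: DMSO wells must not carry a dose index"
                )
        else:
            if self.dose_index is None or not 0 <= self.dose_index <= 3:
                raise RegistryError(
                    f"{self.well_id}: dose_index must be 0..3 for "
                    f"compound {self.compound!r}"
                )


@dataclass
class PlateMap:
    """Validated collection of plate entries.

    Invariant: every ``post`` entry has a matching ``pre`` entry for the
    same well.
    """

    entries: list[PlateEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, Phase]] = set()
        for e in self.entries:
            key = (e.well_id, e.phase)
            if key in seen:
                raise RegistryError(f"duplicate plate entry {key}")
            seen.add(key)
        for e in self.entries:
            if e.phase is Phase.POST and (e.well_id, Phase.PRE) not in seen:
                raise RegistryError(
                    f"post entry {e.well_id} has no matching pre entry"
                )

    def lookup(self, well_id: str, phase: Phase) -> PlateEntry:
        for e in self.entries:
            if e.well_id == well_id and e.phase == phase:
                return e
        raise KeyError((well_id, phase))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass
class Trace:
    """One well's uniformly sampled fluorescence recording."""

    times: np.ndarray
    values: np.ndarray
    sampling_rate: float
    meta: PlateEntry

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size < 2:
            raise TraceFormatError("trace must have at least 2 samples")
        if self.times.shape != self.values.shape:
            raise TraceFormatError("times and values must have equal length")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise TraceFormatError("times must be strictly increasing")
        if np.ptp(steps) > _UNIFORM_TOL:
            raise TraceFormatError(
                f"time grid not uniform within {_UNIFORM_TOL} s"
            )
        if not np.all(np.isfinite(self.values)):
            raise TraceFormatError("trace values must be finite")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)


# ---------------------------------------------------------------------------
# Registry I/O
# ---------------------------------------------------------------------------

def _bundled(name: str) -> Path:
    return Path(str(resources.files("catrisk.data").joinpath(name)))


def load_registry(path: str | Path | None = None) -> list[CompoundRecord]:
    """Load a compound registry CSV.

    With ``path=None`` the bundled reference-compound registry (11
    compounds: 3 high-, 4 intermediate-, 4 low-risk) is loaded.
    """
    src = _bundled("registry.csv") if path is None else Path(path)
    try:
        df = pd.read_csv(src, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise RegistryError(f"could not parse registry file {src}: {exc}") from exc
    expected = ["name", "category", "cmax_nM", "dose1_nM", "dose2_nM",
                "dose3_nM", "dose4_nM"]
    if list(df.columns) != expected:
        raise RegistryError(
            f"registry header must be {expected}, got {list(df.columns)}"
        )
    records: list[CompoundRecord] = []
    for idx, row in df.iterrows():
        try:
            doses = tuple(float(row[c]) for c in expected[3:])
            rec = CompoundRecord(
                name=str(row["name"]).strip(),
                risk_label=RiskLabel.parse(row["category"]),
                cmax=float(row["cmax_nM"]),
                doses=doses,  # type: ignore[arg-type]
            )
        except (TypeError, ValueError) as exc:
            raise RegistryError(
                f"registry row {idx + 1} ({row.get('name', '?')!r}): {exc}"
            ) from exc
        records.append(rec)
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        raise RegistryError("duplicate compound names in registry")
    return records


def _fmt(x: float) -> str:
    """Format a concentration without trailing zeros (round-trip stable)."""
    if x == int(x):
        return str(int(x))
    return repr(float(x))


def write_registry(records: Sequence[CompoundRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "name": r.name,
                "category": r.risk_label.value,
                "cmax_nM": _fmt(r.cmax),
                "dose1_nM": _fmt(r.doses[0]),
                "dose2_nM": _fmt(r.doses[1]),
                "dose3_nM": _fmt(r.doses[2]),
                "dose4_nM": _fmt(r.doses[3]),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Plate-map I/O
# ---------------------------------------------------------------------------

def read_platemap(path: str | Path) -> PlateMap:
    df = pd.read_csv(path, dtype=str)
    expected = ["well_id", "cell_line", "compound", "dose_index", "phase"]
    if list(df.columns) != expected:
        raise RegistryError(
            f"plate-map header must be {expected}, got {list(df.columns)}"
        )
    entries = []
    for idx, row in df.iterrows():
        raw_di = row["dose_index"]
        dose_index = None if pd.isna(raw_di) or raw_di == "" else int(raw_di)
        try:
            entries.append(
                PlateEntry(
                    well_id=str(row["well_id"]),
                    cell_line=CellLine(row["cell_line"]),
                    compound=str(row["compound"]),
                    dose_index=dose_index,
                    phase=Phase(row["phase"]),
                )
            )
        except ValueError as exc:
            raise RegistryError(f"plate-map row {idx + 1}: {exc}") from exc
    return PlateMap(entries)


def write_platemap(platemap: PlateMap, path: str | Path) -> None:
    rows = [
        {
            "well_id": e.well_id,
            "cell_line": e.cell_line.value,
            "compound": e.compound,
            "dose_index": "" if e.dose_index is None else e.dose_index,
            "phase": e.phase.value,
        }
        for e in platemap
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Trace I/O
# ---------------------------------------------------------------------------

def _column_name(meta: PlateEntry) -> str:
    return f"{meta.well_id}:{meta.phase.value}"


def write_traces(traces: Sequence[Trace], path: str | Path) -> None:
    """Write traces as one CSV: ``time_s`` plus one ``well:phase`` column each.

    All traces must share the same time grid.
    """
    if not traces:
        raise TraceFormatError("no traces to write")
    t0 = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != t0.shape or np.max(np.abs(tr.times - t0)) > _UNIFORM_TOL:
            raise TraceFormatError("all traces must share one time grid")
    data = {_TIME_COLUMN: np.round(t0, _TRACE_DECIMALS)}
    for tr in traces:
        name = _column_name(tr.meta)
        if name in data:
            raise TraceFormatError(f"duplicate trace column {name}")
        data[name] = np.round(tr.values, _TRACE_DECIMALS)
    pd.DataFrame(data).to_csv(path, index=False, float_format=f"%.{_TRACE_DECIMALS}f")


def read_traces(trace_path: str | Path, platemap_path: str | Path) -> list[Trace]:
    """Read a trace CSV and join well metadata from a plate map.

    Every ``well:phase`` column must have a plate-map entry and vice
    versa; a mismatch in either direction is an error.
    """
    platemap = read_platemap(platemap_path)
    df = pd.read_csv(trace_path)
    if df.columns.size < 2 or df.columns[0] != _TIME_COLUMN:
        raise TraceFormatError(
            f"trace file must start with a {_TIME_COLUMN!r} column"
        )
    times = df[_TIME_COLUMN].to_numpy(dtype=float)
    steps = np.diff(times)
    if times.size < 2 or np.any(steps <= 0) or np.ptp(steps) > 1e-6:
        raise TraceFormatError("trace time grid is not uniform")
    fs = 1.0 / float(np.mean(steps))

    by_key = {(e.well_id, e.phase): e for e in platemap}
    seen: set[tuple[str, Phase]] = set()
    traces = []
    for col in df.columns[1:]:
        if ":" not in col:
            raise TraceFormatError(
                f"trace column {col!r} is not of the form well:phase"
            )
        well_id, phase_text = col.rsplit(":", 1)
        try:
            phase = Phase(phase_text)
        except ValueError as exc:
            raise TraceFormatError(f"trace column {col!r}: {exc}") from exc
        key = (well_id, phase)
        if key not in by_key:
            raise TraceFormatError(
                f"trace column {col!r} has no plate-map entry"
            )
        values = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(values)):
            raise TraceFormatError(f"trace column {col!r} contains NaN")
        seen.add(key)
        traces.append(Trace(times=times, values=values, sampling_rate=fs,
                            meta=by_key[key]))
    missing = set(by_key) - seen
    if missing:
        raise TraceFormatError(
            f"plate-map entries without trace columns: {sorted(missing)[:5]}"
        )
    return traces
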