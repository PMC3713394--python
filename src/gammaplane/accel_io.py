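"""Session-file I/O and reduction of max-deviation vectors to magnitude series.

Input data are per-session delimited text files (one file per roughly
hour-long recording dump), with a header row and columns::

    t, x_mean, y_mean, z_mean, x_maxdev, y_maxdev, z_maxdev

The ``*_mean`` columns are optional.  ``t`` is seconds since session start
and is used only to validate within-session ordering: the downstream
statistics are indexed by acquisition order, not wall-clock time.  The
three ``*_maxdev`` columns hold the X, Y, Z components of the maximum
deviation from the mean acceleration over the device's summarisation
interval; their Euclidean norm is the scalar each analysis consumes.
Device units pass through unconverted — the Gamma scale parameter is
equivariant under rescaling, so units only rescale the plane.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AccelReading",
    "Session",
    "MagnitudeSeries",
    "ReadWarnings",
    "vector_magnitude",
    "read_session",
    "write_session",
    "magnitude_series",
    "write_magnitude_series",
    "read_participant_dir",
]

MAXDEV_COLUMNS = ("x_maxdev", "y_maxdev", "z_maxdev")
MEAN_COLUMNS = ("x_mean", "y_mean", "z_mean")


class FormatError(ValueError):
    """Raised when a session file does not match the expected dialect."""


@dataclass(frozen=True)
class AccelReading:
    """One summarised accelerometer reading.

    t: seconds since session start (ordering only).
    maxdev: (X, Y, Z) maximum deviation from the mean acceleration.
    mean_acc: optional (X, Y, Z) mean acceleration.
    """

    t: float
    maxdev: tuple[float, float, float]
    mean_acc: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.t) or self.t < 0:
            raise ValueError(f"reading time must be finite and >= 0, got {self.t}")
        if len(self.maxdev) != 3 or not all(math.isfinite(c) for c in self.maxdev):
            raise ValueError(f"maxdev must be a finite 3-vector, got {self.maxdev!r}")
        if self.mean_acc is not None and (
            len(self.mean_acc) != 3 or not all(math.isfinite(c) for c in self.mean_acc)
        ):
            raise ValueError(f"mean_acc must be a finite 3-vector, got {self.mean_acc!r}")


@dataclass
class Session:
    """One recording dump: ordered readings for (participant, day, session)."""

    participant_id: str
    day_index: int
    session_index: int
    readings: list[AccelReading]

    def __post_init__(self) -> None:
        if self.day_index < 1 or self.session_index < 1:
            raise ValueError("day_index and session_index must be >= 1")
        times = [r.t for r in self.readings]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(
                f"readings of {self.participant_id} day {self.day_index} "
                f"session {self.session_index} are not ordered by t"
            )

    def __len__(self) -> int:
        return len(self.readings)


@dataclass
class ReadWarnings:
    """Row-level issues encountered while reading a session file."""

    dropped_rows: int = 0
    dropped_row_indices: list[int] = field(default_factory=list)


@dataclass
class MagnitudeSeries:
    """Acquisition-ordered scalar max-deviation magnitudes for one person.

    provenance[i] is the (day_index, session_index) the i-th value came from.
    """

    participant_id: str
    values: np.ndarray
    provenance: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if len(self.values) != len(self.provenance):
            raise ValueError("one provenance tag required per value")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("magnitudes must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.values)


def vector_magnitude(v: Sequence[float]) -> float:
    """Euclidean norm of a 3-component deviation vector."""
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite component in {v!r}")
    return float(np.sqrt(np.dot(arr, arr)))


def _parse_session_name(path: Path) -> tuple[str, int, int]:
    """Infer (participant, day, session) from <participant>/<day>/<session>.csv."""
    try:
        session_index = int(path.stem)
        day_index = int(path.parent.name)
        participant_id = path.parent.parent.name
        return participant_id, day_index, session_index
    except (ValueError, AttributeError) as exc:
        raise FormatError(
            f"cannot infer (participant, day, session) from path {path}; "
            "expected <participant>/<day>/<session>.csv"
        ) from exc


def read_session(
    path: str | Path,
    *,
    participant_id: str | None = None,
    day_index: int | None = None,
    session_index: int | None = None,
) -> tuple[Session, ReadWarnings]:
    """Read one delimited session file (comma or tab, auto-detected).

    Rows with missing or non-numeric max-deviation components are dropped
    and counted in the returned :class:`ReadWarnings`.  Identity fields not
    given explicitly are inferred from the ``<participant>/<day>/<session>``
    path convention.
    """
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no such session file: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error) as exc:
        raise FormatError(f"unreadable session file {path}: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in ("t", *MAXDEV_COLUMNS) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    has_mean = all(c in df.columns for c in MEAN_COLUMNS)

    required = ["t", *MAXDEV_COLUMNS] + (list(MEAN_COLUMNS) if has_mean else [])
    numeric = df[required].apply(pd.to_numeric, errors="coerce")
    ok = np.isfinite(numeric[["t", *MAXDEV_COLUMNS]]).all(axis=1).to_numpy()
    warnings = ReadWarnings(
        dropped_rows=int((~ok).sum()),
        dropped_row_indices=list(np.flatnonzero(~ok)),
    )
    numeric = numeric[ok]

    if participant_id is None or day_index is None or session_index is None:
        pid, day, ses = _parse_session_name(path)
        participant_id = participant_id if participant_id is not None else pid
        day_index = day_index if day_index is not None else day
        session_index = session_index if session_index is not None else ses

    readings = []
    for row in numeric.itertuples(index=False):
        mean_acc = None
        if has_mean and all(math.isfinite(getattr(row, c)) for c in MEAN_COLUMNS):
            mean_acc = tuple(float(getattr(row, c)) for c in MEAN_COLUMNS)
        readings.append(
            AccelReading(
                t=float(row.t),
                maxdev=tuple(float(getattr(row, c)) for c in MAXDEV_COLUMNS),
                mean_acc=mean_acc,
            )
        )
    session = Session(
        participant_id=participant_id,
        day_index=day_index,
        session_index=session_index,
        readings=readings,
    )
    return session, warnings


def write_session(session: Session, path: str | Path, *, sep: str = ",") -> Path:
    """Write a session back to the delimited dialect read_session accepts."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    has_mean = all(r.mean_acc is not None for r in session.readings)
    cols: dict[str, list[float]] = {"t": [r.t for r in session.readings]}
    if has_mean:
        for i, c in enumerate(MEAN_COLUMNS):
            cols[c] = [r.mean_acc[i] for r in session.readings]  # type: ignore[index]
    for i, c in enumerate(MAXDEV_COLUMNS):
        cols[c] = [r.maxdev[i] for r in session.readings]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format="%.10g")
    return path


def magnitude_series(sessions: Iterable[Session]) -> MagnitudeSeries:
    """Concatenate per-reading max-deviation magnitudes across sessions.

    Sessions are ordered by (day_index, session_index) regardless of the
    order supplied; readings keep file order within each session.  All
    sessions must belong to one participant.
    """
    ordered = sorted(sessions, key=lambda s: (s.day_index, s.session_index))
    if not ordered:
        raise ValueError("no sessions given")
    pids = {s.participant_id for s in ordered}
    if len(pids) != 1:
        raise ValueError(f"sessions mix participants: {sorted(pids)}")
    keys = [(s.day_index, s.session_index) for s in ordered]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (day, session) index pairs")

    values: list[float] = []
    provenance: list[tuple[int, int]] = []
    for s in ordered:
        for r in s.readings:
            values.append(vector_magnitude(r.maxdev))
            provenance.append((s.day_index, s.session_index))
    return MagnitudeSeries(
        participant_id=ordered[0].participant_id,
        values=np.asarray(values, dtype=float),
        provenance=provenance,
    )


def write_magnitude_series(series: MagnitudeSeries, path: str | Path) -> Path:
    """Write (index, magnitude) delimited file plus a JSON provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"index": np.arange(len(series)), "magnitude": series.values}
    ).to_csv(path, index=False, float_format="%.10g")
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(
        json.dumps(
            {
                "participant_id": series.participant_id,
                "provenance": [list(p) for p in series.provenance],
            }
        )
    )
    return path


def read_participant_dir(root: str | Path, participant_id: str) -> tuple[MagnitudeSeries, ReadWarnings]:
    """Read every <day>/<session>.csv under root/participant_id into one series."""
    base = Path(root) / participant_id
    if not base.is_dir():
        raise FormatError(f"no participant directory {base}")
    sessions: list[Session] = []
    total = ReadWarnings()
    for f in sorted(base.glob("*/*.csv")):
        session, warn = read_session(f)
        sessions.append(session)
        total.dropped_rows += warn.dropped_rows
    return magnitude_series(sessions), total
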