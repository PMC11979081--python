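"""Plain-text I/O for pressure traces and subject metadata.

Trace dialect
-------------
A trace file is CSV with an optional block of ``# key = value`` comment
lines (subject_id, channel, start_time), then either

* a header ``time_s,pressure_mmHg`` and two numeric columns, time in
  seconds from trace start (uniform step), pressure in mmHg; or
* headerless numeric columns: two columns are taken as time_s and
  pressure_mmHg; a single column is pressure only, in which case the
  sampling rate must be supplied by the caller.

Metadata dialect
----------------
CSV with header ``subject_id,operated_side,acom,a1_ipsi,a1_contra,
pcom_ipsi,pcom_contra,p1_ipsi,p1_contra,backflow_grade,
contralateral_stenosis_pct``. Segment columns hold NORMAL / HYPOPLASTIC /
ABSENT; backflow is the surgeon's semi-quantitative grade (1 weak and
discontinuous, 2 continuous but not pulsatile, 3 strong and pulsatile);
stenosis is NASCET percent of the contralateral carotid.

All pressures are mmHg throughout the package; time is seconds, 0-based
from trace start.
"""
from __future__ import annotations

import dataclasses
import enum
import warnings
from pathlib import Path
from typing import List, Optional

import numpy as np

from .cow import CowSegment, SegState, Side
from .exceptions import FormatError, ValidationError

__all__ = [
    "Channel",
    "PressureTrace",
    "SubjectMetadata",
    "read_trace",
    "write_trace",
    "read_metadata_table",
    "write_metadata_table",
]

#: Maximum deviation of the time step from uniformity (seconds).
UNIFORMITY_TOL_S = 1e-6

METADATA_SEGMENT_COLUMNS = {
    "acom": CowSegment.ACOM,
    "a1_ipsi": CowSegment.A1_IPSI,
    "a1_contra": CowSegment.A1_CONTRA,
    "pcom_ipsi": CowSegment.PCOM_IPSI,
    "pcom_contra": CowSegment.PCOM_CONTRA,
    "p1_ipsi": CowSegment.P1_IPSI,
    "p1_contra": CowSegment.P1_CONTRA,
}

METADATA_COLUMNS = (
    ["subject_id", "operated_side"]
    + list(METADATA_SEGMENT_COLUMNS)
    + ["backflow_grade", "contralateral_stenosis_pct"]
)


class Channel(str, enum.Enum):
    """Which artery the catheter was in."""

    ICA_STUMP = "ICA_STUMP"
    RADIAL = "RADIAL"


@dataclasses.dataclass
class PressureTrace:
    """A uniformly sampled arterial pressure time series.

    Attributes
    ----------
    samples : ndarray
        Pressure values in mmHg.
    sampling_rate : float
        Samples per second (Hz).
    channel : Channel
        ICA stump or radial (systemic reference) line.
    subject_id : str
    start_time : str, optional
        Free-form acquisition timestamp; not used in computation.
    """

    samples: np.ndarray
    sampling_rate: float
    channel: Channel = Channel.ICA_STUMP
    subject_id: str = ""
    start_time: Optional[str] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValidationError("a trace needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("all samples must be finite")
        if not (self.sampling_rate > 0):
            raise ValidationError("sampling_rate must be positive")
        self.channel = Channel(self.channel)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n samples cover n/fs seconds)."""
        return self.n / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "PressureTrace":
        """Copy of this trace with new samples (same rate and labels)."""
        return dataclasses.replace(self, samples=np.asarray(samples, dtype=float))


@dataclasses.dataclass
class SubjectMetadata:
    """Per-subject clinical annotations used by the cohort layer."""

    subject_id: str
    operated_side: Side
    cow_segments: dict
    backflow_grade: int
    contralateral_stenosis: float

    def __post_init__(self):
        self.operated_side = Side(self.operated_side)
        self.cow_segments = {
            CowSegment(k): SegState(v) for k, v in self.cow_segments.items()
        }
        if len(self.cow_segments) != len(CowSegment):
            missing = set(CowSegment) - set(self.cow_segments)
            raise ValidationError(
                "missing CoW segment state(s): "
                + ", ".join(sorted(s.value for s in missing))
            )
        if self.backflow_grade not in (1, 2, 3):
            raise ValidationError(
                f"backflow_grade must be 1, 2 or 3, got {self.backflow_grade}"
            )
        if not 0.0 <= self.contralateral_stenosis <= 100.0:
            raise ValidationError(
                "contralateral_stenosis must be in [0, 100] percent, got "
                f"{self.contralateral_stenosis}"
            )


def _parse_float(token: str, path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"{path}: non-numeric value {token!r} on line {lineno}")


def read_trace(
    path,
    sampling_rate: Optional[float] = None,
    channel: Channel = Channel.ICA_STUMP,
    subject_id: Optional[str] = None,
) -> PressureTrace:
    """Read a pressure trace from the documented CSV dialect.

    The sampling rate is inferred from the ``time_s`` column when present
    (after checking uniformity to within 1e-6 s), otherwise it must be
    supplied via ``sampling_rate``.
    """
    path = Path(path)
    meta = {"channel": channel, "subject_id": subject_id or "", "start_time": None}
    rows: list = []
    header_cols: Optional[list] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line.lstrip("#").partition("=")
                    key, value = key.strip(), value.strip()
                    if key in meta and value:
                        meta[key] = value
                continue
            tokens = [t.strip() for t in line.split(",")]
            if header_cols is None and any(
                not _is_number(t) for t in tokens
            ):
                header_cols = [t.lower() for t in tokens]
                if "pressure_mmhg" not in header_cols:
                    raise FormatError(
                        f"{path}: header must contain a pressure_mmHg column, "
                        f"got {tokens}"
                    )
                continue
            rows.append((lineno, [ _parse_float(t, path, lineno) for t in tokens ]))

    if len(rows) < 2:
        raise FormatError(f"{path}: a trace needs at least 2 data rows")

    lengths = {len(vals) for _, vals in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: rows have inconsistent column counts")
    data = np.array([vals for _, vals in rows], dtype=float)
    if header_cols is not None:
        p_idx = header_cols.index("pressure_mmhg")
        t_idx = header_cols.index("time_s") if "time_s" in header_cols else None
    elif data.shape[1] == 2:
        t_idx, p_idx = 0, 1
    elif data.shape[1] == 1:
        t_idx, p_idx = None, 0
    else:
        raise FormatError(
            f"{path}: headerless files must have 1 (pressure) or 2 "
            "(time, pressure) columns"
        )
    pressure = data[:, p_idx]
    if t_idx is not None:
        t = data[:, t_idx]
        dt = np.diff(t)
        if dt.size == 0 or np.any(dt <= 0):
            raise FormatError(f"{path}: time column must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > UNIFORMITY_TOL_S:
            raise FormatError(
                f"{path}: non-uniform sampling (time step varies by more "
                f"than {UNIFORMITY_TOL_S} s)"
            )
        sampling_rate = 1.0 / float(np.mean(dt))

    if sampling_rate is None:
        raise FormatError(
            f"{path}: no time column and no sampling_rate supplied"
        )
    return PressureTrace(
        samples=pressure,
        sampling_rate=float(sampling_rate),
        channel=Channel(meta["channel"]),
        subject_id=str(meta["subject_id"]),
        start_time=meta["start_time"],
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_trace(trace: PressureTrace, path) -> Path:
    """Write a trace to the documented CSV dialect (full float precision).

    Round-trip contract: ``read_trace(write_trace(t))`` reproduces the
    samples bit-for-bit and the same sampling rate.
    """
    path = Path(path)
    t = trace.times
    with open(path, "w") as fh:
        if trace.subject_id:
            fh.write(f"# subject_id = {trace.subject_id}\n")
        fh.write(f"# channel = {trace.channel.value}\n")
        if trace.start_time:
            fh.write(f"# start_time = {trace.start_time}\n")
        fh.write(f"# sampling_rate_hz = {trace.sampling_rate!r}\n")
        fh.write("time_s,pressure_mmHg\n")
        for ti, pi in zip(t, trace.samples):
            fh.write(f"{float(ti)!r},{float(pi)!r}\n")
    return path


def read_metadata_table(path) -> List[SubjectMetadata]:
    """Read subject metadata records; validates every row."""
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s) {missing}")
    if df.empty:
        warnings.warn(f"{path}: empty metadata table", stacklevel=2)
        return []
    records = []
    for idx, row in df.iterrows():
        try:
            segments = {
                seg: SegState(str(row[col]).strip().upper())
                for col, seg in METADATA_SEGMENT_COLUMNS.items()
            }
        except ValueError as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from None
        try:
            records.append(
                SubjectMetadata(
                    subject_id=str(row["subject_id"]),
                    operated_side=Side(str(row["operated_side"]).strip().upper()),
                    cow_segments=segments,
                    backflow_grade=int(row["backflow_grade"]),
                    contralateral_stenosis=float(row["contralateral_stenosis_pct"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from None
    return records


def write_metadata_table(records: List[SubjectMetadata], path) -> Path:
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "operated_side": r.operated_side.value,
        }
        for col, seg in METADATA_SEGMENT_COLUMNS.items():
            row[col] = r.cow_segments[seg].value
        row["backflow_grade"] = r.backflow_grade
        row["contralateral_stenosis_pct"] = r.contralateral_stenosis
        rows.append(row)
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, index=False)
    return Path(path)
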