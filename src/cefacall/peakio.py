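"""Peak tables and raw traces: the sample-level data model and file formats.

Peak tables are CSV (``sample_id,dye,size_bp,height,area``), the shape of a
fragment-analysis software export.  Raw traces are JSON with one RFU array per
dye channel plus the LIZ ladder channel.  Both round-trip losslessly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import DYE_CHANNELS

__all__ = [
    "Peak",
    "PeakTable",
    "SampleTrace",
    "PeakTableFormatError",
    "TraceFormatError",
    "read_peak_table",
    "write_peak_table",
    "read_trace",
    "write_trace",
]

CSV_COLUMNS = ["sample_id", "dye", "size_bp", "height", "area"]


class PeakTableFormatError(ValueError):
    pass


class TraceFormatError(ValueError):
    pass


@dataclass
class Peak:
    """One detected fragment peak.

    ``size`` is NaN before size calibration.  ``height`` is the peak apex in
    RFU and is the quantity used throughout calling; ``area`` is carried but
    unused.  ``flags`` holds per-peak QC annotations (e.g. OUT_OF_RANGE).
    """

    dye: str
    size: float
    height: float
    area: float | None = None
    scan_position: int | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.dye not in DYE_CHANNELS:
            raise ValueError(f"unknown dye {self.dye!r}")
        if self.height < 0:
            raise ValueError(f"negative peak height {self.height}")

    @property
    def calibrated(self) -> bool:
        return not math.isnan(self.size)


@dataclass
class PeakTable:
    sample_id: str
    peaks: list[Peak] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


@dataclass
class SampleTrace:
    """Raw per-dye signal arrays (RFU versus scan index)."""

    sample_id: str
    signals: dict[str, np.ndarray]
    scan_count: int

    def __post_init__(self) -> None:
        sigs = {}
        for dye in DYE_CHANNELS:
            if dye not in self.signals:
                raise TraceFormatError(f"trace missing dye channel {dye!r}")
            arr = np.asarray(self.signals[dye], dtype=float)
            if arr.ndim != 1 or arr.shape[0] != self.scan_count:
                raise TraceFormatError(
                    f"channel {dye!r} has length {arr.shape}, expected "
                    f"({self.scan_count},)"
                )
            if not np.all(np.isfinite(arr)):
                raise TraceFormatError(f"channel {dye!r} contains non-finite values")
            sigs[dye] = arr
        self.signals = sigs


# ---------------------------------------------------------------------------
# peak-table CSV
# ---------------------------------------------------------------------------

def read_peak_table(path, *, on_bad: str = "error") -> PeakTable:
    """Read a peak-table CSV.

    Rows with an unknown dye or a non-numeric/negative height are rejected.
    With ``on_bad="error"`` the first bad row raises
    :class:`PeakTableFormatError` naming the row and value; with
    ``on_bad="collect"`` rejected rows are reported in
    ``table.metadata["rejected_rows"]`` as ``(row_number, reason)`` pairs, so
    that rows in = peaks kept + rejections.
    """
    if on_bad not in ("error", "collect"):
        raise ValueError("on_bad must be 'error' or 'collect'")
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise PeakTableFormatError(f"unreadable peak-table CSV: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c != "area" and c not in frame.columns]
    if missing:
        raise PeakTableFormatError(
            f"peak-table CSV missing required column(s): {', '.join(missing)}"
        )
    has_area = "area" in frame.columns

    peaks: list[Peak] = []
    rejected: list[tuple[int, str]] = []
    sample_ids = set()
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        reason = None
        dye = getattr(row, "dye")
        if dye not in DYE_CHANNELS:
            reason = f"unknown dye {dye!r}"
        else:
            try:
                height = float(getattr(row, "height"))
                if height < 0 or not math.isfinite(height):
                    reason = f"invalid height {getattr(row, 'height')!r}"
            except ValueError:
                reason = f"non-numeric height {getattr(row, 'height')!r}"
        if reason is None:
            raw_size = getattr(row, "size_bp")
            try:
                size = float(raw_size) if raw_size != "" else math.nan
            except ValueError:
                reason = f"non-numeric size {raw_size!r}"
        if reason is not None:
            if on_bad == "error":
                raise PeakTableFormatError(f"row {row_number}: {reason}")
            rejected.append((row_number, reason))
            continue
        area = None
        if has_area:
            raw_area = getattr(row, "area")
            if raw_area != "":
                try:
                    area = float(raw_area)
                except ValueError:
                    if on_bad == "error":
                        raise PeakTableFormatError(
                            f"row {row_number}: non-numeric area {raw_area!r}"
                        )
                    rejected.append((row_number, f"non-numeric area {raw_area!r}"))
                    continue
        sample_ids.add(getattr(row, "sample_id"))
        peaks.append(Peak(dye=dye, size=size, height=height, area=area))

    if len(sample_ids) > 1:
        raise PeakTableFormatError(
            f"peak table mixes {len(sample_ids)} sample ids: {sorted(sample_ids)}"
        )
    sample_id = sample_ids.pop() if sample_ids else ""
    metadata = {"rejected_rows": rejected} if rejected else {}
    return PeakTable(sample_id=sample_id, peaks=peaks, metadata=metadata)


def write_peak_table(table: PeakTable, path) -> None:
    """Write a peak table as CSV (deterministic column order, repr floats)."""
    rows = []
    for p in table.peaks:
        rows.append({
            "sample_id": table.sample_id,
            "dye": p.dye,
            "size_bp": "" if math.isnan(p.size) else repr(float(p.size)),
            "height": repr(float(p.height)),
            "area": "" if p.area is None else repr(float(p.area)),
        })
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trace JSON
# ---------------------------------------------------------------------------

def read_trace(path) -> SampleTrace:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TraceFormatError(f"unreadable trace JSON: {exc}") from exc
    try:
        scan_count = int(raw["scans"])
        signals = {dye: np.asarray(raw[dye], dtype=float) for dye in DYE_CHANNELS}
        sample_id = str(raw["sample_id"])
    except (KeyError, TypeError, ValueError) as exc:
        raise TraceFormatError(f"malformed trace JSON: {exc}") from exc
    return SampleTrace(sample_id=sample_id, signals=signals, scan_count=scan_count)


def write_trace(trace: SampleTrace, path) -> None:
    payload = {"sample_id": trace.sample_id, "scans": trace.scan_count}
    for dye in DYE_CHANNELS:
        payload[dye] = [float(v) for v in trace.signals[dye]]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)
        fh.write("\n")
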