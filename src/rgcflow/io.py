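"""Readers and writers: event tables (CSV/FCS), flatmount images, reports.

CSV is the canonical interchange format: comma-separated, mandatory header,
'.' decimal separator, UTF-8. Floats are written with Python ``repr``
semantics so a write/read cycle is bit-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .events import (
    CANONICAL_CHANNELS,
    EventTable,
    FlatmountImage,
    MissingChannelError,
    REQUIRED_CHANNELS,
    normalize_channel_name,
)
from .fcs import read_fcs

logger = logging.getLogger(__name__)

LABEL_COLUMN = "label"


def read_event_table(path: str | Path, format: Optional[str] = None) -> EventTable:
    """Read a cytometry event table from CSV or FCS.

    Parameters
    ----------
    path:
        Input file. ``format`` is inferred from the suffix when omitted.
    format:
        ``"csv"`` or ``"fcs"``.

    Returns
    -------
    EventTable
        With ``compensated=False`` and channel names canonicalised.
    """
    path = Path(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if format == "fcs":
        frame = read_fcs(path)
    elif format == "csv":
        try:
            # round_trip float parsing keeps write/read cycles bit-identical
            frame = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed CSV event table {path}: {exc}") from exc
        if frame.columns.str.startswith("Unnamed").all():
            raise ValueError(f"CSV event table {path} lacks a header row")
    else:
        raise ValueError(f"unknown event-table format {format!r}")

    labels = None
    for col in frame.columns:
        if str(col).strip().lower() == LABEL_COLUMN:
            labels = frame.pop(col).astype(str)
            break
    frame = frame.rename(columns={c: normalize_channel_name(str(c)) for c in frame.columns})
    missing = [c for c in REQUIRED_CHANNELS if c not in frame.columns]
    if missing:
        raise MissingChannelError(missing)
    table = EventTable(frame, compensated=False, labels=labels)
    logger.info("read %d events x %d channels from %s", table.n_events,
                len(table.channels), path)
    return table


def write_event_table(table: EventTable, path: str | Path) -> None:
    """Write an event table to CSV (values round-trip bit-identically)."""
    path = Path(path)
    frame = table.data.copy()
    if table.labels is not None:
        frame[LABEL_COLUMN] = table.labels.to_numpy()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(map(str, frame.columns)) + "\n")
        for row in frame.itertuples(index=False):
            fh.write(",".join(repr(v) if isinstance(v, float) else str(v) for v in row) + "\n")
    logger.info("wrote %d events to %s", len(frame), path)


def read_flatmount_image(path: str | Path, scale: float,
                         region: Optional[str] = None) -> FlatmountImage:
    """Read a TIFF or PNG micrograph as a grayscale flatmount field.

    RGB images are converted to 8-bit grayscale with the Rec. 601 luma
    weights before any thresholding downstream.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = (arr[..., :3] @ np.array([0.299, 0.587, 0.114])).astype(np.uint8)
    field_um = (arr.shape[1] * scale, arr.shape[0] * scale)
    image = FlatmountImage(arr, scale=scale, region=region, field_um=field_um)
    logger.info("read %sx%s image from %s (%.3f um/px)", *arr.shape, path, scale)
    return image


def write_report(report, path: str | Path, precision: int = 4) -> None:
    """Write a population report as TSV.

    Deterministic column and row order; the numeric precision used is stated
    in the file's comment header, so repeated writes are byte-identical.
    """
    path = Path(path)
    frame = report.to_frame()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# rgcflow population report (numeric precision: {precision} dp)\n")
        fh.write("\t".join(frame.columns) + "\n")
        for row in frame.itertuples(index=False):
            cells = []
            for v in row:
                if isinstance(v, float):
                    cells.append("n/a" if np.isnan(v) else f"{v:.{precision}f}")
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")
    logger.info("wrote report (%d rows) to %s", len(frame), path)


def read_report_frame(path: str | Path) -> pd.DataFrame:
    """Parse a TSV report back into a DataFrame (``n/a`` becomes NaN)."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["n/a"])
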