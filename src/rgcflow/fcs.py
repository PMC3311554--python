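"""Minimal read-only FCS 3.0/3.1 list-mode parser.

Covers the subset of the standard that benchtop three-colour instruments
actually emit: ``$MODE L`` list mode, ``$DATATYPE`` F (float32), D (float64)
or I (unsigned integers of ``$PnB`` bits), both byte orders, and the
``$PnE`` log-amplification transform (values are returned linear-scale).
Anything outside that subset raises :class:`FCSParseError` with offset
context rather than guessing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class FCSParseError(ValueError):
    """Malformed or unsupported FCS content."""


def _read_offset(header: bytes, start: int, end: int, label: str) -> int:
    raw = header[start:end].strip()
    try:
        return int(raw or b"0")
    except ValueError as exc:
        raise FCSParseError(
            f"non-numeric {label} offset {raw!r} at header bytes {start}-{end}"
        ) from exc


def _parse_text_segment(blob: bytes, begin: int, end: int) -> dict[str, str]:
    if end <= begin or end > len(blob):
        raise FCSParseError(f"TEXT segment bounds [{begin}, {end}] out of range")
    seg = blob[begin : end + 1]
    delim = seg[:1]
    if not delim:
        raise FCSParseError("empty TEXT segment")
    # Split on the delimiter; the standard's escaped-delimiter convention
    # (doubled delimiter inside a value) is rare in practice and unsupported.
    parts = seg[1:].split(delim)
    if parts and parts[-1] in (b"", b" "):
        parts = parts[:-1]
    if len(parts) % 2:
        raise FCSParseError(
            f"TEXT segment at byte {begin} holds an odd number of tokens"
        )
    return {
        parts[i].decode("latin-1").strip().upper(): parts[i + 1].decode("latin-1").strip()
        for i in range(0, len(parts), 2)
    }


def read_fcs(path: str | Path) -> pd.DataFrame:
    """Read an FCS 3.0/3.1 file into a DataFrame of linear-scale values.

    Columns are the instrument channel names ($PnN) in acquisition order;
    channel-name canonicalisation is the caller's concern.
    """
    blob = Path(path).read_bytes()
    if len(blob) < 58:
        raise FCSParseError(f"file is {len(blob)} bytes, shorter than an FCS header")
    version = blob[:6].decode("latin-1", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FCSParseError(f"unsupported FCS version {version!r} at byte 0")

    text_begin = _read_offset(blob, 10, 18, "TEXT begin")
    text_end = _read_offset(blob, 18, 26, "TEXT end")
    data_begin = _read_offset(blob, 26, 34, "DATA begin")
    data_end = _read_offset(blob, 34, 42, "DATA end")
    text = _parse_text_segment(blob, text_begin, text_end)

    if data_begin == 0:
        data_begin = int(text.get("$BEGINDATA", "0"))
        data_end = int(text.get("$ENDDATA", "0"))
    if data_begin == 0 or data_end <= data_begin:
        raise FCSParseError("DATA segment offsets missing from header and TEXT")

    mode = text.get("$MODE", "L").upper()
    if mode != "L":
        raise FCSParseError(f"only list mode is supported, got $MODE={mode}")
    try:
        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
    except KeyError as exc:
        raise FCSParseError(f"required keyword {exc.args[0]} missing") from exc
    datatype = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    names, dtypes, decades, scales, ranges = [], [], [], [], []
    for i in range(1, n_par + 1):
        names.append(text.get(f"$P{i}N", f"P{i}"))
        bits = int(text.get(f"$P{i}B", "32"))
        if datatype == "F":
            if bits != 32:
                raise FCSParseError(f"$P{i}B={bits} invalid for $DATATYPE F")
            dtypes.append(np.dtype(f"{endian}f4"))
        elif datatype == "D":
            if bits != 64:
                raise FCSParseError(f"$P{i}B={bits} invalid for $DATATYPE D")
            dtypes.append(np.dtype(f"{endian}f8"))
        elif datatype == "I":
            if bits not in (8, 16, 32):
                raise FCSParseError(f"unsupported integer width $P{i}B={bits}")
            dtypes.append(np.dtype(f"{endian}u{bits // 8}"))
        else:
            raise FCSParseError(f"unsupported $DATATYPE {datatype!r}")
        dec, zero = (float(v) for v in text.get(f"$P{i}E", "0,0").split(","))
        decades.append(dec)
        scales.append(zero)
        ranges.append(float(text.get(f"$P{i}R", "1024")))

    raw = blob[data_begin : data_end + 1]
    row = np.dtype({"names": names, "formats": dtypes})
    need = row.itemsize * n_tot
    if len(raw) < need:
        raise FCSParseError(
            f"DATA segment holds {len(raw)} bytes at byte {data_begin}, "
            f"need {need} for {n_tot} events x {n_par} parameters"
        )
    events = np.frombuffer(raw[:need], dtype=row)

    out = {}
    for name, dec, zero, rng in zip(names, decades, scales, ranges):
        col = events[name].astype(float)
        if dec != 0.0:
            # Log-amplified channel: stored value is a fraction of the
            # display range; decode to linear intensity.
            col = (zero if zero > 0 else 1.0) * 10.0 ** (dec * col / rng)
        out[name] = col
    return pd.DataFrame(out)
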