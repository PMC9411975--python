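"""Minimal FCS (Flow Cytometry Standard) file reader and writer.

Supports reading FCS 2.0/3.0/3.1 files with DATATYPE F (float32),
D (float64) or I (unsigned integers of uniform bit width) in list mode,
and writing FCS 3.0 files with float32 data.  Only the keywords the
preprocessing pipeline relies on are interpreted: data offsets, byte
order, parameter names ($PnN), stains ($PnS), bit widths and ranges.
"""

from __future__ import annotations

import os
import struct
from typing import Sequence

import numpy as np

__all__ = ["read_fcs_file", "write_fcs_file", "FcsReadError"]


class FcsReadError(RuntimeError):
    """Raised when a file cannot be parsed as FCS."""


def _parse_text_segment(raw: bytes) -> dict:
    if not raw:
        raise FcsReadError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    # double-delimiter escapes are rare in instrument files; split and
    # re-join empty fields produced by escaped delimiters
    parts = body.split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    fields: list[bytes] = []
    i = 0
    while i < len(parts):
        if parts[i] == b"" and fields:
            # escaped delimiter inside previous field
            fields[-1] += delim + (parts[i + 1] if i + 1 < len(parts) else b"")
            i += 2
        else:
            fields.append(parts[i])
            i += 1
    kv = {}
    for k, v in zip(fields[::2], fields[1::2]):
        kv[k.decode("latin-1").strip().upper()] = v.decode("latin-1").strip()
    return kv

def read_fcs_file(path: str | os.PathLike) -> tuple[np.ndarray, list[str], list[str], dict]:
    """Read one FCS file.

    Returns ``(data, channel_names, marker_names, text)`` where *data* is an
    events x channels float64 array, *channel_names* holds $PnN, and
    *marker_names* holds $PnS (empty string where absent).
    """
    path = os.fspath(path)
    try:
        with open(path, "rb") as fh:
            header = fh.read(58)
            if len(header) < 58 or not header[:3] == b"FCS":
                raise FcsReadError(f"{path}: not an FCS file")
            text_start = int(header[10:18])
            text_end = int(header[18:26])
            data_start = int(header[26:34] or b"0")
            data_end = int(header[34:42] or b"0")
            fh.seek(text_start)
            text = _parse_text_segment(fh.read(text_end - text_start + 1))
            if data_start == 0 or data_end == 0:
                data_start = int(text.get("$BEGINDATA", 0))
                data_end = int(text.get("$ENDDATA", 0))
            n_par = int(text["$PAR"])
            n_tot = int(text["$TOT"])
            dtype_code = text.get("$DATATYPE", "F").upper()
            byteord = text.get("$BYTEORD", "1,2,3,4")
            little = byteord.startswith("1")
            order = "<" if little else ">"
            if dtype_code == "F":
                dt = np.dtype(order + "f4")
            elif dtype_code == "D":
                dt = np.dtype(order + "f8")
            elif dtype_code == "I":
                bits = {int(text[f"$P{i}B"]) for i in range(1, n_par + 1)}
                if len(bits) != 1 or bits.pop() not in (8, 16, 32):
                    raise FcsReadError(f"{path}: unsupported integer layout")
                nbytes = int(text["$P1B"]) // 8
                dt = np.dtype(f"{order}u{nbytes}")
            else:
                raise FcsReadError(f"{path}: unsupported $DATATYPE {dtype_code}")
            fh.seek(data_start)
            raw = fh.read(data_end - data_start + 1)
    except (OSError, ValueError, KeyError) as exc:
        raise FcsReadError(f"cannot read FCS file {path}: {exc}") from exc
    n_expected = n_par * n_tot
    arr = np.frombuffer(raw, dtype=dt, count=n_expected)
    if arr.size < n_expected:
        raise FcsReadError(f"{path}: truncated DATA segment")
    data = arr.astype(np.float64).reshape(n_tot, n_par) if n_tot else np.empty((0, n_par))
    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    stains = [text.get(f"$P{i}S", "") for i in range(1, n_par + 1)]
    return data, names, stains, text


def write_fcs_file(
    path: str | os.PathLike,
    data: np.ndarray,
    channel_names: Sequence[str],
    marker_names: Sequence[str] | None = None,
) -> None:
    """Write an events x channels matrix as an FCS 3.0 file (float32, little endian)."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2:
        raise ValueError("data must be 2-dimensional (events x channels)")
    n_tot, n_par = data.shape
    if len(channel_names) != n_par:
        raise ValueError("channel_names length must match number of columns")
    if marker_names is None:
        marker_names = [""] * n_par
    ranges = np.nanmax(data, axis=0) if n_tot else np.ones(n_par)

    kv: list[tuple[str, str]] = [
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
        ("$NEXTDATA", "0"),
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
    ]
    for i in range(n_par):
        kv.append((f"$P{i + 1}N", str(channel_names[i])))
        if marker_names[i]:
            kv.append((f"$P{i + 1}S", str(marker_names[i])))
        kv.append((f"$P{i + 1}B", "32"))
        kv.append((f"$P{i + 1}E", "0,0"))
        kv.append((f"$P{i + 1}R", str(int(max(float(ranges[i]), 1)) + 1)))

    delim = "/"
    # data offsets are written with fixed width so TEXT length is stable
    def render(begin: str, end: str) -> bytes:
        fields = kv + [("$BEGINDATA", begin), ("$ENDDATA", end)]
        return (delim + delim.join(f"{k}{delim}{v}" for k, v in fields) + delim).encode("latin-1")

    width = 12
    text = render("0" * width, "0" * width)
    text_start = 58
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + data.nbytes - 1 if data.nbytes else data_start
    text = render(str(data_start).zfill(width), str(data_end).zfill(width))

    def hfield(x: int) -> bytes:
        s = str(x)
        return (s if len(s) <= 8 else "0").rjust(8).encode("ascii")

    header = b"FCS3.0    " + b"".join(
        hfield(x) for x in (text_start, text_end, data_start, data_end, 0, 0)
    )
    payload = data.astype("<f4").tobytes()
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload if payload else struct.pack("<f", 0.0)[:0])
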