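"""Minimal FCS 3.0/3.1 reading and FCS 3.1 writing.

Covers the subset of the standard this package needs: single data set,
list mode, float32 data, TEXT-segment keywords ($PnN/$PnS channel
names, $TOT event count, offsets).  Integer data ($DATATYPE I) with
common bit widths is read as well.  Written files round-trip through
the reader bit-exactly.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

_DELIM = "/"
_HEADER_LEN = 58


class FcsFormatError(ValueError):
    """Malformed or unsupported FCS content."""


def write_fcs(
    path: str | Path,
    events: pd.DataFrame,
    extra_keywords: dict[str, str] | None = None,
) -> None:
    """Write an events x channels frame as an FCS 3.1 file (float32)."""
    data = np.ascontiguousarray(events.to_numpy(dtype="<f4"))
    n_events, n_par = data.shape
    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(events.columns, start=1):
        kw[f"$P{i}N"] = str(name)
        kw[f"$P{i}S"] = str(name)
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(max(1, np.ceil(np.nanmax(data[:, i - 1]) if n_events else 1))))
    for k, v in (extra_keywords or {}).items():
        if _DELIM in k or _DELIM in str(v):
            raise FcsFormatError(f"keyword {k!r} contains the delimiter")
        kw[k] = str(v)

    # fixed-width offsets so TEXT length is stable while we fill them in
    kw["$BEGINDATA"] = "%010d" % 0
    kw["$ENDDATA"] = "%010d" % 0

    def render() -> bytes:
        parts = [_DELIM]
        for k, v in kw.items():
            parts.append(f"{k}{_DELIM}{v}{_DELIM}")
        return "".join(parts).encode("ascii")

    text = render()
    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + data.nbytes - 1 if data.nbytes else 0
    kw["$BEGINDATA"] = "%010d" % data_begin
    kw["$ENDDATA"] = "%010d" % data_end
    text = render()

    def hdr_field(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # too large for the header: TEXT keywords carry it
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        hdr_field(v)
        for v in (
            text_begin,
            text_end,
            data_begin if data_begin <= 99999999 else 0,
            data_end if data_end <= 99999999 else 0,
            0,
            0,
        )
    )
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def _parse_text(segment: bytes) -> dict[str, str]:
    if not segment:
        raise FcsFormatError("empty TEXT segment")
    delim = segment[0:1].decode("latin-1")
    body = segment.decode("latin-1")
    parts = body.split(delim)[1:]
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2:
        raise FcsFormatError("odd number of TEXT tokens")
    return {parts[i].strip(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read one FCS data set: (events frame, TEXT keywords).

    Channel columns are named from $PnS, falling back to $PnN.  A $TOT
    that disagrees with the decodable event count is an error naming
    both numbers.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_LEN:
        raise FcsFormatError("file shorter than an FCS header")
    version = raw[:6].decode("latin-1", errors="replace")
    if not version.startswith("FCS3"):
        raise FcsFormatError(f"unsupported FCS version {version!r}")

    def hdr_int(i: int) -> int:
        field = raw[10 + 8 * i : 18 + 8 * i].decode("latin-1").strip()
        try:
            return int(field) if field else 0
        except ValueError as e:
            raise FcsFormatError(f"bad header offset field {field!r}") from e

    text_begin, text_end = hdr_int(0), hdr_int(1)
    if not (0 < text_begin <= text_end < len(raw)):
        raise FcsFormatError("TEXT segment offsets out of range")
    kw = _parse_text(raw[text_begin : text_end + 1])

    def need(key: str) -> str:
        if key not in kw:
            raise FcsFormatError(f"required keyword {key} missing")
        return kw[key]

    n_par = int(need("$PAR"))
    n_tot = int(need("$TOT"))
    datatype = need("$DATATYPE").upper()
    byteord = need("$BYTEORD")
    endian = "<" if byteord.startswith("1") else ">"
    if kw.get("$MODE", "L").upper() != "L":
        raise FcsFormatError("only list mode ($MODE L) is supported")

    data_begin = int(kw.get("$BEGINDATA", "0") or 0) or hdr_int(2)
    data_end = int(kw.get("$ENDDATA", "0") or 0) or hdr_int(3)
    if data_begin <= 0:
        raise FcsFormatError("no DATA segment offsets")
    blob = raw[data_begin : data_end + 1]

    widths = {int(b) for i in range(1, n_par + 1) for b in [kw.get(f"$P{i}B", "32")]}
    if len(widths) != 1:
        raise FcsFormatError("mixed parameter bit widths unsupported")
    width = widths.pop()
    if datatype == "F":
        if width != 32:
            raise FcsFormatError("$DATATYPE F requires 32-bit parameters")
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
    elif datatype == "I":
        if width not in (16, 32):
            raise FcsFormatError(f"unsupported integer width {width}")
        dtype = np.dtype(endian + ("u2" if width == 16 else "u4"))
    else:
        raise FcsFormatError(f"unsupported $DATATYPE {datatype!r}")

    n_decodable = len(blob) // (dtype.itemsize * n_par)
    if n_decodable != n_tot:
        raise FcsFormatError(
            f"$TOT={n_tot} but {n_decodable} events decodable from the DATA segment"
        )
    arr = np.frombuffer(blob[: n_tot * n_par * dtype.itemsize], dtype=dtype)
    mat = arr.reshape(n_tot, n_par).astype(float)
    names = [
        kw.get(f"$P{i}S") or kw.get(f"$P{i}N") or f"P{i}" for i in range(1, n_par + 1)
    ]
    return pd.DataFrame(mat, columns=names), kw
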