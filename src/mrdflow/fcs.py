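"""Minimal FCS 3.0/3.1 reader and writer.

Covers the subset of the standard this package needs: list-mode (``$MODE L``)
data in float (``$DATATYPE F``/``D``) or unsigned integer (``I``) encoding,
single data set, channel names from ``$PnS`` (stain) falling back to ``$PnN``
(short name).  Spillover/compensation keywords are ignored: events are
assumed compensated upstream.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

HEADER_LEN = 58


class FCSError(IOError):
    """File is not a readable FCS 3.0/3.1 list-mode data set."""


def _read_segment_offsets(header: bytes) -> dict[str, int]:
    version = header[0:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise FCSError(f"unsupported FCS version {version!r}")
    fields = [header[10 + 8 * i: 18 + 8 * i] for i in range(6)]
    try:
        nums = [int(f.decode("ascii").strip() or "0") for f in fields]
    except ValueError as exc:  # pragma: no cover - malformed header
        raise FCSError("malformed FCS header offsets") from exc
    return {
        "text_begin": nums[0],
        "text_end": nums[1],
        "data_begin": nums[2],
        "data_end": nums[3],
    }


def _parse_text(raw: bytes) -> dict[str, str]:
    delim = raw[0:1].decode("latin-1")
    body = raw[1:].decode("latin-1")
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 == 1:
        parts = parts[:-1]
    return {parts[i].strip(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read one FCS data set; returns (events dataframe, TEXT keywords).

    Column names prefer ``$PnS`` over ``$PnN``.
    """
    blob = Path(path).read_bytes()
    if len(blob) < HEADER_LEN:
        raise FCSError("file too short for an FCS header")
    off = _read_segment_offsets(blob[:HEADER_LEN])
    text = _parse_text(blob[off["text_begin"]: off["text_end"] + 1])

    data_begin = off["data_begin"] or int(text.get("$BEGINDATA", "0"))
    data_end = off["data_end"] or int(text.get("$ENDDATA", "0"))
    if data_begin <= 0 or data_end <= data_begin:
        raise FCSError("missing DATA segment offsets")

    mode = text.get("$MODE", "L")
    if mode != "L":
        raise FCSError(f"only list mode supported (got $MODE {mode})")
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text.get("$DATATYPE", "F")
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    bits = [int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if len(set(bits)) != 1:
        raise FCSError("mixed per-parameter bit widths are not supported")
    nbytes = bits[0] // 8
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        dtype = np.dtype(f"{endian}u{nbytes}")
    else:
        raise FCSError(f"unsupported $DATATYPE {datatype}")
    if datatype in ("F", "D") and dtype.itemsize != nbytes:
        raise FCSError(f"$PnB {bits[0]} inconsistent with $DATATYPE {datatype}")

    raw = blob[data_begin: data_end + 1]
    expected = n_par * n_tot * dtype.itemsize
    if len(raw) < expected:
        raise FCSError("DATA segment shorter than $PAR * $TOT events")
    values = np.frombuffer(raw[:expected], dtype=dtype).reshape(n_tot, n_par)
    names = [
        text.get(f"$P{i}S") or text.get(f"$P{i}N", f"P{i}")
        for i in range(1, n_par + 1)
    ]
    return pd.DataFrame(np.asarray(values, dtype=np.float64), columns=names), text


def write_fcs(path: str | Path, df: pd.DataFrame) -> None:
    """Write a dataframe as a single FCS 3.1 list-mode data set.

    Float32 storage, little endian, ``$PnN`` = ``$PnS`` = column name.
    Intended for interoperability of simulated samples with external flow
    software; lossless up to float32 precision.
    """
    values = np.ascontiguousarray(df.to_numpy(dtype=np.float32))
    n_tot, n_par = values.shape
    delim = "/"

    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BEGINDATA", "%012d"),
        ("$ENDDATA", "%012d"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
    ]
    for i, name in enumerate(df.columns, start=1):
        if delim in str(name):
            raise FCSError(f"channel name {name!r} contains the delimiter {delim!r}")
        rng = float(np.nanmax(values[:, i - 1])) if n_tot else 0.0
        keywords += [
            (f"$P{i}N", str(name)),
            (f"$P{i}S", str(name)),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(max(rng, 1.0)) + 1)),
        ]

    def render(data_begin: int, data_end: int) -> bytes:
        parts = [delim]
        for key, val in keywords:
            if val == "%012d":
                val = "%012d" % (data_begin if key == "$BEGINDATA" else data_end)
            parts.append(f"{key}{delim}{val}{delim}")
        return "".join(parts).encode("latin-1")

    # fixed-width data offsets make the TEXT length independent of the values
    text = render(0, 0)
    text_begin = HEADER_LEN
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + values.nbytes - 1
    text = render(data_begin, data_end)

    header = b"FCS3.1    " + b"".join(
        ("%8d" % n).encode("ascii")
        for n in (text_begin, text_end, data_begin, data_end, 0, 0)
    )
    assert len(header) == HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(values.tobytes())
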