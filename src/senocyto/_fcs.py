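"""Minimal FCS 3.1 codec (single data segment, list mode).

Supports the common Helios-style layout: one TEXT segment, one DATA segment,
$DATATYPE F (float32), D (float64) or I (unsigned integer), common byte
orders, $PnS as the stain/marker name with $PnN as the channel (metal) name.
Spillover matrices, multi-dataset files and analysis segments are out of
scope.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_fcs", "write_fcs", "FCSFormatError"]


class FCSFormatError(ValueError):
    pass


_DELIM = "/"


def _escape(value: str) -> str:
    return value.replace(_DELIM, _DELIM * 2)


def write_fcs(
    path: str | Path,
    data: np.ndarray,
    channel_names: list[str],
    marker_names: list[str] | None = None,
) -> Path:
    """Write events x channels float data as FCS 3.1 (float32, little-endian)."""
    path = Path(path)
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2:
        raise FCSFormatError("data must be 2-D (events x channels)")
    n_events, n_chan = data.shape
    if n_chan != len(channel_names):
        raise FCSFormatError("channel_names length does not match data")
    marker_names = marker_names or channel_names

    keywords: list[tuple[str, str]] = [
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_chan)),
        ("$TOT", str(n_events)),
        ("$NEXTDATA", "0"),
    ]
    for i, (name, stain) in enumerate(zip(channel_names, marker_names), start=1):
        keywords += [
            (f"$P{i}N", name),
            (f"$P{i}S", stain),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(max(1.0, float(data[:, i - 1].max(initial=0.0)) + 1)))),
        ]

    # Assemble TEXT with placeholder offsets first, then patch: offsets are
    # written into fixed-width fields so the segment length does not change.
    def render_text(begin_data: int, end_data: int) -> bytes:
        parts = [_DELIM]
        kv = keywords + [
            ("$BEGINDATA", f"{begin_data:>12d}"),
            ("$ENDDATA", f"{end_data:>12d}"),
            ("$BEGINANALYSIS", "0"),
            ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"),
            ("$ENDSTEXT", "0"),
        ]
        for key, value in kv:
            # FCS forbids empty keyword values; a single space stands in
            parts.append(f"{_escape(key)}{_DELIM}{_escape(value) or ' '}{_DELIM}")
        return "".join(parts).encode("utf-8")

    header_len = 58  # "FCS3.1    " + 8 offset fields of 8 chars
    text = render_text(0, 0)
    text_begin = header_len
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + data.nbytes - 1 if n_events else 0
    text = render_text(data_begin if n_events else 0, data_end)

    header = (
        b"FCS3.1    "
        + f"{text_begin:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + (f"{data_begin:>8d}".encode() if n_events and data_end < 10**8 else b"       0")
        + (f"{data_end:>8d}".encode() if n_events and data_end < 10**8 else b"       0")
        + b"       0"
        + b"       0"
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())
    return path


def _parse_text(raw: bytes) -> dict[str, str]:
    text = raw.decode("utf-8", errors="replace")
    delim = text[0]
    body = text[1:]
    # Double delimiters escape a literal delimiter inside a value.
    fields = body.replace(delim * 2, "\x00").split(delim)
    fields = [f.replace("\x00", delim) for f in fields]
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) % 2:
        fields = fields[:-1]
    return {fields[i].strip(): fields[i + 1] for i in range(0, len(fields), 2)}


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read an FCS file -> (events x channels float64, channel names, marker names)."""
    blob = Path(path).read_bytes()
    if len(blob) < 58 or not blob[:3] == b"FCS":
        raise FCSFormatError(f"{path}: not an FCS file")

    def offset(lo: int, hi: int) -> int:
        s = blob[lo:hi].decode("ascii", errors="replace").strip()
        return int(s) if s else 0

    text_begin, text_end = offset(10, 18), offset(18, 26)
    kw = _parse_text(blob[text_begin : text_end + 1])

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype_code = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"

    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    stains = [kw.get(f"$P{i}S", names[i - 1]) for i in range(1, n_par + 1)]
    bits = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]

    data_begin = offset(26, 34) or int(kw.get("$BEGINDATA", "0"))
    data_end = offset(34, 42) or int(kw.get("$ENDDATA", "0"))
    if n_tot == 0:
        return np.zeros((0, n_par)), names, stains
    raw = blob[data_begin : data_end + 1]

    if dtype_code == "F":
        arr = np.frombuffer(raw, dtype=f"{order}f4", count=n_tot * n_par)
    elif dtype_code == "D":
        arr = np.frombuffer(raw, dtype=f"{order}f8", count=n_tot * n_par)
    elif dtype_code == "I":
        if len(set(bits)) != 1 or bits[0] not in (16, 32, 64):
            raise FCSFormatError("integer data requires uniform $PnB of 16/32/64")
        arr = np.frombuffer(raw, dtype=f"{order}u{bits[0] // 8}", count=n_tot * n_par)
    else:
        raise FCSFormatError(f"unsupported $DATATYPE {dtype_code!r}")
    return arr.reshape(n_tot, n_par).astype(np.float64), names, stains
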