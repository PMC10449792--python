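"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Supports the subset of the standard produced by CyTOF-style acquisition
software and needed for import of pre-gated event data: list mode
(``$MODE L``), floating-point data (``$DATATYPE F`` or ``D``), uniform
bit width per parameter, little- or big-endian byte order.  Integer data,
analysis segments and multi-dataset files are out of scope.  The writer
exists so synthetic fixtures can be produced at run time.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_DELIM = "/"


def read_fcs(path) -> tuple[list[str], np.ndarray, dict]:
    """Read one dataset from an FCS 3.0/3.1 file.

    Returns ``(channel_names, events_x_channels, keywords)``.  Channel
    names prefer the stain name ``$PnS`` and fall back to ``$PnN``.
    """
    raw = Path(path).read_bytes()
    version = raw[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"unsupported FCS version {version!r}")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_begin : text_end + 1].decode("latin-1")
    delim = text[0]
    # empty keyword values (two consecutive delimiters) are not supported;
    # standard escaping (doubled delimiter) is not needed for our writers.
    parts = text.strip(delim).split(delim)
    if len(parts) % 2 != 0:
        raise ValueError("malformed FCS TEXT segment")
    keywords = {k.strip(): v for k, v in zip(parts[::2], parts[1::2])}

    if keywords.get("$MODE", "L").upper() != "L":
        raise ValueError("only list-mode ($MODE L) FCS files are supported")
    datatype = keywords.get("$DATATYPE", "F").upper()
    if datatype not in ("F", "D"):
        raise ValueError(f"unsupported $DATATYPE {datatype!r} (need F or D)")
    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    byteord = keywords.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    dtype = np.dtype(("<" if little else ">") + ("f4" if datatype == "F" else "f8"))

    data_begin = int(keywords.get("$BEGINDATA") or raw[26:34])
    data_end = int(keywords.get("$ENDDATA") or raw[34:42])
    buf = raw[data_begin : data_end + 1]
    expected = n_par * n_tot * dtype.itemsize
    if len(buf) < expected:
        raise ValueError("FCS DATA segment shorter than $PAR*$TOT events")
    matrix = np.frombuffer(buf[:expected], dtype=dtype).reshape(n_tot, n_par)

    names = []
    for i in range(1, n_par + 1):
        name = keywords.get(f"$P{i}S") or keywords.get(f"$P{i}N") or f"P{i}"
        names.append(name)
    return names, matrix.astype(np.float64), keywords


def write_fcs(path, channel_names, matrix, extra_keywords: dict | None = None) -> None:
    """Write a minimal FCS 3.0 list-mode float32 file (testing/export aid)."""
    matrix = np.asarray(matrix, dtype="<f4")
    n_tot, n_par = matrix.shape
    if n_par != len(channel_names):
        raise ValueError("channel_names length does not match matrix width")
    data = matrix.tobytes()

    keywords = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(channel_names, start=1):
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}S"] = str(name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(1.0, float(np.nanmax(matrix[:, i - 1], initial=1.0)))) + 1)
    if extra_keywords:
        keywords.update({str(k): str(v) for k, v in extra_keywords.items()})

    header_len = 58
    # iterate because BEGINDATA/ENDDATA values change their own width
    begin_data = header_len + 1024
    for _ in range(8):
        keywords["$BEGINDATA"] = str(begin_data)
        keywords["$ENDDATA"] = str(begin_data + len(data) - 1)
        text = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in keywords.items()) + _DELIM
        text_bytes = text.encode("latin-1")
        new_begin = header_len + len(text_bytes)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    text_begin = header_len
    text_end = text_begin + len(text_bytes) - 1
    data_begin = begin_data
    data_end = data_begin + len(data) - 1

    header = b"FCS3.0    "
    header += f"{text_begin:8d}{text_end:8d}".encode("ascii")
    header += f"{data_begin:8d}{data_end:8d}".encode("ascii")
    header += f"{0:8d}{0:8d}".encode("ascii")  # no ANALYSIS segment
    assert len(header) == header_len, len(header)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_bytes)
        fh.write(data)
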