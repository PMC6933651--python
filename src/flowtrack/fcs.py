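"""Minimal reader (and writer, for round-trip testing) of FCS event files.

Supports FCS 2.0/3.0/3.1 list-mode files with $DATATYPE F (float32),
D (float64) or I (unsigned integers of 8/16/32/64 bits), both byte
orders.  This covers the files exported by common cytometry software;
analysis-segment contents and spillover/compensation keywords are
ignored (compensated data should be exported upstream).
"""

from __future__ import annotations

import os
import struct
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .dataset import BlockKey, DataValidationError, TimeSeriesDataset


class FCSFormatError(ValueError):
    """The file does not parse as a supported FCS file."""


_SUPPORTED_VERSIONS = ("FCS2.0", "FCS3.0", "FCS3.1")


def _parse_text_segment(raw: bytes) -> Dict[str, str]:
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    parts = raw.decode("latin-1").strip(delim).split(delim)
    if len(parts) % 2:
        parts = parts[:-1]
    return {parts[i].strip().upper(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(path: str, channels: Optional[Sequence[str]] = None) -> Tuple[np.ndarray, List[str]]:
    """Read event data from one FCS file.

    Returns ``(events, channel_names)`` where ``events`` has shape
    (n_events, n_selected_channels).  If ``channels`` is given, columns
    are selected and ordered by those $PnN names.
    """
    with open(path, "rb") as fh:
        header = fh.read(58)
        if len(header) < 58:
            raise FCSFormatError(f"{path}: truncated header")
        version = header[0:6].decode("latin-1")
        if version not in _SUPPORTED_VERSIONS:
            raise FCSFormatError(f"{path}: unsupported version {version!r}")

        def _offset(a: int, b: int) -> int:
            text = header[a:b].decode("latin-1").strip()
            return int(text) if text else 0

        text_begin, text_end = _offset(10, 18), _offset(18, 26)
        data_begin, data_end = _offset(26, 34), _offset(34, 42)
        fh.seek(text_begin)
        kw = _parse_text_segment(fh.read(text_end - text_begin + 1))

        if data_begin == 0:
            data_begin = int(kw.get("$BEGINDATA", "0"))
        if data_end == 0:
            data_end = int(kw.get("$ENDDATA", "0"))
        if data_begin <= 0 or data_end < data_begin:
            raise FCSFormatError(f"{path}: missing data segment offsets")

        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        datatype = kw.get("$DATATYPE", "F").upper()
        mode = kw.get("$MODE", "L").upper()
        if mode != "L":
            raise FCSFormatError(f"{path}: only list mode ($MODE L) is supported")
        byteord = kw.get("$BYTEORD", "1,2,3,4")
        little = byteord.startswith("1")
        endian = "<" if little else ">"

        names = []
        bits = []
        for i in range(1, n_par + 1):
            names.append(kw.get(f"$P{i}N", f"P{i}").strip())
            bits.append(int(kw.get(f"$P{i}B", "32")))

        if datatype == "F":
            if any(b != 32 for b in bits):
                raise FCSFormatError(f"{path}: $DATATYPE F requires 32-bit parameters")
            dtype = np.dtype(f"{endian}f4")
        elif datatype == "D":
            if any(b != 64 for b in bits):
                raise FCSFormatError(f"{path}: $DATATYPE D requires 64-bit parameters")
            dtype = np.dtype(f"{endian}f8")
        elif datatype == "I":
            widths = set(bits)
            if len(widths) != 1 or bits[0] not in (8, 16, 32, 64):
                raise FCSFormatError(
                    f"{path}: $DATATYPE I needs uniform 8/16/32/64-bit parameters"
                )
            dtype = np.dtype(f"{endian}u{bits[0] // 8}")
        else:
            raise FCSFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

        fh.seek(data_begin)
        need = n_tot * n_par * dtype.itemsize
        raw = fh.read(need)
        if len(raw) < need:
            raise FCSFormatError(f"{path}: data segment shorter than $TOT*$PAR events")
        events = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par).astype(float)

    if channels is not None:
        idx = []
        for ch in channels:
            if ch not in names:
                raise FCSFormatError(f"{path}: channel '{ch}' not present (has {names})")
            idx.append(names.index(ch))
        return events[:, idx], [names[i] for i in idx]
    return events, names


def write_fcs(path: str, events: np.ndarray, channel_names: Sequence[str]) -> None:
    """Write a minimal FCS3.1 list-mode file ($DATATYPE F, little-endian).

    Intended for fixtures and interchange, not as a full exporter.
    """
    events = np.asarray(events, dtype="<f4")
    n_tot, n_par = events.shape
    if n_par != len(channel_names):
        raise ValueError("channel_names length must match event columns")

    kw = {
        "$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par), "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(channel_names, start=1):
        kw[f"$P{i}N"] = str(name)
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = "262144"

    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in kw.items()) + delim
    text_begin = 58
    text_bytes = text.encode("latin-1")
    data_begin = text_begin + len(text_bytes)
    data_end = data_begin + events.nbytes - 1
    header = (
        "FCS3.1    "
        + f"{text_begin:>8d}{text_begin + len(text_bytes) - 1:>8d}"
        + f"{data_begin:>8d}{data_end:>8d}"
        + f"{0:>8d}{0:>8d}"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("latin-1"))
        fh.write(text_bytes)
        fh.write(events.tobytes())


def read_fcs_series(
    manifest: Union[str, Dict],
    channels: Optional[Sequence[str]] = None,
    asinh_cofactor: Optional[float] = None,
) -> TimeSeriesDataset:
    """Assemble a TimeSeriesDataset from a manifest of FCS files.

    The manifest (a dict or a YAML file path) maps (time, case) pairs to
    files::

        channels: [CD4, CD8]          # optional here if passed as an argument
        asinh_cofactor: 5             # optional; x -> asinh(x / cofactor)
        files:
          - {time: 1, case: 1, path: t1_case1.fcs}
          - {time: 2, case: 1, path: t2_case1.fcs}

    Channel order is harmonised across files by $PnN name, so listing
    channels in a different order in each file is immaterial.
    """
    if isinstance(manifest, str):
        base = os.path.dirname(os.path.abspath(manifest))
        with open(manifest) as fh:
            manifest = yaml.safe_load(fh)
    else:
        base = os.getcwd()
    if not isinstance(manifest, dict) or "files" not in manifest:
        raise DataValidationError("manifest must be a mapping with a 'files' list")
    channels = channels or manifest.get("channels")
    if asinh_cofactor is None:
        asinh_cofactor = manifest.get("asinh_cofactor")

    blocks: Dict[BlockKey, np.ndarray] = {}
    names_ref: Optional[List[str]] = None
    for entry in manifest["files"]:
        t, d = int(entry["time"]), int(entry["case"])
        fpath = entry["path"]
        if not os.path.isabs(fpath):
            fpath = os.path.join(base, fpath)
        events, names = read_fcs(fpath, channels)
        if channels is None:
            if names_ref is None:
                names_ref = names
            elif names != names_ref:
                raise FCSFormatError(
                    f"{fpath}: channel set {names} differs from {names_ref}; "
                    "pass an explicit channel list"
                )
        if asinh_cofactor:
            events = np.arcsinh(events / float(asinh_cofactor))
        blocks[(t, d)] = events
    final_names = list(channels) if channels is not None else names_ref
    return TimeSeriesDataset(blocks, marker_names=final_names)
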