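"""Minimal read-only mzML support for centroided peak lists.

Only the pieces the pipeline needs: m/z and intensity binary data arrays
(32/64-bit floats, optionally zlib-compressed) from each spectrum element.
"""

from __future__ import annotations

import base64
import struct
import zlib
import xml.etree.ElementTree as ET
from pathlib import Path

_NS = "{http://psi.hupo.org/ms/mzml}"

_ACC_MZ = "MS:1000514"
_ACC_INTENSITY = "MS:1000515"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _decode_array(elem) -> tuple[str | None, list[float]]:
    kind = None
    fmt = "d"
    compressed = False
    for cv in elem.iter(f"{_NS}cvParam"):
        acc = cv.get("accession")
        if acc == _ACC_MZ:
            kind = "mz"
        elif acc == _ACC_INTENSITY:
            kind = "intensity"
        elif acc == _ACC_32BIT:
            fmt = "f"
        elif acc == _ACC_64BIT:
            fmt = "d"
        elif acc == _ACC_ZLIB:
            compressed = True
    binary = elem.find(f"{_NS}binary")
    if binary is None or not (binary.text or "").strip():
        return kind, []
    raw = base64.b64decode(binary.text.strip())
    if compressed:
        raw = zlib.decompress(raw)
    n = len(raw) // struct.calcsize(fmt)
    return kind, list(struct.unpack(f"<{n}{fmt}", raw))


def read_mzml_peaks(path: str | Path) -> list[tuple[float, float]]:
    """All (m/z, intensity) pairs across the spectra of an mzML file."""
    tree = ET.parse(path)
    peaks: list[tuple[float, float]] = []
    for spectrum in tree.iter(f"{_NS}spectrum"):
        mz, intensity = [], []
        for arr in spectrum.iter(f"{_NS}binaryDataArray"):
            kind, values = _decode_array(arr)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                intensity = values
        if len(mz) != len(intensity):
            raise ValueError(f"m/z and intensity array lengths differ in {path}")
        peaks.extend(zip(mz, intensity))
    return peaks
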