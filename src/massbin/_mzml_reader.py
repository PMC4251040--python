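"""Streaming mzML 1.1 reader.

Iterates ``<spectrum>`` elements with :mod:`lxml` and decodes the binary
data arrays (base64, 32/64-bit float, optionally zlib-compressed) guided by
their cvParam accessions.  Namespace-agnostic, so indexed and plain mzML
both parse.  Only the fields the data model needs are extracted: ms level,
scan start time (with its unit) and the m/z / intensity arrays.
"""

from __future__ import annotations

import base64
import zlib
from typing import Iterator

import numpy as np
from lxml import etree

# cvParam accessions (PSI-MS controlled vocabulary)
ACC_MS_LEVEL = "MS:1000511"
ACC_SCAN_START = "MS:1000016"
ACC_64BIT = "MS:1000523"
ACC_32BIT = "MS:1000521"
ACC_ZLIB = "MS:1000574"
ACC_NO_COMPRESSION = "MS:1000576"
ACC_MZ_ARRAY = "MS:1000514"
ACC_INTENSITY_ARRAY = "MS:1000515"


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _cvparams(elem) -> dict[str, dict]:
    out = {}
    for cv in elem:
        if _local(cv.tag) == "cvParam":
            out[cv.get("accession", "")] = dict(cv.attrib)
    return out


def _decode_array(bda) -> tuple[str, np.ndarray]:
    """Decode one binaryDataArray; returns (kind, values)."""
    dtype = "<f8"
    compressed = False
    kind = ""
    text = ""
    for child in bda.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == ACC_32BIT:
                dtype = "<f4"
            elif acc == ACC_64BIT:
                dtype = "<f8"
            elif acc == ACC_ZLIB:
                compressed = True
            elif acc == ACC_MZ_ARRAY:
                kind = "mz"
            elif acc == ACC_INTENSITY_ARRAY:
                kind = "intensity"
        elif name == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def iter_spectra(path: str) -> Iterator[dict]:
    """Yield one dict per spectrum: ms_level, rt_seconds, mz, intensity."""
    context = etree.iterparse(path, events=("end",), recover=False,
                              huge_tree=True)
    for _, elem in context:
        if _local(elem.tag) != "spectrum":
            continue
        ms_level = 1
        rt = None
        mz = np.empty(0)
        intensity = np.empty(0)
        params = _cvparams(elem)
        if ACC_MS_LEVEL in params:
            ms_level = int(params[ACC_MS_LEVEL].get("value", 1))
        for sub in elem.iter():
            name = _local(sub.tag)
            if name == "scan":
                scan_params = _cvparams(sub)
                if ACC_SCAN_START in scan_params:
                    p = scan_params[ACC_SCAN_START]
                    value = float(p.get("value", "nan"))
                    unit = p.get("unitName", "second")
                    rt = value * 60.0 if unit.startswith("min") else value
            elif name == "binaryDataArray":
                kind, values = _decode_array(sub)
                if kind == "mz":
                    mz = values
                elif kind == "intensity":
                    intensity = values
        yield {"ms_level": ms_level, "rt": rt, "mz": mz,
               "intensity": intensity}
        # free the subtree to keep memory flat on large files
        elem.clear()
        parent = elem.getparent()
        while parent is not None and elem.getprevious() is not None:
            del parent[0]
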