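"""Minimal serializers used by the synthetic exporter and the test suite.

Only what a reader needs is written: a bare-bones (non-indexed) mzML 1.1
document with uncompressed 64-bit little-endian arrays, and an ANDI-MS
netCDF-3 file with the canonical scan_index / point_count / mass_values /
intensity_values / scan_acquisition_time variables.  These are internal
helpers, not a public export surface.
"""

from __future__ import annotations

import base64
from xml.sax.saxutils import escape

import numpy as np

from .msdata_io import Run


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(
        np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/viewvc/obo/obo/ontology/phenotype/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="massbin" version="0.1.0"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="export">
      <processingMethod order="1" softwareRef="massbin">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
"""

_SPECTRUM_TEMPLATE = """      <spectrum index="{index}" id="scan={scan_no}" defaultArrayLength="{npts}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""


def write_mzml(run: Run, path: str) -> str:
    """Serialize a run as a minimal non-indexed mzML 1.1 document."""
    parts = [_MZML_HEADER]
    parts.append(f'  <run id="{escape(run.source_name or "run", {chr(34): "&quot;"})}" '
                 f'defaultInstrumentConfigurationRef="IC1">\n')
    parts.append(f'    <spectrumList count="{len(run.scans)}" '
                 f'defaultDataProcessingRef="export">\n')
    for i, scan in enumerate(run.scans):
        mz_b64 = _b64(scan.mz)
        int_b64 = _b64(scan.intensity)
        parts.append(_SPECTRUM_TEMPLATE.format(
            index=i, scan_no=i + 1, npts=scan.n_points,
            ms_level=scan.ms_level, rt=repr(float(scan.rt)),
            mz_len=len(mz_b64), mz_b64=mz_b64,
            int_len=len(int_b64), int_b64=int_b64))
    parts.append("    </spectrumList>\n  </run>\n</mzML>\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("".join(parts))
    return path


def write_andi_netcdf(run: Run, path: str) -> str:
    """Serialize a run as an ANDI-MS netCDF-3 classic file."""
    from scipy.io import netcdf_file

    counts = np.array([s.n_points for s in run.scans], dtype=np.int32)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.int32)
    total = int(counts.sum())
    mass = (np.concatenate([s.mz for s in run.scans if s.n_points])
            if total else np.empty(0))
    inten = (np.concatenate([s.intensity for s in run.scans if s.n_points])
             if total else np.empty(0))
    times = np.array([s.rt for s in run.scans], dtype=float)

    with netcdf_file(path, "w") as nc:
        nc.createDimension("scan_number", len(run.scans))
        nc.createDimension("point_number", max(total, 1))
        v = nc.createVariable("scan_index", "i", ("scan_number",))
        v[:] = starts
        v = nc.createVariable("point_count", "i", ("scan_number",))
        v[:] = counts
        v = nc.createVariable("scan_acquisition_time", "d", ("scan_number",))
        v[:] = times
        v = nc.createVariable("mass_values", "d", ("point_number",))
        v[:] = mass if total else np.zeros(1)
        v = nc.createVariable("intensity_values", "d", ("point_number",))
        v[:] = inten if total else np.zeros(1)
    return path
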