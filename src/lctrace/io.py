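"""File formats: target lists, feature tables, truth records, centroided mzML.

mzML support is a compact in-package reader/writer restricted to what the
pipeline consumes and produces: centroided MS1 spectra with base64-encoded
float arrays (64- or 32-bit, optionally zlib-compressed on read; the writer
emits uncompressed 64-bit). Round-trips are covered by the test suite.
"""

from __future__ import annotations

import base64
import json
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .chem import CompoundSpec, parse_formula

__all__ = [
    "Scan",
    "RawRun",
    "read_target_list",
    "write_target_list",
    "read_feature_table",
    "write_feature_table",
    "read_sample_metadata",
    "write_truth",
    "read_truth",
    "write_mzml",
    "read_mzml",
]


# ---------------------------------------------------------------- raw runs

@dataclass
class Scan:
    """One centroided MS1 scan: acquisition time (s) and centroid arrays."""

    time: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")


@dataclass
class RawRun:
    """A time-ordered series of centroided MS1 scans (one LC-MS injection)."""

    scans: list[Scan] = field(default_factory=list)
    run_id: str = "run"

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.scans])

    def __len__(self) -> int:
        return len(self.scans)


# ------------------------------------------------------------ target lists

def read_target_list(path: str | Path) -> list[CompoundSpec]:
    """Read a compound target list CSV.

    Columns: id, name, formula, label_isotope, label_max, adducts, class.
    ``adducts`` is a ;-separated list; ``label_isotope``/``label_max`` may
    hold ;-separated parallel entries for multiply labelable compounds.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"id", "name", "formula", "label_isotope", "label_max",
                "adducts", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"target list missing columns: {sorted(missing)}")
    compounds = []
    for row in df.itertuples(index=False):
        isotopes = str(row.label_isotope).split(";")
        maxima = str(row.label_max).split(";")
        labelable = {iso: int(n) for iso, n in zip(isotopes, maxima) if iso}
        compounds.append(
            CompoundSpec(
                id=row.id,
                name=row.name,
                formula=parse_formula(row.formula),
                labelable=labelable,
                adducts=tuple(str(row.adducts).split(";")),
                compound_class=row._6,  # "class" is a keyword
            )
        )
    return compounds


def write_target_list(compounds: list[CompoundSpec], path: str | Path) -> None:
    rows = []
    for c in compounds:
        rows.append({
            "id": c.id,
            "name": c.name,
            "formula": c.formula.hill(),
            "label_isotope": ";".join(c.labelable),
            "label_max": ";".join(str(n) for n in c.labelable.values()),
            "adducts": ";".join(c.adducts),
            "class": c.compound_class,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------- feature tables

META_COLUMNS = ("feature_id", "mz", "rt_sec")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    for col in META_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"feature table missing column {col!r}")
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in META_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"feature table missing column {col!r}")
    return table


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Sample sidecar: sample_id, group, time_weeks, compartment."""
    meta = pd.read_csv(path)
    required = {"sample_id", "group", "time_weeks"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    return meta


# ------------------------------------------------------------ truth records

def write_truth(truth: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())


# ------------------------------------------------------------------- mzML

def _b64(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *map(float, values))
    return base64.b64encode(raw).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{n}" defaultDataProcessingRef="dp">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{npts}">
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{time:.6f}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
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

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(run: RawRun, path: str | Path) -> None:
    """Write a centroided MS1-only positive-mode mzML file."""
    parts = [_MZML_HEADER.format(run_id=escape(run.run_id, {'"': "&quot;"}),
                                 n=len(run.scans))]
    for i, scan in enumerate(run.scans):
        mz_b64 = _b64(scan.mz)
        int_b64 = _b64(scan.intensity)
        parts.append(_MZML_SPECTRUM.format(
            index=i, scan=i + 1, npts=len(scan.mz), time=scan.time,
            mz_len=len(mz_b64), mz_b64=mz_b64,
            int_len=len(int_b64), int_b64=int_b64,
        ))
    parts.append(_MZML_FOOTER)
    text = "".join(parts)
    ET.fromstring(text)  # refuse to write ill-formed XML
    Path(path).write_text(text)


_NS = "{http://psi.hupo.org/ms/mzml}"

# cvParam accessions relevant to array decoding and scan metadata
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_TIME = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _decode_binary_array(bda: ET.Element) -> np.ndarray:
    accessions = {cv.get("accession") for cv in bda.iter(f"{_NS}cvParam")}
    binary = bda.find(f"{_NS}binary")
    raw = base64.b64decode(binary.text or "")
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> RawRun:
    """Read centroided MS1 scans from an mzML file.

    Handles 64/32-bit float arrays, optional zlib compression, and scan
    start times in seconds or minutes.
    """
    scans = []
    for _, spectrum in ET.iterparse(str(path)):
        if spectrum.tag != f"{_NS}spectrum":
            continue
        params = {cv.get("accession"): cv
                  for cv in spectrum.iter(f"{_NS}cvParam")}
        level = params.get(_ACC_MS_LEVEL)
        if level is not None and level.get("value") not in ("", "1", None):
            spectrum.clear()
            continue
        time_param = params.get(_ACC_SCAN_TIME)
        time = float(time_param.get("value")) if time_param is not None \
            else float(len(scans))
        if time_param is not None and \
                time_param.get("unitName", "second") == "minute":
            time *= 60.0
        mz = intensity = np.empty(0)
        for bda in spectrum.iter(f"{_NS}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter(f"{_NS}cvParam")}
            if _ACC_MZ_ARRAY in accs:
                mz = _decode_binary_array(bda)
            elif _ACC_INT_ARRAY in accs:
                intensity = _decode_binary_array(bda)
        scans.append(Scan(time=time, mz=mz, intensity=intensity))
        spectrum.clear()
    scans.sort(key=lambda s: s.time)
    return RawRun(scans=scans, run_id=Path(path).stem)
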