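"""Minimal centroided-mzML reading and writing.

Only what the XIC extractor and the synthetic fixtures need: MS1 centroid
spectra with scan start times (minutes), polarity, and m/z / intensity
arrays (64- or 32-bit, plain or zlib-compressed on read; uncompressed
64-bit on write). Output is deliberately timestamp-free so identical inputs
yield byte-identical files; files written here read back identically
through reference mzML implementations (validated against Bioconductor's
mzR in the test suite).
"""

from __future__ import annotations

import base64
import xml.etree.ElementTree as ET
import zlib
from pathlib import Path

import numpy as np

__all__ = ["write_mzml", "read_centroided_scans", "Scan"]

_NS = "http://psi.hupo.org/ms/mzml"


class Scan:
    """One centroided MS1 scan: retention time (minutes) + peak lists."""

    __slots__ = ("rt_minutes", "mz", "intensity", "polarity")

    def __init__(self, rt_minutes: float, mz, intensity, polarity: str = "positive"):
        self.rt_minutes = float(rt_minutes)
        self.mz = np.asarray(mz, dtype=np.float64)
        self.intensity = np.asarray(intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {polarity!r}")
        self.polarity = polarity


def _cv(parent, accession, name, value="", unit=None):
    el = ET.SubElement(
        parent, "cvParam", cvRef="MS", accession=accession, name=name, value=value
    )
    if unit is not None:
        el.set("unitCvRef", unit[0])
        el.set("unitAccession", unit[1])
        el.set("unitName", unit[2])
    return el


def _binary_array(parent, data: np.ndarray, accession: str, name: str) -> None:
    raw = base64.b64encode(np.ascontiguousarray(data, dtype="<f8").tobytes()).decode()
    arr = ET.SubElement(parent, "binaryDataArray", encodedLength=str(len(raw)))
    _cv(arr, "MS:1000523", "64-bit float")
    _cv(arr, "MS:1000576", "no compression")
    unit = ("MS", "MS:1000040", "m/z") if name == "m/z array" else None
    _cv(arr, accession, name, unit=unit)
    ET.SubElement(arr, "binary").text = raw


def write_mzml(scans: list[Scan], path: str | Path, run_id: str = "run") -> Path:
    """Write centroided scans (sorted by retention time) to an mzML file."""
    scans = sorted(scans, key=lambda s: s.rt_minutes)
    ET.register_namespace("", _NS)
    root = ET.Element("mzML", xmlns=_NS, version="1.1.0")
    cvlist = ET.SubElement(root, "cvList", count="2")
    ET.SubElement(
        cvlist, "cv", id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    ET.SubElement(
        cvlist, "cv", id="UO", fullName="Unit Ontology",
        URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
    )
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000127", "centroid spectrum")
    soft = ET.SubElement(root, "softwareList", count="1")
    ET.SubElement(soft, "software", id="polysirm", version="0.1.0")
    icl = ET.SubElement(root, "instrumentConfigurationList", count="1")
    ET.SubElement(icl, "instrumentConfiguration", id="IC1")
    dpl = ET.SubElement(root, "dataProcessingList", count="1")
    dp = ET.SubElement(dpl, "dataProcessing", id="DP1")
    pm = ET.SubElement(dp, "processingMethod", order="1", softwareRef="polysirm")
    _cv(pm, "MS:1000544", "Conversion to mzML")
    run = ET.SubElement(root, "run", id=run_id, defaultInstrumentConfigurationRef="IC1")
    slist = ET.SubElement(
        run, "spectrumList", count=str(len(scans)), defaultDataProcessingRef="DP1"
    )
    for idx, scan in enumerate(scans):
        spec = ET.SubElement(
            slist, "spectrum", index=str(idx), id=f"scan={idx + 1}",
            defaultArrayLength=str(scan.mz.size),
        )
        _cv(spec, "MS:1000511", "ms level", "1")
        _cv(spec, "MS:1000127", "centroid spectrum")
        if scan.polarity == "positive":
            _cv(spec, "MS:1000130", "positive scan")
        else:
            _cv(spec, "MS:1000129", "negative scan")
        scan_list = ET.SubElement(spec, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        sc = ET.SubElement(scan_list, "scan")
        _cv(
            sc, "MS:1000016", "scan start time", f"{scan.rt_minutes:.6f}",
            unit=("UO", "UO:0000031", "minute"),
        )
        bdal = ET.SubElement(spec, "binaryDataArrayList", count="2")
        _binary_array(bdal, scan.mz, "MS:1000514", "m/z array")
        _binary_array(bdal, scan.intensity, "MS:1000515", "intensity array")
    path = Path(path)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")
    return path


# --------------------------------------------------------------------------
# reading


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    dtype, compressed, name, payload = "<f8", False, None, ""
    for child in bda:
        tag = _local(child.tag)
        if tag == "cvParam":
            acc = child.get("accession")
            if acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                name = "mz"
            elif acc == "MS:1000515":
                name = "intensity"
        elif tag == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    return name, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def read_centroided_scans(path: str | Path):
    """Iterate MS1 scans of an mzML file as :class:`Scan` objects.

    Supports the mzML subset this package needs: MS1 spectra, scan start
    time in minutes or seconds, positive/negative polarity, 32/64-bit
    plain or zlib-compressed arrays. Profile-mode spectra raise, since XIC
    integration here assumes centroids.
    """
    for event, elem in ET.iterparse(str(path), events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        ms_level, polarity, centroided, rt_minutes = None, "positive", None, None
        arrays: dict[str, np.ndarray] = {}
        for sub in elem.iter():
            tag = _local(sub.tag)
            if tag == "cvParam":
                acc = sub.get("accession")
                if acc == "MS:1000511":
                    ms_level = int(sub.get("value"))
                elif acc == "MS:1000127":
                    centroided = True
                elif acc == "MS:1000128":
                    centroided = False
                elif acc == "MS:1000129":
                    polarity = "negative"
                elif acc == "MS:1000130":
                    polarity = "positive"
                elif acc == "MS:1000016":
                    rt = float(sub.get("value"))
                    unit = sub.get("unitName", "minute")
                    rt_minutes = rt / 60.0 if unit == "second" else rt
            elif tag == "binaryDataArray":
                name, data = _decode_binary_array(sub)
                if name:
                    arrays[name] = data
        if ms_level == 1:
            if centroided is False:
                raise ValueError("profile-mode data: centroided mzML required")
            yield Scan(
                rt_minutes if rt_minutes is not None else 0.0,
                arrays.get("mz", np.empty(0)),
                arrays.get("intensity", np.empty(0)),
                polarity,
            )
        elem.clear()
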