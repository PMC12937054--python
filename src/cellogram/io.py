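"""Reading and writing of centroided MS runs and tabular inputs.

Only centroided mzML with MS1 scans is supported: direct-infusion
single-cell acquisitions are continuous full-scan experiments, and most
vendor formats convert to mzML.  Retention times are normalised to
minutes internally regardless of the unit stored in the file, because
every downstream time parameter (refractory period, cell rate) is in
minutes.

The mzML support here covers the subset of the PSI standard that
centroided MS1 data actually uses: per-spectrum m/z and intensity
arrays (64- or 32-bit float, zlib-compressed or raw), scan start time,
polarity, MS level, and an optional non-standard per-peak noise array.
"""

from __future__ import annotations

import base64
import csv
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree

import numpy as np

__all__ = [
    "Spectrum",
    "Run",
    "MzListEntry",
    "UnsupportedFormatError",
    "EmptyRunError",
    "read_mzml",
    "write_mzml",
    "read_peak_list_csv",
    "read_mz_list_csv",
]


class UnsupportedFormatError(ValueError):
    """Raised when a file contains data this reader does not support."""


class EmptyRunError(ValueError):
    """Raised when an mzML file contains no MS1 spectra."""


@dataclass
class Spectrum:
    """One centroided scan.

    Attributes
    ----------
    scan_index : int
        0-based position in acquisition order.
    retention_time : float
        Scan start time in minutes.
    mz : numpy.ndarray
        Strictly ascending centroid m/z values (Th).
    intensity : numpy.ndarray
        Non-negative intensities, same length as ``mz``.
    noise : numpy.ndarray or None
        Optional per-peak noise estimates (lost in most mzML
        conversions; ``None`` then).
    """

    scan_index: int
    retention_time: float
    mz: np.ndarray
    intensity: np.ndarray
    noise: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.noise is not None:
            self.noise = np.asarray(self.noise, dtype=np.float64)

    def validate(self) -> None:
        if self.mz.shape != self.intensity.shape:
            raise ValueError(
                f"scan {self.scan_index}: mz and intensity lengths differ"
            )
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError(f"scan {self.scan_index}: m/z not strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError(f"scan {self.scan_index}: negative intensity")
        if self.noise is not None and self.noise.shape != self.mz.shape:
            raise ValueError(f"scan {self.scan_index}: noise length mismatch")


@dataclass
class Run:
    """An ordered centroided MS1 acquisition — the cellogram substrate."""

    spectra: list[Spectrum]
    source_path: str = ""
    polarity: str = "positive"
    mz_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mz_range is None:
            lows = [s.mz[0] for s in self.spectra if s.mz.size]
            highs = [s.mz[-1] for s in self.spectra if s.mz.size]
            if lows:
                self.mz_range = (float(min(lows)), float(max(highs)))
            else:
                self.mz_range = (0.0, float("inf"))

    @property
    def n_scans(self) -> int:
        return len(self.spectra)

    @property
    def times(self) -> np.ndarray:
        """Retention times of all scans, minutes."""
        return np.array([s.retention_time for s in self.spectra])

    def validate(self) -> None:
        lo, hi = self.mz_range
        prev_rt = -np.inf
        for i, s in enumerate(self.spectra):
            if s.scan_index != i:
                raise ValueError(f"scan_index not contiguous at position {i}")
            s.validate()
            if s.retention_time < prev_rt:
                raise ValueError(f"retention time decreases at scan {i}")
            prev_rt = s.retention_time
            if s.mz.size and (s.mz[0] < lo or s.mz[-1] > hi):
                raise ValueError(f"scan {i}: m/z outside run mz_range")


@dataclass
class MzListEntry:
    """One row of a target / exclusion m/z list."""

    mz: float
    name: str = ""
    class_tag: str = "target"
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# mzML reading
# ---------------------------------------------------------------------------

_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_POSITIVE = "MS:1000130"
_ACC_NEGATIVE = "MS:1000129"
_ACC_SCAN_START = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_NONSTD_ARRAY = "MS:1000786"

_UNIT_MINUTE = "UO:0000031"
_UNIT_SECOND = "UO:0000010"
_UNIT_MS = "UO:0000028"


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(bda: ElementTree.Element) -> tuple[str | None, np.ndarray]:
    """Decode one binaryDataArray element → (array kind, values)."""
    dtype = np.float64
    compressed = False
    kind = None
    text = ""
    for child in bda.iter():
        name = _localname(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_F32:
                dtype = np.float32
            elif acc == _ACC_F64:
                dtype = np.float64
            elif acc == _ACC_ZLIB:
                compressed = True
            elif acc == _ACC_MZ_ARRAY:
                kind = "mz"
            elif acc == _ACC_INT_ARRAY:
                kind = "intensity"
            elif acc == _ACC_NONSTD_ARRAY:
                if "noise" in (child.get("value") or "").lower():
                    kind = "noise"
        elif name == "binary":
            text = child.text or ""
    raw = base64.b64decode(text.strip()) if text.strip() else b""
    if compressed and raw:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _parse_spectrum(elem: ElementTree.Element) -> dict:
    info: dict = {
        "ms_level": None,
        "profile": False,
        "polarity": None,
        "rt_min": None,
        "arrays": {},
        "id": elem.get("id", ""),
    }
    for child in elem.iter():
        name = _localname(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_MS_LEVEL:
                info["ms_level"] = int(child.get("value", "0"))
            elif acc == _ACC_PROFILE:
                info["profile"] = True
            elif acc == _ACC_POSITIVE:
                info["polarity"] = "positive"
            elif acc == _ACC_NEGATIVE:
                info["polarity"] = "negative"
            elif acc == _ACC_SCAN_START:
                value = float(child.get("value", "nan"))
                unit = child.get("unitAccession", "")
                unit_name = (child.get("unitName") or "").lower()
                if unit == _UNIT_SECOND or unit_name == "second":
                    value /= 60.0
                elif unit == _UNIT_MS or unit_name == "millisecond":
                    value /= 60000.0
                # minutes (UO:0000031) or unspecified: taken as minutes
                info["rt_min"] = value
        elif name == "binaryDataArray":
            kind, values = _decode_binary(child)
            if kind is not None:
                info["arrays"][kind] = values
    return info


def read_mzml(path: str | Path) -> Run:
    """Read a centroided mzML file into a :class:`Run`.

    All MS1 scans are kept in acquisition order; MSn scans are skipped.
    Retention times are converted to minutes whatever the source unit.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    UnsupportedFormatError
        If a profile-mode MS1 spectrum is encountered (names the scan).
    EmptyRunError
        If the file contains no MS1 spectra.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))

    spectra: list[Spectrum] = []
    polarity = "positive"
    for _event, elem in ElementTree.iterparse(str(path), events=("end",)):
        if _localname(elem.tag) != "spectrum":
            continue
        info = _parse_spectrum(elem)
        elem.clear()
        if info["ms_level"] is not None and info["ms_level"] != 1:
            continue
        if info["profile"]:
            raise UnsupportedFormatError(
                f"profile-mode spectrum not supported: {info['id'] or 'scan'}"
            )
        if info["polarity"]:
            polarity = info["polarity"]
        mz = info["arrays"].get("mz", np.empty(0))
        inten = info["arrays"].get("intensity", np.empty(0))
        noise = info["arrays"].get("noise")
        if mz.size > 1 and np.any(np.diff(mz) <= 0):
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
            if noise is not None:
                noise = noise[order]
        rt = info["rt_min"]
        spectra.append(
            Spectrum(
                scan_index=len(spectra),
                retention_time=float(rt) if rt is not None else 0.0,
                mz=mz,
                intensity=inten,
                noise=noise,
            )
        )
    if not spectra:
        raise EmptyRunError(f"no MS1 spectra in {path}")
    return Run(spectra=spectra, source_path=str(path), polarity=polarity)


# ---------------------------------------------------------------------------
# mzML writing
# ---------------------------------------------------------------------------

def _encode_array(values: np.ndarray) -> str:
    raw = np.asarray(values, dtype=np.float64).tobytes()
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


_ARRAY_CV = {
    "mz": (
        f'<cvParam cvRef="MS" accession="{_ACC_MZ_ARRAY}" name="m/z array" value="" '
        'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
    ),
    "intensity": (
        f'<cvParam cvRef="MS" accession="{_ACC_INT_ARRAY}" name="intensity array" value="" '
        'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'
    ),
    "noise": (
        f'<cvParam cvRef="MS" accession="{_ACC_NONSTD_ARRAY}" '
        'name="non-standard data array" value="noise"/>'
    ),
}

_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
<cvList count="2">
<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
<cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
</cvList>
<fileDescription><fileContent>
<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
</fileContent></fileDescription>
<softwareList count="1"><software id="sw" version="0.1">
<cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="cellogram"/>
</software></softwareList>
<instrumentConfigurationList count="1"><instrumentConfiguration id="IC1">
<cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
</instrumentConfiguration></instrumentConfigurationList>
<dataProcessingList count="1"><dataProcessing id="DP1">
<processingMethod order="1" softwareRef="sw">
<cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
</processingMethod></dataProcessing></dataProcessingList>
"""


def write_mzml(run: Run, path: str | Path) -> Path:
    """Write ``run`` as centroided mzML (64-bit zlib-compressed arrays).

    The written file re-reads to the same spectrum count, scan order and
    arrays (float64 is preserved exactly; the round-trip contract is
    checked by the test suite to well within float32 tolerance).
    """
    path = Path(path)
    run.validate()
    pol_acc, pol_name = (
        (_ACC_POSITIVE, "positive scan")
        if run.polarity == "positive"
        else (_ACC_NEGATIVE, "negative scan")
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER)
        fh.write('<run id="run1" defaultInstrumentConfigurationRef="IC1">\n')
        fh.write(
            f'<spectrumList count="{run.n_scans}" defaultDataProcessingRef="DP1">\n'
        )
        for s in run.spectra:
            arrays = {"mz": s.mz, "intensity": s.intensity}
            if s.noise is not None:
                arrays["noise"] = s.noise
            fh.write(
                f'<spectrum index="{s.scan_index}" id="scan={s.scan_index + 1}" '
                f'defaultArrayLength="{s.mz.size}">\n'
                f'<cvParam cvRef="MS" accession="{_ACC_MS_LEVEL}" name="ms level" value="1"/>\n'
                '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>\n'
                f'<cvParam cvRef="MS" accession="{_ACC_CENTROID}" name="centroid spectrum" value=""/>\n'
                f'<cvParam cvRef="MS" accession="{pol_acc}" name="{pol_name}" value=""/>\n'
                '<scanList count="1">'
                '<cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>'
                "<scan>"
                f'<cvParam cvRef="MS" accession="{_ACC_SCAN_START}" name="scan start time" '
                f'value="{s.retention_time!r}" unitCvRef="UO" '
                f'unitAccession="{_UNIT_MINUTE}" unitName="minute"/>'
                "</scan></scanList>\n"
                f'<binaryDataArrayList count="{len(arrays)}">\n'
            )
            for kind, values in arrays.items():
                enc = _encode_array(values)
                fh.write(
                    f'<binaryDataArray encodedLength="{len(enc)}">\n'
                    f'<cvParam cvRef="MS" accession="{_ACC_F64}" name="64-bit float" value=""/>\n'
                    f'<cvParam cvRef="MS" accession="{_ACC_ZLIB}" name="zlib compression" value=""/>\n'
                    f"{_ARRAY_CV[kind]}\n"
                    f"<binary>{enc}</binary>\n"
                    "</binaryDataArray>\n"
                )
            fh.write("</binaryDataArrayList></spectrum>\n")
        fh.write("</spectrumList></run></mzML>\n")
    return path


# ---------------------------------------------------------------------------
# CSV inputs
# ---------------------------------------------------------------------------

def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except (TypeError, ValueError):
        return False


def _read_csv_rows(path: str | Path) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh) if any(cell.strip() for cell in row)]
    # header auto-detection: non-numeric first field on the first row
    if rows and not _is_number(rows[0][0]):
        rows = rows[1:]
    return rows


def read_peak_list_csv(path: str | Path) -> list[tuple[float, float]]:
    """Read manually supplied cell-peak windows (start, end times in minutes).

    Rows are returned sorted by start time.  Overlapping intervals or a
    row with ``end <= start`` raise a ``ValueError`` naming the row.
    """
    rows = _read_csv_rows(path)
    intervals = []
    for i, row in enumerate(rows, start=1):
        if len(row) < 2:
            raise ValueError(f"row {i}: expected two columns (start, end)")
        start, end = float(row[0]), float(row[1])
        if end <= start:
            raise ValueError(f"row {i}: end ({end}) <= start ({start})")
        intervals.append((start, end))
    intervals.sort()
    for (s0, e0), (s1, _e1) in zip(intervals, intervals[1:]):
        if s1 < e0:
            raise ValueError(
                f"overlapping intervals: ({s0}, {e0}) and starting {s1}"
            )
    return intervals


_CLASS_TAGS = {"target", "internal_standard", "solvent_blank"}


def read_mz_list_csv(path: str | Path) -> list[MzListEntry]:
    """Read a target / exclusion list: m/z, optional name, optional class tag.

    The class tag defaults to ``target``; extra columns are ignored.
    """
    rows = _read_csv_rows(path)
    entries = []
    for i, row in enumerate(rows, start=1):
        if not _is_number(row[0]):
            raise ValueError(f"row {i}: non-numeric m/z {row[0]!r}")
        name = row[1].strip() if len(row) > 1 else ""
        tag = row[2].strip() if len(row) > 2 and row[2].strip() else "target"
        if tag not in _CLASS_TAGS:
            warnings.warn(f"row {i}: unknown class tag {tag!r}, using 'target'")
            tag = "target"
        entries.append(MzListEntry(mz=float(row[0]), name=name, class_tag=tag))
    return entries
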