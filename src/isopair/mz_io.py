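"""Reading centroid LC-HRMS runs and extracted ion chromatograms.

Supports the two open XML interchange formats for mass-spectrometry runs,
mzML (PSI standard) and mzXML, restricted to what this pipeline needs:
centroid-mode MS¹ spectra with 32/64-bit float peak arrays, optional zlib
array compression, and optional gzip file compression.  Profile-mode data
are rejected — centroiding is an upstream conversion step.

Retention times are normalised to seconds on read and scan numbering is
0-based internally regardless of file dialect.
"""

from __future__ import annotations

import base64
import gzip
import io
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "CentroidPeak",
    "Spectrum",
    "Run",
    "XIC",
    "read_run",
    "extract_xic",
    "write_tsv",
]


class FormatError(ValueError):
    """Raised for unreadable, garbled or profile-mode input files."""


class CentroidPeak(NamedTuple):
    mz: float           # u per elementary charge
    intensity: float    # detector counts


@dataclass
class Spectrum:
    """One centroid MS¹ scan: sorted m/z and intensity arrays.

    Peaks are stored as two aligned numpy arrays (strictly ascending
    ``mz``); the ``peaks`` property gives a tuple view for convenience.
    """

    scan_index: int
    rt_seconds: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be aligned 1-D arrays")
        if self.rt_seconds < 0:
            raise ValueError("rt_seconds must be non-negative")
        if self.mz.size:
            if np.any(self.mz <= 0):
                raise ValueError("all m/z values must be positive")
            if np.any(self.intensity < 0):
                raise ValueError("intensities must be non-negative")
            if np.any(np.diff(self.mz) <= 0):
                order = np.argsort(self.mz, kind="stable")
                self.mz = self.mz[order]
                self.intensity = self.intensity[order]
                # merge exact duplicates produced by ladder overlap
                if np.any(np.diff(self.mz) <= 0):
                    uniq, inv = np.unique(self.mz, return_inverse=True)
                    summed = np.zeros_like(uniq)
                    np.add.at(summed, inv, self.intensity)
                    self.mz, self.intensity = uniq, summed

    @property
    def peaks(self) -> list[CentroidPeak]:
        return [CentroidPeak(m, i) for m, i in zip(self.mz, self.intensity)]

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class Run:
    """An ordered sequence of centroid MS¹ spectra — one LC-HRMS file."""

    spectra: list[Spectrum]
    source_path: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.rt_seconds for s in self.spectra]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must be strictly increasing")
        for i, s in enumerate(self.spectra):
            s.scan_index = i

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt_seconds for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)


@dataclass
class XIC:
    """Extracted ion chromatogram aligned to a Run's scan indices."""

    target_mz: float
    ppm_window: float
    intensities: np.ndarray   # one entry per scan, 0 where no peak

    def __len__(self) -> int:
        return int(self.intensities.size)


# ---------------------------------------------------------------------------
# reading

_GZIP_MAGIC = b"\x1f\x8b"


def _open_maybe_gzip(path: str | Path) -> io.BufferedReader:
    fh = open(path, "rb")
    if fh.peek(2)[:2] == _GZIP_MAGIC:
        fh = gzip.open(fh, "rb")  # type: ignore[assignment]
    return fh


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_mzml_array(bda: ET.Element) -> tuple[str, np.ndarray]:
    """Decode one mzML <binaryDataArray>: returns (kind, values)."""
    dtype = "<f8"
    compressed = False
    kind = ""
    text = ""
    for child in bda.iter():
        t = _strip_ns(child.tag)
        if t == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif t == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _rt_to_seconds(value: str, unit: str) -> float:
    rt = float(value)
    if unit in ("minute", "UO:0000031", "min"):
        rt *= 60.0
    return rt


def _parse_mzml(fh) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    for _, elem in ET.iterparse(fh):
        if _strip_ns(elem.tag) != "spectrum":
            continue
        ms_level = None
        profile = False
        rt = None
        arrays: dict[str, np.ndarray] = {}
        for child in elem.iter():
            t = _strip_ns(child.tag)
            if t == "cvParam":
                acc = child.get("accession", "")
                if acc == "MS:1000511":
                    ms_level = int(child.get("value", "0"))
                elif acc == "MS:1000128":
                    profile = True
                elif acc == "MS:1000016":
                    rt = _rt_to_seconds(
                        child.get("value", "0"),
                        child.get("unitName", child.get("unitAccession", "second")),
                    )
            elif t == "binaryDataArray":
                kind, values = _decode_mzml_array(child)
                if kind:
                    arrays[kind] = values
        if ms_level == 1:
            if profile:
                raise FormatError(
                    "profile-mode spectrum encountered: centroid data required"
                )
            spectra.append(
                Spectrum(
                    scan_index=len(spectra),
                    rt_seconds=rt if rt is not None else float(len(spectra)),
                    mz=arrays.get("mz", np.empty(0)),
                    intensity=arrays.get("intensity", np.empty(0)),
                )
            )
        elem.clear()
    return spectra


def _parse_mzxml_rt(value: str) -> float:
    # ISO-8601 duration, e.g. "PT123.45S"
    v = value.strip()
    if v.startswith("PT") and v.endswith("S"):
        return float(v[2:-1])
    return float(v)


def _parse_mzxml(fh) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    for _, elem in ET.iterparse(fh):
        if _strip_ns(elem.tag) != "scan":
            continue
        if int(elem.get("msLevel", "1")) != 1:
            elem.clear()
            continue
        if elem.get("centroided", "1") == "0":
            raise FormatError(
                "profile-mode scan encountered: centroid data required"
            )
        rt = _parse_mzxml_rt(elem.get("retentionTime", str(len(spectra))))
        mz = np.empty(0)
        inten = np.empty(0)
        for child in elem.iter():
            if _strip_ns(child.tag) != "peaks":
                continue
            raw = base64.b64decode(child.text or "")
            if child.get("compressionType", "none") == "zlib":
                raw = zlib.decompress(raw)
            prec = int(child.get("precision", "32"))
            fmt = ">%d%s" % (len(raw) // (prec // 8), "f" if prec == 32 else "d")
            flat = np.array(struct.unpack(fmt, raw))
            mz, inten = flat[0::2], flat[1::2]
        spectra.append(
            Spectrum(
                scan_index=len(spectra), rt_seconds=rt, mz=mz, intensity=inten
            )
        )
        elem.clear()
    return spectra


def read_run(path: str | Path, format: str = "auto") -> Run:
    """Read a centroid mzML or mzXML file into a :class:`Run`.

    MS² spectra are skipped; profile-mode data raise :class:`FormatError`.
    ``format`` may be ``mzML``, ``mzXML`` or ``auto`` (sniff the root tag;
    gzip containers are transparent).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        with _open_maybe_gzip(path) as fh:
            head = fh.read(4096).decode("utf-8", errors="replace")
        if "mzXML" in head:
            format = "mzXML"
        elif "mzML" in head:
            format = "mzML"
        else:
            raise FormatError(f"{path}: not recognisable as mzML or mzXML")
    parser = {"mzML": _parse_mzml, "mzXML": _parse_mzxml}.get(format)
    if parser is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        with _open_maybe_gzip(path) as fh:
            spectra = parser(fh)
    except (ET.ParseError, OSError, EOFError, zlib.error, struct.error) as exc:
        raise FormatError(f"{path}: unreadable ({exc})") from exc
    if not spectra:
        raise FormatError(f"{path}: no MS1 spectra found")
    return Run(spectra=spectra, source_path=str(path))


# ---------------------------------------------------------------------------
# XIC construction

def extract_xic(run: Run, target_mz: float, ppm: float) -> XIC:
    """Per-scan summed intensity within ``±ppm`` of ``target_mz``.

    Multiple centroid peaks falling inside the window of one scan are
    summed (robust to centroiding splits and deterministic); scans with
    no matching peak contribute 0, so an all-zero XIC is valid output.
    """
    if ppm <= 0:
        raise ValueError("ppm must be positive")
    lo = target_mz * (1.0 - ppm * 1e-6)
    hi = target_mz * (1.0 + ppm * 1e-6)
    out = np.zeros(len(run))
    for i, spec in enumerate(run):
        a = np.searchsorted(spec.mz, lo, side="left")
        b = np.searchsorted(spec.mz, hi, side="right")
        if b > a:
            out[i] = spec.intensity[a:b].sum()
    return XIC(target_mz=target_mz, ppm_window=ppm, intensities=out)


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with a stable column order."""
    frame.to_csv(path, sep="\t", index=False)
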