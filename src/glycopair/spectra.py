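"""Spectrum containers, mzML/MGF reading and writing, and scan pairing.

A paired acquisition (e.g. HCD-product-dependent-EThcD) interleaves, between
MS1 survey scans, a collisional MS2 scan and an electron-activation MS2 scan
of the same precursor.  :func:`pair_scans` reconstitutes those pairs from a
flat scan list using the MS1 scans as block boundaries: within each block,
each scan of the first activation type is greedily paired with the earliest
subsequent unpaired scan of the second type whose precursor matches.

MGF goes through :mod:`pyteomics.mgf` with two extra per-scan header tags
(``ACTIVATION=``, ``MSLEVEL=``) since plain MGF carries neither activation
type nor MS1 scans.  mzML reading/writing is a compact lxml implementation
covering the centroided subset this package needs (plain or indexed
documents, 32/64-bit float arrays, optional zlib compression).
"""

from __future__ import annotations

import base64
import logging
import struct
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf

log = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "SpectrumPair",
    "read_run",
    "write_mgf",
    "write_mzml",
    "pair_scans",
    "base_peak_normalize",
]

COLLISIONAL = frozenset({"HCD"})
ELECTRON = frozenset({"ETD", "EThcD", "EAD"})


@dataclass(frozen=True)
class Spectrum:
    """One centroided scan.  Peaks are kept sorted ascending by m/z."""

    scan_id: int
    ms_level: int
    activation: str = "unknown"  # HCD | ETD | EThcD | EAD | unknown
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    retention_time: float = 0.0  # seconds
    mz: np.ndarray = None  # type: ignore[assignment]
    intensity: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        mz = np.asarray(self.mz if self.mz is not None else [], dtype=float)
        inten = np.asarray(
            self.intensity if self.intensity is not None else [], dtype=float
        )
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity arrays differ in length")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])
        if self.ms_level == 2 and (self.precursor_mz is None or self.precursor_mz <= 0):
            raise ValueError(f"MS2 scan {self.scan_id} lacks a positive precursor m/z")

    @property
    def n_peaks(self) -> int:
        return len(self.mz)

    def match_count(self, targets: Sequence[float], tol_ppm: float) -> int:
        """Number of target m/z values with at least one peak within tol."""
        return sum(1 for t in targets if self.has_peak(t, tol_ppm))

    def has_peak(self, target: float, tol_ppm: float) -> bool:
        half = target * tol_ppm * 1e-6
        i = np.searchsorted(self.mz, target - half)
        return i < len(self.mz) and self.mz[i] <= target + half


@dataclass(frozen=True)
class SpectrumPair:
    """An identification scan plus its (optional) localization scan."""

    first_scan: Spectrum
    second_scan: Spectrum | None
    mode: str  # hcd_first | etd_first | single_scan

    @property
    def localization_scan(self) -> Spectrum | None:
        return self.second_scan


def base_peak_normalize(spectrum: Spectrum) -> dict[float, float]:
    """Intensities relative to the base peak, as an m/z -> [0,1] mapping."""
    if spectrum.n_peaks == 0:
        raise ValueError("cannot normalize an empty spectrum")
    top = float(spectrum.intensity.max())
    return {float(m): float(i) / top for m, i in zip(spectrum.mz, spectrum.intensity)}


# ---------------------------------------------------------------------------
# Reading

def read_run(path: str | Path, format: str = "auto") -> list[Spectrum]:
    """Read a centroided run (mzML or MGF) into acquisition-ordered spectra."""
    path = Path(path)
    if format == "auto":
        suffix = path.suffix.lower()
        format = {"mzml": "mzML", ".mzml": "mzML", ".mgf": "MGF"}.get(suffix, "")
        if not format:
            raise ValueError(f"cannot infer run format from {path.name!r}")
    if format.lower() == "mzml":
        return _read_mzml(path)
    if format.lower() == "mgf":
        return _read_mgf(path)
    raise ValueError(f"unsupported run format {format!r}")


def _scan_number(id_text: str, fallback: int) -> int:
    for token in str(id_text).replace("=", " ").split():
        if token.isdigit():
            last = token
    try:
        return int(last)  # last numeric token, e.g. "scan=12" -> 12
    except UnboundLocalError:
        return fallback


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element) -> dict[str, dict]:
    params = {}
    for child in element:
        if _local(child.tag) == "cvParam":
            params[child.get("name")] = dict(child.attrib)
    return params


def _decode_binary_array(bda, path: Path) -> np.ndarray:
    params = _cv_params(bda)
    binary = None
    for child in bda:
        if _local(child.tag) == "binary":
            binary = child.text or ""
    if binary is None:
        raise IOError(f"{path}: binaryDataArray without <binary>")
    raw = base64.b64decode(binary)
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> list[Spectrum]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise IOError(f"{path}: malformed mzML ({exc})") from None
    root = tree.getroot()
    if _local(root.tag) == "indexedmzML":
        root = next(c for c in root if _local(c.tag) == "mzML")
    out: list[Spectrum] = []
    for i, sp in enumerate(root.iter(), 0):
        if _local(sp.tag) != "spectrum":
            continue
        params = _cv_params(sp)
        ms_level = int(params.get("ms level", {}).get("value", 1))
        rt = 0.0
        prec_mz = prec_z = None
        activation = "unknown"
        arrays: dict[str, np.ndarray] = {}
        for node in sp.iter():
            tag = _local(node.tag)
            if tag == "scan":
                p = _cv_params(node)
                if "scan start time" in p:
                    attrs = p["scan start time"]
                    rt = float(attrs["value"])
                    if attrs.get("unitName") == "minute":
                        rt *= 60.0
            elif tag == "selectedIon":
                p = _cv_params(node)
                if "selected ion m/z" in p:
                    prec_mz = float(p["selected ion m/z"]["value"])
                if "charge state" in p:
                    prec_z = int(p["charge state"]["value"])
            elif tag == "activation":
                p = _cv_params(node)
                etd = "electron transfer dissociation" in p
                hcd = "beam-type collision-induced dissociation" in p
                ead = "electron activated dissociation" in p
                if etd and hcd:
                    activation = "EThcD"
                elif etd:
                    activation = "ETD"
                elif ead:
                    activation = "EAD"
                elif hcd:
                    activation = "HCD"
            elif tag == "binaryDataArray":
                p = _cv_params(node)
                arr = _decode_binary_array(node, path)
                if "m/z array" in p:
                    arrays["mz"] = arr
                elif "intensity array" in p:
                    arrays["intensity"] = arr
        if "mz" not in arrays or "intensity" not in arrays:
            raise IOError(f"{path}: spectrum {sp.get('id')} lacks peak arrays")
        if ms_level >= 2 and prec_mz is None:
            raise IOError(f"{path}: MS2 scan {sp.get('id')} lacks precursor data")
        out.append(
            Spectrum(
                scan_id=_scan_number(sp.get("id", ""), i + 1),
                ms_level=ms_level,
                activation=activation,
                precursor_mz=prec_mz,
                precursor_charge=prec_z,
                retention_time=rt,
                mz=arrays["mz"],
                intensity=arrays["intensity"],
            )
        )
    return out


def _read_mgf(path: Path) -> list[Spectrum]:
    out: list[Spectrum] = []
    with _mgf.read(str(path), use_index=False) as reader:
        for i, entry in enumerate(reader, 1):
            params = entry["params"]
            ms_level = int(params.get("mslevel", 2))
            title = params.get("title", "")
            scan_id = _scan_number(title, i)
            prec_mz = None
            charge = None
            if ms_level >= 2:
                pepmass = params.get("pepmass")
                if pepmass is None or pepmass[0] in (None, 0):
                    raise IOError(f"{path}: MS2 block {title!r} lacks PEPMASS")
                prec_mz = float(pepmass[0])
                if params.get("charge"):
                    charge = int(params["charge"][0])
            out.append(
                Spectrum(
                    scan_id=scan_id,
                    ms_level=ms_level,
                    activation=str(params.get("activation", "unknown")),
                    precursor_mz=prec_mz,
                    precursor_charge=charge,
                    retention_time=float(params.get("rtinseconds", 0.0)),
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return out


# ---------------------------------------------------------------------------
# Writing

def write_mgf(run: Iterable[Spectrum], path: str | Path) -> None:
    """Write a run as MGF, with ACTIVATION and MSLEVEL header tags.

    MS1 scans are emitted as MSLEVEL=1 blocks so that MS1 block boundaries
    survive a round trip (plain MGF has no native MS1 representation).
    """
    with open(path, "w") as fh:
        for s in run:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE=scan={s.scan_id}\n")
            fh.write(f"MSLEVEL={s.ms_level}\n")
            fh.write(f"RTINSECONDS={s.retention_time:.3f}\n")
            if s.ms_level >= 2:
                fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
                if s.precursor_charge:
                    fh.write(f"CHARGE={s.precursor_charge}+\n")
                if s.activation != "unknown":
                    fh.write(f"ACTIVATION={s.activation}\n")
            for m, i in zip(s.mz, s.intensity):
                fh.write(f"{m:.6f} {i:.4f}\n")
            fh.write("END IONS\n\n")


def _b64_floats(values: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{len(values)}d", *map(float, values))
    ).decode()


_ACTIVATION_CV = {
    "HCD": [("MS:1000422", "beam-type collision-induced dissociation")],
    "ETD": [("MS:1000598", "electron transfer dissociation")],
    "EAD": [("MS:1003294", "electron activated dissociation")],
    "EThcD": [
        ("MS:1000598", "electron transfer dissociation"),
        ("MS:1000422", "beam-type collision-induced dissociation"),
    ],
}


def write_mzml(run: Sequence[Spectrum], path: str | Path) -> None:
    """Write a minimal centroided mzML 1.1.0 document."""
    NS = "http://psi.hupo.org/ms/mzml"
    root = etree.Element(f"{{{NS}}}mzML", version="1.1.0")
    etree.SubElement(root, f"{{{NS}}}cvList", count="1")
    etree.SubElement(root, f"{{{NS}}}fileDescription")
    runel = etree.SubElement(root, f"{{{NS}}}run", id="run1")
    sl = etree.SubElement(runel, f"{{{NS}}}spectrumList", count=str(len(run)))

    def cv(parent, accession, name, value="", unit=None):
        attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
        if unit:
            attrs.update(
                unitCvRef="UO", unitAccession=unit[0], unitName=unit[1]
            )
        etree.SubElement(parent, f"{{{NS}}}cvParam", **attrs)

    for idx, s in enumerate(run):
        sp = etree.SubElement(
            sl,
            f"{{{NS}}}spectrum",
            index=str(idx),
            id=f"scan={s.scan_id}",
            defaultArrayLength=str(s.n_peaks),
        )
        cv(sp, "MS:1000511", "ms level", str(s.ms_level))
        cv(sp, "MS:1000127", "centroid spectrum")
        scan_list = etree.SubElement(sp, f"{{{NS}}}scanList", count="1")
        cv(scan_list, "MS:1000795", "no combination")
        scan = etree.SubElement(scan_list, f"{{{NS}}}scan")
        cv(
            scan,
            "MS:1000016",
            "scan start time",
            f"{s.retention_time:.4f}",
            unit=("UO:0000010", "second"),
        )
        if s.ms_level >= 2:
            pl = etree.SubElement(sp, f"{{{NS}}}precursorList", count="1")
            prec = etree.SubElement(pl, f"{{{NS}}}precursor")
            sil = etree.SubElement(prec, f"{{{NS}}}selectedIonList", count="1")
            ion = etree.SubElement(sil, f"{{{NS}}}selectedIon")
            cv(ion, "MS:1000744", "selected ion m/z", f"{s.precursor_mz:.6f}")
            if s.precursor_charge:
                cv(ion, "MS:1000041", "charge state", str(s.precursor_charge))
            act = etree.SubElement(prec, f"{{{NS}}}activation")
            for acc, name in _ACTIVATION_CV.get(s.activation, []):
                cv(act, acc, name)
        bal = etree.SubElement(sp, f"{{{NS}}}binaryDataArrayList", count="2")
        for arr, acc, name in [
            (s.mz, "MS:1000514", "m/z array"),
            (s.intensity, "MS:1000515", "intensity array"),
        ]:
            encoded = _b64_floats(arr)
            bda = etree.SubElement(
                bal, f"{{{NS}}}binaryDataArray", encodedLength=str(len(encoded))
            )
            cv(bda, "MS:1000523", "64-bit float")
            cv(bda, "MS:1000576", "no compression")
            cv(bda, acc, name)
            etree.SubElement(bda, f"{{{NS}}}binary").text = encoded
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


# ---------------------------------------------------------------------------
# Pairing

def _role_sets(mode: str) -> tuple[frozenset, frozenset]:
    if mode == "hcd_first":
        return COLLISIONAL, ELECTRON
    if mode == "etd_first":
        return ELECTRON, COLLISIONAL
    raise ValueError(f"unknown pairing mode {mode!r}")


def pair_scans(
    run: Sequence[Spectrum],
    mode: str = "hcd_first",
    precursor_tol_ppm: float = 30.0,
    require_same_charge: bool = True,
) -> list[SpectrumPair]:
    """Pair MS2 scans of the same precursor within MS1-bounded blocks.

    ``single_scan`` mode makes every MS2 scan its own pair (identification
    and localization both read the same scan).  In the paired modes, a
    first-type scan left without a partner is still returned — with no
    localization scan — so that it remains identifiable; its localization
    will carry no electron-scan evidence.
    """
    if mode == "single_scan":
        return [
            SpectrumPair(s, s, "single_scan") for s in run if s.ms_level == 2
        ]
    first_types, second_types = _role_sets(mode)

    pairs: list[SpectrumPair] = []
    block: list[Spectrum] = []

    def flush(block: list[Spectrum]) -> None:
        used: set[int] = set()
        for i, s in enumerate(block):
            if s.activation not in first_types or i in used:
                continue
            partner = None
            for j in range(i + 1, len(block)):
                t = block[j]
                if j in used or t.activation not in second_types:
                    continue
                tol = s.precursor_mz * precursor_tol_ppm * 1e-6
                if abs(t.precursor_mz - s.precursor_mz) > tol:
                    continue
                if (
                    require_same_charge
                    and s.precursor_charge is not None
                    and t.precursor_charge is not None
                    and s.precursor_charge != t.precursor_charge
                ):
                    continue
                partner = j
                break
            if partner is not None:
                used.add(i)
                used.add(partner)
                pairs.append(SpectrumPair(s, block[partner], mode))
            else:
                log.debug("scan %d left unpaired", s.scan_id)
                pairs.append(SpectrumPair(s, None, mode))

    for s in run:
        if s.ms_level == 1:
            flush(block)
            block = []
        else:
            block.append(s)
    flush(block)
    return pairs
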