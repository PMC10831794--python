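"""Readers/writers for the open formats the pipeline touches.

mzML is the single raw-data ingest format (vendor files are expected to be
converted upstream); reading uses a compact lxml stream parser, writing a
minimal mzML 1.1 serializer (uncompressed 64-bit arrays); the two
round-trip each other.  Reference spectra travel as MSP (strict dialect,
own parser) or MGF (pyteomics) text.  Sessions persist as a directory of
JSON manifest + CSV matrix + mzML parts.
"""

from __future__ import annotations

import base64
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lxml import etree

MZML_NS = "http://psi.hupo.org/ms/mzml"


class FormatError(ValueError):
    """Input file violates the expected dialect; readers fail fast."""


@dataclass
class Scan:
    rt: float                 # retention time, minutes
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    precursor_mz: float | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < 0):
            raise FormatError("negative intensities")


@dataclass
class Run:
    """One LC-MS(/MS) acquisition: centroided MS1 + DDA MS2 scans."""

    sample_id: str
    polarity: str = "positive"
    ms1: list[Scan] = field(default_factory=list)
    ms2: list[Scan] = field(default_factory=list)
    batch: str = "batch1"
    role: str = "sample"      # sample | blank | QC | standard
    n_peaks_dropped: int = 0  # removed by the conversion ("low") threshold

    def __post_init__(self):
        for scans in (self.ms1, self.ms2):
            rts = [s.rt for s in scans]
            if any(b < a for a, b in zip(rts, rts[1:])):
                raise FormatError("scan RTs must be non-decreasing per MS level")


@dataclass
class SpectrumRecord:
    """A reference or merged MS/MS spectrum.

    Peaks are (m/z, relative intensity) sorted by m/z and normalized to base
    peak = 100; ``provenance`` is one of experimental/predicted/merged/
    validated.  ``fragment_formulas`` maps peak index -> formula string for
    validator-assigned peaks; ``unmatched`` lists flagged peak indices.
    """

    peaks: list[tuple[float, float]]
    precursor_mz: float | None = None
    polarity: str = "positive"
    provenance: str = "experimental"
    name: str = ""
    metadata: dict = field(default_factory=dict)
    fragment_formulas: dict[int, str] = field(default_factory=dict)
    unmatched: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.peaks = sorted((float(m), float(i)) for m, i in self.peaks)
        if self.peaks:
            base = max(i for _, i in self.peaks)
            if base > 0:
                self.peaks = [(m, 100.0 * i / base) for m, i in self.peaks]

    def mz_array(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


def _iter_mzml_spectra(path: str):
    """Stream spectra out of an mzML file.

    A compact XML-level parser (lxml iterparse): handles 32/64-bit float
    binary arrays, optional zlib compression, minute/second RT units,
    centroid/profile flags, polarity and DDA precursors.
    """
    import zlib

    tag = f"{{{MZML_NS}}}spectrum"
    for _, el in etree.iterparse(path, events=("end",), tag=tag):
        accs = {cv.get("accession"): cv
                for cv in el.iter(f"{{{MZML_NS}}}cvParam")}
        out = {
            "ms_level": int(accs["MS:1000511"].get("value")) if "MS:1000511" in accs else 1,
            "profile": "MS:1000128" in accs,
            "polarity": "negative" if "MS:1000129" in accs else "positive",
            "rt": None,
            "precursor_mz": None,
        }
        scan = el.find(f"{{{MZML_NS}}}scanList/{{{MZML_NS}}}scan")
        if scan is not None:
            for cv in scan.iter(f"{{{MZML_NS}}}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    rt = float(cv.get("value"))
                    if cv.get("unitName", "minute") == "second":
                        rt /= 60.0
                    out["rt"] = rt
        si = el.find(f"{{{MZML_NS}}}precursorList/{{{MZML_NS}}}precursor/"
                     f"{{{MZML_NS}}}selectedIonList/{{{MZML_NS}}}selectedIon")
        if si is not None:
            for cv in si.iter(f"{{{MZML_NS}}}cvParam"):
                if cv.get("accession") == "MS:1000744":
                    out["precursor_mz"] = float(cv.get("value"))
        arrays = {}
        for ba in el.iter(f"{{{MZML_NS}}}binaryDataArray"):
            ba_accs = {cv.get("accession") for cv in ba.iter(f"{{{MZML_NS}}}cvParam")}
            binary = ba.find(f"{{{MZML_NS}}}binary")
            raw = base64.b64decode(binary.text or "")
            if "MS:1000574" in ba_accs:  # zlib
                raw = zlib.decompress(raw)
            dtype = "<f4" if "MS:1000521" in ba_accs else "<f8"
            data = np.frombuffer(raw, dtype=dtype).astype(float)
            if "MS:1000514" in ba_accs:
                arrays["mz"] = data
            elif "MS:1000515" in ba_accs:
                arrays["intensity"] = data
        if "mz" not in arrays or "intensity" not in arrays:
            raise FormatError("spectrum without m/z or intensity array")
        out["mz"], out["intensity"] = arrays["mz"], arrays["intensity"]
        yield out
        el.clear()


def write_run(run: Run, path: str) -> None:
    """Serialize a Run as centroided mzML 1.1 (uncompressed 64-bit arrays)."""
    root = etree.Element(f"{{{MZML_NS}}}mzML", version="1.1.0")
    runel = etree.SubElement(root, f"{{{MZML_NS}}}run", id=run.sample_id)
    scans = sorted([(s, 1) for s in run.ms1] + [(s, 2) for s in run.ms2],
                   key=lambda t: (t[0].rt, t[1]))
    slist = etree.SubElement(runel, f"{{{MZML_NS}}}spectrumList",
                             count=str(len(scans)))

    def cv(parent, acc, name, value="", unit=None):
        el = etree.SubElement(parent, f"{{{MZML_NS}}}cvParam",
                              cvRef="MS", accession=acc, name=name, value=str(value))
        if unit:
            el.set("unitAccession", "UO:0000031")
            el.set("unitName", unit)
        return el

    for i, (scan, level) in enumerate(scans):
        sp = etree.SubElement(slist, f"{{{MZML_NS}}}spectrum", index=str(i),
                              id=f"scan={i + 1}",
                              defaultArrayLength=str(len(scan.mz)))
        cv(sp, "MS:1000511", "ms level", level)
        cv(sp, "MS:1000127", "centroid spectrum")
        if run.polarity == "positive":
            cv(sp, "MS:1000130", "positive scan")
        else:
            cv(sp, "MS:1000129", "negative scan")
        sl = etree.SubElement(sp, f"{{{MZML_NS}}}scanList", count="1")
        sc = etree.SubElement(sl, f"{{{MZML_NS}}}scan")
        cv(sc, "MS:1000016", "scan start time", f"{scan.rt:.6f}", unit="minute")
        if level == 2:
            pl = etree.SubElement(sp, f"{{{MZML_NS}}}precursorList", count="1")
            pr = etree.SubElement(pl, f"{{{MZML_NS}}}precursor")
            sil = etree.SubElement(pr, f"{{{MZML_NS}}}selectedIonList", count="1")
            si = etree.SubElement(sil, f"{{{MZML_NS}}}selectedIon")
            cv(si, "MS:1000744", "selected ion m/z", f"{scan.precursor_mz:.6f}")
        bl = etree.SubElement(sp, f"{{{MZML_NS}}}binaryDataArrayList", count="2")
        for acc, nm, arr in (("MS:1000514", "m/z array", scan.mz),
                             ("MS:1000515", "intensity array", scan.intensity)):
            enc = _b64(arr)
            ba = etree.SubElement(bl, f"{{{MZML_NS}}}binaryDataArray",
                                  encodedLength=str(len(enc)))
            cv(ba, "MS:1000523", "64-bit float")
            cv(ba, "MS:1000576", "no compression")
            cv(ba, acc, nm)
            etree.SubElement(ba, f"{{{MZML_NS}}}binary").text = enc
    etree.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8",
                                  pretty_print=True)


def read_run(path: str, min_intensity: float = 0.0, sample_id: str | None = None,
             role: str = "sample", batch: str = "batch1") -> Run:
    """Read a centroided mzML file into a :class:`Run`.

    Peaks below ``min_intensity`` (the conversion or "low" threshold) are
    dropped at import and are not recoverable later in the session; the
    number removed is recorded on the Run.  Profile-mode spectra are
    rejected.
    """
    ms1, ms2 = [], []
    dropped = 0
    polarity = "positive"
    for spec in _iter_mzml_spectra(path):
        if spec["profile"]:
            raise FormatError("profile-mode data: centroid before import")
        if spec["polarity"] == "negative":
            polarity = "negative"
        rt = spec["rt"]
        if rt is None:
            raise FormatError("spectrum without scan start time")
        mz = spec["mz"]
        inten = spec["intensity"]
        keep = inten >= min_intensity
        dropped += int((~keep).sum())
        if spec["ms_level"] == 1:
            ms1.append(Scan(rt, mz[keep], inten[keep], 1))
        else:
            ms2.append(Scan(rt, mz[keep], inten[keep], 2, spec["precursor_mz"]))
    sid = sample_id or os.path.splitext(os.path.basename(path))[0]
    ms1.sort(key=lambda s: s.rt)
    ms2.sort(key=lambda s: s.rt)
    return Run(sid, polarity, ms1, ms2, batch=batch, role=role,
               n_peaks_dropped=dropped)


def apply_conversion_threshold(run: Run, min_intensity: float) -> Run:
    """Drop peaks below the conversion threshold from an in-memory Run
    (idempotent; mirrors what :func:`read_run` does at import)."""
    dropped = run.n_peaks_dropped

    def _filter(scans):
        nonlocal dropped
        out = []
        for s in scans:
            keep = s.intensity >= min_intensity
            dropped += int((~keep).sum())
            out.append(Scan(s.rt, s.mz[keep], s.intensity[keep], s.ms_level,
                            s.precursor_mz))
        return out

    return Run(run.sample_id, run.polarity, _filter(run.ms1), _filter(run.ms2),
               run.batch, run.role, dropped)


# ---------------------------------------------------------------------------
# MSP / MGF reference spectra
# ---------------------------------------------------------------------------

def read_spectra(path: str) -> list[SpectrumRecord]:
    """Read MSP (``Name:``/``PrecursorMZ:``/``Num Peaks:`` dialect) or MGF."""
    if path.lower().endswith(".mgf"):
        return _read_mgf(path)
    return _read_msp(path)


def write_spectra(spectra: list[SpectrumRecord], path: str) -> None:
    if path.lower().endswith(".mgf"):
        _write_mgf(spectra, path)
    else:
        _write_msp(spectra, path)


def _read_msp(path: str) -> list[SpectrumRecord]:
    out = []
    with open(path) as fh:
        block: list[str] = []
        for line in list(fh) + [""]:
            line = line.rstrip("\n")
            if line.strip():
                block.append(line)
                continue
            if block:
                out.append(_parse_msp_block(block))
                block = []
    return out


def _parse_msp_block(lines: list[str]) -> SpectrumRecord:
    meta: dict[str, str] = {}
    i = 0
    while i < len(lines) and ":" in lines[i] and not _looks_like_peak(lines[i]):
        key, _, val = lines[i].partition(":")
        meta[key.strip().lower()] = val.strip()
        i += 1
    if "num peaks" not in meta:
        raise FormatError("MSP record missing 'Num Peaks'")
    n = int(meta["num peaks"])
    peaks = []
    for line in lines[i:]:
        for token in line.replace(";", " ").split():
            peaks.append(float(token))
    if len(peaks) < 2 * n:
        raise FormatError(f"truncated MSP record: expected {n} peaks")
    pairs = [(peaks[2 * j], peaks[2 * j + 1]) for j in range(n)]
    prec = meta.get("precursormz") or meta.get("precursor_mz")
    polarity = meta.get("ion mode", meta.get("ionmode", "positive")).lower()
    polarity = "negative" if polarity.startswith("n") else "positive"
    return SpectrumRecord(pairs, float(prec) if prec else None, polarity,
                          meta.get("provenance", "experimental"),
                          name=meta.get("name", ""), metadata=meta)


def _looks_like_peak(line: str) -> bool:
    parts = line.split()
    try:
        float(parts[0])
        return True
    except (ValueError, IndexError):
        return False


def _write_msp(spectra: list[SpectrumRecord], path: str) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write(f"Name: {s.name}\n")
            if s.precursor_mz is not None:
                fh.write(f"PrecursorMZ: {s.precursor_mz:.6f}\n")
            fh.write(f"Ion mode: {'P' if s.polarity == 'positive' else 'N'}\n")
            fh.write(f"Provenance: {s.provenance}\n")
            fh.write(f"Num Peaks: {len(s.peaks)}\n")
            for m, i in s.peaks:
                fh.write(f"{m:.6f} {i:.4f}\n")
            fh.write("\n")


def _read_mgf(path: str) -> list[SpectrumRecord]:
    from pyteomics import mgf

    out = []
    with mgf.read(path) as reader:
        for entry in reader:
            pairs = list(zip(entry["m/z array"], entry["intensity array"]))
            params = entry.get("params", {})
            pep = params.get("pepmass")
            prec = float(pep[0]) if pep else None
            out.append(SpectrumRecord(pairs, prec, name=str(params.get("title", "")),
                                      metadata=dict(params)))
    return out


def _write_mgf(spectra: list[SpectrumRecord], path: str) -> None:
    from pyteomics import mgf

    entries = []
    for s in spectra:
        entries.append({
            "m/z array": s.mz_array(),
            "intensity array": s.intensity_array(),
            "params": {"title": s.name,
                       **({"pepmass": s.precursor_mz} if s.precursor_mz else {})},
        })
    mgf.write(entries, path, file_mode="w")


# ---------------------------------------------------------------------------
# Feature naming and matrix CSV
# ---------------------------------------------------------------------------

def feature_name(mz: float, rt: float, ccs: float | None = None) -> str:
    """Render the canonical ``m/z@RT`` (or ``m/z@RT(CCS)``) column name:
    m/z to 4 decimals, RT to 2 decimals (minutes)."""
    base = f"{mz:.4f}@{rt:.2f}"
    return f"{base}({ccs:.1f})" if ccs is not None else base


def parse_feature_name(name: str) -> tuple[float, float, float | None]:
    base, _, idx = name.partition("#")
    ccs = None
    if "(" in base:
        base, _, rest = base.partition("(")
        ccs = float(rest.rstrip(")"))
    mz_s, _, rt_s = base.partition("@")
    return float(mz_s), float(rt_s), ccs


def export_matrix(matrix, path: str, include_annotations: bool = False,
                  annotations=None, include_super: bool = True) -> None:
    """Write a data matrix to CSV: one row per sample, feature names as
    column headers; annotation rows (prefixed ``#``) appended on request."""
    df = matrix.areas.copy()
    if include_super and getattr(matrix, "super_sample", None) is not None:
        df = pd.concat([df, matrix.super_sample.to_frame("SuperSample").T])
    df.index.name = "sample"
    with open(path, "w") as fh:
        df.to_csv(fh)
        if include_annotations and annotations:
            best: dict[str, object] = {}
            for a in annotations:
                cur = best.get(a.feature)
                if cur is None or a.os > cur.os:
                    best[a.feature] = a
            for label, getter in (
                ("#annotation_compound", lambda a: a.compound_name),
                ("#annotation_adduct", lambda a: a.adduct),
                ("#annotation_OS", lambda a: f"{a.os:.2f}"),
                ("#annotation_color", lambda a: a.color),
            ):
                row = [label] + [str(getter(best[c])) if c in best else ""
                                 for c in df.columns]
                fh.write(",".join(row) + "\n")


def import_matrix_csv(path: str):
    """Re-import a matrix CSV written by :func:`export_matrix`."""
    from .features import DataMatrix, Feature

    df = pd.read_csv(path, index_col=0, comment="#")
    if "SuperSample" in df.index:
        df = df.drop(index="SuperSample")
    feats = {}
    for name in df.columns:
        mz, rt, ccs = parse_feature_name(name)
        feats[name] = Feature(mz=mz, rt=rt, ccs=ccs)
    return DataMatrix(areas=df, features=feats, operation="import_csv")


# ---------------------------------------------------------------------------
# Session persistence
# ---------------------------------------------------------------------------

def save_session(directory: str, matrix, runs: dict[str, Run] | None = None,
                 annotations=None) -> None:
    """Persist a session as a directory: JSON manifest + CSV matrix + mzML."""
    os.makedirs(directory, exist_ok=True)
    export_matrix(matrix, os.path.join(directory, "matrix.csv"))
    manifest = {
        "samples": list(matrix.areas.index),
        "features": list(matrix.areas.columns),
        "runs": [],
        "operation_chain": matrix.operation_chain(),
    }
    if runs:
        for sid, run in runs.items():
            fn = f"run_{sid}.mzML"
            write_run(run, os.path.join(directory, fn))
            manifest["runs"].append({"sample": sid, "file": fn, "role": run.role,
                                     "batch": run.batch, "polarity": run.polarity})
    if annotations is not None:
        from .annotate import annotations_to_frame

        annotations_to_frame(annotations).to_csv(
            os.path.join(directory, "annotations.csv"), index=False)
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_session(directory: str):
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    matrix = import_matrix_csv(os.path.join(directory, "matrix.csv"))
    runs = {}
    for entry in manifest.get("runs", []):
        runs[entry["sample"]] = read_run(os.path.join(directory, entry["file"]),
                                         sample_id=entry["sample"],
                                         role=entry.get("role", "sample"),
                                         batch=entry.get("batch", "batch1"))
    return matrix, runs, manifest
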