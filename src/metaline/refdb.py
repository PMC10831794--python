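"""Reference-database manager: build, validate, extend and isotope-label
compound databases used for identification.

Databases persist as a human-diffable directory (JSON index + one MSP file
per polarity).  Spectra imported from public sources can be cleaned by an
import threshold and validated against in-silico fragments so that every
kept peak carries an elemental composition; that composition is what makes
exact 13C label conversion of fragment m/z possible.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import chem
from .msio import Run, SpectrumRecord, read_spectra, write_spectra


@dataclass
class CompoundRecord:
    id: str
    name: str
    formula: chem.Formula
    monoisotopic_mass: float
    structure: object | None = None          # RDKit Mol when available
    smiles: str | None = None
    spectra: dict[str, SpectrumRecord] = field(default_factory=dict)  # adduct -> spectrum
    rt: float | None = None                  # minutes
    ccs: float | None = None                 # A^2
    compound_class: str = ""
    subclass: str = ""
    external_ids: dict[str, str] = field(default_factory=dict)
    label_state: str = "unlabeled"           # unlabeled | 13C-full | custom

    def __post_init__(self):
        expect = chem.monoisotopic_mass(self.formula)
        if abs(expect - self.monoisotopic_mass) > 1e-4:
            raise ValueError(
                f"{self.id}: mass {self.monoisotopic_mass} inconsistent with "
                f"formula {self.formula} ({expect:.5f})")


@dataclass
class ReferenceDB:
    records: list[CompoundRecord] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate record ids")

    def get(self, rid: str) -> CompoundRecord | None:
        return next((r for r in self.records if r.id == rid), None)

    def append_log(self, msg: str) -> None:
        self.log.append(msg)

    @property
    def polarity_coverage(self) -> set[str]:
        return {s.polarity for r in self.records for s in r.spectra.values()}


# ---------------------------------------------------------------------------
# Imports
# ---------------------------------------------------------------------------

_SDF_NAME_FIELDS = ("GENERIC_NAME", "NAME", "SYNONYMS")


def import_sdf(path: str, spectra_dir: str | None = None,
               import_threshold: float = 0.5) -> ReferenceDB:
    """Build a database from a V2000 SDF (HMDB-dialect property fields
    ``HMDB_ID``/``FORMULA``/``EXACT_MASS`` recognized).

    Linked spectra are read from ``spectra_dir`` as ``<id>.msp``; peaks
    below ``import_threshold`` percent of the base peak are dropped at
    import.  Records whose stated formula/mass disagree with the structure
    are skipped with a log entry.
    """
    from rdkit import Chem
    from rdkit.Chem import rdMolDescriptors

    db = ReferenceDB()
    supplier = Chem.SDMolSupplier(path, sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            db.append_log(f"record {i}: unparseable structure, skipped")
            continue
        props = mol.GetPropsAsDict()
        rid = str(props.get("HMDB_ID", props.get("DATABASE_ID", f"rec{i}")))
        name = next((str(props[k]) for k in _SDF_NAME_FIELDS if k in props),
                    rid)
        mol_formula = rdMolDescriptors.CalcMolFormula(mol).rstrip("+-")
        formula_text = str(props.get("FORMULA", mol_formula))
        try:
            formula = chem.parse_formula(formula_text)
        except chem.FormulaError as exc:
            db.append_log(f"{rid}: bad formula ({exc}), skipped")
            continue
        mass = chem.monoisotopic_mass(formula)
        if abs(mass - chem.monoisotopic_mass(mol_formula)) > 1e-3:
            db.append_log(f"{rid}: formula/structure mismatch, skipped")
            continue
        if "EXACT_MASS" in props and abs(float(props["EXACT_MASS"]) - mass) > 0.01:
            db.append_log(f"{rid}: stated exact mass disagrees, skipped")
            continue
        rec = CompoundRecord(
            id=rid, name=name, formula=formula, monoisotopic_mass=mass,
            structure=mol, smiles=Chem.MolToSmiles(mol),
            compound_class=str(props.get("CLASS", "")),
            subclass=str(props.get("SUB_CLASS", "")),
            external_ids={"HMDB_ID": rid} if "HMDB_ID" in props else {})
        if spectra_dir:
            spath = os.path.join(spectra_dir, f"{rid}.msp")
            if os.path.exists(spath):
                for spec in read_spectra(spath):
                    kept = [(m, i2) for m, i2 in spec.peaks if i2 >= import_threshold]
                    adduct = spec.metadata.get("adduct",
                                               "[M+H]+" if spec.polarity == "positive" else "[M-H]-")
                    rec.spectra[adduct] = replace(spec, peaks=kept)
        db.records.append(rec)
        db.append_log(f"{rid}: imported")
    # orphan spectra
    if spectra_dir and os.path.isdir(spectra_dir):
        known = {r.id for r in db.records}
        for fn in sorted(os.listdir(spectra_dir)):
            rid = os.path.splitext(fn)[0]
            if fn.endswith(".msp") and rid not in known:
                db.append_log(f"orphan spectrum file {fn}: no matching record")
    return db


def attach_rt_ccs(db: ReferenceDB, csv_path: str) -> ReferenceDB:
    """Attach RT and/or CCS values from a ``compound_id,rt_min,ccs`` CSV."""
    table = pd.read_csv(csv_path)
    for _, row in table.iterrows():
        rec = db.get(str(row["compound_id"]))
        if rec is None:
            db.append_log(f"rt/ccs row {row['compound_id']}: unknown id")
            continue
        if "rt_min" in row and pd.notna(row.get("rt_min")):
            rec.rt = float(row["rt_min"])
        if "ccs" in row and pd.notna(row.get("ccs")):
            rec.ccs = float(row["ccs"])
    return db


def import_inhouse(manifest: pd.DataFrame, runs: dict[str, Run],
                   mz_tol_ppm: float = 5.0, rt_tol: float = 0.2) -> ReferenceDB:
    """Build an in-house library from standards acquisitions.

    ``manifest`` rows: compound, formula, adduct, rt, run (the key into
    ``runs``).  For each row the EIC apex at the adduct m/z near the stated
    RT is located; its linked MS/MS becomes the record's spectrum and the
    observed apex RT is stored.  Rows whose peak cannot be found are skipped
    with a log entry; duplicate rows merge their spectra.
    """
    db = ReferenceDB()
    for _, row in manifest.iterrows():
        cid = str(row["compound"])
        formula = chem.parse_formula(str(row["formula"]))
        adduct = str(row["adduct"])
        mz0 = chem.adduct_mz(chem.monoisotopic_mass(formula), adduct)
        run = runs.get(str(row["run"]))
        if run is None:
            db.append_log(f"{cid}: run {row['run']} not available, skipped")
            continue
        best = None
        for scan in run.ms1:
            if abs(scan.rt - float(row["rt"])) > rt_tol:
                continue
            sel = np.abs(scan.mz - mz0) <= mz0 * mz_tol_ppm * 1e-6
            if sel.any():
                inten = float(scan.intensity[sel].max())
                if best is None or inten > best[1]:
                    best = (scan.rt, inten)
        if best is None:
            db.append_log(f"{cid}: no peak at {mz0:.4f} near RT {row['rt']}, skipped")
            continue
        spectrum = None
        for s2 in run.ms2:
            if (s2.precursor_mz is not None
                    and abs(s2.precursor_mz - mz0) <= mz0 * mz_tol_ppm * 1e-6
                    and abs(s2.rt - best[0]) <= rt_tol):
                spectrum = SpectrumRecord(list(zip(s2.mz, s2.intensity)), mz0,
                                          run.polarity, "experimental", name=cid)
                break
        rec = db.get(cid)
        if rec is None:
            rec = CompoundRecord(id=cid, name=cid, formula=formula,
                                 monoisotopic_mass=chem.monoisotopic_mass(formula),
                                 rt=float(best[0]))
            db.records.append(rec)
        if spectrum is not None:
            if adduct in rec.spectra:
                merged = SpectrumRecord(rec.spectra[adduct].peaks + spectrum.peaks,
                                        mz0, run.polarity, "merged", name=cid)
                rec.spectra[adduct] = merged
            else:
                rec.spectra[adduct] = spectrum
        db.append_log(f"{cid}: imported from run {row['run']}")
    return db


# ---------------------------------------------------------------------------
# MS/MS validator
# ---------------------------------------------------------------------------

def validate_spectrum(record: CompoundRecord, spectrum: SpectrumRecord,
                      mz_tol: float = 0.01, discard_unmatched: bool = False
                      ) -> SpectrumRecord:
    """Check a spectrum against in-silico fragments of the record.

    Peaks matching a calculated fragment keep that fragment's formula; the
    precursor peak is always kept; remaining peaks are flagged unmatched
    (and dropped only when ``discard_unmatched``).  The result carries
    provenance ``validated`` and the operation is idempotent.
    """
    candidates: list[tuple[float, chem.Formula]] = []
    mode = spectrum.polarity
    if record.structure is not None or record.smiles:
        fs = chem.fragment_in_silico(record.structure or record.smiles,
                                     depth=2, mode=mode, parent_id=record.id)
        candidates = [(fr.mz, fr.formula) for fr in fs.fragments]
    elif record.formula is not None:
        # formula-only: neutral-loss ions of the precursor
        ion = (record.formula + chem.parse_formula("H")
               if mode == "positive"
               else record.formula.subtract(chem.parse_formula("H")))
        if ion is not None:
            for loss_text in chem.NEUTRAL_LOSSES.values():
                for k in (1, 2):
                    sub = ion
                    for _ in range(k):
                        sub = sub.subtract(chem.parse_formula(loss_text)) if sub else None
                    if sub is not None and sub.n_atoms:
                        mz = chem.monoisotopic_mass(sub) + (
                            -chem.ELECTRON_MASS if mode == "positive" else chem.ELECTRON_MASS)
                        candidates.append((mz, sub))
    else:
        raise ValueError("record has neither structure nor formula")

    kept, formulas, unmatched = [], {}, []
    for mz, inten in spectrum.peaks:
        is_precursor = (spectrum.precursor_mz is not None
                        and abs(mz - spectrum.precursor_mz) <= mz_tol)
        hit = next(((fmz, f) for fmz, f in candidates if abs(fmz - mz) <= mz_tol),
                   None)
        if hit is not None:
            formulas[len(kept)] = hit[1].hill()
            kept.append((mz, inten))
        elif is_precursor:
            kept.append((mz, inten))
        elif not discard_unmatched:
            unmatched.append(len(kept))
            kept.append((mz, inten))
    return SpectrumRecord(kept, spectrum.precursor_mz, spectrum.polarity,
                          "validated", spectrum.name, dict(spectrum.metadata),
                          formulas, unmatched)


def validate_db(db: ReferenceDB, mz_tol: float = 0.01,
                discard_unmatched: bool = False) -> ReferenceDB:
    for rec in db.records:
        for adduct, spec in list(rec.spectra.items()):
            rec.spectra[adduct] = validate_spectrum(rec, spec, mz_tol,
                                                    discard_unmatched)
        db.append_log(f"{rec.id}: spectra validated")
    return db


# ---------------------------------------------------------------------------
# User promotions and labeling
# ---------------------------------------------------------------------------

def promote_annotation(db: ReferenceDB, annotation, spectrum: SpectrumRecord,
                       formula: chem.Formula | None = None) -> ReferenceDB:
    """Attach an approved annotation's merged spectrum to the database.

    Known compounds get the spectrum under the annotation's adduct (merged
    with an existing one); approved identifications of originally unknown
    metabolites create a new record.
    """
    rid = getattr(annotation, "compound_id", None) or getattr(annotation, "compound_name", None)
    adduct = getattr(annotation, "adduct", "[M+H]+")
    rec = db.get(rid) if rid else None
    if rec is None:
        if formula is None:
            raise ValueError("promoting an unknown compound requires a formula")
        rec = CompoundRecord(id=rid or f"user{len(db.records)}",
                             name=rid or "user compound", formula=formula,
                             monoisotopic_mass=chem.monoisotopic_mass(formula))
        db.records.append(rec)
        db.append_log(f"{rec.id}: new user record from approved annotation")
    if adduct in rec.spectra:
        rec.spectra[adduct] = SpectrumRecord(
            rec.spectra[adduct].peaks + spectrum.peaks, spectrum.precursor_mz,
            spectrum.polarity, "merged", rec.name)
    else:
        rec.spectra[adduct] = replace(spectrum, provenance="experimental")
    db.append_log(f"{rec.id}: spectrum promoted for {adduct}")
    return db


def build_labeled_db(db: ReferenceDB) -> ReferenceDB:
    """Convert a database to fully 13C-labeled records.

    Precursor masses shift by ``n_C * 1.0033548``; validated spectrum peaks
    (those carrying a fragment formula) shift by their own fragment carbon
    count; unvalidated peaks are dropped with a warning since their
    composition, hence shift, is unknown.
    """
    out = ReferenceDB(log=list(db.log))
    for rec in db.records:
        labeled = chem.convert_to_13C(rec.formula)
        spectra = {}
        for adduct, spec in rec.spectra.items():
            peaks, formulas = [], {}
            dropped = 0
            for i, (mz, inten) in enumerate(spec.peaks):
                ftext = spec.fragment_formulas.get(i)
                if ftext is None:
                    if (spec.precursor_mz is not None
                            and abs(mz - spec.precursor_mz) < 0.01):
                        shift = rec.formula.n_carbon * chem.C13_DELTA
                        peaks.append((mz + shift, inten))
                    else:
                        dropped += 1
                    continue
                ffrag = chem.parse_formula(ftext)
                shift = ffrag.n_carbon * chem.C13_DELTA
                formulas[len(peaks)] = chem.convert_to_13C(ffrag).hill()
                peaks.append((mz + shift, inten))
            if dropped:
                warnings.warn(
                    f"{rec.id}/{adduct}: {dropped} unvalidated peaks omitted "
                    "from the labeled spectrum")
            prec = spec.precursor_mz
            if prec is not None:
                prec = prec + rec.formula.n_carbon * chem.C13_DELTA
            spectra[adduct] = SpectrumRecord(peaks, prec, spec.polarity,
                                             spec.provenance, spec.name,
                                             dict(spec.metadata), formulas)
        out.records.append(CompoundRecord(
            id=rec.id, name=rec.name, formula=labeled,
            monoisotopic_mass=chem.monoisotopic_mass(labeled),
            structure=rec.structure, smiles=rec.smiles, spectra=spectra,
            rt=rec.rt, ccs=rec.ccs, compound_class=rec.compound_class,
            subclass=rec.subclass, external_ids=dict(rec.external_ids),
            label_state="13C-full"))
        out.append_log(f"{rec.id}: converted to 13C-full")
    return out


# ---------------------------------------------------------------------------
# Persistence (JSON index + MSP per polarity)
# ---------------------------------------------------------------------------

def save_db(db: ReferenceDB, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    index = []
    by_pol: dict[str, list[SpectrumRecord]] = {}
    for rec in db.records:
        entry = {
            "id": rec.id, "name": rec.name, "formula": rec.formula.hill(),
            "mass": rec.monoisotopic_mass, "rt": rec.rt, "ccs": rec.ccs,
            "class": rec.compound_class, "subclass": rec.subclass,
            "smiles": rec.smiles, "external_ids": rec.external_ids,
            "label_state": rec.label_state, "spectra": [],
        }
        for adduct, spec in rec.spectra.items():
            key = f"{rec.id}|{adduct}"
            entry["spectra"].append({"adduct": adduct, "key": key,
                                     "polarity": spec.polarity})
            tagged = replace(spec, name=key,
                             metadata={**spec.metadata, "adduct": adduct,
                                       "fragment_formulas": json.dumps(spec.fragment_formulas),
                                       "unmatched": json.dumps(spec.unmatched)})
            by_pol.setdefault(spec.polarity, []).append(tagged)
        index.append(entry)
    with open(os.path.join(directory, "index.json"), "w") as fh:
        json.dump({"records": index, "log": db.log}, fh, indent=1)
    for pol, spectra in by_pol.items():
        write_spectra(spectra, os.path.join(directory, f"spectra_{pol}.msp"))


def load_db(directory: str) -> ReferenceDB:
    with open(os.path.join(directory, "index.json")) as fh:
        data = json.load(fh)
    spectra: dict[str, SpectrumRecord] = {}
    for pol in ("positive", "negative"):
        path = os.path.join(directory, f"spectra_{pol}.msp")
        if os.path.exists(path):
            for spec in read_spectra(path):
                ff = json.loads(spec.metadata.get("fragment_formulas", "{}"))
                um = json.loads(spec.metadata.get("unmatched", "[]"))
                spec.fragment_formulas = {int(k): v for k, v in ff.items()}
                spec.unmatched = list(um)
                spec.polarity = pol
                spec.provenance = spec.metadata.get("provenance", spec.provenance)
                spectra[spec.name] = spec
    db = ReferenceDB(log=list(data.get("log", [])))
    for entry in data["records"]:
        rec = CompoundRecord(
            id=entry["id"], name=entry["name"],
            formula=chem.parse_formula(entry["formula"]),
            monoisotopic_mass=entry["mass"], smiles=entry.get("smiles"),
            rt=entry.get("rt"), ccs=entry.get("ccs"),
            compound_class=entry.get("class", ""),
            subclass=entry.get("subclass", ""),
            external_ids=entry.get("external_ids", {}),
            label_state=entry.get("label_state", "unlabeled"))
        for sp in entry["spectra"]:
            if sp["key"] in spectra:
                rec.spectra[sp["adduct"]] = spectra[sp["key"]]
        db.records.append(rec)
    return db
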