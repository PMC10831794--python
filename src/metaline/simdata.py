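"""Synthetic multi-sample LC-MS studies with known ground truth.

The generator emulates the structures the downstream algorithms assume:
each compound emits its adduct ions at the exact theoretical m/z with a
natural-abundance isotope envelope, optional in-source fragments coeluting
at the same RT, Gaussian chromatographic peaks, per-sample areas following
a group trend with multiplicative lognormal noise, DDA MS/MS on the
protonated precursor, missing low-intensity peaks (gaps) below an emission
floor, and optional blank contamination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import chem
from .msio import Run, Scan, SpectrumRecord

#: Gaussian peak sigma such that the default "width" (FWHM) is 0.1 min.
DEFAULT_PEAK_FWHM = 0.1


@dataclass
class SimCompound:
    name: str
    formula: str
    rt: float                      # minutes
    base_area: float = 1e6
    adducts: tuple[str, ...] = ("[M+H]+",)
    isf_losses: tuple[str, ...] = ()      # e.g. ("H2O",) or ("NH3",)
    group_means: dict[str, float] = field(default_factory=dict)  # group -> multiplier
    in_blank: bool = False


@dataclass
class EmittedIon:
    compound: str
    adduct: str
    loss: str | None               # neutral loss for ISF ions
    isotopologue: int
    mz: float
    true_area: dict[str, float]    # per sample (0 when not emitted)
    apex: dict[str, float]
    emitted: dict[str, bool]


@dataclass
class GroundTruth:
    compounds: list[SimCompound]
    ions: list[EmittedIon]
    design: dict[str, list[str]]   # group -> sample ids
    seed: int

    def ions_for(self, compound: str) -> list[EmittedIon]:
        return [i for i in self.ions if i.compound == compound]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({
                "seed": self.seed,
                "design": self.design,
                "compounds": [asdict(c) for c in self.compounds],
                "ions": [asdict(i) for i in self.ions],
            }, fh, indent=1)


def reference_fragments(formula: str, polarity: str = "positive",
                        adduct: str = "[M+H]+") -> list[tuple[float, float]]:
    """Deterministic reference MS/MS peak list for a formula: the precursor's
    small-neutral-loss ions plus two deeper pseudo-fragments, with fixed
    relative intensities.  Used both for the emitted DDA spectra and for
    building the matching reference database, so spectral recovery against a
    complete database is exact by construction."""
    f = chem.parse_formula(formula)
    mass = chem.monoisotopic_mass(f)
    prec = chem.adduct_mz(mass, adduct)
    losses = ["H2O", "NH3", "CO2", "CH2O2", "C2H4O2"]
    peaks = []
    inten = 100.0
    for loss in losses:
        sub = f.subtract(chem.parse_formula(loss))
        if sub is not None and sub.n_atoms > 1:
            peaks.append((chem.adduct_mz(chem.monoisotopic_mass(sub), adduct), inten))
            inten *= 0.75
    if not peaks:
        peaks = [(prec * 0.5, 100.0)]
    return sorted(peaks)


def default_compound_library(n: int = 20, rt_start: float = 1.0,
                             rt_step: float = 0.25) -> list[SimCompound]:
    """A ladder of n amino-acid-like compositions (all contain N and O so
    every built-in neutral loss is available), well separated in m/z and RT."""
    out = []
    for i in range(n):
        c = 6 + i
        h = 2 * c - 3
        formula = f"C{c}H{h}NO2"
        out.append(SimCompound(name=f"cmpd{i:02d}", formula=formula,
                               rt=rt_start + i * rt_step))
    return out


def simulate_study(compounds: list[SimCompound],
                   design: dict[str, int] | dict[str, list[str]],
                   noise_sigma: float = 0.15,
                   emission_floor: float = 0.0,
                   seed: int = 0,
                   rt_max: float | None = None,
                   scan_interval: float = 0.01,
                   peak_fwhm: float = DEFAULT_PEAK_FWHM,
                   k_isotopologues: int = 3,
                   noise_peaks_per_scan: int = 0,
                   n_blanks: int = 0,
                   blank_fraction: float = 0.02,
                   dda: bool = True,
                   polarity: str = "positive") -> tuple[dict[str, Run], GroundTruth]:
    """Simulate a multi-sample study and return (runs by sample, ground truth).

    ``design`` maps group name -> replicate count (or explicit sample ids).
    Per-sample areas are ``base_area * group_mean * lognormal(sigma)``; peaks
    whose apex intensity falls below ``emission_floor`` are omitted entirely,
    creating gaps with known provenance.  With the same seed the output is
    bit-identical.
    """
    if not compounds:
        raise ValueError("need at least one compound")
    if not design:
        raise ValueError("empty design")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[str]] = {}
    for g, v in design.items():
        groups[g] = list(v) if isinstance(v, (list, tuple)) else [
            f"{g}_{r + 1}" for r in range(int(v))]
        if not groups[g]:
            raise ValueError(f"empty group {g!r}")
    samples = [s for g in groups.values() for s in g]
    blanks = [f"blank_{b + 1}" for b in range(n_blanks)]

    sigma_rt = peak_fwhm / 2.3548200450309493  # FWHM -> Gaussian sigma
    if rt_max is None:
        rt_max = max(c.rt for c in compounds) + 1.0
    grid = np.arange(scan_interval, rt_max, scan_interval)

    # ion table with per-sample true areas
    ions: list[EmittedIon] = []
    areas_by_sample: dict[str, list[float]] = {s: [] for s in samples + blanks}
    for c in compounds:
        pattern = chem.theoretical_isotope_pattern(c.formula, k_isotopologues)
        mass = chem.monoisotopic_mass(c.formula)
        comp_area: dict[str, float] = {}
        for g, ss in groups.items():
            mean = c.group_means.get(g, 1.0) * c.base_area
            for s in ss:
                noise = float(np.exp(rng.normal(0.0, noise_sigma))) if noise_sigma > 0 else 1.0
                comp_area[s] = mean * noise
        for s in blanks:
            comp_area[s] = c.base_area * blank_fraction if c.in_blank else 0.0

        targets: list[tuple[str, str | None, float, float]] = []
        for ad in c.adducts:
            targets.append((ad, None, chem.adduct_mz(mass, ad), 1.0))
        for loss in c.isf_losses:
            sub = chem.parse_formula(c.formula).subtract(chem.parse_formula(loss))
            if sub is None:
                continue
            ad = c.adducts[0]
            targets.append((ad, loss, chem.adduct_mz(chem.monoisotopic_mass(sub), ad), 0.4))
        for ad, loss, mz0, scale in targets:
            for k in range(k_isotopologues):
                rel = pattern.abundances[k]
                if rel <= 0:
                    continue
                true_area, apex, emitted = {}, {}, {}
                for s in samples + blanks:
                    a = comp_area[s] * scale * rel
                    ap = a / (sigma_rt * np.sqrt(2 * np.pi))
                    ok = a > 0 and ap >= emission_floor
                    true_area[s] = a if ok else 0.0
                    apex[s] = ap if ok else 0.0
                    emitted[s] = bool(ok)
                ions.append(EmittedIon(c.name, ad, loss, k,
                                       mz0 + pattern.offsets[k], true_area,
                                       apex, emitted))

    runs: dict[str, Run] = {}
    for s in samples + blanks:
        ms1 = []
        for rt in grid:
            mzs, intens = [], []
            for ion in ions:
                if not ion.emitted.get(s):
                    continue
                d = rt - _ion_rt(ion, compounds)
                if abs(d) > 5 * sigma_rt:
                    continue
                inten = ion.apex[s] * np.exp(-0.5 * (d / sigma_rt) ** 2)
                if inten > 0:
                    mzs.append(ion.mz)
                    intens.append(inten)
            for _ in range(noise_peaks_per_scan):
                mzs.append(float(rng.uniform(60, 600)))
                intens.append(float(rng.uniform(1, 50)))
            order = np.argsort(mzs)
            ms1.append(Scan(float(rt), np.array(mzs)[order],
                            np.array(intens)[order], 1))
        ms2 = []
        if dda:
            for c in compounds:
                prec = chem.adduct_mz(chem.monoisotopic_mass(c.formula), c.adducts[0])
                ion0 = next((i for i in ions if i.compound == c.name
                             and i.loss is None and i.isotopologue == 0
                             and i.adduct == c.adducts[0]), None)
                if ion0 is None or not ion0.emitted.get(s):
                    continue
                peaks = reference_fragments(c.formula, polarity, c.adducts[0])
                scale = ion0.apex[s] / 100.0
                ms2.append(Scan(c.rt + scan_interval / 2,
                                np.array([m for m, _ in peaks]),
                                np.array([i * scale for _, i in peaks]),
                                2, prec))
            ms2.sort(key=lambda sc: sc.rt)
        role = "blank" if s in [*blanks] else "sample"
        runs[s] = Run(s, polarity, ms1, ms2, role=role)

    gt_design = dict(groups)
    if blanks:
        gt_design["blank"] = blanks
    return runs, GroundTruth(compounds, ions, gt_design, seed)


def _ion_rt(ion: EmittedIon, compounds: list[SimCompound]) -> float:
    for c in compounds:
        if c.name == ion.compound:
            return c.rt
    raise KeyError(ion.compound)


def simulate_calibration(compound: SimCompound, levels: list[float],
                         response_slope: float = 1e4, noise_sigma: float = 0.0,
                         heteroscedastic: bool = False, seed: int = 0
                         ) -> list[tuple[float, float]]:
    """Calibration points for a standard: area = slope * conc * (1 + eps).

    With ``heteroscedastic`` the relative error is constant (so absolute
    error grows with concentration), the regime where 1/x^2-weighted fits
    beat unweighted ones.  Returns (concentration, area) pairs.
    """
    if len(levels) < 3:
        raise ValueError("need at least 3 calibration levels")
    if any(c <= 0 for c in levels):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for conc in levels:
        eps = rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0
        if heteroscedastic:
            area = response_slope * conc * (1.0 + eps)
        else:
            area = response_slope * conc + response_slope * levels[0] * eps
        out.append((float(conc), float(max(area, 0.0))))
    return out


def reference_db_for(compounds: list[SimCompound], polarity: str = "positive"):
    """Build the complete matching reference database for a simulated study
    (formulas, RTs and the same deterministic fragment spectra the DDA scans
    carry)."""
    from .refdb import CompoundRecord, ReferenceDB

    records = []
    for c in compounds:
        f = chem.parse_formula(c.formula)
        spectra = {}
        for ad in c.adducts:
            peaks = reference_fragments(c.formula, polarity, ad)
            spectra[ad] = SpectrumRecord(peaks,
                                         chem.adduct_mz(chem.monoisotopic_mass(f), ad),
                                         polarity, "predicted", name=c.name)
        records.append(CompoundRecord(id=c.name, name=c.name, formula=f,
                                      monoisotopic_mass=chem.monoisotopic_mass(f),
                                      rt=c.rt, spectra=spectra,
                                      external_ids={"HMDB_ID": f"SIM{c.name}"}))
    return ReferenceDB(records=records)
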