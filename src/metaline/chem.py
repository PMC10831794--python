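"""Molecular formula arithmetic, adduct m/z computation, isotope patterns,
in-silico fragmentation, biotransformation rules and 13C label conversion.

All masses are monoisotopic and derive from a single hard-coded table of
CODATA/NIST values (given to >= 6 decimals below); nothing in the package
computes a mass through any other route, so adduct arithmetic, isotope
spacings and label shifts are exactly self-consistent.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np

#: Electron mass, Da (CODATA).
ELECTRON_MASS = 0.000548579909

#: Mass difference between 13C and 12C, Da; also the canonical isotopologue
#: spacing used throughout (isotope clustering, label conversion).
C13_DELTA = 1.0033548378

#: Principal-isotope (monoisotopic) masses, Da.  NIST atomic mass evaluation.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "D": 2.0141017781,
    "C": 12.0,
    "13C": 12.0 + C13_DELTA,   # pseudo-element for uniformly labeled carbon
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984031627,
    "Na": 22.9897692820,
    "Mg": 23.9850416980,
    "Si": 27.9769265347,
    "P": 30.9737615120,
    "S": 31.9720706912,
    "Cl": 34.9688527100,
    "K": 38.9637064864,
    "Ca": 39.9625908560,
    "Fe": 55.9349363000,
    "Cu": 62.9295977200,
    "Zn": 63.9291420100,
    "Se": 79.9165218000,
    "Br": 78.9183376000,
    "I": 126.9044719000,
}

#: Natural isotope distributions as (neutron offset, abundance) per element.
#: Offsets are relative to the principal isotope.  Elements absent here are
#: treated as monoisotopic.
ISOTOPE_DISTRIBUTIONS: dict[str, list[tuple[int, float]]] = {
    "H": [(0, 0.999885), (1, 0.000115)],
    "C": [(0, 0.9893), (1, 0.0107)],
    "13C": [(0, 1.0)],
    "N": [(0, 0.99636), (1, 0.00364)],
    "O": [(0, 0.99757), (1, 0.00038), (2, 0.00205)],
    "S": [(0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)],
    "Cl": [(0, 0.7576), (2, 0.2424)],
    "K": [(0, 0.932581), (1, 0.000117), (2, 0.067302)],
    "Br": [(0, 0.5069), (2, 0.4931)],
    "Si": [(0, 0.92223), (1, 0.04685), (2, 0.03092)],
    "Se": [(0, 0.4961), (-4, 0.0089), (-3, 0.0937), (-2, 0.0763), (-1, 0.2377), (2, 0.0873)],
    "Zn": [(0, 0.4917), (2, 0.2773), (3, 0.0404), (4, 0.1845), (6, 0.0061)],
    "Fe": [(0, 0.91754), (-2, 0.05845), (1, 0.02119), (2, 0.00282)],
}

_FORMULA_TOKEN = re.compile(r"(\[13C\]|[A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula text or unknown element symbol."""


@dataclass(frozen=True)
class Formula:
    """Elemental composition with optional net charge.

    Counts are non-negative integers keyed by element symbol; the pseudo
    element ``13C`` represents uniformly labeled carbon.
    """

    counts: tuple[tuple[str, int], ...]
    charge: int = 0

    def __post_init__(self):
        for el, n in self.counts:
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")

    @classmethod
    def from_dict(cls, d: dict[str, int], charge: int = 0) -> "Formula":
        items = tuple(sorted((el, int(n)) for el, n in d.items() if n))
        return cls(items, charge)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, el: str) -> int:
        return dict(self.counts).get(el, 0)

    def __add__(self, other: "Formula") -> "Formula":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return Formula.from_dict(d, self.charge + other.charge)

    def subtract(self, other: "Formula") -> "Formula | None":
        """Element-wise difference, or None when any count would go negative."""
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) - n
            if d[el] < 0:
                return None
        return Formula.from_dict(d, self.charge - other.charge)

    def contains(self, other: "Formula") -> bool:
        return self.subtract(other) is not None

    @property
    def n_atoms(self) -> int:
        return sum(n for _, n in self.counts)

    @property
    def n_carbon(self) -> int:
        return self["C"] + self["13C"]

    def hill(self) -> str:
        """Canonical Hill-order string (C, H, then alphabetical)."""
        d = self.as_dict()
        c13 = d.pop("13C", 0)
        parts = []
        if "C" in d or c13:
            for el in ("C", "H"):
                n = d.pop(el, 0)
                if el == "C" and c13:
                    parts.append(f"[13C]{c13 if c13 > 1 else ''}")
                if n:
                    parts.append(f"{el}{n if n > 1 else ''}")
        for el in sorted(d):
            n = d[el]
            parts.append(f"{el}{n if n > 1 else ''}")
        return "".join(parts) or ""

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str) -> Formula:
    """Parse a Hill-notation molecular formula such as ``C11H12N2O2``.

    Raises :class:`FormulaError` on empty input, unknown element symbols or
    malformed counts; the result round-trips through :meth:`Formula.hill`.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        el = m.group(1).strip("[]")
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol: {el!r}")
        n = int(m.group(2)) if m.group(2) else 1
        if n == 0:
            raise FormulaError(f"zero count for {el} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return Formula.from_dict(counts)


def monoisotopic_mass(f: Formula | str | dict) -> float:
    """Monoisotopic mass in Da: sum of principal-isotope masses minus
    ``charge`` electron masses for charged species."""
    if isinstance(f, str):
        f = parse_formula(f)
    elif isinstance(f, dict):
        f = Formula.from_dict(f)
    m = sum(MONOISOTOPIC_MASS[el] * n for el, n in f.counts)
    return m - f.charge * ELECTRON_MASS


# ---------------------------------------------------------------------------
# Adducts
# ---------------------------------------------------------------------------

_ADDUCT_RE = re.compile(r"^\[(\d*)M((?:[+-][A-Za-z0-9]+)*)\](\d*)([+-])$")
_TERM_RE = re.compile(r"([+-])(\d*)([A-Za-z][A-Za-z0-9]*)")


@dataclass(frozen=True)
class AdductDef:
    """An ionization adduct such as ``[M+H]+`` or ``[M-NH3+H]+``.

    ``delta_add``/``delta_sub`` are the formulas gained/lost relative to
    ``multimer`` copies of the neutral molecule; ``charge`` is signed.
    """

    name: str
    delta_add: Formula
    delta_sub: Formula
    charge: int
    multimer: int = 1

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError(f"adduct {self.name}: charge must be non-zero")
        if self.multimer < 1:
            raise ValueError(f"adduct {self.name}: multimer must be >= 1")

    @property
    def delta_mass(self) -> float:
        return monoisotopic_mass(self.delta_add) - monoisotopic_mass(self.delta_sub)

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"


def parse_adduct(name: str) -> AdductDef:
    """Parse adduct notation like ``[M+H]+``, ``[2M+Na]+``, ``[M-H]-``,
    ``[M+2H]2+`` or ``[M-NH3+H]+`` (ASCII or Unicode minus)."""
    norm = name.replace("−", "-").replace(" ", "")
    m = _ADDUCT_RE.match(norm)
    if not m:
        raise ValueError(f"cannot parse adduct notation: {name!r}")
    multimer = int(m.group(1)) if m.group(1) else 1
    z = int(m.group(3)) if m.group(3) else 1
    if m.group(4) == "-":
        z = -z
    add = Formula.from_dict({})
    sub = Formula.from_dict({})
    body = m.group(2)
    consumed = 0
    for t in _TERM_RE.finditer(body):
        consumed += len(t.group(0))
        mult = int(t.group(2)) if t.group(2) else 1
        f = parse_formula(t.group(3))
        f = Formula.from_dict({el: n * mult for el, n in f.counts})
        if t.group(1) == "+":
            add = add + f
        else:
            sub = sub + f
    if consumed != len(body):
        raise ValueError(f"cannot parse adduct terms in {name!r}")
    return AdductDef(norm, add, sub, z, multimer)


def adduct_mz(neutral_mass: float, adduct: AdductDef | str) -> float:
    """m/z of an adduct ion of a neutral molecule of ``neutral_mass`` Da:
    ``(n*M + delta - z*m_e) / |z|``."""
    if isinstance(adduct, str):
        adduct = parse_adduct(adduct)
    if neutral_mass < 0:
        raise ValueError("neutral mass must be non-negative")
    z = adduct.charge
    return (adduct.multimer * neutral_mass + adduct.delta_mass - z * ELECTRON_MASS) / abs(z)


COMMON_ADDUCTS_POS = ["[M+H]+", "[M+Na]+", "[M+K]+", "[M+NH4]+", "[2M+H]+", "[M-H2O+H]+", "[M-NH3+H]+"]
COMMON_ADDUCTS_NEG = ["[M-H]-", "[M+Cl]-", "[M-H2O-H]-", "[2M-H]-"]


# ---------------------------------------------------------------------------
# Isotope patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated (unit-mass) isotopologue pattern.

    ``offsets`` are mass offsets in Da from the monoisotopic peak, strictly
    increasing; ``abundances`` are normalized so the maximum equals 1.
    """

    offsets: tuple[float, ...]
    abundances: tuple[float, ...]

    def __post_init__(self):
        if len(self.offsets) != len(self.abundances) or not self.offsets:
            raise ValueError("pattern must have k >= 1 matching entries")
        if any(b > a for a, b in zip(self.offsets[1:], self.offsets)):
            raise ValueError("offsets must be strictly increasing")

    def __len__(self):
        return len(self.offsets)


def _element_distribution(el: str, n: int) -> np.ndarray:
    """Abundance distribution over neutron offsets for ``n`` atoms of ``el``,
    computed by repeated convolution (exact polynomial expansion)."""
    iso = ISOTOPE_DISTRIBUTIONS.get(el, [(0, 1.0)])
    shift = -min(o for o, _ in iso)
    base = np.zeros(max(o for o, _ in iso) + shift + 1)
    for off, ab in iso:
        base[off + shift] = ab
    out = np.array([1.0])
    # binary exponentiation keeps this fast for large counts
    power = base
    k = n
    while k:
        if k & 1:
            out = np.convolve(out, power)
        k >>= 1
        if k:
            power = np.convolve(power, power)
    # out index i corresponds to neutron offset i - n*shift
    return out if shift == 0 else np.concatenate([np.zeros(0), out])  # offsets handled by caller


def theoretical_isotope_pattern(f: Formula | str, k: int = 3, charge: int = 1) -> IsotopePattern:
    """First ``k`` isotopologue abundances of a formula.

    Uses exact per-element polynomial expansion convolved across elements,
    aggregated on the unit (neutron-count) grid; successive isotopologues
    are spaced by ``1.0033548/|charge|`` Da.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(f, str):
        f = parse_formula(f)
    dist = np.array([1.0])
    neg_shift = 0
    for el, n in f.counts:
        iso = ISOTOPE_DISTRIBUTIONS.get(el, [(0, 1.0)])
        lo = min(o for o, _ in iso)
        el_dist = _element_distribution(el, n)
        dist = np.convolve(dist, el_dist)
        neg_shift += -lo * n if lo < 0 else 0
    # drop offsets below the monoisotopic peak (from elements like Fe/Se
    # whose principal isotope is not the lightest); keep A+0 ... A+(k-1)
    start = neg_shift
    window = dist[start:start + k]
    if window.size < k:
        window = np.pad(window, (0, k - window.size))
    if window.max() <= 0:
        window = np.array([1.0] + [0.0] * (k - 1))
    window = window / window.max()
    z = max(1, abs(charge))
    offsets = tuple(i * C13_DELTA / z for i in range(k))
    return IsotopePattern(offsets, tuple(float(x) for x in window))


# ---------------------------------------------------------------------------
# In-silico fragmentation
# ---------------------------------------------------------------------------

#: Small-molecule neutral losses applied to the parent ion and to bond-cut
#: fragments (water, ammonia, CO, CO2, formic acid).
NEUTRAL_LOSSES: dict[str, str] = {
    "H2O": "H2O",
    "NH3": "NH3",
    "CO": "CO",
    "CO2": "CO2",
    "HCOOH": "CH2O2",
}


@dataclass(frozen=True)
class Fragment:
    formula: Formula
    mz: float
    depth: int
    source: str  # "bond_cut", "neutral_loss", or "bond_cut+neutral_loss"


@dataclass
class FragmentSet:
    """In-silico fragments of one parent structure in one polarity."""

    parent_id: str
    parent_formula: Formula
    mode: str  # "positive" | "negative"
    fragments: list[Fragment] = field(default_factory=list)

    def mz_values(self) -> list[float]:
        return [fr.mz for fr in self.fragments]


def _ion_mz(f: Formula, mode: str) -> float:
    m = monoisotopic_mass(f)
    return m - ELECTRON_MASS if mode == "positive" else m + ELECTRON_MASS


def _mol_fragment_formulas(mol, depth: int) -> list[tuple[Formula, int]]:
    from rdkit import Chem

    molH = Chem.AddHs(mol)
    cuttable = [
        b.GetIdx()
        for b in molH.GetBonds()
        if not b.IsInRing()
        and b.GetBondType() == Chem.BondType.SINGLE
        and b.GetBeginAtom().GetAtomicNum() > 1
        and b.GetEndAtom().GetAtomicNum() > 1
    ]
    out: list[tuple[Formula, int]] = []
    combos: list[tuple[tuple[int, ...], int]] = [((b,), 1) for b in cuttable]
    if depth >= 2:
        combos += [(pair, 2) for pair in itertools.combinations(cuttable, 2)]
    for bonds, d in combos:
        frag_mol = Chem.FragmentOnBonds(molH, list(bonds), addDummies=False)
        for piece in Chem.GetMolFrags(frag_mol, asMols=True, sanitizeFrags=False):
            counts: dict[str, int] = {}
            for atom in piece.GetAtoms():
                sym = atom.GetSymbol()
                counts[sym] = counts.get(sym, 0) + 1
                counts["H"] = counts.get("H", 0) + atom.GetNumImplicitHs()
            counts = {el: n for el, n in counts.items() if n}
            if counts:
                out.append((Formula.from_dict(counts), d))
    return out


def fragment_in_silico(structure, depth: int = 2, mode: str = "positive",
                       parent_id: str = "") -> FragmentSet:
    """Enumerate fragments from acyclic single-bond cuts (single cuts, and
    pairs of cuts at ``depth`` 2) plus standard neutral losses applied to the
    parent and to every bond-cut fragment.

    ``structure`` is an RDKit Mol, a SMILES string, or a V2000 molblock.
    Each fragment is reported with its formula and singly charged m/z in the
    requested polarity (formula mass minus/plus one electron mass).
    """
    from rdkit import Chem

    if depth not in (1, 2):
        raise ValueError("depth must be 1 or 2")
    if mode not in ("positive", "negative"):
        raise ValueError("mode must be 'positive' or 'negative'")
    if isinstance(structure, str):
        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            mol = Chem.MolFromMolBlock(structure)
        if mol is None:
            raise ValueError("cannot parse structure input")
    else:
        mol = structure
    from rdkit.Chem import rdmolops

    if len(rdmolops.GetMolFrags(mol)) > 1:
        raise ValueError("structure must be connected")

    parent = _mol_formula(mol)
    parent_mz = _ion_mz(parent + Formula.from_dict({"H": 1}) if mode == "positive"
                        else parent, mode)  # proxy upper bound: [M+H]+ / [M-H]- handled below

    seen: dict[str, Fragment] = {}

    def _add(f: Formula, d: int, source: str):
        key = f.hill()
        heavy = f.n_atoms - f["H"] - f["D"]
        if not parent.contains(f) or heavy == 0:
            return
        mz = _ion_mz(f, mode)
        if mz >= parent_mz:
            return
        if key not in seen or seen[key].depth > d:
            seen[key] = Fragment(f, mz, d, source)

    cut_frags = _mol_fragment_formulas(mol, depth)
    for f, d in cut_frags:
        _add(f, d, "bond_cut")
    # neutral losses from the parent (as the protonated/deprotonated ion)
    ion_parent = (parent + Formula.from_dict({"H": 1})) if mode == "positive" else \
        parent.subtract(Formula.from_dict({"H": 1}))
    for name, loss_text in NEUTRAL_LOSSES.items():
        loss = parse_formula(loss_text)
        if ion_parent is not None:
            nl = ion_parent.subtract(loss)
            if nl is not None:
                _add(nl, 1, "neutral_loss")
        for f, d in cut_frags:
            sub = f.subtract(loss)
            if sub is not None and d < depth + 1:
                _add(sub, d + 1, "bond_cut+neutral_loss")
    frags = sorted(seen.values(), key=lambda fr: fr.mz)
    return FragmentSet(parent_id, parent, mode, frags)


def _mol_formula(mol) -> Formula:
    from rdkit import Chem

    molH = Chem.AddHs(mol)
    counts: dict[str, int] = {}
    for atom in molH.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
    return Formula.from_dict(counts)


# ---------------------------------------------------------------------------
# Biotransformation rules (xenobiotic metabolism)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiotransformationRule:
    name: str
    add: Formula
    sub: Formula
    smarts_precondition: str | None = None


def _rule(name, add="", sub="", smarts=None):
    z = Formula.from_dict({})
    return BiotransformationRule(
        name,
        parse_formula(add) if add else z,
        parse_formula(sub) if sub else z,
        smarts,
    )


#: Built-in phase-I/II biotransformation rules.
BUILTIN_RULES: dict[str, BiotransformationRule] = {
    r.name: r
    for r in [
        _rule("oxidation", add="O", smarts="[#6]"),
        _rule("reduction", add="H2", smarts="[CX3]=[CX3,OX1]"),
        _rule("demethylation", sub="CH2", smarts="[CH3][#6,#7,#8]"),
        _rule("dehydration", sub="H2O", smarts="[OX2H]"),
        _rule("hydrolysis", add="H2O", smarts="[CX3](=O)[OX2,NX3]"),
        _rule("glucuronidation", add="C6H8O6", smarts="[OX2H,NX3;!$([NX3]=*)]"),
        _rule("sulfation", add="SO3", smarts="[OX2H]"),
        _rule("acetylation", add="C2H2O", smarts="[OX2H,NX3;!$([NX3]=*)]"),
    ]
}


@dataclass(frozen=True)
class MetaboliteCandidate:
    formula: Formula
    chain: tuple[str, ...]
    verified_site: bool

    @property
    def name(self) -> str:
        return "+".join(self.chain)


def apply_biotransformations(parent, rules=None, depth: int = 2) -> list[MetaboliteCandidate]:
    """Generate candidate metabolite formulas from biotransformation rules.

    ``parent`` is a Formula/formula string (formula-only mode, candidates are
    flagged ``verified_site=False``) or an RDKit Mol / SMILES (site
    preconditions checked by SMARTS substructure match).  Depth-2 rule
    compositions are allowed; any candidate whose element counts would go
    negative is discarded.
    """
    if rules is None:
        rules = list(BUILTIN_RULES)
    if not rules:
        raise ValueError("rule set must be non-empty")
    rule_objs = []
    for r in rules:
        if isinstance(r, BiotransformationRule):
            rule_objs.append(r)
        elif r in BUILTIN_RULES:
            rule_objs.append(BUILTIN_RULES[r])
        else:
            raise KeyError(f"unknown biotransformation rule: {r!r}")
    if depth < 1 or depth > 2:
        raise ValueError("depth must be 1 or 2")

    mol = None
    if isinstance(parent, Formula):
        base = parent
    elif isinstance(parent, str):
        try:
            base = parse_formula(parent)
        except FormulaError:
            from rdkit import Chem

            mol = Chem.MolFromSmiles(parent)
            if mol is None:
                raise ValueError(f"cannot interpret parent {parent!r}")
            base = _mol_formula(mol)
    else:
        mol = parent
        base = _mol_formula(mol)

    def _site_ok(rule: BiotransformationRule) -> bool | None:
        """True/False via SMARTS when a structure is given, None otherwise."""
        if mol is None or rule.smarts_precondition is None:
            return None
        from rdkit import Chem

        patt = Chem.MolFromSmarts(rule.smarts_precondition)
        return mol.HasSubstructMatch(patt)

    out: dict[str, MetaboliteCandidate] = {}
    frontier: list[tuple[Formula, tuple[str, ...], bool]] = [(base, (), True)]
    for _level in range(depth):
        nxt = []
        for f, chain, verified in frontier:
            for rule in rule_objs:
                site = _site_ok(rule) if not chain else None  # structure known only for the parent
                if site is False:
                    continue
                g = (f + rule.add).subtract(rule.sub)
                if g is None or g.n_atoms == 0:
                    continue
                v = verified and site is True
                cand = MetaboliteCandidate(g, chain + (rule.name,), v)
                key = g.hill()
                if key != base.hill() and (key not in out or (cand.verified_site and not out[key].verified_site)):
                    out[key] = cand
                nxt.append((g, chain + (rule.name,), v))
        frontier = nxt
    return sorted(out.values(), key=lambda c: (len(c.chain), c.name))


# ---------------------------------------------------------------------------
# Stable-isotope (13C) labeling
# ---------------------------------------------------------------------------

def convert_to_13C(f: Formula | str) -> Formula:
    """Fully 13C-labeled version of a formula: every ``C`` becomes ``13C``.

    The labeled monoisotopic mass equals the unlabeled one plus
    ``n_C * 1.0033548`` Da; carbon-free formulas are returned unchanged.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    d = f.as_dict()
    n = d.pop("C", 0)
    if n:
        d["13C"] = d.get("13C", 0) + n
    return Formula.from_dict(d, f.charge)


def carbon_count_from_shift(mass_shift: float) -> int:
    """Invert a 13C labeling mass shift back to the carbon count."""
    return int(round(mass_shift / C13_DELTA))
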