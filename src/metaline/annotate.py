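"""Two-run identification against a reference database, weighted composite
scoring, color/star/level confidence labeling, in-source-fragment detection,
adduct clustering and the xenobiotic-metabolite search.

The overall score is the weighted average of four partial scores

    OS = (x*S_M + y*S_IP + z*S_F + w*S_CCS) / N,   N = x + y + z + w

with default weights x=30 (mass), y=10 (isotopic pattern), z=60 (fragment),
w=0 (CCS).  A partial score that cannot be computed (no spectrum, no CCS)
contributes 0 while its weight stays in N, so with defaults a mass-only
match scores OS = 30.  Identification runs on the Super Sample, so its cost
scales with the number of features, not samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem
from .features import DataMatrix, observed_isotope_pattern
from .msio import SpectrumRecord
from .refdb import ReferenceDB


@dataclass(frozen=True)
class ScoreWeights:
    """Non-negative weights for the mass / isotope / fragment / CCS scores."""

    x: float = 30.0
    y: float = 10.0
    z: float = 60.0
    w: float = 0.0

    def __post_init__(self):
        if min(self.x, self.y, self.z, self.w) < 0:
            raise ValueError("weights must be non-negative")
        if self.n <= 0:
            raise ValueError("sum of weights must be positive")

    @property
    def n(self) -> float:
        return self.x + self.y + self.z + self.w


@dataclass
class PartialScores:
    """Each partial score is in [0, 100] or None when inapplicable; an
    inapplicable score contributes 0 with its weight retained in N."""

    s_m: float | None = None
    s_ip: float | None = None
    s_f: float | None = None
    s_ccs: float | None = None


@dataclass
class Annotation:
    feature: str
    compound_id: str
    compound_name: str
    adduct: str
    scores: PartialScores
    os: float
    color: str = "red"          # green | light-green | orange | red
    stars: int = 1
    level: str = "5"            # 1 | 2a | 2b | 3 | 4 | 5
    run: int = 1
    rank: int = 1
    approved: bool = False
    cluster_id: int | None = None
    is_isf: bool = False
    external_ids: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


@dataclass
class AdductCluster:
    cluster_id: int
    compound_id: str
    members: list[Annotation]
    representative: Annotation
    rt_spread: float
    trend_r: float | None = None


# ---------------------------------------------------------------------------
# Partial scores
# ---------------------------------------------------------------------------

def mass_score(delta_ppm: float, tol_ppm: float) -> float:
    """Linear ppm decay: 100 at Delta-ppm 0, 0 at the tolerance edge."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    return 100.0 * max(0.0, 1.0 - abs(delta_ppm) / tol_ppm)


def isotope_score(observed, theoretical) -> float:
    """100 x cosine similarity of aligned isotopologue abundance vectors;
    0 when no observed pattern is available.

    Both arguments are (offsets, abundances) pairs or
    :class:`~metaline.chem.IsotopePattern` objects; vectors are compared over
    the first k shared isotopologues.
    """
    if observed is None:
        return 0.0
    obs = np.asarray(observed[1] if isinstance(observed, tuple) else observed.abundances,
                     dtype=float)
    theo = np.asarray(theoretical[1] if isinstance(theoretical, tuple) else theoretical.abundances,
                      dtype=float)
    k = min(len(obs), len(theo))
    if k == 0:
        return 0.0
    obs, theo = obs[:k], theo[:k]
    na, nb = np.linalg.norm(obs), np.linalg.norm(theo)
    if na == 0 or nb == 0:
        return 0.0
    return float(100.0 * np.dot(obs, theo) / (na * nb))


def _greedy_match(qa: np.ndarray, ra: np.ndarray, tol: float) -> list[tuple[int, int]]:
    """Greedy closest-pair peak matching within an absolute m/z tolerance."""
    pairs = []
    for i, mq in enumerate(qa):
        for j, mr in enumerate(ra):
            d = abs(mq - mr)
            if d <= tol:
                pairs.append((d, i, j))
    pairs.sort()
    used_q, used_r, out = set(), set(), []
    for _, i, j in pairs:
        if i in used_q or j in used_r:
            continue
        used_q.add(i)
        used_r.add(j)
        out.append((i, j))
    return out


def fragment_score(query: SpectrumRecord | None, ref: SpectrumRecord | None,
                   mz_tol: float = 0.01) -> float:
    """100 x cosine similarity on square-root intensities with greedy peak
    matching; 0 when either spectrum is absent or empty."""
    if query is None or ref is None or not query.peaks or not ref.peaks:
        return 0.0
    qm, qi = query.mz_array(), np.sqrt(query.intensity_array())
    rm, ri = ref.mz_array(), np.sqrt(ref.intensity_array())
    pairs = _greedy_match(qm, rm, mz_tol)
    if not pairs:
        return 0.0
    dot = sum(qi[i] * ri[j] for i, j in pairs)
    return float(100.0 * dot / (np.linalg.norm(qi) * np.linalg.norm(ri)))


def ccs_score(observed_ccs: float | None, ref_ccs: float | None,
              tol_pct: float = 2.0) -> float | None:
    """Linear percent-difference decay; None (inapplicable) when either
    value is missing."""
    if observed_ccs is None or ref_ccs is None:
        return None
    dpct = 100.0 * abs(observed_ccs - ref_ccs) / ref_ccs
    return 100.0 * max(0.0, 1.0 - dpct / tol_pct)


def overall_score(p: PartialScores, wts: ScoreWeights = ScoreWeights()) -> float:
    """Weighted average of the partial scores; inapplicable scores count as
    0 while their weight stays in the denominator."""
    vals = [(p.s_m, wts.x), (p.s_ip, wts.y), (p.s_f, wts.z), (p.s_ccs, wts.w)]
    return sum((v or 0.0) * w for v, w in vals) / wts.n


# ---------------------------------------------------------------------------
# Confidence labels
# ---------------------------------------------------------------------------

STAR_BANDS = (40.0, 60.0, 80.0)  # 1* below, then 2*, 3*, 4* at/above 80


def assign_confidence(os_score: float, has_candidates: bool, run: int = 1,
                      evidence: dict | None = None) -> tuple[str, int, str]:
    """Map score context to (color, stars, level).

    Green for OS strictly above 60 in run 1; orange when candidates exist
    at OS <= 60; red when no candidate matched within tolerance; run-2
    promotions are light-green ("p-high").  Stars follow fixed OS bands;
    the level follows a Schymanski-style scheme driven by which evidence
    (mass / MS-MS / RT / CCS) matched.
    """
    ev = evidence or {}
    if not has_candidates:
        return "red", 1, "5"
    stars = 1 + sum(os_score >= b for b in STAR_BANDS)
    if run == 2:
        color = "light-green"
        level = "2b"
    elif os_score > 60.0:
        color = "green"
        level = "1" if (ev.get("rt_match") and ev.get("msms_match")) else "2a"
    else:
        color = "orange"
        level = "3" if ev.get("mass") or ev.get("msms_match") else "4"
    return color, stars, level


# ---------------------------------------------------------------------------
# Run 1
# ---------------------------------------------------------------------------

def identify_run1(matrix: DataMatrix, db: ReferenceDB,
                  tol_ppm: float = 5.0, rt_tol: float = 0.2,
                  first_run_adducts: list[str] | None = None,
                  wts: ScoreWeights = ScoreWeights(),
                  frag_mz_tol: float = 0.01, rt_filter: bool = True,
                  polarity: str | None = None) -> list[Annotation]:
    """First identification run on the Super Sample.

    Every visible (monoisotopic) feature is searched for the first-run
    adducts (protonated/deprotonated by default) of every database
    compound within the ppm tolerance; candidates whose database RT
    conflicts with the feature RT are removed before scoring; survivors
    get all four partial scores from Super-Sample evidence and are ranked
    by OS.  Features without any candidate are annotated red.  Isobaric
    candidates with identical evidence tie exactly.
    """
    if not db.records:
        raise ValueError("empty reference database")
    if matrix.super_sample is None:
        raise ValueError("build the Super Sample before identification")
    polarity = polarity or next(
        (f.polarity for f in matrix.features.values()), "positive")
    if first_run_adducts is None:
        first_run_adducts = ["[M+H]+"] if polarity == "positive" else ["[M-H]-"]
    adducts = [(a, chem.parse_adduct(a)) for a in first_run_adducts]

    out: list[Annotation] = []
    for name in matrix.visible_features():
        feat = matrix.features[name]
        cands: list[Annotation] = []
        for rec in db.records:
            for aname, adef in adducts:
                mz_theo = chem.adduct_mz(rec.monoisotopic_mass, adef)
                dppm = (feat.mz - mz_theo) / mz_theo * 1e6
                if abs(dppm) > tol_ppm:
                    continue
                if (rt_filter and rec.rt is not None
                        and abs(feat.rt - rec.rt) > rt_tol):
                    continue
                obs_pattern = observed_isotope_pattern(matrix, name)
                theo_pattern = chem.theoretical_isotope_pattern(
                    rec.formula, k=max(2, len(obs_pattern[0]) if obs_pattern else 2),
                    charge=adef.charge)
                s_ip = isotope_score(obs_pattern, theo_pattern) if obs_pattern else 0.0
                ref_spec = rec.spectra.get(aname)
                s_f = fragment_score(feat.merged_ms2, ref_spec, frag_mz_tol)
                scores = PartialScores(
                    s_m=mass_score(dppm, tol_ppm), s_ip=s_ip, s_f=s_f,
                    s_ccs=ccs_score(feat.ccs, rec.ccs))
                osc = overall_score(scores, wts)
                evidence = {
                    "mass": True,
                    "msms_match": s_f > 60.0,
                    "rt_match": rec.rt is not None and abs(feat.rt - rec.rt) <= rt_tol,
                    "ccs_match": scores.s_ccs is not None and scores.s_ccs > 60.0,
                }
                color, stars, level = assign_confidence(osc, True, 1, evidence)
                cands.append(Annotation(name, rec.id, rec.name, aname, scores,
                                        osc, color, stars, level,
                                        external_ids=dict(rec.external_ids)))
        if not cands:
            out.append(Annotation(name, "", "", "", PartialScores(), 0.0,
                                  "red", 1, "5"))
            continue
        cands.sort(key=lambda a: (-a.os, a.compound_id))
        for r, a in enumerate(cands, start=1):
            a.rank = r
        out.extend(cands)
    return out


# ---------------------------------------------------------------------------
# Run 2
# ---------------------------------------------------------------------------

DEFAULT_SECOND_RUN_LOSSES = ["H2O", "NH3"]


def trend_correlation(matrix: DataMatrix, a: str, b: str) -> float:
    """Pearson correlation of two features' area profiles over the samples
    where both carry signal."""
    xa = matrix.areas[a].to_numpy(dtype=float)
    xb = matrix.areas[b].to_numpy(dtype=float)
    ok = np.isfinite(xa) & np.isfinite(xb)
    if ok.sum() < 3:
        return 0.0
    xa, xb = xa[ok], xb[ok]
    # two essentially flat profiles carry the same (absent) trend
    cv_a = np.std(xa) / abs(np.mean(xa)) if np.mean(xa) else 0.0
    cv_b = np.std(xb) / abs(np.mean(xb)) if np.mean(xb) else 0.0
    if cv_a < 1e-3 and cv_b < 1e-3:
        return 1.0
    if np.std(xa) == 0 or np.std(xb) == 0:
        return 0.0
    return float(np.corrcoef(xa, xb)[0, 1])


def extend_run2(annotations: list[Annotation], matrix: DataMatrix,
                db: ReferenceDB, second_run_adducts: list[str] | None = None,
                neutral_losses: list[str] | None = None,
                tol_ppm: float = 5.0, rt_tol: float = 0.1,
                trend_r_min: float = 0.8, isotope_min: float = 50.0,
                wts: ScoreWeights = ScoreWeights()) -> list[Annotation]:
    """Second identification run: inspect coeluting peaks of every compound
    identified in run 1.

    For each anchor (a green run-1 annotation), the expected m/z values of
    the selected additional adducts and small neutral losses are searched
    among features coeluting within ``rt_tol``.  A match is accepted when
    the mass fits, the observed isotope pattern is compatible (when one
    exists) and the candidate's trend across the samples correlates with
    the anchor's at Pearson r >= ``trend_r_min``; accepted features are
    promoted to light-green (p-high) even if previously orange or red.
    Run 2 never demotes a run-1 annotation.
    """
    if second_run_adducts is None:
        second_run_adducts = ["[M+Na]+", "[M+K]+", "[M+NH4]+"]
    if neutral_losses is None:
        neutral_losses = list(DEFAULT_SECOND_RUN_LOSSES)
    anchors = [a for a in annotations if a.run == 1 and a.color == "green"
               and a.rank == 1]
    by_feature: dict[str, list[Annotation]] = {}
    for a in annotations:
        by_feature.setdefault(a.feature, []).append(a)

    out = list(annotations)
    for anchor in anchors:
        rec = db.get(anchor.compound_id)
        if rec is None:
            continue
        anchor_feat = matrix.features[anchor.feature]
        anchor_adduct = chem.parse_adduct(anchor.adduct)
        targets: list[tuple[str, float, bool]] = []
        for aname in second_run_adducts:
            targets.append((aname,
                            chem.adduct_mz(rec.monoisotopic_mass, aname), False))
        for loss in neutral_losses:
            sub = rec.formula.subtract(chem.parse_formula(loss))
            if sub is not None:
                targets.append((f"{anchor.adduct}-{loss}",
                                chem.adduct_mz(chem.monoisotopic_mass(sub),
                                               anchor_adduct), True))
        for name in matrix.visible_features():
            if name == anchor.feature:
                continue
            feat = matrix.features[name]
            if abs(feat.rt - anchor_feat.rt) > rt_tol:
                continue
            for tname, mz_theo, is_isf in targets:
                dppm = (feat.mz - mz_theo) / mz_theo * 1e6
                if abs(dppm) > tol_ppm:
                    continue
                obs = observed_isotope_pattern(matrix, name)
                if obs is not None:
                    theo = chem.theoretical_isotope_pattern(
                        rec.formula, k=len(obs[0]))
                    if isotope_score(obs, theo) < isotope_min:
                        continue
                r = trend_correlation(matrix, name, anchor.feature)
                if r < trend_r_min:
                    continue
                scores = PartialScores(s_m=mass_score(dppm, tol_ppm),
                                       s_ip=isotope_score(obs, chem.theoretical_isotope_pattern(
                                           rec.formula, k=len(obs[0]))) if obs else 0.0)
                osc = overall_score(scores, wts)
                color, stars, level = assign_confidence(osc, True, 2)
                promoted = Annotation(name, rec.id, rec.name, tname, scores,
                                      osc, color, stars, level, run=2,
                                      is_isf=is_isf,
                                      external_ids=dict(rec.external_ids),
                                      notes=[f"promoted via {anchor.feature} (r={r:.2f})"])
                existing = by_feature.get(name, [])
                if existing and all(e.color == "red" for e in existing):
                    for e in existing:
                        out.remove(e)
                    by_feature[name] = []
                out.append(promoted)
                by_feature.setdefault(name, []).append(promoted)
                break
    return out


# ---------------------------------------------------------------------------
# ISF detection and adduct clustering
# ---------------------------------------------------------------------------

def detect_isf(matrix: DataMatrix, rt_tol: float = 0.1,
               mz_tol: float = 0.01) -> list[tuple[str, str]]:
    """Parent-ion rule for in-source fragments: for each coeluting feature
    pair, when the higher-m/z feature's MS/MS contains a peak at the lower
    feature's m/z, the lower feature is marked as an ISF of the higher.
    Returns (fragment feature, parent feature) links."""
    links = []
    names = matrix.visible_features()
    for hi_name in names:
        hi = matrix.features[hi_name]
        if hi.merged_ms2 is None or not hi.merged_ms2.peaks:
            continue
        peak_mzs = hi.merged_ms2.mz_array()
        for lo_name in names:
            lo = matrix.features[lo_name]
            if lo.mz >= hi.mz or abs(lo.rt - hi.rt) > rt_tol:
                continue
            if np.any(np.abs(peak_mzs - lo.mz) <= mz_tol):
                links.append((lo_name, hi_name))
    return links


def cluster_adducts(annotations: list[Annotation], matrix: DataMatrix,
                    isf_links: list[tuple[str, str]] | None = None,
                    rt_tol: float = 0.1, require_trend: bool = False,
                    trend_r_min: float = 0.8) -> list[AdductCluster]:
    """Merge approved annotations of the same compound into adduct/ISF
    clusters.

    Coeluting annotations (RT spread within ``rt_tol``) naming one compound
    form a cluster whose representative is the highest-OS monoisotopic
    member; with ``require_trend`` members must also correlate with the
    representative at r >= ``trend_r_min``.  ISF links attach fragments to
    their parent's cluster.
    """
    isf_parent = dict(isf_links or [])
    accepted = [a for a in annotations
                if a.compound_id and a.rank == 1 and a.color != "red"]
    by_compound: dict[str, list[Annotation]] = {}
    for a in accepted:
        by_compound.setdefault(a.compound_id, []).append(a)

    clusters: list[AdductCluster] = []
    cid = 0
    for comp, members in sorted(by_compound.items()):
        members = sorted(members, key=lambda a: -a.os)
        while members:
            rep = members[0]
            rep_rt = matrix.features[rep.feature].rt
            group, rest = [], []
            for a in members:
                rt = matrix.features[a.feature].rt
                linked_parent = isf_parent.get(a.feature)
                coelutes = abs(rt - rep_rt) <= rt_tol
                if linked_parent is not None and any(
                        g.feature == linked_parent for g in [rep] + group):
                    coelutes = True
                    a.is_isf = True
                if not coelutes:
                    rest.append(a)
                    continue
                if require_trend and a is not rep:
                    r = trend_correlation(matrix, a.feature, rep.feature)
                    if r < trend_r_min:
                        rest.append(a)
                        continue
                group.append(a)
            cid += 1
            rts = [matrix.features[a.feature].rt for a in group]
            trend_r = None
            if len(group) > 1:
                trend_r = float(np.mean([
                    trend_correlation(matrix, a.feature, rep.feature)
                    for a in group if a is not rep]))
            for a in group:
                a.cluster_id = cid
            clusters.append(AdductCluster(cid, comp, group, rep,
                                          max(rts) - min(rts), trend_r))
            members = rest
    return clusters


# ---------------------------------------------------------------------------
# Xenobiotic-metabolite search
# ---------------------------------------------------------------------------

def search_xenobiotic_metabolites(matrix: DataMatrix, parents: list,
                                  rules: list[str] | None = None,
                                  adducts: list[str] | None = None,
                                  tol_ppm: float = 5.0, depth: int = 2
                                  ) -> dict[str, list[str]]:
    """Label matrix features that match predicted metabolites of exogenous
    parent compounds.

    ``parents`` are (name, structure-or-formula) pairs.  Biotransformation
    candidates x selected adducts give an m/z list; features matching
    within tolerance get an advisory ``potential metabolite of <parent>
    via <rule chain>`` label.  Labels never override database annotations.
    """
    if adducts is None:
        adducts = ["[M+H]+"]
    labels: dict[str, list[str]] = {}
    for pname, structure in parents:
        cands = chem.apply_biotransformations(structure, rules, depth)
        for cand in cands:
            mass = chem.monoisotopic_mass(cand.formula)
            for aname in adducts:
                mz_theo = chem.adduct_mz(mass, aname)
                for fname in matrix.visible_features():
                    mz = matrix.features[fname].mz
                    if abs(mz - mz_theo) <= mz_theo * tol_ppm * 1e-6:
                        labels.setdefault(fname, []).append(
                            f"potential metabolite of {pname} via {cand.name}")
    return labels


# ---------------------------------------------------------------------------
# Output table
# ---------------------------------------------------------------------------

def annotations_to_frame(annotations: list[Annotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append({
            "feature": a.feature, "compound": a.compound_name,
            "adduct": a.adduct,
            "S_M": a.scores.s_m, "S_IP": a.scores.s_ip,
            "S_F": a.scores.s_f, "S_CCS": a.scores.s_ccs,
            "OS": round(a.os, 2), "color": a.color, "stars": a.stars,
            "level": a.level, "run": a.run, "rank": a.rank,
            "cluster_id": a.cluster_id, "is_isf": a.is_isf,
        })
    return pd.DataFrame(rows)
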