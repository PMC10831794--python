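"""Processing steps from centroided runs to an aligned, deisotoped,
gap-filled data matrix with a virtual Super Sample.

The chain is: EIC extraction with Savitzky-Golay smoothing and rolling-
minimum baseline -> RT correction against promoted reference features ->
cross-sample grouping -> isotope clustering on the 1.0033548/z grid ->
dual-threshold gap filling -> optional per-column reintegration -> Super
Sample construction (average areas + occurrence-merged MS/MS).

Every derived matrix keeps a pointer to its parent and the operation that
produced it, so the session history forms a replayable tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d
from scipy.signal import find_peaks, savgol_filter

from .chem import C13_DELTA
from .msio import Run, SpectrumRecord, feature_name

DEFAULT_PARAMS = {
    "mz_tol_ppm": 5.0,
    "rt_tol_min": 0.1,
    "snr_min": 5.0,
    "sg_window": 7,
    "sg_order": 2,
    "baseline_window": 101,
    "low_thr": 0.0,
    "high_thr": 0.0,
    "max_charge": 2,
    "k_isotopologues": 3,
}


@dataclass
class PeakTrace:
    """One chromatographic peak in one sample."""

    sample_id: str
    mz: float
    rt: float                  # apex, minutes (RT-corrected when aligned)
    rt_lo: float
    rt_hi: float
    area: float
    height: float
    snr: float
    rt_raw: float = None       # apex in the raw run, for reintegration
    ms2: list[SpectrumRecord] = field(default_factory=list)
    ccs: float | None = None

    def __post_init__(self):
        if self.rt_raw is None:
            self.rt_raw = self.rt
        if self.area <= 0:
            raise ValueError("peak area must be positive")
        if not (self.rt_lo <= self.rt <= self.rt_hi):
            raise ValueError("RT bounds must contain the apex")


@dataclass
class Feature:
    """An aligned m/z@RT(CCS) column of the data matrix."""

    mz: float
    rt: float
    ccs: float | None = None
    polarity: str = "positive"
    isotope_role: str = "monoisotopic"   # or "A+n"
    isotope_group: int | None = None
    hidden: bool = False                  # A+n columns hidden from identification
    traces: dict[str, PeakTrace] = field(default_factory=dict)
    merged_ms2: SpectrumRecord | None = None

    @property
    def name(self) -> str:
        return feature_name(self.mz, self.rt, self.ccs)

    def sample_ms2(self) -> list[SpectrumRecord]:
        out = []
        for t in self.traces.values():
            out.extend(t.ms2)
        return out


@dataclass
class DataMatrix:
    """Samples x features area table with refinement provenance.

    ``areas`` holds peak areas (NaN = missing); ``provenance`` the per-cell
    origin (detected / gap_filled / reintegrated / missing); the parent
    pointer plus ``operation``/``params`` labels form the session tree.
    """

    areas: pd.DataFrame
    features: dict[str, Feature]
    provenance: pd.DataFrame = None
    parent: "DataMatrix | None" = None
    operation: str = "root"
    params: dict = field(default_factory=dict)
    super_sample: pd.Series | None = None

    def __post_init__(self):
        if self.provenance is None:
            prov = pd.DataFrame("missing", index=self.areas.index,
                                columns=self.areas.columns)
            prov[self.areas.notna()] = "detected"
            self.provenance = prov

    @property
    def samples(self) -> list[str]:
        return list(self.areas.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.areas.columns)

    def visible_features(self) -> list[str]:
        return [n for n in self.areas.columns if not self.features[n].hidden]

    def child(self, areas, operation, params=None, provenance=None,
              features=None, super_sample=None) -> "DataMatrix":
        prov = provenance
        if prov is None:
            prov = self.provenance.reindex(index=areas.index,
                                           columns=areas.columns)
        return DataMatrix(areas=areas,
                          features=features if features is not None else
                          {n: self.features[n] for n in areas.columns},
                          provenance=prov, parent=self, operation=operation,
                          params=params or {},
                          super_sample=super_sample if super_sample is not None
                          else (self.super_sample.reindex(areas.columns)
                                if self.super_sample is not None else None))

    def root(self) -> "DataMatrix":
        node = self
        while node.parent is not None:
            node = node.parent
        return node

    def operation_chain(self) -> list[dict]:
        chain = []
        node = self
        while node.parent is not None:
            chain.append({"operation": node.operation, "params": node.params})
            node = node.parent
        return list(reversed(chain))

    def replay(self) -> "DataMatrix":
        """Re-apply the recorded operation chain to the root matrix."""
        from . import matrixops

        node = self.root()
        for step in self.operation_chain():
            fn = matrixops.REPLAYABLE.get(step["operation"])
            if fn is None:
                raise ValueError(
                    f"operation {step['operation']!r} needs external data and "
                    "cannot be replayed from the matrix alone")
            node = fn(node, **step["params"])
        return node

    def detected_mask(self) -> pd.DataFrame:
        """Cells that carry real signal (detected, gap-filled, reintegrated)."""
        return self.provenance.isin(["detected", "gap_filled", "reintegrated"])


# ---------------------------------------------------------------------------
# (1)-(4): EIC extraction, smoothing, baseline, S/N
# ---------------------------------------------------------------------------

def _bin_mz(mzs: np.ndarray, ppm: float) -> np.ndarray:
    """Group sorted m/z values into EIC bins: split where the gap between
    neighbours exceeds twice the ppm tolerance."""
    if mzs.size == 0:
        return np.array([], dtype=int)
    gaps = np.diff(mzs)
    cut = gaps > (mzs[:-1] * 2 * ppm * 1e-6)
    return np.concatenate([[0], np.cumsum(cut)])


def extract_peaks(run: Run, params: dict | None = None,
                  inclusion_list: list[tuple[float, float]] | None = None) -> list[PeakTrace]:
    """Detect chromatographic peaks in one run.

    EICs are built by ppm-tolerance m/z binning over all MS1 scans, smoothed
    with a Savitzky-Golay filter, baseline-corrected by a rolling minimum,
    and local maxima with S/N >= ``snr_min`` (and apex >= ``high_thr``, the
    processing threshold) become peaks; the area is the trapezoidal integral
    of the baseline-corrected signal over the peak bounds.

    With an ``inclusion_list`` of (m/z, RT) pairs, only traces matching a
    listed entry within tolerance are returned (semi-targeted mode).
    """
    p = {**DEFAULT_PARAMS, **(params or {})}
    if p["sg_window"] <= p["sg_order"]:
        raise ValueError("sg_window must exceed sg_order")
    scans = run.ms1
    if not scans:
        return []
    rts = np.array([s.rt for s in scans])
    n_scans = len(scans)
    triplets = []
    for i, s in enumerate(scans):
        for m, it in zip(s.mz, s.intensity):
            triplets.append((m, i, it))
    if not triplets:
        return []
    triplets.sort()
    mzs = np.array([t[0] for t in triplets])
    bins = _bin_mz(mzs, p["mz_tol_ppm"])

    traces: list[PeakTrace] = []
    for b in range(bins[-1] + 1):
        sel = bins == b
        bmz = mzs[sel]
        bscan = np.array([triplets[i][1] for i in np.flatnonzero(sel)])
        bint = np.array([triplets[i][2] for i in np.flatnonzero(sel)])
        signal = np.zeros(n_scans)
        np.add.at(signal, bscan, bint)
        if (signal > 0).sum() < 3:
            continue
        window = min(p["sg_window"], n_scans if n_scans % 2 else n_scans - 1)
        if window > p["sg_order"]:
            smooth = savgol_filter(signal, window, p["sg_order"])
        else:
            smooth = signal
        smooth = np.clip(smooth, 0, None)
        base = minimum_filter1d(smooth, size=min(p["baseline_window"], n_scans))
        corrected = smooth - base
        raw_corr = np.clip(signal - base, 0, None)
        resid = np.abs(corrected - np.median(corrected))
        noise = 1.4826 * np.median(resid)
        noise = max(noise, 1e-9)
        idx, _ = find_peaks(corrected, prominence=max(corrected.max() * 0.01, 1e-9))
        for apex in idx:
            height = corrected[apex]
            if height / noise < p["snr_min"] or height < p["high_thr"]:
                continue
            lo, hi = _peak_bounds(corrected, apex)
            area = float(np.trapezoid(raw_corr[lo:hi + 1], rts[lo:hi + 1]))
            if area <= 0:
                continue
            mask = (bscan >= lo) & (bscan <= hi)
            if not mask.any():
                continue
            mz_c = float(np.average(bmz[mask], weights=np.maximum(bint[mask], 1e-12)))
            trace = PeakTrace(run.sample_id, mz_c, float(rts[apex]),
                              float(rts[lo]), float(rts[hi]), area,
                              float(height), float(height / noise))
            trace.ms2 = [
                SpectrumRecord(list(zip(s2.mz, s2.intensity)), s2.precursor_mz,
                               run.polarity)
                for s2 in run.ms2
                if s2.precursor_mz is not None
                and abs(s2.precursor_mz - mz_c) <= mz_c * p["mz_tol_ppm"] * 1e-6
                and trace.rt_lo - 0.02 <= s2.rt <= trace.rt_hi + 0.02
            ]
            traces.append(trace)
    if inclusion_list is not None:
        kept = []
        for t in traces:
            for mz0, rt0 in inclusion_list:
                if (abs(t.mz - mz0) <= mz0 * p["mz_tol_ppm"] * 1e-6
                        and abs(t.rt - rt0) <= p["rt_tol_min"]):
                    kept.append(t)
                    break
        traces = kept
    return traces


def _peak_bounds(y: np.ndarray, apex: int, frac: float = 0.005) -> tuple[int, int]:
    """Walk outward from the apex until the signal falls below ``frac`` of
    the apex height or starts rising again (valley between peaks)."""
    thr = y[apex] * frac
    lo = apex
    while lo > 0 and y[lo - 1] > thr and y[lo - 1] <= y[lo]:
        lo -= 1
    hi = apex
    while hi < len(y) - 1 and y[hi + 1] > thr and y[hi + 1] <= y[hi]:
        hi += 1
    return lo, hi


# ---------------------------------------------------------------------------
# (5): RT correction
# ---------------------------------------------------------------------------

def rt_align(traces_by_sample: dict[str, list[PeakTrace]],
             mode: str = "reference_features",
             standards: list[tuple[float, float]] | None = None,
             mz_tol_ppm: float = 5.0, intra_tol: float = 0.2,
             inter_tol: float = 0.5, n_anchors: int = 20,
             batches: dict[str, str] | None = None) -> dict[str, list[PeakTrace]]:
    """Correct per-sample retention times with a monotone piecewise-linear
    warp to the median anchor RT.

    Anchors are either a user ``standards`` list of (m/z, RT) pairs, or
    high-intensity features matched across *all* samples within tolerance
    ("reference features" mode).  With batch metadata, matching uses
    ``intra_tol`` within a batch and ``inter_tol`` across batches.  Fewer
    than 3 anchors falls back to the identity warp with a warning.
    """
    samples = list(traces_by_sample)
    if len(samples) < 2:
        return traces_by_sample
    rt_tol = inter_tol if (batches and len(set(batches.values())) > 1) else intra_tol

    anchors: list[dict[str, PeakTrace]] = []
    if mode == "standards_list" and standards:
        for mz0, rt0 in standards:
            hit = {}
            for s in samples:
                cands = [t for t in traces_by_sample[s]
                         if abs(t.mz - mz0) <= mz0 * mz_tol_ppm * 1e-6
                         and abs(t.rt - rt0) <= rt_tol]
                if cands:
                    hit[s] = max(cands, key=lambda t: t.height)
            if len(hit) == len(samples):
                anchors.append(hit)
    else:
        ref_sample = max(samples,
                         key=lambda s: sum(t.height for t in traces_by_sample[s]))
        seeds = sorted(traces_by_sample[ref_sample], key=lambda t: -t.height)
        for seed in seeds:
            if len(anchors) >= n_anchors:
                break
            hit = {ref_sample: seed}
            for s in samples:
                if s == ref_sample:
                    continue
                cands = [t for t in traces_by_sample[s]
                         if abs(t.mz - seed.mz) <= seed.mz * mz_tol_ppm * 1e-6
                         and abs(t.rt - seed.rt) <= rt_tol]
                if not cands:
                    break
                hit[s] = min(cands, key=lambda t: abs(t.rt - seed.rt))
            if len(hit) == len(samples):
                anchors.append(hit)

    if len(anchors) < 3:
        warnings.warn("fewer than 3 RT anchors found; identity warp applied")
        return traces_by_sample

    targets = [float(np.median([h[s].rt for s in samples])) for h in anchors]
    out = {}
    for s in samples:
        xs = np.array([h[s].rt for h in anchors])
        ys = np.array(targets)
        order = np.argsort(xs)
        xs, ys = xs[order], ys[order]
        keep = np.concatenate([[True], np.diff(xs) > 1e-9])
        xs, ys = xs[keep], ys[keep]
        ys = np.maximum.accumulate(ys)  # enforce monotone warp
        shifts = ys - xs                # interpolate the shift, so RTs
        warped = []                     # outside the anchor range get the
        for t in traces_by_sample[s]:   # constant edge correction
            shift = float(np.interp(t.rt, xs, shifts))
            warped.append(replace(t, rt=t.rt + shift, rt_lo=t.rt_lo + shift,
                                  rt_hi=t.rt_hi + shift, rt_raw=t.rt_raw))
        out[s] = warped
    return out


# ---------------------------------------------------------------------------
# (6): cross-sample grouping
# ---------------------------------------------------------------------------

def group_align(traces_by_sample: dict[str, list[PeakTrace]],
                mz_tol_ppm: float = 5.0, rt_tol: float = 0.1,
                polarity: str = "positive") -> DataMatrix:
    """Group RT-corrected traces across samples into features (greedy,
    intensity-ordered, hence order-invariant) and build the raw matrix."""
    samples = list(traces_by_sample)
    pool = [(t.height, s, t) for s in samples for t in traces_by_sample[s]]
    pool.sort(key=lambda x: (-x[0], x[2].mz, x[2].rt, x[1]))
    used: set[int] = set()
    index = {id(t): i for i, (_, _, t) in enumerate(pool)}
    features: dict[str, Feature] = {}
    rows: dict[str, dict[str, float]] = {s: {} for s in samples}

    for h, seed_sample, seed in pool:
        if index[id(seed)] in used:
            continue
        members: dict[str, PeakTrace] = {}
        for s in samples:
            cands = [t for t in traces_by_sample[s]
                     if index[id(t)] not in used
                     and abs(t.mz - seed.mz) <= seed.mz * mz_tol_ppm * 1e-6
                     and abs(t.rt - seed.rt) <= rt_tol]
            if cands:
                members[s] = min(cands, key=lambda t: (abs(t.rt - seed.rt),
                                                       abs(t.mz - seed.mz)))
        for t in members.values():
            used.add(index[id(t)])
        w = np.array([t.height for t in members.values()])
        mz_c = float(np.average([t.mz for t in members.values()], weights=w))
        rt_c = float(np.average([t.rt for t in members.values()], weights=w))
        feat = Feature(mz=mz_c, rt=rt_c, polarity=polarity, traces=members)
        name = feat.name
        k = 2
        while name in features:
            name = f"{feat.name}#{k}"
            k += 1
        features[name] = feat
        for s, t in members.items():
            rows[s][name] = t.area

    order = sorted(features, key=lambda n: (features[n].mz, features[n].rt))
    areas = pd.DataFrame.from_dict(rows, orient="index").reindex(
        index=samples, columns=order)
    return DataMatrix(areas=areas, features={n: features[n] for n in order},
                      operation="root")


# ---------------------------------------------------------------------------
# (7): isotope clustering / deisotoping
# ---------------------------------------------------------------------------

def isotope_cluster(matrix: DataMatrix, mz_tol_ppm: float = 5.0,
                    rt_tol: float = 0.05, max_charge: int = 2,
                    k_isotopologues: int = 3,
                    abundance_margin: float = 1.3) -> DataMatrix:
    """Column-wise isotope-pattern search.

    Columns whose spacing matches n * 1.0033548/z within tolerance, that
    coelute, and whose A+1/A abundance ratio is compatible with the carbon
    counts plausible at that m/z (at most ``m/z * z / 12`` carbons, with a
    safety margin) are grouped; A+n columns are flagged and hidden from
    identification but kept for isotope-pattern scoring.
    """
    names = sorted(matrix.feature_names, key=lambda n: matrix.features[n].mz)
    mean_area = matrix.areas.mean(axis=0, skipna=True)
    assigned: dict[str, tuple[int, str]] = {}
    group = 0
    for name in names:
        if name in assigned:
            continue
        f = matrix.features[name]
        best_members: list[str] = []
        best_z = 1
        for z in range(1, max_charge + 1):
            members = [name]
            for n_iso in range(1, k_isotopologues):
                target = f.mz + n_iso * C13_DELTA / z
                tol = target * mz_tol_ppm * 1e-6
                cands = [m for m in names
                         if m not in assigned and m != name
                         and abs(matrix.features[m].mz - target) <= tol
                         and abs(matrix.features[m].rt - f.rt) <= rt_tol]
                if not cands:
                    break
                m = min(cands, key=lambda c: abs(matrix.features[c].mz - target))
                if n_iso == 1:
                    ratio = mean_area.get(m, np.nan) / mean_area.get(name, np.nan)
                    max_c = max(1, int(f.mz * z / 12.0))
                    if not np.isfinite(ratio) or ratio > max_c * 0.0108 * abundance_margin:
                        break
                members.append(m)
            if len(members) > len(best_members):
                best_members, best_z = members, z
        group += 1
        assigned[name] = (group, "monoisotopic")
        for i, m in enumerate(best_members[1:], start=1):
            assigned[m] = (group, f"A+{i}")

    feats = {}
    for name in matrix.feature_names:
        g, role = assigned.get(name, (None, "monoisotopic"))
        f = matrix.features[name]
        feats[name] = replace(f, isotope_role=role, isotope_group=g,
                              hidden=role != "monoisotopic",
                              traces=f.traces, merged_ms2=f.merged_ms2)
    return matrix.child(matrix.areas.copy(), "isotope_cluster",
                        {"mz_tol_ppm": mz_tol_ppm, "rt_tol": rt_tol,
                         "max_charge": max_charge}, features=feats,
                        provenance=matrix.provenance.copy())


def observed_isotope_pattern(matrix: DataMatrix, name: str,
                             use_super: bool = True) -> tuple[tuple, tuple] | None:
    """Observed (offset, abundance) pattern of a monoisotopic feature from
    its clustered A+n columns; None when the feature is unclustered."""
    f = matrix.features[name]
    if f.isotope_group is None:
        return None
    members = [(n, matrix.features[n]) for n in matrix.feature_names
               if matrix.features[n].isotope_group == f.isotope_group]
    members.sort(key=lambda kv: kv[1].mz)
    if len(members) < 2:
        return None
    source = (matrix.super_sample if use_super and matrix.super_sample is not None
              else matrix.areas.mean(axis=0, skipna=True))
    vals = np.array([source.get(n, np.nan) for n, _ in members], dtype=float)
    vals = np.nan_to_num(vals)
    if vals.max() <= 0:
        return None
    offs = tuple(m.mz - members[0][1].mz for _, m in members)
    return offs, tuple(vals / vals.max())


# ---------------------------------------------------------------------------
# (8): gap filler
# ---------------------------------------------------------------------------

def gap_fill(matrix: DataMatrix, runs: dict[str, Run], low_thr: float,
             high_thr: float, mz_tol_ppm: float = 5.0,
             rt_tol: float = 0.1) -> DataMatrix:
    """Fill empty cells from peaks retained in the session whose apex
    intensity lies in ``[low_thr, high_thr)``.

    Peaks at or above ``high_thr`` already defined columns; peaks below
    ``low_thr`` were discarded at conversion and are unrecoverable.
    """
    if high_thr < low_thr:
        raise ValueError("high_thr must be >= low_thr")
    areas = matrix.areas.copy()
    prov = matrix.provenance.copy()
    for name in matrix.feature_names:
        f = matrix.features[name]
        for sample in matrix.samples:
            if not pd.isna(areas.at[sample, name]) or sample not in runs:
                continue
            run = runs[sample]
            pts = []
            for scan in run.ms1:
                if abs(scan.rt - f.rt) > rt_tol:
                    continue
                sel = np.abs(scan.mz - f.mz) <= f.mz * mz_tol_ppm * 1e-6
                if sel.any():
                    pts.append((scan.rt, float(scan.intensity[sel].sum())))
            if not pts:
                continue
            apex = max(i for _, i in pts)
            if not (low_thr <= apex < high_thr):
                continue
            pts.sort()
            if len(pts) >= 2:
                area = float(np.trapezoid([i for _, i in pts], [r for r, _ in pts]))
            else:
                area = pts[0][1] * 0.01
            if area > 0:
                areas.at[sample, name] = area
                prov.at[sample, name] = "gap_filled"
    return matrix.child(areas, "gap_fill",
                        {"low_thr": low_thr, "high_thr": high_thr},
                        provenance=prov)


def reintegrate_column(matrix: DataMatrix, runs: dict[str, Run],
                       name: str, mz_tol_ppm: float = 5.0) -> DataMatrix:
    """Recompute one feature's areas over the union of per-sample RT bounds
    (shared bounds increase cross-sample consistency)."""
    if name not in matrix.features:
        raise KeyError(name)
    f = matrix.features[name]
    if not f.traces:
        raise ValueError(f"no trace data retained for {name}")
    lo = min(t.rt_raw - (t.rt - t.rt_lo) for t in f.traces.values())
    hi = max(t.rt_raw + (t.rt_hi - t.rt) for t in f.traces.values())
    areas = matrix.areas.copy()
    prov = matrix.provenance.copy()
    for sample in matrix.samples:
        if sample not in runs:
            continue
        run = runs[sample]
        pts = []
        for scan in run.ms1:
            if lo <= scan.rt <= hi:
                sel = np.abs(scan.mz - f.mz) <= f.mz * mz_tol_ppm * 1e-6
                pts.append((scan.rt, float(scan.intensity[sel].sum())))
        if len(pts) < 2 or max(i for _, i in pts) <= 0:
            areas.at[sample, name] = np.nan
            prov.at[sample, name] = "missing"
            continue
        pts.sort()
        area = float(np.trapezoid([i for _, i in pts], [r for r, _ in pts]))
        areas.at[sample, name] = area if area > 0 else np.nan
        prov.at[sample, name] = "reintegrated" if area > 0 else "missing"
    return matrix.child(areas, "reintegrate", {"feature": name}, provenance=prov)


# ---------------------------------------------------------------------------
# Super Sample
# ---------------------------------------------------------------------------

def merge_spectra(spectra: list[SpectrumRecord], mz_tol: float = 0.01,
                  min_fraction: float = 0.5) -> SpectrumRecord | None:
    """Merge MS/MS spectra across samples: peaks are clustered within
    ``mz_tol`` and kept when present in at least ``min_fraction`` of the
    contributing spectra (occurrence vote discards noise peaks)."""
    spectra = [s for s in spectra if s.peaks]
    if not spectra:
        return None
    n = len(spectra)
    pts = sorted((m, i, k) for k, s in enumerate(spectra) for m, i in s.peaks)
    merged = []
    cluster: list[tuple[float, float, int]] = []
    for pt in pts + [(np.inf, 0.0, -1)]:
        if cluster and pt[0] - cluster[-1][0] > mz_tol:
            occ = len({k for _, _, k in cluster})
            if occ / n >= min_fraction:
                mzs = [m for m, _, _ in cluster]
                ints = [i for _, i, _ in cluster]
                merged.append((float(np.average(mzs, weights=np.maximum(ints, 1e-12))),
                               float(np.mean(ints))))
            cluster = []
        if np.isfinite(pt[0]):
            cluster.append(pt)
    if not merged:
        return None
    prec = next((s.precursor_mz for s in spectra if s.precursor_mz), None)
    return SpectrumRecord(merged, prec, spectra[0].polarity, "merged")


def build_super_sample(matrix: DataMatrix, mz_tol: float = 0.01,
                       min_fraction: float = 0.5) -> DataMatrix:
    """Add the virtual Super Sample: per feature, the average area over all
    cells carrying signal, plus the occurrence-merged MS/MS spectrum."""
    if not matrix.samples:
        raise ValueError("matrix has no samples")
    mask = matrix.detected_mask()
    vals = matrix.areas.where(mask)
    super_row = vals.mean(axis=0, skipna=True)
    feats = {}
    for name, f in matrix.features.items():
        merged = merge_spectra(f.sample_ms2(), mz_tol, min_fraction)
        feats[name] = replace(f, merged_ms2=merged, traces=f.traces)
    return matrix.child(matrix.areas.copy(), "super_sample",
                        {"min_fraction": min_fraction}, features=feats,
                        provenance=matrix.provenance.copy(),
                        super_sample=super_row)


# ---------------------------------------------------------------------------
# One-call pipeline
# ---------------------------------------------------------------------------

def process_study(runs: dict[str, Run], params: dict | None = None,
                  align: bool = True) -> DataMatrix:
    """runs -> extract -> RT-align -> group -> isotope-cluster -> gap-fill ->
    Super Sample, using the module's default parameters."""
    p = {**DEFAULT_PARAMS, **(params or {})}
    sample_runs = {s: r for s, r in runs.items()}
    traces = {s: extract_peaks(r, p) for s, r in sample_runs.items()}
    if align and len(traces) >= 2:
        traces = rt_align(traces, mz_tol_ppm=p["mz_tol_ppm"])
    polarity = next(iter(runs.values())).polarity if runs else "positive"
    matrix = group_align(traces, p["mz_tol_ppm"], p["rt_tol_min"], polarity)
    matrix = isotope_cluster(matrix, p["mz_tol_ppm"], max(0.05, p["rt_tol_min"] / 2),
                             p["max_charge"], p["k_isotopologues"])
    if p["high_thr"] > p["low_thr"]:
        matrix = gap_fill(matrix, sample_runs, p["low_thr"], p["high_thr"],
                          p["mz_tol_ppm"], p["rt_tol_min"])
    return build_super_sample(matrix)
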