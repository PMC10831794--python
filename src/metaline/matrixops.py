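"""Data-matrix refinement: blank subtraction, frequency filtering,
normalization, replicate averaging and polarity merging.

Each operation returns a child matrix that records the operation and its
parameters, so a leaf can be reproduced by replaying the logged sequence
from the root (see :meth:`metaline.features.DataMatrix.replay`).
Gap-filled cells count as "present": they are measured signal recovered
between the two thresholds, not imputations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import DataMatrix

ROLES = {"sample", "blank", "QC", "standard"}


@dataclass
class SampleMeta:
    """Per-sample metadata: role, group, batch, ordered labels for trends,
    injection order and normalization scalars."""

    table: pd.DataFrame

    def __post_init__(self):
        bad = set(self.table.get("role", pd.Series(dtype=str)).dropna()) - ROLES
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")

    @classmethod
    def from_csv(cls, path: str) -> "SampleMeta":
        return cls(pd.read_csv(path, index_col="sample"))

    @classmethod
    def from_design(cls, design: dict[str, list[str]]) -> "SampleMeta":
        rows = []
        for group, samples in design.items():
            for i, s in enumerate(samples):
                rows.append({"sample": s, "group": group, "label": group,
                             "role": "blank" if group == "blank" else "sample",
                             "order": len(rows) + 1})
        return cls(pd.DataFrame(rows).set_index("sample"))

    def require(self, samples) -> None:
        missing = set(samples) - set(self.table.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    def group_of(self, sample: str) -> str:
        return str(self.table.loc[sample, "group"])

    def samples_with_role(self, role: str) -> list[str]:
        t = self.table
        return [s for s in t.index if t.loc[s].get("role") == role]


def blank_subtract(matrix: DataMatrix, blank_ids: list[str],
                   min_fold: float = 5.0) -> DataMatrix:
    """Remove features whose mean sample area does not exceed the mean
    blank area by at least ``min_fold``; missing blank cells count as 0
    (a feature absent from all blanks is always kept)."""
    blanks = [b for b in blank_ids if b in matrix.areas.index]
    if not blanks:
        raise ValueError("no blank samples in matrix")
    samples = [s for s in matrix.samples if s not in blank_ids]
    blank_mean = matrix.areas.loc[blanks].fillna(0.0).mean(axis=0)
    sample_mean = matrix.areas.loc[samples].mean(axis=0, skipna=True).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = sample_mean / blank_mean
    keep = (blank_mean == 0) | (fold >= min_fold)
    kept = [c for c in matrix.feature_names if keep[c]]
    return matrix.child(matrix.areas[kept], "blank_subtract",
                        {"blank_ids": list(blank_ids), "min_fold": min_fold})


def frequency_filter(matrix: DataMatrix, min_frac: float,
                     exclude: list[str] | None = None) -> DataMatrix:
    """Keep features present (detected or gap-filled) in at least
    ``min_frac`` of the samples; the boundary is kept (a feature in exactly
    half the samples survives a 0.5 filter)."""
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    rows = [s for s in matrix.samples if not exclude or s not in exclude]
    frac = matrix.detected_mask().loc[rows].mean(axis=0)
    kept = [c for c in matrix.feature_names if frac[c] >= min_frac]
    return matrix.child(matrix.areas[kept], "frequency_filter",
                        {"min_frac": min_frac, "exclude": exclude})


def normalize(matrix: DataMatrix, mode: str, meta: SampleMeta | None = None,
              scalar_column: str | None = None,
              standard_feature: str | None = None,
              qc_frac: float = 0.7) -> DataMatrix:
    """Per-sample normalization.

    Modes: ``metadata`` divides by a per-sample scalar (cell count, volume,
    weight ... taken from ``scalar_column``); ``total_area`` equalizes row
    sums; ``internal_standard`` divides by the area of a spiked standard
    feature; ``qc`` fits a per-feature LOESS of the QC areas over injection
    order and divides samples by the interpolated drift factor.
    """
    areas = matrix.areas.copy()
    params = {"mode": mode, "scalar_column": scalar_column,
              "standard_feature": standard_feature}
    if mode == "metadata":
        if meta is None or scalar_column is None:
            raise ValueError("metadata mode needs SampleMeta and scalar_column")
        meta.require(matrix.samples)
        factors = meta.table.loc[matrix.samples, scalar_column].astype(float)
        if factors.isna().any() or (factors <= 0).any():
            raise ValueError(f"missing/non-positive {scalar_column} scalar")
        areas = areas.div(factors, axis=0)
    elif mode == "total_area":
        totals = areas.sum(axis=1, skipna=True)
        if (totals <= 0).any():
            raise ValueError("sample with non-positive total area")
        areas = areas.div(totals, axis=0) * float(totals.mean())
    elif mode == "internal_standard":
        if standard_feature not in areas.columns:
            raise ValueError("standard feature not in matrix")
        factors = areas[standard_feature]
        if factors.isna().any() or (factors <= 0).any():
            raise ValueError("standard missing in some sample")
        areas = areas.div(factors, axis=0) * float(factors.mean())
    elif mode == "qc":
        if meta is None:
            raise ValueError("qc mode needs SampleMeta with roles and order")
        meta.require(matrix.samples)
        order = meta.table.loc[matrix.samples, "order"].astype(float)
        qc = [s for s in matrix.samples if meta.table.loc[s].get("role") == "QC"]
        if len(qc) < 3:
            raise ValueError("qc mode needs >= 3 QC injections")
        from statsmodels.nonparametric.smoothers_lowess import lowess

        for col in areas.columns:
            y = areas.loc[qc, col].astype(float)
            ok = y.notna()
            if ok.sum() < 3:
                continue
            fit = lowess(y[ok], order[qc][ok], frac=qc_frac, return_sorted=True)
            drift = np.interp(order, fit[:, 0], fit[:, 1])
            ref = float(np.nanmedian(y))
            if ref <= 0:
                continue
            factor = np.clip(drift / ref, 1e-6, None)
            areas[col] = areas[col] / factor
        params["qc_frac"] = qc_frac
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return matrix.child(areas, "normalize", params)


def average_replicates(matrix: DataMatrix,
                       grouping: dict[str, str] | SampleMeta) -> DataMatrix:
    """Collapse replicate rows to group means of the detected cells; a
    group with no detected cell for a feature stays missing."""
    if isinstance(grouping, SampleMeta):
        grouping = {s: grouping.group_of(s) for s in matrix.samples}
    groups: dict[str, list[str]] = {}
    for s in matrix.samples:
        groups.setdefault(grouping.get(s, s), []).append(s)
    mask = matrix.detected_mask()
    rows, provs = {}, {}
    for g, ss in groups.items():
        vals = matrix.areas.loc[ss].where(mask.loc[ss])
        rows[g] = vals.mean(axis=0, skipna=True)
        provs[g] = np.where(mask.loc[ss].any(axis=0), "detected", "missing")
    areas = pd.DataFrame(rows).T.reindex(columns=matrix.feature_names)
    prov = pd.DataFrame(provs, index=matrix.feature_names).T.reindex(
        columns=matrix.feature_names)
    return matrix.child(areas, "average_replicates",
                        {"grouping": dict(grouping)}, provenance=prov)


def merge_polarity(matrix_pos: DataMatrix, matrix_neg: DataMatrix,
                   rt_tol: float = 0.1) -> DataMatrix:
    """Union the features of positive- and negative-mode matrices acquired
    on the same samples.  Features keep their polarity tag; nothing is
    collapsed across polarities before identification."""
    if set(matrix_pos.samples) != set(matrix_neg.samples):
        raise ValueError("polarity matrices must cover the same samples")
    neg = matrix_neg.areas.reindex(index=matrix_pos.samples)
    rename = {}
    for c in neg.columns:
        rename[c] = f"{c}|neg" if c in matrix_pos.areas.columns else c
    neg = neg.rename(columns=rename)
    areas = pd.concat([matrix_pos.areas, neg], axis=1)
    prov = pd.concat([matrix_pos.provenance,
                      matrix_neg.provenance.reindex(index=matrix_pos.samples)
                      .rename(columns=rename)], axis=1)
    features = dict(matrix_pos.features)
    for old, new in ((c, rename.get(c, c)) for c in matrix_neg.areas.columns):
        features[new] = matrix_neg.features[old]
    out = DataMatrix(areas=areas, features=features, provenance=prov,
                     parent=matrix_pos, operation="merge_polarity",
                     params={"rt_tol": rt_tol})
    return out


#: Operations replayable from the matrix alone (no external run data).
REPLAYABLE = {
    "blank_subtract": blank_subtract,
    "frequency_filter": frequency_filter,
}


def _replay_normalize(matrix, **params):
    raise NotImplementedError


def apply_filter_chain(matrix: DataMatrix, steps: list[dict]) -> DataMatrix:
    """Apply a recorded [{operation, params}, ...] filter sequence."""
    node = matrix
    for step in steps:
        fn = REPLAYABLE[step["operation"]]
        node = fn(node, **step["params"])
    return node
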