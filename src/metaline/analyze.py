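"""Statistics, trend analysis, quantification and pathway projection.

Trend vectors are z-standardized per-feature area profiles, by default over
replicate-group means in label order.  Multivariate methods are standard
(PCA/PLS-DA via scikit-learn, consensus PCA via a NIPALS-style multiblock
iteration); univariate testing is t-test/ANOVA with Benjamini-Hochberg
correction.  Pathway projection colors detected nodes gray and, under a
two-label comparison, up-regulated nodes red and down-regulated blue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import DataMatrix

# ---------------------------------------------------------------------------
# Univariate statistics
# ---------------------------------------------------------------------------

SIGNIFICANCE_STARS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, mark in SIGNIFICANCE_STARS:
        if p <= thr:
            return mark
    return ""


def fold_change_tests(matrix: DataMatrix, group_a: list[str],
                      group_b: list[str]) -> pd.DataFrame:
    """Per-feature log2 fold change (B over A, on means of detected cells),
    Welch t-test p-value and BH-adjusted q-value.

    Features with one group entirely missing are flagged and not tested.
    """
    from statsmodels.stats.multitest import multipletests

    mask = matrix.detected_mask()
    rows = []
    for name in matrix.feature_names:
        xa = matrix.areas.loc[group_a, name].where(mask.loc[group_a, name]).dropna()
        xb = matrix.areas.loc[group_b, name].where(mask.loc[group_b, name]).dropna()
        if len(xa) == 0 or len(xb) == 0:
            rows.append({"feature": name, "log2fc": np.nan, "p": np.nan,
                         "flag": "group_all_missing"})
            continue
        log2fc = float(np.log2(xb.mean() / xa.mean())) if xa.mean() > 0 else np.nan
        if len(xa) < 2 or len(xb) < 2 or (xa.std() == 0 and xb.std() == 0
                                          and xa.mean() == xb.mean()):
            p = 1.0 if xa.mean() == xb.mean() else np.nan
        else:
            p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        rows.append({"feature": name, "log2fc": log2fc, "p": p, "flag": ""})
    out = pd.DataFrame(rows).set_index("feature")
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["stars"] = out["p"].map(lambda p: significance_stars(p) if np.isfinite(p) else "")
    return out


def anova_tests(matrix: DataMatrix, groups: dict[str, list[str]]) -> pd.DataFrame:
    """One-way ANOVA across >= 2 groups with BH correction."""
    from statsmodels.stats.multitest import multipletests

    rows = []
    for name in matrix.feature_names:
        arrays = [matrix.areas.loc[ss, name].dropna() for ss in groups.values()]
        if any(len(a) < 2 for a in arrays):
            rows.append({"feature": name, "p": np.nan})
            continue
        rows.append({"feature": name,
                     "p": float(stats.f_oneway(*arrays).pvalue)})
    out = pd.DataFrame(rows).set_index("feature")
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Multivariate: PCA / PLS-DA / consensus PCA
# ---------------------------------------------------------------------------

def _scale(X: np.ndarray, scaling: str | None) -> np.ndarray:
    X = X - X.mean(axis=0)
    if scaling == "uv":
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    elif scaling == "pareto":
        sd = np.sqrt(X.std(axis=0, ddof=1))
        sd[sd == 0] = 1.0
        X = X / sd
    elif scaling not in (None, "none", "center"):
        raise ValueError(f"unknown scaling {scaling!r}")
    return X


def _fix_signs(scores: np.ndarray, loadings: np.ndarray):
    """Deterministic sign convention: the largest-|loading| entry of each
    component is positive."""
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return scores, loadings


def _as_array(m) -> tuple[np.ndarray, list, list]:
    if isinstance(m, DataMatrix):
        df = m.areas.fillna(0.0)
        return df.to_numpy(dtype=float), list(df.index), list(df.columns)
    df = pd.DataFrame(m)
    return df.to_numpy(dtype=float), list(df.index), list(df.columns)


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca(matrix, n_components: int = 2, scaling: str | None = "uv") -> PCAResult:
    """Principal component analysis with UV/Pareto scaling options and a
    deterministic sign convention.  Accepts a DataMatrix or any table
    (imported CSVs give identical results to in-session matrices)."""
    from sklearn.decomposition import PCA as SkPCA

    X, idx, cols = _as_array(matrix)
    Xs = _scale(X, scaling)
    n_components = min(n_components, min(Xs.shape) - (1 if Xs.shape[0] > 1 else 0) or 1)
    model = SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(Xs)
    loadings = model.components_.T.copy()
    scores, loadings = _fix_signs(scores, loadings)
    pcs = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(pd.DataFrame(scores, index=idx, columns=pcs),
                     pd.DataFrame(loadings, index=cols, columns=pcs),
                     model.explained_variance_ratio_)


@dataclass
class PLSDAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    classes: list[str]
    accuracy: float
    r2y: float


def plsda(matrix, classes: dict[str, str] | pd.Series, n_components: int = 2,
          scaling: str | None = "uv") -> PLSDAResult:
    """PLS-DA: PLS regression on one-hot class membership; reports scores,
    loadings, refit accuracy (nearest class centroid in score space) and
    R2Y."""
    from sklearn.cross_decomposition import PLSRegression

    X, idx, cols = _as_array(matrix)
    y_labels = [classes[s] for s in idx] if not isinstance(classes, pd.Series) \
        else [classes[s] for s in idx]
    uniq = sorted(set(y_labels))
    Y = np.array([[1.0 if lab == u else 0.0 for u in uniq] for lab in y_labels])
    Xs = _scale(X, scaling)
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(Xs, Y - Y.mean(axis=0))
    scores = model.x_scores_.copy()
    loadings = model.x_loadings_.copy()
    scores, loadings = _fix_signs(scores, loadings)
    pred = model.predict(Xs) + Y.mean(axis=0)
    acc = float(np.mean(np.argmax(pred, axis=1)
                        == np.array([uniq.index(l) for l in y_labels])))
    ss_res = float((((Y - Y.mean(axis=0)) - model.predict(Xs)) ** 2).sum())
    ss_tot = float(((Y - Y.mean(axis=0)) ** 2).sum())
    comps = [f"LV{k + 1}" for k in range(n_components)]
    return PLSDAResult(pd.DataFrame(scores, index=idx, columns=comps),
                       pd.DataFrame(loadings, index=cols, columns=comps),
                       uniq, acc, 1.0 - ss_res / ss_tot if ss_tot else np.nan)


@dataclass
class CPCAResult:
    super_scores: pd.DataFrame
    block_scores: list[pd.DataFrame]
    block_loadings: list[pd.DataFrame]
    block_weights: pd.DataFrame       # components x blocks
    explained_variance_ratio: np.ndarray


def cpca(blocks: list, n_components: int = 2, scaling: str | None = "uv",
         max_iter: int = 500, tol: float = 1e-12) -> CPCAResult:
    """Consensus PCA (CPCA-W) over blocks sharing the same samples.

    NIPALS-style iteration: block loadings are regressions of each block on
    the super score, block scores are re-projections, and the super score
    is the weighted combination of block scores; blocks are deflated by the
    super score.  With a single block the super scores and loadings equal
    ordinary PCA of that block.
    """
    if not blocks:
        raise ValueError("need at least one block")
    mats, idx = [], None
    cols_list = []
    for b in blocks:
        X, bi, bc = _as_array(b)
        if idx is None:
            idx = bi
        elif len(bi) != len(idx):
            raise ValueError("blocks must share the same samples")
        mats.append(_scale(X, scaling))
        cols_list.append(bc)
    nb = len(mats)
    total_var = sum(float((X ** 2).sum()) for X in mats)

    T_super = np.zeros((len(idx), n_components))
    Tb = [np.zeros((len(idx), n_components)) for _ in range(nb)]
    Pb = [np.zeros((X.shape[1], n_components)) for X in mats]
    Wsup = np.zeros((nb, n_components))
    evr = []
    Xw = [X.copy() for X in mats]
    for k in range(n_components):
        start = max(range(nb), key=lambda i: np.max(np.sum(Xw[i] ** 2, axis=0)))
        j = int(np.argmax(np.sum(Xw[start] ** 2, axis=0)))
        t = Xw[start][:, j].copy()
        if np.allclose(t, 0):
            t = np.ones(len(idx))
        for _ in range(max_iter):
            t_old = t
            tb_mat = np.empty((len(idx), nb))
            pb = []
            for i, X in enumerate(Xw):
                p = X.T @ t / float(t @ t)
                norm = np.linalg.norm(p)
                p = p / norm if norm > 0 else p
                pb.append(p)
                tb_mat[:, i] = X @ p
            w = tb_mat.T @ t / float(t @ t)
            norm = np.linalg.norm(w)
            w = w / norm if norm > 0 else w
            t = tb_mat @ w
            if np.linalg.norm(t - t_old) <= tol * max(np.linalg.norm(t), 1e-30):
                break
        T_super[:, k] = t
        Wsup[:, k] = w
        var_k = 0.0
        for i, X in enumerate(Xw):
            p_defl = X.T @ t / float(t @ t)
            Pb[i][:, k] = pb[i]
            Tb[i][:, k] = tb_mat[:, i]
            var_k += float(t @ t) * float(p_defl @ p_defl)
            Xw[i] = X - np.outer(t, p_defl)
        evr.append(var_k / total_var if total_var else 0.0)
    # sign convention on the concatenated loading direction
    for k in range(n_components):
        concat = np.concatenate([Pb[i][:, k] for i in range(nb)])
        j = int(np.argmax(np.abs(concat)))
        if concat[j] < 0:
            T_super[:, k] *= -1
            for i in range(nb):
                Pb[i][:, k] *= -1
                Tb[i][:, k] *= -1
    comps = [f"PC{k + 1}" for k in range(n_components)]
    return CPCAResult(
        pd.DataFrame(T_super, index=idx, columns=comps),
        [pd.DataFrame(Tb[i], index=idx, columns=comps) for i in range(nb)],
        [pd.DataFrame(Pb[i], index=cols_list[i], columns=comps) for i in range(nb)],
        pd.DataFrame(np.abs(Wsup), index=[f"block{i + 1}" for i in range(nb)],
                     columns=comps).T,
        np.array(evr))


# ---------------------------------------------------------------------------
# Trend analysis
# ---------------------------------------------------------------------------

@dataclass
class TrendVector:
    feature: str
    values: np.ndarray  # z-standardized profile


@dataclass
class TrendCluster:
    members: list[str]
    centroid: np.ndarray
    quality: float      # % members with r(member, centroid) >= r_hi


def trend_vectors(matrix: DataMatrix, labels: dict[str, str] | None = None,
                  label_order: list[str] | None = None,
                  per_sample: bool = False) -> pd.DataFrame:
    """Per-feature standardized area profiles (features x points).

    By default profiles are replicate-group means in label order; constant
    or all-missing profiles are excluded (they carry no trend).
    """
    areas = matrix.areas
    if not per_sample and labels:
        order = label_order or sorted(set(labels.values()))
        cols = {}
        for lab in order:
            ss = [s for s in matrix.samples if labels.get(s) == lab]
            cols[lab] = areas.loc[ss].mean(axis=0, skipna=True)
        profile = pd.DataFrame(cols)
    else:
        profile = areas.T.copy()
    profile = profile.fillna(0.0)
    sd = profile.std(axis=1, ddof=0)
    keep = sd > 0
    profile = profile.loc[keep]
    z = profile.sub(profile.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return z


def match_trend(matrix: DataMatrix, target: np.ndarray | list,
                r_min: float = 0.8, labels: dict[str, str] | None = None,
                label_order: list[str] | None = None,
                per_sample: bool = False) -> pd.DataFrame:
    """Extract features whose trend correlates with a target profile at
    Pearson r >= ``r_min`` (default 0.8), sorted by decreasing r."""
    z = trend_vectors(matrix, labels, label_order, per_sample)
    target = np.asarray(target, dtype=float)
    if target.std() == 0:
        raise ValueError("target trend is constant")
    rows = []
    for name, vec in z.iterrows():
        r = float(np.corrcoef(vec.to_numpy(), target)[0, 1])
        if r >= r_min:
            rows.append({"feature": name, "r": r})
    return (pd.DataFrame(rows, columns=["feature", "r"])
            .sort_values("r", ascending=False).reset_index(drop=True))


def _cluster_quality(Z: np.ndarray, centroid: np.ndarray, r_hi: float) -> float:
    if Z.shape[0] == 0:
        return 0.0
    cs = centroid.std()
    rs = []
    for row in Z:
        if row.std() == 0 or cs == 0:
            rs.append(0.0)
        else:
            rs.append(np.corrcoef(row, centroid)[0, 1])
    return float(100.0 * np.mean(np.asarray(rs) >= r_hi))


def cluster_trends(matrix: DataMatrix, k: int, method: str = "kmeans",
                   r_hi: float = 0.8, seed: int = 0,
                   labels: dict[str, str] | None = None,
                   label_order: list[str] | None = None,
                   per_sample: bool = False) -> list[TrendCluster]:
    """Group feature trends with K-means or bisecting K-means.

    Each cluster's quality is the percentage of member trends highly
    correlated (r >= ``r_hi``) with the cluster's average trend.
    """
    from sklearn.cluster import BisectingKMeans, KMeans

    z = trend_vectors(matrix, labels, label_order, per_sample)
    Z = z.to_numpy()
    names = list(z.index)
    if k == 1:
        centroid = Z.mean(axis=0)
        return [TrendCluster(names, centroid, _cluster_quality(Z, centroid, r_hi))]
    cls = (KMeans(n_clusters=k, n_init=10, random_state=seed)
           if method == "kmeans"
           else BisectingKMeans(n_clusters=k, random_state=seed))
    assign = cls.fit_predict(Z)
    out = []
    for c in range(k):
        sel = assign == c
        members = [n for n, m in zip(names, sel) if m]
        centroid = Z[sel].mean(axis=0) if sel.any() else np.zeros(Z.shape[1])
        out.append(TrendCluster(members, centroid,
                                _cluster_quality(Z[sel], centroid, r_hi)))
    return out


def split_cluster(matrix: DataMatrix, cluster: TrendCluster, seed: int = 0,
                  r_hi: float = 0.8, labels: dict[str, str] | None = None,
                  label_order: list[str] | None = None,
                  per_sample: bool = False) -> tuple[TrendCluster, TrendCluster]:
    """Preview the bisecting split of one cluster into two subclusters
    without committing it."""
    from sklearn.cluster import KMeans

    z = trend_vectors(matrix, labels, label_order, per_sample).loc[cluster.members]
    Z = z.to_numpy()
    assign = KMeans(n_clusters=2, n_init=10, random_state=seed).fit_predict(Z)
    subs = []
    for c in (0, 1):
        sel = assign == c
        members = [n for n, m in zip(cluster.members, sel) if m]
        centroid = Z[sel].mean(axis=0) if sel.any() else np.zeros(Z.shape[1])
        subs.append(TrendCluster(members, centroid,
                                 _cluster_quality(Z[sel], centroid, r_hi)))
    return subs[0], subs[1]


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    compound: str
    points: list[tuple[float, float, bool]]  # (conc, area, included)
    model: str = "linear"                    # linear | quadratic
    weighting: str = "none"                  # none | 1/x | 1/x2
    coefficients: np.ndarray = field(default_factory=lambda: np.zeros(2))
    r2: float = 0.0

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(conc, dtype=float))

    def inverse(self, area: float) -> float:
        c = self.coefficients
        if self.model == "linear":
            return (area - c[1]) / c[0]
        roots = np.roots([c[0], c[1], c[2] - area])
        roots = roots[np.isreal(roots)].real
        concs = [x for x, _, inc in self.points if inc]
        lo, hi = min(concs), max(concs)
        if roots.size == 0:
            return np.nan
        return float(min(roots, key=lambda r: 0 if lo <= r <= hi else min(abs(r - lo), abs(r - hi))))

    @property
    def conc_range(self) -> tuple[float, float]:
        concs = [x for x, _, inc in self.points if inc]
        return min(concs), max(concs)


def fit_calibration(points: list[tuple[float, float]], model: str = "linear",
                    weighting: str = "none", compound: str = "",
                    excluded: set[int] | None = None) -> CalibrationCurve:
    """Weighted least-squares calibration fit (weights 1, 1/x or 1/x^2)."""
    excluded = excluded or set()
    flags = [(float(x), float(y), i not in excluded)
             for i, (x, y) in enumerate(points)]
    inc = [(x, y) for x, y, keep in flags if keep]
    if len(inc) < 3:
        raise ValueError("need >= 3 included calibration points")
    x = np.array([p[0] for p in inc])
    y = np.array([p[1] for p in inc])
    if weighting == "none":
        w = np.ones_like(x)
    elif weighting == "1/x":
        w = 1.0 / x
    elif weighting in ("1/x2", "1/x^2"):
        w = 1.0 / x ** 2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    deg = 1 if model == "linear" else 2
    coef = np.polyfit(x, y, deg, w=np.sqrt(w))
    yhat = np.polyval(coef, x)
    ybar = np.average(y, weights=w)
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(compound, flags, model, weighting, coef,
                            max(0.0, min(1.0, r2)))


def quantify(matrix: DataMatrix, curve: CalibrationCurve,
             feature: str) -> pd.DataFrame:
    """Inverse-predict concentrations for one feature's areas; values
    outside the calibrated range are flagged as extrapolations."""
    lo, hi = curve.conc_range
    rows = []
    for sample in matrix.samples:
        area = matrix.areas.at[sample, feature]
        if pd.isna(area):
            rows.append({"sample": sample, "concentration": np.nan, "flag": "missing"})
            continue
        conc = curve.inverse(float(area))
        flag = "" if lo <= conc <= hi else "extrapolated"
        rows.append({"sample": sample, "concentration": conc, "flag": flag})
    return pd.DataFrame(rows).set_index("sample")


def relative_quantify(matrix: DataMatrix, feature: str,
                      standard_feature: str) -> pd.Series:
    """Relative quantification: per-sample area ratio to a chosen standard."""
    return matrix.areas[feature] / matrix.areas[standard_feature]


# ---------------------------------------------------------------------------
# Pathway projection
# ---------------------------------------------------------------------------

@dataclass
class PathwayGraph:
    """Metabolite/enzyme graph in the package's JSON dialect:
    {nodes: [{id, name, type, human}], edges: [{src, dst, relation}]}."""

    nodes: dict[str, dict]
    edges: list[dict]
    states: dict[str, str] = field(default_factory=dict)  # id -> absent|detected|up|down

    @classmethod
    def from_json(cls, data: dict | str) -> "PathwayGraph":
        import json as _json

        if isinstance(data, str):
            with open(data) as fh:
                data = _json.load(fh)
        nodes = {}
        for n in data["nodes"]:
            if n["id"] in nodes:
                raise ValueError(f"duplicate node id {n['id']}")
            nodes[n["id"]] = n
        return cls(nodes, list(data.get("edges", [])))


def project_pathway(graph: PathwayGraph, annotations,
                    comparison: pd.DataFrame | None = None,
                    fc_threshold: float = 1.0,
                    p_threshold: float = 0.05,
                    id_key: str = "HMDB_ID") -> PathwayGraph:
    """Project identification results onto a pathway graph.

    Nodes whose id matches an annotation's external id are state
    ``detected`` (gray); with a two-label ``comparison`` table (the output
    of :func:`fold_change_tests`, indexed by feature), nodes move to ``up``
    (red) when log2FC > ``fc_threshold`` at p <= ``p_threshold`` and to
    ``down`` (blue) for the mirrored condition.  Annotations without an
    external id are ignored.
    """
    states = {nid: "absent" for nid in graph.nodes}
    for a in annotations:
        nid = a.external_ids.get(id_key) if a.external_ids else None
        if nid is None or nid not in graph.nodes or not a.compound_id:
            continue
        if a.color == "red":
            continue
        states[nid] = "detected"
        if comparison is not None and a.feature in comparison.index:
            row = comparison.loc[a.feature]
            if np.isfinite(row["p"]) and row["p"] <= p_threshold:
                if row["log2fc"] > fc_threshold:
                    states[nid] = "up"
                elif row["log2fc"] < -fc_threshold:
                    states[nid] = "down"
    graph.states = states
    return graph
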