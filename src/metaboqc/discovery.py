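"""Multivariate marker discovery: PCA, two-class OPLS-DA, S-plot selection,
and t-test/fold-change ranking.

OPLS-DA separates between-class variation (one predictive component for a
two-class problem) from orthogonal within-class variation, computed by the
NIPALS orthogonal-projection algorithm.  The S-plot places each feature by
its covariance p[1] (model influence) and correlation p(corr)[1]
(reliability) with the predictive score; features with |p(corr)[1]| above a
threshold (0.7 in the canonical protocol) are selected as candidates.

Scaling default is Pareto (centering, then division by the square root of
each feature's standard deviation), the usual choice for LC-MS intensity
matrices; unit-variance and centre-only scaling are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SkPCA

log = logging.getLogger(__name__)

SCALINGS = ("pareto", "unit_variance", "center_only")


def _as_matrix(X) -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, list(range(X.shape[1]))


def _scale_factors(X: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray]:
    if scaling not in SCALINGS:
        raise ValueError(f"scaling must be one of {SCALINGS}, got {scaling!r}")
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scaling == "pareto":
        scale = np.sqrt(sd)
    elif scaling == "unit_variance":
        scale = sd.copy()
    else:
        scale = np.ones_like(sd)
    scale[scale == 0] = 1.0  # constant features pass through centred
    return center, scale


def impute_half_minimum(X: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells by half the feature's minimum observed intensity
    (common practice for left-censored LC-MS intensities).

    Expects feature-table orientation: rows are features, columns injections.
    """
    Xv = X.to_numpy(dtype=float)
    row_min = np.nanmin(np.where(np.isnan(Xv), np.inf, Xv), axis=1)
    row_min = np.where(np.isfinite(row_min), row_min, 0.0)
    fill = np.broadcast_to(row_min[:, None] / 2.0, Xv.shape)
    return pd.DataFrame(np.where(np.isnan(Xv), fill, Xv), index=X.index, columns=X.columns)


@dataclass
class LatentModel:
    """Scores/loadings container shared by PCA and OPLS-DA results."""

    scores: pd.DataFrame          # samples × components
    loadings: pd.DataFrame        # features × components
    component_kinds: list[str]    # "predictive" | "orthogonal" | "principal"
    explained_variation: list[float]


def pca(X, n_components: int = 2, scaling: str = "pareto") -> LatentModel:
    """Principal component analysis of a samples × features matrix.

    Constant features are dropped (with a warning) under unit-variance
    scaling.  Explained variation is the fraction of scaled-matrix variance
    per component, non-increasing by construction.
    """
    M, feat_ids = _as_matrix(X)
    if np.isnan(M).any():
        raise ValueError("matrix contains missing values; impute first")
    if scaling == "unit_variance":
        sd = M.std(axis=0, ddof=1)
        if (sd == 0).any():
            log.warning("dropping %d constant feature(s) under unit-variance scaling",
                        int((sd == 0).sum()))
            keep = sd > 0
            M = M[:, keep]
            feat_ids = [f for f, k in zip(feat_ids, keep) if k]
    n_components = min(n_components, min(M.shape) - 1 if min(M.shape) > 1 else 1)
    center, scale = _scale_factors(M, scaling)
    Ms = (M - center) / scale
    model = _SkPCA(n_components=n_components, svd_solver="full").fit(Ms)
    scores = model.transform(Ms)
    comp = [f"PC{i + 1}" for i in range(n_components)]
    sample_index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(M.shape[0])
    return LatentModel(
        scores=pd.DataFrame(scores, index=sample_index, columns=comp),
        loadings=pd.DataFrame(model.components_.T, index=feat_ids, columns=comp),
        component_kinds=["principal"] * n_components,
        explained_variation=[float(v) for v in model.explained_variance_ratio_],
    )


class OPLSDA(BaseEstimator, TransformerMixin):
    """Two-class orthogonal PLS discriminant analysis.

    Parameters
    ----------
    n_orthogonal : int
        Number of orthogonal (class-uncorrelated) components removed before
        the single predictive component is computed.  With 0 the model
        reduces exactly to single-component PLS1.
    scaling : {"pareto", "unit_variance", "center_only"}

    Attributes (after fit)
    ----------------------
    classes_ : the two class labels, predictive score oriented so that
        ``classes_[1]`` has the higher mean score.
    predictive_scores_ : (n_samples,) predictive component t.
    orthogonal_scores_ : (n_samples, n_orthogonal).
    explained_variation_ : fraction of scaled-X sum of squares per component
        (predictive first).
    """

    def __init__(self, n_orthogonal: int = 1, scaling: str = "pareto"):
        self.n_orthogonal = n_orthogonal
        self.scaling = scaling

    def fit(self, X, y):
        M, feat_ids = _as_matrix(X)
        if np.isnan(M).any():
            raise ValueError("matrix contains missing values; impute first")
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"OPLS-DA requires exactly 2 classes, got {classes.size}")
        counts = [(y == c).sum() for c in classes]
        if min(counts) < 2:
            raise ValueError("each class needs at least 2 samples")
        yc = np.where(y == classes[1], 1.0, -1.0)
        yc = yc - yc.mean()

        self.x_center_, self.x_scale_ = _scale_factors(M, self.scaling)
        Xs = (M - self.x_center_) / self.x_scale_
        total_ss = float((Xs ** 2).sum())
        Xc = Xs.copy()

        W_o, P_o, T_o = [], [], []
        for _ in range(self.n_orthogonal):
            w = Xc.T @ yc / (yc @ yc)
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = Xc @ w
            p = Xc.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            n_o = np.linalg.norm(w_o)
            if n_o < 1e-12:
                break  # no orthogonal variation left
            w_o /= n_o
            t_o = Xc @ w_o
            p_o = Xc.T @ t_o / (t_o @ t_o)
            Xc = Xc - np.outer(t_o, p_o)
            W_o.append(w_o); P_o.append(p_o); T_o.append(t_o)

        w = Xc.T @ yc / (yc @ yc)
        w /= np.linalg.norm(w)
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        if t[y == classes[1]].mean() < t[y == classes[0]].mean():
            w, t, p = -w, -t, -p

        self.classes_ = classes
        self.feature_ids_ = feat_ids
        self.weights_ = w
        self.loadings_p_ = p
        self.predictive_scores_ = t
        self.orthogonal_weights_ = np.column_stack(W_o) if W_o else np.empty((M.shape[1], 0))
        self.orthogonal_loadings_ = np.column_stack(P_o) if P_o else np.empty((M.shape[1], 0))
        self.orthogonal_scores_ = np.column_stack(T_o) if T_o else np.empty((M.shape[0], 0))
        self.filtered_matrix_ = Xc
        self.scaled_matrix_ = Xs
        ev = [float((t @ t) * (p @ p) / total_ss)]
        for t_o, p_o in zip(T_o, P_o):
            ev.append(float((t_o @ t_o) * (p_o @ p_o) / total_ss))
        self.explained_variation_ = ev
        return self

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise AttributeError("OPLSDA instance is not fitted yet")

    def transform(self, X) -> np.ndarray:
        """Predictive + orthogonal scores of (new) samples."""
        self._check_fitted()
        M, _ = _as_matrix(X)
        Xs = (M - self.x_center_) / self.x_scale_
        T_o = []
        for j in range(self.orthogonal_weights_.shape[1]):
            t_o = Xs @ self.orthogonal_weights_[:, j]
            Xs = Xs - np.outer(t_o, self.orthogonal_loadings_[:, j])
            T_o.append(t_o)
        t = Xs @ self.weights_
        return np.column_stack([t, *T_o]) if T_o else t[:, None]

    def to_latent_model(self) -> LatentModel:
        self._check_fitted()
        n_o = self.orthogonal_scores_.shape[1]
        comp = ["predictive"] + [f"orthogonal{i + 1}" for i in range(n_o)]
        scores = np.column_stack([self.predictive_scores_, self.orthogonal_scores_]) \
            if n_o else self.predictive_scores_[:, None]
        loadings = np.column_stack([self.loadings_p_, self.orthogonal_loadings_]) \
            if n_o else self.loadings_p_[:, None]
        return LatentModel(
            scores=pd.DataFrame(scores, columns=comp),
            loadings=pd.DataFrame(loadings, index=self.feature_ids_, columns=comp),
            component_kinds=["predictive"] + ["orthogonal"] * n_o,
            explained_variation=list(self.explained_variation_),
        )


def opls_da(X, labels, n_orthogonal: int = 1, scaling: str = "pareto") -> OPLSDA:
    """Functional front end: fit and return an :class:`OPLSDA` model."""
    return OPLSDA(n_orthogonal=n_orthogonal, scaling=scaling).fit(X, labels)


def s_plot(model: OPLSDA, X=None) -> pd.DataFrame:
    """Per-feature S-plot coordinates against the predictive score.

    p1 is the covariance of the (scaled, centred) feature with the predictive
    score; pcorr1 the Pearson correlation.  Zero-variance features are
    excluded with a warning.  Returns a DataFrame indexed by feature_id with
    columns ``p1`` and ``pcorr1``.

    By default the model's own (scaled) training matrix is used.  An explicit
    ``X`` — any matrix with the same samples, e.g. with extra columns — is
    correlated as given (p(corr)[1] is scale-invariant; p[1] is then on the
    scale of the supplied matrix).
    """
    model._check_fitted()
    if X is None:
        Xs = model.scaled_matrix_
        feat_ids = model.feature_ids_
    else:
        Xs, feat_ids = _as_matrix(X)
    t = model.predictive_scores_
    n = len(t)
    tc = t - t.mean()
    Xc = Xs - Xs.mean(axis=0)
    p1 = Xc.T @ tc / (n - 1)
    sd_x = Xc.std(axis=0, ddof=1)
    sd_t = tc.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pcorr1 = p1 / (sd_x * sd_t)
    keep = sd_x > 0
    if (~keep).any():
        log.warning("s_plot: excluded %d zero-variance feature(s)", int((~keep).sum()))
    out = pd.DataFrame({"p1": p1, "pcorr1": pcorr1},
                       index=pd.Index(feat_ids, name="feature_id"))
    return out[keep]


def select_by_pcorr(points: pd.DataFrame, threshold: float = 0.7) -> list:
    """Features with p(corr)[1] above +threshold or below −threshold."""
    sel = points[(points["pcorr1"] > threshold) | (points["pcorr1"] < -threshold)]
    return list(sel.index)


@dataclass
class MarkerCandidate:
    feature_id: str
    p_value: float
    fold_change: float      # stored-group mean over control-group mean
    direction: str          # "increasing" | "decreasing"
    pcorr1: float = float("nan")


def rank_candidates(X, labels, top_n: int = 40, equal_var: bool = False,
                    pcorr: pd.Series | None = None) -> list[MarkerCandidate]:
    """Rank features by two-sample t-test p-value, then |log fold change|.

    ``labels`` is boolean/two-class per sample (False/first class = control,
    True/second class = stored).  Welch's test by default; ``equal_var=True``
    gives the pooled-variance Student test.  Features with zero variance in
    both groups are skipped.
    """
    M, feat_ids = _as_matrix(X)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("rank_candidates needs exactly two groups")
    g0 = M[labels == classes[0]]
    g1 = M[labels == classes[1]]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both groups must be non-empty")

    candidates = []
    with np.errstate(invalid="ignore", divide="ignore"):
        tt = stats.ttest_ind(g1, g0, equal_var=equal_var, axis=0)
    for j, fid in enumerate(feat_ids):
        if g0[:, j].std() == 0 and g1[:, j].std() == 0:
            continue
        p = float(tt.pvalue[j])
        if np.isnan(p):
            p = 1.0
        m0, m1 = float(g0[:, j].mean()), float(g1[:, j].mean())
        fc = m1 / m0 if m0 > 0 else float("inf")
        direction = "increasing" if fc >= 1 else "decreasing"
        pc = float(pcorr.get(fid, float("nan"))) if pcorr is not None else float("nan")
        candidates.append(MarkerCandidate(fid, p, fc, direction, pc))

    def sort_key(c: MarkerCandidate):
        lfc = abs(np.log(c.fold_change)) if 0 < c.fold_change < np.inf else np.inf
        return (c.p_value, -lfc)

    candidates.sort(key=sort_key)
    return candidates[:top_n]
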