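"""Multivariate calibration and classification.

Implements PCA by SVD on mean-centred data, canonical discriminant
analysis (LDA) on leading PC scores with nearest-centroid assignment,
PLS1 regression via NIPALS with deflation, grouped cross-validation with
RMSECV-driven latent-variable selection, and loading-based important
wavelength extraction.

Nothing here delegates to scikit-learn: the estimators are authored so
the test suite can cross-check them against independent oracles.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import ConfigError, DataError, DegenerateResponseError, FoldDesignError
from .spectra import SpectraSet

log = logging.getLogger(__name__)


# ======================================================================
# Metrics


@dataclass
class FitMetrics:
    r2: float | None = None
    r2_cv: float | None = None
    rmsec: float | None = None
    rmsecv: float | None = None
    accuracy_recognition_pct: float | None = None
    accuracy_prediction_pct: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def regression_metrics(y_true, y_pred) -> FitMetrics:
    """R^2 = 1 - SSres/SStot (SStot about the mean of y_true) and RMSE."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise DataError("y_true and y_pred must have equal length >= 2")
    sstot = float(np.sum((y_true - y_true.mean()) ** 2))
    if sstot == 0.0:
        raise DataError("R^2 undefined for constant y_true")
    ssres = float(np.sum((y_true - y_pred) ** 2))
    return FitMetrics(
        r2=1.0 - ssres / sstot, rmsec=float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    )


# ======================================================================
# Cross-validation schemes


@dataclass
class CVScheme:
    """Fold design.

    kind="replicate_3fold": fold r holds out every row with replicate r
    (replicates must be 1..3). kind="group_kfold_by_time": germination
    time points are shuffled with `seed` and dealt round-robin into `k`
    folds, so all spectra sharing a time point share a fold.
    """

    kind: str = "replicate_3fold"
    k: int = 6
    seed: int = 0

    def folds(self, meta) -> list[np.ndarray]:
        """Return a list of validation-row index arrays partitioning the data."""
        if self.kind == "replicate_3fold":
            reps = np.asarray(meta["replicate"], dtype=float)
            uniq = np.unique(reps)
            if not set(uniq).issubset({1.0, 2.0, 3.0}):
                raise FoldDesignError(
                    f"replicate_3fold requires replicate labels in {{1,2,3}}, got {uniq}"
                )
            return [np.flatnonzero(reps == r) for r in (1.0, 2.0, 3.0)]
        if self.kind == "group_kfold_by_time":
            times = np.asarray(meta["germination_h"], dtype=float)
            uniq = np.unique(times)
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(len(uniq))
            fold_of_time = {uniq[j]: i % self.k for i, j in enumerate(order)}
            assign = np.array([fold_of_time[t] for t in times])
            return [np.flatnonzero(assign == f) for f in range(self.k)]
        raise ConfigError(f"unknown CV scheme kind {self.kind!r}")


# ======================================================================
# PCA


@dataclass
class PCAModel:
    center: np.ndarray
    loadings: np.ndarray  # (n_pcs, n_features)
    scores: np.ndarray  # (n_samples, n_pcs)
    explained_var_pct: np.ndarray
    wavelengths: np.ndarray | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) @ self.loadings.T

    def to_dict(self) -> dict:
        d = {
            "center": self.center.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_var_pct": self.explained_var_pct.tolist(),
        }
        if self.wavelengths is not None:
            d["wavelengths"] = self.wavelengths.tolist()
        return d


def _as_matrix(X) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(X, SpectraSet):
        return X.absorbance, X.wavelengths
    return np.asarray(X, dtype=float), None


def pca_fit(data, n_pcs: int) -> PCAModel:
    """PCA by SVD on mean-centred data.

    explained_var_pct_i = 100 * s_i^2 / sum_j s_j^2. Sign convention:
    each loading's largest-magnitude element is made positive.
    """
    X, wl = _as_matrix(data)
    n, p = X.shape
    if n < 2:
        raise ConfigError("PCA requires at least 2 samples")
    if n_pcs > min(n - 1, p):
        raise ConfigError(
            f"n_pcs={n_pcs} exceeds min(n_samples-1, n_features)={min(n - 1, p)}"
        )
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var_pct = 100.0 * s**2 / np.sum(s**2)
    loadings = Vt[:n_pcs]
    # fix signs: largest-|.| element of each loading positive
    signs = np.sign(loadings[np.arange(n_pcs), np.argmax(np.abs(loadings), axis=1)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs[:, None]
    scores = Xc @ loadings.T
    return PCAModel(center, loadings, scores, var_pct[:n_pcs], wl)


# ======================================================================
# LDA on PC scores


@dataclass
class LDAModel:
    n_pcs: int
    class_labels: list
    canonical_axes: np.ndarray  # (n_roots, n_pcs), in PC-score space
    class_centroids: np.ndarray  # (n_classes, n_roots), in root space
    pooled_within_scatter: np.ndarray
    pca: PCAModel | None = None
    between_var_along_roots: np.ndarray | None = None

    def project(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, dtype=float) @ self.canonical_axes.T

    def classify_scores(self, scores: np.ndarray) -> np.ndarray:
        """Nearest class centroid in root space; ties break to the
        lowest class label."""
        roots = self.project(scores)
        d2 = ((roots[:, None, :] - self.class_centroids[None, :, :]) ** 2).sum(axis=2)
        idx = np.argmin(d2, axis=1)
        labels = np.asarray(self.class_labels, dtype=object)
        return labels[idx]

    def classify_spectra(self, data) -> np.ndarray:
        if self.pca is None:
            raise ConfigError("LDA model carries no PCA; classify via scores")
        X, _ = _as_matrix(data)
        return self.classify_scores(self.pca.transform(X))


def _lda_from_scores(scores: np.ndarray, labels: np.ndarray, n_pcs: int) -> LDAModel:
    classes = sorted(set(labels.tolist()))
    k = len(classes)
    n, p = scores.shape
    if k == 1:
        # degenerate: no discriminant axes, everything maps to the class
        return LDAModel(
            n_pcs=n_pcs,
            class_labels=classes,
            canonical_axes=np.zeros((0, p)),
            class_centroids=np.zeros((1, 0)),
            pooled_within_scatter=np.cov(scores, rowvar=False).reshape(p, p),
        )
    grand = scores.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    means = np.zeros((k, p))
    for i, c in enumerate(classes):
        sub = scores[labels == c]
        if len(sub) < 2:
            raise DataError(f"class {c!r} has fewer than 2 samples")
        means[i] = sub.mean(axis=0)
        d = sub - means[i]
        Sw += d.T @ d
        g = means[i] - grand
        Sb += len(sub) * np.outer(g, g)
    Sw /= n - k
    cond = np.linalg.cond(Sw)
    if not np.isfinite(cond) or cond > 1e12:
        eps = 1e-8 * np.trace(Sw) / p
        log.warning("pooled within-class scatter ill-conditioned; adding ridge %g", eps)
        Sw = Sw + eps * np.eye(p)
    # eigen-decomposition of Sw^{-1} Sb via the symmetric whitened form
    evals, evecs = np.linalg.eigh(Sw)
    evals = np.clip(evals, 1e-300, None)
    W = evecs @ np.diag(evals**-0.5) @ evecs.T  # Sw^{-1/2}
    M = W @ Sb @ W
    lam, V = np.linalg.eigh(M)
    order = np.argsort(lam)[::-1]
    n_roots = min(k - 1, p)
    axes = (W @ V[:, order[:n_roots]]).T  # rows are canonical axes
    # normalise and fix sign (largest-|.| coefficient positive)
    axes = axes / np.linalg.norm(axes, axis=1, keepdims=True)
    signs = np.sign(axes[np.arange(n_roots), np.argmax(np.abs(axes), axis=1)])
    signs[signs == 0] = 1.0
    axes = axes * signs[:, None]
    centroids = means @ axes.T
    return LDAModel(
        n_pcs=n_pcs,
        class_labels=classes,
        canonical_axes=axes,
        class_centroids=centroids,
        pooled_within_scatter=Sw,
        between_var_along_roots=np.sort(lam)[::-1][:n_roots],
    )


def pca_lda_fit(data, labels, n_pcs: int = 10) -> LDAModel:
    """PCA to ``n_pcs`` scores, then canonical discriminant analysis.

    Classification of new spectra is nearest class centroid (Euclidean)
    in the canonical-root space.
    """
    X, _ = _as_matrix(data)
    labels = np.asarray(labels, dtype=object)
    n_pcs = min(n_pcs, min(X.shape[0] - 1, X.shape[1]))
    pca = pca_fit(data, n_pcs)
    model = _lda_from_scores(pca.scores, labels, n_pcs)
    model.pca = pca
    return model


def crossval_lda(
    data, labels, scheme: CVScheme, n_pcs: int = 10
) -> tuple[FitMetrics, np.ndarray, list]:
    """Cross-validated PCA-LDA classification.

    PCA and LDA are refit on calibration rows only in every fold (no
    leakage). Returns (metrics, pooled confusion matrix over validation
    folds, class labels). Recognition accuracy is measured on
    calibration rows, prediction accuracy on held-out rows, both
    averaged over folds.
    """
    X, _ = _as_matrix(data)
    meta = data.meta if isinstance(data, SpectraSet) else None
    if meta is None:
        raise ConfigError("crossval_lda needs a SpectraSet with metadata")
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels.tolist()))
    folds = scheme.folds(meta)
    all_idx = np.sort(np.concatenate(folds))
    if not np.array_equal(all_idx, np.arange(len(labels))):
        raise FoldDesignError("folds do not partition the data")
    idx_of = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    rec_accs, pred_accs = [], []
    for val_idx in folds:
        cal_mask = np.ones(len(labels), dtype=bool)
        cal_mask[val_idx] = False
        cal_labels = labels[cal_mask]
        if set(cal_labels.tolist()) != set(classes):
            raise FoldDesignError("a class is absent from a calibration fold")
        n_pcs_fold = min(n_pcs, cal_mask.sum() - 1, X.shape[1])
        pca = pca_fit(X[cal_mask], n_pcs_fold)
        model = _lda_from_scores(pca.transform(X[cal_mask]), cal_labels, n_pcs_fold)
        rec = model.classify_scores(pca.transform(X[cal_mask]))
        rec_accs.append(100.0 * np.mean(rec == cal_labels))
        pred = model.classify_scores(pca.transform(X[val_idx]))
        true = labels[val_idx]
        pred_accs.append(100.0 * np.mean(pred == true))
        for t, p in zip(true, pred):
            confusion[idx_of[t], idx_of[p]] += 1
    metrics = FitMetrics(
        accuracy_recognition_pct=float(np.mean(rec_accs)),
        accuracy_prediction_pct=float(np.mean(pred_accs)),
    )
    return metrics, confusion, classes


# ======================================================================
# PLS1 (NIPALS)


@dataclass
class PLSRModel:
    n_lv: int
    x_center: np.ndarray
    y_center: float
    weights: np.ndarray  # (n_lv, p)
    x_loadings: np.ndarray  # (n_lv, p)
    y_loadings: np.ndarray  # (n_lv,)
    regression_vector: np.ndarray  # (p,)
    metrics: FitMetrics = field(default_factory=FitMetrics)
    wavelengths: np.ndarray | None = None

    def predict(self, X) -> np.ndarray:
        X, _ = _as_matrix(X)
        return (X - self.x_center) @ self.regression_vector + self.y_center

    def predict_sequential(self, X) -> np.ndarray:
        """Prediction by explicit LV-by-LV deflation; must agree with the
        regression-vector route (cross-check invariant)."""
        X, _ = _as_matrix(X)
        E = X - self.x_center
        yhat = np.full(X.shape[0], self.y_center)
        for a in range(self.n_lv):
            t = E @ self.weights[a]
            yhat += t * self.y_loadings[a]
            E = E - np.outer(t, self.x_loadings[a])
        return yhat

    def to_dict(self) -> dict:
        d = {
            "n_lv": self.n_lv,
            "x_center": self.x_center.tolist(),
            "y_center": self.y_center,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "regression_vector": self.regression_vector.tolist(),
            "metrics": self.metrics.to_dict(),
        }
        if self.wavelengths is not None:
            d["wavelengths"] = self.wavelengths.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PLSRModel":
        return cls(
            n_lv=int(d["n_lv"]),
            x_center=np.asarray(d["x_center"], dtype=float),
            y_center=float(d["y_center"]),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            regression_vector=np.asarray(d["regression_vector"], dtype=float),
            metrics=FitMetrics(**d.get("metrics", {})),
            wavelengths=(
                np.asarray(d["wavelengths"], dtype=float) if "wavelengths" in d else None
            ),
        )


def plsr_fit(X, y, n_lv: int) -> PLSRModel:
    """Single-response PLS regression via NIPALS with deflation."""
    Xm, wl = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if y.shape != (n,):
        raise DataError("y must be a vector matching the number of rows in X")
    if np.allclose(y, y[0]):
        raise DegenerateResponseError("response has zero variance")
    if n_lv > min(n - 1, p):
        raise ConfigError(f"n_lv={n_lv} exceeds min(n_samples-1, n_predictors)")
    x_center = Xm.mean(axis=0)
    y_center = float(y.mean())
    E = Xm - x_center
    f = y - y_center
    W = np.zeros((n_lv, p))
    P = np.zeros((n_lv, p))
    q = np.zeros(n_lv)
    for a in range(n_lv):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-14:  # X residual orthogonal to y residual: rank exhausted
            W, P, q = W[:a], P[:a], q[:a]
            n_lv = a
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-28:
            W, P, q = W[:a], P[:a], q[:a]
            n_lv = a
            break
        P[a] = E.T @ t / tt
        q[a] = float(f @ t) / tt
        W[a] = w
        E = E - np.outer(t, P[a])
        f = f - t * q[a]
    if n_lv == 0:
        raise DataError("no usable latent variable could be extracted")
    # b = W (P' W)^{-1} q, with W rows as columns in the textbook form
    Wt, Pt = W.T, P.T  # (p, A)
    b = Wt @ np.linalg.solve(Pt.T @ Wt, q)
    model = PLSRModel(
        n_lv=n_lv,
        x_center=x_center,
        y_center=y_center,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        regression_vector=b,
        wavelengths=wl,
    )
    m = regression_metrics(y, model.predict(Xm))
    model.metrics = FitMetrics(r2=m.r2, rmsec=m.rmsec)
    return model


def plsr_crossval(
    X, y, scheme: CVScheme, max_lv: int = 20, meta=None
) -> tuple[PLSRModel, FitMetrics]:
    """Grouped cross-validation over candidate latent-variable counts.

    For each candidate A in 1..max_lv every fold refits PLSR on the
    calibration rows only and predicts the held-out rows; RMSECV(A) is
    the pooled root mean squared error. The selected A is the smallest
    candidate whose RMSECV is within 2% of the global minimum (parsimony
    rule). The final model is refit on all rows at that A.
    """
    Xm, _ = _as_matrix(X)
    if meta is None:
        if not isinstance(X, SpectraSet):
            raise ConfigError("plsr_crossval needs metadata (SpectraSet or meta=)")
        meta = X.meta
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    folds = scheme.folds(meta)
    cap = min(max_lv, n - 1 - max(len(f) for f in folds), p)
    if cap < max_lv:
        log.info("max_lv capped at %d by data rank", cap)
    if cap < 1:
        raise ConfigError("not enough rows to cross-validate a single latent variable")
    press = np.zeros(cap)
    for val_idx in folds:
        cal_mask = np.ones(n, dtype=bool)
        cal_mask[val_idx] = False
        a_max = min(cap, int(cal_mask.sum()) - 1, p)
        full = plsr_fit(Xm[cal_mask], y[cal_mask], a_max)
        # sequential predictions at every A from one fit
        E = Xm[val_idx] - full.x_center
        yhat = np.full(len(val_idx), full.y_center)
        for a in range(cap):
            if a < full.n_lv:
                t = E @ full.weights[a]
                yhat = yhat + t * full.y_loadings[a]
                E = E - np.outer(t, full.x_loadings[a])
            press[a] += float(np.sum((y[val_idx] - yhat) ** 2))
    rmsecv = np.sqrt(press / n)
    best = float(rmsecv.min())
    selected = int(np.flatnonzero(rmsecv <= 1.02 * best)[0]) + 1
    model = plsr_fit(X, y, selected)
    metrics = FitMetrics(
        r2=model.metrics.r2,
        rmsec=model.metrics.rmsec,
        rmsecv=float(rmsecv[selected - 1]),
    )
    # cross-validated R^2 from pooled PRESS at the selected A
    sstot = float(np.sum((y - y.mean()) ** 2))
    metrics.r2_cv = 1.0 - press[selected - 1] / sstot
    model.metrics = metrics
    return model, metrics


# ======================================================================
# Important-wavelength extraction


def select_important_wavelengths(
    model: PCAModel,
    pcs: list[int] | None = None,
    prominence_frac: float = 0.5,
    min_separation_nm: float = 10.0,
) -> list[float]:
    """Local extrema of PC loading curves above a relative threshold.

    For each requested PC (1-based), local maxima of |loading| with
    |loading| >= prominence_frac * max|loading| are collected; the union
    is deduplicated within ``min_separation_nm`` keeping the larger
    |loading|, and returned sorted ascending.
    """
    if model.wavelengths is None:
        raise ConfigError("PCA model was not fitted on a wavelength-indexed dataset")
    pcs = pcs or [1, 2]
    wl = model.wavelengths
    candidates: list[tuple[float, float]] = []  # (nm, |loading|)
    for pc in pcs:
        if pc < 1 or pc > model.loadings.shape[0]:
            raise ConfigError(f"PC {pc} not available in the fitted model")
        curve = np.abs(model.loadings[pc - 1])
        height = prominence_frac * curve.max()
        peaks, _ = find_peaks(curve, height=height)
        # end points count as extrema when they dominate their neighbour
        if curve[0] >= height and curve[0] > curve[1]:
            peaks = np.concatenate([[0], peaks])
        if curve[-1] >= height and curve[-1] > curve[-2]:
            peaks = np.concatenate([peaks, [len(curve) - 1]])
        candidates.extend((float(wl[i]), float(curve[i])) for i in peaks)
    if not candidates:
        warnings.warn("no loading extrema above the prominence threshold")
        return []
    # greedy dedup: keep the strongest peak in each min_separation window
    kept: list[tuple[float, float]] = []
    for nm, mag in sorted(candidates, key=lambda t: -t[1]):
        if all(abs(nm - k_nm) >= min_separation_nm for k_nm, _ in kept):
            kept.append((nm, mag))
    return sorted(nm for nm, _ in kept)


# ======================================================================
# Model serialisation


def save_model_json(model, path) -> None:
    kind = type(model).__name__
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"kind": kind, "model": model.to_dict()}, fh, indent=1)


def load_plsr_json(path) -> PLSRModel:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    if d.get("kind") != "PLSRModel":
        raise ConfigError(f"expected a PLSRModel JSON, got {d.get('kind')!r}")
    return PLSRModel.from_dict(d["model"])
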