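"""Inverse models: random forest (primary), Beer-Lambert baseline, SVR, k-NN.

The learned regressors map normalized absorption-domain feature vectors to
the physiological targets (oxygenation ``s`` and first-layer blood volume
fraction ``v_hb``), both fractions in [0, 1]. The random forest is a single
multivariate forest predicting both targets jointly; SVR and k-NN fit one
model per target. The modified Beer-Lambert estimator is training-free: it
solves a linear least-squares unmixing of band absorbance onto the
band-averaged extinction spectra of HbO2 and Hb plus a constant offset that
absorbs wavelength-independent scattering losses, and reports
``s = x1 / (x1 + x2)``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

from .bands import BandMeasurement, BandSystem, normalize_features
from .tissue_model import ChromophoreTable

__all__ = [
    "TrainingSet",
    "RFHyperparams",
    "RegressorModel",
    "train_rf",
    "train_svr",
    "train_knn",
    "grid_search_rf",
    "predict",
    "beer_lambert_estimate",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainingSet:
    """Feature matrix (p x K) with labels (p x 2): columns (s, v_hb)."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.features, float)
        y = np.asarray(self.labels, float)
        if X.ndim != 2 or y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("features must be (p, K), labels (p, 2)")
        if X.shape[0] != y.shape[0]:
            raise ValueError("feature/label row counts differ")
        if (y < 0).any() or (y > 1).any():
            raise ValueError("labels must be fractions in [0, 1]")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class RFHyperparams:
    """Random forest settings; defaults are the cross-validated choice
    (10 trees, depth 9, minimum 10 samples per leaf)."""

    n_trees: int = 10
    max_depth: int = 9
    min_samples_leaf: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_trees, self.max_depth, self.min_samples_leaf) < 1:
            raise ValueError("hyperparameters must be positive")


@dataclass
class RegressorModel:
    """A fitted inverse model plus the context it is valid for.

    ``band_fingerprint`` ties the model to the band system it was trained
    on; prediction on features from a different system is refused.
    """

    kind: str                      # rf | svr | knn
    estimators: list               # one (rf) or two (svr/knn) fitted models
    band_fingerprint: str
    normalization: str = "l1_log_l2"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("rf", "svr", "knn"):
            raise ValueError(f"unknown model kind {self.kind!r}")


def _check_labels(data: TrainingSet) -> None:
    if np.ptp(data.labels, axis=0).min() == 0:
        warnings.warn("degenerate (constant) labels; model fitted anyway",
                      stacklevel=3)


def train_rf(data: TrainingSet, hp: RFHyperparams = RFHyperparams(),
             band_fingerprint: str = "") -> RegressorModel:
    """Fit one multivariate random forest jointly predicting (s, v_hb)."""
    if data.n_samples < 2 * hp.min_samples_leaf:
        raise ValueError("too few samples for the requested leaf size")
    _check_labels(data)
    rf = RandomForestRegressor(
        n_estimators=hp.n_trees, max_depth=hp.max_depth,
        min_samples_leaf=hp.min_samples_leaf, random_state=hp.seed,
        n_jobs=1)
    rf.fit(data.features, data.labels)
    return RegressorModel("rf", [rf], band_fingerprint,
                          metadata={"hyperparams": vars(hp).copy(),
                                    "n_train": data.n_samples})


def train_svr(data: TrainingSet, C: float = 100.0, gamma: float = 10.0,
              kernel: str = "rbf", band_fingerprint: str = "") -> RegressorModel:
    """Fit RBF-kernel support vector regression, one model per target."""
    _check_labels(data)
    ests = []
    for j in range(2):
        m = SVR(C=C, gamma=gamma, kernel=kernel)
        m.fit(data.features, data.labels[:, j])
        ests.append(m)
    return RegressorModel("svr", ests, band_fingerprint,
                          metadata={"C": C, "gamma": gamma, "kernel": kernel,
                                    "n_train": data.n_samples})


def train_knn(data: TrainingSet, k: int = 5,
              band_fingerprint: str = "") -> RegressorModel:
    """Fit k-nearest-neighbors regression (k=5 by default), one per target."""
    _check_labels(data)
    ests = []
    for j in range(2):
        m = KNeighborsRegressor(n_neighbors=k, algorithm="auto")
        m.fit(data.features, data.labels[:, j])
        ests.append(m)
    return RegressorModel("knn", ests, band_fingerprint,
                          metadata={"k": k, "n_train": data.n_samples})


def grid_search_rf(data: TrainingSet, depth_grid=range(3, 11),
                   leaf_grid=(1, 5, 10, 20, 100), folds: int = 5,
                   seed: int = 0, n_trees: int = 10) -> RFHyperparams:
    """Five-fold CV grid search over forest depth and minimum leaf size.

    The selection criterion is the mean CV median-absolute error on the
    oxygenation target; ties break toward the simpler model (smaller depth,
    then larger leaf).
    """
    if data.n_samples < folds:
        raise ValueError("need at least as many samples as folds")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(data.features))
    best = None
    for depth in depth_grid:
        for leaf in leaf_grid:
            errs = []
            for tr, te in splits:
                y_tr = data.labels[tr]
                if np.ptp(y_tr[:, 0]) == 0:
                    warnings.warn("fold with constant labels skipped",
                                  stacklevel=2)
                    continue
                rf = RandomForestRegressor(
                    n_estimators=n_trees, max_depth=depth,
                    min_samples_leaf=leaf, random_state=seed, n_jobs=1)
                rf.fit(data.features[tr], y_tr)
                pred = rf.predict(data.features[te])
                errs.append(np.median(np.abs(pred[:, 0] - data.labels[te, 0])))
            if not errs:
                continue
            score = float(np.mean(errs))
            # tie-break key prefers smaller depth, then larger leaf
            key = (score, depth, -leaf)
            if best is None or key < best[0]:
                best = (key, depth, leaf)
    if best is None:
        raise ValueError("no valid grid point (all folds degenerate)")
    return RFHyperparams(n_trees=n_trees, max_depth=best[1],
                         min_samples_leaf=best[2], seed=seed)


def predict(model: RegressorModel, features: np.ndarray,
            band_fingerprint: str | None = None) -> np.ndarray:
    """Predict (s, v_hb) per feature row; outputs clamped to [0, 1].

    If ``band_fingerprint`` is given it must match the model's.
    """
    X = np.atleast_2d(np.asarray(features, float))
    if band_fingerprint is not None and model.band_fingerprint and \
            band_fingerprint != model.band_fingerprint:
        raise ValueError("features come from a different band system "
                         "than the model was trained for")
    n_feat = _model_n_features(model)
    if n_feat is not None and X.shape[1] != n_feat:
        raise ValueError(f"model expects {n_feat} features, got {X.shape[1]}")
    if model.kind == "rf":
        out = model.estimators[0].predict(X)
    else:
        out = np.column_stack([est.predict(X) for est in model.estimators])
    return np.clip(out, 0.0, 1.0)


def _model_n_features(model: RegressorModel):
    est = model.estimators[0]
    return getattr(est, "n_features_in_", None)


def beer_lambert_estimate(measurement: BandMeasurement | np.ndarray,
                          bands: BandSystem,
                          table: ChromophoreTable) -> float | np.ndarray:
    """Modified Beer-Lambert oxygenation estimate from one or many spectra.

    Absorbance ``A_k = -log(r_k / sum_j r_j)`` is regressed onto
    ``[eps_HbO2_k, eps_Hb_k, 1]`` (extinctions band-averaged with the same
    transmissions as the measurement); the constant column absorbs
    wavelength-independent scattering/pathlength losses. The estimate
    ``x1/(x1+x2)`` is clamped to [0, 1]; NaN is returned when the recovered
    total hemoglobin ``x1+x2`` is not positive. Invariant to positive
    rescaling of the measurement (the offset absorbs the scale).
    """
    if bands.n_bands < 3:
        raise ValueError("the baseline needs at least 3 bands")
    r = measurement.r_k if isinstance(measurement, BandMeasurement) else measurement
    r = np.atleast_2d(np.asarray(r, float))
    single = (r.shape[0] == 1 and (isinstance(measurement, BandMeasurement)
              or np.asarray(measurement).ndim == 1))
    eps_o, eps_d = table.extinction(bands.grid)
    eps_o_k = bands.transmissions @ eps_o
    eps_d_k = bands.transmissions @ eps_d
    design = np.column_stack([eps_o_k, eps_d_k, np.ones(bands.n_bands)])
    if np.linalg.matrix_rank(design) < 3:
        raise np.linalg.LinAlgError("singular Beer-Lambert design matrix")
    l1 = np.sum(np.abs(r), axis=1, keepdims=True)
    rr = np.maximum(r / np.maximum(l1, 1e-300), 1e-6)
    A = -np.log(rr)
    coef, *_ = np.linalg.lstsq(design, A.T, rcond=None)
    x1, x2 = coef[0], coef[1]
    tot = x1 + x2
    with np.errstate(invalid="ignore", divide="ignore"):
        s_hat = np.where(tot > 0, np.clip(x1 / tot, 0.0, 1.0), np.nan)
    return float(s_hat[0]) if single else s_hat


def save_model(model: RegressorModel, path: str | Path) -> None:
    """Serialize a fitted model with a YAML metadata sidecar."""
    path = Path(path)
    joblib.dump({"format_version": _FORMAT_VERSION,
                 "kind": model.kind,
                 "estimators": model.estimators,
                 "band_fingerprint": model.band_fingerprint,
                 "normalization": model.normalization,
                 "metadata": model.metadata}, path)
    Path(str(path) + ".yaml").write_text(yaml.safe_dump({
        "format_version": _FORMAT_VERSION,
        "kind": model.kind,
        "band_fingerprint": model.band_fingerprint,
        "normalization": model.normalization,
        "metadata": _yaml_safe(model.metadata)}))


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_model(path: str | Path) -> RegressorModel:
    """Load a model saved by :func:`save_model`; refuses version mismatches."""
    try:
        blob = joblib.load(path)
    except Exception as exc:
        raise IOError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(blob, dict) or blob.get("format_version") != _FORMAT_VERSION:
        raise IOError("unsupported or corrupted model file")
    return RegressorModel(blob["kind"], blob["estimators"],
                          blob["band_fingerprint"], blob["normalization"],
                          blob["metadata"])
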