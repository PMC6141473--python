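"""Chemometric SOC regression: PLS, random forest and SVM, plus the
range-constraint and depth-stratified bias-correction rules.

Model settings follow the imaging study this pipeline reproduces: PLS
component count chosen by 5-fold cross-validated MSEP; 200-tree random
forest grown on 33% without-replacement draws (67% out-of-bag) with
sqrt(p) candidate predictors per split; epsilon-SVR with radial kernel
tuned over a (gamma, C, epsilon) grid by 10-fold CV and subsampling
bootstrap.  Tree predictions cannot leave the training SOC range; linear
PLS can, which motivates the explicit constraint operator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import BaggingRegressor
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .cube import SOCMap, SpectralCube
from .preprocessing import UnitIntervalScaler
from .roi import CalibrationSet

DEFAULT_SVM_GRID = {
    "gamma": (1e-3, 1e-2, 1e-1, 1.0),
    "C": (1, 2, 4, 8, 16, 32),
    "epsilon": (0.05, 0.1, 0.2),
}

#: reference SVM operating point; a grid containing only this point
#: reproduces exactly this configuration
REFERENCE_SVM_POINT = {"gamma": (0.01,), "C": (8.0,), "epsilon": (0.1,)}


@dataclass
class ModelConfig:
    algorithm: str = "rf"  # pls | rf | svm
    pls_max_components: int = 20
    pls_cv_folds: int = 5
    pls_force_components: int | None = None
    rf_n_trees: int = 200
    rf_sample_fraction: float = 0.33
    rf_mtry: int | None = None  # default floor(sqrt(n_bands))
    rf_min_split: int = 2
    rf_min_leaf: int = 1
    svm_grid: dict = field(default_factory=lambda: dict(DEFAULT_SVM_GRID))
    svm_cv_folds: int = 10
    svm_bootstrap_reps: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ("pls", "rf", "svm"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not 0 < self.rf_sample_fraction < 1:
            raise ValueError("rf_sample_fraction must lie in (0, 1)")
        if self.pls_cv_folds < 2 or self.svm_cv_folds < 2:
            raise ValueError("cross-validation needs at least 2 folds")
        if any(len(v) == 0 for v in self.svm_grid.values()):
            raise ValueError("svm_grid axes must be non-empty")


@dataclass
class BiasCorrection:
    """Additive depth-stratified offsets removing horizon-dependent bias.

    ``offset = -mean(predicted - measured)`` per horizon, so an
    underestimated topsoil (negative mean residual) yields a positive
    topsoil offset.
    """

    topsoil_offset: float
    subsoil_offset: float
    horizon_boundary_cm: float
    column_correlation: float | None = None

    def rounded(self, decimals: int = 1) -> tuple[float, float]:
        return (
            round(self.topsoil_offset, decimals),
            round(self.subsoil_offset, decimals),
        )


@dataclass
class FittedSOCModel:
    algorithm: str
    estimator: object
    treatment: str
    soc_min: float  # calibration limits, mg g^-1
    soc_max: float
    hyperparameters: dict = field(default_factory=dict)
    scaler: UnitIntervalScaler | None = None
    bias_correction: BiasCorrection | None = None
    n_bands: int = 0
    seed: int = 0

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        """Predict SOC (mg g^-1) for a (n, bands) spectra matrix."""
        spectra = np.asarray(spectra, dtype=float)
        if spectra.ndim != 2 or spectra.shape[1] != self.n_bands:
            raise ValueError(
                f"expected (n, {self.n_bands}) spectra, got {spectra.shape}"
            )
        X = self.scaler.transform(spectra) if self.scaler is not None else spectra
        return np.asarray(self.estimator.predict(X)).ravel()


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_pls(cal: CalibrationSet, config: ModelConfig | None = None) -> FittedSOCModel:
    """PLS regression with CV-selected component count.

    Components 1..max are scored by k-fold cross-validated mean squared
    error of prediction on the training samples; the minimising count wins
    (ties to fewer components) and the final model is refit on all training
    samples.  ``pls_force_components`` overrides the CV choice while the CV
    optimum is still recorded.
    """
    config = config or ModelConfig(algorithm="pls")
    X, y = cal.X("train"), cal.y("train")
    folds = min(config.pls_cv_folds, len(y))
    kf = KFold(n_splits=folds, shuffle=True, random_state=config.seed)
    min_train = min(len(tr) for tr, _ in kf.split(X))
    cap = min(config.pls_max_components, X.shape[1], min_train - 1)
    if cap < config.pls_max_components:
        warnings.warn(
            f"PLS component search capped at {cap} by data rank", stacklevel=2
        )
    msep = np.empty(cap)
    for i, ncomp in enumerate(range(1, cap + 1)):
        sse = 0.0
        for tr, te in kf.split(X):
            m = PLSRegression(n_components=ncomp, scale=False)
            m.fit(X[tr], y[tr])
            pred = m.predict(X[te]).ravel()
            sse += float(np.sum((pred - y[te]) ** 2))
        msep[i] = sse / len(y)
    cv_best = int(np.argmin(msep)) + 1  # first minimum -> fewest components
    ncomp = config.pls_force_components or cv_best
    final = PLSRegression(n_components=ncomp, scale=False)
    final.fit(X, y)
    return FittedSOCModel(
        algorithm="pls",
        estimator=final,
        treatment=cal.treatment,
        soc_min=cal.soc_min,
        soc_max=cal.soc_max,
        hyperparameters={
            "n_components": ncomp,
            "cv_optimal_components": cv_best,
            "cv_msep": msep.tolist(),
        },
        n_bands=X.shape[1],
        seed=config.seed,
    )


def fit_rf(cal: CalibrationSet, config: ModelConfig | None = None) -> FittedSOCModel:
    """Random forest: 200 trees, each on a 33% without-replacement draw.

    The remaining 67% of training samples per tree form the out-of-bag set;
    OOB predictions and OOB RMSE are reported in the hyperparameters.
    """
    config = config or ModelConfig(algorithm="rf")
    X, y = cal.X("train"), cal.y("train")
    mtry = config.rf_mtry or int(np.floor(np.sqrt(X.shape[1])))
    est = BaggingRegressor(
        estimator=DecisionTreeRegressor(
            max_features=mtry,
            min_samples_split=config.rf_min_split,
            min_samples_leaf=config.rf_min_leaf,
        ),
        n_estimators=config.rf_n_trees,
        max_samples=config.rf_sample_fraction,
        bootstrap=False,  # without replacement: a true 33/67 in/out split
        random_state=config.seed,
        n_jobs=1,
    )
    est.fit(X, y)

    # out-of-bag predictions: average trees that never saw the sample
    n = len(y)
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, dtype=int)
    for tree, samp in zip(est.estimators_, est.estimators_samples_):
        out = np.setdiff1d(np.arange(n), samp, assume_unique=False)
        if out.size:
            oob_sum[out] += tree.predict(X[out])
            oob_cnt[out] += 1
    with np.errstate(invalid="ignore"):
        oob_pred = np.where(oob_cnt > 0, oob_sum / np.maximum(oob_cnt, 1), np.nan)
    ok = oob_cnt > 0
    oob_rmse = float(np.sqrt(np.mean((oob_pred[ok] - y[ok]) ** 2)))
    return FittedSOCModel(
        algorithm="rf",
        estimator=est,
        treatment=cal.treatment,
        soc_min=cal.soc_min,
        soc_max=cal.soc_max,
        hyperparameters={
            "n_trees": config.rf_n_trees,
            "sample_fraction": config.rf_sample_fraction,
            "mtry": mtry,
            "oob_rmse": oob_rmse,
            "train_min": float(y.min()),
            "train_max": float(y.max()),
        },
        n_bands=X.shape[1],
        seed=config.seed,
    )


def fit_svm(cal: CalibrationSet, config: ModelConfig | None = None) -> FittedSOCModel:
    """Radial-kernel epsilon-SVR with grid search over (gamma, C, epsilon).

    Predictors are scaled per band to [0, 1] on the training set (the
    scaler is stored and re-applied at prediction time) and then
    standardised to zero mean / unit variance inside the estimator, the
    convention of the R SVM implementations this module mirrors; gamma
    (and the reference operating point gamma = 0.01, C = 8, epsilon = 0.1)
    is therefore interpreted on the standardised scale, where the radial
    kernel is local enough that spectra far outside the calibration domain
    revert toward the intercept instead of extrapolating.  The response
    stays on its original mg g^-1 scale.  Every grid point is scored by
    k-fold CV RMSE and by a 1/3-train / 2/3-test subsampling bootstrap
    RMSE; the CV score decides, ties going to the first point in grid
    order.
    """
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    config = config or ModelConfig(algorithm="svm")
    X_raw, y = cal.X("train"), cal.y("train")
    scaler = UnitIntervalScaler().fit(X_raw)
    X = scaler.transform(X_raw)
    grid = [
        {"gamma": g, "C": c, "epsilon": e}
        for g in config.svm_grid["gamma"]
        for c in config.svm_grid["C"]
        for e in config.svm_grid["epsilon"]
    ]
    if len(grid) == 1:
        warnings.warn("SVM grid contains a single point", stacklevel=2)
    folds = min(config.svm_cv_folds, len(y))
    kf = KFold(n_splits=folds, shuffle=True, random_state=config.seed)
    splits = list(kf.split(X))
    rng = np.random.default_rng(config.seed)
    n = len(y)
    boot = []
    for _ in range(config.svm_bootstrap_reps):
        tr = rng.choice(n, size=max(n // 3, 2), replace=False)
        te = np.setdiff1d(np.arange(n), tr)
        boot.append((tr, te))

    def _make(params):
        return make_pipeline(
            StandardScaler(), SVR(kernel="rbf", **params)
        )

    def _rmse_over(params, pairs):
        sse, cnt = 0.0, 0
        for tr, te in pairs:
            m = _make(params)
            m.fit(X[tr], y[tr])
            pred = m.predict(X[te])
            sse += float(np.sum((pred - y[te]) ** 2))
            cnt += len(te)
        return np.sqrt(sse / cnt)

    cv_scores = np.array([_rmse_over(p, splits) for p in grid])
    boot_scores = np.array([_rmse_over(p, boot) for p in grid]) if boot else None
    best = int(np.argmin(cv_scores))
    params = grid[best]
    final = _make(params)
    final.fit(X, y)
    return FittedSOCModel(
        algorithm="svm",
        estimator=final,
        treatment=cal.treatment,
        soc_min=cal.soc_min,
        soc_max=cal.soc_max,
        hyperparameters={
            **params,
            "n_support_vectors": int(final[-1].support_.size),
            "cv_rmse": float(cv_scores[best]),
            "bootstrap_rmse": (
                float(boot_scores[best]) if boot_scores is not None else None
            ),
        },
        scaler=scaler,
        n_bands=X_raw.shape[1],
        seed=config.seed,
    )


FITTERS = {"pls": fit_pls, "rf": fit_rf, "svm": fit_svm}


def fit_model(cal: CalibrationSet, config: ModelConfig) -> FittedSOCModel:
    return FITTERS[config.algorithm](cal, config)


# ---------------------------------------------------------------------------
# Prediction and adjustment
# ---------------------------------------------------------------------------


def predict_map(
    model: FittedSOCModel, cube: SpectralCube, chunk: int = 65536
) -> SOCMap:
    """Predict SOC for every unmasked pixel of a cube.

    The cube's spectral treatment must match the model's; masked pixels
    carry NaN.  Prediction runs in chunks to bound memory on full-resolution
    cubes.
    """
    if cube.treatment != model.treatment:
        raise ValueError(
            f"cube treatment {cube.treatment!r} does not match model "
            f"treatment {model.treatment!r}"
        )
    if cube.n_bands != model.n_bands:
        raise ValueError("band count mismatch between cube and model")
    values = np.full(cube.shape[:2], np.nan)
    X = cube.unmasked_spectra()
    preds = np.empty(X.shape[0])
    for i in range(0, X.shape[0], chunk):
        preds[i : i + chunk] = model.predict(X[i : i + chunk])
    values[cube.mask] = preds
    return SOCMap(
        values=values,
        mask=cube.mask.copy(),
        pixel_size_um=cube.pixel_size_um,
        depth_origin_cm=cube.depth_origin_cm,
        source=f"{model.algorithm}:{model.treatment}",
    )


def constrain_predictions(
    soc_map: SOCMap, soc_min: float, soc_max: float
) -> SOCMap:
    """Clip implausible predictions to the calibration limits.

    Values below zero are replaced by the minimum calibrated SOC and values
    above the maximum calibrated SOC by that maximum; values in
    [0, soc_max] - including those between 0 and soc_min - are untouched.
    Idempotent; original values preserved in ``raw_values``.
    """
    if not (np.isfinite(soc_min) and np.isfinite(soc_max)) or soc_min >= soc_max:
        raise ValueError("calibration limits must be finite with min < max")
    raw = soc_map.raw_values if soc_map.raw_values is not None else soc_map.values
    v = soc_map.values.copy()
    with np.errstate(invalid="ignore"):
        v[v < 0] = soc_min
        v[v > soc_max] = soc_max
    return soc_map.replace(
        values=v, raw_values=raw, source=soc_map.source + "+constrained"
    )


def estimate_bias_correction(
    predicted: np.ndarray,
    measured: np.ndarray,
    depth_cm: np.ndarray,
    horizon_boundary_cm: float,
    columns: np.ndarray | None = None,
    min_per_horizon: int = 3,
) -> BiasCorrection:
    """Estimate additive per-horizon offsets from evaluation residuals.

    Residuals are ``predicted - measured``; the offset for a horizon is the
    negated mean residual, so applying the offsets removes the mean bias in
    each horizon.  When ``columns`` is given, the correlation of residuals
    with horizontal position is reported as a check that horizontal
    location carries no bias.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    depth_cm = np.asarray(depth_cm, dtype=float)
    resid = predicted - measured
    top = depth_cm < horizon_boundary_cm
    for name, sel in (("topsoil", top), ("subsoil", ~top)):
        if sel.sum() == 0:
            raise ValueError(f"no {name} samples: cannot estimate its offset")
        if sel.sum() < min_per_horizon:
            warnings.warn(
                f"only {int(sel.sum())} {name} samples for bias estimation",
                stacklevel=2,
            )
    col_corr = None
    if columns is not None:
        columns = np.asarray(columns, dtype=float)
        if np.std(columns) > 0 and np.std(resid) > 0:
            col_corr = float(np.corrcoef(resid, columns)[0, 1])
    return BiasCorrection(
        topsoil_offset=float(-resid[top].mean()),
        subsoil_offset=float(-resid[~top].mean()),
        horizon_boundary_cm=float(horizon_boundary_cm),
        column_correlation=col_corr,
    )


def apply_bias_correction(soc_map: SOCMap, bc: BiasCorrection) -> SOCMap:
    """Shift rows above/below the horizon boundary by their offsets.

    A pure additive shift: no clipping afterwards, so corrected maps may
    extend slightly past the calibration limits.
    """
    depth = soc_map.depth_axis_cm()
    shift = np.where(
        depth < bc.horizon_boundary_cm, bc.topsoil_offset, bc.subsoil_offset
    )
    raw = soc_map.raw_values if soc_map.raw_values is not None else soc_map.values
    return soc_map.replace(
        values=soc_map.values + shift[:, None],
        raw_values=raw,
        source=soc_map.source + "+biascorrected",
    )


def validate_model(model: FittedSOCModel, cal: CalibrationSet):
    """Predicted vs measured on the validation samples; returns FitMetrics."""
    from .evaluation import compute_metrics

    Xv, yv = cal.X("validate"), cal.y("validate")
    return compute_metrics(yv, model.predict(Xv))
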