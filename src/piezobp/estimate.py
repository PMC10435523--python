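"""BP regression: feature assembly, training protocol, prediction, tuning.

Two independent regressors (one for SBP, one for DBP) are trained on
feature vectors combining per-beat pulse morphology (systolic/diastolic
time spans and heights, augmentation index, area ratio, fiducial times),
heart rate, subject physiology (age, sex, BMI) and local PWV.

The training protocol: shuffle, hold out 1/5 of the rows as a test set
(4:1 split), and run fivefold cross-validation on the training portion.
The default algorithm is gradient-boosted trees (XGBoost) with the
Bayesian-optimized hyperparameters max_depth=13, n_estimators=437,
gamma=3.265, reg_alpha=0.006, learning_rate=0.039; KNN, SVR and
AdaBoost are available for comparison.  Hyperparameter tuning is
sequential model-based optimization (Gaussian-process surrogate,
expected-improvement acquisition) minimizing cross-validated RMSE.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern
from sklearn.model_selection import KFold, train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .errors import ConfigurationError, DataError

__all__ = [
    "FEATURE_COLUMNS",
    "ModelConfig",
    "TrainedModel",
    "BPPair",
    "build_feature_matrix",
    "train",
    "predict",
    "tune_hyperparameters",
    "compare_algorithms",
]

#: Canonical feature-column manifest (order is part of the model contract).
FEATURE_COLUMNS = (
    "st",
    "dt",
    "systolic_height",
    "diastolic_height",
    "augmentation_index",
    "area_ratio",
    "t_systolic_peak",
    "t_dicrotic_notch",
    "t_diastolic_peak",
    "heart_rate",
    "age",
    "sex",  # 0 = male, 1 = female
    "bmi",
    "pwv",
)

ALGORITHMS = ("xgboost", "knn", "svr", "adaboost")

BP_LIMITS = (30.0, 260.0)


@dataclass(frozen=True)
class ModelConfig:
    """Regressor choice plus training-protocol settings."""

    algorithm: str = "xgboost"
    max_depth: int = 13
    n_estimators: int = 437
    gamma: float = 3.265
    reg_alpha: float = 0.006
    learning_rate: float = 0.039
    test_fraction: float = 0.2  # 4:1 train:test split
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}; pick from {ALGORITHMS}")
        if self.max_depth < 1 or self.n_estimators < 1:
            raise ConfigurationError("depth and tree count must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ConfigurationError("learning rate must be in (0, 1]")
        if not 0 < self.test_fraction < 1:
            raise ConfigurationError("test fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ConfigurationError("need at least 2 CV folds")


@dataclass(frozen=True)
class BPPair:
    """One systolic/diastolic estimate (mmHg)."""

    sbp: float
    dbp: float
    clamped: bool = False
    extrapolated: bool = False


@dataclass
class TrainedModel:
    """Fitted SBP/DBP regressors with their manifest and CV report."""

    algorithm: str
    sbp_model: object
    dbp_model: object
    manifest: tuple[str, ...]
    config: ModelConfig
    fingerprint: str
    cv_report: pd.DataFrame  # one row per fold per target + held-out rows
    label_range: dict[str, tuple[float, float]]  # training label span per target


def _error_summary(pred: np.ndarray, ref: np.ndarray) -> dict[str, float]:
    err = pred - ref
    return {
        "me": float(np.mean(err)),
        "sd": float(np.std(err, ddof=1)) if err.size > 1 else 0.0,
        "mae": float(np.mean(np.abs(err))),
        "rmse": float(np.sqrt(np.mean(err**2))),
    }


def _data_fingerprint(X: pd.DataFrame, y_sbp: np.ndarray, y_dbp: np.ndarray) -> str:
    """Order-independent hash of the training rows."""
    block = np.column_stack([X.to_numpy(dtype=float), y_sbp, y_dbp])
    block = block[np.lexsort(block.T[::-1])]
    return hashlib.sha256(np.ascontiguousarray(np.round(block, 9)).tobytes()).hexdigest()[:16]


def build_feature_matrix(
    rows: Sequence[dict] | pd.DataFrame,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Assemble the regression design matrix and SBP/DBP label vectors.

    Each row must carry every manifest feature plus reference ``sbp`` and
    ``dbp`` labels.  Rows with missing values are rejected (their indices
    reported) rather than imputed — degenerate beats are dropped upstream.
    """
    df = pd.DataFrame(rows).copy()
    if len(df) < 10:
        raise DataError(f"need at least 10 rows, got {len(df)}")
    if df["sex"].dtype == object:
        df["sex"] = df["sex"].map({"male": 0, "female": 1})
    missing_cols = [c for c in (*FEATURE_COLUMNS, "sbp", "dbp") if c not in df.columns]
    if missing_cols:
        raise DataError(f"missing columns: {missing_cols}")
    subset = df[list(FEATURE_COLUMNS) + ["sbp", "dbp"]]
    bad = subset.index[subset.isna().any(axis=1)].tolist()
    if bad:
        raise DataError(f"rows with missing values: {bad}")
    X = subset[list(FEATURE_COLUMNS)].astype(float)
    return X, subset["sbp"].to_numpy(float), subset["dbp"].to_numpy(float)


def _make_regressor(cfg: ModelConfig, seed: int):
    if cfg.algorithm == "xgboost":
        return XGBRegressor(
            max_depth=cfg.max_depth,
            n_estimators=cfg.n_estimators,
            gamma=cfg.gamma,
            reg_alpha=cfg.reg_alpha,
            learning_rate=cfg.learning_rate,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    if cfg.algorithm == "knn":
        return KNeighborsRegressor(n_neighbors=5)
    if cfg.algorithm == "svr":
        return SVR(C=10.0, epsilon=0.5)
    if cfg.algorithm == "adaboost":
        return AdaBoostRegressor(
            estimator=DecisionTreeRegressor(max_depth=6, random_state=seed),
            n_estimators=100,
            learning_rate=0.5,
            random_state=seed,
        )
    raise ConfigurationError(f"unknown algorithm {cfg.algorithm!r}")


def train(
    X: pd.DataFrame,
    y_sbp: np.ndarray,
    y_dbp: np.ndarray,
    cfg: ModelConfig | None = None,
) -> TrainedModel:
    """Train SBP and DBP regressors with the shuffled-split + CV protocol.

    The rows are shuffled and split 4:1 into training and held-out test
    portions; fivefold cross-validation on the training portion yields
    per-fold error summaries, and the final models are refit on the full
    training portion.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or ModelConfig()
    n = len(X)
    if n < cfg.n_folds:
        raise ConfigurationError(f"{n} rows is fewer than {cfg.n_folds} folds")
    idx_train, idx_test = train_test_split(
        np.arange(n), test_size=cfg.test_fraction, shuffle=True, random_state=cfg.seed
    )
    Xtr, Xte = X.iloc[idx_train], X.iloc[idx_test]
    report_rows = []
    models = {}
    for target, y in (("sbp", y_sbp), ("dbp", y_dbp)):
        ytr, yte = y[idx_train], y[idx_test]
        kf = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
        for fold, (ia, ib) in enumerate(kf.split(Xtr)):
            m = _make_regressor(cfg, cfg.seed)
            m.fit(Xtr.iloc[ia], ytr[ia])
            report_rows.append(
                {"target": target, "split": f"fold{fold}",
                 **_error_summary(np.asarray(m.predict(Xtr.iloc[ib]), float), ytr[ib])}
            )
        final = _make_regressor(cfg, cfg.seed)
        final.fit(Xtr, ytr)
        models[target] = final
        report_rows.append(
            {"target": target, "split": "holdout",
             **_error_summary(np.asarray(final.predict(Xte), float), yte)}
        )
    return TrainedModel(
        algorithm=cfg.algorithm,
        sbp_model=models["sbp"],
        dbp_model=models["dbp"],
        manifest=FEATURE_COLUMNS,
        config=cfg,
        fingerprint=_data_fingerprint(X, y_sbp, y_dbp),
        cv_report=pd.DataFrame(report_rows),
        label_range={
            "sbp": (float(y_sbp[idx_train].min()), float(y_sbp[idx_train].max())),
            "dbp": (float(y_dbp[idx_train].min()), float(y_dbp[idx_train].max())),
        },
    )


def predict(model: TrainedModel, features: pd.DataFrame, extrapolation_margin: float = 40.0) -> list[BPPair]:
    """Predict per-window SBP/DBP pairs.

    Values outside the physiologic range are clamped (and flagged, never
    silently); predictions farther than ``extrapolation_margin`` mmHg
    outside the training label span are flagged as extrapolated.
    """
    if list(features.columns) != list(model.manifest):
        raise DataError(
            f"feature manifest mismatch: expected {list(model.manifest)}, got {list(features.columns)}"
        )
    if len(features) == 0:
        return []
    sbp = np.asarray(model.sbp_model.predict(features), dtype=float)
    dbp = np.asarray(model.dbp_model.predict(features), dtype=float)
    out = []
    lo, hi = BP_LIMITS
    for s, d in zip(sbp, dbp):
        clamped = not (lo <= s <= hi) or not (lo <= d <= hi)
        extrap = False
        for val, target in ((s, "sbp"), (d, "dbp")):
            tlo, thi = model.label_range[target]
            if val < tlo - extrapolation_margin or val > thi + extrapolation_margin:
                extrap = True
        out.append(BPPair(float(np.clip(s, lo, hi)), float(np.clip(d, lo, hi)), clamped, extrap))
    return out


# ---------------------------------------------------------------------------
# Sequential model-based hyperparameter optimization


#: (low, high, is_integer, log-scale) per tunable dimension.
DEFAULT_SPACE = {
    "max_depth": (2, 16, True, False),
    "n_estimators": (50, 600, True, False),
    "gamma": (0.0, 5.0, False, False),
    "reg_alpha": (1e-4, 1.0, False, True),
    "learning_rate": (0.005, 0.3, False, True),
}


def _decode(u: np.ndarray, space: dict) -> dict:
    params = {}
    for ui, (name, (lo, hi, is_int, log)) in zip(u, space.items()):
        if log:
            val = float(np.exp(np.log(lo) + ui * (np.log(hi) - np.log(lo))))
        else:
            val = float(lo + ui * (hi - lo))
        params[name] = int(round(val)) if is_int else val
    return params


def _cv_rmse(X, y, cfg: ModelConfig) -> float:
    kf = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    errs = []
    for ia, ib in kf.split(X):
        m = _make_regressor(cfg, cfg.seed)
        m.fit(X.iloc[ia], y[ia])
        errs.append(np.sqrt(np.mean((np.asarray(m.predict(X.iloc[ib]), float) - y[ib]) ** 2)))
    return float(np.mean(errs))


def tune_hyperparameters(
    X: pd.DataFrame,
    y: np.ndarray,
    space: dict | None = None,
    budget: int = 25,
    base: ModelConfig | None = None,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Bayesian optimization of the boosted-tree hyperparameters.

    A Gaussian-process surrogate (Matern 5/2) is fit to the evaluated
    (configuration, CV-RMSE) pairs in the unit hypercube; each iteration
    evaluates the candidate maximizing expected improvement over a random
    pool.  The incumbent default configuration is always included, so the
    tuned result is never worse than the default on the CV objective.
    Returns the best configuration and the full search trace.
    """
    space = space if space is not None else dict(DEFAULT_SPACE)
    if not space:
        raise ConfigurationError("empty search space")
    if budget < 10:
        raise ConfigurationError("budget must be >= 10 evaluations")
    base = base or ModelConfig()
    rng = np.random.default_rng(base.seed)
    dims = len(space)

    def encode_default() -> np.ndarray:
        u = np.empty(dims)
        for k, (name, (lo, hi, is_int, log)) in enumerate(space.items()):
            val = getattr(base, name)
            val = float(np.clip(val, lo, hi))
            if log:
                u[k] = (np.log(val) - np.log(lo)) / (np.log(hi) - np.log(lo))
            else:
                u[k] = (val - lo) / (hi - lo) if hi > lo else 0.5
        return u

    evaluated_u: list[np.ndarray] = [encode_default()]
    n_init = max(2, min(budget // 3, 8))
    evaluated_u += [rng.random(dims) for _ in range(min(n_init, budget - 1))]
    trace_rows = []
    scores: list[float] = []

    def run(u: np.ndarray) -> float:
        cfg = replace(base, **_decode(u, space))
        score = _cv_rmse(X, y, cfg)
        trace_rows.append({**_decode(u, space), "cv_rmse": score})
        scores.append(score)
        return score

    for u in evaluated_u:
        run(u)

    kernel = ConstantKernel(1.0) * Matern(length_scale=np.full(dims, 0.3), nu=2.5)
    while len(scores) < budget:
        U = np.vstack(evaluated_u)
        z = np.asarray(scores)
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True, alpha=1e-6,
                                      random_state=base.seed)
        gp.fit(U, z)
        pool = rng.random((256, dims))
        mu, sd = gp.predict(pool, return_std=True)
        best = z.min()
        with np.errstate(divide="ignore", invalid="ignore"):
            gamma_ = (best - mu) / np.where(sd > 0, sd, np.inf)
        from scipy.stats import norm

        ei = sd * (gamma_ * norm.cdf(gamma_) + norm.pdf(gamma_))
        u_next = pool[int(np.argmax(ei))]
        evaluated_u.append(u_next)
        run(u_next)

    trace = pd.DataFrame(trace_rows)
    best_row = trace.iloc[int(np.argmin(trace["cv_rmse"]))]
    best_cfg = replace(
        base, **{name: (int(best_row[name]) if space[name][2] else float(best_row[name]))
                 for name in space}
    )
    return best_cfg, trace


def compare_algorithms(
    X: pd.DataFrame, y_sbp: np.ndarray, y_dbp: np.ndarray, seed: int = 0
) -> pd.DataFrame:
    """Held-out error comparison across the candidate algorithms.

    A non-binding report: boosted trees are expected to match or beat
    KNN/SVR/AdaBoost on pulse-feature benchmarks, but no ordering is
    asserted here.
    """
    rows = []
    for algo in ALGORITHMS:
        model = train(X, y_sbp, y_dbp, ModelConfig(algorithm=algo, seed=seed))
        holdout = model.cv_report.query("split == 'holdout'")
        for _, r in holdout.iterrows():
            rows.append({"algorithm": algo, "target": r["target"],
                         "mae": r["mae"], "rmse": r["rmse"], "sd": r["sd"], "me": r["me"]})
    return pd.DataFrame(rows)
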