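"""Classical baseline protocol: repeated k-fold CV, ensemble voting, metrics.

The learning algorithms themselves (SVR, random forest, gradient
boosting, XGBoost) come from scikit-learn / xgboost; this module owns the
evaluation protocol — per-iteration reshuffled k-fold splits with every
sample predicted exactly once, z-score scaling fitted inside each
training fold, mean +/- std statistics over iterations, and the weighted
ensemble vote — plus the feature-vs-target correlation analysis used to
compare quantum-encoded representations with the original descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Metrics",
    "MetricsReport",
    "metrics",
    "make_learner",
    "cross_validate",
    "voting_predict",
    "feature_target_correlation",
    "LEARNER_NAMES",
]

LEARNER_NAMES = ("svr", "rfr", "gbdt", "xgb", "vote")

#: SVR:GBDT weights of the ensemble vote.
VOTE_WEIGHTS = (1.5, 1.0)


@dataclass(frozen=True)
class Metrics:
    """R^2, MAE and RMSE for one prediction vector (kcal/mol scale)."""

    r2: float
    mae: float
    rmse: float


def metrics(y, y_pred) -> Metrics:
    """Standard regression metrics; R^2 = 1 - SS_res / SS_tot.

    A constant ``y`` has no total sum of squares, so R^2 is reported as
    ``nan`` (an explicit undefined marker, never silently 0) while MAE
    and RMSE are still computed.
    """
    from sklearn.metrics import (
        mean_absolute_error,
        r2_score,
        root_mean_squared_error,
    )

    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape:
        raise ValueError("y and y_pred must have the same length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    r2 = float(r2_score(y, y_pred)) if np.ptp(y) > 0 else float("nan")
    return Metrics(
        r2=r2,
        mae=float(mean_absolute_error(y, y_pred)),
        rmse=float(root_mean_squared_error(y, y_pred)),
    )


@dataclass
class MetricsReport:
    """Per-repetition metrics with mean +/- std across repetitions."""

    per_iteration: list[Metrics] = field(default_factory=list)

    def _agg(self, attr: str) -> tuple[float, float]:
        vals = np.array([getattr(m, attr) for m in self.per_iteration])
        return float(vals.mean()), float(vals.std())

    @property
    def r2(self):
        return self._agg("r2")

    @property
    def mae(self):
        return self._agg("mae")

    @property
    def rmse(self):
        return self._agg("rmse")

    def summary(self) -> str:
        rows = [("R2", self.r2), ("MAE", self.mae), ("RMSE", self.rmse)]
        lines = [f"{name:>5}: {m:.3f} +/- {s:.3f}" for name, (m, s) in rows]
        return "\n".join(lines)


def make_learner(name: str, seed: int = 0):
    """Baseline estimator by short name, wrapped in a fold-local z-scorer.

    Scaling lives inside the returned pipeline so that fitting on a
    training fold never sees held-out statistics.
    """
    from sklearn.ensemble import (
        GradientBoostingRegressor,
        RandomForestRegressor,
        VotingRegressor,
    )
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVR
    from xgboost import XGBRegressor

    if name == "svr":
        return make_pipeline(StandardScaler(), SVR())
    if name == "rfr":
        return make_pipeline(
            StandardScaler(), RandomForestRegressor(random_state=seed, n_jobs=1)
        )
    if name == "gbdt":
        return make_pipeline(
            StandardScaler(), GradientBoostingRegressor(random_state=seed)
        )
    if name == "xgb":
        return make_pipeline(
            StandardScaler(),
            XGBRegressor(random_state=seed, n_jobs=1, verbosity=0),
        )
    if name == "vote":
        return make_pipeline(
            StandardScaler(),
            VotingRegressor(
                [("svr", SVR()), ("gbdt", GradientBoostingRegressor(random_state=seed))],
                weights=list(VOTE_WEIGHTS),
            ),
        )
    raise ValueError(f"unknown learner {name!r}; choose from {LEARNER_NAMES}")


def cross_validate(learner_spec, X, y, k: int = 5, iterations: int = 20,
                   seed: int = 0) -> MetricsReport:
    """Repeated k-fold CV with out-of-fold prediction.

    Per iteration ``i`` the data are reshuffled with seed ``seed + i``
    and split into ``k`` folds; each fold is predicted by a model trained
    on the other ``k - 1``, so every sample is predicted exactly once per
    iteration.  Metrics are computed per iteration on the assembled
    out-of-fold vector; the report aggregates mean +/- std.

    ``learner_spec`` is a registry name (see :data:`LEARNER_NAMES`) or a
    callable ``seed -> estimator`` with fit/predict.
    """
    from sklearn.model_selection import KFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < k:
        raise ValueError("need at least k samples")
    factory = (
        learner_spec if callable(learner_spec)
        else (lambda s: make_learner(learner_spec, seed=s))
    )
    report = MetricsReport()
    for it in range(iterations):
        it_seed = seed + it
        kf = KFold(n_splits=k, shuffle=True, random_state=it_seed)
        oof = np.empty_like(y)
        for fold_id, (tr, te) in enumerate(kf.split(X)):
            try:
                model = factory(it_seed)
                model.fit(X[tr], y[tr])
                oof[te] = np.asarray(model.predict(X[te]), dtype=float).ravel()
            except Exception as exc:
                raise RuntimeError(
                    f"learner failed on iteration {it}, fold {fold_id}: {exc}"
                ) from exc
        report.per_iteration.append(metrics(y, oof))
    return report


def voting_predict(predictions, weights=VOTE_WEIGHTS) -> np.ndarray:
    """Elementwise weighted mean of prediction vectors."""
    preds = [np.asarray(p, dtype=float) for p in predictions]
    w = np.asarray(weights, dtype=float)
    if len(preds) != w.size:
        raise ValueError("one weight per prediction vector")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    lengths = {p.shape for p in preds}
    if len(lengths) != 1:
        raise ValueError("prediction vectors must have equal length")
    return np.average(np.stack(preds), axis=0, weights=w)


def feature_target_correlation(Z, y, method: str = "pearson") -> np.ndarray:
    """Per-column correlation with the target, aligned to column order.

    Constant columns get ``nan`` (correlation undefined), never a silent
    zero.  ``method`` is ``"pearson"`` (default) or ``"spearman"``.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != y.size:
        raise ValueError("Z must be (n_samples, n_features) matching y")
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if method == "spearman":
        from scipy.stats import rankdata

        Z = np.apply_along_axis(rankdata, 0, Z)
        y = rankdata(y)
    out = np.full(Z.shape[1], np.nan)
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    for j in range(Z.shape[1]):
        col = Z[:, j]
        cc = col - col.mean()
        ss_c = float(cc @ cc)
        if ss_c > 0 and ss_y > 0:
            out[j] = float(cc @ yc) / np.sqrt(ss_c * ss_y)
    return out
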