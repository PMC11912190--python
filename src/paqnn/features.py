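"""Descriptor-matrix filtering, importance-based selection, and scalers.

The descriptor table is a compounds-by-features numeric matrix with a
provenance kind per column (2D/3D physicochemical, quantum-chemical,
fingerprint bit).  Filtering removes unusable columns (missing values,
near-zero variance, pairwise |Pearson r| above a cutoff); selection ranks
the survivors by gradient-boosting gain importance and keeps the top-k or
runs a progressive-removal loop.  Three scalers cover the models' needs:
z-score for the classical baselines, min-max to [0, pi] for rotation-angle
encoding, and min-max to [0, 1] for the regression target.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorTable",
    "ScalerSpec",
    "filter_descriptors",
    "select_by_importance",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
    "split_evenly",
]

FEATURE_KINDS = (
    "2D-physicochemical",
    "3D-physicochemical",
    "quantum-chemical",
    "fingerprint-bit",
)


@dataclass
class DescriptorTable:
    """Named numeric feature matrix with per-column provenance.

    ``kinds`` maps feature name -> one of :data:`FEATURE_KINDS`; columns
    without an entry default to ``"2D-physicochemical"``.
    """

    frame: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            dupes = self.frame.columns[self.frame.columns.duplicated()].tolist()
            raise ValueError(f"duplicated feature names: {dupes}")
        for name, kind in self.kinds.items():
            if kind not in FEATURE_KINDS:
                raise ValueError(f"unknown feature kind {kind!r} for {name!r}")
            if kind == "fingerprint-bit" and name in self.frame:
                vals = self.frame[name].dropna().unique()
                if not np.isin(vals, (0, 1)).all():
                    raise ValueError(f"fingerprint-bit column {name!r} not binary")

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def kind_of(self, name: str) -> str:
        return self.kinds.get(name, "2D-physicochemical")

    def subset(self, names, dropped=None) -> "DescriptorTable":
        return DescriptorTable(
            frame=self.frame[list(names)].copy(),
            kinds={n: k for n, k in self.kinds.items() if n in set(names)},
            dropped=list(dropped or []),
        )

    @classmethod
    def from_csv(cls, path, kinds=None) -> "DescriptorTable":
        return cls(frame=pd.read_csv(path), kinds=dict(kinds or {}))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def filter_descriptors(table: DescriptorTable, var_tol: float = 1e-8,
                       corr_max: float = 0.9) -> DescriptorTable:
    """Drop unusable descriptor columns; record what was dropped and why.

    Order of removal: (1) any missing value; (2) variance <= ``var_tol``
    (near-zero variance); (3) of each pair with |Pearson r| >= ``corr_max``,
    walking pairs in fixed column order, the later column.  Raises if
    nothing survives.
    """
    if table.frame.shape[1] == 0:
        raise ValueError("descriptor table has no columns")
    df = table.frame
    dropped: list[tuple[str, str]] = []

    keep = []
    for name in df.columns:
        if df[name].isna().any():
            dropped.append((name, "missing values"))
        else:
            keep.append(name)

    survivors = []
    for name in keep:
        v = df[name].to_numpy(dtype=float)
        # var of a length-1 column is undefined under ddof=1; treat as zero
        var = float(np.var(v, ddof=1)) if len(v) > 1 else 0.0
        if var <= var_tol:
            dropped.append((name, "near-zero variance"))
        else:
            survivors.append(name)

    if len(survivors) > 1:
        corr = df[survivors].corr().to_numpy()
        alive = [True] * len(survivors)
        for i in range(len(survivors)):
            if not alive[i]:
                continue
            for j in range(i + 1, len(survivors)):
                if alive[j] and abs(corr[i, j]) >= corr_max:
                    alive[j] = False
                    dropped.append(
                        (survivors[j], f"|r| >= {corr_max} with {survivors[i]}")
                    )
        survivors = [n for n, a in zip(survivors, alive) if a]

    if not survivors:
        raise ValueError("all descriptor columns were dropped")
    return table.subset(survivors, dropped=dropped)


def _default_eval_protocol(seed: int):
    """3-fold CV mean absolute error with a small gradient-boosted model."""
    from sklearn.model_selection import KFold
    from xgboost import XGBRegressor

    def protocol(X: pd.DataFrame, y: np.ndarray) -> float:
        y = np.asarray(y, dtype=float)
        kf = KFold(n_splits=3, shuffle=True, random_state=seed)
        errs = []
        for tr, te in kf.split(X):
            model = XGBRegressor(
                n_estimators=50, max_depth=3, random_state=seed, n_jobs=1,
                verbosity=0,
            )
            model.fit(X.iloc[tr], y[tr])
            errs.append(np.mean(np.abs(model.predict(X.iloc[te]) - y[te])))
        return float(np.mean(errs))

    return protocol


def select_by_importance(table: DescriptorTable, y, k: int | None = None,
                         eval_protocol=None, decline_frac: float = 0.05,
                         seed: int = 0) -> DescriptorTable:
    """Keep the most informative descriptors by gain importance.

    An XGBoost regressor is fitted on the full table and columns are
    ranked by its gain-based feature importance.  With ``k`` given, the
    top-k columns are returned.  Without ``k``, features are removed one
    at a time starting from the least important, re-evaluating with
    ``eval_protocol`` (a callable ``(X_frame, y) -> MAE``), and the loop
    stops before the first removal that worsens the best MAE seen by more
    than ``decline_frac`` relatively.
    """
    from xgboost import XGBRegressor

    y = np.asarray(y, dtype=float)
    n_feat = table.frame.shape[1]
    if k is not None and not (1 <= k <= n_feat):
        raise ValueError(f"k must be in [1, {n_feat}], got {k}")

    model = XGBRegressor(
        n_estimators=200, max_depth=4, random_state=seed, n_jobs=1, verbosity=0,
        importance_type="gain",
    )
    model.fit(table.frame, y)
    importances = np.asarray(model.feature_importances_, dtype=float)
    order = np.argsort(-importances, kind="stable")  # descending, stable ties
    ranked = [table.feature_names[i] for i in order]

    if k is not None:
        return table.subset(ranked[:k])

    protocol = eval_protocol or _default_eval_protocol(seed)
    current = list(ranked)
    best = protocol(table.frame[current], y)
    while len(current) > 1:
        trial = current[:-1]  # drop least important
        mae = protocol(table.frame[trial], y)
        if mae > best * (1.0 + decline_frac):
            break
        best = min(best, mae)
        current = trial
    return table.subset(current)


# ---------------------------------------------------------------------------
# scalers
# ---------------------------------------------------------------------------

SCALER_KINDS = ("zscore", "minmax_to_0_pi", "minmax_to_0_1")


@dataclass
class ScalerSpec:
    """Per-column statistics learned on a fit set.

    z-score stores mean/std; the min-max kinds store min/max and map the
    fit range onto [0, pi] or [0, 1], clamping out-of-range inputs to the
    boundary at transform time.
    """

    kind: str
    loc: np.ndarray  # mean (zscore) or min (minmax)
    scale: np.ndarray  # std (zscore) or max - min (minmax)

    @property
    def target_span(self) -> float:
        return {"zscore": 1.0, "minmax_to_0_pi": math.pi, "minmax_to_0_1": 1.0}[
            self.kind
        ]

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "loc": self.loc.tolist(), "scale": self.scale.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "ScalerSpec":
        obj = json.loads(text)
        return cls(
            kind=obj["kind"],
            loc=np.asarray(obj["loc"], dtype=float),
            scale=np.asarray(obj["scale"], dtype=float),
        )


def fit_scaler(kind: str, fit_matrix) -> ScalerSpec:
    """Learn per-column statistics; degenerate (constant) columns raise."""
    if kind not in SCALER_KINDS:
        raise ValueError(f"unknown scaler kind {kind!r}")
    M = np.asarray(fit_matrix, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if kind == "zscore":
        loc = M.mean(axis=0)
        scale = M.std(axis=0, ddof=0)
        bad = np.flatnonzero(scale <= 0)
    else:
        loc = M.min(axis=0)
        scale = M.max(axis=0) - loc
        bad = np.flatnonzero(scale <= 0)
    if bad.size:
        raise ValueError(f"degenerate (constant) columns at indices {bad.tolist()}")
    return ScalerSpec(kind=kind, loc=loc, scale=scale)


def apply_scaler(spec: ScalerSpec, matrix) -> np.ndarray:
    M = np.asarray(matrix, dtype=float)
    squeeze = M.ndim == 1
    M = np.atleast_2d(M)
    out = (M - spec.loc) / spec.scale
    if spec.kind != "zscore":
        out = np.clip(out, 0.0, 1.0) * spec.target_span
    return out[0] if squeeze else out


def invert_scaler(spec: ScalerSpec, matrix) -> np.ndarray:
    M = np.asarray(matrix, dtype=float)
    squeeze = M.ndim == 1
    M = np.atleast_2d(M)
    if spec.kind == "zscore":
        out = M * spec.scale + spec.loc
    else:
        out = (M / spec.target_span) * spec.scale + spec.loc
    return out[0] if squeeze else out


def split_evenly(feature_vector, n_blocks: int) -> list[np.ndarray]:
    """Contiguous, order-preserving blocks of equal size."""
    v = np.asarray(feature_vector)
    n = v.shape[-1]
    if n_blocks < 1 or n % n_blocks != 0:
        raise ValueError(f"{n} features not evenly divisible into {n_blocks} blocks")
    return [b for b in np.split(v, n_blocks, axis=-1)]
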