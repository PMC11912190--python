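"""Synthetic fixtures with known ground truth.

Real proton-affinity training data (curated experimental values plus a
descriptor matrix) cannot be redistributed, so every other module is
exercised on synthetic stand-ins:

* a compounds-by-features matrix with a planted, partly nonlinear
  feature-to-target signal and Gaussian noise, targets affinely mapped
  into a PA-like 150-260 kcal/mol window;
* binary fingerprints with planted cluster structure for the
  similarity/diversity toolkit.

The planted signal is a fixed published form — a weighted sum of four
signal columns plus a sine of the first — recorded verbatim in
``signal_spec`` so tests can recompute the noiseless target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticRegressionSet",
    "SyntheticFingerprintSet",
    "make_regression_set",
    "make_fingerprint_set",
    "apply_signal",
    "PA_RANGE",
]

#: Target window mimicking the span of experimental proton affinities.
PA_RANGE = (150.0, 260.0)

# Fixed planted signal: g(x) = w . x[signal_cols] + amp * sin(2*pi*x[sine_col]),
# features uniform on [0, 1].
_SIGNAL_COLUMNS = (0, 1, 2, 3)
_WEIGHTS = (3.0, 2.0, -1.5, 1.0)
_SINE_AMP = 1.2
_SINE_COL = 0
# Range of g over the unit cube (sine bounded by +-amp), used for the
# affine map onto PA_RANGE.
_G_MIN = -1.5 - _SINE_AMP
_G_MAX = 3.0 + 2.0 + 1.0 + _SINE_AMP


def _default_signal_spec() -> dict:
    lo, hi = PA_RANGE
    scale = (hi - lo) / (_G_MAX - _G_MIN)
    return {
        "form": "f(x) = offset + scale * (sum_i w_i * x[c_i] + amp * sin(2*pi*x[sine_col]))",
        "signal_columns": list(_SIGNAL_COLUMNS),
        "weights": list(_WEIGHTS),
        "sine_amplitude": _SINE_AMP,
        "sine_column": _SINE_COL,
        "scale": scale,
        "offset": lo - scale * _G_MIN,
        "target_range": list(PA_RANGE),
    }


def apply_signal(signal_spec: dict, X: np.ndarray) -> np.ndarray:
    """Evaluate the recorded planted function f on a feature matrix."""
    X = np.asarray(X, dtype=float)
    cols = signal_spec["signal_columns"]
    w = np.asarray(signal_spec["weights"], dtype=float)
    g = X[:, cols] @ w
    g = g + signal_spec["sine_amplitude"] * np.sin(
        2.0 * np.pi * X[:, signal_spec["sine_column"]]
    )
    return signal_spec["offset"] + signal_spec["scale"] * g


@dataclass
class SyntheticRegressionSet:
    X: np.ndarray
    y: np.ndarray
    signal_spec: dict
    noise_sd: float
    seed: int
    feature_names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["pa"] = self.y
        return df

    def to_csv(self, path) -> None:
        """Feature columns plus a final ``pa`` target column, header row."""
        self.to_frame().to_csv(path, index=False)


@dataclass
class SyntheticFingerprintSet:
    fingerprints: np.ndarray  # (n, n_bits) uint8 in {0, 1}
    true_cluster_labels: np.ndarray
    seed: int

    def to_lines(self) -> list[str]:
        return ["".join(str(b) for b in row) for row in self.fingerprints]

    def write(self, path) -> None:
        """One bitstring per line."""
        with open(path, "w") as fh:
            fh.write("\n".join(self.to_lines()) + "\n")


def make_regression_set(n_samples: int, n_features: int, noise_sd: float = 0.0,
                        seed: int = 0) -> SyntheticRegressionSet:
    """Feature matrix with a planted signal and PA-like targets.

    The first four columns carry the signal; all remaining columns are
    independent noise features.  With ``noise_sd = 0`` the target is an
    exact deterministic function of X, reproducible bit-for-bit under a
    fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_features < 4:
        raise ValueError("n_features must be >= 4 (four signal columns)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n_samples, n_features))
    spec = _default_signal_spec()
    y = apply_signal(spec, X)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_samples)
    names = [f"x{i:03d}" for i in range(n_features)]
    return SyntheticRegressionSet(
        X=X, y=y, signal_spec=spec, noise_sd=float(noise_sd), seed=int(seed),
        feature_names=names,
    )


def make_fingerprint_set(k_clusters: int, per_cluster: int, n_bits: int = 256,
                         flip_rate: float = 0.02, seed: int = 0,
                         ) -> SyntheticFingerprintSet:
    """Binary fingerprints with planted clusters.

    Each cluster has a random prototype bit vector (bit density 0.3);
    members are independent bit-flips of the prototype at ``flip_rate``.
    Rates at or above 0.5 would erase the cluster structure by
    construction and are rejected.
    """
    if k_clusters < 1 or per_cluster < 1:
        raise ValueError("k_clusters and per_cluster must be >= 1")
    if n_bits < 32:
        raise ValueError("n_bits must be >= 32")
    if not (0.0 <= flip_rate < 0.5):
        raise ValueError("flip_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    protos = (rng.random((k_clusters, n_bits)) < 0.3).astype(np.uint8)
    for i in range(k_clusters):  # a zero fingerprint has no defined similarity
        if protos[i].sum() == 0:
            protos[i, rng.integers(n_bits)] = 1
    n = k_clusters * per_cluster
    labels = np.repeat(np.arange(k_clusters), per_cluster)
    flips = (rng.random((n, n_bits)) < flip_rate).astype(np.uint8)
    fps = np.bitwise_xor(protos[labels], flips)
    return SyntheticFingerprintSet(
        fingerprints=fps, true_cluster_labels=labels, seed=int(seed)
    )
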