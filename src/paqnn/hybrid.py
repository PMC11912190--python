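"""Hybrid quantum-classical regression model for proton-affinity prediction.

The model chains a patch-method quantum feature encoder (S structurally
identical subencoder circuits on Q qubits each, consuming the features as
rotation angles scaled to [0, pi]) into a fixed-shape classical head of
three fully connected layers ``(n, n//2), (n//2, n//4), (n//4, 1)`` with
a sigmoid on the final output, where ``n = S*Q`` is the length of the
concatenated Pauli-Z expectations.  Targets are min-max scaled to [0, 1]
for training, so the sigmoid output is always inside the fitted PA range
after inversion.

Training minimizes mean-squared error with Adam; circuit-angle gradients
come from the parameter-shift rule and head gradients from ordinary
backpropagation, all in numpy.  The API follows the model/results split
familiar from statsmodels: construct :class:`HybridQNN` from data, call
``fit`` to obtain a :class:`HybridQNNResults` carrying the estimates,
loss history, held-out metrics and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import baselines
from .features import ScalerSpec, apply_scaler, fit_scaler, invert_scaler
from .patch import PatchEncoderConfig, count_quantum_params, encode, encode_grad_theta
from .qsim import CircuitSpec, hardware_efficient_ansatz

__all__ = [
    "head_dims",
    "head_param_count",
    "total_param_count",
    "TrainConfig",
    "HybridQNN",
    "HybridQNNResults",
]


def head_dims(n_in: int) -> list[tuple[int, int]]:
    """Layer shapes ``(n, n//2), (n//2, n//4), (n//4, 1)`` (integer division)."""
    if n_in < 4:
        raise ValueError("head needs n_in >= 4")
    return [(n_in, n_in // 2), (n_in // 2, n_in // 4), (n_in // 4, 1)]


def head_param_count(n_in: int) -> int:
    """Trainable weights + biases of the three-layer head."""
    return sum(fan_in * fan_out + fan_out for fan_in, fan_out in head_dims(n_in))


def total_param_count(n_subencoders: int, n_qubits: int, n_params: int,
                      t_features: int) -> int:
    """Total trainable parameters of the hybrid model.

    ``S * N_Params`` circuit angles plus the head consuming the ``S * Q``
    concatenated expectations.  ``t_features`` must split evenly across
    the subencoders.
    """
    if n_subencoders < 1 or t_features % n_subencoders != 0:
        raise ValueError(
            f"{t_features} features not divisible across {n_subencoders} subencoders"
        )
    return n_subencoders * n_params + head_param_count(n_subencoders * n_qubits)


@dataclass
class TrainConfig:
    """Optimization settings (none are dictated by the architecture).

    ``l1_penalty`` acts on the first head layer only: with few informative
    descriptors the lasso-style pressure prunes uninformative subencoder
    outputs instead of letting the head memorize them.  ``theta_init_scale``
    keeps the circuits near the identity-transparent point at the start of
    training (identity-block initialization).  ``n_restarts`` trains that
    many independently initialized models and keeps the one with the
    lowest final training loss — the loss surface of the joint
    quantum/classical parameterization is multimodal.
    """

    learning_rate: float = 2e-2
    epochs: int = 300
    batch_size: int = 32
    l1_penalty: float = 2e-3  # lasso on the first head layer
    weight_decay: float = 0.0  # L2 on head weights (decoupled, AdamW-style)
    theta_init_scale: float = 0.1  # circuit angles start uniform(-s, s)
    n_restarts: int = 3
    target_train_r2: float | None = None  # stop restarting once reached
    seed: int = 0
    split_ratio: float = 0.8  # train fraction of the 8:2 split
    train_quantum: bool = True  # freeze circuit angles when False (ablation)

    def __post_init__(self) -> None:
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError("split_ratio must be in (0, 1)")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


_LEAKY_SLOPE = 0.4


def _leaky(u):
    return np.where(u > 0, u, _LEAKY_SLOPE * u)


def _dleaky(u):
    return np.where(u > 0, 1.0, _LEAKY_SLOPE)


class HybridQNN:
    """Model: data plus architecture, before fitting.

    Parameters
    ----------
    X, y
        Feature matrix (n_samples, t_features) and PA targets (kcal/mol).
    n_subencoders, n_qubits, n_params
        Patch-method architecture: S circuits of Q qubits with N_Params
        trainable gates each.  ``t_features`` must be divisible by S;
        each circuit angle-encodes ``t_features / S`` features, using
        re-uploading rounds when that exceeds Q.
    circuit
        Optional explicit :class:`CircuitSpec` shared by all subencoders;
        by default a hardware-efficient re-uploading ansatz is built to
        match the requested slot counts.
    """

    def __init__(self, X, y, *, n_subencoders: int = 4, n_qubits: int = 4,
                 n_params: int = 12, circuit: CircuitSpec | None = None,
                 feature_names=None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be (n_samples, n_features) matching y")
        t_features = self.X.shape[1]
        if t_features % n_subencoders != 0:
            raise ValueError(
                f"{t_features} features not divisible across {n_subencoders} subencoders"
            )
        per_circuit = t_features // n_subencoders
        if circuit is None:
            circuit = hardware_efficient_ansatz(n_qubits, per_circuit, n_params)
        if circuit.n_encoding_slots != per_circuit:
            raise ValueError(
                f"circuit encodes {circuit.n_encoding_slots} features, "
                f"need {per_circuit} per subencoder"
            )
        self.encoder_config = PatchEncoderConfig(
            circuit=circuit, n_subencoders=n_subencoders
        )
        self.feature_names = (
            list(feature_names) if feature_names is not None
            else [f"x{i:03d}" for i in range(t_features)]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str = "pa", **kwargs):
        feats = [c for c in df.columns if c != target]
        return cls(
            df[feats].to_numpy(dtype=float), df[target].to_numpy(dtype=float),
            feature_names=feats, **kwargs,
        )

    # -- parameter accounting ---------------------------------------------
    @property
    def n_quantum_params(self) -> int:
        return count_quantum_params(self.encoder_config)

    @property
    def n_head_params(self) -> int:
        return head_param_count(self.encoder_config.output_dim)

    @property
    def n_total_params(self) -> int:
        return self.n_quantum_params + self.n_head_params

    # -- fitting ------------------------------------------------------------
    def fit(self, config: TrainConfig | None = None, **overrides) -> "HybridQNNResults":
        """Train with Adam; restarts are ranked by final training loss."""
        config = replace(config or TrainConfig(), **overrides)
        rng = np.random.default_rng(config.seed)
        n = self.y.size
        perm = rng.permutation(n)
        n_train = max(1, int(round(config.split_ratio * n)))
        if n_train >= n:
            raise ValueError("split leaves no test samples")
        train_idx, test_idx = perm[:n_train], perm[n_train:]

        x_scaler = fit_scaler("minmax_to_0_pi", self.X[train_idx])
        y_scaler = fit_scaler("minmax_to_0_1", self.y[train_idx])
        Xs = apply_scaler(x_scaler, self.X[train_idx])
        ts = np.asarray(apply_scaler(y_scaler, self.y[train_idx])).reshape(-1, 1)

        ss_tot = float(np.sum((ts - ts.mean()) ** 2))
        best = None
        for restart in range(config.n_restarts):
            run_rng = np.random.default_rng([config.seed, restart])
            candidate = self._train_once(config, run_rng, Xs, ts)
            if best is None or candidate[0] < best[0]:
                best = candidate
            if config.target_train_r2 is not None:
                _, c_theta, c_w, c_b, _ = candidate
                z = encode(Xs, self.encoder_config, c_theta)
                h = _leaky(z @ c_w[0].T + c_b[0])
                h = _leaky(h @ c_w[1].T + c_b[1])
                pred = _sigmoid(h @ c_w[2].T + c_b[2])
                train_r2 = 1.0 - float(np.sum((pred - ts) ** 2)) / ss_tot
                if train_r2 >= config.target_train_r2:
                    best = candidate
                    break
        _, theta, weights, biases, loss_history = best

        return HybridQNNResults(
            model=self,
            config=config,
            theta=theta,
            weights=weights,
            biases=biases,
            x_scaler=x_scaler,
            y_scaler=y_scaler,
            loss_history=np.asarray(loss_history),
            train_idx=train_idx,
            test_idx=test_idx,
        )

    def _train_once(self, config: TrainConfig, rng: np.random.Generator,
                    Xs: np.ndarray, ts: np.ndarray):
        cfg = self.encoder_config
        S, n_par = cfg.n_subencoders, cfg.circuit.n_trainable_slots
        n_train = Xs.shape[0]
        s0 = config.theta_init_scale
        theta = rng.uniform(-s0, s0, size=(S, n_par))
        weights, biases = [], []
        for fan_in, fan_out in head_dims(cfg.output_dim):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            weights.append(rng.uniform(-limit, limit, size=(fan_out, fan_in)))
            biases.append(np.zeros(fan_out))

        params = [theta] + weights + biases
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        loss_history = []

        for epoch in range(config.epochs):
            order = rng.permutation(n_train)
            epoch_losses = []
            for start in range(0, n_train, config.batch_size):
                idx = order[start:start + config.batch_size]
                xb, tb = Xs[idx], ts[idx]
                B = len(idx)

                z = encode(xb, cfg, theta)  # (B, S*Q)
                h1_pre = z @ weights[0].T + biases[0]
                h1 = _leaky(h1_pre)
                h2_pre = h1 @ weights[1].T + biases[1]
                h2 = _leaky(h2_pre)
                o = h2 @ weights[2].T + biases[2]
                p = _sigmoid(o)
                loss = float(np.mean((p - tb) ** 2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"NaN/inf loss at epoch {epoch}, batch start {start}; "
                        f"lr={config.learning_rate}, |theta|max="
                        f"{np.abs(theta).max():.3g}"
                    )
                epoch_losses.append(loss)

                do = (2.0 / B) * (p - tb) * p * (1.0 - p)
                gW3 = do.T @ h2
                gb3 = do.sum(axis=0)
                dh2 = (do @ weights[2]) * _dleaky(h2_pre)
                gW2 = dh2.T @ h1
                gb2 = dh2.sum(axis=0)
                dh1 = (dh2 @ weights[1]) * _dleaky(h1_pre)
                gW1 = dh1.T @ z
                gb1 = dh1.sum(axis=0)
                if config.l1_penalty:
                    gW1 = gW1 + config.l1_penalty * np.sign(weights[0])

                if config.train_quantum:
                    dz = (dh1 @ weights[0]).reshape(B, S, cfg.circuit.n_qubits)
                    G = encode_grad_theta(xb, cfg, theta)  # (B, S, Q, n_par)
                    gtheta = np.einsum("bsq,bsqn->sn", dz, G)
                else:
                    gtheta = np.zeros_like(theta)

                grads = [gtheta, gW1, gW2, gW3, gb1, gb2, gb3]
                step += 1
                lr_t = config.learning_rate * (
                    np.sqrt(1.0 - b2**step) / (1.0 - b1**step)
                )
                for k, (p_i, g_i, m_i, v_i) in enumerate(zip(params, grads, m, v)):
                    m_i += (1.0 - b1) * (g_i - m_i)
                    v_i += (1.0 - b2) * (g_i**2 - v_i)
                    p_i -= lr_t * m_i / (np.sqrt(v_i) + eps)
                    if config.weight_decay and 1 <= k <= 3:  # head weights only
                        p_i -= config.learning_rate * config.weight_decay * p_i
            loss_history.append(float(np.mean(epoch_losses)))

        return loss_history[-1], theta, weights, biases, loss_history


@dataclass
class HybridQNNResults:
    """Fitted hybrid model: estimates, scalers, loss history, diagnostics."""

    model: HybridQNN
    config: TrainConfig
    theta: np.ndarray
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_scaler: ScalerSpec
    y_scaler: ScalerSpec
    loss_history: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    _test_metrics: baselines.Metrics | None = field(default=None, repr=False)

    # -- prediction pipeline ------------------------------------------------
    def encode_features(self, X) -> np.ndarray:
        """Scaled angle encoding: concatenated subencoder expectations."""
        Xs = apply_scaler(self.x_scaler, np.atleast_2d(np.asarray(X, dtype=float)))
        return encode(Xs, self.model.encoder_config, self.theta)

    def head_forward(self, Z) -> np.ndarray:
        """Three-layer head on encoded features; sigmoid output in [0, 1]."""
        h = np.atleast_2d(Z)
        h = _leaky(h @ self.weights[0].T + self.biases[0])
        h = _leaky(h @ self.weights[1].T + self.biases[1])
        return _sigmoid(h @ self.weights[2].T + self.biases[2]).ravel()

    def predict(self, X) -> np.ndarray:
        """Predicted PA in kcal/mol; always inside the fitted target range."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        scaled = self.head_forward(self.encode_features(np.atleast_2d(X)))
        pa = np.asarray(invert_scaler(self.y_scaler, scaled)).ravel()
        return float(pa[0]) if single else pa

    def evaluate(self, X=None, y=None) -> baselines.Metrics:
        """R^2 / MAE / RMSE on the kcal/mol scale (held-out split by default)."""
        if X is None:
            X, y = self.model.X[self.test_idx], self.model.y[self.test_idx]
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.size == 0:
            raise ValueError("empty evaluation set")
        return baselines.metrics(y, self.predict(X))

    @property
    def test_metrics(self) -> baselines.Metrics:
        if self._test_metrics is None:
            self._test_metrics = self.evaluate()
        return self._test_metrics

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        cfg = self.model.encoder_config
        m = self.test_metrics
        lines = [
            "Hybrid QNN regression results",
            "=" * 45,
            f"subencoders (S):            {cfg.n_subencoders}",
            f"qubits per circuit (Q):     {cfg.circuit.n_qubits}",
            f"params per circuit:         {cfg.circuit.n_trainable_slots}",
            f"features encoded:           {cfg.n_features}",
            f"circuit depth / gates:      {cfg.circuit.depth} / {len(cfg.circuit.gates)}",
            f"quantum parameters:         {self.model.n_quantum_params}",
            f"head parameters:            {self.model.n_head_params}",
            f"total parameters:           {self.model.n_total_params}",
            f"train / test samples:       {self.train_idx.size} / {self.test_idx.size}",
            f"epochs:                     {self.config.epochs}",
            f"final training loss (MSE):  {self.loss_history[-1]:.5f}",
            "-" * 45,
            f"test R^2:                   {m.r2:.3f}",
            f"test MAE (kcal/mol):        {m.mae:.3f}",
            f"test RMSE (kcal/mol):       {m.rmse:.3f}",
        ]
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, self.loss_history.size + 1), self.loss_history)
        ax.set_xlabel("epoch")
        ax.set_ylabel("training MSE (scaled targets)")
        return ax

    # -- serialization -------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "circuit": json.loads(self.model.encoder_config.circuit.to_json()),
                "n_subencoders": self.model.encoder_config.n_subencoders,
                "theta": self.theta.tolist(),
                "weights": [w.tolist() for w in self.weights],
                "biases": [b.tolist() for b in self.biases],
                "x_scaler": json.loads(self.x_scaler.to_json()),
                "y_scaler": json.loads(self.y_scaler.to_json()),
                "loss_history": self.loss_history.tolist(),
            }
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())
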