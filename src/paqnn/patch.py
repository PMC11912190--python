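"""Patch-method feature encoder.

Several structurally identical quantum subencoder circuits, each with its
own independent trainable angles, consume disjoint contiguous blocks of
the scaled feature vector.  Their per-qubit Pauli-Z expectations are
concatenated into one real vector of length ``S * Q`` that feeds the
classical regression head.  Keeping each circuit small sidesteps the need
for many qubits and for long-range entanglement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .qsim import CircuitSpec, evolve_bound, param_shift_grad

__all__ = ["PatchEncoderConfig", "encode", "encode_grad_theta", "count_quantum_params"]


@dataclass
class PatchEncoderConfig:
    """Shared circuit structure plus the subencoder count.

    All ``n_subencoders`` circuits share one :class:`CircuitSpec`; only
    their trainable angle vectors differ.
    """

    circuit: CircuitSpec
    n_subencoders: int

    def __post_init__(self) -> None:
        if self.n_subencoders < 1:
            raise ValueError("n_subencoders must be >= 1")

    @property
    def n_features(self) -> int:
        """Total feature slots consumed by one encode call (S x per-circuit)."""
        return self.n_subencoders * self.circuit.n_encoding_slots

    @property
    def output_dim(self) -> int:
        return self.n_subencoders * self.circuit.n_qubits

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_subencoders": self.n_subencoders,
                "circuit": json.loads(self.circuit.to_json()),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PatchEncoderConfig":
        obj = json.loads(text)
        return cls(
            circuit=CircuitSpec.from_json(json.dumps(obj["circuit"])),
            n_subencoders=int(obj["n_subencoders"]),
        )


def _check_inputs(config: PatchEncoderConfig, x_full: np.ndarray,
                  theta_blocks: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    x_arr = np.asarray(x_full, dtype=float)
    single = x_arr.ndim == 1
    xb = np.atleast_2d(x_arr)
    if xb.shape[1] != config.n_features:
        raise ValueError(
            f"expected {config.n_features} features "
            f"({config.n_subencoders} x {config.circuit.n_encoding_slots}), "
            f"got {xb.shape[1]}"
        )
    tb = np.asarray(theta_blocks, dtype=float)
    if tb.shape != (config.n_subencoders, config.circuit.n_trainable_slots):
        raise ValueError(
            "theta_blocks must have shape (n_subencoders, n_trainable_slots) = "
            f"({config.n_subencoders}, {config.circuit.n_trainable_slots})"
        )
    return xb, tb, single


def encode(x_full, config: PatchEncoderConfig, theta_blocks) -> np.ndarray:
    """Concatenated subencoder expectations, shape ``(S*Q,)`` or ``(B, S*Q)``.

    Block ``i`` of the output is ``run_circuit(circuit, x_block_i,
    theta_block_i)`` where ``x_block_i`` is the i-th contiguous slice of
    ``x_full`` (features already scaled to [0, pi]).
    """
    xb, tb, single = _check_inputs(config, x_full, theta_blocks)
    m = config.circuit.n_encoding_slots
    S, B = config.n_subencoders, xb.shape[0]
    # One vectorized pass over all S x B (subencoder, sample) pairs: the
    # circuits share one structure, only the bound angles differ per row.
    x_rows = xb.reshape(B, S, m).transpose(1, 0, 2).reshape(S * B, m)
    t_rows = np.repeat(tb, B, axis=0)
    expect = evolve_bound(config.circuit, x_rows, t_rows)
    out = (
        expect.reshape(S, B, config.circuit.n_qubits)
        .transpose(1, 0, 2)
        .reshape(B, S * config.circuit.n_qubits)
    )
    return out[0] if single else out


def encode_grad_theta(x_full, config: PatchEncoderConfig, theta_blocks) -> np.ndarray:
    """Parameter-shift gradient of every output entry w.r.t. every angle.

    Returns shape ``(B, S, Q, n_trainable)`` (leading batch axis dropped
    for a single sample): entry ``[b, s, q, j]`` is the derivative of
    subencoder ``s``'s qubit-``q`` expectation w.r.t. its own angle ``j``.
    Cross-subencoder derivatives are identically zero by construction.
    Each subencoder's shifted circuits are evaluated in one vectorized
    statevector pass (see :func:`paqnn.qsim.param_shift_grad`).
    """
    xb, tb, single = _check_inputs(config, x_full, theta_blocks)
    m = config.circuit.n_encoding_slots
    grads = np.stack(
        [
            param_shift_grad(config.circuit, xb[:, i * m:(i + 1) * m], tb[i])
            for i in range(config.n_subencoders)
        ],
        axis=1,
    )  # (B, S, Q, n_trainable)
    return grads[0] if single else grads


def count_quantum_params(config: PatchEncoderConfig) -> int:
    """Total trainable circuit angles: S x N_Params."""
    return config.n_subencoders * config.circuit.n_trainable_slots
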