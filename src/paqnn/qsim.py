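"""Minimal statevector simulator for parameterized quantum circuits.

Noiseless pure-state simulation of the small circuits used as feature
encoders: a handful of qubits, single-qubit rotations, and CNOT/CZ
entanglers.  Exact Pauli-Z expectations are read off the statevector and
gradients with respect to rotation angles come from the parameter-shift
rule, so no autodiff framework is needed.

Conventions
-----------
* Qubit 0 is the **most significant bit** of the computational-basis
  index: for two qubits the amplitudes are ordered |00>, |01>, |10>,
  |11> with qubit 0 the left bit.
* Rotation gates use the half-angle convention, e.g.
  ``RY(t) = [[cos(t/2), -sin(t/2)], [sin(t/2), cos(t/2)]]``.
* Every operation accepts a batch of encoding-angle vectors and is
  vectorized over the batch; trainable angles are shared across a batch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Gate",
    "CircuitSpec",
    "init_state",
    "apply_gate",
    "expectation_z",
    "run_circuit",
    "param_shift_grad",
    "hardware_efficient_ansatz",
]

GATE_KINDS = ("RX", "RY", "RZ", "X", "H", "CNOT", "CZ")
ROTATION_KINDS = ("RX", "RY", "RZ")
TWO_QUBIT_KINDS = ("CNOT", "CZ")

MAX_QUBITS = 14


@dataclass(frozen=True)
class Gate:
    """One gate in a circuit.

    ``role`` is one of ``"fixed"`` (angle given, or non-parametric gate),
    ``"encoding"`` (angle bound to feature slot ``slot`` at run time) or
    ``"trainable"`` (angle bound to trainable slot ``slot``).
    """

    kind: str
    wires: tuple[int, ...]
    role: str = "fixed"
    slot: int | None = None
    angle: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in GATE_KINDS:
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if self.kind in TWO_QUBIT_KINDS:
            if len(self.wires) != 2 or self.wires[0] == self.wires[1]:
                raise ValueError(f"{self.kind} needs two distinct wires")
        elif len(self.wires) != 1:
            raise ValueError(f"{self.kind} acts on exactly one wire")
        if self.role in ("encoding", "trainable"):
            if self.kind not in ROTATION_KINDS:
                raise ValueError("only rotation gates can carry a parameter slot")
            if self.slot is None or self.slot < 0:
                raise ValueError("parameterized gate needs a non-negative slot index")
        elif self.role == "fixed":
            if self.kind in ROTATION_KINDS and self.angle is None:
                raise ValueError("fixed rotation gate needs an angle")
        else:
            raise ValueError(f"unknown param role {self.role!r}")


@dataclass
class CircuitSpec:
    """Ordered gate list over ``n_qubits`` wires with named parameter slots."""

    n_qubits: int
    gates: list[Gate] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (1 <= self.n_qubits <= MAX_QUBITS):
            raise ValueError(f"n_qubits must be in [1, {MAX_QUBITS}]")
        for g in self.gates:
            if any(w < 0 or w >= self.n_qubits for w in g.wires):
                raise ValueError(f"gate {g} has a wire outside 0..{self.n_qubits - 1}")
        for role in ("encoding", "trainable"):
            slots = sorted({g.slot for g in self.gates if g.role == role})
            if slots and slots != list(range(len(slots))):
                raise ValueError(f"{role} slots must be contiguous from 0, got {slots}")

    @property
    def n_encoding_slots(self) -> int:
        return len({g.slot for g in self.gates if g.role == "encoding"})

    @property
    def n_trainable_slots(self) -> int:
        """Number of distinct trainable angles (the per-circuit N_Params)."""
        return len({g.slot for g in self.gates if g.role == "trainable"})

    @property
    def depth(self) -> int:
        """Circuit depth under greedy left-alignment of gates onto wires."""
        level = [0] * self.n_qubits
        for g in self.gates:
            d = 1 + max(level[w] for w in g.wires)
            for w in g.wires:
                level[w] = d
        return max(level, default=0)

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "n_qubits": self.n_qubits,
                "gates": [
                    {
                        "kind": g.kind,
                        "wires": list(g.wires),
                        "role": g.role,
                        "slot": g.slot,
                        "angle": g.angle,
                    }
                    for g in self.gates
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CircuitSpec":
        obj = json.loads(text)
        gates = [
            Gate(
                kind=d["kind"],
                wires=tuple(d["wires"]),
                role=d.get("role", "fixed"),
                slot=d.get("slot"),
                angle=d.get("angle"),
            )
            for d in obj["gates"]
        ]
        return cls(n_qubits=int(obj["n_qubits"]), gates=gates)


# ---------------------------------------------------------------------------
# state evolution
# ---------------------------------------------------------------------------

def init_state(n_qubits: int, batch: int | None = None) -> np.ndarray:
    """|0...0> statevector; shape ``(2**Q,)`` or ``(batch, 2**Q)``."""
    if not (1 <= n_qubits <= MAX_QUBITS):
        raise ValueError(f"n_qubits must be in [1, {MAX_QUBITS}]")
    dim = 2**n_qubits
    if batch is None:
        psi = np.zeros(dim, dtype=np.complex128)
        psi[0] = 1.0
    else:
        psi = np.zeros((batch, dim), dtype=np.complex128)
        psi[:, 0] = 1.0
    return psi


def _rotation_entries(kind: str, theta):
    """2x2 entries (a, b, c, d) of a rotation; theta scalar or (B,) array."""
    theta = np.asarray(theta)
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    if kind == "RX":
        return c, -1j * s, -1j * s, c
    if kind == "RY":
        return c, -s, s, c
    if kind == "RZ":
        return np.exp(-1j * theta / 2.0), 0.0 * s, 0.0 * s, np.exp(1j * theta / 2.0)
    raise ValueError(kind)


_SQRT2 = 1.0 / math.sqrt(2.0)
_FIXED_1Q = {
    "X": (0.0, 1.0, 1.0, 0.0),
    "H": (_SQRT2, _SQRT2, _SQRT2, -_SQRT2),
}


def _apply_1q(psi: np.ndarray, entries, wire: int, n_qubits: int) -> np.ndarray:
    """Apply a 2x2 unitary on ``wire``; batched entries broadcast over axis 0."""
    batched = psi.ndim == 2
    lead = psi.shape[0] if batched else 1
    a, b, c, d = entries
    view = psi.reshape(lead, 2**wire, 2, -1)
    if np.ndim(a):  # per-sample angles
        a = np.asarray(a).reshape(-1, 1, 1)
        b = np.asarray(b).reshape(-1, 1, 1)
        c = np.asarray(c).reshape(-1, 1, 1)
        d = np.asarray(d).reshape(-1, 1, 1)
    s0, s1 = view[:, :, 0, :], view[:, :, 1, :]
    out = np.empty_like(view)
    out[:, :, 0, :] = a * s0 + b * s1
    out[:, :, 1, :] = c * s0 + d * s1
    return out.reshape(psi.shape)


def _apply_2q(psi: np.ndarray, kind: str, control: int, target: int,
              n_qubits: int) -> np.ndarray:
    batched = psi.ndim == 2
    lead = psi.shape[0] if batched else 1
    view = psi.reshape([lead] + [2] * n_qubits).copy()
    moved = np.moveaxis(view, [1 + control, 1 + target], [1, 2])
    if kind == "CNOT":
        tmp = moved[:, 1, 0].copy()
        moved[:, 1, 0] = moved[:, 1, 1]
        moved[:, 1, 1] = tmp
    elif kind == "CZ":
        moved[:, 1, 1] = -moved[:, 1, 1]
    else:  # pragma: no cover - guarded upstream
        raise ValueError(kind)
    return view.reshape(psi.shape)


def apply_gate(state: np.ndarray, gate: Gate, n_qubits: int | None = None,
               angle=None) -> np.ndarray:
    """Return the state after ``gate``; does not mutate the input.

    ``angle`` overrides the bound angle for parameterized gates (scalar or
    per-batch array).  ``n_qubits`` is inferred from the state length when
    omitted.
    """
    if n_qubits is None:
        dim = state.shape[-1]
        n_qubits = int(round(math.log2(dim)))
        if 2**n_qubits != dim:
            raise ValueError("state length is not a power of two")
    if any(w >= n_qubits for w in gate.wires):
        raise ValueError(f"gate wire out of range for {n_qubits} qubits")
    if gate.kind in TWO_QUBIT_KINDS:
        return _apply_2q(state, gate.kind, gate.wires[0], gate.wires[1], n_qubits)
    if gate.kind in ROTATION_KINDS:
        if angle is None:
            angle = gate.angle
        if angle is None:
            raise ValueError("rotation gate applied without an angle")
        entries = _rotation_entries(gate.kind, angle)
    else:
        entries = _FIXED_1Q[gate.kind]
    return _apply_1q(state, entries, gate.wires[0], n_qubits)


def expectation_z(state: np.ndarray, qubit: int, n_qubits: int | None = None):
    """Exact <Z> on ``qubit``; in [-1, 1].  Batched states give a vector."""
    dim = state.shape[-1]
    if n_qubits is None:
        n_qubits = int(round(math.log2(dim)))
    if not (0 <= qubit < n_qubits):
        raise ValueError(f"qubit {qubit} out of range")
    bits = (np.arange(dim) >> (n_qubits - 1 - qubit)) & 1
    signs = 1.0 - 2.0 * bits
    probs = np.abs(state) ** 2
    return probs @ signs


def run_circuit(spec: CircuitSpec, x, theta) -> np.ndarray:
    """Bind angles, evolve |0...0>, and return per-qubit <Z> in wire order.

    ``x`` has shape ``(n_encoding_slots,)`` or ``(batch, n_encoding_slots)``;
    ``theta`` has shape ``(n_trainable_slots,)`` and is shared across the
    batch.  Output shape ``(Q,)`` or ``(batch, Q)``.
    """
    x_arr = np.asarray(x, dtype=float)
    single = x_arr.ndim == 1
    x = np.atleast_2d(x_arr)
    theta = np.asarray(theta, dtype=float).ravel()
    if x.shape[1] != spec.n_encoding_slots:
        raise ValueError(
            f"expected {spec.n_encoding_slots} encoding angles, got {x.shape[1]}"
        )
    if theta.shape[0] != spec.n_trainable_slots:
        raise ValueError(
            f"expected {spec.n_trainable_slots} trainable angles, got {theta.shape[0]}"
        )
    psi = init_state(spec.n_qubits, batch=x.shape[0])
    for g in spec.gates:
        if g.role == "encoding":
            psi = apply_gate(psi, g, spec.n_qubits, angle=x[:, g.slot])
        elif g.role == "trainable":
            psi = apply_gate(psi, g, spec.n_qubits, angle=theta[g.slot])
        else:
            psi = apply_gate(psi, g, spec.n_qubits)
    out = np.stack(
        [expectation_z(psi, q, spec.n_qubits) for q in range(spec.n_qubits)], axis=-1
    )
    return out[0] if single else out


def run_circuit_single(spec: CircuitSpec, x, theta) -> np.ndarray:
    """Convenience wrapper returning a flat ``(Q,)`` vector for one sample."""
    return run_circuit(spec, np.atleast_2d(x), theta)[0]


def evolve_bound(spec: CircuitSpec, x_bound, theta_bound) -> np.ndarray:
    """Evolve a batch with fully bound per-row angles; return <Z> per qubit.

    ``x_bound`` has shape ``(B, n_encoding_slots)``; ``theta_bound`` has
    shape ``(B, n_trainable_slots)`` so every row of the batch may carry
    its own trainable angles (the workhorse behind vectorized
    parameter-shift evaluation and multi-subencoder encoding).
    """
    xb = np.atleast_2d(np.asarray(x_bound, dtype=float))
    tb = np.atleast_2d(np.asarray(theta_bound, dtype=float))
    if tb.shape[0] == 1 and xb.shape[0] > 1:
        tb = np.broadcast_to(tb, (xb.shape[0], tb.shape[1]))
    if xb.shape[1] != spec.n_encoding_slots or tb.shape[1] != spec.n_trainable_slots:
        raise ValueError("bound angle arrays do not match the circuit's slot counts")
    psi = init_state(spec.n_qubits, batch=xb.shape[0])
    for g in spec.gates:
        if g.role == "encoding":
            psi = apply_gate(psi, g, spec.n_qubits, angle=xb[:, g.slot])
        elif g.role == "trainable":
            psi = apply_gate(psi, g, spec.n_qubits, angle=tb[:, g.slot])
        else:
            psi = apply_gate(psi, g, spec.n_qubits)
    return np.stack(
        [expectation_z(psi, q, spec.n_qubits) for q in range(spec.n_qubits)], axis=-1
    )


def param_shift_grad(spec: CircuitSpec, x, theta) -> np.ndarray:
    """d<Z_q>/d theta_j by the parameter-shift rule.

    Returns shape ``(Q, n_trainable)`` for a single encoding vector or
    ``(batch, Q, n_trainable)`` for a batch.  A slot reused by several
    gates accumulates the shift contributions of each occurrence
    (shifting the slot everywhere at once would not be the product rule).
    All ``2 x occurrences x batch`` shifted circuits are evaluated in one
    vectorized statevector pass.
    """
    occ_gates = [i for i, g in enumerate(spec.gates) if g.role == "trainable"]
    for i in occ_gates:
        if spec.gates[i].kind not in ROTATION_KINDS:
            raise ValueError("parameter-shift requires rotation trainable gates")
    x_arr = np.asarray(x, dtype=float)
    single = x_arr.ndim == 1
    theta = np.asarray(theta, dtype=float).ravel()
    xb = np.atleast_2d(x_arr)
    B, n_tr, m = xb.shape[0], spec.n_trainable_slots, len(occ_gates)
    if m == 0:
        out = np.zeros((B, spec.n_qubits, n_tr))
        return out[0] if single else out

    # Row layout: (variant v = 2m shifts) x (batch b); occurrence k gets
    # +pi/2 at variant 2k and -pi/2 at variant 2k+1, on that gate only.
    n_rows = 2 * m * B
    xs_big = np.tile(xb, (2 * m, 1))
    psi = init_state(spec.n_qubits, batch=n_rows)
    occ_pos = {gate_idx: k for k, gate_idx in enumerate(occ_gates)}
    for i, g in enumerate(spec.gates):
        if g.role == "encoding":
            psi = apply_gate(psi, g, spec.n_qubits, angle=xs_big[:, g.slot])
        elif g.role == "trainable":
            ang = np.full(n_rows, theta[g.slot])
            k = occ_pos[i]
            ang[2 * k * B:(2 * k + 1) * B] += math.pi / 2.0
            ang[(2 * k + 1) * B:(2 * k + 2) * B] -= math.pi / 2.0
            psi = apply_gate(psi, g, spec.n_qubits, angle=ang)
        else:
            psi = apply_gate(psi, g, spec.n_qubits)
    expect = np.stack(
        [expectation_z(psi, q, spec.n_qubits) for q in range(spec.n_qubits)], axis=-1
    ).reshape(2 * m, B, spec.n_qubits)

    grads = np.zeros((B, spec.n_qubits, n_tr))
    for k, gate_idx in enumerate(occ_gates):
        slot = spec.gates[gate_idx].slot
        grads[:, :, slot] += (expect[2 * k] - expect[2 * k + 1]) / 2.0
    return grads[0] if single else grads


# ---------------------------------------------------------------------------
# default ansatz
# ---------------------------------------------------------------------------

def _cz_ring(n_qubits: int) -> list[Gate]:
    if n_qubits < 2:
        return []
    if n_qubits == 2:
        return [Gate("CZ", (0, 1))]
    return [Gate("CZ", (i, (i + 1) % n_qubits)) for i in range(n_qubits)]


def hardware_efficient_ansatz(n_qubits: int, n_encoding_slots: int,
                              n_trainable: int) -> CircuitSpec:
    """Hardware-efficient re-uploading circuit with exact slot counts.

    Layout per round: a CZ entangling ring (skipped before the first
    round), one RY encoding gate per wire for the next block of feature
    slots (angle encoding; rounds beyond the first upload the remaining
    slots), then a trainable-RY layer.  Rounds continue after the
    encoding slots are exhausted until exactly ``n_trainable``
    parameterized gates have been placed, so the per-circuit parameter
    count matches the requested N_Params.

    CZ entanglers between rotation layers are used rather than CNOT
    rings after them: diagonal entanglers leave the all-zero-angle
    circuit an exact per-wire cosine feature map, so training starts
    from an information-preserving embedding (identity-block
    initialization) instead of a scrambled one, while nonzero trainable
    angles activate genuine entanglement.
    """
    if n_encoding_slots < 1 or n_trainable < 1:
        raise ValueError("need at least one encoding and one trainable slot")
    gates: list[Gate] = []
    enc_next, tr_next = 0, 0
    first = True
    while enc_next < n_encoding_slots or tr_next < n_trainable:
        if not first:
            gates.extend(_cz_ring(n_qubits))
        first = False
        if enc_next < n_encoding_slots:
            block = min(n_qubits, n_encoding_slots - enc_next)
            for w in range(block):
                gates.append(Gate("RY", (w,), role="encoding", slot=enc_next))
                enc_next += 1
        if tr_next < n_trainable:
            block = min(n_qubits, n_trainable - tr_next)
            for w in range(block):
                gates.append(Gate("RY", (w,), role="trainable", slot=tr_next))
                tr_next += 1
    return CircuitSpec(n_qubits=n_qubits, gates=gates)
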