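import numpy as np
import pytest

from paqnn.qsim import CircuitSpec, Gate

# ---------------------------------------------------------------------------
# dense-unitary oracle: builds the full 2^Q x 2^Q matrix by Kronecker
# products, independent of the simulator's sparse gate application.
# ---------------------------------------------------------------------------

_I2 = np.eye(2, dtype=complex)
_X = np.array([[0, 1], [1, 0]], dtype=complex)
_Z = np.array([[1, 0], [0, -1]], dtype=complex)
_H = np.array([[1, 1], [1, -1]], dtype=complex) / np.sqrt(2)
_P0 = np.array([[1, 0], [0, 0]], dtype=complex)
_P1 = np.array([[0, 0], [0, 1]], dtype=complex)


def _rot(kind: str, theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2), np.sin(theta / 2)
    if kind == "RX":
        return np.array([[c, -1j * s], [-1j * s, c]])
    if kind == "RY":
        return np.array([[c, -s], [s, c]])
    if kind == "RZ":
        return np.array([[np.exp(-1j * theta / 2), 0], [0, np.exp(1j * theta / 2)]])
    raise ValueError(kind)


def _place(factors: dict[int, np.ndarray], n_qubits: int) -> np.ndarray:
    """Kronecker product with qubit 0 as the leftmost (most significant) factor."""
    out = np.array([[1.0 + 0j]])
    for w in range(n_qubits):
        out = np.kron(out, factors.get(w, _I2))
    return out


def gate_unitary(gate: Gate, n_qubits: int, angle=None) -> np.ndarray:
    if gate.kind in ("RX", "RY", "RZ"):
        u = _rot(gate.kind, angle if angle is not None else gate.angle)
        return _place({gate.wires[0]: u}, n_qubits)
    if gate.kind == "X":
        return _place({gate.wires[0]: _X}, n_qubits)
    if gate.kind == "H":
        return _place({gate.wires[0]: _H}, n_qubits)
    c, t = gate.wires
    if gate.kind == "CNOT":
        return _place({c: _P0}, n_qubits) + _place({c: _P1, t: _X}, n_qubits)
    if gate.kind == "CZ":
        return _place({c: _P0}, n_qubits) + _place({c: _P1, t: _Z}, n_qubits)
    raise ValueError(gate.kind)


def circuit_unitary(spec: CircuitSpec, x, theta) -> np.ndarray:
    """Full circuit unitary as an ordered dense matrix product."""
    U = np.eye(2**spec.n_qubits, dtype=complex)
    for g in spec.gates:
        if g.role == "encoding":
            ang = x[g.slot]
        elif g.role == "trainable":
            ang = theta[g.slot]
        else:
            ang = g.angle
        U = gate_unitary(g, spec.n_qubits, angle=ang) @ U
    return U


def oracle_expectations(spec: CircuitSpec, x, theta) -> np.ndarray:
    """<Z_q> computed from the dense unitary acting on |0...0>."""
    U = circuit_unitary(spec, x, theta)
    psi = U[:, 0]  # U |0...0>
    dim = 2**spec.n_qubits
    out = np.empty(spec.n_qubits)
    for q in range(spec.n_qubits):
        bits = (np.arange(dim) >> (spec.n_qubits - 1 - q)) & 1
        out[q] = float(np.sum((1 - 2 * bits) * np.abs(psi) ** 2))
    return out


def random_circuit(rng: np.random.Generator, n_qubits: int, n_gates: int = 12,
                   n_enc: int = 2, n_tr: int = 3) -> CircuitSpec:
    """Random circuit over the full gate set with both slot roles used."""
    gates = []
    # guarantee each encoding/trainable slot appears at least once
    for slot in range(n_enc):
        gates.append(Gate("RY", (int(rng.integers(n_qubits)),),
                          role="encoding", slot=slot))
    for slot in range(n_tr):
        kind = rng.choice(["RX", "RY", "RZ"])
        gates.append(Gate(str(kind), (int(rng.integers(n_qubits)),),
                          role="trainable", slot=slot))
    for _ in range(n_gates):
        kind = rng.choice(["RX", "RY", "RZ", "X", "H", "CNOT", "CZ"])
        if kind in ("CNOT", "CZ"):
            if n_qubits < 2:
                continue
            w = rng.choice(n_qubits, size=2, replace=False)
            gates.append(Gate(str(kind), (int(w[0]), int(w[1]))))
        elif kind in ("RX", "RY", "RZ"):
            role = rng.choice(["fixed", "encoding", "trainable"])
            if role == "fixed":
                gates.append(Gate(str(kind), (int(rng.integers(n_qubits)),),
                                  angle=float(rng.uniform(-np.pi, np.pi))))
            elif role == "encoding":
                gates.append(Gate(str(kind), (int(rng.integers(n_qubits)),),
                                  role="encoding", slot=int(rng.integers(n_enc))))
            else:
                gates.append(Gate(str(kind), (int(rng.integers(n_qubits)),),
                                  role="trainable", slot=int(rng.integers(n_tr))))
        else:
            gates.append(Gate(str(kind), (int(rng.integers(n_qubits)),)))
    order = rng.permutation(len(gates))
    return CircuitSpec(n_qubits=n_qubits, gates=[gates[i] for i in order])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
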