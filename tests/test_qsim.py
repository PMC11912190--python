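"""Statevector simulator checked against a dense Kronecker-product oracle."""

import numpy as np
import pytest

from paqnn.qsim import (
    CircuitSpec,
    Gate,
    apply_gate,
    evolve_bound,
    expectation_z,
    hardware_efficient_ansatz,
    init_state,
    param_shift_grad,
    run_circuit,
)

from .conftest import oracle_expectations, random_circuit


class TestInitState:
    def test_ground_state(self):
        assert np.allclose(init_state(1), [1, 0])
        assert np.allclose(init_state(2), [1, 0, 0, 0])
        assert abs(np.linalg.norm(init_state(5)) - 1) < 1e-12

    @pytest.mark.parametrize("q", [0, 15])
    def test_qubit_range_enforced(self, q):
        with pytest.raises(ValueError):
            init_state(q)


class TestSingleGates:
    def test_x_flips(self):
        psi = apply_gate(init_state(1), Gate("X", (0,)))
        assert np.allclose(psi, [0, 1])

    def test_hadamard_superposition(self):
        psi = apply_gate(init_state(1), Gate("H", (0,)))
        assert np.allclose(psi, [1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_cnot_control_first(self):
        # |10> (control=qubit 0 set) -> |11>
        psi = apply_gate(init_state(2), Gate("X", (0,)))
        psi = apply_gate(psi, Gate("CNOT", (0, 1)))
        assert np.allclose(psi, [0, 0, 0, 1])

    def test_ry_half_angle_convention(self):
        theta = 0.7
        psi = apply_gate(init_state(1), Gate("RY", (0,), angle=theta))
        assert np.allclose(psi, [np.cos(theta / 2), np.sin(theta / 2)])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            Gate("SWAP", (0, 1))


class TestExpectationZ:
    def test_basis_states(self):
        assert expectation_z(init_state(1), 0) == pytest.approx(1.0)
        flipped = apply_gate(init_state(1), Gate("X", (0,)))
        assert expectation_z(flipped, 0) == pytest.approx(-1.0)

    @pytest.mark.parametrize("theta", [0.0, 0.3, np.pi / 2, np.pi, 2.5])
    def test_ry_rotation_closed_form(self, theta):
        psi = apply_gate(init_state(1), Gate("RY", (0,), angle=theta))
        assert expectation_z(psi, 0) == pytest.approx(np.cos(theta), abs=1e-12)

    def test_bell_state_marginals_vanish(self):
        psi = apply_gate(init_state(2), Gate("H", (0,)))
        psi = apply_gate(psi, Gate("CNOT", (0, 1)))
        assert expectation_z(psi, 0) == pytest.approx(0.0, abs=1e-12)
        assert expectation_z(psi, 1) == pytest.approx(0.0, abs=1e-12)


class TestRunCircuit:
    def _per_wire_ry(self, q=3):
        gates = [Gate("RY", (w,), role="encoding", slot=w) for w in range(q)]
        return CircuitSpec(q, gates)

    def test_zero_angles_give_plus_one(self):
        spec = self._per_wire_ry()
        assert np.allclose(run_circuit(spec, np.zeros(3), []), 1.0)

    def test_pi_angles_give_minus_one(self):
        spec = self._per_wire_ry()
        assert np.allclose(run_circuit(spec, np.full(3, np.pi), []), -1.0)

    def test_slot_length_mismatch(self):
        spec = self._per_wire_ry()
        with pytest.raises(ValueError):
            run_circuit(spec, np.zeros(2), [])

    def test_batched_equals_loop(self, rng):
        spec = random_circuit(rng, 3)
        xb = rng.uniform(0, np.pi, (6, spec.n_encoding_slots))
        th = rng.uniform(-np.pi, np.pi, spec.n_trainable_slots)
        batched = run_circuit(spec, xb, th)
        rows = np.stack([run_circuit(spec, x, th) for x in xb])
        assert np.allclose(batched, rows, atol=1e-12)


class TestAgainstDenseOracle:
    """Sparse gate application must equal the full-unitary matrix product."""

    @pytest.mark.parametrize("n_qubits", [1, 2, 3, 4])
    def test_random_circuits_match_oracle(self, rng, n_qubits):
        for _ in range(30):
            spec = random_circuit(rng, n_qubits)
            x = rng.uniform(0, np.pi, spec.n_encoding_slots)
            th = rng.uniform(-np.pi, np.pi, spec.n_trainable_slots)
            got = run_circuit(spec, x, th)
            want = oracle_expectations(spec, x, th)
            assert np.allclose(got, want, atol=1e-10)
            assert np.all(np.abs(got) <= 1 + 1e-12)

    def test_norm_preserved_gate_by_gate(self, rng):
        spec = random_circuit(rng, 4, n_gates=25)
        psi = init_state(4)
        x = rng.uniform(0, np.pi, spec.n_encoding_slots)
        th = rng.uniform(-np.pi, np.pi, spec.n_trainable_slots)
        for g in spec.gates:
            if g.role == "encoding":
                psi = apply_gate(psi, g, 4, angle=x[g.slot])
            elif g.role == "trainable":
                psi = apply_gate(psi, g, 4, angle=th[g.slot])
            else:
                psi = apply_gate(psi, g, 4)
            assert abs(np.linalg.norm(psi) - 1) < 1e-10


class TestParamShift:
    def test_single_ry_gradient_is_minus_sine(self):
        spec = CircuitSpec(1, [Gate("RY", (0,), role="trainable", slot=0)])
        for theta in (0.0, 0.4, 1.2, np.pi / 2):
            g = param_shift_grad(spec, np.zeros(0), np.array([theta]))
            assert g[0, 0] == pytest.approx(-np.sin(theta), abs=1e-12)

    def test_theta_independent_output_gives_zero(self):
        # trainable RZ commutes with the Z measurement on |0>
        spec = CircuitSpec(1, [Gate("RZ", (0,), role="trainable", slot=0)])
        g = param_shift_grad(spec, np.zeros(0), np.array([0.9]))
        assert g[0, 0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_finite_differences(self, rng, trial):
        spec = random_circuit(rng, 4)
        x = rng.uniform(0, np.pi, spec.n_encoding_slots)
        th = rng.uniform(-np.pi, np.pi, spec.n_trainable_slots)
        got = param_shift_grad(spec, x, th)
        h = 1e-5
        for j in range(spec.n_trainable_slots):
            tp, tm = th.copy(), th.copy()
            tp[j] += h
            tm[j] -= h
            fd = (run_circuit(spec, x, tp) - run_circuit(spec, x, tm)) / (2 * h)
            assert np.allclose(got[:, j], fd, atol=1e-6)

    def test_reused_slot_sums_contributions(self):
        # two RY gates bound to one slot: d cos(2t) / dt = -2 sin(2t)
        spec = CircuitSpec(1, [
            Gate("RY", (0,), role="trainable", slot=0),
            Gate("RY", (0,), role="trainable", slot=0),
        ])
        t = 0.35
        g = param_shift_grad(spec, np.zeros(0), np.array([t]))
        assert g[0, 0] == pytest.approx(-2 * np.sin(2 * t), abs=1e-10)


class TestCircuitSpec:
    def test_json_round_trip(self, rng):
        spec = random_circuit(rng, 3)
        back = CircuitSpec.from_json(spec.to_json())
        assert back.n_qubits == spec.n_qubits
        assert back.gates == spec.gates

    def test_non_contiguous_slots_rejected(self):
        with pytest.raises(ValueError):
            CircuitSpec(1, [Gate("RY", (0,), role="encoding", slot=1)])

    def test_wire_bounds_enforced(self):
        with pytest.raises(ValueError):
            CircuitSpec(1, [Gate("CNOT", (0, 1))])


class TestAnsatz:
    @pytest.mark.parametrize(
        "q,enc,tr", [(4, 4, 12), (4, 8, 20), (8, 8, 20), (10, 16, 64), (2, 2, 5)]
    )
    def test_slot_counts_exact(self, q, enc, tr):
        spec = hardware_efficient_ansatz(q, enc, tr)
        assert spec.n_encoding_slots == enc
        assert spec.n_trainable_slots == tr

    def test_identity_start_is_cosine_feature_map(self):
        # all trainable angles zero: CZ layers cancel pairwise and the
        # circuit reduces to one RY(x) per wire, so <Z_q> = cos(x_q)
        spec = hardware_efficient_ansatz(4, 4, 12)
        x = np.array([0.3, 1.1, 2.0, 2.9])
        out = run_circuit(spec, x, np.zeros(12))
        assert np.allclose(out, np.cos(x), atol=1e-12)

    def test_evolve_bound_matches_run_circuit(self, rng):
        spec = hardware_efficient_ansatz(3, 3, 7)
        xb = rng.uniform(0, np.pi, (5, 3))
        th = rng.uniform(-1, 1, 7)
        got = evolve_bound(spec, xb, np.tile(th, (5, 1)))
        want = run_circuit(spec, xb, th)
        assert np.allclose(got, want, atol=1e-12)
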