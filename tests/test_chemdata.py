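"""Curation rules, Tanimoto similarity, Butina clustering vs brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paqnn.chemdata import (
    CompoundRecord,
    Fingerprint,
    butina_cluster,
    curate_records,
    diversity_summary,
    morgan_fingerprints,
    tanimoto,
)
from paqnn.synthetic import make_fingerprint_set


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_leader(fps, cutoff):
    """Naive O(n^3) leader clustering with pure-python loops."""
    n = len(fps)
    sims = [[tanimoto(fps[i], fps[j]) if i != j else 1.0 for j in range(n)]
            for i in range(n)]
    labels = [None] * n
    next_label = 0
    while any(l is None for l in labels):
        best, best_count = None, -1
        for i in range(n):
            if labels[i] is not None:
                continue
            count = sum(
                1 for j in range(n)
                if j != i and labels[j] is None and sims[i][j] >= cutoff
            )
            if count > best_count:  # strict: ties keep the lowest index
                best, best_count = i, count
        labels[best] = next_label
        for j in range(n):
            if j != best and labels[j] is None and sims[best][j] >= cutoff:
                labels[j] = next_label
        next_label += 1
    return labels


def connected_components(fps, cutoff):
    """Similarity-graph components: an upper bound grouping for planted sets."""
    n = len(fps)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if tanimoto(fps[i], fps[j]) >= cutoff:
                parent[find(i)] = find(j)
    roots = {find(i) for i in range(n)}
    return len(roots)


# ---------------------------------------------------------------------------
# tanimoto
# ---------------------------------------------------------------------------

class TestTanimoto:
    def test_identity_is_one(self):
        fp = Fingerprint(np.array([1, 0, 1, 1, 0, 0, 1, 0]))
        assert tanimoto(fp, fp) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        a = Fingerprint(np.array([1, 1, 0, 0]))
        b = Fingerprint(np.array([0, 0, 1, 1]))
        assert tanimoto(a, b) == 0.0

    def test_worked_formula_example(self):
        # a=4 set bits, b=6 set bits, c=2 shared: 2 / (4 + 6 - 2) = 0.25
        a = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        b = np.array([1, 1, 0, 0, 1, 1, 1, 1, 0, 0])
        assert tanimoto(a, b) == pytest.approx(0.25)

    def test_both_empty_is_an_error(self):
        z = np.zeros(16, dtype=int)
        with pytest.raises(ValueError):
            tanimoto(z, z)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(np.ones(8, dtype=int), np.ones(16, dtype=int))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**24 - 1), st.integers(1, 2**24 - 1))
    def test_symmetry_and_bounds(self, abits, bbits):
        a = np.array([(abits >> i) & 1 for i in range(24)], dtype=np.uint8)
        b = np.array([(bbits >> i) & 1 for i in range(24)], dtype=np.uint8)
        if a.sum() == 0 and b.sum() == 0:
            return
        t = tanimoto(a, b)
        assert t == pytest.approx(tanimoto(b, a))
        assert 0.0 <= t <= 1.0


# ---------------------------------------------------------------------------
# butina
# ---------------------------------------------------------------------------

class TestButina:
    def test_all_dissimilar_gives_singletons(self):
        fps = np.eye(8, dtype=np.uint8)  # pairwise tanimoto 0
        labels = butina_cluster(fps, cutoff=0.5)
        assert len(set(labels.tolist())) == 8

    def test_all_identical_gives_one_cluster(self):
        fps = np.tile(np.array([1, 0, 1, 1], dtype=np.uint8), (6, 1))
        labels = butina_cluster(fps, cutoff=0.7)
        assert set(labels.tolist()) == {0}

    def test_partition_property(self, rng):
        fps = (rng.random((30, 64)) < 0.3).astype(np.uint8)
        fps[fps.sum(axis=1) == 0, 0] = 1
        labels = butina_cluster(fps, cutoff=0.4)
        sizes = np.bincount(labels)
        assert sizes.sum() == 30
        assert (labels >= 0).all()

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_brute_force_oracle(self, rng, trial):
        n = int(rng.integers(5, 50))
        fps = (rng.random((n, 48)) < 0.35).astype(np.uint8)
        fps[fps.sum(axis=1) == 0, 0] = 1
        cutoff = float(rng.uniform(0.2, 0.8))
        assert butina_cluster(fps, cutoff).tolist() == brute_force_leader(fps, cutoff)

    def test_recovers_planted_clusters(self):
        fp = make_fingerprint_set(5, 10, n_bits=256, flip_rate=0.02, seed=13)
        labels = butina_cluster(fp.fingerprints, cutoff=0.7)
        assert len(set(labels.tolist())) == 5
        # clustering agrees with the planted partition exactly
        for k in set(labels.tolist()):
            truth = fp.true_cluster_labels[labels == k]
            assert len(set(truth.tolist())) == 1
        # independent check: similarity-graph components agree
        assert connected_components(fp.fingerprints, 0.7) == 5

    def test_empty_input(self):
        assert butina_cluster(np.zeros((0, 8), dtype=np.uint8)).size == 0


class TestDiversitySummary:
    def test_identical_pair(self):
        fps = np.tile(np.array([1, 1, 0, 0], dtype=np.uint8), (2, 1))
        s = diversity_summary(fps, cutoff=0.7)
        assert s.mean_similarity == pytest.approx(1.0)
        assert s.std_similarity == pytest.approx(0.0)

    def test_disjoint_pair(self):
        fps = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.uint8)
        s = diversity_summary(fps, cutoff=0.7)
        assert s.mean_similarity == pytest.approx(0.0)
        assert s.n_singletons == 2

    def test_matches_brute_force_pairwise_loop(self, rng):
        fps = (rng.random((10, 32)) < 0.4).astype(np.uint8)
        fps[fps.sum(axis=1) == 0, 0] = 1
        s = diversity_summary(fps, cutoff=0.6)
        vals = [tanimoto(fps[i], fps[j]) for i in range(10) for j in range(i + 1, 10)]
        assert s.mean_similarity == pytest.approx(np.mean(vals))
        assert s.std_similarity == pytest.approx(np.std(vals))

    def test_needs_two(self):
        with pytest.raises(ValueError):
            diversity_summary(np.ones((1, 8), dtype=np.uint8))


# ---------------------------------------------------------------------------
# curation (rdkit-backed)
# ---------------------------------------------------------------------------

class TestCuration:
    def test_disallowed_element_removed(self):
        recs = [
            CompoundRecord("ok", "CCN", 210.0),
            CompoundRecord("fluoro", "CCF", 205.0),
        ]
        out = curate_records(recs)
        assert [r.id for r in out] == ["ok"]

    def test_radical_removed(self):
        recs = [
            CompoundRecord("methyl_radical", "[CH3]", 180.0),
            CompoundRecord("methane", "C", 130.0),
        ]
        out = curate_records(recs)
        assert [r.id for r in out] == ["methane"]

    def test_unparsable_smiles_rejected_not_raised(self):
        recs = [
            CompoundRecord("bad", "not_a_smiles(", 200.0),
            CompoundRecord("ok", "CCO", 188.0),
        ]
        out = curate_records(recs)
        assert [r.id for r in out] == ["ok"]

    def test_close_stereoisomers_merged_to_mean(self):
        recs = [
            CompoundRecord("l", "C[C@H](N)C(=O)O", 200.0),
            CompoundRecord("d", "C[C@@H](N)C(=O)O", 200.5),
        ]
        out = curate_records(recs)
        assert len(out) == 1
        assert out[0].pa == pytest.approx(200.25)

    def test_distant_stereoisomers_both_kept(self):
        recs = [
            CompoundRecord("l", "C[C@H](N)C(=O)O", 200.0),
            CompoundRecord("d", "C[C@@H](N)C(=O)O", 202.0),
        ]
        out = curate_records(recs)
        assert [r.id for r in out] == ["l", "d"]

    def test_survivor_order_is_input_order(self):
        recs = [
            CompoundRecord("c", "CCC", 160.0),
            CompoundRecord("a", "N", 204.0),
            CompoundRecord("b", "CCO", 188.0),
        ]
        out = curate_records(recs)
        assert [r.id for r in out] == ["c", "a", "b"]


def test_morgan_fingerprints_similar_molecules_score_high():
    fps = morgan_fingerprints(["CCCCO", "CCCCCO", "c1ccccc1"])
    close = tanimoto(fps[0], fps[1])
    far = tanimoto(fps[0], fps[2])
    assert close > far
    assert tanimoto(fps[0], fps[0]) == pytest.approx(1.0)
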