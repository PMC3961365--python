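"""Harmonic label propagation and sequential region-ranked prediction."""

import numpy as np
import pytest

from conftest import two_cluster_similarity
from seednet.propagate import (
    LabelPropagationModel,
    PropagationConfig,
    asymmetric_evidence_guard,
    fits,
    partition_matrix,
    sequential_predict,
)


def _chain_W():
    # L1 - U1 - U2 - L2 with unit weights (plus unit diagonal)
    W = np.eye(4)
    for i, j in [(0, 1), (1, 2), (2, 3)]:
        W[i, j] = W[j, i] = 1.0
    return W, ["L1", "U1", "U2", "L2"]


def test_partition_shapes_and_reassembly(rng):
    n = 6
    A = rng.random((n, n))
    W = (A + A.T) / 2
    index = [f"p{i}" for i in range(n)]
    labeled = {"p0", "p3"}
    W_LL, W_LU, W_UL, W_UU, L, U = partition_matrix(W, index, labeled)
    assert W_LL.shape == (2, 2) and W_LU.shape == (2, 4)
    assert W_UL.shape == (4, 2) and W_UU.shape == (4, 4)
    assert np.allclose(W_UL, W_LU.T)  # symmetry of W
    # reassembling the blocks in the reordered basis reproduces W
    order = [index.index(p) for p in L + U]
    reassembled = np.block([[W_LL, W_LU], [W_UL, W_UU]])
    assert np.allclose(reassembled, W[np.ix_(order, order)])


def test_partition_requires_both_sides():
    W = np.eye(2)
    with pytest.raises(ValueError):
        partition_matrix(W, ["a", "b"], {"a", "b"})
    with pytest.raises(ValueError):
        partition_matrix(W, ["a", "b"], set())


def test_fits_bridge_between_up_labels():
    W = np.eye(3)
    W[0, 1] = W[1, 0] = 1.0
    W[1, 2] = W[2, 1] = 1.0
    scores = fits(W, ["L1", "U", "L2"], {"L1": 1, "L2": 1})
    assert scores["U"] == pytest.approx(1.0)


def test_fits_balanced_tie():
    W = np.eye(3)
    W[0, 1] = W[1, 0] = 1.0
    W[1, 2] = W[2, 1] = 1.0
    scores = fits(W, ["L1", "U", "L2"], {"L1": 1, "L2": 0})
    assert scores["U"] == pytest.approx(0.5)


def test_fits_chain_hand_solution():
    W, index = _chain_W()
    scores = fits(W, index, {"L1": 1, "L2": 0})
    assert scores["U1"] == pytest.approx(2 / 3)
    assert scores["U2"] == pytest.approx(1 / 3)


def test_fits_matches_dense_oracle(rng):
    """On random connected systems with <= 10 unknowns the harmonic scores
    equal an independent dense linear solve to 1e-8."""
    for _ in range(25):
        n = int(rng.integers(4, 13))
        n_lab = int(rng.integers(1, 3))
        A = (rng.random((n, n)) < 0.6).astype(float) * rng.random((n, n))
        W = np.triu(A, 1)
        W = W + W.T + np.eye(n)
        for i in range(n - 1):  # ring keeps the system connected/nonsingular
            W[i, i + 1] = W[i + 1, i] = max(W[i, i + 1], 0.5)
        index = [f"p{i}" for i in range(n)]
        y = {index[i]: int(rng.integers(0, 2)) for i in range(n_lab)}
        scores = fits(W, index, y)
        # oracle: explicit block inversion in the permuted basis
        L = sorted(y)
        U = [p for p in index if p not in y]
        pos = {p: i for i, p in enumerate(index)}
        D = np.diag(W.sum(axis=1))
        ui = [pos[p] for p in U]
        li = [pos[p] for p in L]
        lhs = (D - W)[np.ix_(ui, ui)]
        rhs = W[np.ix_(ui, li)] @ np.array([y[p] for p in L], dtype=float)
        expected = np.linalg.solve(lhs, rhs)
        for p, e in zip(U, expected):
            assert scores[p] == pytest.approx(min(max(e, 0), 1), abs=1e-8)


def test_fits_maximum_principle(rng):
    """Harmonic scores stay within [min(y_L), max(y_L)] on random graphs."""
    for _ in range(100):
        n = int(rng.integers(5, 15))
        A = (rng.random((n, n)) < 0.4).astype(float)
        W = np.triu(A, 1)
        W = W + W.T + np.eye(n)
        index = [f"p{i}" for i in range(n)]
        n_lab = int(rng.integers(1, n - 1))
        y = {index[i]: int(rng.integers(0, 2)) for i in range(n_lab)}
        scores = fits(W, index, y)
        lo, hi = min(y.values()), max(y.values())
        for s in scores.values():
            if not np.isnan(s):
                assert lo - 1e-9 <= s <= hi + 1e-9


def test_fits_disconnected_unpredictable():
    W = np.eye(4)
    W[0, 1] = W[1, 0] = 1.0  # L - U1 ; U2 isolated from labels
    index = ["L", "U1", "U2", "U3"]
    with pytest.warns(UserWarning, match="no connection"):
        scores = fits(W, index, {"L": 1})
    assert scores["U1"] == pytest.approx(1.0)
    assert np.isnan(scores["U2"]) and np.isnan(scores["U3"])


def test_monotone_in_up_tie_strength():
    """Strengthening an unlabeled protein's tie to an UP label never lowers
    its score."""
    base = np.eye(3)
    base[1, 2] = base[2, 1] = 1.0  # U tied to DOWN label
    prev = -1.0
    for w in [0.1, 0.5, 1.0, 2.0]:
        W = base.copy()
        W[0, 1] = W[1, 0] = w  # tie to the UP label
        s = fits(W, ["UPL", "U", "DWL"], {"UPL": 1, "DWL": 0})["U"]
        assert s >= prev
        prev = s


def test_k_one_reduces_to_single_fits_pass():
    W, index = _chain_W()
    labels = {"L1": 1, "L2": 0}
    res = LabelPropagationModel(W, index, labels).fit(
        config=PropagationConfig(k=1)
    )
    raw = fits(W, index, labels)
    assert res.scores["U1"] == pytest.approx(raw["U1"])
    assert res.scores["U2"] == pytest.approx(raw["U2"])


def test_sequential_shrinkage_preserves_side_and_orders_regions():
    W, index = _chain_W()
    res = LabelPropagationModel(W, index, {"L1": 1, "L2": 0}).fit()
    # U1 and U2 tie on labeled connectivity (1 each); ID order breaks the tie
    assert res.regions["U1"] == 0 and res.regions["U2"] == 1
    # region 1 score shrinks toward 0.5 by 1/(1+l) but keeps its side
    assert res.scores["U1"] == pytest.approx(2 / 3)
    assert 1 / 3 < res.scores["U2"] < 0.5
    assert res.direction_side("U1") == "UP"
    assert res.direction_side("U2") == "DOWN"


def test_all_up_neighbors_all_up_calls():
    W = np.eye(4)
    W[0, 2] = W[2, 0] = 1.0
    W[0, 3] = W[3, 0] = 1.0
    W[1, 2] = W[2, 1] = 1.0
    W[1, 3] = W[3, 1] = 1.0
    res = LabelPropagationModel(
        W, ["La", "Lb", "U1", "U2"], {"La": 1, "Lb": 1}
    ).fit()
    # guard: no DOWN evidence, but these are UP calls so they survive
    assert res.calls == {"U1": "UP", "U2": "UP"}


def test_planted_two_cluster_recovery():
    """>= 90% of unlabeled proteins land on their planted side at 10%
    cross-cluster mixing; 100% with no mixing."""
    for mixing, floor in [(0.1, 0.9), (0.0, 1.0)]:
        W, index, labels, truth = two_cluster_similarity(mixing=mixing, seed=11)
        res = LabelPropagationModel(W, index, labels).fit()
        unlabeled = [p for p in index if p not in labels]
        correct = sum(
            1 for p in unlabeled if res.direction_side(p) == truth[p]
        )
        assert correct / len(unlabeled) >= floor


def test_asymmetric_evidence_guard():
    sup, msgs = asymmetric_evidence_guard({f"u{i}": 1 for i in range(21)} | {"d": 0})
    assert sup == {"DOWN"} and "DOWN" in msgs[0]
    sup, _ = asymmetric_evidence_guard({f"u{i}": 1 for i in range(3)})
    assert sup == {"DOWN"}
    sup, msgs = asymmetric_evidence_guard({"a": 1, "b": 1, "c": 0, "d": 0})
    assert sup == set() and msgs == []


def test_guard_suppresses_down_calls():
    W, index = _chain_W()
    res = sequential_predict(W, index, {"L1": 1, "L2": 0})
    # only one DOWN label: the DOWN side must abstain
    assert "DOWN" not in set(res.calls.values())
    assert any("DOWN" in w for w in res.warnings_)


def test_labeled_proteins_carry_no_score():
    W, index = _chain_W()
    res = sequential_predict(W, index, {"L1": 1, "L2": 0})
    assert set(res.scores) == {"U1", "U2"}
    frame = res.to_frame()
    mined = frame[frame.provenance == "mined"]
    assert mined.score.isna().all()
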