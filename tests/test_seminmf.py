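import numpy as np
import pytest

from stagemine.seminmf import (
    LabelConstraints,
    NumericalError,
    _init_factors,
    fit_semi_nmf,
    kkt_residual,
    load_result,
    objective_value,
    save_result,
    update_step,
)
from tests.conftest import random_problem


def _objective_oracle(X, F, H, G, cons):
    """Elementwise-summation re-implementation of the objective."""
    L, K = X.shape
    S = F.shape[1]
    total = 0.0
    for i in range(L):
        for j in range(K):
            recon = 0.0
            for s in range(S):
                for t in range(S):
                    recon += F[i, s] * H[s, t] * G[j, t]
            total += (X[i, j] - recon) ** 2
    for i in range(L):
        for s in range(S):
            total += cons.alpha * cons.c0[i] * (F[i, s] - cons.F0[i, s]) ** 2
    for j in range(K):
        for s in range(S):
            total += cons.beta * cons.c1[j] * (G[j, s] - cons.G0[j, s]) ** 2
    return total


def test_objective_matches_summation_oracle():
    rng = np.random.default_rng(3)
    X, cons = random_problem(3, L=6, K=4, S=2)
    F = rng.random((6, 2))
    H = rng.random((2, 2))
    G = rng.random((4, 2))
    assert objective_value(X, F, H, G, cons) == pytest.approx(
        _objective_oracle(X, F, H, G, cons), abs=1e-10
    )


def test_objective_zero_at_perfect_constrained_fit():
    rng = np.random.default_rng(0)
    F = rng.random((5, 3))
    H = rng.random((3, 3))
    G = rng.random((4, 3))
    X = F @ H @ G.T
    cons = LabelConstraints(F0=np.zeros((5, 3)), G0=np.zeros((4, 3)))
    assert objective_value(X, F, H, G, cons) == pytest.approx(0.0, abs=1e-12)


def test_objective_reduces_to_reconstruction_error_without_labels():
    rng = np.random.default_rng(1)
    X, _ = random_problem(1, L=8, K=5, S=3)
    F, H, G = rng.random((8, 3)), np.eye(3), rng.random((5, 3))
    cons = LabelConstraints(F0=np.zeros((8, 3)), G0=np.zeros((5, 3)))
    assert objective_value(X, F, H, G, cons) == pytest.approx(
        np.linalg.norm(X - F @ H @ G.T) ** 2
    )


def test_constraints_reject_non_one_hot_rows():
    bad = np.zeros((3, 2))
    bad[0] = [1, 1]
    with pytest.raises(ValueError, match="one-hot"):
        LabelConstraints(F0=bad, G0=np.zeros((2, 2)))
    with pytest.raises(ValueError, match="alpha"):
        LabelConstraints(F0=np.zeros((3, 2)), G0=np.zeros((2, 2)), alpha=0.0)


def test_update_preserves_nonnegativity_and_absorbs_zeros():
    X, cons = random_problem(5, L=12, K=8, S=3)
    F, H, G = _init_factors(X, cons, seed=5)
    F[2, 1] = 0.0
    for it in range(100):
        F, H, G = update_step(X, F, H, G, cons, iteration=it)
        assert np.all(F >= 0) and np.all(H >= 0) and np.all(G >= 0)
        assert F[2, 1] == 0.0  # multiplicative fixed point


@pytest.mark.parametrize("seed", range(10))
def test_single_update_never_increases_objective(seed):
    X, cons = random_problem(seed, L=20, K=10, S=3)
    F, H, G = _init_factors(X, cons, seed=seed)
    for it in range(25):
        before = objective_value(X, F, H, G, cons)
        F, H, G = update_step(X, F, H, G, cons, iteration=it)
        after = objective_value(X, F, H, G, cons)
        assert after <= before * (1 + 1e-8)


def test_projection_rule_differs_from_monotone():
    X, cons = random_problem(2, L=10, K=6, S=2)
    F, H, G = _init_factors(X, cons, seed=2)
    F1, _, _ = update_step(X, F, H, G, cons, update_rule="monotone")
    F2, _, _ = update_step(X, F, H, G, cons, update_rule="projection")
    assert not np.allclose(F1, F2)


def test_fit_fast_path_matches_update_step_sequence():
    X, cons = random_problem(7, L=20, K=12, S=3)
    result = fit_semi_nmf(X, cons, max_iter=50, tol=0.0, seed=7)
    F, H, G = _init_factors(X, cons, seed=7)
    for it in range(50):
        F, H, G = update_step(X, F, H, G, cons, iteration=it)
    assert np.allclose(result.F_raw, F, rtol=1e-9)
    assert np.allclose(result.H, H, rtol=1e-9)
    assert np.allclose(result.G_raw, G, rtol=1e-9)
    assert result.objective == pytest.approx(
        objective_value(X, F, H, G, cons), rel=1e-8
    )


def test_fit_loop_contract_and_row_normalization():
    X, cons = random_problem(4, L=15, K=9, S=3)
    result = fit_semi_nmf(X, cons, max_iter=5, tol=0.0, seed=4)
    assert result.iterations == 5
    assert len(result.objective_trace) == 5
    assert not result.converged
    assert np.allclose(result.F.sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(result.G.sum(axis=1), 1.0, atol=1e-9)


def test_fit_converges_before_cap_with_loose_tol():
    X, cons = random_problem(6, L=15, K=9, S=3)
    result = fit_semi_nmf(X, cons, max_iter=5000, tol=1e-4, seed=6)
    assert result.converged
    assert result.iterations < 5000


def test_kkt_residual_zero_at_exact_fit():
    rng = np.random.default_rng(9)
    F = rng.random((6, 3))
    H = rng.random((3, 3))
    G = rng.random((5, 3))
    X = F @ H @ G.T
    cons = LabelConstraints(F0=np.zeros((6, 3)), G0=np.zeros((5, 3)))
    assert kkt_residual(X, F, H, G, cons) == pytest.approx(0.0, abs=1e-10)


def test_kkt_residual_small_after_tight_fit():
    X, cons = random_problem(11, L=30, K=15, S=3)
    result = fit_semi_nmf(X, cons, max_iter=500000, tol=1e-10, seed=11)
    scaled = result.kkt_residual_F / (X * X).sum()
    assert scaled < 1e-6


def test_unsupervised_reduction_matches_generic_nmf_within_5pct():
    from sklearn.decomposition import NMF

    errors = []
    for seed in range(3):
        rng = np.random.default_rng(seed)
        X = rng.random((40, 20))
        X /= X.sum(axis=1, keepdims=True)
        cons = LabelConstraints(F0=np.zeros((40, 3)), G0=np.zeros((20, 3)))
        r = fit_semi_nmf(X, cons, max_iter=20000, tol=1e-12, seed=seed)
        err_tri = np.linalg.norm(X - r.F_raw @ r.H @ r.G_raw.T)
        model = NMF(n_components=3, init="random", random_state=seed,
                    max_iter=5000, tol=1e-10)
        W = model.fit_transform(X)
        err_two = np.linalg.norm(X - W @ model.components_)
        errors.append(abs(err_tri - err_two) / err_two)
    assert max(errors) < 0.05


def test_numpy_fallback_loop_matches_compiled_path(monkeypatch):
    import stagemine.seminmf as sm

    X, cons = random_problem(13, L=15, K=9, S=3)
    fast = fit_semi_nmf(X, cons, max_iter=40, tol=0.0, seed=13)
    monkeypatch.setattr(sm, "_HAVE_NUMBA", False)
    slow = fit_semi_nmf(X, cons, max_iter=40, tol=0.0, seed=13)
    assert np.allclose(fast.F_raw, slow.F_raw, rtol=1e-9)
    assert np.allclose(fast.G_raw, slow.G_raw, rtol=1e-9)
    assert np.allclose(fast.objective_trace, slow.objective_trace, rtol=1e-8)


def test_nan_input_raises_numerical_error():
    X, cons = random_problem(8, L=10, K=6, S=2)
    X[0, 0] = np.inf
    with pytest.raises(NumericalError, match="iteration"):
        F, H, G = _init_factors(X, cons, seed=8)
        for it in range(5):
            F, H, G = update_step(X, F, H, G, cons, iteration=it)


def test_save_load_round_trip(tmp_path):
    X, cons = random_problem(12, L=10, K=6, S=2)
    result = fit_semi_nmf(X, cons, max_iter=20, tol=0.0, seed=12)
    save_result(result, tmp_path / "factors")
    back = load_result(tmp_path / "factors")
    assert np.allclose(back.F, result.F)
    assert np.allclose(back.H, result.H)
    assert np.allclose(back.G, result.G)
    assert back.iterations == result.iterations
    assert back.seed == result.seed
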