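import numpy as np
import pytest

from plmmkit import (
    SimSpec,
    build_preconditioner,
    compute_grm,
    design_from_arrays,
    eigendecompose,
    estimate_eta,
    profile_loglik,
    rotate,
    simulate_genotypes,
    simulate_phenotype,
)
from plmmkit.exceptions import DegenerateDataError, SingularityError

from oracles import dense_restricted_loglik


def _eig_from(rng, n=60, p=150):
    X = rng.normal(size=(n, p))
    d = design_from_arrays(X, rng.normal(size=n))
    K = compute_grm(d)
    return d, K, eigendecompose(K, p=d.n_penalized)


def test_null_outcome_gives_small_eta(rng):
    """iid outcomes on an unstructured K: η̂ should be near 0 on average."""
    etas = []
    for _ in range(20):
        X = rng.normal(size=(200, 400))
        d = design_from_arrays(X, rng.normal(size=200))
        eig = eigendecompose(compute_grm(d))
        etas.append(estimate_eta(eig, d.y).eta)
    assert np.mean(etas) < 0.15


def test_pure_structure_outcome_gives_large_eta(rng):
    """y = u with u ~ N(0, K): η̂ should approach 1 on average."""
    etas = []
    for _ in range(20):
        X = rng.normal(size=(100, 300))
        d = design_from_arrays(X, np.zeros(100))
        eig = eigendecompose(compute_grm(d))
        u = eig.U @ (np.sqrt(np.clip(eig.S, 0, None)) * rng.standard_normal(100))
        etas.append(estimate_eta(eig, u).eta)
    assert np.mean(etas) > 0.85


def test_eta_matches_dense_likelihood_oracle(rng):
    """Grid-searched η̂ agrees with a dense-matrix GLS likelihood evaluation."""
    X = rng.normal(size=(30, 80))
    d = design_from_arrays(X, np.zeros(30))
    K = compute_grm(d)
    eig = eigendecompose(K)
    u = eig.U @ (np.sqrt(np.clip(0.6 * eig.S, 0, None)) * rng.standard_normal(30))
    y = u + np.sqrt(0.4) * rng.standard_normal(30)
    vc = estimate_eta(eig, y)
    grid = np.linspace(0, 0.999, 400)
    W = np.ones((30, 1))
    dense = [dense_restricted_loglik(e, K, y, W) for e in grid]
    eta_dense = grid[int(np.argmax(dense))]
    assert abs(vc.eta - eta_dense) < 0.02
    # rotated-basis likelihood equals the dense evaluation pointwise
    yr, Wr = eig.U.T @ y, eig.U.T @ W
    for e in (0.0, 0.3, 0.7):
        np.testing.assert_allclose(
            profile_loglik(e, eig.S, yr, Wr), dense_restricted_loglik(e, K, y, W),
            rtol=1e-8,
        )


def test_eta_recovery_moderate(rng):
    """Light recovery check: simulated η=0.5 recovered within 0.2 on average."""
    spec = SimSpec(n_samples=150, n_features=600, n_causal=0, eta_true=0.5, seed=21)
    g = simulate_genotypes(spec)
    d = design_from_arrays(np.asarray(g.dosages), np.zeros(spec.n_samples),
                           feature_ids=list(g.feature_ids))
    eig = eigendecompose(compute_grm(d), p=d.n_penalized)
    errs = []
    for _ in range(5):
        y, _ = simulate_phenotype(g, spec, rng=rng)
        errs.append(abs(estimate_eta(eig, y).eta - 0.5))
    assert np.mean(errs) < 0.2


def test_profile_maximum_beats_endpoints(rng):
    _, K, eig = _eig_from(rng)
    u = eig.U @ (np.sqrt(np.clip(0.5 * eig.S, 0, None)) * rng.standard_normal(eig.n))
    y = u + np.sqrt(0.5) * rng.standard_normal(eig.n)
    vc = estimate_eta(eig, y)
    yr, Wr = eig.U.T @ y, eig.U.T @ np.ones((eig.n, 1))
    ll_hat = profile_loglik(vc.eta, eig.S, yr, Wr)
    assert ll_hat >= profile_loglik(0.0, eig.S, yr, Wr) - 1e-8
    assert ll_hat >= profile_loglik(0.99, eig.S, yr, Wr) - 1e-8


def test_variance_component_consistency(rng):
    _, _, eig = _eig_from(rng)
    y = rng.normal(size=eig.n)
    vc = estimate_eta(eig, y)
    assert 0.0 <= vc.eta <= 1.0
    if vc.sigma2_total > 0:
        np.testing.assert_allclose(vc.eta, vc.sigma2_s / vc.sigma2_total, atol=1e-10)


def test_constant_outcome_rejected(rng):
    _, _, eig = _eig_from(rng)
    with pytest.raises(DegenerateDataError):
        estimate_eta(eig, np.ones(eig.n))


class TestPreconditioner:
    def test_eta_zero_is_orthogonal_rotation(self, rng):
        _, _, eig = _eig_from(rng, n=20, p=40)
        pc = build_preconditioner(eig, 0.0)
        np.testing.assert_allclose(pc.w, 1.0)
        F = pc.matrix()
        np.testing.assert_allclose(F @ F.T, np.eye(20), atol=1e-10)

    def test_weight_arithmetic(self):
        from plmmkit import EigenRelatedness

        eig = EigenRelatedness(U=np.eye(2), S=np.array([2.0, 1.0]), n=2, p=5)
        pc = build_preconditioner(eig, 1.0)
        np.testing.assert_allclose(pc.w[0], 1 / np.sqrt(2))

    def test_whitening_identity_on_grid(self, rng):
        _, K, eig = _eig_from(rng, n=40, p=100)
        for eta in [0.0, 0.2, 0.5, 0.9, 0.99]:
            pc = build_preconditioner(eig, eta)
            F = pc.matrix()
            Sigma = eta * K + (1 - eta) * np.eye(40)
            np.testing.assert_allclose(F @ Sigma @ F.T, np.eye(40), atol=1e-8)

    def test_singular_sigma_raises(self):
        from plmmkit import EigenRelatedness

        eig = EigenRelatedness(U=np.eye(2), S=np.array([1.0, 0.0]), n=2, p=5)
        with pytest.raises(SingularityError):
            build_preconditioner(eig, 1.0)

    def test_rotated_intercept_not_constant(self, rng):
        _, _, eig = _eig_from(rng, n=20, p=40)
        pc = build_preconditioner(eig, 0.7)
        ones = np.ones(20)
        rotated = pc.apply(ones)
        assert np.std(rotated) > 1e-6

    def test_rotation_whitens_outcome_covariance(self, rng):
        """Empirical covariance of ỹ over many draws from Σ_unit is near identity."""
        n = 10
        A = rng.normal(size=(n, 25))
        d = design_from_arrays(A, np.zeros(n))
        K = compute_grm(d)
        eig = eigendecompose(K)
        eta = 0.6
        pc = build_preconditioner(eig, eta)
        L = np.linalg.cholesky(eta * K + (1 - eta) * np.eye(n) + 1e-12 * np.eye(n))
        draws = np.array([pc.apply(L @ rng.standard_normal(n)) for _ in range(2000)])
        C = draws.T @ draws / 2000
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 0.1
        np.testing.assert_allclose(np.diag(C), 1.0, atol=0.15)
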