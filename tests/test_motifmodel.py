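import numpy as np
import pytest

from motifpoim import motifmodel as mm
from motifpoim.initeval import consensus, greedy_pwm_init, MotifRegion, one_hot_pwm
from motifpoim.motifmodel import (
    FitSpec,
    Ppm,
    dependency_matrix,
    fit,
    gaussian_position,
    matched_lambda,
    motif_weight,
    motifpoim_bruteforce,
    motifpoim_reduced_sum,
    objective,
    objective_gradient,
    reconstruct_motifpoim,
    subppms,
    weight_matrix,
)
from motifpoim.poim import Poim
from motifpoim.wdsvm import po_code


def sharp_ppm(motif, mu, sigma=0.5, lam=1.0, eps=1e-3):
    r = np.clip(one_hot_pwm(motif), eps, 1.0)
    r /= r.sum(axis=0, keepdims=True)
    return Ppm(r=r, mu=float(mu), sigma=sigma, lam=lam)


def random_ppm(rng, k, L, sigma=None):
    r = rng.dirichlet(np.ones(4), size=k).T
    return Ppm(
        r=r,
        mu=float(rng.uniform(1, L - k + 1)),
        sigma=float(rng.uniform(0.5, 2.0)) if sigma is None else sigma,
        lam=float(rng.uniform(0.2, 2.0)),
    )


class TestPpmBasics:
    def test_invariants(self):
        with pytest.raises(ValueError):
            Ppm(r=np.full((4, 3), 0.3), mu=1.0, sigma=1.0)  # columns sum 1.2
        with pytest.raises(ValueError):
            Ppm(r=np.full((4, 3), 0.25), mu=1.0, sigma=0.0)
        with pytest.raises(ValueError):
            Ppm(r=np.full((4, 3), 0.25), mu=0.5, sigma=1.0)

    def test_motif_weight_uniform_pwm_is_oligomer_independent(self):
        m = Ppm(r=np.full((4, 3), 0.25), mu=4.0, sigma=1.0)
        g = gaussian_position(2, 4.0, 1.0)
        for z in ("AAA", "CGT", "TTT"):
            assert motif_weight(m, z, 2) == pytest.approx(g * 0.25**3)

    def test_motif_weight_one_hot_peak(self):
        m = sharp_ppm("AC", 5, sigma=0.8)
        peak = motif_weight(m, "AC", 5)
        assert peak == pytest.approx(1 / np.sqrt(2 * np.pi * 0.8**2), rel=1e-2)
        assert motif_weight(m, "GG", 5) < 1e-4 * peak

    def test_subppm_decomposition(self):
        rng = np.random.default_rng(0)
        m = random_ppm(rng, 12, 30)
        subs = subppms(m, 3)
        assert len(subs) == 10
        assert [s.mu for s in subs] == [m.mu + d for d in range(10)]
        for d, s in enumerate(subs):
            assert np.array_equal(s.r, m.r[:, d : d + 3])
        only = subppms(m, 12)
        assert len(only) == 1 and np.array_equal(only[0].r, m.r)
        with pytest.raises(ValueError):
            subppms(m, 13)


class TestDependencyAndWeightMatrices:
    def test_dependency_matrix_values_ktilde2(self):
        y = po_code("AC", 1, 2)
        A = dependency_matrix(y, 2)
        assert A.shape == (16, 3)
        assert A[y, 1] == pytest.approx(15 / 16)  # full overlap with itself
        gg = po_code("GG", 1, 2)
        assert A[gg, 1] == pytest.approx(-1 / 16)  # incompatible at zero offset
        # offset -1: z = ?A compatible (c=1), others -1/16
        ta = po_code("TA", 1, 2)
        assert A[ta, 0] == pytest.approx((4 - 1) / 16)
        tg = po_code("TG", 1, 2)
        assert A[tg, 0] == pytest.approx(-1 / 16)

    def test_weight_matrix_boundary_columns_are_zero(self):
        m = sharp_ppm("ACG", 2, sigma=1.0)
        sub = subppms(m, 3)[0]
        C = weight_matrix(0, 1, sub, 10)
        # offsets addressing positions <= 0 must carry zero weight
        assert np.all(C[:, :2] == 0)
        assert np.any(C[:, 2] != 0)

    def test_weight_matrix_uniform_pwm_constant_in_oligomer(self):
        m = Ppm(r=np.full((4, 2), 0.25), mu=4.0, sigma=1.0)
        sub = subppms(m, 2)[0]
        C = weight_matrix(0, 4, sub, 10)
        for col in range(C.shape[1]):
            nz = C[:, col]
            assert np.allclose(nz, nz[0])

    def test_weights_vanish_outside_six_sigma(self):
        m = sharp_ppm("AC", 10, sigma=0.5)
        sub = subppms(m, 2)[0]
        V = mm.sub_weight_table(sub, 30)
        far = np.abs(np.arange(1, 30) - 10) > 6 * 0.5
        assert np.max(V[:, far]) <= 1e-7 * np.max(V)


class TestReconstruction:
    def test_uniform_pwm_reconstructs_to_zero(self):
        m = Ppm(r=np.full((4, 3), 0.25), mu=3.0, sigma=1.0)
        R = reconstruct_motifpoim(m, 2, 8, truncate=False)
        assert np.max(np.abs(R)) < 1e-12

    def test_one_hot_argmax_at_planted_location(self):
        m = sharp_ppm("AC", 3, sigma=0.5)
        R = reconstruct_motifpoim(m, 2, 8, truncate=False)
        flat = np.argmax(R)
        y, j0 = divmod(flat, R.shape[1])
        assert (y, j0 + 1) == (po_code("AC", 1, 2), 3)

    def test_reconstruction_triple_equivalence(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 5))
            L = int(rng.integers(k + 1, 8))
            m = random_ppm(rng, k, L)
            R_inner = reconstruct_motifpoim(m, 2, L, truncate=False)
            R_sum = motifpoim_reduced_sum(m, 2, L)
            R_enum = motifpoim_bruteforce(m, 2, L)
            assert np.max(np.abs(R_inner - R_sum)) < 1e-9
            assert np.max(np.abs(R_inner - R_enum)) < 1e-9

    def test_truncation_bias_is_small_for_reasonable_sigma(self, rng):
        for _ in range(10):
            m = random_ppm(rng, 4, 20, sigma=float(rng.uniform(0.5, 2.0)))
            full = reconstruct_motifpoim(m, 2, 20, truncate=False)
            trunc = reconstruct_motifpoim(m, 2, 20, truncate=True)
            assert np.max(np.abs(full - trunc)) <= 0.005 * np.max(np.abs(full))

    def test_brute_force_refuses_large_L(self):
        m = sharp_ppm("AC", 2)
        with pytest.raises(ValueError):
            motifpoim_bruteforce(m, 2, 9)


class TestObjective:
    def test_exact_match_gives_zero(self, rng):
        L = 10
        m = random_ppm(rng, 4, L)
        R = reconstruct_motifpoim(m, 2, L, truncate=False)
        Q = Poim(order=2, values=m.lam * R, L=L)
        assert objective([m], Q) == pytest.approx(0.0, abs=1e-18)

    def test_zero_lambda_leaves_q_norm(self, rng):
        L = 10
        m = random_ppm(rng, 4, L)
        m = Ppm(r=m.r, mu=m.mu, sigma=m.sigma, lam=0.0)
        Qv = rng.normal(size=(16, L - 1))
        Q = Poim(order=2, values=Qv, L=L)
        assert objective([m], Q) == pytest.approx(0.5 * np.sum(Qv**2))

    def test_quadratic_scaling_of_residual(self, rng):
        L = 10
        m = random_ppm(rng, 4, L)
        R = reconstruct_motifpoim(m, 2, L, truncate=False)
        Q1 = Poim(order=2, values=m.lam * R + 1.0, L=L)
        Q2 = Poim(order=2, values=m.lam * R + 2.0, L=L)
        assert objective([m], Q2) == pytest.approx(4 * objective([m], Q1))

    def test_permutation_symmetry(self, rng):
        L = 12
        a, b = random_ppm(rng, 4, L), random_ppm(rng, 4, L)
        Qv = rng.normal(size=(16, L - 1))
        Q = Poim(order=2, values=Qv, L=L)
        assert objective([a, b], Q) == pytest.approx(objective([b, a], Q))

    @pytest.mark.parametrize("normalize", [True, False])
    def test_analytic_gradient_matches_finite_differences(self, rng, normalize):
        L = 12
        Qv = rng.normal(size=(16, L - 1)) * 0.1
        Q = Poim(order=2, values=Qv, L=L)
        ppms = [random_ppm(rng, 4, L), random_ppm(rng, 6, L)]
        ks = [m.k for m in ppms]
        x0 = mm._pack(ppms)
        mask = np.ones(Qv.shape[1], dtype=bool)
        groups = [[0, 1]]
        _, g = mm._value_and_grad(x0, ks, Q, groups, mask, normalize)
        h = 1e-6
        num = np.zeros_like(x0)
        for i in range(len(x0)):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += h
            xm[i] -= h
            fp, _ = mm._value_and_grad(xp, ks, Q, groups, mask, normalize)
            fmn, _ = mm._value_and_grad(xm, ks, Q, groups, mask, normalize)
            num[i] = (fp - fmn) / (2 * h)
        rel = np.abs(g - num) / np.maximum(1e-8, np.abs(g) + np.abs(num))
        assert rel.max() < 1e-5


class TestFit:
    def test_fixed_point_at_global_minimum(self, rng):
        L = 14
        truth = sharp_ppm("ACGT", 6, sigma=0.8, lam=0.5)
        R = reconstruct_motifpoim(truth, 2, L, truncate=False)
        Q = Poim(order=2, values=truth.lam * R, L=L)
        res = fit(Q, FitSpec(K=(4,)), [truth])
        assert res.f_opt < 1e-10
        assert consensus(res.ppms[0]) == "ACGT"
        assert res.ppms[0].mu == pytest.approx(6.0, abs=0.05)

    def test_parameter_recovery_from_greedy_init(self):
        recovered = 0
        trials = 20
        for t in range(trials):
            rng = np.random.default_rng(1000 + t)
            k = int(rng.integers(3, 7))
            L = 20
            mu = int(rng.integers(2, L - k))
            letters = "".join("ACGT"[c] for c in rng.integers(0, 4, k))
            truth = sharp_ppm(letters, mu, sigma=0.7, lam=1.0)
            Q = Poim(
                order=2,
                values=reconstruct_motifpoim(truth, 2, L, truncate=False),
                L=L,
            )
            Q1 = Poim(
                order=1,
                values=reconstruct_motifpoim(truth, 1, L, truncate=False),
                L=L,
            )
            init = greedy_pwm_init(Q1, MotifRegion(start=mu, length=k, score=0.0))
            init = Ppm(
                r=init.r, mu=init.mu, sigma=init.sigma, lam=matched_lambda(Q, init)
            )
            res = fit(Q, FitSpec(K=(k,)), [init])
            got = res.ppms[0]
            if consensus(got) == letters and abs(got.mu - mu) <= 0.5:
                recovered += 1
        assert recovered >= 0.9 * trials

    def test_init_length_mismatch_rejected(self, rng):
        Q = Poim(order=2, values=np.zeros((16, 9)), L=10)
        with pytest.raises(ValueError):
            fit(Q, FitSpec(K=(5,)), [random_ppm(rng, 4, 10)])

    def test_fitspec_validation(self):
        with pytest.raises(ValueError):
            FitSpec(K=(6,), ktilde=4)
        with pytest.raises(ValueError):
            FitSpec(K=(2,), ktilde=3)
        with pytest.raises(ValueError):
            FitSpec(K=(6, 8), T=(1,))


def test_matched_lambda_recovers_scale(rng):
    L = 12
    m = random_ppm(rng, 4, L)
    R = reconstruct_motifpoim(m, 2, L, truncate=False)
    Q = Poim(order=2, values=3.5 * R, L=L)
    assert matched_lambda(Q, m) == pytest.approx(3.5, rel=1e-10)
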