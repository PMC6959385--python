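"""Exact OU theory: drift assembly, Poisson solutions, variances, spectra,
projections, transforms and the critically damped preconditioner."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrlangevin import (
    GaussianTarget,
    PerturbationConfig,
    QuadraticObservable,
    asymptotic_variance,
    build_drift_system,
    curvature_at_zero,
    drift_spectrum,
    generator_spectrum,
    limiting_variance,
    observable_mean,
    project_to_kernel,
    solve_poisson_quadratic,
    suggest_preconditioner,
    transform_to_unit,
)
from nrlangevin._validate import ValidationError
from nrlangevin.targets import random_antisymmetric, random_observable, random_spd


def finite_difference_generator(system, chi, x, h=0.05):
    # central differences are exact for quadratics, so a large h minimises roundoff
    """Brute-force evaluation of L·chi = -Bx·grad(chi) + Tr(Q Hess(chi)) at x."""
    n = x.size
    grad = np.zeros(n)
    hess = np.zeros((n, n))
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h
        grad[i] = (chi(x + ei) - chi(x - ei)) / (2 * h)
        for j in range(n):
            ej = np.zeros(n)
            ej[j] = h
            hess[i, j] = (
                chi(x + ei + ej) - chi(x + ei - ej) - chi(x - ei + ej) + chi(x - ei - ej)
            ) / (4 * h * h)
    return -(system.B @ x) @ grad + np.trace(system.Q @ hess)


class TestBuildDriftSystem:
    def test_unperturbed_blocks(self):
        target = GaussianTarget.standard(2)
        pert = PerturbationConfig.unit(2, gamma=2.0)
        sys = build_drift_system(target, pert)
        I = np.eye(2)
        assert np.allclose(sys.B[:2, :2], 0)
        assert np.allclose(sys.B[:2, 2:], -I)
        assert np.allclose(sys.B[2:, :2], I)
        assert np.allclose(sys.B[2:, 2:], 2.0 * I)
        assert np.allclose(sys.Q[2:, 2:], 2.0 * I)
        assert np.allclose(sys.Q[:2, :], 0)

    def test_general_case_is_ergodic(self, rotation_J):
        S = np.diag([4.0, 1.0])
        target = GaussianTarget(S)
        pert = PerturbationConfig.coupled(target, gamma=2.0, mu=1.0, J1=0.5 * rotation_J)
        sys = build_drift_system(target, pert)
        assert sys.spectral_abscissa() > 0
        assert np.allclose(sys.Sigma_inf[:2, :2], np.linalg.inv(S))
        assert np.allclose(sys.Sigma_inf[2:, 2:], S)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), d=st.integers(1, 5))
    def test_lyapunov_identity_property(self, seed, d):
        """B Sigma_inf + Sigma_inf B^T = 2Q for arbitrary admissible parameters."""
        rng = np.random.default_rng(seed)
        target = GaussianTarget(random_spd(rng, d))
        pert = PerturbationConfig(
            J1=random_antisymmetric(rng, d), J2=random_antisymmetric(rng, d),
            mu=rng.uniform(-2, 2), nu=rng.uniform(-2, 2),
            M=random_spd(rng, d), Gamma=random_spd(rng, d))
        sys = build_drift_system(target, pert)
        assert sys.lyapunov_residual() < 1e-10 * max(np.abs(sys.Q).max(), 1.0)

    def test_rejects_dimension_mismatch(self):
        target = GaussianTarget.standard(3)
        pert = PerturbationConfig.unit(2, gamma=1.0)
        with pytest.raises(ValidationError):
            build_drift_system(target, pert)

    def test_rejects_non_spd_inputs(self):
        with pytest.raises(ValidationError):
            GaussianTarget(np.diag([1.0, -1.0]))
        with pytest.raises(ValidationError):
            PerturbationConfig.unit(2, gamma=-1.0)


class TestObservableMean:
    @pytest.mark.parametrize(
        "K, S, c, expected",
        [
            (np.eye(2), np.eye(2), 0.0, 2.0),
            (np.diag([2.0, 1.0]), np.eye(2), -3.0, 0.0),
            (np.diag([2.0, 1.0]), np.diag([4.0, 1.0]), 0.0, 1.5),
        ],
    )
    def test_gaussian_means(self, K, S, c, expected):
        obs = QuadraticObservable(K=K, l=np.zeros(2), c=c)
        assert observable_mean(GaussianTarget(S), obs) == pytest.approx(expected)


class TestPoissonQuadratic:
    def test_linear_observable_hand_solution(self):
        """d=1, f=q: the 2x2 system gives D = (gamma, 1)."""
        gamma = 2.0
        target = GaussianTarget.standard(1)
        sys = build_drift_system(target, PerturbationConfig.unit(1, gamma))
        sol = solve_poisson_quadratic(sys, QuadraticObservable.linear([1.0]))
        assert np.allclose(sol.D, [gamma, 1.0], atol=1e-12)

    @pytest.mark.parametrize("gamma", [1.5, 2.0, 3.0])
    def test_quadratic_observable_hand_solution(self, gamma):
        """d=1, f=q^2-1: C has entries (gamma/2 + 1/(2 gamma), +/-1/2, 1/(2 gamma))."""
        target = GaussianTarget.standard(1)
        sys = build_drift_system(target, PerturbationConfig.unit(1, gamma))
        obs = QuadraticObservable(K=[[1.0]], l=[0.0], c=-1.0)
        sol = solve_poisson_quadratic(sys, obs)
        assert sol.Cmat[0, 0] == pytest.approx(gamma / 2 + 1 / (2 * gamma), abs=1e-12)
        assert abs(sol.Cmat[0, 1]) == pytest.approx(0.5, abs=1e-12)
        assert sol.Cmat[1, 1] == pytest.approx(1 / (2 * gamma), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_generator_oracle(self, seed):
        """-L chi evaluated by finite differences matches f - pi(f) pointwise."""
        rng = np.random.default_rng(seed)
        d = 2
        target = GaussianTarget(random_spd(rng, d))
        pert = PerturbationConfig.coupled(
            target, gamma=2.0, mu=0.7, J1=random_antisymmetric(rng, d))
        obs = random_observable(rng, d)
        sys = build_drift_system(target, pert)
        sol = solve_poisson_quadratic(sys, obs)
        mean = observable_mean(target, obs)

        def chi(x):
            return x @ sol.Cmat @ x + sol.D @ x

        for _ in range(20):
            x = rng.standard_normal(2 * d)
            q = x[:d]
            f_centered = obs(q) - mean
            lhs = -finite_difference_generator(sys, chi, x)
            assert lhs == pytest.approx(f_centered, abs=1e-6 * (1 + abs(f_centered)))

    def test_non_ergodic_system_rejected(self):
        target = GaussianTarget.standard(1)
        sys = build_drift_system(target, PerturbationConfig.unit(1, 1.0))
        broken = type(sys)(B=-sys.B, Q=sys.Q, Sigma_inf=sys.Sigma_inf)
        with pytest.raises(ValidationError):
            solve_poisson_quadratic(broken, QuadraticObservable.linear([1.0]))


class TestAsymptoticVariance:
    @pytest.mark.parametrize("gamma", [1.5, 2.0, 3.0])
    def test_closed_forms_d1(self, gamma):
        """sigma^2(f=q) = gamma and sigma^2(f=q^2) = gamma + 1/gamma, exactly."""
        target = GaussianTarget.standard(1)
        pert = PerturbationConfig.unit(1, gamma)
        lin = asymptotic_variance(target, pert, QuadraticObservable.linear([1.0]))
        quad = asymptotic_variance(
            target, pert, QuadraticObservable(K=[[1.0]], l=[0.0], c=0.0))
        assert lin == pytest.approx(gamma, abs=1e-10)
        assert quad == pytest.approx(gamma + 1 / gamma, abs=1e-10)

    @pytest.mark.parametrize("mu", [0.5, 1.0, 2.0])
    def test_even_in_mu(self, mu, unit_target_2d, worked_observable):
        J = np.array([[0.0, 1.0], [-1.0, 0.0]])
        plus = asymptotic_variance(
            unit_target_2d, PerturbationConfig.unit(2, 2.0, mu=mu, J=J), worked_observable)
        minus = asymptotic_variance(
            unit_target_2d, PerturbationConfig.unit(2, 2.0, mu=-mu, J=J), worked_observable)
        assert plus == pytest.approx(minus, rel=1e-10)

    def test_nonnegative_and_constant_free(self, unit_target_2d, worked_observable):
        pert = PerturbationConfig.unit(2, 2.5, mu=1.3,
                                       J=np.array([[0.0, 1.0], [-1.0, 0.0]]))
        base = asymptotic_variance(unit_target_2d, pert, worked_observable)
        shifted = QuadraticObservable(K=worked_observable.K, l=worked_observable.l, c=7.0)
        assert base >= 0
        assert asymptotic_variance(unit_target_2d, pert, shifted) == pytest.approx(base)


class TestCurvatureAtZero:
    def test_worked_example_value(self, worked_observable):
        J = np.array([[0.0, 1.0], [-1.0, 0.0]])
        first, second = curvature_at_zero(worked_observable, J, gamma=2.0)
        assert first == 0.0
        assert second == pytest.approx(-23.0, abs=1e-12)

    def test_commuting_case_flat(self):
        J = np.array([[0.0, 1.0], [-1.0, 0.0]])
        obs = QuadraticObservable(K=np.eye(2), l=np.zeros(2))  # [J, I] = 0, l = 0
        assert curvature_at_zero(obs, J, gamma=3.0) == (0.0, 0.0)

    @pytest.mark.parametrize("gamma", [2.0, 2.5])
    def test_matches_finite_differences(self, gamma, unit_target_2d, worked_observable):
        """Closed-form curvature equals a 5-point FD of the Sylvester variance."""
        J = np.array([[0.0, 1.0], [-1.0, 0.0]])

        def s2(mu):
            pert = PerturbationConfig.unit(2, gamma, mu=mu, J=J)
            return asymptotic_variance(unit_target_2d, pert, worked_observable)

        h = 1e-3
        fd2 = (-s2(2 * h) + 16 * s2(h) - 30 * s2(0.0) + 16 * s2(-h) - s2(-2 * h)) / (
            12 * h * h)
        _, second = curvature_at_zero(worked_observable, J, gamma)
        assert fd2 == pytest.approx(second, rel=1e-4)

    def test_negative_for_large_friction(self, worked_observable):
        J = np.array([[0.0, 1.0], [-1.0, 0.0]])
        _, second = curvature_at_zero(worked_observable, J, gamma=1.5)  # > sqrt(2)
        assert second < 0

    def test_rejects_non_antisymmetric(self, worked_observable):
        with pytest.raises(ValidationError):
            curvature_at_zero(worked_observable, np.eye(2), gamma=2.0)


class TestSpectra:
    def test_closed_form_double_pair(self, rotation_J):
        pert = PerturbationConfig.unit(2, 2.0, mu=1.0, J=rotation_J)
        res = drift_spectrum(pert)
        assert res.closed_form
        eigs = np.sort_complex(res.eigenvalues)
        assert np.allclose(eigs, [1 - 1j, 1 - 1j, 1 + 1j, 1 + 1j])

    def test_closed_form_d1(self):
        res = drift_spectrum(PerturbationConfig.unit(1, 3.0))
        expected = sorted([(3 - np.sqrt(5)) / 2, (3 + np.sqrt(5)) / 2])
        assert np.allclose(np.sort(res.eigenvalues.real), expected)
        assert np.allclose(res.eigenvalues.imag, 0)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("gamma", [1.2, 3.7])
    def test_closed_form_matches_numerics(self, seed, gamma):
        """Both friction branches (gamma < 2 and > 2) agree with brute-force eig."""
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 5))
        J = random_antisymmetric(rng, d)
        mu = float(rng.uniform(0.1, 3.0))
        pert = PerturbationConfig.unit(d, gamma, mu=mu, J=J)
        res = drift_spectrum(pert)
        assert res.closed_form
        sys_eigs = np.linalg.eigvals(
            build_drift_system(GaussianTarget.standard(d), pert).B)
        a = sorted(res.eigenvalues, key=lambda z: (round(z.real, 8), round(z.imag, 8)))
        b = sorted(sys_eigs, key=lambda z: (round(z.real, 8), round(z.imag, 8)))
        assert np.abs(np.array(a) - np.array(b)).max() < 1e-10

    @pytest.mark.parametrize("mu", [0.0, 0.5, 2.0, 10.0])
    def test_spectral_bound_unaffected_by_perturbation(self, mu, rotation_J):
        """Equal perturbations shift eigenvalues only along the imaginary axis."""
        pert = PerturbationConfig.unit(2, 3.0, mu=mu, J=rotation_J)
        base = drift_spectrum(PerturbationConfig.unit(2, 3.0, mu=0.0, J=rotation_J))
        assert drift_spectrum(pert).spectral_bound == pytest.approx(
            base.spectral_bound, abs=1e-12)

    def test_generator_spectrum_sums(self, rotation_J):
        pert = PerturbationConfig.unit(1, 2.0, mu=1.0)
        order1 = generator_spectrum(pert, 1)
        drift = drift_spectrum(pert).eigenvalues
        assert 0 in order1
        for lam in drift:
            assert np.min(np.abs(order1 - (-lam))) < 1e-9
        order2 = generator_spectrum(pert, 2)
        # gamma=2, d=1: sigma(B) = {1 (double)} so sums give {0, -1, -2}
        assert np.allclose(np.sort(order2.real), [-2, -1, 0], atol=1e-9)
        assert np.allclose(order2.imag, 0, atol=1e-9)


class TestKernelProjection:
    def test_zero_J_is_identity(self, worked_observable):
        proj = project_to_kernel(worked_observable, np.zeros((2, 2)))
        assert np.allclose(proj.K, worked_observable.K)
        assert np.allclose(proj.l, worked_observable.l)

    def test_rotation_commutant_is_trace_part(self, worked_observable, rotation_J):
        proj = project_to_kernel(worked_observable, rotation_J)
        assert np.allclose(proj.K, 1.5 * np.eye(2), atol=1e-12)
        assert np.allclose(proj.l, 0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_trace_part_survives_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        d = 4
        J = random_antisymmetric(rng, d)
        obs = random_observable(rng, d)
        proj = project_to_kernel(obs, J)
        # the isotropic part is always in the kernel
        assert np.trace(proj.K) == pytest.approx(np.trace(obs.K), rel=1e-10)
        again = project_to_kernel(proj, J)
        assert np.allclose(again.K, proj.K, atol=1e-12)
        assert np.allclose(again.l, proj.l, atol=1e-12)
        # projected part commutes with J
        assert np.abs(J @ proj.K - proj.K @ J).max() < 1e-10


class TestLimitingVariance:
    def test_worked_example_limit(self, unit_target_2d, worked_observable):
        """Projection keeps 1.5|q|^2, whose unperturbed variance is 11.25 at gamma=2."""
        J = np.array([[0.0, 1.0], [-1.0, 0.0]])
        pert = PerturbationConfig.coupled(unit_target_2d, 2.0, 1.0, J)
        limit = limiting_variance(unit_target_2d, pert, worked_observable)
        assert limit == pytest.approx(11.25, abs=1e-10)
        # cross-check against the direct Sylvester value at large mu
        big = PerturbationConfig.coupled(unit_target_2d, 2.0, 1e3, J)
        direct = asymptotic_variance(unit_target_2d, big, worked_observable)
        assert abs(direct - limit) < 1e-3 * (1 + limit)
        # never exceeds the unperturbed value
        zero = PerturbationConfig.coupled(unit_target_2d, 2.0, 0.0, J)
        assert limit <= asymptotic_variance(unit_target_2d, zero, worked_observable) + 1e-10

    def test_linear_with_trivial_kernel_vanishes(self, unit_target_2d, rotation_J):
        obs = QuadraticObservable.linear([1.0, 1.0])
        pert = PerturbationConfig.coupled(unit_target_2d, 2.0, 1.0, rotation_J)
        assert limiting_variance(unit_target_2d, pert, obs) == pytest.approx(0.0, abs=1e-10)

    def test_kernel_observable_unchanged(self, unit_target_2d, rotation_J):
        """[J,K]=0 and l in ker J: the perturbation leaves sigma^2 alone."""
        obs = QuadraticObservable(K=np.eye(2), l=np.zeros(2))
        pert = PerturbationConfig.coupled(unit_target_2d, 2.0, 1.0, rotation_J)
        zero = PerturbationConfig.coupled(unit_target_2d, 2.0, 0.0, rotation_J)
        expected = asymptotic_variance(unit_target_2d, zero, obs)
        assert limiting_variance(unit_target_2d, pert, obs) == pytest.approx(
            expected, abs=1e-10)

    def test_constancy_over_mu_for_kernel_observables(self, unit_target_2d, rotation_J):
        obs = QuadraticObservable(K=np.eye(2), l=np.zeros(2))
        zero = PerturbationConfig.coupled(unit_target_2d, 2.0, 0.0, rotation_J)
        base = asymptotic_variance(unit_target_2d, zero, obs)
        for mu in np.arange(0.0, 10.5, 0.5):
            pert = PerturbationConfig.coupled(unit_target_2d, 2.0, mu, rotation_J)
            assert abs(asymptotic_variance(unit_target_2d, pert, obs) - base) < 1e-8

    def test_coupling_violation_rejected(self, unit_target_2d, rotation_J):
        pert = PerturbationConfig.unit(2, 2.0, mu=1.0, nu=0.5, J=rotation_J)
        with pytest.raises(ValidationError):
            limiting_variance(unit_target_2d, pert,
                              QuadraticObservable.linear([1.0, 1.0]))


class TestTransformToUnit:
    def test_identity_when_unit(self, unit_target_2d, worked_observable, rotation_J):
        pert = PerturbationConfig.coupled(unit_target_2d, 2.0, 1.0, rotation_J)
        t, p, o = transform_to_unit(unit_target_2d, pert, worked_observable)
        assert np.allclose(t.precision, np.eye(2))
        assert np.allclose(p.J1, rotation_J)
        assert np.allclose(o.K, worked_observable.K)

    def test_whitened_K(self):
        S = np.diag([4.0, 1.0])
        target = GaussianTarget(S)
        pert = PerturbationConfig.coupled(target, 2.0, 1.0,
                                          np.array([[0.0, 0.5], [-0.5, 0.0]]))
        obs = QuadraticObservable(K=np.eye(2), l=np.zeros(2))
        _, _, o = transform_to_unit(target, pert, obs)
        assert np.allclose(o.K, np.diag([0.25, 1.0]))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_variance_invariant(self, seed):
        """sigma^2 is invariant under the whitening transform (two Sylvester solves)."""
        rng = np.random.default_rng(seed)
        d = 3
        target = GaussianTarget(random_spd(rng, d))
        pert = PerturbationConfig.coupled(
            target, gamma=2.2, mu=1.4, J1=random_antisymmetric(rng, d))
        obs = random_observable(rng, d)
        before = asymptotic_variance(target, pert, obs)
        ut, up, uo = transform_to_unit(target, pert, obs)
        after = asymptotic_variance(ut, up, uo)
        assert after == pytest.approx(before, abs=1e-9 * (1 + abs(before)))


class TestPreconditioner:
    def test_critical_damping(self):
        S = np.diag([4.0, 1.0])
        M, Gamma = suggest_preconditioner(GaussianTarget(S), c=1.0)
        assert np.allclose(M, S)
        assert np.allclose(Gamma, 2.0 * S)
        # per-coordinate decay rate sqrt(s_i/m_i) = 1 for both coordinates
        for s, m in zip(np.diag(S), np.diag(M)):
            assert np.sqrt(s / m) == pytest.approx(1.0)

    def test_double_root_when_critically_damped(self):
        target = GaussianTarget.standard(1)
        M, Gamma = suggest_preconditioner(target, c=1.0)
        pert = PerturbationConfig(J1=np.zeros((1, 1)), J2=np.zeros((1, 1)),
                                  mu=0.0, nu=0.0, M=M, Gamma=Gamma)
        eigs = np.linalg.eigvals(build_drift_system(target, pert).B)
        assert np.allclose(eigs, 1.0, atol=1e-7)

    def test_rejects_nonpositive_c(self):
        with pytest.raises(ValidationError):
            suggest_preconditioner(GaussianTarget.standard(2), c=0.0)
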