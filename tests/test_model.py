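import math

import numpy as np
import pytest
from scipy import special

import metacov as mc
from metacov.model import CoverageModel, FitError


def synthetic_curve(alpha, beta, n_points=15, noise_sd=0.0, seed=0, span=(0.02, 0.98)):
    """Noiseless (or noisy) curve sampled from the gamma-CDF model itself."""
    x = np.linspace(
        special.gammaincinv(alpha, span[0]) / beta,
        special.gammaincinv(alpha, span[1]) / beta,
        n_points,
    )
    efforts = np.expm1(x)
    cov = special.gammainc(alpha, beta * x)
    if noise_sd:
        rng = np.random.default_rng(seed)
        cov = np.clip(cov + rng.normal(0, noise_sd, size=n_points), 1e-6, 1 - 1e-6)
    return mc.RarefactionCurve(
        efforts_bp=efforts,
        coverage_mean=cov,
        coverage_sd=np.full(n_points, max(noise_sd, 1e-3)),
        metadata={"bases": float(efforts[-1])},
    )


class TestGammaModelCoverage:
    def test_zero_effort(self):
        assert mc.gamma_model_coverage(0.0, 3.0, 0.5) == 0.0

    def test_alpha_one_closed_form(self):
        # alpha=1: C = 1 - (LR+1)^(-beta)
        lr = math.e - 1
        assert mc.gamma_model_coverage(lr, 1.0, 1.0) == pytest.approx(
            1 - math.exp(-1), rel=1e-9
        )

    def test_alpha_two_closed_form(self):
        # gammainc(2, x) = 1 - (1 + x) e^(-x); at x = 1
        lr = math.e - 1
        assert mc.gamma_model_coverage(lr, 2.0, 1.0) == pytest.approx(
            1 - 2 * math.exp(-1), rel=1e-9
        )

    def test_saturates_to_one(self):
        assert mc.gamma_model_coverage(1e30, 5.0, 1.0) == pytest.approx(1.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            mc.gamma_model_coverage(10.0, -1.0, 1.0)


class TestFitModel:
    def test_noiseless_parameter_recovery(self):
        curve = synthetic_curve(5.0, 0.5)
        model = mc.fit_model(curve)
        assert model.converged
        assert model.alpha == pytest.approx(5.0, rel=1e-3)
        assert model.beta == pytest.approx(0.5, rel=1e-3)

    def test_noisy_nd_recovery(self):
        # alpha=22, beta=1 -> Nd = 21; median over replicate noisy fits
        nds = []
        for seed in range(50):
            curve = synthetic_curve(22.0, 1.0, noise_sd=0.01, seed=seed)
            nds.append(mc.fit_model(curve).nd)
        assert np.median(nds) == pytest.approx(21.0, rel=0.02)

    def test_too_few_points(self):
        curve = synthetic_curve(5.0, 0.5, n_points=2)
        with pytest.raises(FitError):
            mc.fit_model(curve)

    def test_all_zero_coverage(self):
        curve = mc.RarefactionCurve(
            efforts_bp=np.array([10.0, 100.0, 1000.0, 10000.0]),
            coverage_mean=np.zeros(4),
            coverage_sd=np.full(4, 1e-3),
        )
        with pytest.raises(FitError):
            mc.fit_model(curve)

    def test_deterministic(self):
        curve = synthetic_curve(8.0, 0.7, noise_sd=0.01, seed=1)
        a = mc.fit_model(curve)
        b = mc.fit_model(curve)
        assert a.alpha == b.alpha and a.beta == b.beta

    @pytest.mark.parametrize("alpha,beta,rel", [(20.0, 1.0, 0.10), (80.0, 4.0, 0.025)])
    def test_scale_consistency_via_projection(self, alpha, beta, rel):
        # multiplying efforts by 10 scales the projected effort by ~10.
        # The gamma-CDF family on ln(LR+1) is not closed under effort
        # scaling (a log-shift is only absorbed by raising the shape), so
        # the equivariance is approximate and tightens as alpha grows.
        curve = synthetic_curve(alpha, beta, noise_sd=0.002, seed=2)
        scaled = mc.RarefactionCurve(
            efforts_bp=curve.efforts_bp * 10,
            coverage_mean=curve.coverage_mean,
            coverage_sd=curve.coverage_sd,
        )
        lr_base = mc.project_effort(mc.fit_model(curve), 0.95)
        lr_scaled = mc.project_effort(mc.fit_model(scaled), 0.95)
        assert lr_scaled / lr_base == pytest.approx(10.0, rel=rel)

    def test_random_parameter_recovery_median(self):
        rng = np.random.default_rng(99)
        rel_errors = []
        for _ in range(100):
            alpha = rng.uniform(1.5, 30.0)
            beta = rng.uniform(0.3, 3.0)
            curve = synthetic_curve(alpha, beta, noise_sd=0.01, seed=int(rng.integers(1 << 30)))
            got = mc.fit_model(curve).nd
            true = (alpha - 1) / beta
            rel_errors.append(abs(got - true) / true)
        assert np.median(rel_errors) < 0.05


class TestNd:
    def test_gamma_mode(self):
        assert mc.nd(CoverageModel(2.0, 1.0, 0.0, 0, True)) == pytest.approx(1.0)

    def test_alpha_at_most_one_reports_zero(self):
        assert mc.nd(CoverageModel(1.0, 5.0, 0.0, 0, True)) == 0.0
        assert mc.nd(CoverageModel(0.5, 5.0, 0.0, 0, True)) == 0.0

    def test_soil_range_magnitude(self):
        assert mc.nd(CoverageModel(23.0, 1.0, 0.0, 0, True)) == pytest.approx(22.0)


class TestProjectEffort:
    def test_alpha_one_closed_form_inverse(self):
        model = CoverageModel(1.0, 1.0, 0.0, 0, True)
        target = 1 - math.exp(-1)
        assert mc.project_effort(model, target) == pytest.approx(math.e - 1, rel=1e-9)

    def test_small_target_limit(self):
        model = CoverageModel(3.0, 1.0, 0.0, 0, True)
        assert mc.project_effort(model, 1e-9) < 1e-2

    def test_target_one_is_infinite(self):
        model = CoverageModel(3.0, 1.0, 0.0, 0, True)
        assert mc.project_effort(model, 1.0) == math.inf

    def test_invalid_target(self):
        model = CoverageModel(3.0, 1.0, 0.0, 0, True)
        with pytest.raises(ValueError):
            mc.project_effort(model, 1.5)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            alpha = rng.uniform(0.5, 30)
            beta = rng.uniform(0.1, 5)
            t = rng.uniform(0.01, 0.99)
            model = CoverageModel(alpha, beta, 0.0, 0, True)
            lr = mc.project_effort(model, t)
            assert mc.gamma_model_coverage(lr, alpha, beta) == pytest.approx(
                t, abs=1e-10
            )

    def test_monotone_in_target(self):
        model = CoverageModel(4.0, 0.9, 0.0, 0, True)
        assert mc.project_effort(model, 0.99) > mc.project_effort(model, 0.95)


class TestCoverageAtActualEffort:
    def test_closed_form(self):
        model = CoverageModel(1.0, 1.0, 0.0, 0, True)
        curve = mc.RarefactionCurve(
            efforts_bp=np.array([1.0, math.e - 1]),
            coverage_mean=np.array([0.3, 0.6]),
            coverage_sd=np.array([0.01, 0.01]),
            metadata={"bases": math.e - 1},
        )
        assert mc.coverage_at_actual_effort(model, curve) == pytest.approx(
            1 - math.exp(-1), rel=1e-6
        )
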