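"""Benchmark generators: S-system, RK4, cAMP oscillator, noise, normalization."""

import numpy as np
import pytest

from ltvgrn.ltv_core import ExpressionSeriesSet
from ltvgrn.simulators import (
    CAMP_COMPONENTS,
    OdeRunConfig,
    SSystemParameters,
    add_noise,
    camp_rate_constants,
    five_gene_benchmark,
    generate_camp_dataset,
    generate_ssystem_dataset,
    integrate,
    laub_loomis_derivatives,
    normalize,
    ssystem_derivatives,
)


class TestSSystemDerivatives:
    def test_exponent_free_case_is_rate_difference(self):
        p = SSystemParameters([3.0, 1.0], [1.0, 4.0], np.zeros((2, 2)), np.zeros((2, 2)))
        d = ssystem_derivatives(p, np.array([0.7, 0.2]))
        assert np.allclose(d, [2.0, -3.0])

    def test_benchmark_gene2_balances_when_x1_equals_x2(self):
        # dX2/dt = 10 X1^2 - 10 X2^2 vanishes on the diagonal
        p = five_gene_benchmark()
        for v in (0.3, 0.8, 1.0):
            x = np.array([v, v, 0.5, 0.6, 0.7])
            assert ssystem_derivatives(p, x)[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_log_space_oracle(self, rng):
        n = 3
        p = SSystemParameters(
            rng.uniform(1, 10, n), rng.uniform(1, 10, n), rng.uniform(-2, 2, (n, n)), rng.uniform(-2, 2, (n, n))
        )
        x = rng.uniform(0.2, 1.5, n)
        expected = np.array(
            [
                p.rate_alpha[i] * np.prod(x ** p.g[i]) - p.rate_beta[i] * np.prod(x ** p.h[i])
                for i in range(n)
            ]
        )
        assert np.allclose(ssystem_derivatives(p, x), expected, rtol=1e-12)

    def test_nonpositive_state_rejected(self):
        p = five_gene_benchmark()
        with pytest.raises(ValueError):
            ssystem_derivatives(p, np.array([0.5, 0.0, 0.5, 0.5, 0.5]))


class TestIntegrate:
    def test_zero_derivative_constant_series(self):
        cfg = OdeRunConfig(t_end=1.0, n_points=5, step=0.01)
        out = integrate(lambda x: np.zeros_like(x), np.array([0.4, 0.9]), cfg)
        assert np.allclose(out, [0.4, 0.9])

    def test_exponential_decay_closed_form(self):
        cfg = OdeRunConfig(t_end=0.5, n_points=6, step=1e-3)
        out = integrate(lambda x: -x, np.array([1.0]), cfg)
        times = np.linspace(0, 0.5, 6)
        assert np.allclose(out[:, 0], np.exp(-times), atol=1e-6)
        assert out[-1, 0] == pytest.approx(0.6065306597126334, abs=1e-8)

    def test_fourth_order_convergence(self):
        # halving the step shrinks the error ~16x on a nonlinear ODE
        f = lambda x: -(x**2)  # noqa: E731  (solution 1/(1+t))
        exact = 1.0 / (1.0 + 1.0)
        errs = []
        for step in (0.1, 0.05, 0.025):
            cfg = OdeRunConfig(t_end=1.0, n_points=2, step=step)
            errs.append(abs(integrate(f, np.array([1.0]), cfg)[-1, 0] - exact))
        rates = [errs[i] / errs[i + 1] for i in range(2)]
        assert all(10 < r < 22 for r in rates)

    def test_divergence_reported(self):
        cfg = OdeRunConfig(t_end=2.0, n_points=3, step=0.01)
        with pytest.raises(RuntimeError, match="diverged"):
            integrate(lambda x: x**2, np.array([5.0]), cfg)


class TestSSystemDataset:
    def test_sample_counts_benchmark_design(self):
        cfg = OdeRunConfig(n_replicates=10, n_points=11, seed=0)
        data = generate_ssystem_dataset(cfg=cfg)
        assert data.n_series == 10 and data.n_times == 11 and data.n_genes == 5
        assert data.n_series * data.n_times == 110  # samples per gene

    def test_minimal_design(self):
        cfg = OdeRunConfig(n_replicates=1, n_points=2, seed=1)
        data = generate_ssystem_dataset(cfg=cfg)
        assert data.n_series == 1 and data.n_times == 2

    def test_seed_reproducibility_bitwise(self):
        cfg = OdeRunConfig(n_replicates=3, n_points=5, seed=42)
        a = generate_ssystem_dataset(cfg=cfg).as_array()
        b = generate_ssystem_dataset(cfg=cfg).as_array()
        assert np.array_equal(a, b)

    def test_trajectories_positive_and_bounded(self):
        cfg = OdeRunConfig(n_replicates=10, n_points=11, seed=7)
        arr = generate_ssystem_dataset(cfg=cfg).as_array()
        assert np.all(arr > 0) and np.all(arr < 10)


class TestLaubLoomis:
    def test_zero_state_with_zero_constant_production(self):
        k = camp_rate_constants()
        k = k.copy()
        k[6] = 0.0  # remove the constitutive RegA production term
        assert np.allclose(laub_loomis_derivatives(np.zeros(7), k), 0.0)

    def test_wrong_state_length_rejected(self):
        with pytest.raises(ValueError):
            laub_loomis_derivatives(np.ones(6))

    def test_sustained_oscillations(self):
        cfg = OdeRunConfig(t_end=60.0, n_points=601, step=1e-3)
        x0 = np.array([1.2, 1.05, 1.5, 2.4, 1.0, 0.1, 0.45])
        traj = integrate(lambda x: laub_loomis_derivatives(x), x0, cfg)
        campi = traj[200:, 4]  # discard transient
        maxima = np.sum((campi[1:-1] > campi[:-2]) & (campi[1:-1] > campi[2:]))
        assert maxima >= 2
        # non-decaying amplitude: last quarter swings comparably to the window
        last = campi[-100:]
        assert last.max() - last.min() > 0.5 * (campi.max() - campi.min())

    def test_jacobian_signs_match_wiring(self):
        # finite-difference partials at a positive state
        x = np.array([0.8, 1.1, 0.9, 1.3, 0.7, 0.5, 0.6])
        eps = 1e-6

        def partial(i, j):
            xp = x.copy()
            xp[j] += eps
            return (laub_loomis_derivatives(xp)[i] - laub_loomis_derivatives(x)[i]) / eps

        names = {g: i for i, g in enumerate(CAMP_COMPONENTS)}
        assert partial(names["ACA"], names["PKA"]) < 0  # PKA inhibits ACA
        assert partial(names["ACA"], names["CAR1"]) > 0  # CAR1 activates ACA
        assert partial(names["PKA"], names["cAMPi"]) > 0
        assert partial(names["ERK2"], names["PKA"]) < 0
        assert partial(names["RegA"], names["ERK2"]) < 0
        assert partial(names["cAMPi"], names["RegA"]) < 0
        assert partial(names["cAMPe"], names["ACA"]) > 0
        assert partial(names["CAR1"], names["cAMPe"]) > 0

    def test_camp_dataset_design_and_normalization(self):
        cfg = OdeRunConfig(t_end=9.0, n_points=10, init_range=(0.1, 2.0), n_replicates=5, seed=5)
        data = generate_camp_dataset(cfg=cfg)
        assert data.n_series == 5 and data.n_times == 10 and data.n_genes == 7
        assert data.n_series * data.n_times == 50
        arr = data.as_array()
        assert np.all(arr > 0) and np.all(arr <= 1.0)
        assert np.allclose(arr.max(axis=(0, 1)), 1.0)  # per-gene max is exactly 1


class TestNoise:
    def test_zero_level_is_identity(self, self_generated_data):
        out = add_noise(self_generated_data, 0.0, seed=1)
        assert np.array_equal(out.as_array(), self_generated_data.as_array())

    def test_negative_level_rejected(self, self_generated_data):
        with pytest.raises(ValueError):
            add_noise(self_generated_data, -0.1)

    def test_relative_std_matches_level(self):
        base = ExpressionSeriesSet(
            series=[np.full((200, 5), 0.5)], times=np.arange(200.0), gene_names=list("abcde")
        )
        out = add_noise(base, 0.05, seed=3)
        rel = (out.as_array() - 0.5) / 0.5
        assert np.std(rel) == pytest.approx(0.05, rel=0.1)

    def test_floor_enforced(self):
        base = ExpressionSeriesSet(
            series=[np.full((50, 2), 1e-6)], times=np.arange(50.0), gene_names=["a", "b"]
        )
        out = add_noise(base, 0.5, seed=4)
        assert np.all(out.as_array() >= 1e-6)


class TestNormalize:
    def test_hand_example_with_zero_replacement(self):
        data = ExpressionSeriesSet(series=[np.array([[0.0], [2.0], [4.0]])], times=[0, 1, 2], gene_names=["g"])
        out = normalize(data)
        assert np.allclose(out.series[0][:, 0], [1e-4, 0.5, 1.0])

    def test_idempotent_after_first_application(self, self_generated_data):
        once = normalize(self_generated_data)
        twice = normalize(once)
        assert np.allclose(once.as_array(), twice.as_array(), atol=1e-15)

    def test_all_zero_gene_rejected(self):
        data = ExpressionSeriesSet(
            series=[np.array([[0.0, 1.0], [0.0, 2.0]])], times=[0, 1], gene_names=["dead", "live"]
        )
        with pytest.raises(ValueError, match="dead"):
            normalize(data)
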