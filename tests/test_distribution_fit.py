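import math

import numpy as np
import pytest
from scipy import stats

from idrscape.distribution_fit import (
    DiscreteSummary,
    StableParams,
    discrete_summary,
    fit_hyperbolic,
    fit_stable,
    kde2d,
    kde2d_evaluate,
    stable_pdf,
    welch_ttest,
)


def cms_stable_s0(params: StableParams, size: int, rng: np.random.Generator):
    """Chambers-Mallows-Stuck sampler, written independently of scipy.

    Generates standard S1 variates from (V, W) and shifts them to the S0
    parameterization (x0 = x1 - beta * tan(pi*alpha/2)).
    """
    a, b = params.alpha, params.beta
    V = rng.uniform(-np.pi / 2, np.pi / 2, size)
    W = rng.exponential(1.0, size)
    if a == 1.0:
        X = (2 / np.pi) * (
            (np.pi / 2 + b * V) * np.tan(V)
            - b * np.log((np.pi / 2) * W * np.cos(V) / (np.pi / 2 + b * V))
        )
        shift = 0.0
    else:
        t = b * math.tan(math.pi * a / 2)
        B = math.atan(t) / a
        S = (1 + t * t) ** (1 / (2 * a))
        X = (
            S
            * np.sin(a * (V + B))
            / np.cos(V) ** (1 / a)
            * (np.cos(V - a * (V + B)) / W) ** ((1 - a) / a)
        )
        shift = t
    return params.mu + params.sigma * (X - shift)


class TestStablePdf:
    def test_gaussian_limit(self):
        # alpha = 2 is N(mu, 2 sigma^2)
        p = stable_pdf(0.0, StableParams(2.0, 0.0, 0.0, 1.0))
        assert p == pytest.approx(1 / (2 * math.sqrt(math.pi)), rel=1e-6)

    def test_cauchy_limit(self):
        params = StableParams(1.0, 0.0, 1.5, 2.0)
        xs = np.array([-3.0, 0.0, 1.5, 4.0, 10.0])
        np.testing.assert_allclose(
            stable_pdf(xs, params),
            stats.cauchy.pdf(xs, loc=1.5, scale=2.0),
            rtol=1e-6,
        )

    def test_matches_monte_carlo_histogram(self, rng):
        """Density agrees with a hand-written CMS simulation oracle."""
        params = StableParams(1.34, 0.6, 2.0, 1.5)
        n = 1_000_000
        samples = cms_stable_s0(params, n, rng)
        edges = np.linspace(-6, 10, 17)
        counts, _ = np.histogram(samples, bins=edges)
        # expected bin mass: Simpson integral of the pdf across each bin
        fine = np.linspace(edges[0], edges[-1], 16 * 8 + 1)
        pdf_fine = stable_pdf(fine, params)
        from scipy.integrate import simpson

        p_bin = np.array(
            [
                simpson(pdf_fine[i * 8 : i * 8 + 9], x=fine[i * 8 : i * 8 + 9])
                for i in range(16)
            ]
        )
        se = np.sqrt(p_bin * (1 - p_bin) / n)
        assert np.all(np.abs(counts / n - p_bin) < 4 * se + 1e-5)

    def test_integrates_to_one_over_alpha_beta_lattice(self):
        center = np.linspace(-40, 40, 241)
        tail = np.geomspace(40, 50000, 60)
        grid = np.unique(np.concatenate([-tail[::-1], center, tail]))
        for alpha in (0.9, 1.3, 1.8):
            for beta in (-0.5, 0.0, 0.9):
                params = StableParams(alpha, beta, 0.0, 1.0)
                total = np.trapezoid(stable_pdf(grid, params), grid)
                assert total == pytest.approx(1.0, abs=1e-3), (alpha, beta)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            StableParams(2.3, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            StableParams(0.0, 0.0, 0.0, 1.0)


class TestFitStable:
    def test_quantile_fit_recovers_simulated_parameters(self, rng):
        params = StableParams(1.34, 0.99, 9.73, 2.24)
        samples = cms_stable_s0(params, 5000, rng)
        est = fit_stable(samples, method="quantile")
        assert est.alpha == pytest.approx(params.alpha, abs=0.2)
        assert est.mu == pytest.approx(params.mu, abs=0.5)

    def test_fit_invariant_to_sample_order(self, rng):
        samples = cms_stable_s0(StableParams(1.3, 0.5, 0.0, 1.0), 500, rng)
        a = fit_stable(samples, method="quantile")
        b = fit_stable(samples[::-1].copy(), method="quantile")
        assert a == b

    def test_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_stable([3.0] * 100)

    def test_small_sample_warns(self, rng):
        with pytest.warns(UserWarning, match="unreliable"):
            fit_stable(rng.normal(size=20), method="quantile")


class TestFitHyperbolic:
    def test_noiseless_curve_recovered_exactly(self):
        x = np.arange(50, 1001, 50, dtype=float)
        y = 6.05937 + 651.62 / x
        fit = fit_hyperbolic(x, y)
        assert fit.a == pytest.approx(6.05937, rel=1e-9)
        assert fit.b == pytest.approx(651.62, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_y_gives_zero_curvature(self):
        x = np.array([10.0, 20.0, 40.0, 80.0])
        fit = fit_hyperbolic(x, np.full(4, 7.0))
        assert fit.b == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == 0.0

    def test_matches_normal_equation_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 40))
            x = rng.uniform(10, 1000, n)
            y = rng.normal(8, 3, n)
            fit = fit_hyperbolic(x, y)
            u = 1.0 / x
            # closed-form 2x2 normal equations
            A = np.array([[n, u.sum()], [u.sum(), (u * u).sum()]])
            rhs = np.array([y.sum(), (u * y).sum()])
            a_exp, b_exp = np.linalg.solve(A, rhs)
            assert fit.a == pytest.approx(a_exp, rel=1e-8, abs=1e-8)
            assert fit.b == pytest.approx(b_exp, rel=1e-8, abs=1e-6)
            # residual orthogonality to [1, 1/x]
            resid = y - fit.predict(x)
            assert abs(resid.sum()) < 1e-7 * max(1, abs(y).sum())
            assert abs(resid @ u) < 1e-9 * max(1, abs(y).sum())

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            fit_hyperbolic([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


class TestKde2d:
    def test_identical_points_peak_at_point(self):
        surf = kde2d([3.0, 3.0], [7.0, 7.0], bandwidths=(1.0, 1.0))
        i, j = np.unravel_index(np.argmax(surf.density), surf.density.shape)
        assert surf.x_grid[i] == pytest.approx(3.0, abs=0.2)
        assert surf.y_grid[j] == pytest.approx(7.0, abs=0.2)

    def test_grid_integral_near_one(self, rng):
        x = rng.normal(400, 120, 200)
        y = rng.uniform(0, 30, 200)
        surf = kde2d(x, y)
        total = np.trapezoid(
            np.trapezoid(surf.density, surf.y_grid, axis=1), surf.x_grid
        )
        assert total == pytest.approx(1.0, abs=0.01)

    def test_matches_double_loop_kernel_oracle(self, rng):
        x = rng.normal(0, 2, 40)
        y = rng.normal(5, 1, 40)
        hx, hy = 0.8, 0.5
        surf = kde2d(x, y, bandwidths=(hx, hy))
        idx = rng.integers(0, surf.x_grid.size, 10)
        idy = rng.integers(0, surf.y_grid.size, 10)
        for i, j in zip(idx, idy):
            px, py = surf.x_grid[i], surf.y_grid[j]
            expected = 0.0
            for xk, yk in zip(x, y):  # brute-force kernel sum
                expected += math.exp(
                    -0.5 * (((px - xk) / hx) ** 2 + ((py - yk) / hy) ** 2)
                ) / (2 * math.pi * hx * hy)
            expected /= x.size
            assert surf.density[i, j] == pytest.approx(expected, rel=1e-10)
            probe = kde2d_evaluate([px], [py], x, y, (hx, hy))[0]
            assert probe == pytest.approx(expected, rel=1e-10)

    def test_zero_variance_requires_explicit_bandwidth(self):
        with pytest.raises(ValueError, match="bandwidth"):
            kde2d([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestWelch:
    def test_identical_distinct_groups(self):
        res = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        res = welch_ttest(a, b)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_exp = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df_exp = (va + vb) ** 2 / (
            va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        )
        assert res.t_statistic == pytest.approx(t_exp)
        assert res.degrees_of_freedom == pytest.approx(df_exp)
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(abs(t_exp), df_exp)
        )

    def test_swap_symmetry(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 15)
        r1, r2 = welch_ttest(a, b), welch_ttest(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_identical_constants_rejected(self):
        with pytest.raises(ValueError):
            welch_ttest([2.0, 2.0], [2.0, 2.0])


class TestDiscreteSummary:
    def test_singleton(self):
        d = discrete_summary([8.36])
        assert (d.minimum, d.maximum, d.mean, d.median) == (8.36, 8.36, 8.36, 8.36)

    def test_small_set(self):
        d = discrete_summary([1.0, 2.0, 3.0, 4.0])
        assert d.mean == 2.5 and d.median == 2.5

    def test_matches_sorting_oracle(self, rng):
        for _ in range(200):
            v = rng.uniform(0, 50, int(rng.integers(1, 60)))
            d = discrete_summary(v)
            sv = np.sort(v)
            assert d.minimum == sv[0] and d.maximum == sv[-1]
            assert d.mean == pytest.approx(sv.sum() / sv.size)
            mid = sv.size // 2
            med = sv[mid] if sv.size % 2 else 0.5 * (sv[mid - 1] + sv[mid])
            assert d.median == pytest.approx(med)
            assert d.minimum <= d.median <= d.maximum
            assert d.minimum <= d.mean <= d.maximum

    def test_mode_is_modal_bin_midpoint(self):
        v = [1.2, 1.4, 1.9, 5.5, 5.6, 5.7, 5.8, 9.0]
        assert discrete_summary(v).mode == 5.5  # bin [5,6) midpoint
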