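"""DFA window schemes, fluctuation plots, exponents and ML-DFA verdicts."""

import numpy as np
import pytest

from phasecrit.dfa import (
    CANDIDATE_MODELS,
    FluctuationPlot,
    dfa,
    dfa_exponent,
    dfa_fluctuations,
    dfa_profile,
    make_windows,
    mldfa_validate,
    scaled_log_fluctuations,
)
from phasecrit.errors import (
    DegeneratePlotError,
    ParameterError,
    SeriesTooShortError,
)

from .reference import dfa_reference, linear_pseudo_loglik_grid


class TestMakeWindows:
    def test_full_scale_maximum(self):
        scheme = make_windows(4_194_304, min_window=600)
        assert scheme.max_window == 419_430
        assert scheme.min_window == 600

    def test_desk_scale_maximum(self):
        scheme = make_windows(6100, min_window=8)
        assert scheme.max_window == 610

    def test_too_short_raises(self):
        with pytest.raises(SeriesTooShortError):
            make_windows(50, min_window=8)

    def test_log_spacing_and_uniqueness(self):
        sizes = make_windows(100_000, min_window=8).sizes
        assert np.all(np.diff(sizes) > 0)
        assert len(sizes) <= 20
        ratios = np.diff(np.log(sizes.astype(float)))
        assert ratios.std() / ratios.mean() < 0.5  # roughly geometric


class TestProfile:
    def test_constant_input_zero_profile(self):
        assert np.allclose(dfa_profile(np.full(100, 3.7)), 0.0)

    def test_profile_linearity(self, rng):
        x = rng.standard_normal(256)
        assert np.allclose(dfa_profile(-x), -dfa_profile(x))

    def test_white_noise_profile_is_random_walk(self, rng):
        x = rng.standard_normal(2**14)
        profile = dfa_profile(x)
        early = profile[: 2**10].var()
        late = profile.var()
        assert late > 5 * early


class TestExponent:
    def test_exact_power_law(self):
        sizes = make_windows(100_000, 8).sizes
        plot = FluctuationPlot(window_sizes=sizes, fluctuations=sizes.astype(float) ** 0.7)
        assert dfa_exponent(plot) == pytest.approx(0.7, abs=1e-10)

    def test_scale_invariance(self):
        sizes = make_windows(100_000, 8).sizes
        f = sizes.astype(float) ** 0.63
        p1 = FluctuationPlot(window_sizes=sizes, fluctuations=f)
        p2 = FluctuationPlot(window_sizes=sizes, fluctuations=2.0 * f)
        assert dfa_exponent(p1) == pytest.approx(dfa_exponent(p2), abs=1e-12)

    def test_degenerate_plot_raises(self):
        sizes = make_windows(10_000, 8).sizes
        plot = FluctuationPlot(window_sizes=sizes, fluctuations=np.zeros(len(sizes)))
        with pytest.raises(DegeneratePlotError):
            dfa_exponent(plot)

    @pytest.mark.parametrize(
        "builder,expected,tol",
        [
            (lambda r: r.standard_normal(2**16), 0.5, 0.05),
            (lambda r: np.cumsum(r.standard_normal(2**16)), 1.5, 0.05),
        ],
        ids=["white-noise", "brownian"],
    )
    def test_canonical_exponents(self, builder, expected, tol):
        exps = [dfa(builder(np.random.default_rng(s)))[1] for s in range(3)]
        assert np.mean(exps) == pytest.approx(expected, abs=tol)


class TestOracleEquivalence:
    def test_matches_naive_reference_within_one_percent(self):
        """Vectorized F(n) equals a loop/polyfit reference on random inputs."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            kind = seed % 3
            if kind == 0:
                x = r.standard_normal(4000)
            elif kind == 1:
                x = np.cumsum(r.standard_normal(4000))
            else:
                x = np.sin(np.arange(4000) / 40.0) + r.standard_normal(4000)
            scheme = make_windows(x.size, 8)
            ours = dfa_fluctuations(x, scheme).fluctuations
            ref = dfa_reference(x, scheme.sizes)
            assert np.all(np.abs(ours - ref) / ref < 0.01)


class TestMLDFA:
    def test_candidate_family_parameter_counts(self):
        by_name = {m.name: m.param_count for m in CANDIDATE_MODELS}
        assert by_name["poly1"] == 2
        assert by_name["spline4"] == 8
        assert by_name["root3"] == by_name["log"] == by_name["exp"] == 3

    def test_collinear_points_valid_with_line_slope(self):
        x = np.linspace(0.9, 2.9, 20)
        plot = FluctuationPlot(
            window_sizes=np.round(10**x).astype(int),
            fluctuations=10 ** (0.42 * x - 0.3),
        )
        res = mldfa_validate(plot, seed=0)
        assert res.valid
        assert res.exponent == pytest.approx(0.42, abs=1e-2)

    def test_scaled_fluctuations_span_0_100(self, rng):
        plot, _ = dfa(rng.standard_normal(2**14))
        y = scaled_log_fluctuations(plot)
        assert y.min() == 0.0 and y.max() == 100.0
        res = mldfa_validate(plot, seed=1)
        assert res.scaled_fluctuations.min() == 0.0
        assert res.scaled_fluctuations.max() == 100.0

    def test_verdict_invariant_to_amplitude_scaling(self, rng):
        x = rng.standard_normal(2**14)
        r1 = mldfa_validate(dfa(x)[0], seed=5)
        r2 = mldfa_validate(dfa(1e3 * x)[0], seed=5)
        assert r1.valid == r2.valid
        assert r1.best_model == r2.best_model

    def test_pure_sine_crossover_rejected(self):
        """Oscillatory series produce a crossover; the plot is not linear."""
        s = np.sin(2 * np.pi * np.arange(6000) / 100.0)
        res = mldfa_validate(dfa(s)[0], seed=2)
        assert not res.valid

    def test_farima_plot_accepted_with_correct_slope(self):
        from phasecrit.surrogates import FarimaSpec, farima_generate

        x = farima_generate(FarimaSpec(d=0.25, n=2**16, seed=11))
        plot, slope = dfa(x)
        res = mldfa_validate(plot, seed=3)
        assert res.valid
        assert res.exponent == pytest.approx(0.75, abs=0.05)

    def test_too_few_points_rejected(self):
        sizes = np.array([8, 16, 32, 64, 128])
        plot = FluctuationPlot(window_sizes=sizes, fluctuations=sizes.astype(float) ** 0.5)
        with pytest.raises(ParameterError):
            mldfa_validate(plot, seed=0)

    def test_degenerate_plot_invalid_not_crash(self):
        sizes = make_windows(10_000, 8).sizes
        plot = FluctuationPlot(window_sizes=sizes, fluctuations=np.zeros(len(sizes)))
        res = mldfa_validate(plot, seed=0)
        assert not res.valid
        assert res.exponent is None
        assert "degenerate" in res.diagnostic

    def test_exponent_present_iff_valid(self, rng):
        for seed in range(4):
            x = np.random.default_rng(seed).standard_normal(2**13)
            res = mldfa_validate(dfa(x)[0], seed=seed)
            assert (res.exponent is not None) == res.valid

    def test_linear_fit_matches_grid_search_oracle(self):
        """The optimizer's linear pseudo-likelihood matches a coarse
        independent grid search within 1e-3 on random plots."""
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal(2**13)
            plot, _ = dfa(x)
            res = mldfa_validate(plot, seed=seed)
            lin = res.fits[0]
            assert lin.feasible
            xs = plot.log_sizes
            ys = res.scaled_fluctuations
            a1, a2 = lin.params[0], lin.params[1]
            span = abs(a1) + abs(a2) + 1.0
            ref = linear_pseudo_loglik_grid(
                xs, ys,
                (a1 - 0.02 * span, a1 + 0.02 * span),
                (a2 - 0.02 * span, a2 + 0.02 * span),
                n_grid=41,
            )
            # grid refinement can only approach the optimum from below
            assert lin.loglik >= ref - 1e-3


class TestAICBookkeeping:
    def test_aic_finite_only_for_feasible(self, rng):
        res = mldfa_validate(dfa(rng.standard_normal(2**13))[0], seed=7)
        for fit in res.fits:
            assert np.isfinite(fit.aic) == fit.feasible

    def test_validity_requires_strict_minimum(self, rng):
        res = mldfa_validate(dfa(rng.standard_normal(2**13))[0], seed=9)
        if res.valid:
            linear_aic = res.fits[0].aic
            others = [f.aic for f in res.fits[1:] if f.feasible]
            assert all(linear_aic < a for a in others)
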