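import numpy as np
import pytest
from scipy.special import logit

from cmrpop.cjs_model import (
    FitOptions,
    FormulaSyntaxError,
    build_design,
    cjs_neg_log_likelihood,
    compute_aicc,
    count_estimable,
    fit_cjs,
    model_selection_table,
    parse_formula,
    parse_model_spec,
    _row_probabilities,
)
from cmrpop.encounter_data import build_marray
from cmrpop.synthetic_data import SimulationConfig, simulate_histories

from _oracles import constant_model_grid, individual_nll2
from conftest import make_set, random_set

FAST = FitOptions(n_starts=2, compute_hessian=False)


class TestGrammar:
    def test_independent_age_segments(self):
        f = parse_formula("a(1).t/a(>=2)")
        assert len(f.segments) == 2
        assert [str(t) for t in f.segments[0].terms] == ["age.t"]
        assert [str(t) for t in f.segments[1].terms] == ["age"]
        assert f.segments[1].classes[0].hi is None

    def test_additive_time(self):
        f = parse_formula("a(1,>=2)+t")
        seg = f.segments[0]
        assert len(seg.classes) == 2
        assert [str(t) for t in seg.terms] == ["age", "t"]

    def test_bare_time(self):
        f = parse_formula("t")
        assert len(f.segments) == 1
        assert f.segments[0].classes[0].lo == 1
        assert [str(t) for t in f.segments[0].terms] == ["age.t"]

    def test_unicode_ge_accepted(self):
        assert str(parse_formula("a(1).t/a(≥2)")) == "a(1).t/a(>=2)"

    @pytest.mark.parametrize("bad", [
        "", "a(1,3)", "a(>=2,3)", "a(1)..t", "a(1)+", "a(2,>=3)",
        "a(1)/", "a(1,>=2)t",
    ])
    def test_syntax_errors(self, bad):
        with pytest.raises(FormulaSyntaxError):
            parse_formula(bad)

    def test_covariates_collected(self):
        f = parse_formula("a(1).FISH/a(>=2).NAO")
        assert f.covariates == ("FISH", "NAO")


class TestBuildDesign:
    def test_covariate_intercept_plus_slope(self):
        # class 1: intercept + slope; class >=2: one intercept
        spec = parse_model_spec("a(1).FISH/a(>=2)", "t")
        cov = {"FISH": {y: float(y % 5) for y in range(2000, 2009)}}
        d = build_design(spec, range(2000, 2009), ["g"], cov)
        assert d.phi.n_params == 3

    def test_constant_single_parameter(self):
        spec = parse_model_spec("a(1)", "1")
        d = build_design(spec, [2000, 2001], ["g"])
        assert d.phi.n_params == 1

    def test_full_age_time_counts(self):
        # 9 occasions, 3 age classes: class1 sees 8 intervals, class2 7,
        # class >=3 the rest -> full interaction = realized (class, time) cells
        spec = parse_model_spec("a(1,2,>=3).t", "t")
        d = build_design(spec, range(1998, 2007), ["g"])
        assert d.phi.n_params == 8 + 7 + 6
        assert d.p.n_params == 8

    def test_additive_time_reference_coding(self):
        spec = parse_model_spec("a(1,>=2)+t", "1")
        d = build_design(spec, range(2000, 2006), ["g"])
        # 2 intercepts + (5 realized intervals - 1 reference)
        assert d.phi.n_params == 2 + 4

    def test_colony_crossing(self):
        spec = parse_model_spec("a(1,>=2).col", "1")
        d = build_design(spec, range(2000, 2005), ["A", "B"])
        assert d.phi.n_params == 4

    def test_shared_additive_covariate_slope(self):
        spec = parse_model_spec("a(1,>=2)+NAO", "1")
        cov = {"NAO": {y: float(y) for y in range(2000, 2005)}}
        d = build_design(spec, range(2000, 2005), ["g"], cov)
        assert d.phi.n_params == 3  # 2 intercepts + 1 shared slope

    def test_interactive_covariate_slope_per_class(self):
        spec = parse_model_spec("a(1,>=2).NAO", "1")
        cov = {"NAO": {y: float(y) for y in range(2000, 2005)}}
        d = build_design(spec, range(2000, 2005), ["g"], cov)
        assert d.phi.n_params == 4  # intercept + slope per class

    def test_unknown_covariate_rejected(self):
        spec = parse_model_spec("a(1).FISH/a(>=2)", "1")
        with pytest.raises(ValueError, match="unknown covariate"):
            build_design(spec, range(2000, 2005), ["g"])

    def test_missing_covariate_year_directs_to_gap_filling(self):
        spec = parse_model_spec("a(1).FISH/a(>=2)", "1")
        cov = {"FISH": {2000: 1.0, 2001: 2.0, 2003: 4.0}}
        with pytest.raises(ValueError, match="fill_covariate_gaps"):
            build_design(spec, range(2000, 2005), ["g"], cov)


class TestLikelihood:
    def test_single_cohort_two_occasions(self):
        # R=10, m=4, phi*p = 0.4 -> -2[4 ln .4 + 6 ln .6] ~ 13.46
        chs = make_set(["11"] * 4 + ["10"] * 6)
        ma = build_marray(chs)
        d = build_design(parse_model_spec("1", "1"), chs.occasions, ["g"],
                         cohorts={"g": [0]})
        beta = np.array([logit(0.5), logit(0.8)])
        expected = -2 * (4 * np.log(0.4) + 6 * np.log(0.6))
        assert cjs_neg_log_likelihood(d, beta, ma) == pytest.approx(expected)

    def test_degenerate_certain_detection(self):
        chs = make_set(["111"] * 5)
        ma = build_marray(chs)
        d = build_design(parse_model_spec("1", "1"), chs.occasions, ["g"],
                         cohorts={"g": [0]})
        beta = np.array([30.0, 30.0])  # phi ~ 1, p ~ 1
        assert cjs_neg_log_likelihood(d, beta, ma) == pytest.approx(0.0, abs=1e-8)

    def test_row_normalization(self, rng):
        chs = random_set(rng, 5, 30)
        ma = build_marray(chs)
        d = build_design(parse_model_spec("a(1,>=2).t", "t"), chs.occasions,
                         ["g"], cohorts={"g": ma.cohorts("g")})
        beta = rng.normal(size=d.parameter_count_nominal)
        prob, chi, mask = _row_probabilities(d, beta, ma)
        np.testing.assert_allclose(prob.sum(axis=1) + chi, 1.0, atol=1e-12)

    def test_beta_length_checked(self, three_occasion_set):
        ma = build_marray(three_occasion_set)
        d = build_design(parse_model_spec("1", "1"),
                         three_occasion_set.occasions, ["g"],
                         cohorts={"g": [0]})
        with pytest.raises(ValueError, match="nominal parameter count"):
            cjs_neg_log_likelihood(d, np.zeros(5), ma)
        with pytest.raises(ValueError, match="non-finite"):
            cjs_neg_log_likelihood(d, np.array([np.nan, 0.0]), ma)

    def test_matches_individual_oracle(self, rng):
        for _ in range(10):
            t = int(rng.integers(3, 6))
            chs = random_set(rng, t, int(rng.integers(8, 31)))
            ma = build_marray(chs)
            phi_tab = {(a, k): rng.uniform(0.2, 0.9)
                       for a in range(1, t + 1) for k in range(t)}
            p_tab = {(a, j): rng.uniform(0.2, 0.9)
                     for a in range(1, t + 1) for j in range(t)}
            ages = (",".join(str(a) for a in range(1, t - 1)) + f",>={t - 1}"
                    if t > 2 else ">=1")
            spec = parse_model_spec(f"a({ages}).t", f"a({ages}).t")
            d = build_design(spec, chs.occasions, ["g"],
                             cohorts={"g": ma.cohorts("g")})
            beta = np.zeros(d.parameter_count_nominal)
            for (g, si, ci, k), i in d.phi.cell_index.items():
                cls = spec.survival.segments[si].classes[ci]
                beta[i] = logit(phi_tab[(cls.lo, k)])
            off = d.phi.n_params
            for (g, si, ci, j), i in d.p.cell_index.items():
                cls = spec.resight.segments[si].classes[ci]
                beta[off + i] = logit(p_tab[(cls.lo, j)])
            ours = cjs_neg_log_likelihood(d, beta, ma)
            oracle = individual_nll2(
                chs, lambda a, k: phi_tab[(a, k)], lambda a, j: p_tab[(a, j)]
            )
            assert ours == pytest.approx(oracle, abs=1e-8)


class TestFit:
    def test_closed_form_proportions(self):
        # certain detection: phi_1 = 60/100, phi_2 = 30/60
        chs = make_set(["111"] * 30 + ["110"] * 30 + ["100"] * 40)
        ma = build_marray(chs)
        fit = fit_cjs(ma, parse_model_spec("t", "1"), options=FAST)
        est = fit.real_scale("phi").estimate.to_numpy()
        assert est == pytest.approx([0.6, 0.5], abs=1e-3)

    def test_matches_grid_oracle(self, rng):
        chs = random_set(rng, 3, 30)
        ma = build_marray(chs)
        fit = fit_cjs(ma, parse_model_spec("1", "1"), options=FAST)
        gphi, gp, gnll2 = constant_model_grid(chs, resolution=1e-3)
        assert fit.nll2 <= gnll2 + 1e-6
        assert fit.real_scale("phi").estimate.iloc[0] == pytest.approx(
            gphi, abs=2e-3)
        assert fit.real_scale("p").estimate.iloc[0] == pytest.approx(
            gp, abs=2e-3)

    def test_nesting_monotonicity(self, rng):
        chs = random_set(rng, 5, 60)
        ma = build_marray(chs)
        reduced = fit_cjs(ma, parse_model_spec("1", "t"), options=FAST)
        richer = fit_cjs(ma, parse_model_spec("t", "t"), options=FAST)
        assert richer.deviance <= reduced.deviance + 1e-6

    def test_recovery_smoke(self):
        cfg = SimulationConfig(
            occasions=tuple(range(2000, 2008)),
            cohort_sizes={y: 250 for y in range(2000, 2007)},
            survival={1: 0.5, 2: 0.8},
            resight={1: 0.5},
            seed=11,
        )
        ma = build_marray(simulate_histories(cfg))
        fit = fit_cjs(ma, parse_model_spec("a(1,>=2)", "t"), options=FAST)
        df = fit.real_scale("phi")
        juv = df[df.age_lo == 1].estimate.iloc[0]
        adult = df[df.age_lo == 2].estimate.iloc[0]
        assert juv == pytest.approx(0.5, abs=0.05)
        assert adult == pytest.approx(0.8, abs=0.05)

    def test_ci_inside_unit_interval(self, rng):
        chs = random_set(rng, 4, 50)
        ma = build_marray(chs)
        fit = fit_cjs(ma, parse_model_spec("1", "1"),
                      options=FitOptions(n_starts=2))
        for kind in ("phi", "p"):
            df = fit.real_scale(kind)
            assert ((df.ci_lo >= 0) & (df.ci_hi <= 1)).all()
            assert ((df.ci_lo <= df.estimate) & (df.estimate <= df.ci_hi)).all()

    def test_ci_coverage_coarse(self):
        # ~95% coverage of the constant-survival CI over seeded replicates
        hits = 0
        n_rep = 40
        for s in range(n_rep):
            cfg = SimulationConfig(
                occasions=(0, 1, 2, 3, 4),
                cohort_sizes={0: 150, 1: 150},
                survival={1: 0.6},
                resight={1: 0.5},
                seed=100 + s,
            )
            ma = build_marray(simulate_histories(cfg))
            fit = fit_cjs(ma, parse_model_spec("1", "1"),
                          options=FitOptions(n_starts=1))
            row = fit.real_scale("phi").iloc[0]
            hits += row.ci_lo <= 0.6 <= row.ci_hi
        assert 0.85 <= hits / n_rep <= 1.0


class TestAicc:
    def test_zero_parameters(self):
        assert compute_aicc(100.0, 0, 50) == pytest.approx(100.0)

    def test_printed_row(self):
        assert compute_aicc(4026.82, 33, 2455) == pytest.approx(4093.75,
                                                                abs=0.005)

    def test_undefined_when_sample_too_small(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_aicc(10.0, 5, 6)


class TestCountEstimable:
    def test_full_time_cjs_confounding(self):
        # fully time-dependent CJS: 2(T-1) nominal, 2(T-1)-1 estimable
        cfg = SimulationConfig(
            occasions=(0, 1, 2, 3),
            cohort_sizes={0: 400, 1: 400, 2: 400},
            survival={1: 0.65},
            resight={1: 0.5},
            seed=4,
        )
        ma = build_marray(simulate_histories(cfg))
        fit = fit_cjs(ma, parse_model_spec("t", "t"),
                      options=FitOptions(n_starts=2))
        assert fit.np_nominal == 6
        assert fit.np_estimable == 5

    def test_constant_model_rank_two(self):
        cfg = SimulationConfig(
            occasions=(0, 1, 2, 3, 4),
            cohort_sizes={0: 200, 1: 200},
            survival={1: 0.6},
            resight={1: 0.5},
            seed=5,
        )
        ma = build_marray(simulate_histories(cfg))
        fit = fit_cjs(ma, parse_model_spec("1", "1"),
                      options=FitOptions(n_starts=2))
        assert fit.np_estimable == 2

    def test_covariate_model_full_rank(self):
        cov = {"X": {y: float((y * 37) % 11) for y in range(2000, 2008)}}
        cfg = SimulationConfig(
            occasions=tuple(range(2000, 2008)),
            cohort_sizes={y: 150 for y in range(2000, 2007)},
            survival={1: 0.5, 2: 0.8},
            resight={1: 0.5},
            seed=6,
        )
        ma = build_marray(simulate_histories(cfg))
        fit = fit_cjs(ma, parse_model_spec("a(1).X/a(>=2)", "1"), cov,
                      options=FitOptions(n_starts=2))
        assert fit.np_estimable == fit.np_nominal

    def test_rank_drops_identical_duplicate_direction(self):
        h = np.diag([1.0, 1e-9, 2.0])
        assert count_estimable(h, 3) == 2


class TestModelSelectionTable:
    def _fits(self, rng):
        chs = random_set(rng, 5, 80)
        ma = build_marray(chs)
        return [
            fit_cjs(ma, parse_model_spec(s, "t", name=s), options=FAST)
            for s in ("1", "t", "a(1,>=2)")
        ]

    def test_sorted_with_delta(self, rng):
        fits = self._fits(rng)
        table = model_selection_table(fits)
        assert table.delta_aicc.iloc[0] == 0
        assert table.aicc.is_monotonic_increasing
        assert table.best.iloc[0]

    def test_permutation_invariance(self, rng):
        fits = self._fits(rng)
        t1 = model_selection_table(fits)
        t2 = model_selection_table(fits[::-1])
        assert t1.model.tolist() == t2.model.tolist()

    def test_single_fit(self, rng):
        chs = random_set(rng, 4, 30)
        ma = build_marray(chs)
        fit = fit_cjs(ma, parse_model_spec("1", "1"), options=FAST)
        table = model_selection_table([fit])
        assert table.delta_aicc.tolist() == [0.0]

    def test_mixed_n_eff_rejected(self, rng):
        chs = random_set(rng, 4, 30)
        ma = build_marray(chs)
        f1 = fit_cjs(ma, parse_model_spec("1", "1"), options=FAST)
        f2 = fit_cjs(ma, parse_model_spec("1", "1"), options=FAST,
                     n_eff=9999)
        with pytest.raises(ValueError, match="mixed"):
            model_selection_table([f1, f2])
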