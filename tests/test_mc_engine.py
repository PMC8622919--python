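"""Monte Carlo scenario grid, sampler and the deterministic oracle."""

import numpy as np
import pytest

from tacmc.mc_engine import (
    C0D_BY_GENOTYPE,
    InputDistribution,
    ScenarioSpec,
    analytic_fraction_below,
    build_published_scenarios,
    paired_ar_contrast,
    run_simulation,
    sample_inputs,
    scenario_report,
    scenario_seed,
)
from tacmc.outcome_model import PUBLISHED_COEFFICIENTS


def _spec(**kw):
    base = dict(
        egfr6_dist=InputDistribution.uniform_range(30, 44),
        ipv_dist=InputDistribution.uniform_range(30, 59.99),
        c0d_dist=InputDistribution.uniform_mean_sd(1.30, 0.54, min_value=0.0),
        sex=0,
        ar=1,
        n_draws=1000,
        seed=123,
    )
    base.update(kw)
    return ScenarioSpec(**base)


def test_published_grid_is_full_factorial():
    scens = build_published_scenarios(n_draws=1000, base_seed=0)
    assert len(scens) == 32
    assert all(s.n_draws == 1000 for s in scens)
    keys = {tuple(sorted(s.labels.items())) for s in scens}
    assert len(keys) == 32
    low = [s for s in scens if s.labels["genotype"] == "*1/*3"][0]
    assert (low.c0d_dist.mean, low.c0d_dist.sd) == (1.30, 0.54)
    high = [s for s in scens if s.labels["genotype"] == "*3/*3"][0]
    assert (high.c0d_dist.mean, high.c0d_dist.sd) == (1.92, 0.98)


def test_scenario_seeds_deterministic_and_stable():
    a = build_published_scenarios(n_draws=10, base_seed=5)
    b = build_published_scenarios(n_draws=10, base_seed=5)
    assert [s.seed for s in a] == [s.seed for s in b]
    assert len({s.seed for s in a}) == 32  # distinct per cell
    assert all(0 <= s.seed < 2**31 for s in a)
    assert scenario_seed(5, "x") != scenario_seed(5, "y")


def test_point_distributions_give_identical_draws():
    spec = _spec(
        egfr6_dist=InputDistribution.point(47.48),
        ipv_dist=InputDistribution.point(21.21),
        c0d_dist=InputDistribution.point(1.91),
        sex=1,
        ar=0,
        n_draws=50,
    )
    r = run_simulation(spec, PUBLISHED_COEFFICIENTS, (30.0, 45.0))
    assert r.sd == pytest.approx(0.0, abs=1e-12)
    assert r.mean == pytest.approx(49.99, abs=0.01)
    assert np.all(r.egfr_draws == r.egfr_draws[0])


def test_uniform_support_respected():
    draws = sample_inputs(_spec(n_draws=5000))
    assert draws["egfr6"].between(30, 44).all()
    assert draws["ipv_percent"].between(30, 59.99).all()
    assert draws["c0d"].between(1.30 - 0.54, 1.30 + 0.54).all()
    assert (draws["sex"] == 0).all()
    assert (draws["ar"] == 1).all()


def test_sampling_reproducible_from_seed():
    a = sample_inputs(_spec())
    b = sample_inputs(_spec())
    assert a.equals(b)


def test_c0d_truncation_rejects_nonpositive():
    spec = _spec(c0d_dist=InputDistribution.uniform_mean_sd(0.3, 0.5, min_value=0.0), n_draws=4000)
    assert (sample_inputs(spec)["c0d"] > 0).all()


def test_degenerate_uniform_rejected():
    with pytest.raises(ValueError):
        InputDistribution.uniform_range(10.0, 5.0)


def test_fraction_monotone_in_threshold():
    r = run_simulation(_spec(), PUBLISHED_COEFFICIENTS, (30.0, 45.0))
    assert 0.0 <= r.fractions_below[30.0] <= r.fractions_below[45.0] <= 1.0
    assert len(r.egfr_draws) == 1000


def test_mean_of_draws_matches_affine_mean():
    """Linearity: the MC mean equals the model at the distribution means."""
    for spec in build_published_scenarios(n_draws=4000, base_seed=17)[:8]:
        r = run_simulation(spec, PUBLISHED_COEFFICIENTS, ())
        means = {
            "egfr6": np.mean(spec.egfr6_dist.support()),
            "ipv_percent": np.mean(spec.ipv_dist.support()),
            "sex": spec.sex,
            "c0d": np.mean(spec.c0d_dist.support()),
            "ar": spec.ar,
        }
        from tacmc.outcome_model import evaluate_model

        expected = evaluate_model(PUBLISHED_COEFFICIENTS, means)
        assert abs(r.mean - expected) < 4 * r.sd / np.sqrt(len(r.egfr_draws))


def test_paired_seed_ar_contrast_is_exact():
    y0, y1 = paired_ar_contrast(_spec(n_draws=500))
    np.testing.assert_allclose(y1, y0 - 10.112, rtol=0, atol=1e-12)


def test_analytic_oracle_closed_form_single_uniform():
    """One uniform input -> the affine map has a closed-form uniform CDF."""
    spec = _spec(
        egfr6_dist=InputDistribution.point(37.0),
        ipv_dist=InputDistribution.point(45.0),
        c0d_dist=InputDistribution.uniform_range(0.76, 1.84),
    )
    got = analytic_fraction_below(spec, PUBLISHED_COEFFICIENTS, 27.0)
    c = PUBLISHED_COEFFICIENTS
    const = c.intercept + c.b_egfr6 * 37.0 + c.b_ipv * 45.0 + c.b_ar
    cut = (27.0 - const) / c.b_c0d
    expected = (cut - 0.76) / (1.84 - 0.76)
    assert got == pytest.approx(expected, abs=2e-4)


def test_analytic_oracle_closed_form_three_uniforms():
    """Sum of three scaled uniforms: inclusion-exclusion simplex volume."""

    def exact_fraction(spec, threshold):
        c = PUBLISHED_COEFFICIENTS
        const = c.intercept + c.b_sex * spec.sex + c.b_ar * spec.ar
        widths, lows = [], []
        for a, d in ((c.b_egfr6, spec.egfr6_dist), (c.b_ipv, spec.ipv_dist), (c.b_c0d, spec.c0d_dist)):
            lo, hi = d.support()
            w_lo, w_hi = sorted((a * lo, a * hi))
            lows.append(w_lo)
            widths.append(w_hi - w_lo)
        t = threshold - const - sum(lows)
        total = 1.0
        vol = 0.0
        for mask in range(8):
            shift = sum(widths[i] for i in range(3) if mask >> i & 1)
            sign = (-1) ** bin(mask).count("1")
            vol += sign * max(0.0, t - shift) ** 3
        return min(1.0, max(0.0, vol / 6.0 / np.prod(widths)))

    for sex in (0, 1):
        for thr in (25.0, 30.0, 35.0):
            spec = _spec(sex=sex)
            assert analytic_fraction_below(spec, PUBLISHED_COEFFICIENTS, thr) == pytest.approx(
                exact_fraction(spec, thr), abs=5e-4
            )


def test_analytic_oracle_saturates_outside_support():
    spec = _spec()
    assert analytic_fraction_below(spec, PUBLISHED_COEFFICIENTS, -100.0) == 0.0
    assert analytic_fraction_below(spec, PUBLISHED_COEFFICIENTS, 500.0) == 1.0


def test_mc_agrees_with_oracle_binomial_bound():
    """Sampler vs deterministic convolution for a spread of scenarios."""
    n = 50_000
    for spec in build_published_scenarios(n_draws=n, base_seed=29)[::5]:
        r = run_simulation(spec, PUBLISHED_COEFFICIENTS, (30.0, 45.0))
        for t in (30.0, 45.0):
            p = analytic_fraction_below(spec, PUBLISHED_COEFFICIENTS, t)
            bound = 3 * np.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(r.fractions_below[t] - p) <= bound + 1e-4


def test_truncated_normal_modes_available():
    scens = build_published_scenarios(n_draws=2000, base_seed=2, band_mode="truncated_normal", c0d_mode="truncated_normal")
    draws = sample_inputs(scens[0])
    lo, hi = scens[0].egfr6_dist.low, scens[0].egfr6_dist.high
    assert draws["egfr6"].between(lo, hi).all()
    assert (draws["c0d"] > 0).all()


def test_scenario_report_shape_and_determinism():
    scens = build_published_scenarios(n_draws=200, base_seed=8)
    results = [run_simulation(s, PUBLISHED_COEFFICIENTS, (30.0, 45.0)) for s in scens]
    table = scenario_report(results)
    assert len(table) == 32
    assert {"frac_below_30", "frac_below_45"} <= set(table.columns)
    results2 = [run_simulation(s, PUBLISHED_COEFFICIENTS, (30.0, 45.0)) for s in scens]
    table2 = scenario_report(results2)
    assert table.equals(table2)
    # empty threshold list -> no fraction columns
    bare = scenario_report([run_simulation(scens[0], PUBLISHED_COEFFICIENTS, ())])
    assert not [c for c in bare.columns if c.startswith("frac_below")]
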