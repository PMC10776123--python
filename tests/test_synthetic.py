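"""Generators: planted trends, correlated modules, survival cohorts, fibers."""

import numpy as np
import pytest

from metaboaging import preprocess, trends
from metaboaging.mortality import cumulative_mortality
from metaboaging.synthetic import (
    HubSpec,
    ModuleSpec,
    SurvivalSpec,
    TrendSpec,
    default_trend_mixture,
    expected_log10_cumulative_mortality,
    generate_abundance,
    generate_fiber_areas,
    generate_survival,
    trend_pattern,
)


def test_generate_abundance_deterministic():
    specs = default_trend_mixture(50)
    t1, truth1 = generate_abundance(specs, seed=9)
    t2, truth2 = generate_abundance(specs, seed=9)
    assert t1.values.equals(t2.values)
    assert truth1.equals(truth2)
    t3, _ = generate_abundance(specs, seed=10)
    assert not t1.values.equals(t3.values)


def test_mixture_proportions_match_printed_fractions():
    specs = default_trend_mixture(1000)
    types = [s.trend_type for s in specs]
    assert len(specs) == 1000
    assert types.count("no_change") == 721
    assert types.count("bell_both") == 128


def test_planted_group_means_follow_pattern():
    spec = TrendSpec("bell_both", base_log2_mean=10, effect_size=2.0, noise_sd=0.3)
    table, truth = generate_abundance([spec] * 20, n_per_group=7, seed=0)
    log2 = preprocess.log_transform(table, base=2)
    cols = log2.group_columns()
    means = [log2.values[c].to_numpy().mean() for c in cols.values()]
    expected = 10 + trend_pattern("bell_both", 2.0)
    assert np.allclose(means, expected, atol=0.15)
    assert (truth["trend_group"] == "bell").all()


def test_module_members_are_correlated():
    """Within-module correlation averages to loading^2 across modules.

    A single module's realized correlation varies with the sampled factor
    (only 21 samples), so the check pools ten independent modules.
    """
    specs = [TrendSpec("no_change")] * 220
    table, truth = generate_abundance(
        specs, modules=[ModuleSpec(size=20, loading=0.9)] * 10, n_per_group=7, seed=1
    )
    X = np.log2(table.values.to_numpy())
    within = []
    for m in range(10):
        rows = np.where(truth["module"].to_numpy() == m)[0]
        R = np.corrcoef(X[rows])
        within.append(R[np.triu_indices(len(rows), 1)].mean())
    assert np.mean(within) == pytest.approx(0.81, abs=0.05)
    outside = np.corrcoef(X[0], X[210])[0, 1]  # module 0 vs unassigned metabolite
    assert abs(outside) < 0.5


def test_hub_correlates_with_spanned_modules():
    specs = [TrendSpec("no_change")] * 60
    table, truth = generate_abundance(
        specs,
        modules=[ModuleSpec(20), ModuleSpec(20), ModuleSpec(20)],
        hubs=[HubSpec(modules=(0, 1, 2))],
        n_per_group=7,
        seed=2,
    )
    assert truth["is_hub"].sum() == 1
    X = np.log2(table.values.to_numpy())
    hub_row = X[-1]
    r_to_members = [np.corrcoef(hub_row, X[i])[0, 1] for i in range(60)]
    # hub loading * sqrt(rho) * member loading = 0.98*0.866*0.9 ~ 0.76
    assert np.mean(r_to_members) > 0.6


def test_small_n_per_group_is_error():
    with pytest.raises(ValueError, match="n_per_group"):
        generate_abundance([TrendSpec()], n_per_group=2)


def test_oversized_modules_are_error():
    with pytest.raises(ValueError, match="module sizes"):
        generate_abundance([TrendSpec()] * 5, modules=[ModuleSpec(10)])


def test_invalid_trend_spec():
    with pytest.raises(ValueError):
        TrendSpec("sideways")
    with pytest.raises(ValueError):
        TrendSpec(noise_sd=0.0)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


def test_survival_deterministic_and_complete():
    spec = SurvivalSpec(n=39, seed=5)
    d1 = generate_survival(spec)
    d2 = generate_survival(spec)
    assert np.array_equal(d1.death_weeks, d2.death_weeks)
    assert len(d1.death_weeks) + len(d1.censor_weeks) == 39


def test_continuous_plateau_has_no_hazard_jump():
    spec = SurvivalSpec(n=10, plateau_week=45.0, plateau_hazard=1e-4 * np.exp(0.2 * 45))
    h_before = spec.hazard(44.999)
    h_after = spec.hazard(45.001)
    assert h_after == pytest.approx(h_before, rel=1e-3)
    # closed-form curve is smooth through the plateau week
    w = np.arange(40, 50)
    y = expected_log10_cumulative_mortality(spec, w)
    assert np.all(np.isfinite(y))
    assert np.all(np.diff(y) > 0)


def test_huge_hazard_kills_cohort_in_week_one():
    spec = SurvivalSpec(n=100, gompertz_a=5.0, gompertz_b=0.2, seed=0)
    data = generate_survival(spec)
    assert (data.death_weeks == 1).mean() > 0.95


def test_plateau_week_must_be_positive():
    with pytest.raises(ValueError, match="plateau_week"):
        SurvivalSpec(plateau_week=0.0)


def test_expected_curve_matches_large_cohort():
    spec = SurvivalSpec(n=20000, seed=3)
    data = generate_survival(spec)
    series = cumulative_mortality(data)
    weeks = series.log_weeks
    expected = expected_log10_cumulative_mortality(spec, weeks)
    # empirical log-mortality tracks the closed form once counts are sizeable
    late = weeks >= 20
    assert np.abs(series.log_values[late] - expected[late]).max() < 0.05


# ---------------------------------------------------------------------------
# Fibers
# ---------------------------------------------------------------------------


def test_fiber_generator_determinism_and_size():
    a1 = generate_fiber_areas(100, seed=7)
    a2 = generate_fiber_areas(100, seed=7)
    assert np.array_equal(a1, a2)
    assert (a1 > 0).all()


def test_fiber_generator_empty():
    assert len(generate_fiber_areas(0)) == 0


def test_fiber_generator_validates_mixture():
    with pytest.raises(ValueError, match="sum to 1"):
        generate_fiber_areas(10, components=((0.5, 800, 0.4),))
    with pytest.raises(ValueError, match="positive"):
        generate_fiber_areas(10, components=((1.0, -800, 0.4),))
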