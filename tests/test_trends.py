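"""ANOVA/Tukey statistics and the 17-type trend taxonomy."""

from itertools import product

import numpy as np
import pytest
from scipy import stats

from metaboaging import trends
from metaboaging.trends import TrendConfig, anova_tukey, classify_trend

from conftest import build_table

SIG, NS = 0.001, 0.5


def test_studentized_range_sf_matches_scipy_oracle():
    """Fast Gauss-Legendre SF agrees with scipy's integrator to 1e-10."""
    rng = np.random.default_rng(0)
    q = rng.uniform(0.05, 10, 25)
    for df in (6, 18, 57):
        ref = stats.studentized_range.sf(q, 3, df)
        mine = trends.studentized_range_sf(q, 3, df)
        assert np.abs(mine - ref).max() < 1e-10


def test_anova_tukey_matches_statsmodels_on_random_fixtures():
    """Full ANOVA+Tukey path agrees with an independent standard implementation."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rng = np.random.default_rng(1)
    for rep in range(50):
        ns = rng.integers(3, 8, size=3)
        groups = [rng.normal(rng.uniform(-1, 1), rng.uniform(0.2, 2), n) for n in ns]
        F, p, tk = anova_tukey(groups)
        F_ref, p_ref = stats.f_oneway(*groups)
        assert F == pytest.approx(F_ref, abs=1e-8)
        assert p == pytest.approx(p_ref, abs=1e-8)
        data = np.concatenate(groups)
        labels = np.repeat(["A", "B", "C"], ns)
        res = pairwise_tukeyhsd(data, labels)
        # statsmodels orders pairs (A,B), (A,C), (B,C); ours is (AB, BC, AC)
        p_ab, p_ac, p_bc = res.pvalues
        assert tk[0] == pytest.approx(p_ab, abs=1e-8)
        assert tk[1] == pytest.approx(p_bc, abs=1e-8)
        assert tk[2] == pytest.approx(p_ac, abs=1e-8)


def test_no_variance_no_effect():
    F, p, tk = anova_tukey([[1, 1, 1], [1, 1, 1], [1, 1, 1]])
    assert (F, p) == (0.0, 1.0)
    assert tk == (1.0, 1.0, 1.0)


def test_zero_variance_unequal_means_is_maximally_significant():
    F, p, tk = anova_tukey([[1, 1, 1], [2, 2, 2], [2, 2, 2]])
    assert np.isinf(F) and p == 0.0
    assert tk == (0.0, 1.0, 0.0)


def test_strong_bell_fixture_significant():
    rng = np.random.default_rng(3)
    groups = [rng.normal(m, 0.1, 5) for m in (0, 3, 0)]
    F, p, tk = anova_tukey(groups)
    assert p < 1e-6
    assert tk[0] < 0.05 and tk[1] < 0.05


def test_group_label_swap_permutes_tukey():
    rng = np.random.default_rng(4)
    g = [rng.normal(m, 0.5, 5) for m in (0, 1, 2)]
    F1, p1, tk1 = anova_tukey(g)
    F2, p2, tk2 = anova_tukey([g[2], g[1], g[0]])  # reverse the ordering
    assert F2 == pytest.approx(F1) and p2 == pytest.approx(p1)
    assert tk2[0] == pytest.approx(tk1[1])  # AB' = CB = BC
    assert tk2[1] == pytest.approx(tk1[0])
    assert tk2[2] == pytest.approx(tk1[2])


def test_small_group_is_error():
    with pytest.raises(ValueError, match="fewer than 2"):
        anova_tukey([[1.0], [1, 2], [1, 2]])


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

MEANS = {
    (1, 1): (0.0, 1.0, 2.0),
    (-1, -1): (0.0, -1.0, -2.0),
    (1, -1): (0.0, 1.0, 0.0),
    (-1, 1): (0.0, -1.0, 0.0),
}


def test_taxonomy_counts():
    assert trends.taxonomy_size() == (17, 5)


def test_every_input_maps_to_exactly_one_of_17_codes():
    """Brute force over 4 sign patterns x 8 significance patterns."""
    seen = set()
    for means in MEANS.values():
        for flags in product((False, True), repeat=3):
            ps = tuple(SIG if f else NS for f in flags)
            t, g = classify_trend(means, ps)
            assert t in trends.TREND_TYPES
            assert g in trends.TREND_GROUPS
            seen.add(t)
    assert seen == set(trends.TREND_TYPES)  # no code unreachable


def test_all_nonsignificant_is_no_change():
    assert classify_trend((0, 3, 0), (NS, NS, NS)) == ("no_change", "no_change")


def test_bell_both_limbs():
    t, g = classify_trend((0, 3, 0), (SIG, SIG, NS))
    assert (t, g) == ("bell_both", "bell")


def test_gradual_up_only_endpoint_significant():
    t, g = classify_trend((0, 0.4, 3), (NS, NS, SIG))
    assert (t, g) == ("up_gradual", "up")


def test_mean_tie_broken_by_endpoint_direction():
    t, g = classify_trend((0, 0, 3), (NS, SIG, SIG))
    assert g == "up"
    t, g = classify_trend((3, 0, 0), (SIG, NS, SIG))
    assert g == "down"


def test_all_equal_means_with_significance_is_impossible_state():
    with pytest.raises(ValueError, match="impossible"):
        classify_trend((1, 1, 1), (SIG, NS, NS))


def test_bell_calls_have_middle_peak():
    """Bell implies mean B above both flanks; U-shape the reverse."""
    for means in MEANS.values():
        for flags in product((False, True), repeat=3):
            ps = tuple(SIG if f else NS for f in flags)
            t, g = classify_trend(means, ps)
            if g == "bell":
                assert means[1] > means[0] and means[1] > means[2]
            if g == "u_shape":
                assert means[1] < means[0] and means[1] < means[2]


def test_raising_alpha_never_moves_into_no_change():
    """Monotonicity: more liberal alpha can only move calls out of no_change."""
    rng = np.random.default_rng(5)
    for _ in range(200):
        means = rng.normal(size=3)
        ps = rng.uniform(0, 1, 3)
        _, g_lo = classify_trend(means, ps, TrendConfig(alpha=0.01))
        _, g_hi = classify_trend(means, ps, TrendConfig(alpha=0.2))
        if g_lo != "no_change":
            assert g_hi != "no_change"


# ---------------------------------------------------------------------------
# Table-level analysis
# ---------------------------------------------------------------------------


def test_run_trend_analysis_requires_three_groups(toy_table):
    from metaboaging import preprocess

    log2 = preprocess.log_transform(toy_table, base=2)
    with pytest.raises(ValueError, match="3 groups"):
        trends.run_trend_analysis(log2)


def test_run_trend_analysis_matches_per_metabolite_path(three_group_table):
    """Vectorized table analysis equals the scalar anova_tukey per row."""
    from metaboaging import preprocess

    log2 = preprocess.log_transform(three_group_table, base=2)
    calls, summary = trends.run_trend_analysis(log2)
    for met in log2.values.index:
        F, p, tk = anova_tukey(log2.group_arrays(met))
        row = calls.loc[met]
        assert row["anova_F"] == pytest.approx(F, abs=1e-10)
        assert row["anova_p"] == pytest.approx(p, abs=1e-10)
        for col, val in zip(("tukey_p_AB", "tukey_p_BC", "tukey_p_AC"), tk):
            assert row[col] == pytest.approx(val, abs=1e-9)
    assert sum(summary.values()) == pytest.approx(1.0)


def test_run_trend_analysis_requires_log2(three_group_table):
    with pytest.raises(ValueError, match="log2"):
        trends.run_trend_analysis(three_group_table)
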