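"""Breeding-window statistics against independent brute-force oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermsds import (
    BreedingWindow,
    ClimateGrid,
    MonthlySeries,
    RangeMask,
    interannual_fluctuation,
    median_ambient,
    null_window_test,
    range_series,
    resolve_open_window,
    seasonality,
    summarize_species,
    window_months,
)


# ---------------------------------------------------------------------------
# independent oracles: plain double loops, no vectorisation
# ---------------------------------------------------------------------------
def oracle_median(values, window):
    pool = []
    for yr in range(values.shape[0]):
        for m in window_months(window):
            pool.append(values[yr, m - 1])
    pool.sort()
    k = len(pool)
    if k % 2:
        return pool[k // 2]
    return 0.5 * (pool[k // 2 - 1] + pool[k // 2])


def oracle_seasonality(values, window):
    months = window_months(window)
    if len(months) < 2:
        return 0.0
    per_year = []
    for yr in range(values.shape[0]):
        xs = [values[yr, m - 1] for m in months]
        mean = sum(xs) / len(xs)
        per_year.append(sum((x - mean) ** 2 for x in xs) / (len(xs) - 1))
    return sum(per_year) / len(per_year)


def oracle_interannual(values, window):
    per_month = []
    for m in window_months(window):
        xs = [values[yr, m - 1] for yr in range(values.shape[0])]
        mean = sum(xs) / len(xs)
        per_month.append(sum((x - mean) ** 2 for x in xs) / (len(xs) - 1))
    return sum(per_month) / len(per_month)


def random_series(seed, n_years=30):
    rng = np.random.default_rng(seed)
    return MonthlySeries(rng.normal(20, 5, size=(n_years, 12)),
                         np.arange(n_years))


# ---------------------------------------------------------------------------
# window arithmetic
# ---------------------------------------------------------------------------
@pytest.mark.parametrize(
    "start,end,expected",
    [
        (3, 6, [3, 4, 5, 6]),
        (11, 2, [11, 12, 1, 2]),
        (1, 12, list(range(1, 13))),
        (12, 12, [12]),
        (7, 6, list(range(7, 13)) + list(range(1, 7))),
    ],
)
def test_window_months(start, end, expected):
    assert window_months(BreedingWindow(start, end)) == expected


def test_window_month_out_of_range_rejected():
    with pytest.raises(ValueError):
        BreedingWindow(0, 5)
    with pytest.raises(ValueError):
        BreedingWindow(1, 13)


@pytest.mark.parametrize("start,expected_len", [(5, 8), (12, 1), (1, 12)])
def test_resolve_open_window_closes_in_december(start, expected_len):
    w = resolve_open_window(start)
    assert w.end == 12
    assert w.length == expected_len


# ---------------------------------------------------------------------------
# range extraction
# ---------------------------------------------------------------------------
def test_single_cell_mask_is_identity():
    rng = np.random.default_rng(0)
    grid = ClimateGrid(rng.normal(size=(3, 12, 4, 4)), np.arange(3))
    s = range_series(grid, RangeMask.from_indices([(2, 1)]))
    assert np.array_equal(s.values, grid.values[:, :, 2, 1])


def test_two_constant_cells_average():
    vals = np.zeros((2, 12, 1, 2))
    vals[:, :, 0, 0] = 10.0
    vals[:, :, 0, 1] = 20.0
    grid = ClimateGrid(vals, np.arange(2))
    s = range_series(grid, RangeMask.from_indices([(0, 0), (0, 1)]))
    assert np.allclose(s.values, 15.0)


def test_range_series_matches_loop_oracle():
    rng = np.random.default_rng(7)
    grid = ClimateGrid(rng.normal(size=(4, 12, 5, 5)), np.arange(4))
    cells = [(0, 0), (2, 3), (4, 4), (1, 2)]
    s = range_series(grid, RangeMask.from_indices(cells))
    for yr in range(4):
        for m in range(12):
            expected = sum(grid.values[yr, m, r, c] for r, c in cells) / 4
            assert s.values[yr, m] == pytest.approx(expected, abs=1e-12)


def test_empty_and_out_of_grid_masks_rejected():
    grid = ClimateGrid(np.zeros((2, 12, 3, 3)), np.arange(2))
    with pytest.raises(ValueError):
        range_series(grid, RangeMask.from_indices([]))
    with pytest.raises(ValueError):
        range_series(grid, RangeMask.from_indices([(5, 0)]))


# ---------------------------------------------------------------------------
# the three statistics
# ---------------------------------------------------------------------------
def test_constant_series_statistics():
    s = MonthlySeries(np.full((5, 12), 7.25), np.arange(5))
    w = BreedingWindow(2, 9)
    assert median_ambient(s, w) == 7.25
    assert seasonality(s, w) == 0.0
    assert interannual_fluctuation(s, w) == 0.0


def test_odd_count_median():
    vals = np.zeros((1, 12))
    vals[0, :5] = [1, 2, 3, 4, 5]
    s = MonthlySeries(vals, np.arange(1))
    assert median_ambient(s, BreedingWindow(1, 5)) == 3


def test_two_point_variance():
    vals = np.zeros((3, 12))
    vals[:, 0] = 0.0
    vals[:, 1] = 2.0
    s = MonthlySeries(vals, np.arange(3))
    assert seasonality(s, BreedingWindow(1, 2)) == pytest.approx(2.0)


def test_interannual_alternating_month():
    vals = np.zeros((2, 12))
    vals[0, 4] = 0.0
    vals[1, 4] = 2.0
    s = MonthlySeries(vals, np.arange(2))
    assert interannual_fluctuation(s, BreedingWindow(5, 5)) == pytest.approx(2.0)


def test_single_year_interannual_rejected():
    s = MonthlySeries(np.zeros((1, 12)), np.arange(1))
    with pytest.raises(ValueError):
        interannual_fluctuation(s, BreedingWindow(1, 3))


@pytest.mark.parametrize("seed", [1, 2, 3])
@pytest.mark.parametrize("window", [(4, 7), (11, 2), (1, 12), (6, 6)])
def test_statistics_match_brute_force_oracles(seed, window):
    s = random_series(seed)
    w = BreedingWindow(*window)
    assert median_ambient(s, w) == pytest.approx(
        oracle_median(s.values, w), abs=1e-10)
    assert seasonality(s, w) == pytest.approx(
        oracle_seasonality(s.values, w), abs=1e-10)
    assert interannual_fluctuation(s, w) == pytest.approx(
        oracle_interannual(s.values, w), abs=1e-10)


# ---------------------------------------------------------------------------
# invariance properties
# ---------------------------------------------------------------------------
@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), start=st.integers(1, 12),
       end=st.integers(1, 12))
def test_year_permutation_invariance(seed, start, end):
    rng = np.random.default_rng(seed)
    s = random_series(seed)
    w = BreedingWindow(start, end)
    perm = rng.permutation(s.n_years)
    s2 = MonthlySeries(s.values[perm], s.years)
    assert seasonality(s2, w) == pytest.approx(seasonality(s, w), rel=1e-12)
    assert interannual_fluctuation(s2, w) == pytest.approx(
        interannual_fluctuation(s, w), rel=1e-12)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), shift=st.floats(-50, 50),
       start=st.integers(1, 12), end=st.integers(1, 12))
def test_constant_shift_moves_median_only(seed, shift, start, end):
    s = random_series(seed)
    w = BreedingWindow(start, end)
    s2 = MonthlySeries(s.values + shift, s.years)
    assert median_ambient(s2, w) == pytest.approx(
        median_ambient(s, w) + shift, abs=1e-9)
    assert seasonality(s2, w) == pytest.approx(seasonality(s, w), abs=1e-9)
    assert interannual_fluctuation(s2, w) == pytest.approx(
        interannual_fluctuation(s, w), abs=1e-9)


def test_observed_window_within_enumerated_bracket():
    """Any same-length window's seasonality lies between the enumerated
    null's min and max."""
    s = random_series(11)
    for start in (1, 5, 9):
        w = BreedingWindow(start, (start - 1 + 3) % 12 + 1)
        obs = seasonality(s, w)
        null = null_window_test(s, 4).null_values
        assert null.min() - 1e-12 <= obs <= null.max() + 1e-12


# ---------------------------------------------------------------------------
# summaries and the null-window test
# ---------------------------------------------------------------------------
def test_full_year_window_breeding_equals_annual():
    rng = np.random.default_rng(5)
    gt = ClimateGrid(rng.normal(20, 3, (4, 12, 3, 3)), np.arange(4))
    gp = ClimateGrid(rng.gamma(2, 40, (4, 12, 3, 3)), np.arange(4),
                     "precipitation")
    mask = RangeMask.from_indices([(0, 0), (1, 1)])
    summ = summarize_species(gt, gp, mask, BreedingWindow(1, 12))
    for s in summ.values():
        assert s.median_breeding == s.median_annual
        assert s.seasonality_breeding == s.seasonality_annual
        assert s.interannual_breeding == s.interannual_annual


def test_one_month_window_flagged_degenerate():
    rng = np.random.default_rng(6)
    gt = ClimateGrid(rng.normal(size=(3, 12, 2, 2)), np.arange(3))
    summ = summarize_species(gt, None, RangeMask.from_indices([(0, 0)]),
                             BreedingWindow(4, 4))
    assert summ["temperature"].degenerate_seasonality
    assert summ["temperature"].seasonality_breeding == 0.0


def test_null_window_constant_series():
    s = MonthlySeries(np.full((3, 12), 4.0), np.arange(3))
    res = null_window_test(s, 3, observed=0.0)
    assert np.allclose(res.null_values, 0.0)
    assert res.quantile == 1.0  # ties counted as <=


def test_null_window_length_12_single_value():
    s = random_series(8)
    res = null_window_test(s, 12)
    assert np.allclose(res.null_values, res.null_values[0])


def test_null_window_sinusoid_flattest_phase_is_minimum():
    """A window centred on the flat phase of a within-year sinusoid attains
    the enumerated minimum."""
    months = np.arange(1, 13)
    year = 10 + 5 * np.cos(2 * np.pi * (months - 7) / 12)
    s = MonthlySeries(np.tile(year, (4, 1)), np.arange(4))
    null = null_window_test(s, 3)
    # exhaustively find the flattest 3-month placement
    best = min(
        seasonality(s, BreedingWindow(int(st), int((st + 1) % 12 + 1)))
        for st in months
    )
    assert null.null_values.min() == pytest.approx(best, abs=1e-12)


def test_null_window_sample_mode_requires_n_draws():
    s = random_series(9)
    with pytest.raises(ValueError):
        null_window_test(s, 4, mode="sample")
    res = null_window_test(s, 4, mode="sample", n_draws=50, seed=3)
    assert len(res.null_values) == 50
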