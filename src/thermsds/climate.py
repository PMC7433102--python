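"""Breeding-window climate statistics over species ranges.

Monthly gridded climate is averaged over a species' range cells into a
(year x 12) series, and three statistics summarise the months of the
breeding window:

* ambient value — the median over all (year, window-month) values;
* seasonality — the mean over years of the within-year variance across the
  window's months;
* interannual fluctuation — the mean over window months of the across-year
  variance of that month.

A consecutive-month randomisation null compares the observed window's
seasonality against same-length windows at every (or sampled) start month.
Sample (n-1) variances throughout.  Wrap-around windows (start > end) take
their months from the same calendar year.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BreedingWindow",
    "ClimateGrid",
    "RangeMask",
    "MonthlySeries",
    "ClimateSummary",
    "NullWindowResult",
    "window_months",
    "resolve_open_window",
    "range_series",
    "median_ambient",
    "seasonality",
    "interannual_fluctuation",
    "summarize_species",
    "null_window_test",
]


@dataclass(frozen=True)
class BreedingWindow:
    """Inclusive month interval, January=1 .. December=12.

    ``start > end`` means the window wraps the year boundary
    (e.g. (11, 2) covers Nov, Dec, Jan, Feb).
    """

    start: int
    end: int

    def __post_init__(self):
        for m in (self.start, self.end):
            if not (isinstance(m, (int, np.integer)) and 1 <= m <= 12):
                raise ValueError(f"month {m!r} outside 1..12")

    @property
    def length(self) -> int:
        return len(window_months(self))


def window_months(w: BreedingWindow) -> list[int]:
    """The cyclic inclusive month sequence of a window, length 1..12."""
    months = [w.start]
    m = w.start
    while m != w.end:
        m = m % 12 + 1
        months.append(m)
    return months


def resolve_open_window(start: int, end: int | None = None) -> BreedingWindow:
    """Close an open-ended breeding season: an unknown end month becomes
    December."""
    return BreedingWindow(start, 12 if end is None else end)


@dataclass
class ClimateGrid:
    """Monthly gridded climate: values[year, month-1, row, col]."""

    values: np.ndarray
    years: np.ndarray
    variable: str = "temperature"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        if self.values.ndim != 4 or self.values.shape[1] != 12:
            raise ValueError(
                f"expected (years, 12, rows, cols), got {self.values.shape}"
            )
        if len(self.years) != self.values.shape[0]:
            raise ValueError("year labels do not match the first axis")

    @property
    def n_years(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def crop_period(self, start_year: int, end_year: int) -> "ClimateGrid":
        """Restrict to the inclusive year range [start_year, end_year]."""
        keep = (self.years >= start_year) & (self.years <= end_year)
        if not keep.any():
            raise ValueError(f"no data in period {start_year}..{end_year}")
        return ClimateGrid(self.values[keep], self.years[keep], self.variable)


@dataclass(frozen=True)
class RangeMask:
    """A species' range as grid-cell (row, col) indices."""

    cells: tuple

    @classmethod
    def from_indices(cls, indices) -> "RangeMask":
        cells = tuple(sorted((int(r), int(c)) for r, c in indices))
        return cls(cells)

    def __len__(self) -> int:
        return len(self.cells)

    def rows_cols(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.array(self.cells, dtype=int)
        return arr[:, 0], arr[:, 1]


@dataclass
class MonthlySeries:
    """Range-averaged climate, values[year, month-1]."""

    values: np.ndarray
    years: np.ndarray
    variable: str = "temperature"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 12:
            raise ValueError("MonthlySeries needs shape (years, 12)")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("missing values in extracted series")

    @property
    def n_years(self) -> int:
        return self.values.shape[0]


def range_series(grid: ClimateGrid, mask: RangeMask) -> MonthlySeries:
    """Unweighted mean over the mask's cells for each (year, month)."""
    if len(mask) == 0:
        raise ValueError("empty range mask: the range does not intersect the grid")
    rows, cols = mask.rows_cols()
    _, _, nr, nc = grid.shape
    if rows.max() >= nr or cols.max() >= nc or rows.min() < 0 or cols.min() < 0:
        raise ValueError("range mask has cells outside the climate grid")
    vals = grid.values[:, :, rows, cols].mean(axis=2)
    return MonthlySeries(vals, grid.years, grid.variable)


def median_ambient(series: MonthlySeries, window: BreedingWindow) -> float:
    """Median over the pooled {(year, window month)} values."""
    idx = np.array(window_months(window)) - 1
    return float(np.median(series.values[:, idx]))


def seasonality(series: MonthlySeries, window: BreedingWindow) -> float:
    """Mean over years of the within-year sample variance across window months.

    A one-month window has no within-year spread; by convention the value
    is 0 (callers flag this case rather than dropping the species).
    """
    idx = np.array(window_months(window)) - 1
    if len(idx) < 2:
        return 0.0
    return float(series.values[:, idx].var(axis=1, ddof=1).mean())


def interannual_fluctuation(series: MonthlySeries, window: BreedingWindow) -> float:
    """Mean over window months of the across-year sample variance."""
    if series.n_years < 2:
        raise ValueError("interannual fluctuation needs at least two years")
    idx = np.array(window_months(window)) - 1
    return float(series.values[:, idx].var(axis=0, ddof=1).mean())


@dataclass
class ClimateSummary:
    """Windowed and annual climate statistics for one species and variable."""

    variable: str
    median_breeding: float
    median_annual: float
    seasonality_breeding: float
    seasonality_annual: float
    interannual_breeding: float
    interannual_annual: float
    window_length: int
    degenerate_seasonality: bool = False  # one-month window: seasonality 0 by fiat

    def to_dict(self) -> dict:
        return {
            f"{k}_{self.variable}" if k != "variable" else k: v
            for k, v in self.__dict__.items()
            if k != "variable"
        }


def _summary_one(series: MonthlySeries, window: BreedingWindow) -> ClimateSummary:
    annual = BreedingWindow(1, 12)
    return ClimateSummary(
        variable=series.variable,
        median_breeding=median_ambient(series, window),
        median_annual=median_ambient(series, annual),
        seasonality_breeding=seasonality(series, window),
        seasonality_annual=seasonality(series, annual),
        interannual_breeding=interannual_fluctuation(series, window),
        interannual_annual=interannual_fluctuation(series, annual),
        window_length=window.length,
        degenerate_seasonality=window.length == 1,
    )


def summarize_species(
    grid_temp: ClimateGrid,
    grid_precip: ClimateGrid | None,
    mask: RangeMask,
    window: BreedingWindow,
) -> dict[str, ClimateSummary]:
    """All six statistics per climate variable for one species."""
    out = {"temperature": _summary_one(range_series(grid_temp, mask), window)}
    if grid_precip is not None:
        out["precipitation"] = _summary_one(
            range_series(grid_precip, mask), window
        )
    return out


@dataclass
class NullWindowResult:
    null_values: np.ndarray
    observed: float
    quantile: float  # P(null <= observed), ties counted as <=
    mode: str
    window_length: int


def null_window_test(
    series: MonthlySeries,
    window_length: int,
    observed: float | None = None,
    mode: str = "enumerate",
    n_draws: int | None = None,
    seed: int | None = None,
    statistic=seasonality,
) -> NullWindowResult:
    """Consecutive-month randomisation null for a window statistic.

    ``enumerate`` evaluates all 12 cyclic placements of a window of the
    given length (the exact null); ``sample`` draws start months with
    replacement.  ``observed`` defaults to nothing: when given, its
    empirical quantile under the null is reported with ties counted as <=.
    """
    if not 1 <= window_length <= 12:
        raise ValueError("window_length must be in 1..12")
    if mode == "enumerate":
        starts = np.arange(1, 13)
    elif mode == "sample":
        if n_draws is None:
            raise ValueError("sample mode requires n_draws")
        rng = np.random.default_rng(seed)
        starts = rng.integers(1, 13, size=n_draws)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    null_vals = np.array(
        [
            statistic(
                series,
                BreedingWindow(int(s), int((s - 1 + window_length - 1) % 12 + 1)),
            )
            for s in starts
        ]
    )
    q = np.nan
    obs = np.nan
    if observed is not None:
        obs = float(observed)
        q = float(np.mean(null_vals <= obs))
    return NullWindowResult(null_vals, obs, q, mode, window_length)
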