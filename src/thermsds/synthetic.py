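"""Synthetic study generator: phylogeny, sex-determination states, climate,
ranges, breeding windows and life-history traits with the statistical
structure the comparative analysis assumes.

Defaults emulate the study conditions of the empirical dataset the pipeline
targets: 213 species, 38-ish families, 11 clustered GSD-to-TSD transitions,
30 years of monthly climate, TSD ranges centred on cells warmer by ~3 deg C,
and breeding windows aligned with the warm months.  Everything is
deterministic under a fixed seed.
"""
from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .climate import (
    BreedingWindow,
    ClimateGrid,
    MonthlySeries,
    RangeMask,
    range_series,
    seasonality,
    window_months,
)
from .trees import Phylogeny

__all__ = [
    "SimConfig",
    "SyntheticStudy",
    "MkResult",
    "simulate_tree",
    "simulate_binary_mk",
    "simulate_climate_grid",
    "simulate_ranges_and_windows",
    "simulate_ou_trait",
    "simulate_study",
    "default_window_length_probs",
]


def default_window_length_probs() -> np.ndarray:
    """Breeding-window length distribution.

    The empirical split is 144/213 short windows (1-4 months) versus 69/213
    long windows (5-12 months); within each band lengths are uniform.
    """
    p = np.empty(12)
    p[:4] = (144 / 213) / 4
    p[4:] = (69 / 213) / 8
    return p / p.sum()


@dataclass
class SimConfig:
    """Configuration of a synthetic study.

    Temperature model per cell/month/year:
    ``T = base - gradient*|lat| + amplitude(lat)*cos(2pi(month-peak)/12)
    + year noise + month noise`` with ``amplitude(lat) = amp0 +
    amp_slope*|lat|`` and the seasonal peak phase-flipped by six months in
    the southern hemisphere.  Latitude is the row index mapped linearly to
    [-60, 60] degrees.  Precipitation is analogous with a nonnegativity
    clamp.
    """

    n_species: int = 213
    n_years: int = 30
    grid_rows: int = 40
    grid_cols: int = 40
    seed: int = 0

    # tree
    birth_rate: float = 1.0
    death_rate: float = 0.0

    # binary sex-determination trait (0=GSD, 1=TSD)
    mk_rates: tuple[float, float] | None = None  # None: auto from target
    target_transitions: int | None = 11
    mk_max_attempts: int = 10_000

    # range placement and windows
    sds_temp_effect: float = 3.0  # deg C warmer TSD range centroids
    range_size_median: float = 25.0  # cells
    range_size_sigma: float = 0.6  # lognormal sigma
    cell_area_km2: float = 1000.0
    window_mode: str = "warmest"  # warmest | stablest | random
    window_length_probs: np.ndarray = field(
        default_factory=default_window_length_probs
    )

    # continuous (life-history) traits
    ou_alpha: float = 1.0
    ou_sigma: float = 1.0
    trait_obs_prob: float = 0.6
    frac_viviparous: float = 31 / 213

    # climate model
    temp_base: float = 28.0
    temp_gradient: float = 0.35  # deg C per degree latitude
    temp_amp0: float = 2.0
    temp_amp_slope: float = 0.15
    temp_year_sd: float = 0.5
    temp_month_sd: float = 1.0
    peak_month: int = 7
    precip_base: float = 150.0
    precip_gradient: float = 1.5
    precip_amp0: float = 20.0
    precip_amp_slope: float = 0.5
    precip_year_sd: float = 10.0
    precip_month_sd: float = 20.0

    def __post_init__(self):
        for name in ("n_species", "n_years", "grid_rows", "grid_cols"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if self.mk_rates is not None and any(r < 0 for r in self.mk_rates):
            raise ValueError("Mk rates must be nonnegative")
        if self.window_mode not in ("warmest", "stablest", "random"):
            raise ValueError(f"unknown window mode {self.window_mode!r}")
        p = np.asarray(self.window_length_probs, dtype=float)
        if p.shape != (12,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("window_length_probs must be 12 probabilities")
        self.window_length_probs = p


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------
def simulate_tree(
    n_species: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int | None = None,
    scale_depth: float | None = 1.0,
) -> Phylogeny:
    """Birth-death tree conditioned on exactly ``n_species`` extant tips.

    Tips are relabelled ``sp0001..`` in a canonical order and the tree is
    rescaled so the root-to-tip depth equals ``scale_depth`` (default 1),
    which fixes the time units OU rates are quoted in.
    """
    if n_species < 2:
        raise ValueError("need at least two species")
    if not (birth_rate > death_rate >= 0):
        raise ValueError("need birth_rate > death_rate >= 0")
    rng = _random.Random(None if seed is None else int(seed))
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_species,
        rng=rng,
        repeat_until_success=True,
    )
    # the simulation halts exactly at the n-th speciation event, leaving the
    # youngest tips with zero-length branches: run the clock forward by the
    # waiting time to the next event, which preserves ultrametricity
    dt = rng.expovariate(n_species * (birth_rate + death_rate))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + dt
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:04d}"
    phylo = Phylogeny(tree)
    if scale_depth is not None:
        phylo = phylo.scaled_to_depth(scale_depth)
    return phylo


# ---------------------------------------------------------------------------
# binary trait (Mk) simulation
# ---------------------------------------------------------------------------
@dataclass
class MkResult:
    tip_states: pd.Series  # 0/1 per tip label
    n_transitions: int
    rates: tuple[float, float]
    node_states: dict  # id(dendropy node) -> state
    attempts: int = 1


def _mk_once(tree: dendropy.Tree, q01: float, q10: float, root_state: int, rng):
    states: dict[int, int] = {}
    tips: dict[str, int] = {}
    n_changes = 0
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            states[id(node)] = root_state
        else:
            s = states[id(parent)]
            t = node.edge.length
            pos = 0.0
            while True:
                rate = q01 if s == 0 else q10
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if pos + wait > t:
                    break
                pos += wait
                s = 1 - s
                n_changes += 1
            states[id(node)] = s
        if node.is_leaf():
            tips[node.taxon.label] = states[id(node)]
    return tips, n_changes, states


def simulate_binary_mk(
    tree: Phylogeny,
    rates: tuple[float, float] | None = None,
    seed: int | None = None,
    target_transitions: int | None = None,
    root_state: int = 0,
    max_attempts: int = 10_000,
    rng: np.random.Generator | None = None,
) -> MkResult:
    """Simulate a binary trait (0=GSD, 1=TSD) along the tree under an
    asymmetric Mk model, optionally conditioning on the realised number of
    state changes by rejection sampling.

    ``rates=None`` picks ``q01 = target/total_tree_length`` (and ``q10=0``,
    one-way gains as in a GSD root with derived TSD clades), which puts the
    expected change count near the target so rejection is cheap.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    dtree = tree.dendropy_tree
    total_len = sum(
        e.length for e in dtree.preorder_edge_iter() if e.length is not None
    )
    if rates is None:
        goal = target_transitions if target_transitions is not None else 3
        rates = (goal / total_len, 0.0)
    q01, q10 = rates
    if q01 < 0 or q10 < 0:
        raise ValueError("Mk rates must be nonnegative")
    attempts = 0
    while True:
        attempts += 1
        tips, n_changes, states = _mk_once(dtree, q01, q10, root_state, rng)
        if target_transitions is None or n_changes == target_transitions:
            break
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not realise exactly {target_transitions} transitions "
                f"in {max_attempts} attempts (rates {rates})"
            )
    series = pd.Series(
        [tips[lab] for lab in tree.tip_labels], index=tree.tip_labels, dtype=int
    )
    return MkResult(series, n_changes, (q01, q10), states, attempts)


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------
def _latitudes(rows: int) -> np.ndarray:
    if rows == 1:
        return np.zeros(1)
    return np.linspace(-60.0, 60.0, rows)


def _one_grid(
    cfg: SimConfig,
    rng: np.random.Generator,
    base: float,
    gradient: float,
    amp0: float,
    amp_slope: float,
    year_sd: float,
    month_sd: float,
    clamp: bool,
    variable: str,
) -> ClimateGrid:
    lat = _latitudes(cfg.grid_rows)
    months = np.arange(1, 13)
    amp = amp0 + amp_slope * np.abs(lat)  # (rows,)
    peak = np.where(lat >= 0, cfg.peak_month, (cfg.peak_month + 5) % 12 + 1)
    seasonal = amp[None, :] * np.cos(
        2.0 * np.pi * (months[:, None] - peak[None, :]) / 12.0
    )  # (12, rows)
    mean_field = (base - gradient * np.abs(lat))[None, :] + seasonal  # (12, rows)
    shape = (cfg.n_years, 12, cfg.grid_rows, cfg.grid_cols)
    year_noise = rng.normal(0.0, year_sd, size=(cfg.n_years, 1, cfg.grid_rows,
                                               cfg.grid_cols))
    month_noise = rng.normal(0.0, month_sd, size=shape)
    values = mean_field[None, :, :, None] + year_noise + month_noise
    if clamp:
        values = np.clip(values, 0.0, None)
    return ClimateGrid(values, np.arange(cfg.n_years), variable)


def simulate_climate_grid(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[ClimateGrid, ClimateGrid]:
    """Monthly temperature and precipitation grids under the latitudinal
    seasonal model described on :class:`SimConfig`."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    temp = _one_grid(
        cfg, rng, cfg.temp_base, cfg.temp_gradient, cfg.temp_amp0,
        cfg.temp_amp_slope, cfg.temp_year_sd, cfg.temp_month_sd,
        clamp=False, variable="temperature",
    )
    precip = _one_grid(
        cfg, rng, cfg.precip_base, cfg.precip_gradient, cfg.precip_amp0,
        cfg.precip_amp_slope, cfg.precip_year_sd, cfg.precip_month_sd,
        clamp=True, variable="precipitation",
    )
    return temp, precip


# ---------------------------------------------------------------------------
# ranges and breeding windows
# ---------------------------------------------------------------------------
def _centroid_for_target(
    cell_means: np.ndarray, target: float, rng: np.random.Generator,
    n_nearest: int = 30,
) -> int:
    """A flat cell index sampled uniformly among the cells whose mean
    temperature is closest to ``target``."""
    flat = cell_means.ravel()
    k = min(n_nearest, flat.size)
    nearest = np.argpartition(np.abs(flat - target), k - 1)[:k]
    return int(rng.choice(np.sort(nearest)))


def _grow_blob(
    start: tuple[int, int], size: int, rows: int, cols: int,
    rng: np.random.Generator,
) -> RangeMask:
    """Seeded breadth-first blob growth from a centroid cell (4-neighbour)."""
    if size > rows * cols:
        raise ValueError(f"range size {size} exceeds the grid ({rows}x{cols})")
    blob = {start}
    frontier = [start]
    while len(blob) < size:
        if not frontier:  # stuck (cannot happen on a rectangle, kept for safety)
            break
        k = int(rng.integers(len(frontier)))
        r, c = frontier[k]
        neighbours = [
            (r + dr, c + dc)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if 0 <= r + dr < rows and 0 <= c + dc < cols
            and (r + dr, c + dc) not in blob
        ]
        if not neighbours:
            frontier.pop(k)
            continue
        cell = neighbours[int(rng.integers(len(neighbours)))]
        blob.add(cell)
        frontier.append(cell)
    return RangeMask.from_indices(blob)


def _place_window(
    series: MonthlySeries, length: int, mode: str, rng: np.random.Generator
) -> BreedingWindow:
    starts = np.arange(1, 13)
    if mode == "random":
        s = int(rng.integers(1, 13))
    else:
        scores = np.empty(12)
        for i, s0 in enumerate(starts):
            w = BreedingWindow(int(s0), int((s0 - 1 + length - 1) % 12 + 1))
            idx = np.array(window_months(w)) - 1
            if mode == "warmest":
                scores[i] = -series.values[:, idx].mean()  # minimise negative mean
            else:  # stablest
                scores[i] = seasonality(series, w)
        best = scores.min()
        tol = 1e-9 * max(1.0, abs(best))  # float noise must not break ties
        s = int(starts[np.flatnonzero(scores <= best + tol)[0]])
    return BreedingWindow(s, int((s - 1 + length - 1) % 12 + 1))


def simulate_ranges_and_windows(
    tree: Phylogeny,
    sds_states: pd.Series,
    grid_temp: ClimateGrid,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict, dict, dict]:
    """Contiguous range blobs and breeding windows per ``cfg.window_mode``.

    Range placement is phylogenetically conserved: a latent
    habitat-preference trait evolves along the tree under OU, its normal
    quantile maps to the grid's cell-temperature distribution, and TSD
    species get a further ``sds_temp_effect`` warm shift — so TSD range
    centroids are warmer than GSD ones by the configured amount on average
    while related species occupy similar climates, as real ranges do.

    Returns ``(masks, windows, areas)`` keyed by tip label.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid_rows, cfg.grid_cols
    # warm-season warmth per cell: climatological mean of the warmest
    # 4 consecutive months — the temperature a warm-month breeder sees,
    # so the configured TSD shift carries into breeding-window statistics
    clim = grid_temp.values.mean(axis=0)  # (12, rows, cols)
    windows4 = np.stack(
        [np.take(clim, range(s, s + 4), axis=0, mode="wrap").mean(axis=0)
         for s in range(12)]
    )
    cell_means = windows4.max(axis=0)  # (rows, cols)
    flat = np.sort(cell_means.ravel())
    habitat = simulate_ou_trait(tree, alpha=1.0, sigma=1.0, rng=rng)
    habitat = (habitat - habitat.mean()) / max(habitat.std(ddof=0), 1e-12)
    quantiles = pd.Series(stats.norm.cdf(habitat), index=habitat.index)
    masks: dict[str, RangeMask] = {}
    windows: dict[str, BreedingWindow] = {}
    areas: dict[str, float] = {}
    for label in tree.tip_labels:
        if label not in sds_states.index:
            raise ValueError(f"no sex-determination state for tip {label!r}")
        target = flat[int(quantiles[label] * (flat.size - 1))]
        if sds_states[label] == 1:
            target += cfg.sds_temp_effect
        target = float(np.clip(target, flat[0], flat[-1]))
        flat_idx = _centroid_for_target(cell_means, target, rng)
        centroid = (flat_idx // cols, flat_idx % cols)
        size = int(np.clip(
            np.round(rng.lognormal(np.log(cfg.range_size_median),
                                   cfg.range_size_sigma)),
            4, min(200, rows * cols),
        ))
        mask = _grow_blob(centroid, size, rows, cols, rng)
        series = range_series(grid_temp, mask)
        length = int(rng.choice(np.arange(1, 13), p=cfg.window_length_probs))
        windows[label] = _place_window(series, length, cfg.window_mode, rng)
        masks[label] = mask
        areas[label] = len(mask) * cfg.cell_area_km2
    return masks, windows, areas


# ---------------------------------------------------------------------------
# continuous traits
# ---------------------------------------------------------------------------
def simulate_ou_trait(
    tree: Phylogeny,
    alpha: float,
    sigma: float,
    optimum_by_state: dict | None = None,
    node_states: dict | None = None,
    root_value: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Simulate a continuous trait along the tree under an OU process.

    ``alpha=0`` reduces exactly to Brownian motion.  With
    ``optimum_by_state`` (mapping state -> optimum) and ``node_states``
    (from :func:`simulate_binary_mk`), each branch is pulled toward the
    optimum of its child node's state, embedding a recoverable effect of the
    binary trait.
    """
    if alpha < 0 or sigma < 0:
        raise ValueError("need alpha >= 0 and sigma >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    dtree = tree.dendropy_tree
    values: dict[int, float] = {}
    tips: dict[str, float] = {}
    for node in dtree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            values[id(node)] = root_value
        else:
            x0 = values[id(parent)]
            t = node.edge.length
            if optimum_by_state is not None and node_states is not None:
                theta = optimum_by_state[node_states[id(node)]]
            else:
                theta = root_value
            if alpha == 0:
                mean = x0
                var = sigma**2 * t
            else:
                decay = np.exp(-alpha * t)
                mean = theta + (x0 - theta) * decay
                var = sigma**2 * (1.0 - decay**2) / (2.0 * alpha)
            values[id(node)] = mean + rng.normal(0.0, np.sqrt(var))
        if node.is_leaf():
            tips[node.taxon.label] = values[id(node)]
    return pd.Series([tips[lab] for lab in tree.tip_labels],
                     index=tree.tip_labels, dtype=float)


# ---------------------------------------------------------------------------
# whole-study assembly
# ---------------------------------------------------------------------------
@dataclass
class SyntheticStudy:
    tree: Phylogeny
    traits: pd.DataFrame
    grid_temp: ClimateGrid
    grid_precip: ClimateGrid
    masks: dict
    true_params: dict

    def __post_init__(self):
        if set(self.traits.index) != set(self.tree.tip_labels):
            raise ValueError("trait table does not match tree tips 1:1")
        if any(len(self.masks[lab]) == 0 for lab in self.traits.index):
            raise ValueError("every species needs a nonempty range mask")


def _families_from_tree(tree: Phylogeny, target: int = 38) -> pd.Series:
    """Assign family labels by cutting the tree at the depth that yields a
    clade count closest to ``target``."""
    dtree = tree.dendropy_tree
    depths: dict[int, float] = {}
    for node in dtree.preorder_node_iter():
        p = node.parent_node
        depths[id(node)] = 0.0 if p is None else depths[id(p)] + node.edge.length

    def clades_at(frac: float) -> list:
        cut = frac * tree.depth
        roots = []
        for node in dtree.preorder_node_iter():
            p = node.parent_node
            if p is None:
                continue
            if depths[id(p)] <= cut < depths[id(node)] or (
                node.is_leaf() and depths[id(node)] <= cut
            ):
                roots.append(node)
        return roots

    best = None
    for frac in np.linspace(0.05, 0.95, 19):
        roots = clades_at(frac)
        score = abs(len(roots) - target)
        if best is None or score < best[0]:
            best = (score, roots)
    fam = {}
    for k, root in enumerate(best[1]):
        for leaf in root.leaf_iter():
            fam[leaf.taxon.label] = f"fam{k + 1:02d}"
    return pd.Series([fam[lab] for lab in tree.tip_labels],
                     index=tree.tip_labels)


_CONTINENTS = ["Africa", "Americas", "Asia", "Europe", "Oceania"]


def simulate_study(cfg: SimConfig) -> SyntheticStudy:
    """Generate a complete, internally consistent synthetic study."""
    rng = np.random.default_rng(cfg.seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=6)]
    tree = simulate_tree(cfg.n_species, cfg.birth_rate, cfg.death_rate,
                         seed=sub[0])
    mk = simulate_binary_mk(
        tree, rates=cfg.mk_rates, target_transitions=cfg.target_transitions,
        max_attempts=cfg.mk_max_attempts, rng=np.random.default_rng(sub[1]),
    )
    grid_temp, grid_precip = simulate_climate_grid(
        cfg, rng=np.random.default_rng(sub[2])
    )
    masks, windows, areas = simulate_ranges_and_windows(
        tree, mk.tip_states, grid_temp, cfg, rng=np.random.default_rng(sub[3])
    )

    trng = np.random.default_rng(sub[4])
    latent_size = simulate_ou_trait(tree, cfg.ou_alpha, cfg.ou_sigma, rng=trng)
    body_length = latent_size + trng.normal(0, 0.3, tree.n_tips)
    body_mass = 2.0 * latent_size + trng.normal(0, 0.5, tree.n_tips)
    longevity = (
        0.5 * latent_size
        + simulate_ou_trait(tree, cfg.ou_alpha, cfg.ou_sigma, rng=trng)
    )
    obs = trng.random((tree.n_tips, 3)) < cfg.trait_obs_prob
    body_length = body_length.where(pd.Series(obs[:, 0], index=body_length.index))
    body_mass = body_mass.where(pd.Series(obs[:, 1], index=body_mass.index))
    longevity = longevity.where(pd.Series(obs[:, 2], index=longevity.index))

    labels = tree.tip_labels
    med_temp = pd.Series(
        {lab: float(np.median(range_series(grid_temp, masks[lab]).values))
         for lab in labels}
    )
    # viviparity: overwhelmingly GSD species in the coldest ranges
    n_viv = int(round(cfg.frac_viviparous * cfg.n_species))
    repro = pd.Series(0, index=labels, dtype=int)
    if n_viv > 0:
        gsd = [lab for lab in labels if mk.tip_states[lab] == 0]
        tsd = [lab for lab in labels if mk.tip_states[lab] == 1]
        cold_gsd = med_temp[gsd].sort_values().index[: max(0, n_viv - 1)]
        repro[cold_gsd] = 1
        if tsd and n_viv > 1:
            repro[med_temp[tsd].sort_values().index[0]] = 1

    centro_col = {lab: np.mean([c for _, c in masks[lab].cells]) for lab in labels}
    cont = pd.Series(
        {lab: _CONTINENTS[min(4, int(centro_col[lab] / cfg.grid_cols * 5))]
         for lab in labels}
    )

    traits = pd.DataFrame(
        {
            "species": labels,
            "sds": mk.tip_states[labels].values,
            "reproductive_mode": repro[labels].values,
            "breed_start": [windows[lab].start for lab in labels],
            "breed_end": [windows[lab].end for lab in labels],
            "family": _families_from_tree(tree).values,
            "continent": cont[labels].values,
            "area": [areas[lab] for lab in labels],
            "body_length": body_length[labels].values,
            "body_mass": body_mass[labels].values,
            "longevity": longevity[labels].values,
        }
    ).set_index("species")

    true_params = {
        "seed": cfg.seed,
        "sds_temp_effect": cfg.sds_temp_effect,
        "mk_rates": list(mk.rates),
        "n_transitions": mk.n_transitions,
        "mk_attempts": mk.attempts,
        "window_mode": cfg.window_mode,
        "ou_alpha": cfg.ou_alpha,
        "ou_sigma": cfg.ou_sigma,
        "n_viviparous": int(repro.sum()),
    }
    return SyntheticStudy(tree, traits, grid_temp, grid_precip, masks,
                          true_params)
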