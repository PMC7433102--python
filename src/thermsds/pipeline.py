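"""End-to-end comparative analysis: assemble per-species records, run the
hypothesis tests and robustness schemes, and emit a results report.

The pipeline links the type of sex-determination system (SDS; 0=GSD,
1=TSD) of each species to the climate its range experiences during the
breeding season.  Core models regress the binary SDS on each windowed
climate statistic by OU-PGLS (with and without viviparous species, with
and without range-size weights), contrast group variances and
interactions, compute Pagel-lambda signal for every variable, and probe
robustness by continent jackknife and family-constrained subsampling.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .climate import (
    BreedingWindow,
    ClimateGrid,
    RangeMask,
    null_window_test,
    range_series,
    resolve_open_window,
    seasonality,
    summarize_species,
)
from .phyloreg import (
    OUCorrelation,
    PGLSFit,
    ancova_interaction,
    area_weights,
    pgls_fit,
    phylosig_lambda,
    variance_heterogeneity_test,
)
from .trees import Phylogeny

__all__ = [
    "LifeHistoryIndex",
    "zscore_index",
    "assemble_records",
    "fit_sds_model",
    "run_core_models",
    "reference_temp_test",
    "continent_jackknife",
    "subsample_robustness",
    "fig_s5_comparison",
]

LIFE_HISTORY_TRAITS = ("body_length", "body_mass", "longevity")

CLIMATE_COLUMNS = [
    "median_breeding_temperature",
    "seasonality_breeding_temperature",
    "interannual_breeding_temperature",
    "median_annual_temperature",
    "seasonality_annual_temperature",
    "interannual_annual_temperature",
    "median_breeding_precipitation",
    "seasonality_breeding_precipitation",
    "interannual_breeding_precipitation",
    "median_annual_precipitation",
    "seasonality_annual_precipitation",
    "interannual_annual_precipitation",
]

# the variables whose phylogenetic signal is routinely reported
SIGNAL_VARIABLES = [
    "sds",
    "reproductive_mode",
    "median_breeding_temperature",
    "seasonality_breeding_temperature",
    "interannual_breeding_temperature",
    "median_breeding_precipitation",
    "seasonality_breeding_precipitation",
    "interannual_breeding_precipitation",
]


# ---------------------------------------------------------------------------
# life-history index
# ---------------------------------------------------------------------------
@dataclass
class LifeHistoryIndex:
    z_scores: pd.DataFrame  # per-trait Z columns (NaN where missing)
    index: pd.Series  # mean of available Z scores; NaN when none available
    n_traits: pd.Series  # how many traits contributed per species


def zscore_index(traits: pd.DataFrame,
                 columns=LIFE_HISTORY_TRAITS) -> LifeHistoryIndex:
    """Z-score each life-history trait over its non-missing species and
    average the available Z scores into a single fast-slow index.

    Z_i = (x_i - mean) / sd per column; a species with only a subset of the
    traits gets the mean of the Z scores it has, so the index covers far
    more species than the complete-case intersection.
    """
    zs = {}
    for col in columns:
        if col not in traits.columns:
            continue
        x = traits[col].astype(float)
        ok = x.notna()
        if ok.sum() < 2:
            warnings.warn(f"life-history column {col!r} is (almost) all "
                          "missing; excluded")
            continue
        sd = x[ok].std(ddof=1)
        if sd == 0:
            warnings.warn(f"life-history column {col!r} is constant; excluded")
            continue
        zs[col] = (x - x[ok].mean()) / sd
    if not zs:
        raise ValueError("no usable life-history columns")
    zdf = pd.DataFrame(zs)
    return LifeHistoryIndex(
        z_scores=zdf,
        index=zdf.mean(axis=1, skipna=True),
        n_traits=zdf.notna().sum(axis=1),
    )


# ---------------------------------------------------------------------------
# record assembly
# ---------------------------------------------------------------------------
def assemble_records(
    traits: pd.DataFrame,
    tree: Phylogeny,
    grid_temp: ClimateGrid,
    grid_precip: ClimateGrid | None,
    masks: dict[str, RangeMask],
) -> tuple[pd.DataFrame, dict]:
    """Merge trait rows with windowed climate summaries.

    Returns (records, exclusions): only species present on the tree and
    holding a nonempty range mask are kept; every exclusion is listed with
    its reason.
    """
    exclusions: dict[str, str] = {}
    tips = set(tree.tip_labels)
    rows = {}
    for sp, row in traits.iterrows():
        if sp not in tips:
            exclusions[sp] = "not a tip of the tree"
            continue
        if sp not in masks or len(masks[sp]) == 0:
            exclusions[sp] = "no range mask"
            continue
        end = row["breed_end"]
        window = resolve_open_window(
            int(row["breed_start"]),
            None if pd.isna(end) else int(end),
        )
        summ = summarize_species(grid_temp, grid_precip, masks[sp], window)
        rec = dict(row)
        rec["breed_end"] = window.end
        rec["window_length"] = window.length
        for var, s in summ.items():
            rec[f"median_breeding_{var}"] = s.median_breeding
            rec[f"median_annual_{var}"] = s.median_annual
            rec[f"seasonality_breeding_{var}"] = s.seasonality_breeding
            rec[f"seasonality_annual_{var}"] = s.seasonality_annual
            rec[f"interannual_breeding_{var}"] = s.interannual_breeding
            rec[f"interannual_annual_{var}"] = s.interannual_annual
        rows[sp] = rec
    records = pd.DataFrame.from_dict(rows, orient="index")
    records.index.name = "species"
    return records, exclusions


# ---------------------------------------------------------------------------
# model fitting helpers
# ---------------------------------------------------------------------------
def fit_sds_model(
    records: pd.DataFrame,
    tree: Phylogeny,
    climate_var: str,
    weighted: bool = False,
    direction: str = "climate_on_sds",
    factor: str = "sds",
) -> PGLSFit:
    """OU-PGLS linking the binary SDS to one climate variable.

    ``direction="climate_on_sds"`` (default) fits climate ~ SDS, putting
    the OU residual model on the climate trait; the slope is then the
    TSD-GSD offset in the variable's own units.  ``"sds_on_climate"``
    fits the 0/1 SDS as a linear-probability response instead (the
    logistic variant lives in
    :func:`thermsds.phyloreg.phylo_logistic_fit`).
    """
    sub = tree.subset(records.index) if len(records) < tree.n_tips else tree
    rec = records.loc[sub.tip_labels]
    w = area_weights(rec["area"].values) if weighted else None
    if direction == "climate_on_sds":
        y = rec[climate_var].values
        X = pd.DataFrame(
            {"const": np.ones(len(rec)), factor: rec[factor].astype(float).values},
            index=rec.index,
        )
        term, formula = factor, f"{climate_var} ~ {factor}"
    elif direction == "sds_on_climate":
        y = rec[factor].astype(float).values
        X = pd.DataFrame(
            {"const": np.ones(len(rec)), climate_var: rec[climate_var].values},
            index=rec.index,
        )
        term, formula = climate_var, f"{factor} ~ {climate_var}"
    else:
        raise ValueError(f"unknown direction {direction!r}")
    fit = pgls_fit(y, X, sub, OUCorrelation(), weights=w, formula=formula)
    fit.term = term
    return fit


def _summary(fit: PGLSFit, term: str) -> dict:
    return {
        "slope": float(fit.params[term]),
        "se": float(fit.bse[term]),
        "p": float(fit.pvalues[term]),
        "alpha": fit.corr_param,
        "n": fit.n,
        "weighted": fit.weights is not None,
    }


def run_core_models(records: pd.DataFrame, tree: Phylogeny) -> dict:
    """The battery of primary analyses.

    For each windowed climate statistic: SDS ~ statistic by OU-PGLS, across
    the four (all vs oviparous-only) x (unweighted vs range-weighted)
    variants; phylogeny-corrected variance-heterogeneity contrasts of
    ambient temperature and precipitation between SDS groups; the
    SDS x breeding-duration ANCOVA; the reproductive-mode interaction
    model; and Pagel-lambda signal for the standard variable set.
    """
    out: dict = {"n_species": len(records)}
    ovi = records[records["reproductive_mode"] == 0]
    subsets = {"all": records, "oviparous": ovi}

    sds_models: dict = {}
    for subset_name, rec in subsets.items():
        sub_tree = tree.subset(rec.index) if len(rec) < tree.n_tips else tree
        for weighted in (False, True):
            for var in CLIMATE_COLUMNS:
                fit = fit_sds_model(rec, sub_tree, var, weighted=weighted)
                key = f"{subset_name}:{'weighted' if weighted else 'unweighted'}:{var}"
                sds_models[key] = _summary(fit, fit.term)
    out["sds_models"] = sds_models

    # variance heterogeneity (phylogeny-corrected ANOVA on spread)
    var_tests = {}
    for subset_name, rec in subsets.items():
        sub_tree = tree.subset(rec.index) if len(rec) < tree.n_tips else tree
        order = sub_tree.tip_labels
        rec = rec.loc[order]
        for var in ("median_breeding_temperature",
                    "median_breeding_precipitation"):
            res = variance_heterogeneity_test(
                rec[var].values, rec["sds"].values, sub_tree
            )
            var_tests[f"{subset_name}:{var}"] = {
                "statistic": res.statistic, "df": res.df, "p": res.pvalue,
                "variance_multipliers": {
                    str(k): v for k, v in res.variance_multipliers.items()
                },
                "n": len(rec),
            }
    out["variance_tests"] = var_tests

    # ANCOVA: ambient ~ SDS + duration + SDS*duration
    ancova = {}
    for subset_name, rec in subsets.items():
        sub_tree = tree.subset(rec.index) if len(rec) < tree.n_tips else tree
        rec = rec.loc[sub_tree.tip_labels]
        for var in ("median_breeding_temperature",
                    "median_breeding_precipitation"):
            fit = ancova_interaction(
                rec[var].values, rec["sds"].values,
                rec["window_length"].values, sub_tree,
            )
            ancova[f"{subset_name}:{var}"] = {
                "interaction_p": float(fit.pvalues["sds:duration"]),
                "sds_p": float(fit.pvalues["sds"]),
                "alpha": fit.corr_param,
                "n": fit.n,
            }
    out["ancova"] = ancova

    # ambient temperature ~ SDS + reproductive mode + interaction
    rec = records.loc[tree.tip_labels] if len(records) == tree.n_tips \
        else records.loc[tree.subset(records.index).tip_labels]
    fit = ancova_interaction(
        rec["median_breeding_temperature"].values, rec["sds"].values,
        rec["reproductive_mode"].values, tree,
        factor_name="sds", covariate_name="reproductive_mode",
    )
    out["reproductive_mode_model"] = {
        "sds_p": float(fit.pvalues["sds"]),
        "interaction_p": float(fit.pvalues["sds:reproductive_mode"]),
        "alpha": fit.corr_param,
        "n": fit.n,
    }

    # phylogenetic signal
    signal = {}
    for var in SIGNAL_VARIABLES:
        y = records.loc[tree.tip_labels, var].astype(float).values
        lf = phylosig_lambda(y, tree)
        signal[var] = {"lambda": lf.lambda_hat, "p": lf.pvalue}
    out["phylogenetic_signal"] = signal
    return out


# ---------------------------------------------------------------------------
# reference-temperature comparison (breeding-length categories vs 25 C)
# ---------------------------------------------------------------------------
def reference_temp_test(groups: dict[str, np.ndarray],
                        reference: float = 25.0) -> pd.DataFrame:
    """One-sample signed-rank test of each group's temperatures against a
    reference value, Benjamini-Hochberg corrected across groups."""
    rows = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 3:
            rows.append({"group": name, "n": len(vals), "p_raw": np.nan,
                         "skipped": True})
            continue
        diffs = vals - reference
        if np.all(diffs == 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diffs, zero_method="wilcox").pvalue)
        rows.append({"group": name, "n": len(vals), "p_raw": p,
                     "skipped": False})
    df = pd.DataFrame(rows).set_index("group")
    tested = df.index[~df["skipped"]]
    adj = pd.Series(np.nan, index=df.index)
    if len(tested):
        adj.loc[tested] = multipletests(df.loc[tested, "p_raw"].values,
                                        method="fdr_bh")[1]
    df["p_adjusted"] = adj
    df["significant"] = df["p_adjusted"] < 0.05
    return df


# ---------------------------------------------------------------------------
# robustness schemes
# ---------------------------------------------------------------------------
def continent_jackknife(
    records: pd.DataFrame,
    tree: Phylogeny,
    climate_var: str = "median_breeding_temperature",
    weighted: bool = False,
    continents: list | None = None,
) -> pd.DataFrame:
    """Refit the SDS-climate model leaving out one continent at a time.

    ``continents`` defaults to those observed in the data; naming a
    continent with no species yields a run identical to the full fit.
    """
    if continents is None:
        continents = sorted(records["continent"].dropna().unique())
    if len(continents) < 2:
        raise ValueError("need at least two continents")
    rows = []
    for cont in continents:
        keep = records[records["continent"] != cont]
        flag = ""
        if len(keep) == len(records):
            flag = "continent absent from data: identical to full fit"
        elif len(keep) < 10:
            flag = "fewer than 10 species remain"
        fit = fit_sds_model(keep, tree, climate_var, weighted=weighted)
        rows.append({
            "left_out": cont, "n": fit.n,
            "slope": float(fit.params[fit.term]),
            "p": float(fit.pvalues[fit.term]),
            "alpha": fit.corr_param, "flag": flag,
        })
    return pd.DataFrame(rows).set_index("left_out")


def subsample_robustness(
    records: pd.DataFrame,
    tree: Phylogeny,
    climate_var: str = "median_breeding_temperature",
    fractions=(0.9, 0.8, 0.7, 0.6),
    replicates: int = 10,
    seed: int | None = None,
    weighted: bool = False,
) -> pd.DataFrame:
    """Random subsampling with a one-species-per-family guarantee.

    For each fraction f, floor(f*n) species are drawn ``replicates`` times:
    one guaranteed representative per family first, the rest uniformly.
    The SDS ~ climate model is refit on every draw.
    """
    rng = np.random.default_rng(seed)
    fams = records.groupby("family").groups
    n = len(records)
    rows = []
    for frac in fractions:
        k = int(np.floor(frac * n))
        if k < len(fams):
            raise ValueError(
                f"fraction {frac} keeps {k} species but there are "
                f"{len(fams)} families to represent"
            )
        for rep in range(replicates):
            chosen: list = []
            for fam, members in fams.items():
                chosen.append(rng.choice(np.asarray(members)))
            rest = records.index.difference(chosen)
            extra = rng.choice(np.asarray(rest), size=k - len(chosen),
                               replace=False)
            sel = records.loc[list(chosen) + list(extra)]
            fit = fit_sds_model(sel, tree, climate_var, weighted=weighted)
            rows.append({
                "fraction": frac, "replicate": rep, "n": fit.n,
                "slope": float(fit.params[fit.term]),
                "p": float(fit.pvalues[fit.term]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# null-window comparison (observed vs same-length random windows)
# ---------------------------------------------------------------------------
def fig_s5_comparison(
    records: pd.DataFrame,
    grid_temp: ClimateGrid,
    masks: dict[str, RangeMask],
) -> dict:
    """Per-species consecutive-month null for breeding seasonality, with a
    per-SDS-group sign test that observed values sit below the null median
    more often than chance.

    Full-year (12-month) windows are degenerate (observed equals the null)
    and are excluded with a flag.
    """
    per_species = []
    for sp, row in records.iterrows():
        window = BreedingWindow(int(row["breed_start"]), int(row["breed_end"]))
        series = range_series(grid_temp, masks[sp])
        obs = seasonality(series, window)
        if window.length == 12:
            per_species.append({
                "species": sp, "sds": int(row["sds"]), "observed": obs,
                "null_median": obs, "quantile": np.nan, "excluded": True,
            })
            continue
        res = null_window_test(series, window.length, observed=obs,
                               mode="enumerate")
        per_species.append({
            "species": sp, "sds": int(row["sds"]), "observed": obs,
            "null_median": float(np.median(res.null_values)),
            "quantile": res.quantile, "excluded": False,
        })
    df = pd.DataFrame(per_species).set_index("species")
    groups = {}
    for sds_value, name in ((0, "GSD"), (1, "TSD")):
        sub = df[(df["sds"] == sds_value) & ~df["excluded"]]
        below = int((sub["observed"] < sub["null_median"]).sum())
        n = len(sub)
        p = float(stats.binomtest(below, n, 0.5,
                                  alternative="greater").pvalue) if n else np.nan
        groups[name] = {"n": n, "below_null_median": below, "sign_test_p": p}
    return {"per_species": df, "groups": groups}
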