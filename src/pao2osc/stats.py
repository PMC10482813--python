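"""Statistics linking cluster membership to the morphology progression
and to cardiorespiratory covariates.

The progression rank (1 = ventilation-dependent ... K = inverted) is
treated as a continuous variable throughout. Per-covariate comparisons
across clusters use one-way ANOVA for continuous variables and Pearson
chi-square (no continuity correction) for categorical ones; no multiple-
testing correction is applied across covariate rows and no post-hoc
pairwise testing is performed. The exploratory intra-animal analysis is
a linear mixed model with a random intercept per animal, fitted by REML.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "ProgressionRegression",
    "MixedModelFit",
    "progression_regression",
    "anova_oneway",
    "chi_square_independence",
    "fit_mixed_progression",
    "select_fixed_effects",
    "cluster_comparison_table",
    "sensitivity_excluding_cluster",
    "mechanical_power_pcv",
]


# --------------------------------------------------------------------------
# progression regression
# --------------------------------------------------------------------------

@dataclass
class ProgressionRegression:
    component: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def progression_regression(
    scores: np.ndarray, ranks: np.ndarray, component: int = 1
) -> ProgressionRegression:
    """OLS of a principal-component score on the progression rank."""
    scores = np.asarray(scores, dtype=float)
    ranks = np.asarray(ranks, dtype=float)
    if len(scores) != len(ranks) or len(scores) < 3:
        raise ValueError("need >= 3 paired (score, rank) observations")
    if np.unique(ranks).size < 2:
        raise ValueError("progression ranks are constant")
    fit = scipy.stats.linregress(ranks, scores)
    return ProgressionRegression(
        component=component,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )


# --------------------------------------------------------------------------
# omnibus tests
# --------------------------------------------------------------------------

def anova_oneway(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA; returns (F, p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one value")
    if all(len(s) < 2 for s in samples):
        raise ValueError("at least one group needs >= 2 values")
    f, p = scipy.stats.f_oneway(*samples)
    return float(f), float(p)


def chi_square_independence(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need a table with >= 2 rows and >= 2 columns")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row or column marginal")
    res = scipy.stats.chi2_contingency(table, correction=False)
    return float(res[0]), float(res[1])


# --------------------------------------------------------------------------
# mixed-effects progression model
# --------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    fixed_effects: dict[str, float]
    fixed_pvalues: dict[str, float]
    random_intercept_sd: float
    criterion: float  # REML (or ML) criterion of the fit
    singular: bool
    converged: bool
    n_groups: int


def fit_mixed_progression(
    data: pd.DataFrame,
    outcome: str = "progression_rank",
    covariates: tuple[str, ...] = ("pf_kpa", "ppv_pct"),
    group: str = "animal_id",
    reml: bool = True,
) -> MixedModelFit:
    """Random-intercept linear mixed model of the progression rank.

    With a single group (or a variance estimate on the boundary) the fit
    is flagged singular rather than raised: one animal degenerates to OLS
    with a zero random-intercept SD.
    """
    missing = [c for c in (outcome, group, *covariates) if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    y = data[outcome].to_numpy(dtype=float)
    X = sm.add_constant(data[list(covariates)].to_numpy(dtype=float))
    names = ["const", *covariates]
    n_groups = data[group].nunique()

    if n_groups < 2:
        ols = sm.OLS(y, X).fit()
        return MixedModelFit(
            fixed_effects=dict(zip(names, map(float, ols.params))),
            fixed_pvalues=dict(zip(names, map(float, ols.pvalues))),
            random_intercept_sd=0.0,
            criterion=float(ols.llf),
            singular=True,
            converged=True,
            n_groups=n_groups,
        )

    model = sm.MixedLM(y, X, groups=data[group].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml)
    re_var = float(np.asarray(result.cov_re)[0, 0])
    singular = bool(re_var < 1e-8 or getattr(result, "converged", True) is False)
    params = np.asarray(result.fe_params, dtype=float)
    pvals = np.asarray(result.pvalues, dtype=float)[: len(params)]
    return MixedModelFit(
        fixed_effects=dict(zip(names, map(float, params))),
        fixed_pvalues=dict(zip(names, map(float, pvals))),
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
        criterion=float(result.llf),
        singular=singular,
        converged=bool(getattr(result, "converged", True)),
        n_groups=n_groups,
    )


def select_fixed_effects(
    data: pd.DataFrame,
    candidates: tuple[str, ...],
    outcome: str = "progression_rank",
    group: str = "animal_id",
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """AIC-guided choice of the fixed-effect subset.

    All subsets of the candidate covariates (at most 10) are fitted by
    maximum likelihood for comparability and ranked by AIC; returns the
    best subset and the full AIC table.
    """
    if len(candidates) > 10:
        raise ValueError("at most 10 candidate covariates")
    rows = []
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            fit = fit_mixed_progression(
                data, outcome=outcome, covariates=subset, group=group, reml=False
            )
            n_params = len(subset) + 1 + 2  # fixed effects + intercept + 2 variances
            rows.append(
                {
                    "covariates": subset,
                    "loglik": fit.criterion,
                    "aic": -2.0 * fit.criterion + 2.0 * n_params,
                }
            )
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    return tuple(table.loc[0, "covariates"]), table


# --------------------------------------------------------------------------
# cluster comparison table and sensitivity analysis
# --------------------------------------------------------------------------

def cluster_comparison_table(
    data: pd.DataFrame,
    numeric: tuple[str, ...],
    categorical: tuple[str, ...] = (),
    cluster_col: str = "progression_rank",
) -> pd.DataFrame:
    """Per-covariate cluster comparison (per-cluster mean (SD) or counts,
    omnibus test statistic and p), cluster columns ordered by rank."""
    clusters = sorted(data[cluster_col].unique())
    if len(clusters) < 2:
        raise ValueError("need at least two clusters to compare")
    rows = []
    for cov in numeric:
        row: dict = {"covariate": cov, "test": "anova"}
        for c in clusters:
            vals = data.loc[data[cluster_col] == c, cov]
            row[f"cluster_{c}"] = f"{vals.mean():.4g} ({vals.std(ddof=1):.3g})"
        f, p = anova_oneway(data[cov].to_numpy(), data[cluster_col].to_numpy())
        row["statistic"], row["p_value"] = f, p
        rows.append(row)
    for cov in categorical:
        row = {"covariate": cov, "test": "chi_square"}
        counts = pd.crosstab(data[cluster_col], data[cov]).reindex(clusters)
        for c in clusters:
            row[f"cluster_{c}"] = "/".join(str(int(v)) for v in counts.loc[c])
        stat, p = chi_square_independence(counts.to_numpy())
        row["statistic"], row["p_value"] = stat, p
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["multiple_testing_correction"] = "none"
    return out


def sensitivity_excluding_cluster(
    data: pd.DataFrame,
    excluded_cluster: int,
    numeric: tuple[str, ...],
    categorical: tuple[str, ...] = (),
    cluster_col: str = "progression_rank",
) -> pd.DataFrame:
    """Recompute the comparison table with one cluster's conditions removed."""
    if excluded_cluster not in set(data[cluster_col].unique()):
        raise ValueError(f"cluster {excluded_cluster} not present")
    remaining = data[data[cluster_col] != excluded_cluster]
    if remaining[cluster_col].nunique() < 2:
        raise ValueError("fewer than two clusters remain after exclusion")
    return cluster_comparison_table(
        remaining, numeric=numeric, categorical=categorical, cluster_col=cluster_col
    )


# --------------------------------------------------------------------------
# mechanical power (simplified pressure-control formula)
# --------------------------------------------------------------------------

def mechanical_power_pcv(
    rr: float, vt: float, delta_p_insp: float, peep: float
) -> float:
    """Mechanical power in J/min for pressure-control ventilation:
    0.098 * RR * VT * (dP_insp + PEEP), with VT in litres and pressures
    in cmH2O."""
    if min(rr, vt, delta_p_insp, peep) < 0:
        raise ValueError("all inputs must be nonnegative")
    return 0.098 * rr * vt * (delta_p_insp + peep)
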