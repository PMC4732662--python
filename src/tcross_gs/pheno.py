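"""Phenotype modelling for multi-location testcross trials.

Raw records are long-format rows (pollinator, tester, location, trait,
value), one observation per hybrid x location (unreplicated trials).  From
these the module derives, per trait:

* hybrid BLUEs from the two-way additive fixed model
  value = mu + hybrid_i + location_l + eps, solved by least squares — with
  complete balanced data this reduces to the hybrid's mean across locations;
* REML variance components sigma2_g (hybrid, random) and sigma2_e (residual)
  with location fixed, by a profiled restricted likelihood with analytic
  per-hybrid block inverses;
* broad-sense heritability H^2 = sigma2_g / (sigma2_g + sigma2_e / n) x 100,
  n the number of locations (the residual variance of a mean over n trials);
* general combining ability per pollinator: its tester-mean BLUE minus the
  grand mean of all hybrid BLUEs, so GCA values are centered deviations;
* Pearson correlations between traits over shared hybrids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ["pollinator", "tester", "location", "trait", "value"]


class PhenotypeError(ValueError):
    pass


@dataclass
class VarianceComponents:
    trait: str
    sigma2_g: float
    sigma2_e: float
    n_locations: int
    method: str = "reml"

    def __post_init__(self) -> None:
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")
        if self.n_locations < 2:
            raise ValueError("variance estimation needs at least 2 locations")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise PhenotypeError(f"trial table lacks columns {missing}")
    dup = trials.duplicated(subset=["pollinator", "tester", "location", "trait"])
    if dup.any():
        raise PhenotypeError(f"{int(dup.sum())} duplicate (hybrid, location, trait) records")
    return trials


def _hybrid_id(df: pd.DataFrame) -> pd.Series:
    return df["pollinator"].astype(str) + "::" + df["tester"].astype(str)


def fit_blues(trials: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Location-adjusted BLUE per hybrid for one trait.

    Returns a DataFrame with columns pollinator, tester, trait, blue. The
    BLUE is the model prediction for the hybrid averaged over *all* observed
    locations, so hybrids missing a location are adjusted onto the common
    scale. With a single location the observed values are returned as-is.
    """
    validate_trials(trials)
    sub = trials[trials["trait"] == trait].copy()
    if sub.empty:
        raise PhenotypeError(f"trait {trait!r} absent from trial data")
    sub["hybrid"] = _hybrid_id(sub)
    locs = sorted(sub["location"].unique())

    if len(locs) == 1:
        warnings.warn("single location: BLUE equals the observed value")
        out = sub[["pollinator", "tester", "value"]].rename(columns={"value": "blue"})
        out.insert(2, "trait", trait)
        return out.reset_index(drop=True)

    hybrids = sorted(sub["hybrid"].unique())
    h_idx = {h: i for i, h in enumerate(hybrids)}
    l_idx = {l: i for i, l in enumerate(locs)}
    n, n_h, n_l = len(sub), len(hybrids), len(locs)

    # full hybrid dummies (absorb the intercept) + drop-first location dummies
    design = np.zeros((n, n_h + n_l - 1))
    rows = np.arange(n)
    design[rows, [h_idx[h] for h in sub["hybrid"]]] = 1.0
    for r, l in zip(rows, sub["location"]):
        if l_idx[l] > 0:
            design[r, n_h + l_idx[l] - 1] = 1.0
    coef, *_ = np.linalg.lstsq(design, sub["value"].to_numpy(dtype=float), rcond=None)
    loc_eff = np.concatenate([[0.0], coef[n_h:]])
    blues = coef[:n_h] + loc_eff.mean()

    key = sub.drop_duplicates("hybrid").set_index("hybrid")[["pollinator", "tester"]]
    out = key.loc[hybrids].reset_index(drop=True)
    out["trait"] = trait
    out["blue"] = blues
    return out


def _grouped_reml(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray
) -> tuple[float, float]:
    """REML for y = X beta + Z g + e with one random intercept per group.

    The covariance V = sigma2_e (I + gamma J) is block diagonal with J the
    within-group all-ones matrix, so V^{-1} v = v - gamma/(1+gamma n_i) * group
    sums — every likelihood evaluation is O(n). The restricted likelihood is
    profiled on gamma = sigma2_g / sigma2_e and minimized by bounded scalar
    search on log10(gamma), with the gamma = 0 (pure OLS) boundary checked
    explicitly. Returns (sigma2_g, sigma2_e).
    """
    from scipy.optimize import minimize_scalar

    n, p = X.shape
    uniq, idx = np.unique(groups, return_inverse=True)
    n_i = np.bincount(idx).astype(float)

    def vinv(gamma: float, v: np.ndarray) -> np.ndarray:
        # (I + gamma J)^{-1} v, blockwise rank-1 downdate
        if v.ndim == 1:
            sums = np.bincount(idx, weights=v)
            return v - (gamma * sums / (1.0 + gamma * n_i))[idx]
        out = np.empty_like(v)
        for j in range(v.shape[1]):
            out[:, j] = vinv(gamma, v[:, j])
        return out

    def neg2_reml(gamma: float) -> tuple[float, float]:
        Vx = vinv(gamma, X)
        A = X.T @ Vx
        b = Vx.T @ y
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise PhenotypeError(f"REML failed: singular design ({exc})") from exc
        ypy = float(y @ vinv(gamma, y) - b @ beta)
        ypy = max(ypy, 1e-300)
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            raise PhenotypeError("REML failed: non-positive-definite design")
        crit = (
            (n - p) * np.log(ypy)
            + float(np.sum(np.log1p(gamma * n_i)))
            + logdet_a
        )
        return crit, ypy / (n - p)

    res = minimize_scalar(
        lambda t: neg2_reml(10.0**t)[0],
        bounds=(-12.0, 12.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    gamma = float(10.0**res.x)
    crit, sigma2_e = neg2_reml(gamma)
    crit0, sigma2_e0 = neg2_reml(0.0)
    if crit0 <= crit:  # boundary sigma2_g = 0 wins
        return 0.0, sigma2_e0
    if res.x < 11.5:
        return gamma * sigma2_e, sigma2_e
    # degenerate sigma2_e -> 0 limit: the restricted likelihood is unbounded
    # in gamma, so estimate the genetic variance from the adjusted group
    # effects directly (OLS on group + within-group fixed effects).
    Zg = np.zeros((n, len(uniq)))
    Zg[np.arange(n), idx] = 1.0
    within = X[:, 1:]  # intercept is absorbed by the group dummies
    design = np.hstack([Zg, within]) if within.size else Zg
    coef, rss, *_ = np.linalg.lstsq(design, y, rcond=None)
    ghat = coef[: len(uniq)]
    resid = y - design @ coef
    dof = n - np.linalg.matrix_rank(design)
    sigma2_e = float(resid @ resid / dof) if dof > 0 else 0.0
    return float(np.var(ghat, ddof=1)), sigma2_e


def estimate_variance_components(trials: pd.DataFrame, trait: str) -> VarianceComponents:
    """REML variance components: hybrid random, location fixed.

    Estimates are non-negative by construction (the genetic variance is
    profiled on a bounded ratio, with the zero boundary checked explicitly).
    """
    validate_trials(trials)
    sub = trials[trials["trait"] == trait].copy()
    if sub.empty:
        raise PhenotypeError(f"trait {trait!r} absent from trial data")
    sub["hybrid"] = _hybrid_id(sub)
    n_loc = sub["location"].nunique()
    if n_loc < 2:
        raise PhenotypeError("variance estimation needs at least 2 locations")
    if sub["value"].var() == 0.0:
        return VarianceComponents(trait, 0.0, 0.0, n_loc)

    y = sub["value"].to_numpy(dtype=float)
    X = pd.get_dummies(sub["location"], drop_first=True, dtype=float).to_numpy()
    X = np.column_stack([np.ones(len(y)), X])
    groups = sub["hybrid"].to_numpy()
    sigma2_g, sigma2_e = _grouped_reml(y, X, groups)
    return VarianceComponents(trait, max(sigma2_g, 0.0), max(sigma2_e, 0.0), n_loc)


def broad_sense_heritability(vc: VarianceComponents) -> float:
    """H^2 (%) = 100 * sigma2_g / (sigma2_g + sigma2_e / n_locations)."""
    if vc.sigma2_g == 0.0 and vc.sigma2_e == 0.0:
        raise PhenotypeError("both variance components are zero: H^2 undefined")
    return 100.0 * vc.sigma2_g / (vc.sigma2_g + vc.sigma2_e / vc.n_locations)


def compute_gca(blues: pd.DataFrame, trait: str) -> pd.DataFrame:
    """General combining ability per pollinator from hybrid BLUEs.

    GCA_p = mean over available testers of BLUE(p, t) minus the grand mean of
    all hybrid BLUEs for the trait. Returns columns pollinator, trait, gca.
    When every pollinator carries every tester, the values sum to zero.
    """
    sub = blues[blues["trait"] == trait]
    if sub.empty:
        raise PhenotypeError(f"trait {trait!r} absent from BLUE table")
    grand = sub["blue"].mean()
    gca = sub.groupby("pollinator", sort=True)["blue"].mean() - grand
    out = gca.rename("gca").reset_index()
    out.insert(1, "trait", trait)
    return out


def trait_correlations(blues: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlations between traits over shared hybrids."""
    df = blues.copy()
    df["hybrid"] = _hybrid_id(df)
    wide = df.pivot_table(index="hybrid", columns="trait", values="blue", aggfunc="first")
    if wide.shape[1] < 2:
        raise PhenotypeError("need at least 2 traits for correlations")
    zero_var = [t for t in wide.columns if wide[t].dropna().var() == 0.0]
    if zero_var:
        warnings.warn(f"zero-variance traits, correlations undefined: {zero_var}")
    corr = wide.corr(method="pearson", min_periods=min_shared)
    for t in zero_var:
        corr.loc[t, :] = np.nan
        corr.loc[:, t] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr


def phenotype_summary(trials: pd.DataFrame, trait: str) -> dict:
    """Mean/min/max of hybrid BLUEs plus variance components and H^2."""
    blues = fit_blues(trials, trait)
    vc = estimate_variance_components(trials, trait)
    return {
        "trait": trait,
        "mean": float(blues["blue"].mean()),
        "min": float(blues["blue"].min()),
        "max": float(blues["blue"].max()),
        "sigma2_g": vc.sigma2_g,
        "sigma2_e": vc.sigma2_e,
        "n_locations": vc.n_locations,
        "H2_pct": broad_sense_heritability(vc),
    }
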