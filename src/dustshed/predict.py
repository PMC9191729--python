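"""Posterior prediction on a landscape grid and its summaries.

For every retained MCMC draw the latent field is extended from the
observed plots to the grid by conditional (kriging-style) simulation:
given that draw's field values and covariance parameters, eps at the grid
points is Gaussian with the usual conditional mean and covariance, where
only the spatially structured component theta2*exp(-h/theta3) links sites
(the nugget is micro-scale variance at observed sites and does not
propagate).  The predicted richness intensity is then

    lambda(s0) = exp(beta0 + beta1*d0 + delta0 + eta0 + eps(s0))

reported on the intensity scale (so stratum means can be non-integer).

Summaries mirror the reporting of the original study: per-point posterior
mean / 95% interval / CV with quartile classes of 1/CV for mapping;
per-distance-class stratum means with a paired probability of decrease
toward the road; and area-by-threshold tables split inside/outside the
industrial easement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .io import DEFAULT_CLASS_EDGES, class_labels, distance_class
from .model import PosteriorDraws, _chol_with_jitter, design_matrix


@dataclass
class PredictionDraws:
    """Predicted intensity lambda at grid points for each posterior draw."""

    point_ids: list[str]
    lam: np.ndarray  # (n_draws, n_points), all > 0
    draw_index: pd.DataFrame  # chain/draw bookkeeping

    @property
    def n_draws(self) -> int:
        return self.lam.shape[0]


def posterior_predict(
    draws: PosteriorDraws, grid: pd.DataFrame, seed: int = 0
) -> PredictionDraws:
    """Conditionally simulate the field and intensity at grid points.

    Pools retained draws across chains; one conditional Gaussian draw of
    eps(s0) per posterior sample.  Grid rows must carry x, y, dist_road,
    side and habitat; a missing/NaN covariate raises an error naming the
    point.
    """
    if draws.n_retained == 0:
        raise ValueError("no retained posterior draws")
    g = grid.copy()
    if "log_dist" not in g.columns:
        g["log_dist"] = np.log10(g["dist_road"].to_numpy(dtype=float))
    for col in ("log_dist", "side", "habitat"):
        bad = g[col].isna()
        if bad.any():
            raise ValueError(
                f"grid point(s) with missing {col}: {list(g.loc[bad, 'point_id'])}"
            )
    Xg = design_matrix(g)
    grid_xy = g[["x", "y"]].to_numpy(dtype=float)
    obs_xy = draws.coords
    D_obs = squareform(pdist(obs_xy))
    D_cross = cdist(obs_xy, grid_xy)
    D_grid = squareform(pdist(grid_xy))

    rng = np.random.default_rng(seed)
    n_pts = len(g)
    rows = []
    lam_out = []
    for chain in range(draws.n_chains):
        for k in range(draws.n_retained):
            beta = draws.beta[chain, k]
            th1, th2, th3 = draws.theta[chain, k]
            eps_obs = draws.epsilon[chain, k]
            if th2 > 0:
                C_obs = th2 * np.exp(-D_obs / th3)
                C_obs[np.diag_indices_from(C_obs)] += th1
                K = th2 * np.exp(-D_cross / th3)
                C_g = th2 * np.exp(-D_grid / th3)
                L = _chol_with_jitter(C_obs)
                # solve C_obs^{-1} via the Cholesky factor
                W = np.linalg.solve(L, K)  # L^{-1} K
                alpha = np.linalg.solve(L.T, np.linalg.solve(L, eps_obs))
                mean = K.T @ alpha
                cond = C_g - W.T @ W
                Lc = _chol_with_jitter(cond)
                eps0 = mean + Lc @ rng.standard_normal(n_pts)
            else:
                # no spatially structured component: grid field is zero
                eps0 = np.zeros(n_pts)
            lam_out.append(np.exp(Xg @ beta + eps0))
            rows.append({"chain": chain, "draw": k})
    lam = np.asarray(lam_out)
    return PredictionDraws(list(g["point_id"].astype(str)), lam, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def point_summary(pd_draws: PredictionDraws) -> pd.DataFrame:
    """Per-point posterior mean, 95% interval, CV and 1/CV quartile class."""
    lam = pd_draws.lam
    if lam.shape[0] < 2:
        raise ValueError("need at least 2 draws")
    mean = lam.mean(axis=0)
    lo, hi = np.percentile(lam, [2.5, 97.5], axis=0)
    sd = lam.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
        inv_cv = np.where(cv > 0, 1.0 / cv, np.inf)
    finite = inv_cv[np.isfinite(inv_cv)]
    if len(finite):
        qs = np.quantile(finite, [0.25, 0.5, 0.75])
        precision_class = 1 + np.searchsorted(qs, inv_cv, side="right")
    else:
        precision_class = np.ones(len(mean), dtype=int)
    return pd.DataFrame(
        {
            "point_id": pd_draws.point_ids,
            "mean": mean,
            "pctl_2.5": lo,
            "pctl_97.5": hi,
            "cv": cv,
            "inv_cv_class": precision_class,
        }
    )


def _stratum_means_per_draw(
    pd_draws: PredictionDraws, grid: pd.DataFrame, edges
) -> tuple[np.ndarray, np.ndarray]:
    cls = distance_class(grid["dist_road"].to_numpy(), edges)
    w = grid["area_weight_km2"].to_numpy(dtype=float)
    n_cls = len(edges) - 1
    means = np.empty((pd_draws.n_draws, n_cls))
    for c in range(n_cls):
        mask = cls == c
        if not mask.any():
            raise ValueError(f"empty distance class {class_labels(edges)[c]}")
        wc = w[mask]
        means[:, c] = pd_draws.lam[:, mask] @ wc / wc.sum()
    return means, cls


def stratum_summary(
    pd_draws: PredictionDraws, grid: pd.DataFrame, edges=DEFAULT_CLASS_EDGES
) -> pd.DataFrame:
    """Distance-class summary of the posterior predictions.

    Per class: the stratum mean is the area-weighted mean intensity over
    the class's grid points, computed within each posterior draw; Mean/SE
    and the 2.5/97.5 percentiles summarise that per-draw quantity.
    Min/Max are the extremes of the per-point posterior means in the
    class.  Pr Decrease is the percentage of paired draws in which the
    class's stratum mean is strictly below the next farther class's (ties
    count as non-decreases); the farthest class has none.
    """
    means, cls = _stratum_means_per_draw(pd_draws, grid, edges)
    point_means = pd_draws.lam.mean(axis=0)
    labels = class_labels(edges)
    n_cls = means.shape[1]
    rows = []
    for c in range(n_cls):
        mask = cls == c
        pr_dec = (
            100.0 * np.mean(means[:, c] < means[:, c + 1]) if c < n_cls - 1 else np.nan
        )
        rows.append(
            {
                "class": c + 1,
                "distance_m": labels[c],
                "n": int(mask.sum()),
                "mean_lsr": means[:, c].mean(),
                "se_lsr": means[:, c].std(ddof=1),
                "min_lsr": point_means[mask].min(),
                "max_lsr": point_means[mask].max(),
                "pctl_2.5": np.percentile(means[:, c], 2.5),
                "pctl_97.5": np.percentile(means[:, c], 97.5),
                "pr_decrease": pr_dec,
            }
        )
    return pd.DataFrame(rows)


def area_summary(
    point_means: np.ndarray,
    grid: pd.DataFrame,
    top_stratum_mean: float,
    threshold_fractions=(0.25, 0.5, 0.75, 0.95),
) -> pd.DataFrame:
    """Area by percent-of-top-stratum intensity, split by easement.

    Points are classified by mean intensity relative to the top (farthest)
    stratum mean into half-open classes [0,f1), [f1,f2), ..., [f_last,
    inf): e.g. the defaults give <25%, 25-50%, 50-75%, 75-95% and >=95%
    classes.  Areas are sums of the points' area weights, with cumulative
    and percentage columns and an inside/outside-easement split.
    """
    if top_stratum_mean <= 0:
        raise ValueError("top-stratum mean must be positive")
    fr = tuple(threshold_fractions)
    if any(b <= a for a, b in zip(fr, fr[1:])) or any(not (0 < f < 1) for f in fr):
        raise ValueError("threshold fractions must be strictly increasing in (0,1)")
    pm = np.asarray(point_means, dtype=float)
    ratio = pm / top_stratum_mean
    bounds = (0.0,) + fr + (np.inf,)
    w = grid["area_weight_km2"].to_numpy(dtype=float)
    inside = grid["in_easement"].to_numpy(dtype=bool)
    total_area = w.sum()
    total_in = w[inside].sum()
    total_out = w[~inside].sum()

    rows = []
    cum_area = 0.0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mask = (ratio >= lo) & (ratio < hi)
        area = w[mask].sum()
        cum_area += area
        area_in = w[mask & inside].sum()
        area_out = w[mask & ~inside].sum()
        label = f">={lo * 100:g}" if np.isinf(hi) else f"{lo * 100:g}-{hi * 100:g}"
        lsr_lo = pm[mask].min() if mask.any() else np.nan
        lsr_hi = pm[mask].max() if mask.any() else np.nan
        rows.append(
            {
                "pct_of_top_class": label,
                "lsr_min": lsr_lo,
                "lsr_max": lsr_hi,
                "n": int(mask.sum()),
                "area_km2": area,
                "cum_area_km2": cum_area,
                "pct_area": 100.0 * area / total_area,
                "cum_pct_area": 100.0 * cum_area / total_area,
                "area_inside_km2": area_in,
                "area_outside_km2": area_out,
                "pct_inside": 100.0 * area_in / total_in if total_in > 0 else np.nan,
                "pct_outside": 100.0 * area_out / total_out if total_out > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
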