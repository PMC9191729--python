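"""Bayesian spatial Poisson regression for plot-level species richness.

The model:  Y_i ~ Poisson(lambda_i) with

    log lambda_i = beta0 + beta1 * d_i + delta_i + eta_i + eps(s_i)

where d_i is log10 distance to the road, delta/eta are binary side-of-road
and habitat effects, and eps is a zero-mean Gaussian field with
exponential covariance

    C(h) = theta1 * 1(h = 0) + theta2 * exp(-h / theta3)

(theta1 nugget, theta2 partial sill, theta3 range in metres; the nugget
acts as i.i.d. variance at observed sites).

Inference is by MCMC: elliptical slice sampling for the latent field
(tuning-free given the Gaussian prior) and adaptive random-walk Metropolis
for the regression effects and log covariance parameters.  Regression
effects get diffuse Normal(0, 100) priors; the covariance parameters get
proper, pluggable priors (half-Normal nugget and partial sill, log-uniform
range) rather than an improper reference prior, so the posterior is
guaranteed proper and prior sensitivity can be probed by swapping
hyperparameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

from .config import McmcControls, PriorConfig

log = logging.getLogger("dustshed")

BETA_NAMES = ("beta0", "beta1", "delta", "eta")
THETA_NAMES = ("theta1", "theta2", "theta3")

SIDES = ("south", "north")
HABITATS = ("ericaceous_shrub", "tussock_tundra")


@dataclass(frozen=True)
class CovarianceParams:
    """Exponential-covariance parameters (nugget, partial sill, range m)."""

    theta1: float
    theta2: float
    theta3: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.theta1, self.theta2, self.theta3])):
            raise ValueError("covariance parameters must be finite")
        if self.theta1 < 0 or self.theta2 < 0:
            raise ValueError("nugget and partial sill must be >= 0")
        if self.theta3 <= 0:
            raise ValueError("range must be > 0")
        if self.theta1 + self.theta2 <= 0:
            raise ValueError("theta1 + theta2 must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3])


@dataclass
class ModelParams:
    """One full parameter state: regression effects, covariance, latent field."""

    beta: np.ndarray  # (beta0, beta1, delta, eta)
    theta: CovarianceParams
    epsilon: np.ndarray  # one value per plot

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.beta.shape != (4,):
            raise ValueError("beta must have four components")
        if not (np.all(np.isfinite(self.beta)) and np.all(np.isfinite(self.epsilon))):
            raise ValueError("parameters must be finite")


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _binary_code(values: pd.Series, levels: tuple[str, str], what: str) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(values):
        v = values.to_numpy(dtype=float)
        if not np.isin(v, (0.0, 1.0)).all():
            raise ValueError(f"numeric {what} column must be 0/1")
        return v
    uniq = set(values.unique())
    if uniq <= set(levels):
        return (values == levels[1]).to_numpy(dtype=float)
    order = sorted(uniq)
    if len(order) != 2:
        raise ValueError(f"{what} must be binary; levels found: {order}")
    return (values == order[1]).to_numpy(dtype=float)


def design_matrix(table: pd.DataFrame) -> np.ndarray:
    """Columns: intercept, log10 distance, side (north=1), habitat (0/1)."""
    side = _binary_code(table["side"], SIDES, "side")
    habitat = _binary_code(table["habitat"], HABITATS, "habitat")
    return np.column_stack(
        [np.ones(len(table)), table["log_dist"].to_numpy(), side, habitat]
    )


# ---------------------------------------------------------------------------
# covariance
# ---------------------------------------------------------------------------

def build_covariance(coords: np.ndarray, theta: CovarianceParams) -> np.ndarray:
    """n x n exponential covariance with nugget on coincident pairs."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    D = squareform(pdist(coords))
    C = theta.theta2 * np.exp(-D / theta.theta3)
    coincident = D == 0.0
    if theta.theta1 > 0:
        C[coincident] += theta.theta1
    elif coincident.sum() > len(coords):
        log.warning(
            "duplicate coordinates with zero nugget give a singular "
            "covariance; jitter will be applied at factorization"
        )
    return C


def _chol_with_jitter(C: np.ndarray) -> np.ndarray:
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return np.linalg.cholesky(C + jitter * np.eye(len(C)) if jitter else C)
        except np.linalg.LinAlgError:
            continue
    scale = max(np.mean(np.diag(C)), 1.0)
    return np.linalg.cholesky(C + 1e-6 * scale * np.eye(len(C)))


class _GaussianField:
    """Zero-mean Gaussian density over fixed sites; fast path when theta2=0."""

    def __init__(self, coords: np.ndarray, theta: CovarianceParams):
        self.theta = theta
        self.n = len(coords)
        if theta.theta2 == 0.0:
            self.diagonal = True
            self.var = theta.theta1
            self._logdet = self.n * np.log(self.var)
        else:
            self.diagonal = False
            self.L = _chol_with_jitter(build_covariance(coords, theta))
            self._logdet = 2.0 * np.sum(np.log(np.diag(self.L)))

    def logpdf(self, eps: np.ndarray) -> float:
        if self.diagonal:
            quad = np.dot(eps, eps) / self.var
        else:
            z = np.linalg.solve(self.L, eps)
            quad = np.dot(z, z)
        return -0.5 * (self.n * np.log(2.0 * np.pi) + self._logdet + quad)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.n)
        if self.diagonal:
            return np.sqrt(self.var) * z
        return self.L @ z

    def solve(self, x: np.ndarray) -> np.ndarray:
        """C^{-1} x via the cached Cholesky factor."""
        if self.diagonal:
            return x / self.var
        return np.linalg.solve(self.L.T, np.linalg.solve(self.L, x))

    def scaled(self, s: float) -> "_GaussianField":
        """The density with covariance multiplied by s^2 (no refactorization)."""
        out = object.__new__(_GaussianField)
        out.theta = CovarianceParams(
            self.theta.theta1 * s**2, self.theta.theta2 * s**2, self.theta.theta3
        )
        out.n = self.n
        out.diagonal = self.diagonal
        if self.diagonal:
            out.var = self.var * s**2
        else:
            out.L = self.L * s
        out._logdet = self._logdet + 2.0 * self.n * np.log(s)
        return out


# ---------------------------------------------------------------------------
# likelihood and priors
# ---------------------------------------------------------------------------

def log_likelihood(y: np.ndarray, X: np.ndarray, params: ModelParams) -> float:
    """Poisson log likelihood at the given parameter state.

    Returns -inf for non-finite linear predictors so invalid states are
    simply rejectable inside Metropolis steps.
    """
    y = np.asarray(y)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be non-negative integers")
    loglam = X @ params.beta + params.epsilon
    if not np.all(np.isfinite(loglam)):
        return -np.inf
    lam = np.exp(loglam)
    return float(np.sum(y * loglam - lam - gammaln(y + 1.0)))


def _half_normal_logpdf(x: float, sd: float) -> float:
    if x < 0:
        return -np.inf
    return np.log(2.0) - 0.5 * np.log(2.0 * np.pi * sd**2) - x**2 / (2.0 * sd**2)


def resolve_range_bounds(coords: np.ndarray, prior: PriorConfig) -> tuple[float, float]:
    """Log-uniform range-prior support: [min plot spacing, 2 x domain diameter]."""
    if prior.log_range_bounds is not None:
        return tuple(prior.log_range_bounds)
    d = pdist(np.asarray(coords, dtype=float))
    pos = d[d > 0]
    lo = float(pos.min()) if len(pos) else 1.0
    hi = 2.0 * float(d.max()) if len(d) else 1e4
    return (np.log(lo), np.log(hi))


def log_prior(
    params: ModelParams,
    prior: PriorConfig,
    coords: np.ndarray,
    include_epsilon: bool = True,
) -> float:
    """Joint log prior of (beta, theta, eps).

    Independent Normal(0, beta_sd) on each regression effect; half-Normal
    (theta_sd) on nugget and partial sill; log-uniform range within
    ``resolve_range_bounds``; the latent field contributes its
    multivariate-normal density under C(theta).
    """
    sd = prior.beta_sd
    lp = float(
        np.sum(-0.5 * np.log(2.0 * np.pi * sd**2) - params.beta**2 / (2.0 * sd**2))
    )
    th = params.theta
    lp += _half_normal_logpdf(th.theta1, prior.theta_sd)
    lp += _half_normal_logpdf(th.theta2, prior.theta_sd)
    lo, hi = resolve_range_bounds(coords, prior)
    if not (lo <= np.log(th.theta3) <= hi):
        return -np.inf
    lp += -np.log(th.theta3) - np.log(hi - lo)
    if not np.isfinite(lp):
        return -np.inf
    if include_epsilon:
        lp += _GaussianField(np.asarray(coords, dtype=float), th).logpdf(params.epsilon)
    return lp


# ---------------------------------------------------------------------------
# posterior draws container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Retained MCMC samples, per chain, plus the metadata to reuse them."""

    beta: np.ndarray  # (chains, draws, 4)
    theta: np.ndarray  # (chains, draws, 3)
    epsilon: np.ndarray  # (chains, draws, n_plots)
    plot_ids: list[str]
    coords: np.ndarray  # (n_plots, 2), canonical plot order
    controls: McmcControls
    accept_rates: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_retained(self) -> int:
        return self.beta.shape[1]

    def parameter(self, name: str) -> np.ndarray:
        """Draws of one parameter as a (chains, draws) array."""
        if name in BETA_NAMES:
            return self.beta[:, :, BETA_NAMES.index(name)]
        if name in THETA_NAMES:
            return self.theta[:, :, THETA_NAMES.index(name)]
        if name.startswith("eps_"):
            return self.epsilon[:, :, self.plot_ids.index(name[4:])]
        raise KeyError(name)

    def parameter_names(self, include_epsilon: bool = False) -> list[str]:
        names = list(BETA_NAMES + THETA_NAMES)
        if include_epsilon:
            names += [f"eps_{pid}" for pid in self.plot_ids]
        return names

    def to_long_dataframe(self, include_epsilon: bool = True) -> pd.DataFrame:
        frames = []
        for name in self.parameter_names(include_epsilon):
            x = self.parameter(name)
            c, d = np.meshgrid(
                np.arange(self.n_chains), np.arange(self.n_retained), indexing="ij"
            )
            frames.append(
                pd.DataFrame(
                    {
                        "draw": d.ravel(),
                        "chain": c.ravel(),
                        "parameter": name,
                        "value": x.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_long_dataframe(
        cls, df: pd.DataFrame, plot_table: pd.DataFrame | None = None
    ) -> "PosteriorDraws":
        chains = int(df["chain"].max()) + 1
        draws = int(df["draw"].max()) + 1
        wide = df.pivot_table(
            index=["chain", "draw"], columns="parameter", values="value", sort=False
        )
        beta = np.stack(
            [wide[n].to_numpy().reshape(chains, draws) for n in BETA_NAMES], axis=-1
        )
        theta = np.stack(
            [wide[n].to_numpy().reshape(chains, draws) for n in THETA_NAMES], axis=-1
        )
        eps_cols = sorted(c for c in wide.columns if c.startswith("eps_"))
        plot_ids = [c[4:] for c in eps_cols]
        if eps_cols:
            epsilon = np.stack(
                [wide[c].to_numpy().reshape(chains, draws) for c in eps_cols], axis=-1
            )
        else:
            epsilon = np.zeros((chains, draws, 0))
        if plot_table is not None:
            t = plot_table.set_index("plot_id").loc[plot_ids]
            coords = t[["x", "y"]].to_numpy(dtype=float)
        else:
            coords = np.zeros((len(plot_ids), 2))
        controls = McmcControls(iters=draws + 1, burnin=1, thin=1, chains=chains)
        return cls(beta, theta, epsilon, plot_ids, coords, controls)


def write_posterior(draws: PosteriorDraws, path) -> None:
    draws.to_long_dataframe(include_epsilon=True).to_csv(path, index=False)


def read_posterior(path, plot_table: pd.DataFrame | None = None) -> PosteriorDraws:
    return PosteriorDraws.from_long_dataframe(pd.read_csv(path), plot_table)


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def _elliptical_slice(eps, loglik, cur_ll, prior_draw, rng, max_shrink=200):
    """One elliptical slice update of the latent field (Murray et al. style)."""
    nu = prior_draw
    logy = cur_ll + np.log(rng.random())
    phi = rng.uniform(0.0, 2.0 * np.pi)
    lo, hi = phi - 2.0 * np.pi, phi
    for _ in range(max_shrink):
        prop = eps * np.cos(phi) + nu * np.sin(phi)
        ll = loglik(prop)
        if ll > logy:
            return prop, ll
        if phi < 0.0:
            lo = phi
        else:
            hi = phi
        phi = rng.uniform(lo, hi)
    return eps, cur_ll


class _AdaptiveRW:
    """Random-walk Metropolis proposal with Haario-style covariance adaptation."""

    def __init__(self, dim: int, init_scale: float = 0.1):
        self.dim = dim
        self.log_scale = np.log(init_scale)
        self.mean = np.zeros(dim)
        self.cov = np.eye(dim)
        self.count = 0
        self.accepted = 0
        self.proposed = 0
        self._L = np.eye(dim)

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        self.proposed += 1
        step = self._L @ rng.standard_normal(self.dim)
        return x + np.exp(self.log_scale) * step

    def update(self, x: np.ndarray, accepted: bool, adapting: bool) -> None:
        if accepted:
            self.accepted += 1
        if not adapting:
            return
        self.count += 1
        w = 1.0 / (self.count + 1.0)
        delta = x - self.mean
        self.mean = self.mean + w * delta
        self.cov = (1.0 - w) * self.cov + w * np.outer(delta, delta)
        rate = self.accepted / max(self.proposed, 1)
        self.log_scale += self.count ** -0.6 * (rate - 0.25)
        if self.count >= 10 * self.dim and self.count % 25 == 0:
            self._L = np.linalg.cholesky(
                self.cov + 1e-8 * np.eye(self.dim)
            )

    @property
    def rate(self) -> float:
        return self.accepted / max(self.proposed, 1)


def _init_beta(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Crude IRLS Poisson fit for a sane starting point."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 0.1))
    for _ in range(25):
        eta = np.clip(X @ beta, -20, 20)
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        W = mu
        XtWX = X.T @ (X * W[:, None])
        new = np.linalg.solve(XtWX + 1e-8 * np.eye(X.shape[1]), X.T @ (W * z))
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return beta


def run_mcmc(
    table: pd.DataFrame,
    prior: PriorConfig | None = None,
    controls: McmcControls | None = None,
    fix: dict[str, float] | None = None,
) -> PosteriorDraws:
    """Sample the posterior of the spatial Poisson model.

    ``fix`` may pin covariance components, e.g. ``{"theta2": 0.0}`` for the
    non-spatial (nugget-only) limit.  Plots are re-ordered internally into
    a canonical order (sorted plot_id) before any random number is drawn,
    so the retained draws are exactly invariant to the row order of the
    input table.
    """
    if len(table) == 0:
        raise ValueError("empty plot table")
    prior = prior or PriorConfig()
    controls = controls or McmcControls()
    fix = dict(fix or {})
    for key in fix:
        if key not in THETA_NAMES:
            raise KeyError(f"only covariance parameters can be fixed, got {key!r}")

    t = table.sort_values("plot_id", kind="mergesort").reset_index(drop=True)
    y = t["richness"].to_numpy(dtype=float)
    X_raw = design_matrix(t)
    # sample with centred covariate columns (intercept then absorbs their
    # means), which largely decorrelates beta0 from the slopes; draws are
    # stored back on the original scale
    col_means = X_raw[:, 1:].mean(axis=0)
    X = X_raw.copy()
    X[:, 1:] -= col_means
    coords = t[["x", "y"]].to_numpy(dtype=float)
    plot_ids = t["plot_id"].astype(str).tolist()
    n = len(t)
    log_lo, log_hi = resolve_range_bounds(coords, prior)

    theta0 = {
        "theta1": fix.get("theta1", 0.1),
        "theta2": fix.get("theta2", 0.1),
        "theta3": fix.get("theta3", float(np.exp(0.5 * (log_lo + log_hi)))),
    }
    free_theta = [k for k in THETA_NAMES if k not in fix]
    beta_init = _init_beta(y, X)

    def theta_logprior(th: CovarianceParams) -> float:
        lp = _half_normal_logpdf(th.theta1, prior.theta_sd)
        lp += _half_normal_logpdf(th.theta2, prior.theta_sd)
        if not (log_lo <= np.log(th.theta3) <= log_hi):
            return -np.inf
        lp += -np.log(th.theta3) - np.log(log_hi - log_lo)
        return lp

    n_ret = controls.retained_per_chain
    out_beta = np.empty((controls.chains, n_ret, 4))
    out_theta = np.empty((controls.chains, n_ret, 3))
    out_eps = np.empty((controls.chains, n_ret, n))
    accept_rates = {}

    for chain in range(controls.chains):
        rng = np.random.Generator(
            np.random.Philox(key=np.uint64(controls.seed) * np.uint64(2**32) + np.uint64(chain))
        )
        beta = beta_init.copy()
        theta = CovarianceParams(**theta0)
        field_dens = _GaussianField(coords, theta)
        eps = np.zeros(n)

        Xb = X @ beta

        def poisson_ll(eps_vec, Xb_vec):
            loglam = Xb_vec + eps_vec
            if np.any(loglam > 700.0):
                return -np.inf
            return float(np.dot(y, loglam) - np.exp(loglam).sum())

        cur_ll = poisson_ll(eps, Xb)
        beta_rw = _AdaptiveRW(4, init_scale=0.05)
        theta_rw = _AdaptiveRW(len(free_theta), init_scale=0.2) if free_theta else None
        kept = 0

        # joint rescaling of (eps, variance components) moves the sampler
        # along the funnel axis that plain conditional updates mix slowly on;
        # it is valid only when every fixed variance component is zero
        var_free = [k for k in ("theta1", "theta2") if k not in fix]
        can_scale = len(var_free) > 0 and all(
            fix.get(k, 0.0) == 0.0 for k in ("theta1", "theta2")
        )
        scale_step = 0.3
        scale_acc = 0

        for it in range(controls.iters):
            adapting = it < controls.burnin

            # --- latent field: elliptical slice ---
            eps, cur_ll = _elliptical_slice(
                eps,
                lambda e: poisson_ll(e, Xb),
                cur_ll,
                field_dens.sample(rng),
                rng,
            )

            # --- regression effects: adaptive RWM ---
            prop = beta_rw.propose(beta, rng)
            Xb_prop = X @ prop
            ll_prop = poisson_ll(eps, Xb_prop)
            lp_cur = -np.sum(beta**2) / (2.0 * prior.beta_sd**2)
            lp_prop = -np.sum(prop**2) / (2.0 * prior.beta_sd**2)
            if np.log(rng.random()) < (ll_prop + lp_prop) - (cur_ll + lp_cur):
                beta, Xb, cur_ll = prop, Xb_prop, ll_prop
                beta_rw.update(beta, True, adapting)
            else:
                beta_rw.update(beta, False, adapting)

            # --- covariance parameters: RWM on log scale ---
            if free_theta:
                z = np.log([getattr(theta, k) for k in free_theta])
                z_prop = theta_rw.propose(z, rng)
                if np.all(z_prop > -25.0):
                    vals = {**{k: getattr(theta, k) for k in THETA_NAMES}}
                    vals.update({k: float(np.exp(v)) for k, v in zip(free_theta, z_prop)})
                    try:
                        theta_prop = CovarianceParams(**vals)
                    except ValueError:
                        theta_prop = None
                    if theta_prop is not None:
                        lp_t_prop = theta_logprior(theta_prop)
                        if np.isfinite(lp_t_prop):
                            dens_prop = _GaussianField(coords, theta_prop)
                            num = lp_t_prop + dens_prop.logpdf(eps) + z_prop.sum()
                            den = (
                                theta_logprior(theta)
                                + field_dens.logpdf(eps)
                                + z.sum()
                            )
                            if np.log(rng.random()) < num - den:
                                theta, field_dens = theta_prop, dens_prop
                                theta_rw.update(np.log(theta.as_array()[[THETA_NAMES.index(k) for k in free_theta]]), True, adapting)
                            else:
                                theta_rw.update(z, False, adapting)
                        else:
                            theta_rw.update(z, False, adapting)
                    else:
                        theta_rw.update(z, False, adapting)
                else:
                    theta_rw.update(z, False, adapting)

            # --- translation move: exact Gibbs transfer between beta and eps
            # along the design columns ((beta, eps) -> (beta + c, eps - Xc)
            # leaves the likelihood invariant; c has a Gaussian conditional
            # from the field and beta priors) ---
            CiX = field_dens.solve(X)
            Ci_eps = field_dens.solve(eps)
            A = X.T @ CiX + np.eye(4) / prior.beta_sd**2
            b = X.T @ Ci_eps - beta / prior.beta_sd**2
            LA = np.linalg.cholesky(A)
            c_mean = np.linalg.solve(LA.T, np.linalg.solve(LA, b))
            c = c_mean + np.linalg.solve(LA.T, rng.standard_normal(4))
            beta = beta + c
            eps = eps - X @ c
            Xb = X @ beta

            # --- funnel move: scale eps and free variance components ---
            if can_scale:
                z = scale_step * rng.standard_normal()
                s = float(np.exp(z))
                vals = {k: getattr(theta, k) for k in THETA_NAMES}
                for k in var_free:
                    vals[k] = vals[k] * s**2
                eps_prop = s * eps
                ll_prop = poisson_ll(eps_prop, Xb)
                d_prior = sum(
                    _half_normal_logpdf(vals[k], prior.theta_sd)
                    - _half_normal_logpdf(getattr(theta, k), prior.theta_sd)
                    for k in var_free
                )
                log_acc = (ll_prop - cur_ll) + d_prior + 2.0 * len(var_free) * z
                accepted = np.log(rng.random()) < log_acc
                if accepted:
                    eps, cur_ll = eps_prop, ll_prop
                    theta = CovarianceParams(**vals)
                    field_dens = field_dens.scaled(s)
                    scale_acc += 1
                if adapting:
                    scale_step *= np.exp((it + 1) ** -0.6 * (float(accepted) - 0.3))

            if it == controls.burnin - 1:
                if beta_rw.rate < 0.01:
                    raise RuntimeError(
                        "adaptation failed: regression-effect acceptance below 1% "
                        "at the end of burn-in"
                    )
                # freeze adaptation and reset acceptance counters
                beta_rw.accepted = beta_rw.proposed = 0
                if theta_rw is not None:
                    theta_rw.accepted = theta_rw.proposed = 0

            j = it - controls.burnin
            if j >= 0 and (j + 1) % controls.thin == 0 and kept < n_ret:
                out_beta[chain, kept] = beta
                out_beta[chain, kept, 0] -= col_means @ beta[1:]
                out_theta[chain, kept] = theta.as_array()
                out_eps[chain, kept] = eps
                kept += 1

        accept_rates[f"chain{chain}"] = {
            "beta": beta_rw.rate,
            "theta": theta_rw.rate if theta_rw is not None else None,
        }
        log.info(
            "chain %d: beta acceptance %.2f, theta acceptance %s",
            chain,
            beta_rw.rate,
            f"{theta_rw.rate:.2f}" if theta_rw is not None else "n/a",
        )

    return PosteriorDraws(
        out_beta, out_theta, out_eps, plot_ids, coords, controls, accept_rates
    )


# ---------------------------------------------------------------------------
# convergence diagnostic
# ---------------------------------------------------------------------------

def gelman_rubin(draws: PosteriorDraws | np.ndarray, parameter: str | None = None) -> float:
    """Split-chain potential scale reduction factor sqrt(Vhat / W).

    Each chain is split in half; W is the mean within-(half)chain variance
    and Vhat the pooled variance estimate (n-1)/n * W + B/n.  Values near
    1 indicate the chains agree; > 1.1 is conventionally "not converged".
    Returns NaN (with a warning) when the within-chain variance is zero.
    """
    if isinstance(draws, PosteriorDraws):
        x = draws.parameter(parameter)
    else:
        x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("need a (chains, draws) array")
    if x.shape[1] < 10:
        raise ValueError("need at least 10 retained draws per chain")
    # a single chain still yields two split halves
    half = x.shape[1] // 2
    halves = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    n = halves.shape[1]
    W = halves.var(axis=1, ddof=1).mean()
    if W == 0.0:
        log.warning("zero within-chain variance; PSRF undefined")
        return float("nan")
    B = n * halves.mean(axis=1).var(ddof=1)
    vhat = (n - 1.0) / n * W + B / n
    return float(np.sqrt(vhat / W))


def psrf_table(draws: PosteriorDraws, include_epsilon: bool = False) -> pd.Series:
    names = draws.parameter_names(include_epsilon)
    vals = {}
    for name in names:
        x = draws.parameter(name)
        if np.allclose(x.var(), 0.0):  # fixed parameters have no PSRF
            continue
        vals[name] = gelman_rubin(x)
    return pd.Series(vals, name="psrf")
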