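"""Pipeline configuration: seeds, MCMC controls, priors, class edges."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .io import DEFAULT_CLASS_EDGES


@dataclass
class McmcControls:
    """Chain-management settings.

    Defaults follow the study protocol: 1,000 burn-in iterations, 20,000
    post-burn-in iterations with every 100th retained, i.e. 200 posterior
    samples per chain.
    """

    iters: int = 21_000
    burnin: int = 1_000
    thin: int = 100
    chains: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("iters", "burnin", "thin", "chains"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.burnin >= self.iters:
            raise ValueError("burnin must be smaller than iters")

    @property
    def retained_per_chain(self) -> int:
        return (self.iters - self.burnin) // self.thin


@dataclass
class PriorConfig:
    """Hyperparameters of the (proper) priors.

    Regression effects get very diffuse independent Normal(0, beta_sd)
    priors.  The covariance parameters get half-Normal(theta_sd) on the
    nugget and partial sill and a log-uniform prior on the range, bounded
    by ``log_range_bounds`` (metres); when the bounds are None they are
    derived from the data (minimum plot spacing, twice the domain
    diameter).
    """

    beta_sd: float = 100.0
    theta_sd: float = 5.0
    log_range_bounds: tuple[float, float] | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    mcmc: McmcControls = field(default_factory=McmcControls)
    prior: PriorConfig = field(default_factory=PriorConfig)
    class_edges: tuple[float, ...] = DEFAULT_CLASS_EDGES
    threshold_fractions: tuple[float, ...] = (0.25, 0.5, 0.75, 0.95)
    n_permutations: int = 4_999

    def __post_init__(self) -> None:
        edges = tuple(self.class_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("class_edges must be strictly increasing")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path | None) -> "PipelineConfig":
        if path is None:
            return cls()
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mcmc = McmcControls(**raw.pop("mcmc", {}))
        prior = PriorConfig(**raw.pop("prior", {}))
        for key in ("class_edges", "threshold_fractions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(mcmc=mcmc, prior=prior, **raw)
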