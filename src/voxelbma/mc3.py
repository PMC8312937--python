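"""Markov chain Monte Carlo model composition (MC3) over covariate subsets.

A Metropolis sampler on the model space: from the current subset,
propose uniformly among all subsets at Hamming distance one (optionally
including the current subset itself), and accept with probability
min{1, posterior ratio}. Under a uniform model prior the ratio reduces
to the marginal-likelihood ratio, which is available in closed form, so
each visited model's marginal is computed exactly once and cached.

Two posterior estimates are kept: raw post-burn-in visit frequencies,
and the exact marginals renormalized over the set of visited models.
The latter has lower variance and equals the true posterior restricted
to the visited set; it is the pipeline default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .bma import GPrior, ModelSpace, RegressionModel, log_marginal_likelihood
from .design import DesignMatrix


@dataclass(frozen=True)
class MC3Config:
    n_iterations: int = 20_000
    burn_in: int = 2_000
    seed: int = 0
    include_self_in_neighborhood: bool = True
    random_start: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be positive")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")


@dataclass
class MC3Trace:
    """Post-burn-in record of an MC3 run.

    ``visit_counts`` maps mask -> number of post-burn-in iterations spent
    there; ``log_marginals`` maps mask -> exact log marginal (also for
    models proposed but never accepted, since their marginals were
    evaluated). Both probability estimates are over ``visited_masks``.
    """

    k: int
    visit_counts: dict[int, int]
    log_marginals: dict[int, float]
    n_accepted: int
    n_iterations: int
    burn_in: int
    visited_masks: list[int] = field(init=False)
    frequency_probs: np.ndarray = field(init=False)
    renormalized_probs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.visited_masks = sorted(self.visit_counts)
        counts = np.array([self.visit_counts[m] for m in self.visited_masks], dtype=float)
        self.frequency_probs = counts / counts.sum()
        lml = np.array([self.log_marginals[m] for m in self.visited_masks])
        self.renormalized_probs = np.exp(lml - logsumexp(lml))

    def pips(self, estimator: str = "renormalized") -> np.ndarray:
        """Posterior inclusion probabilities from the chosen estimator."""
        probs = {
            "renormalized": self.renormalized_probs,
            "frequency": self.frequency_probs,
        }[estimator]
        masks = np.asarray(self.visited_masks, dtype=np.int64)
        membership = ((masks[:, None] >> np.arange(self.k)) & 1).astype(float)
        return membership.T @ probs


def neighborhood(
    model: RegressionModel, k: int | None = None, include_self: bool = True
) -> list[RegressionModel]:
    """All models at Hamming distance 1 (single add/remove), plus self if asked."""
    k = model.k if k is None else k
    if k != model.k:
        raise ValueError(f"model has k={model.k}, neighborhood asked for k={k}")
    out = [RegressionModel(mask=model.mask ^ (1 << i), k=k) for i in range(k)]
    if include_self:
        out.append(model)
    return out


def mc3_run(
    y: np.ndarray,
    X: DesignMatrix | np.ndarray,
    prior: GPrior,
    cfg: MC3Config,
    space: ModelSpace | None = None,
    rng: np.random.Generator | None = None,
) -> MC3Trace:
    """Run the MC3 chain at one voxel.

    Deterministic given ``cfg.seed`` (or an explicit ``rng``, which the
    pipeline derives from (master seed, voxel index)). The chain starts
    at the null model unless ``cfg.random_start``.
    """
    values = X.values if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    n, k = values.shape
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    if space is not None:
        all_lml = space.log_marginals(np.asarray(y, dtype=float), prior)

        def lml_of(mask: int) -> float:
            return float(all_lml[mask])

    else:
        import warnings

        def lml_of(mask: int) -> float:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return log_marginal_likelihood(
                    y, values, RegressionModel(mask=mask, k=k), prior
                )

    cache: dict[int, float] = {}

    def cached_lml(mask: int) -> float:
        if mask not in cache:
            cache[mask] = lml_of(mask)
        return cache[mask]

    current = int(rng.integers(0, 1 << k)) if cfg.random_start else 0
    current_lml = cached_lml(current)

    n_moves = k + (1 if cfg.include_self_in_neighborhood else 0)
    flips = rng.integers(0, n_moves, size=cfg.n_iterations)
    log_u = np.log1p(-rng.random(size=cfg.n_iterations))  # log of U in (0, 1]

    visit_counts: dict[int, int] = {}
    n_accepted = 0
    for t in range(cfg.n_iterations):
        move = int(flips[t])
        if move < k:  # flip one bit; move == k is the self-proposal
            proposal = current ^ (1 << move)
            prop_lml = cached_lml(proposal)
            if prop_lml - current_lml >= log_u[t]:
                current, current_lml = proposal, prop_lml
                n_accepted += 1
        else:
            n_accepted += 1
        if t >= cfg.burn_in:
            visit_counts[current] = visit_counts.get(current, 0) + 1

    # drop never-visited proposals from the marginal record
    lml_visited = {m: cache[m] for m in visit_counts}
    return MC3Trace(
        k=k,
        visit_counts=visit_counts,
        log_marginals=lml_visited,
        n_accepted=n_accepted,
        n_iterations=cfg.n_iterations,
        burn_in=cfg.burn_in,
    )


def best_model(trace: MC3Trace) -> RegressionModel:
    """Visited model with the largest exact log marginal; ties -> smaller mask."""
    if not trace.visited_masks:
        raise ValueError("empty trace")
    best_mask = min(
        trace.visited_masks, key=lambda m: (-trace.log_marginals[m], m)
    )
    return RegressionModel(mask=best_mask, k=trace.k)
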