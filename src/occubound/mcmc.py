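"""Shared MCMC driver and the Brooks–Gelman–Rubin convergence diagnostic.

Every fitting stage in this package runs several independent chains with
over-dispersed initial values drawn from the priors, discards a burn-in,
and assesses convergence with the potential scale reduction factor
(Brooks–Gelman–Rubin R-hat). The driver here owns the chain loop, the
per-chain seed discipline and the diagnostics so that the samplers only
have to provide a single-chain kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Sequence

import numpy as np

__all__ = [
    "MCMCConfig",
    "ChainDiagnostics",
    "ConvergenceWarning",
    "gelman_rubin",
    "run_chains",
    "chain_rng",
]


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when any monitored parameter has R-hat above threshold."""


@dataclass
class MCMCConfig:
    """Settings shared by all samplers.

    Parameters
    ----------
    n_chains
        Number of independent chains. At least 2 are required for the
        convergence diagnostic to be computed.
    n_iterations
        Total iterations per chain, including burn-in.
    n_burnin
        Iterations discarded from the start of each chain.
    thin
        Keep every ``thin``-th post-burn-in draw.
    seed
        Master seed. Per-chain generators are derived deterministically
        from ``(seed, chain_index)`` so single-chain reruns reproduce.
    rhat_threshold
        Convergence is flagged when every parameter's R-hat is below this.
    """

    n_chains: int = 3
    n_iterations: int = 3000
    n_burnin: int = 1000
    thin: int = 1
    seed: int = 0
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.n_iterations < 2:
            raise ValueError("n_iterations must be >= 2")
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ValueError("n_burnin must satisfy 0 <= burnin < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.rhat_threshold <= 0:
            raise ValueError("rhat_threshold must be positive")

    @property
    def n_kept(self) -> int:
        return len(range(self.n_burnin, self.n_iterations, self.thin))


@dataclass
class ChainDiagnostics:
    """Per-parameter R-hat values plus the overall convergence flag."""

    rhat: Dict[str, float]
    threshold: float
    converged: bool
    n_chains: int
    n_iterations: int
    n_burnin: int
    thin: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "rhat": {k: float(v) for k, v in self.rhat.items()},
            "threshold": self.threshold,
            "converged": bool(self.converged),
            "n_chains": self.n_chains,
            "n_iterations": self.n_iterations,
            "n_burnin": self.n_burnin,
            "thin": self.thin,
            "seed": self.seed,
        }


def chain_rng(seed: int, chain_index: int) -> np.random.Generator:
    """Deterministic per-chain generator derived from (master seed, chain index)."""
    return np.random.default_rng([int(seed), int(chain_index)])


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Potential scale reduction factor for one scalar parameter.

    With m >= 2 chains of equal length n >= 2, let W be the mean
    within-chain variance and B = n * Var(chain means). Then

        R-hat = sqrt(((n - 1)/n * W + B/n) / W)

    reported with a floor of 1 (the no-between-chain-spread case gives
    sqrt((n-1)/n) < 1 which is rounded up by convention). Chains that are
    each constant but at different values have W = 0 with B > 0 and
    return +inf; identical constant chains return exactly 1.
    """
    arrs = [np.asarray(c, dtype=float).ravel() for c in chains]
    if len(arrs) < 2:
        raise ValueError("gelman_rubin requires at least 2 chains")
    n = arrs[0].size
    if n < 2:
        raise ValueError("chains must have length >= 2")
    if any(a.size != n for a in arrs):
        raise ValueError("all chains must have equal length")

    means = np.array([a.mean() for a in arrs])
    within = float(np.mean([a.var(ddof=1) for a in arrs]))
    between = n * float(means.var(ddof=1))
    if within == 0.0:
        return 1.0 if between == 0.0 else float("inf")
    rhat = float(np.sqrt(((n - 1) / n * within + between / n) / within))
    return max(rhat, 1.0)


ChainKernel = Callable[[np.random.Generator, int], Mapping[str, np.ndarray]]


def run_chains(
    sampler: ChainKernel, cfg: MCMCConfig
) -> tuple[Dict[str, np.ndarray], ChainDiagnostics]:
    """Run ``cfg.n_chains`` chains of ``sampler`` and pool the draws.

    ``sampler(rng, n_iterations)`` must return a mapping from parameter
    name to a length-``n_iterations`` array of draws; initial values are
    the sampler's responsibility (drawn from the priors using ``rng``).
    Burn-in is discarded and thinning applied per chain before pooling.
    Non-convergence is reported through a :class:`ConvergenceWarning`
    and the ``converged`` flag, never silently ignored.
    """
    per_chain: list[Mapping[str, np.ndarray]] = []
    for c in range(cfg.n_chains):
        rng = chain_rng(cfg.seed, c)
        out = sampler(rng, cfg.n_iterations)
        per_chain.append(out)

    names = list(per_chain[0].keys())
    kept = {
        name: [np.asarray(ch[name])[cfg.n_burnin :: cfg.thin] for ch in per_chain]
        for name in names
    }

    if cfg.n_chains >= 2:
        rhat = {name: gelman_rubin(kept[name]) for name in names}
    else:
        rhat = {name: float("nan") for name in names}
    converged = cfg.n_chains >= 2 and all(
        np.isfinite(v) and v < cfg.rhat_threshold for v in rhat.values()
    )
    diag = ChainDiagnostics(
        rhat=rhat,
        threshold=cfg.rhat_threshold,
        converged=converged,
        n_chains=cfg.n_chains,
        n_iterations=cfg.n_iterations,
        n_burnin=cfg.n_burnin,
        thin=cfg.thin,
        seed=cfg.seed,
    )
    if cfg.n_chains >= 2 and not converged:
        worst = max(rhat, key=lambda k: rhat[k])
        warnings.warn(
            f"MCMC may not have converged: R-hat[{worst}] = {rhat[worst]:.4f} "
            f">= {cfg.rhat_threshold}",
            ConvergenceWarning,
            stacklevel=2,
        )
    pooled = {name: np.concatenate(kept[name]) for name in names}
    return pooled, diag
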