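"""Synthetic plot-based repeat-survey data with the structure the analysis assumes.

The generative model mirrors the hierarchical survey model end to end:

* plot occupancy ``z_j ~ Bernoulli(gamma)`` across all ``T`` plots of a
  region, optionally conditioned on at least one occupied plot;
* a uniformly random subset of ``J`` plots is flown, each ``K`` times
  (two consecutive passes in the motivating aerial design);
* per-survey detection at an occupied plot with probability ``q`` — either
  a scalar or logit-linked to binary plot strata and plot-survey
  visibility covariates;
* abundance at occupied plots ``N_j ~`` zero-truncated Poisson(lambda);
* observed counts ``C_jt ~ BetaBinomial(N_j, alpha, beta)``, realized as
  Binomial(N_j, p_jt) with ``p_jt ~ Beta(alpha, beta)`` — the
  heterogeneous individual detection of aerial counts.

Occupancy is closed within a plot across the K passes (the repeat surveys
are minutes apart), so a single ``z_j`` drives every pass of plot ``j``.
When both detections and counts are generated they are linked:
``y[j,t] = 1`` exactly when ``C[j,t] >= 1``, so the detection-level and
count-level models can be exercised on one dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import expit

__all__ = [
    "LogitDetectionSpec",
    "SimulationParams",
    "SurveyDataset",
    "simulate_occupancy_dataset",
    "simulate_count_dataset",
    "simulate_covariate_dataset",
    "sample_ztpois",
    "sample_occupancy_conditioned",
]


@dataclass
class LogitDetectionSpec:
    """Logit-scale coefficients for occurrence and detection.

    Occurrence: logit(phi_j) = a0 + a1 * strata_j (strata binary per plot,
    1 = habitat where presence is expected to be lower). Detection:
    logit(q_jt) = b0 + b1 * visibility_jt (1 = poor visibility).
    ``strata_freq`` / ``visibility_freq`` are the Bernoulli rates used to
    draw the covariates; visibility is drawn per plot-survey by default,
    or held constant within a plot with ``visibility_per_survey=False``.
    """

    a0: float = 0.0
    a1: float = 0.0
    b0: float = 0.0
    b1: float = 0.0
    strata_freq: float = 0.5
    visibility_freq: float = 0.5
    visibility_per_survey: bool = True

    def __post_init__(self) -> None:
        for name in ("strata_freq", "visibility_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimulationParams:
    """Parameters of the generative survey model.

    ``q`` (scalar per-survey detection) and ``logit_spec`` are mutually
    exclusive ways to specify detection. ``lam``, ``alpha``, ``beta`` are
    only needed for count simulation.
    """

    T: int
    J: int
    gamma: float
    K: int = 2
    q: Optional[float] = None
    logit_spec: Optional[LogitDetectionSpec] = None
    lam: Optional[float] = None
    alpha: Optional[float] = None
    beta: Optional[float] = None
    condition_on_presence: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be a positive integer")
        if not 0 <= self.J <= self.T:
            raise ValueError("J must satisfy 0 <= J <= T")
        if self.K < 1:
            raise ValueError("K must be a positive integer")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.q is not None and not 0.0 <= self.q <= 1.0:
            raise ValueError("scalar q must be in [0, 1]")
        if self.q is not None and self.logit_spec is not None:
            raise ValueError("specify either scalar q or logit_spec, not both")
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lam must be > 0")
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.condition_on_presence and self.gamma == 0.0:
            raise ValueError(
                "gamma = 0 with condition_on_presence: the conditioning event "
                "(at least one occupied plot) has probability zero"
            )


@dataclass
class SurveyDataset:
    """A simulated (or read) region survey with latent truth attached.

    ``z`` and ``N`` are latent and length ``T``; ``y``, ``counts`` and
    ``visibility`` are ``J x K`` over the sampled plots in the order given
    by ``sampled``.
    """

    T: int
    J: int
    K: int
    sampled: np.ndarray  # (J,) plot indices
    z: Optional[np.ndarray] = None  # (T,) 0/1
    N: Optional[np.ndarray] = None  # (T,) abundance, 0 where z = 0
    y: Optional[np.ndarray] = None  # (J, K) 0/1 detections
    counts: Optional[np.ndarray] = None  # (J, K) nonnegative ints
    strata: Optional[np.ndarray] = None  # (T,) 0/1
    visibility: Optional[np.ndarray] = None  # (J, K) 0/1
    region: str = "sim"

    def validate(self) -> None:
        if self.sampled.shape != (self.J,):
            raise ValueError("sampled must have shape (J,)")
        if self.z is not None:
            if self.z.shape != (self.T,):
                raise ValueError("z must have shape (T,)")
            if self.y is not None and np.any(self.y.max(axis=1) > self.z[self.sampled]):
                raise ValueError("detection implies occupancy: y[j,t] <= z[j]")
        if self.N is not None and self.z is not None:
            if np.any((self.N >= 1) != (self.z == 1)):
                raise ValueError("N[j] >= 1 exactly when z[j] = 1")
        if self.counts is not None and self.N is not None:
            if np.any(self.counts > self.N[self.sampled][:, None]):
                raise ValueError("counts bounded by abundance: C[j,t] <= N[j]")


def sample_occupancy_conditioned(
    rng: np.random.Generator, T: int, gamma: float
) -> np.ndarray:
    """Draw z_1..z_T iid Bernoulli(gamma) conditioned on sum(z) >= 1.

    Exact two-step sampler: the occupied count x ~ Binomial(T, gamma)
    truncated to x >= 1 by inverse CDF, then x plots chosen uniformly.
    This is the conditional distribution itself, with no rejection loop,
    and remains exact for arbitrarily small gamma*T.
    """
    if gamma <= 0.0:
        raise ValueError("conditioning event has probability zero at gamma = 0")
    z = np.zeros(T, dtype=np.int8)
    if gamma >= 1.0:
        z[:] = 1
        return z
    p0 = (1.0 - gamma) ** T
    u = p0 + rng.random() * (1.0 - p0)
    x = int(stats.binom.ppf(u, T, gamma))
    x = min(max(x, 1), T)
    z[rng.choice(T, size=x, replace=False)] = 1
    return z


def _draw_z(rng: np.random.Generator, params: SimulationParams) -> np.ndarray:
    if params.condition_on_presence:
        return sample_occupancy_conditioned(rng, params.T, params.gamma)
    return (rng.random(params.T) < params.gamma).astype(np.int8)


def sample_ztpois(
    rng: np.random.Generator, lam: float, size: int | tuple
) -> np.ndarray:
    """Exact zero-truncated Poisson draws by inverse CDF on the truncated support."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    p0 = np.exp(-lam)
    u = p0 + rng.random(size) * (1.0 - p0)
    n = stats.poisson.ppf(u, lam)
    return np.maximum(n, 1.0).astype(np.int64)


def _detection_prob_matrix(
    rng: np.random.Generator, params: SimulationParams
) -> tuple[np.ndarray, Optional[np.ndarray], Optional[np.ndarray]]:
    """Per sampled-plot-survey detection probabilities plus covariates (if any)."""
    if params.logit_spec is None:
        if params.q is None:
            raise ValueError("detection requires either scalar q or logit_spec")
        q = np.full((params.J, params.K), params.q)
        return q, None, None
    spec = params.logit_spec
    strata = (rng.random(params.T) < spec.strata_freq).astype(np.int8)
    if spec.visibility_per_survey:
        vis = (rng.random((params.J, params.K)) < spec.visibility_freq).astype(np.int8)
    else:
        vis_plot = (rng.random(params.J) < spec.visibility_freq).astype(np.int8)
        vis = np.repeat(vis_plot[:, None], params.K, axis=1)
    q = expit(spec.b0 + spec.b1 * vis)
    return q, strata, vis


def simulate_occupancy_dataset(params: SimulationParams) -> SurveyDataset:
    """Occupancy + detection histories: z ~ Bern(gamma), y[j,t] ~ Bern(z_j q)."""
    rng = np.random.default_rng(params.seed)
    z = _draw_z(rng, params)
    sampled = np.sort(rng.choice(params.T, size=params.J, replace=False))
    q, strata, vis = _detection_prob_matrix(rng, params)
    zs = z[sampled][:, None]
    y = (rng.random((params.J, params.K)) < zs * q).astype(np.int8)
    ds = SurveyDataset(
        T=params.T, J=params.J, K=params.K, sampled=sampled,
        z=z, y=y, strata=strata, visibility=vis,
    )
    ds.validate()
    return ds


def simulate_covariate_dataset(params: SimulationParams) -> SurveyDataset:
    """Detection histories under the logit-linked occurrence/detection model.

    Occupancy is plot-level: phi_j = invlogit(a0 + a1 * strata_j),
    z_j ~ Bernoulli(phi_j); detection q_jt = invlogit(b0 + b1 * vis_jt).
    With a1 = b1 = 0 this reduces to the scalar-q simulator at
    gamma = invlogit(a0), q = invlogit(b0).
    """
    if params.logit_spec is None:
        raise ValueError("simulate_covariate_dataset requires logit_spec")
    spec = params.logit_spec
    rng = np.random.default_rng(params.seed)
    strata = (rng.random(params.T) < spec.strata_freq).astype(np.int8)
    phi = expit(spec.a0 + spec.a1 * strata)
    if params.condition_on_presence:
        # Heterogeneous phi: thin a conditioned homogeneous draw is invalid,
        # so rejection on the (cheap) z vector; phi from invlogit is never 0.
        while True:
            z = (rng.random(params.T) < phi).astype(np.int8)
            if z.sum() >= 1:
                break
    else:
        z = (rng.random(params.T) < phi).astype(np.int8)
    sampled = np.sort(rng.choice(params.T, size=params.J, replace=False))
    if spec.visibility_per_survey:
        vis = (rng.random((params.J, params.K)) < spec.visibility_freq).astype(np.int8)
    else:
        vis_plot = (rng.random(params.J) < spec.visibility_freq).astype(np.int8)
        vis = np.repeat(vis_plot[:, None], params.K, axis=1)
    q = expit(spec.b0 + spec.b1 * vis)
    y = (rng.random((params.J, params.K)) < z[sampled][:, None] * q).astype(np.int8)
    ds = SurveyDataset(
        T=params.T, J=params.J, K=params.K, sampled=sampled,
        z=z, y=y, strata=strata, visibility=vis,
    )
    ds.validate()
    return ds


def simulate_count_dataset(params: SimulationParams) -> SurveyDataset:
    """Counts from the zero-truncated Poisson / beta-binomial model.

    Occupied plots get N_j ~ ZTPois(lam); each sampled plot-survey draws an
    individual detection probability p_jt ~ Beta(alpha, beta) and a count
    C_jt ~ Binomial(N_j, p_jt). Detections are the indicator C >= 1 so one
    dataset serves both the detection-level and count-level models.
    """
    if params.lam is None or params.alpha is None or params.beta is None:
        raise ValueError("count simulation requires lam, alpha and beta")
    rng = np.random.default_rng(params.seed)
    z = _draw_z(rng, params)
    N = np.zeros(params.T, dtype=np.int64)
    occ = np.flatnonzero(z == 1)
    if occ.size:
        N[occ] = sample_ztpois(rng, params.lam, occ.size)
    sampled = np.sort(rng.choice(params.T, size=params.J, replace=False))
    p = rng.beta(params.alpha, params.beta, size=(params.J, params.K))
    counts = rng.binomial(N[sampled][:, None], p)
    y = (counts >= 1).astype(np.int8)
    ds = SurveyDataset(
        T=params.T, J=params.J, K=params.K, sampled=sampled,
        z=z, N=N, y=y, counts=counts,
    )
    ds.validate()
    return ds
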