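"""End-to-end orchestration: reference fit -> q prior -> occupancy -> N*.

The full analysis runs in four stages, threading results forward:

1. fit the covariate detection model on a reference-region survey where
   animals were actually seen;
2. predict per-plot-survey detection in each target region from its own
   visibility table and moment-match the region-mean draws into an
   informative Beta prior for q (or take a configured q-prior override);
3. fit the conditional occupancy model to each target region's detection
   histories (typically all-zero) and derive k = max(1, floor(g95U * T)),
   the upper count of occupied plots;
4. fit the zero-truncated Poisson / beta-binomial model to reference
   counts and sum k per-plot abundance draws into the upper bound N*.

Outputs are CSV summaries (occupancy_summary.csv in the region/J/T/
mean/lo/hi shape, upper_bound_summary.csv), posterior draw CSVs, and a
JSON diagnostics sidecar per fitted stage, all stamped with the config
hash and master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .abundance import (
    BetaBinomParams,
    DEFAULT_BETABINOM,
    derive_upper_bound,
    fit_zt_abundance,
)
from .detection import CovariateTable, derive_q_prior, fit_detection_model, predict_q
from .io import (
    read_counts_csv,
    read_survey_csv,
    write_diagnostics_json,
)
from .mcmc import MCMCConfig
from .occupancy import (
    DetectionHistorySet,
    DetectionPriorQ,
    GammaPrior,
    fit_conditional_occupancy,
    occupied_sites_upper,
)

logger = logging.getLogger("occubound")

__all__ = ["RegionSpec", "PipelineConfig", "run_full_pipeline", "load_config"]


@dataclass
class RegionSpec:
    """One target region: design constants plus (optionally) its survey files.

    Without survey files the region is taken as J all-zero histories —
    the zero-detection outcome the estimator was built for. ``visibility``
    optionally gives the fraction of poor-visibility plot-surveys used
    when predicting the region's detection prior (default 0.5).
    """

    name: str
    T: int
    J: int
    K: int = 2
    plots_csv: Optional[str] = None
    surveys_csv: Optional[str] = None
    poor_visibility_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.T < 1 or not 0 <= self.J <= self.T or self.K < 1:
            raise ValueError(f"region '{self.name}': invalid design constants")
        if not 0.0 <= self.poor_visibility_fraction <= 1.0:
            raise ValueError("poor_visibility_fraction must be in [0, 1]")


@dataclass
class PipelineConfig:
    """Everything one run needs; see the example YAML in the README."""

    regions: list[RegionSpec]
    primary_region: Optional[str] = None  # region whose k feeds N*
    reference_plots_csv: Optional[str] = None
    reference_surveys_csv: Optional[str] = None
    counts_csv: Optional[str] = None
    q_prior_override: Optional[DetectionPriorQ] = None
    gamma_prior: GammaPrior = field(default_factory=GammaPrior)
    betabinom: BetaBinomParams = field(default_factory=lambda: DEFAULT_BETABINOM)
    lambda_max: float = 50.0
    credible_level: float = 0.95
    one_sided_upper: bool = False
    estimand: str = "realized"
    draws_per_lambda: int = 1
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("at least one region is required")
        if not 0.0 < self.credible_level < 1.0:
            raise ValueError("credible_level must be in (0, 1)")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        if self.primary_region is None:
            self.primary_region = self.regions[0].name
        if self.primary_region not in names:
            raise ValueError(f"primary_region '{self.primary_region}' not among regions")

    def config_hash(self) -> str:
        blob = json.dumps(_config_to_dict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _config_to_dict(cfg: PipelineConfig) -> dict:
    return {
        "regions": [vars(r).copy() for r in cfg.regions],
        "primary_region": cfg.primary_region,
        "reference_plots_csv": cfg.reference_plots_csv,
        "reference_surveys_csv": cfg.reference_surveys_csv,
        "counts_csv": cfg.counts_csv,
        "q_prior_override": cfg.q_prior_override.to_dict() if cfg.q_prior_override else None,
        "gamma_prior": {"a": cfg.gamma_prior.a, "b": cfg.gamma_prior.b},
        "betabinom": {"alpha": cfg.betabinom.alpha, "beta": cfg.betabinom.beta},
        "lambda_max": cfg.lambda_max,
        "credible_level": cfg.credible_level,
        "one_sided_upper": cfg.one_sided_upper,
        "estimand": cfg.estimand,
        "draws_per_lambda": cfg.draws_per_lambda,
        "mcmc": vars(cfg.mcmc).copy(),
    }


def load_config(path: str | Path, seed: Optional[int] = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file; ``seed`` overrides the file's."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    regions = [RegionSpec(**r) for r in raw.get("regions", [])]
    q_override = raw.get("q_prior_override")
    mcmc_raw = raw.get("mcmc", {})
    if seed is not None:
        mcmc_raw["seed"] = int(seed)
    gp = raw.get("gamma_prior", {})
    bb = raw.get("betabinom", {})
    return PipelineConfig(
        regions=regions,
        primary_region=raw.get("primary_region"),
        reference_plots_csv=raw.get("reference_plots_csv"),
        reference_surveys_csv=raw.get("reference_surveys_csv"),
        counts_csv=raw.get("counts_csv"),
        q_prior_override=DetectionPriorQ.from_dict(q_override) if q_override else None,
        gamma_prior=GammaPrior(**gp) if gp else GammaPrior(),
        betabinom=BetaBinomParams(**bb) if bb else DEFAULT_BETABINOM,
        lambda_max=raw.get("lambda_max", 50.0),
        credible_level=raw.get("credible_level", 0.95),
        one_sided_upper=raw.get("one_sided_upper", False),
        estimand=raw.get("estimand", "realized"),
        draws_per_lambda=raw.get("draws_per_lambda", 1),
        mcmc=MCMCConfig(**mcmc_raw),
    )


def _region_histories(region: RegionSpec) -> tuple[DetectionHistorySet, Optional[CovariateTable]]:
    if region.surveys_csv and region.plots_csv:
        hist, cov, _ = read_survey_csv(region.plots_csv, region.surveys_csv)
        hist.region = region.name
        return hist, cov
    logger.info(
        "region %s: no survey files; using %d all-zero histories (T=%d, K=%d)",
        region.name, region.J, region.T, region.K,
    )
    return DetectionHistorySet.all_zero(region.T, region.J, region.K, region.name), None


def _region_q_prior(
    cfg: PipelineConfig, region: RegionSpec, det_post, region_cov: Optional[CovariateTable]
) -> DetectionPriorQ:
    if cfg.q_prior_override is not None:
        return cfg.q_prior_override
    if det_post is None:
        raise ValueError(
            "no reference survey data and no q_prior_override: the conditional "
            "occupancy stage needs an informative detection prior"
        )
    if region_cov is None:
        # design-level visibility table: J plots x K surveys at the configured
        # poor-visibility fraction (deterministic rounded split)
        n = region.J * region.K
        n_poor = int(round(region.poor_visibility_fraction * n))
        flat = np.zeros(n, dtype=np.int8)
        flat[:n_poor] = 1
        region_cov = CovariateTable(
            strata=np.zeros(region.J, dtype=np.int8),
            visibility=flat.reshape(region.J, region.K),
        )
    pred = predict_q(det_post, region_cov)
    prior = derive_q_prior(pred.region_mean_draws)
    logger.info("region %s: q prior %s (mean %.3f)", region.name, prior.kind, prior.mean())
    return prior


def run_full_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages, write outputs under ``out_dir``, return the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.mcmc.seed}
    report: dict = {"stamp": stamp, "regions": {}, "warnings": []}

    # stage 1: reference detection model
    det_post = None
    if cfg.reference_plots_csv and cfg.reference_surveys_csv:
        hist, cov, _ = read_survey_csv(cfg.reference_plots_csv, cfg.reference_surveys_csv)
        if cov is None:
            raise ValueError("reference surveys need strata and visibility columns")
        logger.info("reference fit: J=%d plots, K=%d surveys", hist.J, hist.K)
        det_post = fit_detection_model(hist.y, cov, mcmc=cfg.mcmc)
        pd.DataFrame({
            "draw": np.arange(det_post.n_draws),
            "a0": det_post.a0, "a1": det_post.a1,
            "b0": det_post.b0, "b1": det_post.b1,
        }).to_csv(out / "detection_posterior.csv", index=False)
        write_diagnostics_json(det_post.diagnostics, out / "detection_posterior.diag.json")
        if not det_post.diagnostics.converged:
            report["warnings"].append("detection model: R-hat above threshold")

    # stages 2-3: per-region q prior, conditional occupancy, k
    occupancy_rows = []
    k_primary = None
    for region in cfg.regions:
        hist, region_cov = _region_histories(region)
        q_prior = _region_q_prior(cfg, region, det_post, region_cov)
        occ = fit_conditional_occupancy(
            hist, q_prior, cfg.gamma_prior, cfg.mcmc, level=cfg.credible_level
        )
        if not occ.diagnostics.converged:
            report["warnings"].append(f"occupancy ({region.name}): R-hat above threshold")
        summ = occ.summary(cfg.estimand)
        g95u = occ.gamma_95u(cfg.estimand, one_sided=cfg.one_sided_upper)
        k = occupied_sites_upper(g95u, region.T)
        occupancy_rows.append({
            "region": region.name, "J": region.J, "T": region.T,
            "mean": summ["mean"], "lo": summ["lo"], "hi": summ["hi"],
            "gamma_95u": g95u, "k": k,
        })
        pd.DataFrame({
            "draw": np.arange(occ.gamma.size),
            "gamma": occ.gamma,
            "realized_fraction": occ.x_frac,
        }).to_csv(out / f"occupancy_posterior_{region.name}.csv", index=False)
        write_diagnostics_json(occ.diagnostics, out / f"occupancy_posterior_{region.name}.diag.json")
        report["regions"][region.name] = {
            "q_prior": q_prior.to_dict(), **summ, "gamma_95u": g95u, "k": k,
        }
        if region.name == cfg.primary_region:
            k_primary = k
    occ_df = pd.DataFrame(occupancy_rows)
    occ_df.to_csv(out / "occupancy_summary.csv", index=False)

    # stage 4: abundance upper bound for the primary region
    if cfg.counts_csv:
        counts = read_counts_csv(cfg.counts_csv)
        logger.info("abundance fit: %d occupied plots, K=%d", *counts.shape)
        lam_post = fit_zt_abundance(counts, cfg.betabinom, cfg.lambda_max, cfg.mcmc)
        if not lam_post.diagnostics.converged:
            report["warnings"].append("abundance model: R-hat above threshold")
        pd.DataFrame({
            "draw": np.arange(lam_post.draws.size), "lambda": lam_post.draws,
        }).to_csv(out / "lambda_posterior.csv", index=False)
        write_diagnostics_json(lam_post.diagnostics, out / "lambda_posterior.diag.json")
        ub = derive_upper_bound(
            lam_post, k_primary, cfg.draws_per_lambda,
            seed=cfg.mcmc.seed, level=cfg.credible_level,
        )
        pd.DataFrame({
            "draw": np.arange(ub.draws.size), "N_star": ub.draws,
        }).to_csv(out / "upper_bound.csv", index=False)
        pd.DataFrame([ub.summary()]).to_csv(out / "upper_bound_summary.csv", index=False)
        report["upper_bound"] = ub.summary()
        report["lambda"] = {"mean": lam_post.mean(), "ci": lam_post.ci(cfg.credible_level)}

    with open(out / "run_metadata.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=float)
    for w in report["warnings"]:
        logger.warning("%s", w)
    return report
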