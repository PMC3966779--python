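"""CSV readers and writers for survey datasets, counts and posteriors.

Two tables describe a survey (UTF-8, header row, comma separator; plot
identifiers are opaque strings):

* ``plots.csv`` — plot_id, region, sampled, strata, z, N (the latent
  columns z and N are optional and present only for simulated data);
* ``surveys.csv`` — plot_id, survey_index, visibility, detected, count,
  and optionally observer_id. When observer rows are present they are
  pooled: a plot-survey counts as detected if any observer detected.

Counts for the abundance stage live in ``counts.csv`` (plot_id,
survey_index, count). Posterior draws and diagnostics are written as
plain CSV/JSON sidecars by the pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .detection import CovariateTable
from .occupancy import DetectionHistorySet
from .simulate import SurveyDataset

__all__ = [
    "write_survey_csv",
    "read_survey_csv",
    "write_counts_csv",
    "read_counts_csv",
    "write_diagnostics_json",
]


def write_survey_csv(
    ds: SurveyDataset,
    plots_path: str | Path,
    surveys_path: str | Path,
    include_latent: bool = True,
) -> None:
    """Write a dataset to the plots.csv / surveys.csv pair."""
    plots = pd.DataFrame({
        "plot_id": [f"p{i:05d}" for i in range(ds.T)],
        "region": ds.region,
        "sampled": np.isin(np.arange(ds.T), ds.sampled).astype(int),
    })
    if ds.strata is not None:
        plots["strata"] = ds.strata
    if include_latent:
        if ds.z is not None:
            plots["z"] = ds.z
        if ds.N is not None:
            plots["N"] = ds.N
    plots.to_csv(plots_path, index=False)

    rows = []
    for row_idx, plot in enumerate(ds.sampled):
        for t in range(ds.K):
            rec = {"plot_id": f"p{plot:05d}", "survey_index": t}
            if ds.visibility is not None:
                rec["visibility"] = int(ds.visibility[row_idx, t])
            if ds.y is not None:
                rec["detected"] = int(ds.y[row_idx, t])
            if ds.counts is not None:
                rec["count"] = int(ds.counts[row_idx, t])
            rows.append(rec)
    pd.DataFrame(rows).to_csv(surveys_path, index=False)


def _require_binary(df: pd.DataFrame, column: str) -> None:
    bad = ~df[column].isin((0, 1))
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:10]  # +2: header + 0-base
        raise ValueError(f"non-binary values in column '{column}' at file rows {rows}")


def read_survey_csv(
    plots_path: str | Path, surveys_path: str | Path
) -> tuple[DetectionHistorySet, Optional[CovariateTable], SurveyDataset]:
    """Read the plots/surveys pair back into analysis-ready objects.

    Observer-level rows (if an ``observer_id`` column is present) are
    pooled within each plot-survey: detected = max over observers.
    Returns the detection histories, the covariate table when both strata
    and visibility are present, and the full dataset (with any latent
    columns that were stored).
    """
    plots = pd.read_csv(plots_path)
    surveys = pd.read_csv(surveys_path)
    if plots.empty or surveys.empty:
        raise ValueError("empty survey input: plots.csv and surveys.csv must have rows")
    for col in ("plot_id", "region", "sampled"):
        if col not in plots.columns:
            raise ValueError(f"plots.csv is missing required column '{col}'")
    for col in ("plot_id", "survey_index"):
        if col not in surveys.columns:
            raise ValueError(f"surveys.csv is missing required column '{col}'")

    if "observer_id" in surveys.columns:
        key = ["plot_id", "survey_index", "observer_id"]
        dup = surveys.duplicated(subset=key, keep=False)
        if dup.any():
            ids = surveys.loc[dup, key].to_records(index=False).tolist()[:10]
            raise ValueError(f"duplicate (plot, survey, observer) rows: {ids}")
        agg: dict = {}
        if "detected" in surveys.columns:
            agg["detected"] = "max"
        if "count" in surveys.columns:
            agg["count"] = "max"
        if "visibility" in surveys.columns:
            agg["visibility"] = "first"
        surveys = (
            surveys.groupby(["plot_id", "survey_index"], as_index=False).agg(agg)
        )
    else:
        dup = surveys.duplicated(subset=["plot_id", "survey_index"], keep=False)
        if dup.any():
            ids = surveys.loc[dup, ["plot_id", "survey_index"]].to_records(index=False).tolist()[:10]
            raise ValueError(f"duplicate (plot, survey) rows: {ids}")

    _require_binary(plots, "sampled")
    if "strata" in plots.columns:
        _require_binary(plots, "strata")
    if "visibility" in surveys.columns:
        _require_binary(surveys, "visibility")
    if "detected" in surveys.columns:
        _require_binary(surveys, "detected")

    plot_ids = plots["plot_id"].tolist()
    plot_pos = {p: i for i, p in enumerate(plot_ids)}
    T = len(plot_ids)
    sampled = np.flatnonzero(plots["sampled"].to_numpy() == 1)
    J = sampled.size
    K = int(surveys["survey_index"].max()) + 1
    region = str(plots["region"].iloc[0])

    sampled_pos = {int(p): i for i, p in enumerate(sampled)}
    y = np.zeros((J, K), dtype=np.int8) if "detected" in surveys.columns else None
    counts = np.zeros((J, K), dtype=np.int64) if "count" in surveys.columns else None
    vis = np.zeros((J, K), dtype=np.int8) if "visibility" in surveys.columns else None
    for _, row in surveys.iterrows():
        pid = row["plot_id"]
        if pid not in plot_pos:
            raise ValueError(f"surveys.csv references unknown plot_id '{pid}'")
        j = sampled_pos.get(plot_pos[pid])
        if j is None:
            raise ValueError(f"surveys.csv has rows for unsampled plot '{pid}'")
        t = int(row["survey_index"])
        if y is not None:
            y[j, t] = int(row["detected"])
        if counts is not None:
            counts[j, t] = int(row["count"])
        if vis is not None:
            vis[j, t] = int(row["visibility"])

    z = plots["z"].to_numpy(dtype=np.int8) if "z" in plots.columns else None
    N = plots["N"].to_numpy(dtype=np.int64) if "N" in plots.columns else None
    strata = plots["strata"].to_numpy(dtype=np.int8) if "strata" in plots.columns else None
    ds = SurveyDataset(
        T=T, J=J, K=K, sampled=sampled, z=z, N=N, y=y, counts=counts,
        strata=strata, visibility=vis, region=region,
    )
    histories = (
        DetectionHistorySet(T=T, J=J, K=K, y=y, region=region) if y is not None else None
    )
    cov = None
    if strata is not None and vis is not None and J:
        cov = CovariateTable(strata=strata[sampled], visibility=vis)
    if histories is None:
        raise ValueError("surveys.csv has no 'detected' column")
    return histories, cov, ds


def write_counts_csv(counts: np.ndarray, path: str | Path) -> None:
    """Write a (J, K) count matrix as long-form counts.csv."""
    counts = np.asarray(counts)
    rows = [
        {"plot_id": f"c{j:05d}", "survey_index": t, "count": int(counts[j, t])}
        for j in range(counts.shape[0])
        for t in range(counts.shape[1])
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_counts_csv(path: str | Path) -> np.ndarray:
    """Read counts.csv back into a (J, K) matrix (plots in file order)."""
    df = pd.read_csv(path)
    for col in ("plot_id", "survey_index", "count"):
        if col not in df.columns:
            raise ValueError(f"counts.csv is missing required column '{col}'")
    if df.empty:
        raise ValueError("counts.csv is empty")
    if (df["count"] < 0).any():
        raise ValueError("counts must be nonnegative")
    wide = df.pivot_table(
        index="plot_id", columns="survey_index", values="count", sort=False
    )
    if wide.isna().any().any():
        raise ValueError("counts.csv is ragged: every plot needs every survey_index")
    return wide.to_numpy(dtype=np.int64)


def write_diagnostics_json(diag, path: str | Path) -> None:
    """Serialize ChainDiagnostics next to the posterior CSV it belongs to."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(diag.to_dict(), fh, indent=2)
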