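"""Goodness-of-fit statistics, distribution summaries and bulk evaluation.

Conventions fixed here and used throughout the package:

* mean error (ME) is ``mean(predicted - measured)`` - negative ME means the
  model underpredicts on average;
* RPD = sd(measured) / RMSE with the population (n) standard deviation, so
  the identity R^2 = 1 - RPD^-2 holds exactly whenever RMSE and sd share
  the denominator;
* a perfect prediction reports RMSE = 0 and RPD = infinity.

The bulk evaluation follows the protocol of comparing measured depth-
interval (bulk) SOC against the chosen statistic of the predicted map over
the matching depth slab, optionally widened to a +/- 1 sd interval: with
the interval variant the effective prediction is the point of
[stat - sd, stat + sd] closest to the measured value, so a measurement
inside the interval scores zero error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cube import SOCMap
from .synthetic import BulkSample

VARIANT_KEYS = ("mean", "median", "mean_pm_sd", "median_pm_sd")


@dataclass
class FitMetrics:
    me: float
    rmse: float
    mae: float
    rpd: float
    r2: float
    n: int

    def as_dict(self) -> dict:
        return {
            "me": self.me,
            "rmse": self.rmse,
            "mae": self.mae,
            "rpd": self.rpd,
            "r2": self.r2,
            "n": self.n,
        }


@dataclass
class PredictionSummary:
    mean: float
    median: float
    maximum: float
    minimum: float
    sd: float
    proportion_below_zero: float
    proportion_above_upper: float
    n: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class BulkEvaluation:
    """Per-slab predictions and aggregate metrics of one bulk evaluation.

    ``slabs`` has one row per bulk sample (measured value, slab mean/median/
    sd, pixel count); ``metrics`` holds the aggregate FitMetrics for the
    four evaluation variants; ``per_core`` breaks the chosen variants down
    by core.  Slabs with no unmasked pixels are listed in ``excluded``.
    """

    slabs: pd.DataFrame
    metrics: dict[str, FitMetrics]
    per_core: dict[str, dict[str, FitMetrics]] = field(default_factory=dict)
    excluded: list[BulkSample] = field(default_factory=list)


def compute_metrics(measured, predicted) -> FitMetrics:
    """ME, RMSE, MAE, RPD and R^2 of predictions against measurements."""
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape:
        raise ValueError("measured and predicted lengths differ")
    if m.size < 2:
        raise ValueError("need at least 2 pairs")
    err = p - m
    me = float(err.mean())
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    sd = float(m.std(ddof=0))
    if sd == 0:
        warnings.warn("zero variance in measured: RPD and R^2 undefined",
                      stacklevel=2)
        rpd, r2 = float("nan"), float("nan")
    elif rmse == 0:
        rpd, r2 = float("inf"), 1.0
    else:
        rpd = sd / rmse
        r2 = 1.0 - float(np.sum(err**2)) / float(np.sum((m - m.mean()) ** 2))
    return FitMetrics(me=me, rmse=rmse, mae=mae, rpd=rpd, r2=r2, n=m.size)


def summarize_distribution(soc_map: SOCMap, upper_limit: float) -> PredictionSummary:
    """Order statistics, moments and implausible-value proportions of a map.

    ``upper_limit`` is the highest calibrated SOC content; the summary
    reports the fraction of predictions above it and below zero.
    """
    v = soc_map.unmasked()
    if v.size == 0:
        raise ValueError("map has no unmasked predictions")
    return PredictionSummary(
        mean=float(v.mean()),
        median=float(np.median(v)),
        maximum=float(v.max()),
        minimum=float(v.min()),
        sd=float(v.std(ddof=0)),
        proportion_below_zero=float(np.mean(v < 0)),
        proportion_above_upper=float(np.mean(v > upper_limit)),
        n=int(v.size),
    )


# ---------------------------------------------------------------------------
# Bulk-sample evaluation
# ---------------------------------------------------------------------------


def _slab_stats(soc_map: SOCMap, top: float, bottom: float) -> dict | None:
    depth = soc_map.depth_axis_cm()
    map_top = soc_map.depth_origin_cm
    map_bottom = map_top + soc_map.shape[0] * soc_map.pixel_size_cm
    if top < map_top - 1e-9 or bottom > map_bottom + 1e-9:
        raise ValueError(
            f"interval [{top}, {bottom}) is not covered by the map's depth "
            f"range [{map_top}, {map_bottom})"
        )
    sel = (depth >= top) & (depth < bottom)
    if not np.any(sel):
        raise ValueError(f"interval [{top}, {bottom}) contains no pixel rows")
    block = soc_map.values[sel, :][soc_map.mask[sel, :]]
    block = block[np.isfinite(block)]
    if block.size == 0:
        return None
    return {
        "pred_mean": float(block.mean()),
        "pred_median": float(np.median(block)),
        "pred_sd": float(block.std(ddof=0)),
        "n_pixels": int(block.size),
    }


def _effective(measured, stat, sd, band):
    """Point of [stat - band*sd, stat + band*sd] closest to the measurement."""
    if band == 0:
        return stat
    return np.clip(measured, stat - band * sd, stat + band * sd)


def evaluate_bulk(
    maps: SOCMap | Mapping[str, SOCMap],
    bulk: list[BulkSample],
    statistic: str = "mean",
    band: int = 0,
) -> BulkEvaluation:
    """Evaluate a SOC map (or one per core) against bulk depth samples.

    ``statistic`` selects the slab summary (mean or median); ``band`` in
    {0, 1} selects the point estimate or the +/- 1 sd interval variant.
    ``metrics`` in the result always carries all four variants (pooled
    across cores); ``per_core`` the per-core breakdown.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    if band not in (0, 1):
        raise ValueError("band must be 0 or 1")

    def _map_for(core_id: str) -> SOCMap:
        if isinstance(maps, SOCMap):
            return maps
        return maps[core_id]

    rows, excluded = [], []
    for b in bulk:
        st = _slab_stats(_map_for(b.core_id), b.depth_top_cm, b.depth_bottom_cm)
        if st is None:
            excluded.append(b)
            continue
        rows.append(
            {
                "core_id": b.core_id,
                "depth_top_cm": b.depth_top_cm,
                "depth_bottom_cm": b.depth_bottom_cm,
                "measured": b.soc_mg_g,
                **st,
            }
        )
    if excluded:
        warnings.warn(
            f"{len(excluded)} bulk slab(s) had no unmasked pixels and were "
            "excluded",
            stacklevel=2,
        )
    slabs = pd.DataFrame(rows)
    if len(slabs) < 2:
        raise ValueError("fewer than 2 usable bulk slabs")

    def _variant_metrics(df: pd.DataFrame) -> dict[str, FitMetrics]:
        out = {}
        for key, (stat_col, b_) in {
            "mean": ("pred_mean", 0),
            "median": ("pred_median", 0),
            "mean_pm_sd": ("pred_mean", 1),
            "median_pm_sd": ("pred_median", 1),
        }.items():
            eff = _effective(
                df["measured"].to_numpy(),
                df[stat_col].to_numpy(),
                df["pred_sd"].to_numpy(),
                b_,
            )
            out[key] = compute_metrics(df["measured"].to_numpy(), eff)
        return out

    metrics = _variant_metrics(slabs)
    per_core = {
        cid: _variant_metrics(g)
        for cid, g in slabs.groupby("core_id")
        if len(g) >= 2
    }
    # annotate the requested variant's effective predictions on the table
    stat_col = "pred_mean" if statistic == "mean" else "pred_median"
    slabs["effective_prediction"] = _effective(
        slabs["measured"].to_numpy(),
        slabs[stat_col].to_numpy(),
        slabs["pred_sd"].to_numpy(),
        band,
    )
    return BulkEvaluation(
        slabs=slabs, metrics=metrics, per_core=per_core, excluded=excluded
    )


def evaluation_table(maps, bulk) -> pd.DataFrame:
    """Metrics for all four variants as one tidy table (rows = variants)."""
    ev = evaluate_bulk(maps, bulk)
    recs = []
    for key in VARIANT_KEYS:
        recs.append({"variant": key, **ev.metrics[key].as_dict()})
    return pd.DataFrame(recs).set_index("variant")


# ---------------------------------------------------------------------------
# Residual diagnostics
# ---------------------------------------------------------------------------


@dataclass
class ResidualDiagnostics:
    slope_vs_soc: float
    slope_stderr: float
    topsoil_mean_residual: float
    subsoil_mean_residual: float
    column_correlation: float | None
    n: int


def residual_depth_diagnostics(
    predicted,
    measured,
    depth_cm,
    horizon_boundary_cm: float = 30.0,
    columns=None,
) -> ResidualDiagnostics:
    """Residual structure against SOC level, depth horizon and column.

    The regression-to-the-mean signature of tree ensembles shows up as a
    negative residual-vs-SOC slope (high contents underestimated, low
    contents overestimated); a horizon split of the mean residual feeds
    :func:`corespec.models.estimate_bias_correction`.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    depth_cm = np.asarray(depth_cm, dtype=float)
    if predicted.size < 5:
        raise ValueError("need at least 5 residuals")
    resid = predicted - measured
    if np.std(measured) > 0 and np.std(resid) > 0:
        fit = stats.linregress(measured, resid)
        slope, stderr = float(fit.slope), float(fit.stderr)
    else:
        slope, stderr = 0.0, 0.0
    top = depth_cm < horizon_boundary_cm
    col_corr = None
    if columns is not None:
        columns = np.asarray(columns, dtype=float)
        if np.std(columns) > 0 and np.std(resid) > 0:
            col_corr = float(np.corrcoef(resid, columns)[0, 1])
        else:
            col_corr = 0.0
    return ResidualDiagnostics(
        slope_vs_soc=slope,
        slope_stderr=stderr,
        topsoil_mean_residual=float(resid[top].mean()) if top.any() else 0.0,
        subsoil_mean_residual=float(resid[~top].mean()) if (~top).any() else 0.0,
        column_correlation=col_corr,
        n=predicted.size,
    )
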