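"""Home-based annual exposure assignment from a pollutant monitor network.

Annual metrics (the arithmetic mean of the monitor's daily values — for O3
the dailies are daily 1-hr maxima by input contract) are interpolated to
each home with an inverse-distance-weighted average of the nearest k
monitors. Referent levels are a low percentile (default 10th) of the
cohort exposure distribution per pollutant, i.e. a relatively clean
neighborhood in the study area.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .config import ExposureSettings

logger = logging.getLogger(__name__)


def annual_metric(daily_values) -> float:
    """Arithmetic mean of a monitor's daily values (ug/m3)."""
    values = np.asarray(daily_values, dtype=float)
    if values.size == 0:
        raise ValueError("annual_metric: empty daily series")
    return float(values.mean())


def annual_metrics_table(monitors_daily: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long daily table (monitor_id, x, y, pollutant, date, value)
    to one annual metric per monitor."""
    if monitors_daily.empty:
        raise ValueError("empty monitor table")
    out = (
        monitors_daily.groupby(["monitor_id", "pollutant", "x", "y"], as_index=False)["value"]
        .mean()
        .rename(columns={"value": "annual"})
        .sort_values("monitor_id", ignore_index=True)
    )
    return out


def idw_interpolate(
    point,
    monitor_xy,
    monitor_values,
    k: int = 3,
    power: float = 1.0,
    eps: float = 1.0,
    monitor_ids=None,
) -> float:
    """Inverse-distance-weighted average of the k nearest monitors.

    Weights are proportional to 1/distance**power and normalized to sum to
    one, so the result is a convex combination of the k used values. A
    point within ``eps`` meters of a monitor takes that monitor's value
    directly (nearest wins; ties broken by monitor id order).
    """
    xy = np.asarray(monitor_xy, dtype=float).reshape(-1, 2)
    values = np.asarray(monitor_values, dtype=float)
    if xy.shape[0] < k:
        raise ValueError(f"idw_interpolate needs at least k={k} monitors, got {xy.shape[0]}")
    ids = np.arange(xy.shape[0]) if monitor_ids is None else np.asarray(monitor_ids)
    d = np.hypot(xy[:, 0] - point[0], xy[:, 1] - point[1])
    order = np.lexsort((ids, d))  # distance first, monitor id as tiebreak
    if d[order[0]] <= eps:
        return float(values[order[0]])
    sel = order[:k]
    w = 1.0 / d[sel] ** power
    return float(np.sum(w * values[sel]) / np.sum(w))


def assign_exposures(
    participants: pd.DataFrame,
    monitor_annual: pd.DataFrame,
    settings: ExposureSettings | None = None,
    domain_extent_m: float | None = None,
) -> pd.DataFrame:
    """One annual exposure per participant per pollutant.

    ``monitor_annual`` has columns monitor_id, pollutant, x, y, annual.
    Returns a long table participant_id, pollutant, concentration.
    Vectorized over participants (full distance matrix per pollutant).
    """
    settings = settings or ExposureSettings()
    k, power, eps = settings.k_nearest, settings.idw_power, settings.coincidence_epsilon_m
    if domain_extent_m is not None:
        outside = (
            (participants.home_x < 0)
            | (participants.home_x > domain_extent_m)
            | (participants.home_y < 0)
            | (participants.home_y > domain_extent_m)
        )
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} participant(s) outside the domain; "
                "exposures are still interpolated",
                stacklevel=2,
            )
    px = participants.home_x.to_numpy(float)
    py = participants.home_y.to_numpy(float)
    frames = []
    for pollutant, grp in monitor_annual.groupby("pollutant"):
        grp = grp.sort_values("monitor_id", ignore_index=True)
        if len(grp) < k:
            raise ValueError(f"pollutant {pollutant}: {len(grp)} monitors < k={k}")
        mx = grp.x.to_numpy(float)
        my = grp.y.to_numpy(float)
        mv = grp.annual.to_numpy(float)
        d = np.hypot(px[:, None] - mx[None, :], py[:, None] - my[None, :])
        # nearest-k by distance; grp is id-sorted so argsort's stability
        # breaks ties by monitor id
        order = np.argsort(d, axis=1, kind="stable")[:, :k]
        dk = np.take_along_axis(d, order, axis=1)
        vk = mv[order]
        with np.errstate(divide="ignore"):
            w = 1.0 / dk**power
        conc = np.where(
            dk[:, 0] <= eps,
            vk[:, 0],
            np.sum(np.where(np.isfinite(w), w, 0) * vk, axis=1)
            / np.sum(np.where(np.isfinite(w), w, 0), axis=1),
        )
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": participants.participant_id.to_numpy(),
                    "pollutant": pollutant,
                    "concentration": conc,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    logger.info(
        "assigned exposures: k=%d, IDW power=%g, coincidence eps=%g m", k, power, eps
    )
    return out


def referent_levels(exposures: pd.DataFrame, percentile: float = 10.0) -> dict[str, float]:
    """Cohort referent concentration per pollutant: the empirical percentile
    (linear interpolation between order statistics) of exposures."""
    if exposures.empty:
        raise ValueError("referent_levels: empty exposure table")
    out = {}
    for pollutant, grp in exposures.groupby("pollutant"):
        if len(grp) < 10:
            raise ValueError(f"referent_levels needs >= 10 participants for {pollutant}")
        out[str(pollutant)] = float(np.percentile(grp.concentration, percentile))
    logger.info("referent levels (percentile %g, linear-interpolation quantiles): %s",
                percentile, out)
    return out
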