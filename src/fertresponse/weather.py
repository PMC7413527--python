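"""Growing-season weather indices.

Indices over a planting-to-harvest window (closed on both ends):

* ``PPT`` — cumulative rainfall, mm.
* ``SDI`` — Shannon diversity index of daily rainfall shares, normalized by
  ``ln(n)``; 1 means perfectly even rainfall, 0 means all rain on one day.
* ``T``   — mean of daily mean temperatures, deg C.
* ``GDD`` — sum of daily mean temperatures at or above the 5 deg C base.

Site-level features average each index over the historical seasons
preceding the study year (default 5), mirroring the use of past weather as
a stand-in for the unknowable season ahead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WeatherIndices", "season_indices", "weather_indices", "GDD_BASE_C"]

GDD_BASE_C = 5.0


@dataclass(frozen=True)
class WeatherIndices:
    ppt: float
    sdi: float
    t_mean: float
    gdd: float
    window: tuple[pd.Timestamp, pd.Timestamp]
    seasons_averaged: int


def shannon_rainfall_index(rain_mm: np.ndarray) -> float:
    """SDI of one season's daily rainfall; nan when total rainfall is zero."""
    rd = np.asarray(rain_mm, dtype=float)
    if np.any(rd < 0):
        raise ValueError("negative rainfall")
    n = rd.size
    if n < 2:
        raise ValueError("SDI needs at least two days")
    total = rd.sum()
    if total <= 0:
        return float("nan")
    p = rd / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return float(-terms.sum() / np.log(n))


def growing_degree_days(tmean_c: np.ndarray, base: float = GDD_BASE_C) -> float:
    """Sum of daily mean temperatures >= ``base`` (the temperatures
    themselves are summed, not their excess over the base)."""
    tm = np.asarray(tmean_c, dtype=float)
    return float(tm[tm >= base].sum())


def season_indices(rain_mm, tmean_c) -> dict[str, float]:
    """PPT, SDI, T and GDD for one season of aligned daily series."""
    rd = np.asarray(rain_mm, dtype=float)
    tm = np.asarray(tmean_c, dtype=float)
    if rd.size != tm.size:
        raise ValueError("rainfall and temperature series differ in length")
    return {
        "ppt": float(rd.sum()),
        "sdi": shannon_rainfall_index(rd),
        "t_mean": float(tm.mean()),
        "gdd": growing_degree_days(tm),
    }


def weather_indices(
    series: pd.DataFrame,
    window: tuple,
    n_seasons: int = 5,
    date_col: str = "date",
    rain_col: str = "rain_mm",
    temp_col: str = "tmean_c",
) -> WeatherIndices:
    """Average seasonal indices over the ``n_seasons`` years before the window.

    ``window`` is the (planting, harvest) date pair of the study season; for
    each k in 1..n_seasons the same calendar window shifted back k years is
    extracted from ``series`` and its indices computed.  Seasons with zero
    total rainfall have no defined SDI and are skipped with a warning.
    """
    planting = pd.Timestamp(window[0])
    harvest = pd.Timestamp(window[1])
    if harvest <= planting:
        raise ValueError("harvest must follow planting")
    dates = pd.to_datetime(series[date_col])

    rows = []
    for k in range(1, n_seasons + 1):
        start = planting - pd.DateOffset(years=k)
        end = harvest - pd.DateOffset(years=k)
        mask = (dates >= start) & (dates <= end)
        season = series.loc[mask]
        expected = (end - start).days + 1
        if len(season) < expected:
            raise ValueError(
                f"historical season {start.date()}..{end.date()} incomplete: "
                f"{len(season)}/{expected} days"
            )
        idx = season_indices(season[rain_col].to_numpy(), season[temp_col].to_numpy())
        if np.isnan(idx["sdi"]):
            warnings.warn(
                f"season {start.date()}..{end.date()} had zero rainfall; "
                "SDI undefined, season skipped",
                stacklevel=2,
            )
            continue
        rows.append(idx)

    if not rows:
        raise ValueError("no admissible historical season in the series")
    agg = {k: float(np.mean([r[k] for r in rows])) for k in rows[0]}
    return WeatherIndices(
        ppt=agg["ppt"],
        sdi=agg["sdi"],
        t_mean=agg["t_mean"],
        gdd=agg["gdd"],
        window=(planting, harvest),
        seasons_averaged=len(rows),
    )
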