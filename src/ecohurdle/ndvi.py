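"""Vegetation-offtake pressure (iNDVI) from 16-day NDVI composite series.

The offtake proxy is the integrated area between an NDVI time series and its
within-window minimum, accumulated over the three calendar years up to and
including the year a study was sampled.  Composites flagged by their quality
band are discarded and bridged by linear interpolation before integration;
isolated low spikes that escaped the quality flags (unflagged cloud) can be
screened out with a median/MAD rule.

Units: NDVI is dimensionless in [-1, 1]; the integral is reported in
NDVI*days with day counts taken from actual calendar dates.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "NDVISeries",
    "filter_and_interpolate",
    "compute_indvi",
    "screen_influential",
    "window_for_study",
    "compute_pressures",
]

#: Studies sampled before the first full 3-year composite record use the
#: window ending 31 December of this year.
EARLIEST_WINDOW_END_YEAR = 2002


@dataclass
class NDVISeries:
    """One site's NDVI composite series.

    Parameters
    ----------
    site_id : str
    dates : array-like of numpy.datetime64[D]
        Composite dates, strictly increasing, nominally 16 days apart.
    values : array-like of float
        NDVI values in [-1, 1].
    qa : array-like of int
        Quality flags; 0 means a usable composite.
    """

    site_id: str
    dates: np.ndarray
    values: np.ndarray
    qa: np.ndarray = field(default=None)

    def __post_init__(self):
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.values = np.asarray(self.values, dtype=float)
        if self.qa is None:
            self.qa = np.zeros(len(self.values), dtype=int)
        self.qa = np.asarray(self.qa, dtype=int)
        if not (len(self.dates) == len(self.values) == len(self.qa)):
            raise ValidationError(
                f"site {self.site_id}: dates/values/qa lengths differ"
            )
        if len(self.dates) > 1 and not np.all(np.diff(self.dates).astype(int) > 0):
            raise ValidationError(f"site {self.site_id}: dates not strictly increasing")

    @property
    def day_numbers(self) -> np.ndarray:
        """Days since the first composite, as float."""
        return (self.dates - self.dates[0]).astype(int).astype(float)


def filter_and_interpolate(series: NDVISeries) -> NDVISeries:
    """Drop flagged composites and bridge the gaps by linear interpolation.

    Composites with ``qa != 0`` are discarded; each composite date then
    receives the straight-line interpolation between its nearest retained
    neighbours.  Leading and trailing gaps are filled with the nearest
    retained value (constant extension).  Values at retained dates are
    untouched.

    Raises
    ------
    InsufficientDataError
        If fewer than two composites have ``qa == 0``.
    """
    good = series.qa == 0
    if good.sum() < 2:
        raise InsufficientDataError(
            f"site {series.site_id}: only {int(good.sum())} usable NDVI "
            "composites (need >= 2)"
        )
    t = series.day_numbers
    filled = np.interp(t, t[good], series.values[good])
    return replace(series, values=filled, qa=np.zeros(len(t), dtype=int))


def _years_back(end: dt.date, years: int) -> dt.date:
    """Start of the window of `years` calendar years up to and including `end`."""
    try:
        shifted = end.replace(year=end.year - years)
    except ValueError:  # 29 Feb
        shifted = end.replace(year=end.year - years, day=28)
    return shifted + dt.timedelta(days=1)


def compute_indvi(
    series: NDVISeries,
    window_end: dt.date,
    window_years: int = 3,
    window_start: dt.date | None = None,
) -> float:
    """Integrated NDVI above the window minimum, in NDVI*days.

    The gap-free series is treated as piecewise linear between composites;
    the integral of ``v(t) - min v(t)`` over the window is then the exact
    trapezoidal rule on the composite grid, with values at the window
    boundaries obtained by interpolation when composites straddle them.

    Returns 0 exactly iff the series is constant on the window.  An explicit
    ``window_start`` overrides the calendar-years rule (useful for windows
    that are not whole years).

    Raises
    ------
    InsufficientDataError
        If the series does not cover the whole window.
    """
    if np.any(series.qa != 0):
        series = filter_and_interpolate(series)
    start = window_start or _years_back(window_end, window_years)
    d0 = np.datetime64(start, "D")
    d1 = np.datetime64(window_end, "D")
    if series.dates[0] > d0 or series.dates[-1] < d1:
        raise InsufficientDataError(
            f"site {series.site_id}: NDVI series [{series.dates[0]}, "
            f"{series.dates[-1]}] does not cover window [{d0}, {d1}]"
        )
    t = series.day_numbers
    t0 = float((d0 - series.dates[0]).astype(int))
    t1 = float((d1 - series.dates[0]).astype(int))
    inside = (t > t0) & (t < t1)
    tt = np.concatenate([[t0], t[inside], [t1]])
    vv = np.concatenate(
        [[np.interp(t0, t, series.values)], series.values[inside],
         [np.interp(t1, t, series.values)]]
    )
    return float(np.trapezoid(vv - vv.min(), tt))


def screen_influential(
    series: NDVISeries, k: float = 5.0, quiet_mads: float = 1.0
) -> list[int]:
    """Indices of isolated abnormally-low composites (unflagged cloud).

    A composite ``i`` is flagged when it sits more than ``k`` MADs below the
    series median while its immediate neighbours are within ``quiet_mads``
    MADs of the median -- i.e. a one-composite downward spike, the signature
    of cloud contamination that escaped the quality band.  Sustained
    (multi-composite) lows are never flagged.
    """
    v = series.values
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    flagged = []
    for i in range(len(v)):
        if not (med - v[i]) > k * mad:
            continue
        neighbours = [j for j in (i - 1, i + 1) if 0 <= j < len(v)]
        if neighbours and all(abs(v[j] - med) <= quiet_mads * mad for j in neighbours):
            flagged.append(i)
    return flagged


def window_for_study(study_years) -> dt.date:
    """End date of the 3-year NDVI window for a study.

    The window runs up to and including 31 December of the study's last
    sampling year, floored at 2002 so that early studies still get three
    full years of composite record.
    """
    if np.isscalar(study_years):
        last = int(study_years)
    else:
        last = int(max(study_years))
    return dt.date(max(last, EARLIEST_WINDOW_END_YEAR), 12, 31)


def compute_pressures(
    ndvi_long: pd.DataFrame,
    sites: pd.DataFrame,
    k: float = 5.0,
    window_years: int = 3,
    screen: str = "reinterpolate",
) -> pd.DataFrame:
    """Per-site pressure table from a long NDVI table plus site covariates.

    Parameters
    ----------
    ndvi_long : DataFrame with columns site_id, date (ISO-8601), ndvi, qa.
    sites : DataFrame with columns site_id, forest_cover, hpd and either
        sample_year_last or sample_years.
    screen : {"reinterpolate", "drop-site", "none"}
        How to respond to influential unflagged spikes: treat them as
        flagged and re-interpolate (default), drop the site entirely, or
        leave them in place.

    Returns
    -------
    DataFrame with columns site_id, forest_cover, hpd, indvi, n_flagged.
    """
    if screen not in ("reinterpolate", "drop-site", "none"):
        raise ValidationError(f"unknown screening mode {screen!r}")
    ndvi_long = ndvi_long.copy()
    ndvi_long["date"] = pd.to_datetime(ndvi_long["date"])
    rows = []
    for site_id, sub in ndvi_long.groupby("site_id", sort=False):
        sub = sub.sort_values("date")
        series = NDVISeries(
            site_id=str(site_id),
            dates=sub["date"].to_numpy().astype("datetime64[D]"),
            values=sub["ndvi"].to_numpy(),
            qa=sub["qa"].to_numpy(),
        )
        site_row = sites.loc[sites["site_id"] == site_id]
        if site_row.empty:
            raise ValidationError(f"site {site_id} has NDVI data but no site row")
        if "sample_year_last" in site_row:
            year = site_row["sample_year_last"].iloc[0]
        else:
            year = site_row["sample_years"].iloc[0]
        end = window_for_study(year)
        clean = filter_and_interpolate(series)
        flagged = screen_influential(clean, k=k) if screen != "none" else []
        if flagged and screen == "drop-site":
            continue
        if flagged and screen == "reinterpolate":
            qa = clean.qa.copy()
            qa[flagged] = 1
            clean = filter_and_interpolate(replace(clean, qa=qa))
        rows.append(
            {
                "site_id": site_id,
                "forest_cover": float(site_row["forest_cover"].iloc[0]),
                "hpd": float(site_row["hpd"].iloc[0]),
                "indvi": compute_indvi(clean, end, window_years),
                "n_flagged": len(flagged),
            }
        )
    return pd.DataFrame(rows, columns=["site_id", "forest_cover", "hpd", "indvi", "n_flagged"])
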