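"""Phenology summaries and synchrony statistics from plot-level census counts.

A census series is the raw observable: repeated counts of active bee nests
(or of inflorescences in bloom) in one plot across a season, indexed by
integer day-of-year (DOY).  From each series we extract the classical
phenophase dates -- start, peak and end of activity -- plus two fractional
summaries of the activity curve:

* ``doy50``: the day at which the cumulative activity curve first reaches
  50 % of the season total (linear interpolation between census points);
* ``mean date``: the average of the season midpoint ``(start + end) / 2``
  and ``doy50``, a robust centre-of-season statistic for unimodal curves.

Synchrony between a focal plot and the opposite guild is then measured two
ways, always against the pooled resources of the focal plot's *site*:

* percent overlap -- the percentage of the focal plot's active days on
  which the site's resources (union of opposite-role plots) were present;
* asynchrony -- the absolute difference between the focal plot's mean date
  and the mean date of the site's resources, in days.

Days are integers for presence/overlap and fractional for the mean-date
statistics.  Everything assumes a season contained in one calendar year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "CensusSeries",
    "PlotPhenology",
    "PresenceSet",
    "OverlapResult",
    "NoActivityError",
    "summarize_plot_phenology",
    "interpolate_doy50",
    "mean_date",
    "presence_days",
    "pooled_site_presence",
    "percent_overlap",
    "asynchrony",
    "overlap_table",
]

logger = logging.getLogger(__name__)

ROLES = ("bee", "flower")

AsynchronyConvention = Literal["plot-mean", "pooled-curve"]


class NoActivityError(ValueError):
    """Raised when a census series records no positive count."""


@dataclass(frozen=True)
class CensusSeries:
    """One plot-season of census counts for a single role.

    ``doy`` must be strictly increasing integers in 1..366; ``count``
    non-negative integers of the same length.
    """

    site: str
    plot: str
    role: str
    doy: tuple[int, ...]
    count: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if len(self.doy) == 0:
            raise ValueError(f"plot {self.plot}: series needs >=1 observation")
        if len(self.doy) != len(self.count):
            raise ValueError(f"plot {self.plot}: doy/count length mismatch")
        d = np.asarray(self.doy)
        c = np.asarray(self.count)
        if d.dtype.kind not in "iu" or c.dtype.kind not in "iu":
            raise ValueError(f"plot {self.plot}: doy and count must be integers")
        if np.any(d < 1) or np.any(d > 366):
            raise ValueError(f"plot {self.plot}: doy outside 1..366 (no year wrap)")
        if np.any(np.diff(d) <= 0):
            raise ValueError(f"plot {self.plot}: doy not strictly increasing")
        if np.any(c < 0):
            raise ValueError(f"plot {self.plot}: negative count")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.site, self.plot, self.role)


@dataclass(frozen=True)
class PlotPhenology:
    """Phenophase dates and activity summaries for one plot-season."""

    site: str
    plot: str
    role: str
    start_doy: int
    peak_doy: int
    end_doy: int
    doy50: float
    mean_doy: float
    total_activity: float

    def __post_init__(self) -> None:
        if not (self.start_doy <= self.peak_doy <= self.end_doy):
            raise ValueError("phenophase order violated: start <= peak <= end")
        if not (self.start_doy <= self.doy50 <= self.end_doy):
            raise ValueError("doy50 outside [start, end]")
        if not (self.start_doy <= self.mean_doy <= self.end_doy):
            raise ValueError("mean_doy outside [start, end]")


@dataclass(frozen=True)
class PresenceSet:
    """Set of integer days on which activity is considered present."""

    days: frozenset[int]

    def __len__(self) -> int:
        return len(self.days)

    def intersection(self, other: "PresenceSet") -> "PresenceSet":
        return PresenceSet(self.days & other.days)

    def union(self, other: "PresenceSet") -> "PresenceSet":
        return PresenceSet(self.days | other.days)


@dataclass(frozen=True)
class OverlapResult:
    site: str
    plot: str
    role: str
    percent_overlap: float
    asynchrony_days: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_overlap <= 100.0):
            raise ValueError("percent_overlap outside [0, 100]")
        if self.asynchrony_days < 0:
            raise ValueError("asynchrony_days negative")


def interpolate_doy50(series: CensusSeries) -> float:
    """Day at which cumulative activity first reaches 50 % of the total.

    The cumulative curve is defined at each census day as the running sum of
    counts up to and including that census, with linear interpolation
    between census days.  An exact hit at a census day returns that day.
    The result is clamped to the activity window [first positive census,
    last positive census]: when the first active census carries at least
    half the season total, raw interpolation from the preceding zero
    census would date the 50 % point before any activity was seen.
    """
    counts = np.asarray(series.count, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise NoActivityError(f"plot {series.plot}: no activity recorded")
    cum = np.cumsum(counts)
    doys = np.asarray(series.doy, dtype=float)
    target = 0.5 * total
    # first census whose cumulative sum reaches the target (exact hit -> that day)
    i = int(np.searchsorted(cum, target))
    if i == 0 or cum[i] == target:
        raw = float(doys[i])
    else:
        # linear interpolation on the segment (i-1, i); cum[i-1] < target < cum[i]
        frac = (target - cum[i - 1]) / (cum[i] - cum[i - 1])
        raw = float(doys[i - 1] + frac * (doys[i] - doys[i - 1]))
    positive = np.nonzero(counts > 0)[0]
    start, end = float(doys[positive[0]]), float(doys[positive[-1]])
    return min(max(raw, start), end)


def summarize_plot_phenology(series: CensusSeries) -> PlotPhenology:
    """Extract start/peak/end/doy50/mean dates and total activity.

    start = first DOY with a positive count, end = last such DOY, peak = DOY
    of the maximum count (earliest on ties).
    """
    counts = np.asarray(series.count)
    doys = np.asarray(series.doy)
    positive = np.nonzero(counts > 0)[0]
    if positive.size == 0:
        raise NoActivityError(f"plot {series.plot}: no activity recorded")
    start = int(doys[positive[0]])
    end = int(doys[positive[-1]])
    peak = int(doys[int(np.argmax(counts))])  # argmax takes the earliest max
    doy50 = interpolate_doy50(series)
    mid = 0.5 * (start + end)
    mean_doy = 0.5 * (mid + doy50)
    return PlotPhenology(
        site=series.site,
        plot=series.plot,
        role=series.role,
        start_doy=start,
        peak_doy=peak,
        end_doy=end,
        doy50=doy50,
        mean_doy=mean_doy,
        total_activity=float(counts.sum()),
    )


def mean_date(pheno: PlotPhenology) -> float:
    """Centre-of-season date: mean of the season midpoint and the 50 %-activity day."""
    return 0.5 * (0.5 * (pheno.start_doy + pheno.end_doy) + pheno.doy50)


def presence_days(pheno: PlotPhenology) -> PresenceSet:
    """Closed daily interval [start, end]: activity is assumed continuous
    between the first and last positive census."""
    return PresenceSet(frozenset(range(pheno.start_doy, pheno.end_doy + 1)))


def pooled_site_presence(resource_phenologies: Sequence[PlotPhenology]) -> PresenceSet:
    """Union of resource plots' presence intervals (may be non-contiguous)."""
    if len(resource_phenologies) == 0:
        raise ValueError("pooled_site_presence: empty resource list")
    days: frozenset[int] = frozenset()
    for p in resource_phenologies:
        days = days | presence_days(p).days
    return PresenceSet(days)


def percent_overlap(focal: PresenceSet, resources: PresenceSet) -> float:
    """100 * |focal AND resources| / |focal|."""
    if len(focal) == 0:
        raise ValueError("percent_overlap: empty focal presence")
    return 100.0 * len(focal.intersection(resources)) / len(focal)


def asynchrony(focal_mean: float, resource_site_mean: float) -> float:
    """Absolute difference (days) between a plot's mean date and the site
    resource mean date."""
    return abs(float(focal_mean) - float(resource_site_mean))


def _pooled_curve_series(series_list: Sequence[CensusSeries]) -> CensusSeries:
    """Sum census counts of several plots on the union of their census days."""
    acc: dict[int, int] = {}
    for s in series_list:
        for d, c in zip(s.doy, s.count):
            acc[d] = acc.get(d, 0) + int(c)
    doys = tuple(sorted(acc))
    first = series_list[0]
    return CensusSeries(
        site=first.site,
        plot="__pooled__",
        role=first.role,
        doy=doys,
        count=tuple(acc[d] for d in doys),
    )


def _resource_mean_date(
    resource_series: Sequence[CensusSeries],
    resource_phenos: Sequence[PlotPhenology],
    convention: AsynchronyConvention,
) -> float:
    if convention == "plot-mean":
        return float(np.mean([p.mean_doy for p in resource_phenos]))
    if convention == "pooled-curve":
        pooled = _pooled_curve_series(resource_series)
        return summarize_plot_phenology(pooled).mean_doy
    raise ValueError(f"unknown asynchrony convention {convention!r}")


def overlap_table(
    all_series: Iterable[CensusSeries],
    asynchrony_convention: AsynchronyConvention = "plot-mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plot overlap/asynchrony against pooled site resources, plus summaries.

    For every bee plot the resources are the flower plots of its site (and
    vice versa).  Plots with no activity, and plots at sites lacking any
    opposite-role plot, are skipped with a warning.

    Returns
    -------
    results : DataFrame with columns site, plot, role, percent_overlap,
        asynchrony_days (one row per usable focal plot).
    summary : DataFrame with per-role mean and sample SD (ddof=1) of both
        statistics and the plot count n.
    """
    series_list = list(all_series)
    phenos: dict[tuple[str, str, str], PlotPhenology] = {}
    usable: list[CensusSeries] = []
    for s in series_list:
        try:
            phenos[s.key] = summarize_plot_phenology(s)
            usable.append(s)
        except NoActivityError:
            logger.warning(
                "plot %s (%s, %s): no activity recorded; excluded", s.plot, s.site, s.role
            )

    by_site_role: dict[tuple[str, str], list[CensusSeries]] = {}
    for s in usable:
        by_site_role.setdefault((s.site, s.role), []).append(s)

    rows = []
    for s in usable:
        other = "flower" if s.role == "bee" else "bee"
        resources = by_site_role.get((s.site, other), [])
        if not resources:
            logger.warning(
                "plot %s at site %s has no %s resources; excluded from overlap",
                s.plot,
                s.site,
                other,
            )
            continue
        res_phenos = [phenos[r.key] for r in resources]
        focal_pheno = phenos[s.key]
        ov = percent_overlap(presence_days(focal_pheno), pooled_site_presence(res_phenos))
        site_mean = _resource_mean_date(resources, res_phenos, asynchrony_convention)
        asy = asynchrony(focal_pheno.mean_doy, site_mean)
        rows.append(
            OverlapResult(
                site=s.site,
                plot=s.plot,
                role=s.role,
                percent_overlap=ov,
                asynchrony_days=asy,
            )
        )

    results = pd.DataFrame(
        [
            {
                "site": r.site,
                "plot": r.plot,
                "role": r.role,
                "percent_overlap": r.percent_overlap,
                "asynchrony_days": r.asynchrony_days,
            }
            for r in rows
        ],
        columns=["site", "plot", "role", "percent_overlap", "asynchrony_days"],
    )

    summary_rows = []
    for role in ROLES:
        sub = results[results["role"] == role]
        if sub.empty:
            continue
        summary_rows.append(
            {
                "role": role,
                "n_plots": len(sub),
                "overlap_mean": sub["percent_overlap"].mean(),
                "overlap_sd": sub["percent_overlap"].std(ddof=1) if len(sub) > 1 else 0.0,
                "asynchrony_mean": sub["asynchrony_days"].mean(),
                "asynchrony_sd": sub["asynchrony_days"].std(ddof=1) if len(sub) > 1 else 0.0,
            }
        )
    summary = pd.DataFrame(
        summary_rows,
        columns=[
            "role",
            "n_plots",
            "overlap_mean",
            "overlap_sd",
            "asynchrony_mean",
            "asynchrony_sd",
        ],
    )
    return results, summary
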