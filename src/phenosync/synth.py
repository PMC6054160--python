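"""Synthetic census and soil-microclimate data with known ground truth.

The generator emulates one season of a dune plant--pollinator monitoring
campaign: five sites, a handful of bee-nesting plots and six flowering
plots per site, censused roughly every six days from early February to
early July, with soil temperature (1 cm and 25 cm depth) and moisture
measured on the same visits through the end of May.

Microclimate.  Every plot shares a common seasonal warming ramp at 1 cm;
plots differ by an additive thermal offset (site component + plot
component) and by a multiplicative ramp-rate factor, so that seasonal
*maximum* temperature varies partly independently of the seasonal *mean*
-- without this the candidate cue summaries would be collinear and model
selection would have no identifiable truth.  The 25 cm series is a
damped, lagged transform of the 1 cm deterministic course with reduced
measurement noise; moisture declines linearly through spring around a
plot-specific offset and is clipped to a physical range.

Phenology.  A plot's true season start is linear in its realized abiotic
summaries (the same seasonal summaries the analysis recomputes from the
emitted measurement rows, so recovery of the slopes is attenuation-free):

    start = beta0 + betaT * T_cue + betaM * M_ave + u_site + eps_plot

with bees cued by seasonal maximum 25 cm temperature and flowers by the
seasonal mean, and opposite-signed moisture effects.  Activity follows a
symmetric bell over [start, start + duration] scaled to a configurable
peak intensity; observed counts are Poisson draws of the bell evaluated
at the plot's census days (``count_noise="none"`` emits the rounded bell
itself for noise-free checks).

All randomness flows from one integer seed through a single
``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import cues, metrics

__all__ = ["SynthConfig", "SynthDataset", "generate_abiotic", "generate_census",
           "generate_dataset", "temperature_only_config", "null_config",
           "make_fixture", "fixture_names"]


@dataclass(frozen=True)
class SynthConfig:
    """Study-design and generative parameters for one synthetic season.

    Defaults reflect the monitored system: 5 sites; 3 bee plots at three
    sites and 4 at two (17 total); 6 flower plots per site (30 total);
    censuses every 6 +/- 1.5 days; bee timing shifted -15.3 d per degree C
    of seasonal maximum 25 cm soil temperature, flowering -6.6 d per
    degree C of the seasonal mean, with opposite-signed moisture effects.
    """

    n_sites: int = 5
    bee_plots_per_site: tuple[int, ...] | int = (3, 3, 3, 4, 4)
    flower_plots_per_site: tuple[int, ...] | int = 6
    census_interval_mean: float = 6.0
    census_interval_sd: float = 1.5
    season: tuple[int, int] = (32, 190)
    abiotic_window: tuple[int, int] = cues.DEFAULT_WINDOW

    # timing model (days; temperatures in degrees C, moisture in VWC fraction)
    beta0_bee: float = 363.0
    beta0_flower: float = 107.0
    betaT_bee: float = -15.3
    betaT_flower: float = -6.6
    betaM_bee: float = -240.5
    betaM_flower: float = 272.7
    cue_bee: str = "t25_max"
    cue_flower: str = "t25_ave"
    sd_site: float = 3.0
    sd_plot: float = 3.0
    duration_mean: float = 70.0
    duration_sd: float = 8.0
    peak_intensity: float = 50.0
    count_noise: str = "poisson"  # or "none": emit rounded latent intensity

    # microclimate generator
    t1_base: float = 7.5  # degrees C at 1 cm on the first season day
    t1_rate: float = 0.075  # common warming ramp, degrees C per day
    t1_noise: float = 1.0  # measurement/weather noise SD at 1 cm
    site_temp_sd: float = 0.4  # thermal offset SD between sites
    plot_temp_sd: float = 0.3  # thermal offset SD between plots within site
    rate_cv: float = 0.12  # CV of the plot-level ramp-rate factor
    t25_base: float = 8.2
    t25_damp: float = 0.6  # amplitude damping at 25 cm
    t25_lag: float = 8.0  # days of thermal lag at 25 cm
    t25_noise: float = 0.25
    m_base: float = 0.32  # VWC on the first season day
    m_rate: float = 0.0013  # VWC decline per day
    m_plot_sd: float = 0.025
    m_noise: float = 0.015

    seed: int = 0

    def plots(self) -> list[tuple[str, str, str]]:
        """(site, plot, role) triples of the design."""
        out = []
        for role, per_site in (("bee", self.bee_plots_per_site),
                               ("flower", self.flower_plots_per_site)):
            counts = (per_site,) * self.n_sites if isinstance(per_site, int) else tuple(per_site)
            if len(counts) != self.n_sites:
                raise ValueError(f"{role} plots-per-site length != n_sites")
            for i, c in enumerate(counts):
                site = f"S{i + 1}"
                out.extend((site, f"{site}-{role[0].upper()}{j + 1}", role) for j in range(c))
        return out


class SynthDataset(NamedTuple):
    census: pd.DataFrame
    abiotic: pd.DataFrame
    truth: pd.DataFrame
    summaries: pd.DataFrame


def _draw_schedule(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Census days for one plot: gaps ~ round(N(mean, sd)), at least 1 day.

    The first visit is jittered by up to two days, scaled by the gap SD so
    a deterministic cadence (sd = 0) yields identical schedules.
    """
    lo, hi = config.season
    doys = [lo + int(round(rng.uniform(0.0, 2.0) * config.census_interval_sd))]
    while True:
        gap = max(1, int(round(rng.normal(config.census_interval_mean,
                                          config.census_interval_sd))))
        nxt = doys[-1] + gap
        if nxt > hi:
            break
        doys.append(nxt)
    return np.asarray(doys, dtype=int)


def generate_abiotic(
    config: SynthConfig, rng: np.random.Generator | int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict[tuple[str, str], np.ndarray]]:
    """Draw census schedules and soil measurements for every plot.

    Returns the abiotic measurement table (rows only at census days inside
    the measurement campaign, i.e. up to the end of the summary window),
    the per-plot seasonal summaries recomputed from those rows, and the
    full-season census schedule per plot.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    lo, _ = config.season
    site_offsets = {f"S{i + 1}": rng.normal(0.0, config.site_temp_sd)
                    for i in range(config.n_sites)}
    rows = []
    schedules: dict[tuple[str, str], np.ndarray] = {}
    for site, plot, _role in config.plots():
        sched = _draw_schedule(config, rng)
        schedules[(site, plot)] = sched
        offset = site_offsets[site] + rng.normal(0.0, config.plot_temp_sd)
        rate = config.t1_rate * max(1.0 + rng.normal(0.0, config.rate_cv), 0.4)
        m_off = rng.normal(0.0, config.m_plot_sd)
        meas = sched[sched <= config.abiotic_window[1]]
        t1 = (config.t1_base + rate * (meas - lo) + offset
              + rng.normal(0.0, config.t1_noise, meas.size))
        lagged = np.clip(meas - lo - config.t25_lag, 0.0, None)
        t25 = (config.t25_base + config.t25_damp * (rate * lagged + offset)
               + rng.normal(0.0, config.t25_noise, meas.size))
        moist = np.clip(
            config.m_base - config.m_rate * (meas - lo) + m_off
            + rng.normal(0.0, config.m_noise, meas.size),
            0.01, 0.45,
        )
        for d, a, b, m in zip(meas, t1, t25, moist):
            rows.append({"site": site, "plot": plot, "doy": int(d),
                         "temp_1cm": float(a), "temp_25cm": float(b),
                         "moisture": float(m)})
    abiotic = pd.DataFrame(rows, columns=list(cues.ABIOTIC_COLUMNS))
    summaries = cues.summarize_abiotic(abiotic, config.abiotic_window)
    return abiotic, summaries, schedules


def _bell(doy: np.ndarray, start: float, duration: float, peak: float) -> np.ndarray:
    """Symmetric bell on [start, start + duration], zero outside."""
    mid = start + 0.5 * duration
    sigma = duration / 5.0
    lam = peak * np.exp(-0.5 * ((doy - mid) / sigma) ** 2)
    lam[(doy < start) | (doy > start + duration)] = 0.0
    return lam


def generate_census(
    config: SynthConfig,
    summaries: pd.DataFrame,
    schedules: dict[tuple[str, str], np.ndarray],
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate activity counts given per-plot abiotic summaries.

    A plot's true start is linear in its cue summary and mean moisture
    plus a site intercept and plot noise; activity is a symmetric bell
    over [start, start + duration] sampled with Poisson noise at the
    plot's census days.  A true start outside the census season is an
    error (the design could never observe it).
    """
    rng = np.random.default_rng(config.seed + 1 if rng is None else rng)
    lo, hi = config.season
    u_site = {f"S{i + 1}": rng.normal(0.0, config.sd_site) for i in range(config.n_sites)}
    summ = summaries.set_index(["site", "plot"])
    census_rows = []
    truth_rows = []
    for site, plot, role in config.plots():
        srow = summ.loc[(site, plot)]
        if role == "bee":
            beta0, betaT, betaM, cue = (config.beta0_bee, config.betaT_bee,
                                        config.betaM_bee, config.cue_bee)
        else:
            beta0, betaT, betaM, cue = (config.beta0_flower, config.betaT_flower,
                                        config.betaM_flower, config.cue_flower)
        cue_val = float(srow[cue])
        m_ave = float(srow["m_ave"])
        eps = rng.normal(0.0, config.sd_plot)
        start = beta0 + betaT * cue_val + betaM * m_ave + u_site[site] + eps
        if not (lo <= start <= hi):
            raise ValueError(
                f"plot {plot}: true season start {start:.1f} outside census "
                f"window [{lo}, {hi}]; adjust beta0/effect sizes"
            )
        duration = abs(rng.normal(config.duration_mean, config.duration_sd))
        duration = max(duration, 2.0 * config.census_interval_mean)
        sched = schedules[(site, plot)]
        lam = _bell(sched.astype(float), start, duration, config.peak_intensity)
        if config.count_noise == "poisson":
            counts = rng.poisson(lam)
        elif config.count_noise == "none":
            counts = np.round(lam).astype(int)
        else:
            raise ValueError(f"unknown count_noise {config.count_noise!r}")
        for d, c in zip(sched, counts):
            census_rows.append({"site": site, "plot": plot, "role": role,
                                "doy": int(d), "count": int(c)})
        truth_rows.append({
            "site": site, "plot": plot, "role": role,
            "true_start": start, "true_peak": start + 0.5 * duration,
            "true_end": start + duration, "duration": duration,
            "cue": cue, "cue_value": cue_val, "m_ave": m_ave,
            "u_site": u_site[site],
        })
    census = pd.DataFrame(census_rows,
                          columns=["site", "plot", "role", "doy", "count"])
    truth = pd.DataFrame(truth_rows)
    return census, truth


def generate_dataset(config: SynthConfig | None = None,
                     seed: int | None = None) -> SynthDataset:
    """One full synthetic season (abiotic + census + truth) from one seed."""
    config = config or SynthConfig()
    if seed is not None:
        config = replace(config, seed=int(seed))
    root = np.random.SeedSequence(config.seed)
    ab_ss, census_ss = root.spawn(2)
    abiotic, summaries, schedules = generate_abiotic(config, np.random.default_rng(ab_ss))
    census, truth = generate_census(config, summaries, schedules,
                                    np.random.default_rng(census_ss))
    return SynthDataset(census=census, abiotic=abiotic, truth=truth,
                        summaries=summaries)


def temperature_only_config(base: SynthConfig | None = None) -> SynthConfig:
    """Variant with the moisture effects switched off.

    The intercepts are re-centred by the mean moisture contribution they
    lose (bee -240.5 * ~0.243 VWC ~ -58 d; flower +272.7 * ~0.243 ~ +66 d)
    so the mean season timing stays inside the census window; only the
    temperature cue then drives between-plot timing differences.
    """
    base = base or SynthConfig()
    return replace(base, betaM_bee=0.0, betaM_flower=0.0,
                   beta0_bee=base.beta0_bee - 58.0,
                   beta0_flower=base.beta0_flower + 66.0)


def null_config(base: SynthConfig | None = None) -> SynthConfig:
    """Variant with no abiotic effects at all (timing = intercept + noise).

    Intercepts are set to the default configuration's mean start dates
    (bee ~doy 95, flower ~doy 104) so seasons stay observable.
    """
    base = base or SynthConfig()
    return replace(base, betaT_bee=0.0, betaT_flower=0.0,
                   betaM_bee=0.0, betaM_flower=0.0,
                   beta0_bee=95.0, beta0_flower=104.0)


# ---------------------------------------------------------------------------
# hand-constructed worked fixtures for the metrics test suite

def _interval_series(site: str, plot: str, role: str,
                     start: int, end: int, step: int = 5) -> dict:
    doys = list(range(start, end + 1, step))
    if doys[-1] != end:
        doys.append(end)
    return {"site": site, "plot": plot, "role": role,
            "doy": doys, "count": [1] * len(doys)}


_FIXTURES = {
    # two plots active over the identical interval -> 100 % both ways, zero asynchrony
    "two_plot_full_overlap": {
        "series": [_interval_series("S1", "B1", "bee", 100, 120),
                   _interval_series("S1", "F1", "flower", 100, 120)],
        "expected": {"bee_overlap": 100.0, "flower_overlap": 100.0,
                     "bee_asynchrony": 0.0, "flower_asynchrony": 0.0},
    },
    # non-overlapping seasons -> 0 % both ways
    "disjoint_seasons": {
        "series": [_interval_series("S1", "B1", "bee", 100, 110),
                   _interval_series("S1", "F1", "flower", 120, 130)],
        "expected": {"bee_overlap": 0.0, "flower_overlap": 0.0},
    },
    # 50-day focal bee season, resources covering its last 40 days -> 80 %
    "fig2_style": {
        "series": [_interval_series("S1", "B1", "bee", 100, 149),
                   _interval_series("S1", "F1", "flower", 110, 200, step=6)],
        "expected": {"bee_overlap": 80.0},
    },
}


def fixture_names() -> tuple[str, ...]:
    return tuple(_FIXTURES)


def make_fixture(name: str) -> tuple[list[metrics.CensusSeries], dict[str, float]]:
    """Hand-computed worked example: (census series, expected statistics)."""
    try:
        entry = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}") from None
    series = [
        metrics.CensusSeries(site=s["site"], plot=s["plot"], role=s["role"],
                             doy=tuple(s["doy"]), count=tuple(s["count"]))
        for s in entry["series"]
    ]
    return series, dict(entry["expected"])
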