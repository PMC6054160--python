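"""Independent oracles and small builders shared across the test suite.

The oracles deliberately avoid the package's own code paths: overlap by
per-day membership counting over explicit sets, the 50 %-activity day by
bisection on an np.interp representation of the cumulative curve.
"""

from __future__ import annotations

import numpy as np

from phenosync.metrics import CensusSeries


def overlap_oracle(focal_days: set[int], resource_days: set[int]) -> float:
    """Brute-force per-day membership count."""
    hits = sum(1 for d in focal_days if d in resource_days)
    return 100.0 * hits / len(focal_days)


def doy50_oracle(doys, counts) -> float:
    """Leftmost day where the piecewise-linear cumulative curve reaches
    half the total, by bisection on np.interp (independent of the
    package's interpolation code)."""
    doys = np.asarray(doys, dtype=float)
    counts = np.asarray(counts, dtype=float)
    cum = np.cumsum(counts)
    target = 0.5 * cum[-1]
    if target <= cum[0]:
        raw = float(doys[0])
    else:
        lo, hi = float(doys[0]), float(doys[-1])
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if np.interp(mid, doys, cum) >= target:
                hi = mid
            else:
                lo = mid
        raw = hi
    # activity cannot precede the first (or follow the last) positive census
    pos = np.nonzero(counts > 0)[0]
    return min(max(raw, float(doys[pos[0]])), float(doys[pos[-1]]))


def series(doys, counts, site="S1", plot="P1", role="bee") -> CensusSeries:
    return CensusSeries(site=site, plot=plot, role=role,
                        doy=tuple(int(d) for d in doys),
                        count=tuple(int(c) for c in counts))


def random_series(rng: np.random.Generator, max_censuses: int = 12,
                  max_doy: int = 366) -> CensusSeries:
    """A valid census series with at least one positive count."""
    n = int(rng.integers(1, max_censuses + 1))
    doys = np.sort(rng.choice(np.arange(1, max_doy + 1), size=n, replace=False))
    counts = rng.integers(0, 20, size=n)
    if counts.sum() == 0:
        counts[rng.integers(0, n)] = int(rng.integers(1, 20))
    return series(doys, counts)


def interval_series(start: int, end: int, site="S1", plot="P1", role="bee",
                    step: int = 4) -> CensusSeries:
    """Constant-count censuses covering exactly [start, end]."""
    doys = list(range(start, end + 1, step))
    if doys[-1] != end:
        doys.append(end)
    return series(doys, [1] * len(doys), site=site, plot=plot, role=role)
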