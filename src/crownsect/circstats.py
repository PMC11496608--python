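"""Circular statistics for azimuth populations.

Directions are compass azimuths in degrees.  Summaries derive from the mean
resultant vector: mean direction, resultant length R-bar, circular variance
1 - R-bar (unitless) and circular standard deviation sqrt(-2 ln R-bar)
expressed in degrees.  Uniformity is assessed with the Rayleigh test
(series-approximation p-value, Monte-Carlo fallback for very small samples)
and two samples are compared with Watson's two-sample U-squared test
(critical-value table, optional seeded permutation p-value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CircularSummary",
    "WatsonResult",
    "circular_summary",
    "rayleigh_test",
    "watson_two_sample",
    "stratified_circular_report",
]


@dataclass
class CircularSummary:
    n: int
    mean_deg: float | None     # None when R-bar = 0 (mean undefined)
    resultant_length: float    # R-bar in [0, 1]
    variance: float            # 1 - R-bar, unitless
    sd_deg: float              # sqrt(-2 ln R-bar) in degrees; inf at R-bar=0
    rayleigh_stat: float
    rayleigh_p: float


def _resultant(az_deg: np.ndarray) -> tuple[float, float]:
    """(mean direction deg, R-bar) of a circular sample."""
    a = np.radians(np.asarray(az_deg, dtype=float))
    c = np.cos(a).mean()
    s = np.sin(a).mean()
    rbar = float(np.hypot(c, s))
    mean = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return mean, rbar


def circular_summary(azimuths_deg) -> CircularSummary:
    """Mean direction, dispersion and Rayleigh uniformity of azimuths."""
    az = np.asarray(azimuths_deg, dtype=float)
    if az.size < 1:
        raise ValueError("need at least one azimuth")
    mean, rbar = _resultant(az)
    variance = 1.0 - rbar
    sd = (
        float(np.degrees(np.sqrt(-2.0 * np.log(rbar))))
        if rbar > 1e-12
        else np.inf
    )
    if az.size >= 2:
        stat, p = rayleigh_test(az)
    else:
        stat, p = np.nan, np.nan
    return CircularSummary(
        n=int(az.size),
        mean_deg=mean if rbar > 1e-12 else None,
        resultant_length=rbar,
        variance=variance,
        sd_deg=sd,
        rayleigh_stat=stat,
        rayleigh_p=p,
    )


def rayleigh_test(
    azimuths_deg, n_mc: int = 20000, seed: int = 0
) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns (Z, p) with Z = n * R-bar^2.  The p-value uses the standard
    higher-order series approximation; for n < 10, where the series is
    poor, a seeded Monte-Carlo null is used instead.
    """
    az = np.asarray(azimuths_deg, dtype=float)
    n = az.size
    if n < 2:
        raise ValueError("need at least two azimuths")
    _, rbar = _resultant(az)
    z = n * rbar**2
    if n >= 10:
        p = np.exp(-z) * (
            1.0
            + (2.0 * z - z**2) / (4.0 * n)
            - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
        )
        p = float(np.clip(p, 0.0, 1.0))
    else:
        rng = np.random.default_rng(seed)
        sim = rng.uniform(0.0, 2.0 * np.pi, (n_mc, n))
        rb = np.hypot(np.cos(sim).mean(axis=1), np.sin(sim).mean(axis=1))
        p = float((np.count_nonzero(n * rb**2 >= z) + 1) / (n_mc + 1))
    return float(z), p


# Asymptotic critical values for Watson's two-sample U^2
_WATSON_CRIT = [(0.01, 0.268), (0.02, 0.233), (0.05, 0.187), (0.10, 0.152)]


@dataclass
class WatsonResult:
    u2: float
    n_a: int
    n_b: int
    p_range: str              # e.g. "p < 0.05" or "p > 0.10"
    p_permutation: float | None = None

    def significant_at(self, alpha: float) -> bool:
        crit = dict((a, c) for a, c in _WATSON_CRIT)
        if alpha not in crit:
            raise ValueError(f"no tabulated critical value for alpha={alpha}")
        return self.u2 > crit[alpha]


def _watson_u2(a: np.ndarray, b: np.ndarray) -> float:
    """Watson U^2 from pooled circular ranks, midrank tie correction."""
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    which = np.concatenate([np.zeros(n), np.ones(m)])
    order = np.argsort(pooled, kind="stable")
    x = pooled[order]
    w = which[order]
    # cumulative empirical CDFs at the pooled points
    ca = np.cumsum(w == 0) / n
    cb = np.cumsum(w == 1) / m
    d = ca - cb
    # midrank treatment of ties: within a tied group use the group's last d
    if len(x) > 1:
        tied_next = np.r_[x[1:] == x[:-1], False]
        for i in range(len(d) - 2, -1, -1):
            if tied_next[i]:
                d[i] = d[i + 1]
    big_n = n + m
    return float(n * m / big_n**2 * (np.sum(d**2) - np.sum(d) ** 2 / big_n))


def watson_two_sample(
    azimuths_a,
    azimuths_b,
    n_permutations: int = 0,
    seed: int = 0,
) -> WatsonResult:
    """Watson's two-sample U^2 test of a common circular distribution.

    Significance is reported against the asymptotic critical-value table
    (0.10 / 0.05 / 0.02 / 0.01); with ``n_permutations`` > 0 a seeded
    permutation p-value is also computed (recommended for small samples).
    """
    a = np.radians(np.asarray(azimuths_a, dtype=float)) % (2 * np.pi)
    b = np.radians(np.asarray(azimuths_b, dtype=float)) % (2 * np.pi)
    if len(a) < 8 or len(b) < 8:
        raise ValueError("need n >= 8 per sample for tabulated critical values")
    u2 = _watson_u2(a, b)
    p_range = "p > 0.10"
    for alpha, crit in _WATSON_CRIT:
        if u2 > crit:
            p_range = f"p < {alpha:g}"
            break
    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if _watson_u2(perm[: len(a)], perm[len(a):]) >= u2:
                count += 1
        p_perm = (count + 1) / (n_permutations + 1)
    return WatsonResult(u2, len(a), len(b), p_range, p_perm)


def stratified_circular_report(
    table: pd.DataFrame, azimuth_col: str, group_cols: list[str]
) -> pd.DataFrame:
    """Per-group circular summaries (mean, variance, SD, Rayleigh p).

    Shapes one row per group combination, mirroring how preferred growth
    directions are reported per genotype/block in field trials.
    """
    rows = []
    for key, sub in table.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        s = circular_summary(sub[azimuth_col].to_numpy())
        rows.append(
            {
                **dict(zip(group_cols, key)),
                "n": s.n,
                "mean_deg": s.mean_deg,
                "variance": s.variance,
                "sd_deg": s.sd_deg,
                "rayleigh_p": s.rayleigh_p,
            }
        )
    return pd.DataFrame(rows)
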