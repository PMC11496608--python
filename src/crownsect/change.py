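"""Temporal crown-change metrics and accuracy/stem-volume utilities.

Covers the five azimuthal directionality metrics (largest cumulative
projection per epoch; largest growth LG, largest loss LL and largest absolute
change AC on the vertically overlapping region), emulated within/between-row
crown diameters, the signed percent change in wedge volume, the Tasissa
combined-variable outside-bark stem-volume model, and RMSE/bias accuracy
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AZIMUTH_STEP_DEG, AzimuthProfile

__all__ = [
    "DirectionalityMetrics",
    "largest_projection_azimuth",
    "overlap_change_metrics",
    "emulated_row_diameters",
    "stem_volume_tasissa",
    "wedge_percent_change",
    "evaluate_accuracy",
]


@dataclass
class DirectionalityMetrics:
    """Azimuths (deg, multiples of 10) of the five directionality metrics.

    ``None`` marks an undefined metric (no overlap, or no growth/loss at
    all).
    """

    largest_azimuth_e1: float | None = None
    largest_azimuth_e2: float | None = None
    lg_azimuth: float | None = None
    ll_azimuth: float | None = None
    ac_azimuth: float | None = None


def largest_projection_azimuth(profile: AzimuthProfile) -> float:
    """Azimuth whose cumulative stem-to-edge distance over heights is largest.

    Ties resolve to the smallest azimuth.
    """
    cum = profile.cumulative
    if not profile.valid_heights.any():
        raise ValueError("profile has no valid height class")
    return float(np.argmax(cum) * AZIMUTH_STEP_DEG)  # argmax takes first = smallest


def overlap_change_metrics(
    profile_e1: AzimuthProfile, profile_e2: AzimuthProfile
) -> DirectionalityMetrics:
    """LG / LL / AC azimuths from the vertically overlapping height classes.

    Height classes present (non-missing) in both epochs are compared: per
    azimuth the distance differences (epoch 2 - epoch 1) are summed with
    negatives dropped (growth), positives dropped (loss), and signed
    (absolute change).  A metric is undefined when its sums are all zero or
    there is no overlap.
    """
    out = DirectionalityMetrics()
    try:
        out.largest_azimuth_e1 = largest_projection_azimuth(profile_e1)
    except ValueError:
        pass
    try:
        out.largest_azimuth_e2 = largest_projection_azimuth(profile_e2)
    except ValueError:
        pass

    h1 = {round(float(h), 3): i for i, h in enumerate(profile_e1.heights)}
    common = [
        (h1[round(float(h), 3)], j)
        for j, h in enumerate(profile_e2.heights)
        if round(float(h), 3) in h1
    ]
    if not common:
        return out
    i1 = np.array([c[0] for c in common])
    i2 = np.array([c[1] for c in common])
    d1 = profile_e1.distances[i1]
    d2 = profile_e2.distances[i2]
    both = ~(np.isnan(d1) | np.isnan(d2))
    if not both.any():
        return out
    delta = np.where(both, d2 - d1, 0.0)

    growth = np.where(delta > 0, delta, 0.0).sum(axis=0)
    loss = np.where(delta < 0, delta, 0.0).sum(axis=0)
    signed = delta.sum(axis=0)
    if growth.max() > 0:
        out.lg_azimuth = float(np.argmax(growth) * AZIMUTH_STEP_DEG)
    if loss.min() < 0:
        out.ll_azimuth = float(np.argmin(loss) * AZIMUTH_STEP_DEG)
    if np.abs(signed).max() > 0:
        out.ac_azimuth = float(np.argmax(np.abs(signed)) * AZIMUTH_STEP_DEG)
    return out


def emulated_row_diameters(
    profile: AzimuthProfile, row_azimuth_deg: float = 135.0
) -> tuple[float, float]:
    """Emulate tape-measured crown diameters within and between rows.

    The two candidate axes combine the largest individual distances
    (regardless of height) at (a) 50 deg + 230 deg and (b) 140 deg +
    320 deg.  Whichever axis is closer to the plot's row azimuth (mod 180)
    is reported as the within-row diameter, the other as between-row.
    """
    if not profile.valid_heights.any():
        return np.nan, np.nan
    with np.errstate(all="ignore"):
        dmax = np.nanmax(np.nan_to_num(profile.distances, nan=0.0), axis=0)

    def axis_diameter(az: float) -> float:
        i = int(round(az / AZIMUTH_STEP_DEG)) % 36
        j = int(round((az + 180.0) / AZIMUTH_STEP_DEG)) % 36
        return float(dmax[i] + dmax[j])

    d_a = axis_diameter(50.0)
    d_b = axis_diameter(140.0)

    def angular_gap(a: float, b: float) -> float:
        d = abs((a - b) % 180.0)
        return min(d, 180.0 - d)

    if angular_gap(50.0, row_azimuth_deg) <= angular_gap(140.0, row_azimuth_deg):
        return d_a, d_b
    return d_b, d_a


# Tasissa et al. combined-variable model, metric wrapper around imperial
# coefficients: V[ft^3] = 0.21949 + 0.00238 * D[in]^2 * H[ft]
_B1 = 0.393701   # cm -> inch
_B2 = 3.28084    # m -> feet
_B3 = 0.0283168  # ft^3 -> m^3


def stem_volume_tasissa(dbh_cm: float, height_m: float) -> float:
    """Total outside-bark stem volume (m^3) from DBH (cm) and height (m)."""
    d = np.asarray(dbh_cm, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.any(d < 0) or np.any(h < 0):
        raise ValueError("DBH and height must be non-negative")
    vol = (0.21949 + 0.00238 * (d * _B1) ** 2 * (h * _B2)) * _B3
    return float(vol) if vol.ndim == 0 else vol


def wedge_percent_change(vol_e1: float, vol_e2: float) -> float:
    """Signed percent change in a wedge's volume between the two epochs."""
    if vol_e1 <= 0:
        raise ValueError("epoch-1 volume must be positive")
    return 100.0 * (vol_e2 - vol_e1) / vol_e1


def evaluate_accuracy(predicted, observed) -> dict:
    """RMSE, NRMSE (%), bias and normalized bias (%) of paired estimates.

    Normalized forms divide by the mean of the observations and are in
    percent.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must be the same length")
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    bias = float(np.mean(err))
    denom = float(np.mean(obs))
    return {
        "rmse": rmse,
        "nrmse_pct": 100.0 * rmse / denom if denom != 0 else np.nan,
        "bias": bias,
        "nbias_pct": 100.0 * bias / denom if denom != 0 else np.nan,
    }
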