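"""IMU kinematics, gait-cycle segmentation and per-cycle feature extraction.

The ankle joint angle is reconstructed from the two attitude sensors that
bracket the joint: ``ankle = IMU_up + IMU_down + 90 deg`` (90 deg is the
pre-stored static-stance angle).  Gait cycles are delimited by adjacent
ankle-angle maxima (MaxAA, plantarflexion peaks at toe-off); each cycle
contributes MaxAA, MinAA (deepest trough), the maximum angular velocity in
the dorsiflexion interval (trough to next peak), and the gait-cycle
duration GCD (inter-peak sample count times the sample period).
Distributions are summarized as fixed-width histograms (5 deg default) with
the raw-sample mean and unbiased variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from cifes.io import Trace, log, register_config_section

__all__ = ["GaitCycleFeatures", "DistributionSummary", "SegmentationConfig",
           "ankle_angle", "angular_velocity", "segment_gait",
           "distribution_summary"]


@dataclass(frozen=True)
class GaitCycleFeatures:
    maxaa: float         # deg
    minaa: float         # deg
    max_ang_vel: float   # deg/s
    gcd: float           # s
    side: str = ""
    cycle_index: int = 0

    def __post_init__(self) -> None:
        if self.maxaa < self.minaa:
            raise ValueError("maxaa must be >= minaa")
        if self.gcd <= 0:
            raise ValueError("gcd must be > 0")


@dataclass
class SegmentationConfig:
    """Peak-finding parameters for cycle segmentation."""

    prominence: float = 3.0       # deg
    min_separation: float = 0.52  # s (~0.4 of a typical cycle)


register_config_section("kinematics_gait", SegmentationConfig)


@dataclass
class DistributionSummary:
    bin_edges: np.ndarray   # deg, fixed width, aligned to bin-width multiples
    counts: np.ndarray
    mean: float             # deg, raw-sample mean
    variance: float         # deg^2, unbiased


def ankle_angle(imu_up: Trace, imu_down: Trace) -> Trace:
    """Ankle joint angle from the two IMU attitude traces: up + down + 90."""
    if len(imu_up) != len(imu_down):
        raise ValueError(
            f"IMU trace length mismatch: {len(imu_up)} vs {len(imu_down)}")
    if imu_up.sampling_rate != imu_down.sampling_rate:
        raise ValueError("IMU traces must share a sampling rate")
    return imu_up.with_values(imu_up.values + imu_down.values + 90.0,
                              label="ankle_angle", units="deg")


def angular_velocity(angle: Trace) -> Trace:
    """Angular velocity by central finite difference (one-sided endpoints)."""
    if len(angle) < 2:
        raise ValueError("angular_velocity needs at least 2 samples")
    v = np.gradient(angle.values) * angle.sampling_rate
    return angle.with_values(v, label=angle.label + "_vel", units="deg/s")


def segment_gait(angle: Trace, prominence: float = 3.0,
                 min_separation: float | None = 0.52,
                 side: str = "") -> list[GaitCycleFeatures]:
    """Segment an ankle-angle trace into per-cycle features.

    Peaks and troughs are located with the given prominence (and optional
    minimum separation in seconds); each adjacent-peak pair is one cycle
    with ``maxaa`` the opening peak value, ``minaa`` the deepest trough in
    between, ``gcd`` the inter-peak spacing, and ``max_ang_vel`` the largest
    angular velocity within the dorsiflexion interval (trough to closing
    peak).  Fewer than two peaks yields an empty list.
    """
    if len(angle) == 0:
        raise ValueError("segment_gait requires a non-empty trace")
    distance = None
    if min_separation is not None:
        distance = max(1, int(round(min_separation * angle.sampling_rate)))
    peaks, _ = signal.find_peaks(angle.values, prominence=prominence,
                                 distance=distance)
    if peaks.size < 2:
        log(f"segment_gait: {peaks.size} peak(s) found, no complete cycle")
        return []
    vel = angular_velocity(angle).values
    dt = 1.0 / angle.sampling_rate
    out: list[GaitCycleFeatures] = []
    for k in range(peaks.size - 1):
        i0, i1 = peaks[k], peaks[k + 1]
        seg = angle.values[i0:i1 + 1]
        trough_rel = int(np.argmin(seg))
        trough = i0 + trough_rel
        out.append(GaitCycleFeatures(
            maxaa=float(angle.values[i0]),
            minaa=float(seg[trough_rel]),
            max_ang_vel=float(np.max(vel[trough:i1 + 1])),
            gcd=(i1 - i0) * dt,
            side=side,
            cycle_index=k,
        ))
    return out


def distribution_summary(values, bin_width: float = 5.0) -> DistributionSummary:
    """Histogram at fixed bin width plus raw-sample mean and unbiased
    variance.

    Bin edges are aligned to multiples of ``bin_width``; the mean/variance
    are computed from the raw values, so they are invariant to the binning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("distribution_summary needs at least 2 values")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return DistributionSummary(
        bin_edges=edges,
        counts=counts,
        mean=float(np.mean(values)),
        variance=float(np.var(values, ddof=1)),
    )
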