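"""fNIRS hemodynamics: spline motion-artifact correction, 0.01-0.2 Hz
band-pass filtering, modified Beer-Lambert conversion to HbO/HbR/HbT,
block averaging over task onsets, and the task-window variance metric.

The modified Beer-Lambert law relates the optical-density change at each
wavelength to the chromophore concentration changes through the molar
extinction coefficients, the source-detector distance ``d`` and the
differential pathlength factor (DPF)::

    dOD(lambda) = [e_HbO(lambda) dHbO + e_HbR(lambda) dHbR] * d * DPF(lambda)

With two wavelengths this is a 2x2 linear system per sample; the bundled
default coefficients are standard literature values for 760/850 nm in
1/(mM*cm) and are fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import UnivariateSpline

from cifes.io import EventList, Trace, log, register_config_section

__all__ = ["OpticalDensityPair", "ChannelGeometry", "HemoTrace",
           "motion_correct_spline", "bandpass", "mbll", "block_average",
           "task_variance", "DEFAULT_EXTINCTION_760_850"]

#: molar extinction [1/(mM*cm)], rows = wavelengths (760, 850 nm),
#: columns = (HbO, HbR); standard compiled literature values
DEFAULT_EXTINCTION_760_850 = np.array([[0.586, 1.548],
                                       [1.058, 0.691]])


@dataclass
class OpticalDensityPair:
    od_lambda1: Trace
    od_lambda2: Trace
    wavelengths: tuple[float, float] = (760.0, 850.0)

    def __post_init__(self) -> None:
        if len(self.od_lambda1) != len(self.od_lambda2):
            raise ValueError("optical density traces must have equal length")
        if self.od_lambda1.sampling_rate != self.od_lambda2.sampling_rate:
            raise ValueError("optical density traces must share a sampling rate")
        if self.wavelengths[0] == self.wavelengths[1]:
            raise ValueError("wavelengths must be distinct")


@dataclass
class ChannelGeometry:
    source_detector_distance: float = 3.0  # cm
    dpf_lambda1: float = 6.0
    dpf_lambda2: float = 6.0
    extinction: np.ndarray = field(
        default_factory=lambda: DEFAULT_EXTINCTION_760_850.copy())

    def __post_init__(self) -> None:
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.source_detector_distance <= 0:
            raise ValueError("source-detector distance must be > 0")
        if self.extinction.shape != (2, 2):
            raise ValueError("extinction must be a 2x2 matrix")
        cond = np.linalg.cond(self.extinction)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError("extinction matrix is singular")
        log(f"ChannelGeometry: extinction condition number {cond:.3g}")


register_config_section("fnirs", ChannelGeometry)


@dataclass
class HemoTrace:
    """Per-channel hemoglobin concentration-change series (umol/L)."""

    hbo: Trace
    hbr: Trace
    hbt: Trace

    def __post_init__(self) -> None:
        if not np.allclose(self.hbt.values, self.hbo.values + self.hbr.values,
                           atol=1e-9):
            raise ValueError("HbT must equal HbO + HbR sample-for-sample")


def _moving_sd(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving standard deviation (population), partial at edges."""
    import pandas as pd
    return (pd.Series(x).rolling(n, center=True, min_periods=2)
            .std(ddof=0).bfill().ffill().to_numpy())


def motion_correct_spline(od: Trace, detect_window: float = 1.0,
                          detect_threshold: float = 3.0) -> Trace:
    """Spline-based motion artifact correction.

    Segments whose centered moving standard deviation (window
    ``detect_window`` s) exceeds ``detect_threshold`` times the trace's
    median moving SD are treated as artifacts: a smoothing spline fitted to
    each segment (its trend) is subtracted and the segment is re-leveled to
    a straight line joining its clean neighbors.  Samples outside detected
    segments are unchanged; a clean trace returns unchanged.
    """
    if len(od) == 0:
        raise ValueError("motion_correct_spline requires a non-empty trace")
    x = od.values.copy()
    n_win = max(2, int(round(detect_window * od.sampling_rate)))
    msd = _moving_sd(x, n_win)
    med = float(np.median(msd))
    if med <= 0 or not np.any(msd > detect_threshold * med):
        return od.with_values(x)
    mask = msd > detect_threshold * med
    # contiguous artifact runs; runs closer than the detection window are
    # merged so a boxcar artifact (variance spikes only at its edges) is
    # treated as one segment
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
    runs = list(zip(edges[::2], edges[1::2]))
    merged = [list(runs[0])]
    for i0, i1 in runs[1:]:
        if i0 - merged[-1][1] <= int(round(1.5 * n_win)):
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    for i0, i1 in merged:
        seg = x[i0:i1]
        if seg.size < 4:
            trend = np.full(seg.size, np.mean(seg))
        else:
            t = np.arange(seg.size, dtype=float)
            # smoothing level ~ clean noise power so the spline tracks the
            # artifact, not the noise
            spl = UnivariateSpline(t, seg, k=3, s=seg.size * med * med)
            trend = spl(t)
        left = x[i0 - 1] if i0 > 0 else (x[i1] if i1 < x.size else np.mean(seg))
        right = x[i1] if i1 < x.size else left
        base = np.linspace(left, right, seg.size + 2)[1:-1]
        x[i0:i1] = (seg - trend) + base
    return od.with_values(x)


def bandpass(od: Trace, low: float = 0.01, high: float = 0.2) -> Trace:
    """Zero-phase 3rd-order Butterworth band-pass (default 0.01-0.2 Hz).

    Removes DC drift and the cardiac/respiratory bands while preserving the
    slow hemodynamic response (mid-band gain within a few percent).
    """
    if od.sampling_rate <= 2.0 * high:
        raise ValueError(
            f"sampling rate {od.sampling_rate} Hz violates Nyquist for "
            f"band edge {high} Hz")
    sos = signal.butter(3, [low, high], btype="bandpass",
                        fs=od.sampling_rate, output="sos")
    return od.with_values(signal.sosfiltfilt(sos, od.values))


def mbll(od: OpticalDensityPair, geom: ChannelGeometry | None = None) -> HemoTrace:
    """Invert the modified Beer-Lambert law for one channel.

    Solves the per-sample 2x2 system for (dHbO, dHbR) in mM and reports
    umol/L; HbT = HbO + HbR by definition.
    """
    geom = geom or ChannelGeometry()
    d = geom.source_detector_distance
    rhs = np.vstack([od.od_lambda1.values / (d * geom.dpf_lambda1),
                     od.od_lambda2.values / (d * geom.dpf_lambda2)])
    conc_mm = np.linalg.solve(geom.extinction, rhs)  # (2, n) in mM
    conc = conc_mm * 1000.0  # umol/L
    base = od.od_lambda1
    hbo = base.with_values(conc[0], label="hbo", units="umol/L")
    hbr = base.with_values(conc[1], label="hbr", units="umol/L")
    hbt = base.with_values(conc[0] + conc[1], label="hbt", units="umol/L")
    return HemoTrace(hbo=hbo, hbr=hbr, hbt=hbt)


def mbll_forward(hbo_umol: np.ndarray, hbr_umol: np.ndarray,
                 geom: ChannelGeometry | None = None,
                 sampling_rate: float = 10.0) -> OpticalDensityPair:
    """Forward Beer-Lambert model: concentrations (umol/L) to dOD traces.

    The exact inverse of :func:`mbll`; used to synthesize optical-density
    fixtures from known hemodynamics.
    """
    geom = geom or ChannelGeometry()
    conc_mm = np.vstack([hbo_umol, hbr_umol]) / 1000.0
    od = geom.extinction @ conc_mm
    d = geom.source_detector_distance
    return OpticalDensityPair(
        Trace("od_l1", sampling_rate, od[0] * d * geom.dpf_lambda1, units="OD"),
        Trace("od_l2", sampling_rate, od[1] * d * geom.dpf_lambda2, units="OD"),
    )


def block_average(hemo: Trace, onsets: EventList, window: float) -> Trace:
    """Onset-aligned average response, baseline-subtracted at each onset.

    Every onset plus ``window`` must lie within the trace; the value at each
    onset is subtracted from its block before averaging, so the averaged
    response starts at zero.
    """
    if len(onsets) == 0:
        raise ValueError("block_average requires at least one onset")
    n_win = int(round(window * hemo.sampling_rate))
    blocks = []
    t0 = hemo.start_time
    end = t0 + len(hemo) / hemo.sampling_rate
    for ev in onsets:
        if ev.onset < t0 or ev.onset + window > end:
            raise ValueError(
                f"onset {ev.onset} s (+{window} s window) outside trace span "
                f"[{t0}, {end}] s")
        i0 = int(round((ev.onset - t0) * hemo.sampling_rate))
        block = hemo.values[i0:i0 + n_win]
        blocks.append(block - block[0])
    avg = np.mean(np.vstack(blocks), axis=0)
    return Trace(hemo.label + "_blockavg", hemo.sampling_rate, avg,
                 units=hemo.units)


def task_variance(hemo: Trace, task_window: float = 45.0) -> float:
    """Unbiased variance of the trace over the first ``task_window`` seconds.

    The summary used to quantify how steady the hemodynamic load is during
    a walking task.
    """
    n = int(round(task_window * hemo.sampling_rate))
    if len(hemo) < n:
        raise ValueError(
            f"trace spans {len(hemo) / hemo.sampling_rate:.1f} s, shorter than "
            f"the {task_window} s task window")
    return float(np.var(hemo.values[:n], ddof=1))
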