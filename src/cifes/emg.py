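"""The sEMG conditioning chain: amplification, rectification, filtering,
integration.

Raw surface EMG is a zero-mean, burst-like interference signal; the controller
and the activation switch both operate on its *linear envelope*.  The chain
here mirrors the analog front end of a wearable sEMG sensor: a gain stage, a
full-wave rectifier, a low-pass filter and a sliding integrator (windowed
mean), with an optional ADC saturation clamp (0–3.3 V range).

For a zero-mean sine of amplitude ``A`` well above the cutoff, the steady
envelope level is ``gain * 2A/pi`` (the mean of the rectified sine), which is
the closed-form anchor the unit tests pin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from cifes.io import Trace, register_config_section

__all__ = ["EnvelopeConfig", "envelope", "moving_average"]


@dataclass
class EnvelopeConfig:
    """Parameters of the envelope chain.

    lowpass_cutoff : Hz, cutoff of the 2nd-order causal Butterworth smoother.
    integrate_window : s, length of the normalized sliding integrator.
    moving_avg_window : s, trailing moving-average window used by the switch
        stage (exposed separately through :func:`moving_average`).
    gain : dimensionless amplification folded into one scalar.
    adc_clamp : V, saturation level of the acquisition stage; ``None``
        disables the clamp.
    """

    lowpass_cutoff: float = 10.0
    integrate_window: float = 0.050
    moving_avg_window: float = 0.100
    gain: float = 1.0
    adc_clamp: float | None = 3.3

    def __post_init__(self) -> None:
        for name in ("lowpass_cutoff", "integrate_window", "moving_avg_window", "gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


register_config_section("emg_chain", EnvelopeConfig)


def _trailing_mean(x: np.ndarray, n: int) -> np.ndarray:
    """Causal sliding mean over the trailing ``n`` samples; the first
    samples use the available partial window."""
    if n <= 1:
        return x.copy()
    c = np.cumsum(x)
    out = np.empty_like(x)
    out[:n] = c[:n] / np.arange(1, min(n, x.size) + 1)
    if x.size > n:
        out[n:] = (c[n:] - c[:-n]) / n
    return out


def moving_average(x: Trace, window: float) -> Trace:
    """Causal trailing moving average of a trace.

    ``window`` is in seconds and must be at least one sample period; a
    one-sample window is the identity.
    """
    if window <= 0:
        raise ValueError("moving-average window must be positive")
    n = int(round(window * x.sampling_rate))
    if n < 1:
        raise ValueError(
            f"window {window} s is shorter than one sample period "
            f"({1.0 / x.sampling_rate} s)")
    return x.with_values(_trailing_mean(x.values, n))


def envelope(raw: Trace, cfg: EnvelopeConfig | None = None) -> Trace:
    """Linear envelope of a raw sEMG trace.

    Stage order: gain -> absolute value -> 2nd-order causal low-pass ->
    sliding integration normalized by its window (a trailing windowed mean),
    then the optional ADC clamp.  Output is non-negative, same length and
    sampling rate as the input, and turns one multi-peaked burst into one
    smooth peak.
    """
    cfg = cfg or EnvelopeConfig()
    if raw.sampling_rate < 2.0 * cfg.lowpass_cutoff:
        raise ValueError(
            f"sampling rate {raw.sampling_rate} Hz violates Nyquist for "
            f"low-pass cutoff {cfg.lowpass_cutoff} Hz")
    x = np.abs(cfg.gain * raw.values)
    if x.size:
        sos = signal.butter(2, cfg.lowpass_cutoff, fs=raw.sampling_rate, output="sos")
        x = signal.sosfilt(sos, x)
        n = max(1, int(round(cfg.integrate_window * raw.sampling_rate)))
        x = _trailing_mean(x, n)
        # causal filtering of a non-negative signal can undershoot slightly
        np.clip(x, 0.0, cfg.adc_clamp, out=x)
    return raw.with_values(x, label=raw.label + "_env")
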