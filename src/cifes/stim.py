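"""Stimulus synthesis: intensity calibration, biphasic pulse trains,
output cap, multi-channel alternation.

The stimulator encodes intensity as a pulse count (the number of
high-frequency carrier pulses charging the boost stage): counts 20..140 map
linearly onto peak voltages 138..255 V, and delivery is capped at 240 V for
tissue safety.  Each stimulus pulse is biphasic with a 1:2 anodic:cathodic
width ratio at the 33 Hz stimulation rate; by default the cathodic amplitude
is halved so the two phases carry equal and opposite charge.  The
16.67 kHz / 83.3 %-duty intensity carrier can optionally be rendered inside
each phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from cifes.io import Trace, register_config_section

__all__ = ["StimConfig", "StimTrain", "count_to_voltage", "render_pulse_train",
           "split_channels"]


@dataclass
class StimConfig:
    pulse_freq: float = 33.0           # Hz
    anodic_width: float = 200e-6       # s
    width_ratio: float = 2.0           # cathodic width = ratio * anodic width
    carrier_freq: float = 16.67e3      # Hz
    carrier_duty: float = 0.833
    count_min: float = 20.0
    count_max: float = 140.0
    v_at_count_min: float = 138.0      # V
    v_at_count_max: float = 255.0      # V
    v_cap: float = 240.0               # V, delivery cap
    n_channels: int = 1
    render_carrier: bool = False
    #: if True, render cathodic phase at -V (charge-imbalanced variant)
    equal_amplitude: bool = False

    def __post_init__(self) -> None:
        if self.anodic_width * (1.0 + self.width_ratio) >= 1.0 / self.pulse_freq:
            raise ValueError("biphasic pulse does not fit in the pulse period")
        if not (0.0 < self.carrier_duty < 1.0):
            raise ValueError("carrier_duty must be in (0, 1)")
        if self.v_cap > self.v_at_count_max:
            raise ValueError("v_cap must not exceed v_at_count_max")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")


register_config_section("stim_waveform", StimConfig)


@dataclass
class StimTrain:
    """Rendered stimulation output: one voltage trace per channel."""

    channels: list[Trace]
    delivered_peak: float                       # V
    pulse_times: list[np.ndarray]               # per-channel pulse onsets, s
    cfg: StimConfig = field(default_factory=StimConfig)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def pulse_counts(self) -> list[int]:
        return [pt.size for pt in self.pulse_times]


def count_to_voltage(count, cfg: StimConfig | None = None):
    """Raw calibration map from intensity counts to pulse peak voltage.

    Monotone piecewise-linear, anchored at (count_min, v_at_count_min) and
    (count_max, v_at_count_max); extrapolation clamps to the anchor values.
    This is the *raw* map, before the delivery cap.
    """
    cfg = cfg or StimConfig()
    if np.any(np.asarray(count) < 0):
        raise ValueError("intensity count must be >= 0")
    out = np.interp(count, [cfg.count_min, cfg.count_max],
                    [cfg.v_at_count_min, cfg.v_at_count_max])
    return float(out) if np.isscalar(count) else out


def render_pulse_train(cfg: StimConfig, intensity: Trace, duration: float,
                       sampling_rate: float) -> StimTrain:
    """Render the biphasic pulse train driven by an intensity-count trace.

    Pulses fire at ``pulse_freq``; the intensity is sampled-and-held at each
    pulse onset, mapped through :func:`count_to_voltage` and capped at
    ``v_cap``.  Each pulse is an anodic phase of ``anodic_width`` at +V
    followed by a cathodic phase of ``width_ratio * anodic_width`` at
    ``-V / width_ratio`` (charge-balanced; ``equal_amplitude`` renders -V
    instead).  With ``render_carrier`` the phases are chopped by the
    high-frequency carrier.
    """
    if cfg.render_carrier and sampling_rate < 10.0 * cfg.carrier_freq:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz too low to render the "
            f"{cfg.carrier_freq} Hz carrier (need >= 10x)")
    if sampling_rate * cfg.anodic_width < 2.0:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz cannot resolve the "
            f"{cfg.anodic_width * 1e6:.0f} us anodic phase")
    if np.any(intensity.values < 0):
        raise ValueError("intensity counts must be non-negative")

    n = int(round(duration * sampling_rate))
    out = np.zeros(n)
    n_anodic = max(1, int(round(cfg.anodic_width * sampling_rate)))
    n_cathodic = max(1, int(round(cfg.width_ratio * cfg.anodic_width * sampling_rate)))
    # cathodic amplitude chosen for exact charge balance on the sample grid
    if cfg.equal_amplitude:
        cath_scale = 1.0
    else:
        cath_scale = n_anodic / n_cathodic

    period = 1.0 / cfg.pulse_freq
    pulse_onsets = np.arange(0.0, duration - 1e-12, period)
    times = []
    peak = 0.0
    for t0 in pulse_onsets:
        # sample-and-hold the intensity at the pulse onset
        idx = int(np.clip(round((t0 - intensity.start_time) * intensity.sampling_rate),
                          0, max(len(intensity) - 1, 0)))
        if len(intensity) == 0:
            break
        v = min(count_to_voltage(float(intensity.values[idx]), cfg), cfg.v_cap)
        i0 = int(round(t0 * sampling_rate))
        if v <= 0.0 or intensity.values[idx] <= 0.0:
            continue
        a_end = min(i0 + n_anodic, n)
        c_end = min(i0 + n_anodic + n_cathodic, n)
        out[i0:a_end] = v
        out[a_end:c_end] = -v * cath_scale
        peak = max(peak, v)
        times.append(t0)
    if cfg.render_carrier:
        t = np.arange(n) / sampling_rate
        phase = (t * cfg.carrier_freq) % 1.0
        out = out * (phase < cfg.carrier_duty)
    trace = Trace("stim_ch1", sampling_rate, out, units="V")
    return StimTrain(channels=[trace], delivered_peak=peak,
                     pulse_times=[np.array(times)], cfg=cfg)


def split_channels(train: StimTrain, n_channels: int) -> StimTrain:
    """Distribute pulses round-robin over ``n_channels`` stimulation sites.

    The union of per-channel pulse times equals the original pulse times and
    the sets are disjoint, so each site sees ``pulse_freq / n`` pulses per
    second — the multi-channel fatigue-mitigation scheme.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if train.n_channels != 1:
        raise ValueError("split_channels expects a single-channel train")
    if n_channels == 1:
        return train
    src = train.channels[0]
    all_times = train.pulse_times[0]
    sr = src.sampling_rate
    cfg = train.cfg
    n_pulse = max(1, int(round((1.0 + cfg.width_ratio) * cfg.anodic_width * sr)))
    channels, times = [], []
    for c in range(n_channels):
        mine = all_times[c::n_channels]
        vals = np.zeros_like(src.values)
        for t0 in mine:
            i0 = int(round(t0 * sr))
            i1 = min(i0 + n_pulse, vals.size)
            vals[i0:i1] = src.values[i0:i1]
        channels.append(src.with_values(vals, label=f"stim_ch{c + 1}"))
        times.append(mine)
    return StimTrain(channels=channels, delivered_peak=train.delivered_peak,
                     pulse_times=times, cfg=replace(cfg, n_channels=n_channels))
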