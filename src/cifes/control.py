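"""The closed-loop, intrinsically-controlled FES controller.

Per gait cycle the controller (i) watches the healthy-side tibialis-anterior
envelope and, while it exceeds T1 = 0.15 V, records it as the intensity
*template* for the upcoming stimulation burst; (ii) triggers stimulation on
the affected-side rectus-femoris envelope crossing T2; (iii) drives the
stimulator with the template scaled by an adaptive gain; and (iv) after each
cycle, nudges the gain with the IMU-measured MaxAA feedback so the affected
ankle converges toward the contralateral reference.

The gain law is a clamped multiplicative proportional rule on the MaxAA
error with a small deadband: MaxAA above target (insufficient assistance)
raises the gain; within the deadband the gain is held.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from cifes import emg, patient, stim
from cifes.io import Trace, log, register_config_section
from cifes.patient import (FatigueState, SubjectProfile, plant_step_response,
                           update_fatigue)
from cifes.switching import SwitchConfig, threshold_switch

__all__ = ["ControllerConfig", "ControllerState", "SimulationLog",
           "capture_template", "modulate_intensity", "update_gain",
           "run_closed_loop"]


@dataclass
class ControllerConfig:
    t1: float = 0.15                 # V, healthy-side record threshold
    t2: float = 0.15                 # V, affected-side trigger threshold
    template_len: int = 100          # samples of the stored waveform
    gain_init: float = 0.5
    gain_eta: float = 0.02           # per-degree multiplicative learning rate
    gain_min: float = 0.0
    gain_max: float = 2.0
    maxaa_target: float = patient.HEALTHY_MAXAA_MEAN  # deg
    maxaa_deadband: float = 2.0      # deg, gain held inside target +- deadband
    maxaa_window: int = 5            # cycles averaged for the feedback error
    stim_window: float = 0.8         # s, stimulation burst = switch countdown
    wifi_delay: float = 0.0          # s, sensor-to-stimulator transport delay
    n_channels: int = 1

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("thresholds must be > 0")
        if self.gain_min > self.gain_max:
            raise ValueError("gain bounds must be ordered")
        if self.maxaa_window < 1:
            raise ValueError("maxaa_window must be >= 1")
        if self.template_len < 2:
            raise ValueError("template_len must be >= 2")


register_config_section("closed_loop", ControllerConfig)


@dataclass
class ControllerState:
    phase: str = "IDLE"  # {IDLE, RECORDING, ARMED, STIMULATING}
    template: np.ndarray = field(default_factory=lambda: np.zeros(0))
    gain: float = 0.5
    recent_maxaa: list[float] = field(default_factory=list)


@dataclass
class SimulationLog:
    """Per-step record of a closed-loop run."""

    maxaa: np.ndarray
    minaa: np.ndarray
    gcd: np.ndarray
    delivered_peak: np.ndarray
    gain: np.ndarray
    fatigue_scale: np.ndarray
    triggered: np.ndarray
    mode: str = "closed"

    def __len__(self) -> int:
        return self.maxaa.size

    def write_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "step": np.arange(len(self)),
            "maxaa": self.maxaa, "minaa": self.minaa, "gcd": self.gcd,
            "delivered_peak": self.delivered_peak, "gain": self.gain,
            "fatigue_scale": self.fatigue_scale,
            "triggered": self.triggered.astype(int),
        }).to_csv(path, index=False, float_format="%.10g")


def capture_template(ta_envelope: Trace, cfg: ControllerConfig | None = None
                     ) -> np.ndarray:
    """Extract and store the healthy-side intensity template.

    The first maximal contiguous supra-T1 segment of the envelope is
    resampled to ``template_len`` points by linear interpolation and
    peak-normalized to 1.  Returns an empty array when no sample exceeds T1
    (the storage released after each use is modeled by the caller simply
    dropping the previous template).
    """
    cfg = cfg or ControllerConfig()
    v = ta_envelope.values
    above = v > cfg.t1
    if not np.any(above):
        return np.zeros(0)
    start = int(np.argmax(above))
    rest = np.nonzero(~above[start:])[0]
    end = start + (int(rest[0]) if rest.size else above.size - start)
    seg = v[start:end]
    if seg.size == 1:
        seg = np.repeat(seg, 2)
    grid = np.linspace(0.0, seg.size - 1.0, cfg.template_len)
    tpl = np.interp(grid, np.arange(seg.size), seg)
    return tpl / tpl.max()


def modulate_intensity(template: np.ndarray, gain: float,
                       cfg: ControllerConfig | None = None,
                       stim_cfg: stim.StimConfig | None = None) -> Trace:
    """Intensity-count drive for one stimulation window.

    ``counts(t) = clamp(count_min + gain * template(t) * (count_max -
    count_min), 0, count_max)`` over ``stim_window`` seconds.  An empty
    template falls back to a constant ``count_min`` drive (logged).
    """
    cfg = cfg or ControllerConfig()
    scfg = stim_cfg or stim.StimConfig()
    if template.size == 0:
        log("modulate_intensity: empty template, constant count_min fallback")
        template = np.zeros(cfg.template_len)
    counts = np.clip(scfg.count_min + gain * template
                     * (scfg.count_max - scfg.count_min),
                     0.0, scfg.count_max)
    rate = cfg.template_len / cfg.stim_window
    return Trace("intensity", rate, counts, units="counts")


def update_gain(gain: float, recent_maxaa, cfg: ControllerConfig | None = None
                ) -> float:
    """Clamped multiplicative proportional update from MaxAA feedback.

    ``error = mean(recent_maxaa) - maxaa_target``; outside the deadband,
    ``gain' = clamp(gain * (1 + eta * error))``.  MaxAA above target means
    insufficient dorsiflexion assistance, so positive error raises the gain.
    """
    cfg = cfg or ControllerConfig()
    recent = np.asarray(recent_maxaa, dtype=float)
    if recent.size == 0:
        raise ValueError("update_gain needs at least one observed cycle")
    error = float(np.mean(recent)) - cfg.maxaa_target
    if abs(error) <= cfg.maxaa_deadband:
        return gain
    return float(np.clip(gain * (1.0 + cfg.gain_eta * error),
                         cfg.gain_min, cfg.gain_max))


def _cycle_semg(rng: np.random.Generator, duration: float, fs: float,
                centers, amps, floor: float) -> Trace:
    """One cycle of burst sEMG (shared carrier machinery with the generator)."""
    n = int(round(duration * fs))
    env = patient._burst_amplitude_profile(
        n, fs, np.asarray(centers), np.full(len(centers), 0.25),
        np.asarray(amps), floor)
    return Trace("semg", fs, env * patient._bandlimited_noise(rng, n, fs), units="V")


def run_closed_loop(profile: SubjectProfile, cfg: ControllerConfig | None = None,
                    n_steps: int = 300, seed: int = 0, mode: str = "closed",
                    sampling_rate: float = 1000.0,
                    env_cfg: emg.EnvelopeConfig | None = None,
                    stim_cfg: stim.StimConfig | None = None) -> SimulationLog:
    """Run the full loop against the virtual patient for ``n_steps`` cycles.

    Modes: ``closed`` (template-modulated, gain-adapted), ``constant``
    (fixed maximal-intensity burst per trigger, the constant-FES control
    condition), ``none`` (no stimulation).  Deterministic given ``seed``.
    """
    cfg = cfg or ControllerConfig()
    env_cfg = env_cfg or emg.EnvelopeConfig()
    scfg = stim_cfg or stim.StimConfig()
    if mode not in ("closed", "constant", "none"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    fatigue = FatigueState(loads=np.zeros(cfg.n_channels))
    state = ControllerState(gain=cfg.gain_init)
    sw_cfg = SwitchConfig(threshold=cfg.t2, direction="above",
                          countdown=cfg.stim_window, refractory=0.3)

    out = {k: np.zeros(n_steps) for k in
           ("maxaa", "minaa", "gcd", "delivered_peak", "gain", "fatigue_scale")}
    trig = np.zeros(n_steps, dtype=bool)
    site = 0
    for step in range(n_steps):
        # healthy-side cycle: TA burst mid-cycle -> envelope -> template
        g_h = max(0.4, rng.normal(profile.healthy_gcd_mean,
                                  math.sqrt(profile.healthy_gcd_var)))
        state.phase = "RECORDING"
        ta = _cycle_semg(rng, g_h, sampling_rate, [0.5 * g_h],
                         [profile.ta_burst_amp], profile.semg_noise_floor)
        ta_env = emg.envelope(ta, env_cfg)
        state.template = capture_template(ta_env, cfg)

        # affected-side trigger: RF burst at swing onset
        state.phase = "ARMED"
        window = max(cfg.stim_window + 0.4, profile.gcd_mean)
        rf = _cycle_semg(rng, window, sampling_rate, [0.15],
                         [profile.rf_burst_amp], profile.semg_noise_floor)
        rf_env = emg.envelope(rf, env_cfg)
        _, activations = threshold_switch(rf_env, sw_cfg)
        triggered = len(activations) > 0 and mode != "none"

        voltage = 0.0
        exposures = np.zeros(cfg.n_channels)
        if triggered:
            state.phase = "STIMULATING"
            if mode == "constant":
                peak_count = scfg.count_max
            else:
                intensity = modulate_intensity(state.template, state.gain, cfg, scfg)
                peak_count = float(np.max(intensity.values))
            voltage = min(stim.count_to_voltage(peak_count, scfg), scfg.v_cap)
            # pulses alternate round-robin over sites within the burst
            exposures[:] = cfg.stim_window / cfg.n_channels
            site = (site + 1) % cfg.n_channels
        state.template = np.zeros(0)  # storage released after one use

        maxaa, minaa, gcd = plant_step_response(profile, fatigue, voltage, rng)
        fatigue = update_fatigue(fatigue, exposures, duration=gcd)

        state.recent_maxaa.append(maxaa)
        recent = state.recent_maxaa[-cfg.maxaa_window:]
        if mode == "closed":
            state.gain = update_gain(state.gain, recent, cfg)
        state.phase = "IDLE"

        out["maxaa"][step] = maxaa
        out["minaa"][step] = minaa
        out["gcd"][step] = gcd
        out["delivered_peak"][step] = voltage
        out["gain"][step] = state.gain
        out["fatigue_scale"][step] = fatigue.response_scale
        trig[step] = triggered

    return SimulationLog(maxaa=out["maxaa"], minaa=out["minaa"], gcd=out["gcd"],
                         delivered_peak=out["delivered_peak"], gain=out["gain"],
                         fatigue_scale=out["fatigue_scale"], triggered=trig,
                         mode=mode)
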