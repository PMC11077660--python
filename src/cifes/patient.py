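"""Virtual foot-drop patient: synthetic gait, gait-locked sEMG, and a
stimulation plant with saturating dose-response and use-dependent fatigue.

No public recordings accompany the system this toolkit models, so this
module *is* the data source: it draws per-cycle gait statistics (maximum and
minimum ankle angle, cycle duration) from subject-specific normal laws,
renders them as smooth raised-cosine ankle-angle curves with an exact
two-IMU decomposition, overlays band-limited sEMG bursts locked to gait
phase, and answers stimulation with a Hill-type saturating dorsiflexion
effect scaled by a first-order fatigue state.

Default profiles
----------------
``foot_drop``: affected-side MaxAA ~ N(105.53, 28.84) deg, the unassisted
patient law; ``healthy``: MaxAA ~ N(100.72, 10) deg.  The dose-response is
calibrated so that at the 200 V operating point a fresh plant lands on the
assisted law N(102.81, 17.71) — the shift a well-tuned closed loop should
reproduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from cifes.io import Event, EventList, Trace, register_config_section

__all__ = ["SubjectProfile", "FatigueState", "GaitRecording", "make_profile",
           "generate_gait", "generate_semg", "plant_step_response",
           "update_fatigue", "HEALTHY_MAXAA_MEAN", "FD_MAXAA_MEAN",
           "FD_MAXAA_VAR", "ASSISTED_MAXAA_MEAN", "ASSISTED_MAXAA_VAR"]

# Published gait statistics (degrees, degrees^2) the defaults are built on.
FD_MAXAA_MEAN = 105.53
FD_MAXAA_VAR = 28.84
ASSISTED_MAXAA_MEAN = 102.81
ASSISTED_MAXAA_VAR = 17.71
HEALTHY_MAXAA_MEAN = 100.72

#: operating voltage at which the default profile is calibrated to land on
#: the assisted law (mid-range of the deliverable 138-240 V span)
CALIBRATION_VOLTAGE = 200.0

# fraction of the FD-to-healthy MaxAA gap closed at the calibration voltage
_S_OP = (FD_MAXAA_MEAN - ASSISTED_MAXAA_MEAN) / (FD_MAXAA_MEAN - HEALTHY_MAXAA_MEAN)


@dataclass
class SubjectProfile:
    """Generative parameters of one virtual subject.

    The ``maxaa_*``/``minaa_*``/``gcd_*`` fields describe the affected side
    (for a healthy subject, both sides); the ``healthy_*`` fields are the
    contralateral reference the plant normalizes toward.
    """

    kind: str = "foot_drop"                 # {"healthy", "foot_drop"}
    maxaa_mean: float = FD_MAXAA_MEAN       # deg
    maxaa_var: float = FD_MAXAA_VAR         # deg^2
    minaa_mean: float = 80.0                # deg
    minaa_var: float = 16.0                 # deg^2
    gcd_mean: float = 1.3                   # s
    gcd_var: float = 0.02                   # s^2
    rf_burst_amp: float = 0.9               # V
    ta_burst_amp: float = 0.8               # V, healthy-side TA burst
    ta_burst_amp_affected: float = 0.3      # V, strictly below healthy side
    semg_noise_floor: float = 0.02          # V
    response_gain: float = FD_MAXAA_MEAN - HEALTHY_MAXAA_MEAN  # deg
    response_v50: float = CALIBRATION_VOLTAGE * math.sqrt((1.0 - _S_OP) / _S_OP)
    variance_shrink: float = (1.0 - ASSISTED_MAXAA_VAR / FD_MAXAA_VAR) / _S_OP
    # contralateral (unaffected) reference statistics
    healthy_maxaa_mean: float = HEALTHY_MAXAA_MEAN
    healthy_maxaa_var: float = 10.0
    healthy_minaa_mean: float = 70.0
    healthy_minaa_var: float = 8.0
    healthy_gcd_mean: float = 1.1
    healthy_gcd_var: float = 0.005

    def __post_init__(self) -> None:
        if self.kind not in ("healthy", "foot_drop"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        for name in ("maxaa_var", "minaa_var", "gcd_var", "healthy_maxaa_var",
                     "healthy_minaa_var", "healthy_gcd_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gcd_mean <= 0 or self.healthy_gcd_mean <= 0:
            raise ValueError("gcd_mean must be > 0")
        if not (0.0 <= self.variance_shrink <= 1.0):
            raise ValueError("variance_shrink must be in [0, 1]")
        if self.kind == "foot_drop" and not (
                self.ta_burst_amp_affected < self.ta_burst_amp):
            raise ValueError(
                "foot-drop profile requires affected-side TA burst amplitude "
                "below the healthy side")
        if not (0.0 < self.response_v50 <= 255.0):
            raise ValueError("response_v50 must lie within the deliverable range")


register_config_section("virtual_patient", SubjectProfile)


_HEALTHY_OVERRIDES = dict(
    kind="healthy",
    maxaa_mean=HEALTHY_MAXAA_MEAN, maxaa_var=10.0,
    minaa_mean=70.0, minaa_var=8.0,
    gcd_mean=1.1, gcd_var=0.005,
    rf_burst_amp=0.8,
    ta_burst_amp_affected=0.75,  # no attenuation: both sides near-equal
)


def make_profile(kind: str, **overrides) -> SubjectProfile:
    """Documented default profile for *kind*, overridden field-wise.

    ``foot_drop`` carries the unassisted patient law
    MaxAA ~ N(105.53, 28.84); ``healthy`` carries N(100.72, 10).
    Overrides that violate a profile invariant raise ``ValueError``.
    """
    if kind == "healthy":
        params = dict(_HEALTHY_OVERRIDES)
    elif kind == "foot_drop":
        params = {}
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    params.update(overrides)
    return SubjectProfile(**params)


@dataclass
class FatigueState:
    """Accumulated per-site stimulation load with first-order recovery.

    ``response_scale`` decays exponentially with the *maximum* per-site
    load, so splitting the same total exposure across sites always keeps
    the muscle fresher — the rationale for multi-channel alternation.
    """

    loads: np.ndarray = field(default_factory=lambda: np.zeros(1))
    tau_recovery: float = 600.0  # s
    #: calibrated so 900 s of continuous single-site exposure at unit rate
    #: drops the response by 25%
    decay_coeff: float = -math.log(0.75) / (600.0 * (1.0 - math.exp(-1.5)))

    def __post_init__(self) -> None:
        self.loads = np.atleast_1d(np.asarray(self.loads, dtype=float))
        if np.any(self.loads < 0):
            raise ValueError("fatigue loads must be >= 0")

    @property
    def response_scale(self) -> float:
        return float(math.exp(-self.decay_coeff * float(np.max(self.loads, initial=0.0))))


def update_fatigue(state: FatigueState, per_channel_exposure, duration: float = 0.0
                   ) -> FatigueState:
    """Advance the fatigue state by one interval.

    ``per_channel_exposure`` is the dimensionless exposure delivered to each
    site over the interval (stimulation-on seconds work well as the unit);
    ``duration`` is the wall-clock length of the interval, during which the
    load also recovers with time constant ``tau_recovery``.  With zero
    duration the exposure is added instantaneously.
    """
    exp_arr = np.atleast_1d(np.asarray(per_channel_exposure, dtype=float))
    if np.any(exp_arr < 0):
        raise ValueError("exposures must be >= 0")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    loads = state.loads
    if exp_arr.size != loads.size:
        # grow/shrink site vector as channel count changes
        loads = np.resize(loads, exp_arr.size) if loads.size < exp_arr.size else loads
        if loads.size > exp_arr.size:
            exp_arr = np.pad(exp_arr, (0, loads.size - exp_arr.size))
    if duration > 0:
        decay = math.exp(-duration / state.tau_recovery)
        rate = exp_arr / duration
        # closed form of dL/dt = rate - L/tau over the interval
        new_loads = loads * decay + rate * state.tau_recovery * (1.0 - decay)
    else:
        new_loads = loads + exp_arr
    return replace(state, loads=new_loads)


@dataclass
class GaitRecording:
    """Bilateral kinematics + sEMG bundle with ground-truth step events."""

    ankle_left: Trace
    ankle_right: Trace
    imu_up_left: Trace
    imu_down_left: Trace
    imu_up_right: Trace
    imu_down_right: Trace
    steps: EventList
    # per-cycle ground-truth draws, keyed by side
    cycle_truth: dict = field(default_factory=dict)
    rf_affected: Trace | None = None
    ta_healthy: Trace | None = None
    ta_affected: Trace | None = None
    #: which side the generator treats as affected
    affected_side: str = "left"

    def traces(self) -> dict[str, Trace]:
        out = {
            "ankle_left": self.ankle_left, "ankle_right": self.ankle_right,
            "imu_up_left": self.imu_up_left, "imu_down_left": self.imu_down_left,
            "imu_up_right": self.imu_up_right, "imu_down_right": self.imu_down_right,
        }
        for name in ("rf_affected", "ta_healthy", "ta_affected"):
            tr = getattr(self, name)
            if tr is not None:
                out[name] = tr
        return out


def _side_curve(peaks: np.ndarray, troughs: np.ndarray, durations: np.ndarray,
                rest_level: float, lead: float, fs: float
                ) -> tuple[np.ndarray, np.ndarray]:
    """Raised-cosine ankle-angle curve through per-cycle (peak, trough) draws.

    Returns (samples, peak_times).  Cycle i runs peak i -> trough i -> peak
    i+1; a half-cycle lead-in/out from/to ``rest_level`` keeps every peak
    interior so peak finding sees all of them.
    """
    n = durations.size
    peak_times = lead + np.concatenate([[0.0], np.cumsum(durations)])
    total = peak_times[-1] + lead
    t = np.arange(int(round(total * fs))) / fs
    y = np.full(t.size, rest_level)
    # lead-in: rest_level up to the first peak
    seg = (t < peak_times[0])
    if lead > 0:
        y[seg] = rest_level + (peaks[0] - rest_level) * 0.5 * (
            1.0 - np.cos(np.pi * np.clip(t[seg] / lead, 0.0, 1.0)))
    for i in range(n):
        t0, t1 = peak_times[i], peak_times[i + 1]
        tm = 0.5 * (t0 + t1)
        first = (t >= t0) & (t < tm)
        second = (t >= tm) & (t < t1)
        # peak -> trough (half raised cosine), trough -> next peak
        y[first] = troughs[i] + (peaks[i] - troughs[i]) * 0.5 * (
            1.0 + np.cos(np.pi * (t[first] - t0) / (tm - t0)))
        y[second] = troughs[i] + (peaks[i + 1] - troughs[i]) * 0.5 * (
            1.0 - np.cos(np.pi * (t[second] - tm) / (t1 - tm)))
    tail = (t >= peak_times[-1])
    if lead > 0:
        y[tail] = rest_level + (peaks[-1] - rest_level) * 0.5 * (
            1.0 + np.cos(np.pi * np.clip((t[tail] - peak_times[-1]) / lead, 0.0, 1.0)))
    return y, peak_times[:-1]


def _draw_cycles(rng: np.random.Generator, n: int, mean_max, var_max,
                 mean_min, var_min, mean_gcd, var_gcd):
    peaks = rng.normal(mean_max, math.sqrt(var_max), n + 1)
    troughs = rng.normal(mean_min, math.sqrt(var_min), n)
    # physiological contrast floor: a cycle whose trough nearly reaches its
    # peaks has no dorsiflexion excursion; keep every trough at least 6 deg
    # below its flanking peaks (affects < 0.2% of draws at the defaults)
    if n:
        troughs = np.minimum(troughs, np.minimum(peaks[:-1], peaks[1:]) - 6.0)
    durations = np.clip(rng.normal(mean_gcd, math.sqrt(var_gcd), n), 0.4, None)
    return peaks, troughs, durations


def generate_gait(profile: SubjectProfile, n_steps: int, sampling_rate: float = 1000.0,
                  seed: int | np.random.Generator = 0) -> GaitRecording:
    """Generate a bilateral ankle-angle recording with ``n_steps`` cycles per
    side.

    Per-cycle maxima, minima and durations are independent normal draws from
    the profile's laws (affected stats on the affected side, contralateral
    reference stats on the other).  The two IMU component traces split the
    angle evenly so the ``IMU_up + IMU_down + 90`` reconstruction is exact.
    Ground-truth swing onsets (the per-cycle MaxAA instants, toe-off) are
    annotated per side.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if sampling_rate < 50.0:
        raise ValueError("sampling_rate must be >= 50 Hz")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def empty(label, units="deg"):
        return Trace(label, sampling_rate, np.zeros(0), units=units)

    if n_steps == 0:
        z = {s: empty(s) for s in ("ankle_left", "ankle_right")}
        rec = GaitRecording(
            ankle_left=z["ankle_left"], ankle_right=z["ankle_right"],
            imu_up_left=empty("imu_up_left"), imu_down_left=empty("imu_down_left"),
            imu_up_right=empty("imu_up_right"), imu_down_right=empty("imu_down_right"),
            steps=EventList([]))
        return rec

    lead = 0.5 * profile.gcd_mean
    affected = _draw_cycles(rng, n_steps, profile.maxaa_mean, profile.maxaa_var,
                            profile.minaa_mean, profile.minaa_var,
                            profile.gcd_mean, profile.gcd_var)
    contra = _draw_cycles(rng, n_steps, profile.healthy_maxaa_mean,
                          profile.healthy_maxaa_var, profile.healthy_minaa_mean,
                          profile.healthy_minaa_var, profile.healthy_gcd_mean,
                          profile.healthy_gcd_var)

    rest_aff = profile.minaa_mean
    rest_con = profile.healthy_minaa_mean
    y_aff, pk_aff = _side_curve(*affected, rest_aff, lead, sampling_rate)
    y_con, pk_con = _side_curve(*contra, rest_con, lead + 0.5 * profile.healthy_gcd_mean,
                                sampling_rate)
    # equal-length bilateral traces: pad the shorter side at rest level
    n_max = max(y_aff.size, y_con.size)
    y_aff = np.pad(y_aff, (0, n_max - y_aff.size), constant_values=rest_aff)
    y_con = np.pad(y_con, (0, n_max - y_con.size), constant_values=rest_con)

    events = []
    for i, t0 in enumerate(pk_aff):
        events.append(Event(t0, t0 + affected[2][i], "left"))
    for i, t0 in enumerate(pk_con):
        events.append(Event(t0, t0 + contra[2][i], "right"))

    def tr(label, vals, units="deg"):
        return Trace(label, sampling_rate, vals, units=units)

    rec = GaitRecording(
        ankle_left=tr("ankle_left", y_aff),
        ankle_right=tr("ankle_right", y_con),
        imu_up_left=tr("imu_up_left", 0.5 * (y_aff - 90.0)),
        imu_down_left=tr("imu_down_left", 0.5 * (y_aff - 90.0)),
        imu_up_right=tr("imu_up_right", 0.5 * (y_con - 90.0)),
        imu_down_right=tr("imu_down_right", 0.5 * (y_con - 90.0)),
        steps=EventList(events),
        cycle_truth={
            "left": {"maxaa": affected[0][:-1], "minaa": affected[1],
                     "gcd": affected[2], "peak_times": pk_aff},
            "right": {"maxaa": contra[0][:-1], "minaa": contra[1],
                      "gcd": contra[2], "peak_times": pk_con},
        },
        affected_side="left",
    )
    return rec


def _burst_amplitude_profile(n: int, fs: float, centers: np.ndarray,
                             widths: np.ndarray, amps: np.ndarray,
                             floor: float) -> np.ndarray:
    """Sum of Hann-lobed burst amplitude envelopes over a noise floor."""
    env = np.full(n, floor)
    for c, w, a in zip(centers, widths, amps):
        i0 = max(0, int(round((c - 0.5 * w) * fs)))
        i1 = min(n, int(round((c + 0.5 * w) * fs)))
        if i1 <= i0:
            continue
        lobe = np.hanning(i1 - i0) * a
        env[i0:i1] = np.maximum(env[i0:i1], lobe + floor)
    return env


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-std noise with 20-450 Hz content (raw sEMG carrier)."""
    x = rng.standard_normal(n)
    high = min(450.0, 0.45 * fs)
    sos = signal.butter(4, [20.0, high], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfilt(sos, x)
    sd = np.std(y)
    return y / sd if sd > 0 else y


def generate_semg(profile: SubjectProfile, gait: GaitRecording,
                  seed: int | np.random.Generator = 0) -> GaitRecording:
    """Attach gait-locked sEMG traces to a recording.

    RF (affected side) fires a main burst at each swing onset plus a weaker
    stance lobe mid-cycle; TA fires one burst per cycle around the
    dorsiflexion trough.  On a foot-drop profile the affected-side TA burst
    is strictly attenuated relative to the healthy side.  Burst carriers are
    20-450 Hz band-limited noise; the inter-burst level sits at the
    profile's noise floor.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = gait.ankle_left.sampling_rate
    n = len(gait.ankle_left)
    if n == 0:
        z = lambda lbl: Trace(lbl, fs, np.zeros(0), units="V")  # noqa: E731
        gait.rf_affected = z("rf_affected")
        gait.ta_healthy = z("ta_healthy")
        gait.ta_affected = z("ta_affected")
        return gait

    aff = gait.cycle_truth["left"]
    con = gait.cycle_truth["right"]
    burst_w = 0.25  # s

    def build(centers, amps):
        centers = np.asarray(centers)
        amps = np.asarray(amps)
        env = _burst_amplitude_profile(n, fs, centers,
                                       np.full(centers.size, burst_w), amps,
                                       profile.semg_noise_floor)
        return env * _bandlimited_noise(rng, n, fs)

    # RF: main lobe at swing onset (toe-off peak), secondary stance lobe
    rf_centers = np.concatenate([aff["peak_times"],
                                 aff["peak_times"] + 0.45 * aff["gcd"]])
    rf_amps = np.concatenate([np.full(len(aff["peak_times"]), profile.rf_burst_amp),
                              np.full(len(aff["peak_times"]), 0.6 * profile.rf_burst_amp)])
    # TA: one burst per cycle around the dorsiflexion trough
    ta_aff_centers = aff["peak_times"] + 0.5 * aff["gcd"]
    ta_con_centers = con["peak_times"] + 0.5 * con["gcd"]

    ta_aff_amp = (profile.ta_burst_amp_affected if profile.kind == "foot_drop"
                  else profile.ta_burst_amp)
    gait.rf_affected = Trace("rf_affected", fs, build(rf_centers, rf_amps), units="V")
    gait.ta_healthy = Trace("ta_healthy", fs,
                            build(ta_con_centers,
                                  np.full(ta_con_centers.size, profile.ta_burst_amp)),
                            units="V")
    gait.ta_affected = Trace("ta_affected", fs,
                             build(ta_aff_centers,
                                   np.full(ta_aff_centers.size, ta_aff_amp)),
                             units="V")
    return gait


def dose_response(profile: SubjectProfile, fatigue: FatigueState,
                  voltage: float) -> float:
    """Assistance a(V) in degrees: Hill-type squared saturation scaled by
    the fatigue state.  a(0) = 0 and a(V) <= response_gain."""
    if voltage < 0:
        raise ValueError("stimulation voltage must be >= 0")
    v2 = voltage * voltage
    return (fatigue.response_scale * profile.response_gain
            * v2 / (v2 + profile.response_v50 ** 2))


def plant_step_response(profile: SubjectProfile, fatigue: FatigueState,
                        delivered_peak_voltage: float,
                        rng: np.random.Generator | int = 0
                        ) -> tuple[float, float, float]:
    """Draw one gait cycle's (MaxAA, MinAA, GCD) under stimulation.

    The assisted MaxAA law interpolates from the unassisted profile law
    toward the contralateral reference by the saturating assistance
    fraction; variance shrinks by ``variance_shrink`` times that fraction.
    The mean never overshoots below the healthy reference.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    a = dose_response(profile, fatigue, delivered_peak_voltage)
    frac = a / profile.response_gain  # in [0, 1]
    mean_max = profile.maxaa_mean - frac * (profile.maxaa_mean
                                            - profile.healthy_maxaa_mean)
    var_max = profile.maxaa_var * (1.0 - profile.variance_shrink * frac)
    mean_min = profile.minaa_mean - frac * (profile.minaa_mean
                                            - profile.healthy_minaa_mean)
    mean_gcd = profile.gcd_mean - frac * (profile.gcd_mean
                                          - profile.healthy_gcd_mean)
    maxaa = rng.normal(mean_max, math.sqrt(max(var_max, 0.0)))
    minaa = rng.normal(mean_min, math.sqrt(profile.minaa_var))
    gcd = max(0.4, rng.normal(mean_gcd, math.sqrt(profile.gcd_var)))
    return float(maxaa), float(minaa), float(gcd)


def plant_mean_maxaa(profile: SubjectProfile, fatigue: FatigueState,
                     voltage: float) -> float:
    """Closed-form mean of the assisted MaxAA law (no draw)."""
    frac = dose_response(profile, fatigue, voltage) / profile.response_gain
    return profile.maxaa_mean - frac * (profile.maxaa_mean - profile.healthy_maxaa_mean)
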