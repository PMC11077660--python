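"""Threshold-based activation switches and the switch-accuracy metric.

One state machine serves all three switch front-ends studied for foot-drop
stimulators — the sEMG envelope switch (threshold 0.15–0.2 V, direction
above), the shank-tilt switch (threshold −25°, direction below) and the
foot-pressure switch (0.25 V, above); only the configs differ.

A trigger turns stimulation on; it persists for at least the *countdown*
hold after the onset and for as long as the signal remains beyond the
threshold, then turns off; a new trigger is ignored within the *refractory*
interval of the previous onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cifes.io import Event, EventList, Trace, register_config_section

__all__ = ["SwitchConfig", "threshold_switch", "switch_accuracy"]


@dataclass
class SwitchConfig:
    threshold: float = 0.15
    direction: str = "above"  # {"above", "below"}
    countdown: float = 0.8
    refractory: float = 0.3
    #: optional release threshold (hysteresis); None means equal to threshold
    release_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ValueError("direction must be 'above' or 'below'")
        if self.countdown < 0 or self.refractory < 0:
            raise ValueError("countdown and refractory must be >= 0")


register_config_section("gait_switch", SwitchConfig)


def threshold_switch(x: Trace, cfg: SwitchConfig | None = None
                     ) -> tuple[Trace, EventList]:
    """Run the threshold switch over a trace.

    A crossing is a sample strictly beyond the threshold preceded by at
    least one sample on the other side (deterministic on discrete samples).
    Returns the binary on/off state trace and one activation event per
    on-interval.
    """
    cfg = cfg or SwitchConfig()
    if len(x) == 0:
        raise ValueError("threshold_switch requires a non-empty trace")
    v = x.values
    thr = cfg.threshold
    rel = cfg.release_threshold if cfg.release_threshold is not None else thr
    if cfg.direction == "above":
        beyond = v > thr
        held = v > rel
    else:
        beyond = v < thr
        held = v < rel
    dt = 1.0 / x.sampling_rate
    state = np.zeros(v.size, dtype=float)
    events: list[Event] = []
    on = False
    onset_i = -1
    last_onset_t = -np.inf
    seen_other_side = False
    for i in range(v.size):
        t = x.start_time + i * dt
        if on:
            state[i] = 1.0
            if (t - (x.start_time + onset_i * dt)) >= cfg.countdown and not held[i]:
                on = False
                state[i] = 0.0
                events.append(Event(x.start_time + onset_i * dt, t, "activation"))
                seen_other_side = not beyond[i]
        else:
            if beyond[i] and seen_other_side and (t - last_onset_t) >= cfg.refractory:
                on = True
                onset_i = i
                last_onset_t = t
                state[i] = 1.0
            elif not beyond[i]:
                seen_other_side = True
    if on:
        end_t = x.start_time + (v.size - 1) * dt
        events.append(Event(x.start_time + onset_i * dt, end_t, "activation"))
    return x.with_values(state, label=x.label + "_switch", units=""), EventList(events)


def switch_accuracy(activations: EventList, truth_steps: EventList,
                    tolerance: float) -> float:
    """Fraction of correctly timed activations.

    Greedy one-to-one matching of activation onsets to true swing onsets
    within ``tolerance`` seconds; accuracy = matched / max(n_true, n_act),
    which penalizes misses and false triggers symmetrically.  An empty pair
    of lists scores 1.0 (nothing to detect, nothing detected).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    a = activations.onsets()
    t = truth_steps.onsets()
    if a.size == 0 and t.size == 0:
        return 1.0
    if a.size == 0 or t.size == 0:
        return 0.0
    matched = 0
    i = j = 0
    # both lists sorted: two-pointer greedy matching
    while i < a.size and j < t.size:
        d = a[i] - t[j]
        if abs(d) <= tolerance:
            matched += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return matched / max(a.size, t.size)
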