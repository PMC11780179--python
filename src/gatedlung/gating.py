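"""Prospective respiratory gating: pillow-trace simulation and the
two-trigger acquisition scheme.

An anesthetized mouse breathes with a fast inhale/exhale followed by a
long end-expiration pause; a pneumatic pillow reports diaphragm
displacement as the gating surrogate.  The first trigger fires near the
end of inhale (acquiring the peak-inspiration image); a second trigger,
delayed by ~350 ms, acquires the end-expiration image during the pause.
The simulated trace carries its exact cycle structure so trigger/phase
assignment can be scored against ground truth.

Defaults: 600 ms breathing period (~100 breaths/min) with an
end-expiratory plateau occupying 0.8 of the cycle — chosen so the
350 ms delayed trigger lands inside the plateau across the physiological
period range (400-1000 ms).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

PEAK_WINDOW_FRACTION = 0.05  # +/- fraction of cycle length counted as "at peak"


@dataclass
class RespiratoryTrace:
    """Sampled displacement trace plus the generator's cycle structure."""

    times_ms: np.ndarray
    displacement: np.ndarray
    period_ms: float
    plateau_fraction: float
    amplitude: float
    cycle_starts: np.ndarray = field(default=None)
    cycle_peaks: np.ndarray = field(default=None)
    plateau_starts: np.ndarray = field(default=None)
    cycle_ends: np.ndarray = field(default=None)

    @property
    def end_ms(self) -> float:
        return float(self.times_ms[-1])


@dataclass(frozen=True)
class TriggerConfig:
    """Trigger-detection parameters.

    ``level``: fraction of the running cycle-amplitude estimate whose
    rising crossing fires the inhale trigger.  ``delay_ms``: delay of the
    second (end-expiration) trigger.  ``refractory_ms``: dead time after a
    trigger.
    """

    level: float = 0.9
    delay_ms: float = 350.0
    refractory_ms: float = 250.0

    def __post_init__(self) -> None:
        if not 0.0 < self.level <= 1.0:
            raise ValueError("trigger level must be in (0, 1]")
        if self.delay_ms < 0:
            raise ValueError("delay must be non-negative")
        if self.refractory_ms < 0:
            raise ValueError("refractory period must be non-negative")


def simulate_trace(
    period_ms: float = 600.0,
    amplitude: float = 1.0,
    plateau_fraction: float = 0.8,
    jitter: float = 0.0,
    noise: float = 0.0,
    duration_ms: float = 6000.0,
    seed: int = 0,
    dt_ms: float = 1.0,
) -> RespiratoryTrace:
    """Simulate a pillow displacement trace.

    Each cycle is a linear rise to the peak, a linear fall, then a
    baseline plateau occupying ``plateau_fraction`` of the cycle; rise and
    fall share the remainder equally.  ``jitter`` is the relative SD of
    cycle-to-cycle period variation; ``noise`` is additive white noise
    relative to the amplitude.  Deterministic given ``seed``.
    """
    if not 0.0 < plateau_fraction < 1.0:
        raise ValueError(f"plateau fraction must be in (0, 1), got {plateau_fraction}")
    if period_ms <= 0:
        raise ValueError("period must be positive")
    if duration_ms < 3 * period_ms:
        raise ValueError("trace duration must cover at least 3 cycles")
    if jitter < 0 or noise < 0:
        raise ValueError("jitter and noise must be non-negative")
    rng = np.random.default_rng(seed)
    starts, peaks, plat_starts, ends = [], [], [], []
    t = 0.0
    while t < duration_ms:
        T = period_ms * max(0.2, 1.0 + jitter * rng.standard_normal())
        rise = (1.0 - plateau_fraction) * T / 2.0
        starts.append(t)
        peaks.append(t + rise)
        plat_starts.append(t + 2.0 * rise)
        ends.append(t + T)
        t += T
    starts = np.array(starts)
    peaks = np.array(peaks)
    plat_starts = np.array(plat_starts)
    ends = np.array(ends)

    times = np.arange(0.0, duration_ms, dt_ms)
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(starts) - 1)
    disp = np.zeros_like(times)
    rise_len = peaks[idx] - starts[idx]
    on_rise = times < peaks[idx]
    disp[on_rise] = amplitude * (times[on_rise] - starts[idx][on_rise]) / rise_len[on_rise]
    on_fall = (times >= peaks[idx]) & (times < plat_starts[idx])
    disp[on_fall] = amplitude * (
        1.0 - (times[on_fall] - peaks[idx][on_fall]) / rise_len[on_fall]
    )
    if noise > 0:
        disp = disp + noise * amplitude * rng.standard_normal(times.shape)
    return RespiratoryTrace(
        times_ms=times,
        displacement=disp,
        period_ms=period_ms,
        plateau_fraction=plateau_fraction,
        amplitude=amplitude,
        cycle_starts=starts,
        cycle_peaks=peaks,
        plateau_starts=plat_starts,
        cycle_ends=ends,
    )


def detect_inhale_triggers(
    trace: RespiratoryTrace, config: TriggerConfig = TriggerConfig()
) -> np.ndarray:
    """Causal end-of-inhale trigger detection.

    After a warm-up (the first observed cycle, whose peak initializes the
    amplitude estimate and fires a trigger just past the peak), a trigger
    fires at the first rising sample crossing ``level`` times the running
    amplitude estimate (mean of the last 3 confirmed cycle peaks), subject
    to the refractory period.  Only past samples are used.  A flat trace
    yields no triggers.
    """
    vals = trace.displacement
    times = trace.times_ms
    peaks_hist: deque = deque(maxlen=3)
    triggers = []
    cur_max = -np.inf
    armed = True
    last_trig = -np.inf
    tiny = 1e-12
    prev = vals[0]
    for i in range(len(times)):
        v = float(vals[i])
        t = float(times[i])
        if v > cur_max:
            cur_max = v
        if not peaks_hist:
            # warm-up: fire at the first confirmed local maximum
            if cur_max > tiny and v <= cur_max * 0.95 and t - last_trig >= config.refractory_ms:
                triggers.append(t)
                last_trig = t
                peaks_hist.append(cur_max)
                cur_max = v
                armed = False
        else:
            amp = float(np.mean(peaks_hist))
            if armed:
                if (
                    v >= config.level * amp
                    and v >= prev
                    and t - last_trig >= config.refractory_ms
                ):
                    triggers.append(t)
                    last_trig = t
                    armed = False
            else:
                if v <= 0.5 * amp:  # cycle over: confirm its peak, rearm
                    peaks_hist.append(cur_max)
                    cur_max = v
                    armed = True
        prev = v
    return np.asarray(triggers)


def delayed_triggers(
    triggers: np.ndarray, delay_ms: float = 350.0, trace_end_ms: float | None = None
) -> np.ndarray:
    """Second-trigger times: each inhale trigger shifted by ``delay_ms``.

    Times beyond the end of the trace are dropped (logged).
    """
    if delay_ms < 0:
        raise ValueError("delay must be non-negative")
    out = np.asarray(triggers, float) + delay_ms
    if trace_end_ms is not None:
        kept = out[out <= trace_end_ms]
        if len(kept) < len(out):
            log.info("dropped %d delayed trigger(s) beyond trace end", len(out) - len(kept))
        out = kept
    return out


def phase_at(trace: RespiratoryTrace, time_ms: float) -> str:
    """Ground-truth phase label from the generator's cycle structure.

    ``peak_inspiration`` within +/-5% of the cycle length around the peak,
    ``end_expiration`` inside the plateau, ``transition`` otherwise.
    """
    if time_ms < trace.cycle_starts[0] or time_ms > trace.cycle_ends[-1]:
        raise ValueError(f"time {time_ms} ms outside the trace")
    i = int(np.clip(
        np.searchsorted(trace.cycle_starts, time_ms, side="right") - 1,
        0, len(trace.cycle_starts) - 1,
    ))
    cycle_len = trace.cycle_ends[i] - trace.cycle_starts[i]
    if abs(time_ms - trace.cycle_peaks[i]) <= PEAK_WINDOW_FRACTION * cycle_len:
        return "peak_inspiration"
    if trace.plateau_starts[i] <= time_ms < trace.cycle_ends[i]:
        return "end_expiration"
    return "transition"


@dataclass(frozen=True)
class GatingScore:
    """Per-phase hit fractions of the two-trigger scheme."""

    first_trigger_fraction: float
    second_trigger_fraction: float
    n_first: int
    n_second: int


def score_gating(
    trace: RespiratoryTrace, config: TriggerConfig = TriggerConfig()
) -> GatingScore:
    """Detect, delay, and score both trigger trains against trace truth."""
    first = detect_inhale_triggers(trace, config)
    second = delayed_triggers(first, config.delay_ms, trace_end_ms=trace.cycle_ends[-1])
    if len(first) == 0:
        return GatingScore(0.0, 0.0, 0, 0)
    first_hits = sum(phase_at(trace, t) == "peak_inspiration" for t in first)
    second_hits = sum(phase_at(trace, t) == "end_expiration" for t in second)
    return GatingScore(
        first_trigger_fraction=first_hits / len(first),
        second_trigger_fraction=second_hits / len(second) if len(second) else 0.0,
        n_first=len(first),
        n_second=len(second),
    )
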