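"""Two-state Gillespie simulation of channel opening/closing under ATP turnover.

The channel alternates between a closed, high-FRET state (exit rate ``k_cat``,
the rate-limiting ADP release) and an open, low-FRET state (exit rate
``k_cleave``, ATP hydrolysis and phosphate release).  Dwell times are exact
exponential variates mapped onto a 1 ms grid; camera sampling is emulated by
adding per-step Gaussian noise and boxcar-averaging over 200 ms windows, the
TIRF frame time.  The long-run closed-state occupancy of the alternating
renewal process is k_cleave / (k_cat + k_cleave).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from gatefret._util import (
    InsufficientDataError,
    InvalidParameterError,
    fwhm_to_sigma,
    rng_from_seed,
)
from gatefret.fret_histograms import FretHistogram, build_histogram

__all__ = [
    "TwoStateModel", "StateTrajectory", "simulate_two_state",
    "emulate_tirf", "trajectory_histogram", "estimate_dwell_rates",
]

#: hard cap on simulated grid points (memory guard)
MAX_STEPS = 50_000_000


@dataclass
class TwoStateModel:
    """Open/closed kinetic scheme with camera emulation settings.

    Defaults are the ATP-turnover parameters: ADP release at 0.27 1/s sets
    the closed-state dwell, hydrolysis at 11.5 1/s the open-state dwell;
    emission levels 0.76 (closed) and 0.45 (open); added noise matched to the
    0.24 FWHM of the closed peak; 1 ms simulation step, 0.2 s camera window.
    """

    k_cat: float = 0.27
    k_cleave: float = 11.5
    E_high: float = 0.76
    E_low: float = 0.45
    noise_width: float = 0.24
    dt: float = 1e-3
    window: float = 0.2
    total_time: float = 600.0

    def validate(self) -> None:
        if self.k_cat <= 0 or self.k_cleave <= 0:
            raise InvalidParameterError("rates must be positive")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.window < self.dt:
            raise InvalidParameterError("window must be at least dt")
        if self.total_time < self.window:
            raise InvalidParameterError("total_time must be at least one window")

    @property
    def high_occupancy(self) -> float:
        """Stationary fraction of time in the high-FRET (closed) state."""
        return self.k_cleave / (self.k_cat + self.k_cleave)


@dataclass
class StateTrajectory:
    """Discretised two-state trajectory: per-step state flags plus the dwell list."""

    times: np.ndarray
    states: np.ndarray          # 1 = high/closed, 0 = low/open
    dwell_records: list[tuple[str, float]] = field(default_factory=list)
    dt: float = 1e-3


def simulate_two_state(model: TwoStateModel, seed=None) -> StateTrajectory:
    """Gillespie simulation of the alternating open/closed process.

    Starts in the high-FRET (ADP-bound, closed) state.  Each dwell is an
    exponential variate with the state's exit rate, rounded up to the time
    grid (minimum one step), so recorded dwell durations sum exactly to the
    discretised total time.
    """
    model.validate()
    n_steps = int(round(model.total_time / model.dt))
    if n_steps > MAX_STEPS:
        raise InvalidParameterError(
            f"trajectory of {n_steps} steps exceeds the cap of {MAX_STEPS}")
    rng = rng_from_seed(seed)

    states = np.empty(n_steps, dtype=np.int8)
    dwells: list[tuple[str, float]] = []
    pos = 0
    high = True
    while pos < n_steps:
        rate = model.k_cat if high else model.k_cleave
        tau = rng.exponential(1.0 / rate)
        steps = max(1, int(math.ceil(tau / model.dt)))
        steps = min(steps, n_steps - pos)
        states[pos:pos + steps] = 1 if high else 0
        dwells.append(("high" if high else "low", steps * model.dt))
        pos += steps
        high = not high

    times = np.arange(n_steps) * model.dt
    return StateTrajectory(times=times, states=states, dwell_records=dwells,
                           dt=model.dt)


def emulate_tirf(traj: StateTrajectory, model: TwoStateModel, seed=None) -> np.ndarray:
    """Camera-sampled FRET trace: per-step emission + noise, window-averaged.

    Noise (sigma from the FWHM ``noise_width``) is added per simulation step
    and the trace is then averaged over non-overlapping camera windows, so
    the post-average noise SD is sigma / sqrt(window/dt).
    """
    model.validate()
    rng = rng_from_seed(seed)
    e = np.where(traj.states == 1, model.E_high, model.E_low).astype(float)
    sigma = fwhm_to_sigma(model.noise_width)
    if sigma > 0:
        e = e + rng.normal(0.0, sigma, size=e.shape)
    steps_per_window = int(round(model.window / traj.dt))
    if abs(steps_per_window * traj.dt - model.window) > 1e-9 * model.window:
        warnings.warn("window is not an integer multiple of dt; rounding to "
                      f"{steps_per_window} steps")
    steps_per_window = max(1, steps_per_window)
    n_windows = len(e) // steps_per_window
    return e[: n_windows * steps_per_window].reshape(n_windows, steps_per_window).mean(axis=1)


def trajectory_histogram(sim_trace: np.ndarray, bin_edges=None) -> FretHistogram:
    """Histogram a simulated camera trace (delegates to build_histogram)."""
    return build_histogram(sim_trace, bin_edges, condition="simulated")


def estimate_dwell_rates(traj: StateTrajectory, min_dwells: int = 10):
    """Maximum-likelihood exponential exit rates from the dwell records.

    The first and last dwells are censored (their start/end are not observed)
    and excluded.  For each state, rate = 1/mean(dwell) and SE = rate/sqrt(n).
    Returns ``((k_high, se_high), (k_low, se_low))``.
    """
    dwells = traj.dwell_records[1:-1]
    out = []
    for name in ("high", "low"):
        durs = np.array([d for s, d in dwells if s == name], dtype=float)
        if len(durs) < min_dwells:
            raise InsufficientDataError(
                f"only {len(durs)} complete {name}-state dwells; need >= {min_dwells}")
        rate = 1.0 / durs.mean()
        out.append((float(rate), float(rate / math.sqrt(len(durs)))))
    return tuple(out)
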