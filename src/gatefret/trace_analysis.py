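"""Single-molecule trace selection and FRET-efficiency estimation.

A valid single-donor / single-acceptor particle is identified by sequential
single-step photobleaching: the acceptor bleaches first (one downward step in
the acceptor channel, accompanied by an anti-correlated upward step in the
donor channel) and the donor bleaches second.  The three resulting donor
segments give the donor intensity during FRET (``I_DA``), the donor intensity
with the acceptor dark (``I_D``) and the background after donor bleaching
(``I_bck``), from which the efficiency is

    E = 1 - (I_DA - I_bck) / (I_D - I_bck)

the acceptor-photobleaching estimator, which needs no correction for channel
sensitivity or quantum-yield changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gatefret._util import InvalidInputError

__all__ = [
    "IntensityTrace", "StepCall", "FretObservation", "SelectionResult",
    "UndefinedEfficiencyError", "detect_steps", "select_smfret_trace",
    "compute_fret_efficiency",
]


class UndefinedEfficiencyError(ValueError):
    """Raised when I_D <= I_bck so the efficiency has no meaning."""


@dataclass
class IntensityTrace:
    """Paired donor/acceptor photon-count time series for one particle."""

    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    frame_period: float = 0.22
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (len(self.time) == len(self.donor) == len(self.acceptor)):
            raise InvalidInputError("time, donor and acceptor must have equal length")
        if self.frame_period <= 0:
            raise InvalidInputError("frame_period must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.donor)


@dataclass
class StepCall:
    """One detected change point: the step occurs between ``frame_index - 1``
    and ``frame_index`` (the new level starts at ``frame_index``)."""

    channel: str
    frame_index: int
    level_before: float
    level_after: float

    @property
    def magnitude(self) -> float:
        return self.level_after - self.level_before

    @property
    def is_downward(self) -> bool:
        return self.level_after < self.level_before


@dataclass
class FretObservation:
    """Background-corrected donor intensities and efficiency of one accepted molecule."""

    I_DA: float
    I_D: float
    I_bck: float
    E: float
    acceptor_bleach_frame: int = -1
    donor_bleach_frame: int = -1


@dataclass
class SelectionResult:
    """Outcome of trace selection: accepted observation, or a reason code."""

    accepted: bool
    observation: FretObservation | None = None
    reason: str | None = None


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD from the median absolute deviation of first differences.

    For i.i.d. noise the first difference has SD sigma*sqrt(2); the MAD is
    scaled by 0.6745 (the normal quartile) to estimate that SD.
    """
    d = np.diff(np.asarray(x, dtype=float))
    if len(d) == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad / (0.6745 * np.sqrt(2.0)))


def _best_split(csum, csum2, lo, hi, min_sep):
    """Least-squares single change point within [lo, hi); None if segment too short."""
    lo_j = lo + min_sep
    hi_j = hi - min_sep
    if lo_j > hi_j:
        return None
    j = np.arange(lo_j, hi_j + 1)
    sl = csum[j] - csum[lo]
    s2l = csum2[j] - csum2[lo]
    nl = j - lo
    sr = csum[hi] - csum[j]
    s2r = csum2[hi] - csum2[j]
    nr = hi - j
    cost = (s2l - sl * sl / nl) + (s2r - sr * sr / nr)
    return int(j[np.argmin(cost)])


def detect_steps(channel: np.ndarray, min_separation: int = 5,
                 threshold: float = 4.0, channel_name: str = "donor") -> list[StepCall]:
    """Detect intensity steps by iterative binary segmentation.

    The trace is recursively split at the least-squares single change point;
    a split is accepted when the level change between the flanking segment
    means exceeds ``threshold`` times the robust noise SD of the whole trace.
    Deterministic and checkable against an exhaustive change-point scan.
    """
    x = np.asarray(channel, dtype=float)
    if len(x) < 2 * min_separation:
        raise InvalidInputError(
            f"trace of {len(x)} frames shorter than 2*min_separation = {2 * min_separation}"
        )
    sigma = robust_noise_sd(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x * x)])

    change_points: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        j = _best_split(csum, csum2, lo, hi, min_separation)
        if j is None:
            return
        mean_l = (csum[j] - csum[lo]) / (j - lo)
        mean_r = (csum[hi] - csum[j]) / (hi - j)
        if abs(mean_r - mean_l) <= threshold * sigma:
            return
        change_points.append(j)
        recurse(lo, j)
        recurse(j, hi)

    recurse(0, len(x))
    change_points.sort()

    calls = []
    bounds = [0] + change_points + [len(x)]
    for i, j in enumerate(change_points):
        lo, hi = bounds[i], bounds[i + 2]
        level_before = float(np.mean(x[lo:j]))
        level_after = float(np.mean(x[j:hi]))
        calls.append(StepCall(channel=channel_name, frame_index=j,
                              level_before=level_before, level_after=level_after))
    return calls


def compute_fret_efficiency(I_DA: float, I_D: float, I_bck: float) -> float:
    """Acceptor-photobleaching FRET efficiency; may fall outside [0, 1] from noise."""
    if I_D <= I_bck:
        raise UndefinedEfficiencyError(
            f"I_D ({I_D}) must exceed I_bck ({I_bck}) for E to be defined"
        )
    return 1.0 - (I_DA - I_bck) / (I_D - I_bck)


def _segment_mean(x: np.ndarray, lo: int, hi: int, margin: int = 2) -> float:
    """Mean of x[lo:hi], trimming ``margin`` frames at each boundary when the
    segment is long enough (step frames carry partial-exposure artefacts)."""
    if hi - lo > 2 * margin + 1:
        lo, hi = lo + margin, hi - margin
    return float(np.mean(x[lo:hi]))


def select_smfret_trace(
    trace: IntensityTrace,
    donor_steps: list[StepCall] | None = None,
    acceptor_steps: list[StepCall] | None = None,
    min_separation: int = 5,
    threshold: float = 4.0,
    anticorrelation_fraction: float = 0.30,
) -> SelectionResult:
    """Apply the sequential-photobleaching selection to one trace.

    Accepted iff the acceptor shows exactly one downward step, the donor
    exactly one downward step strictly later, and the donor rises
    anti-correlatedly (within +-1 frame of the acceptor step, magnitude at
    least ``anticorrelation_fraction`` of the acceptor drop).  Rejection is a
    result with a reason code, never an exception.  The decision is invariant
    under uniform scaling of both channels.
    """
    if donor_steps is None:
        donor_steps = detect_steps(trace.donor, min_separation, threshold, "donor")
    if acceptor_steps is None:
        acceptor_steps = detect_steps(trace.acceptor, min_separation, threshold, "acceptor")

    acc_down = [s for s in acceptor_steps if s.is_downward]
    if len(acc_down) == 0:
        return SelectionResult(False, reason="no-acceptor-step")
    if len(acc_down) > 1:
        return SelectionResult(False, reason="multi-step")
    acc = acc_down[0]

    don_down = [s for s in donor_steps if s.is_downward]
    if len(don_down) == 0:
        return SelectionResult(False, reason="no-donor-bleach")
    if len(don_down) > 1:
        return SelectionResult(False, reason="multi-step")
    don = don_down[0]
    if don.frame_index <= acc.frame_index:
        return SelectionResult(False, reason="donor-first")

    don_up = [s for s in donor_steps
              if not s.is_downward and abs(s.frame_index - acc.frame_index) <= 1]
    if not don_up:
        return SelectionResult(False, reason="no-anticorrelation")
    rise = max(s.magnitude for s in don_up)
    drop = acc.level_before - acc.level_after
    if rise < anticorrelation_fraction * drop:
        return SelectionResult(False, reason="no-anticorrelation")
    up = max(don_up, key=lambda s: s.magnitude)

    i_da = _segment_mean(trace.donor, 0, up.frame_index)
    i_d = _segment_mean(trace.donor, up.frame_index, don.frame_index)
    i_bck = _segment_mean(trace.donor, don.frame_index, trace.n_frames)
    try:
        e = compute_fret_efficiency(i_da, i_d, i_bck)
    except UndefinedEfficiencyError:
        return SelectionResult(False, reason="undefined-efficiency")

    obs = FretObservation(I_DA=i_da, I_D=i_d, I_bck=i_bck, E=e,
                          acceptor_bleach_frame=acc.frame_index,
                          donor_bleach_frame=don.frame_index)
    return SelectionResult(True, observation=obs)
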