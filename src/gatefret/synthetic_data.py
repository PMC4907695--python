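"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the statistical structure the analysis assumes:

* immobilised-particle donor/acceptor intensity traces with sequential
  acceptor-then-donor single-step photobleaching (0.22 s per frame),
* per-molecule FRET-efficiency samples drawn from Gaussian mixtures
  (three conformational states of the lateral gate),
* tight-binding (ligand-depletion) titration curves,
* multi-exponential fluorescence decays (stopped-flow style).

All randomness flows through one explicit ``numpy`` generator per call;
identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from gatefret._util import (
    InvalidParameterError,
    fwhm_to_sigma,
    rng_from_seed,
)
from gatefret.trace_analysis import IntensityTrace
from gatefret.ensemble_assays import KineticTrace, TitrationSeries, tight_binding_model


@dataclass
class TraceParams:
    """Parameters of one synthetic donor/acceptor intensity trace.

    Times are seconds, intensities counts per frame.  ``frame_period``
    defaults to the TIRF repetition time of 0.22 s (0.2 s exposure).
    ``accepted_fixture`` forces the acceptor to bleach before the donor so
    that the trace passes the selection criteria by construction; with it
    off, bleach times are independent and donor-first traces (which the
    selection must reject) occur naturally.
    """

    donor_brightness: float = 1000.0
    fret_efficiency_true: float = 0.6
    background_mean: float = 50.0
    noise_sd: float = 20.0
    acceptor_bleach_rate: float = 0.05
    donor_bleach_rate: float = 0.02
    n_frames: int = 600
    frame_period: float = 0.22
    exposure: float = 0.2
    seed: int | None = None
    accepted_fixture: bool = True

    def validate(self) -> None:
        if self.n_frames <= 0:
            raise InvalidParameterError("n_frames must be positive")
        if self.frame_period <= 0:
            raise InvalidParameterError("frame_period must be positive")
        if not 0.0 <= self.fret_efficiency_true <= 1.0:
            raise InvalidParameterError("fret_efficiency_true must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")
        if self.acceptor_bleach_rate < 0 or self.donor_bleach_rate < 0:
            raise InvalidParameterError("bleach rates must be non-negative")


@dataclass
class MixtureSpec:
    """Gaussian mixture of FRET-efficiency states.

    ``components`` is a list of ``(mean, width, weight)`` with widths in the
    FWHM convention shared with the fitting code.  Defaults mirror the
    study design: 200 molecules per replicate, three replicates.
    """

    components: list[tuple[float, float, float]]
    n_per_replicate: int = 200
    n_replicates: int = 3
    seed: int | None = None

    def validate(self) -> None:
        if not self.components:
            raise InvalidParameterError("at least one mixture component required")
        weights = np.array([c[2] for c in self.components], dtype=float)
        if np.any(weights < 0):
            raise InvalidParameterError("component weights must be non-negative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise InvalidParameterError(
                f"component weights must sum to 1 (got {weights.sum()!r})"
            )
        if any(c[1] < 0 for c in self.components):
            raise InvalidParameterError("component widths must be non-negative")
        if self.n_per_replicate < 0 or self.n_replicates < 0:
            raise InvalidParameterError("counts must be non-negative")


@dataclass
class TitrationSpec:
    """Forward model of a tight-binding titration (concentrations in nM)."""

    F0: float = 1.0
    Bmax: float = 0.47
    E0: float = 10.0
    KD: float = 23.5
    concentrations: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 80.0,
             100.0, 150.0, 200.0, 300.0, 500.0, 750.0, 1000.0, 1500.0,
             2000.0, 3000.0]
        )
    )
    noise_sd: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if self.E0 <= 0:
            raise InvalidParameterError("E0 must be positive")
        if self.KD < 0:
            raise InvalidParameterError("KD must be non-negative")
        s = np.asarray(self.concentrations, dtype=float)
        if np.any(s < 0):
            raise InvalidParameterError("concentrations must be non-negative")


@dataclass
class DecaySpec:
    """Multi-exponential fluorescence decay F(t) = offset + sum A_i exp(-k_i t)."""

    rates: tuple[float, ...] = (0.5,)
    amplitudes: tuple[float, ...] = (1.0,)
    offset: float = 0.0
    duration: float = 30.0
    dt: float = 0.01
    noise_sd: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.duration <= 0:
            raise InvalidParameterError("duration must be positive")
        if len(self.rates) != len(self.amplitudes):
            raise InvalidParameterError("rates and amplitudes must have equal length")
        if any(k <= 0 for k in self.rates):
            raise InvalidParameterError("rates must be positive")


# Six-condition study design used for histogram-level synthetic sets.  The
# 'alone' channel is a pure closed (high-FRET) population; motor + nucleotide
# conditions shift weight into the part-open and open states, with the
# ATP-containing conditions mixing all three.
STUDY_MEANS = (0.76, 0.59, 0.45)
STUDY_WIDTHS = (0.24, 0.16, 0.31)
STUDY_CONDITION_WEIGHTS: dict[str, tuple[float, float, float]] = {
    "alone": (1.0, 0.0, 0.0),
    "ADP": (0.90, 0.02, 0.08),
    "AMPPNP": (0.45, 0.05, 0.50),
    "ATP": (0.45, 0.35, 0.20),
    "ATP+pOA": (0.30, 0.50, 0.20),
    "ATP+high-SecA/pOA": (0.25, 0.45, 0.30),
}


def _draw_bleach_frame(rate: float, frame_period: float, rng: np.random.Generator,
                       after: float = 0.0):
    """Exponential bleach time (s), quantised up to the next frame boundary."""
    if rate <= 0:
        return None, math.inf
    t = after + rng.exponential(1.0 / rate)
    frame = int(math.ceil(t / frame_period))
    return frame, t


def generate_intensity_trace(params: TraceParams) -> IntensityTrace:
    """Simulate one immobilised-particle donor/acceptor trace.

    Piecewise-constant construction: while both dyes are alive the donor sits
    at ``background + brightness*(1 - E)`` and the acceptor at
    ``background + brightness*E``; acceptor photobleaching removes energy
    transfer, so the donor rises anti-correlatedly to
    ``background + brightness`` while the acceptor drops to background;
    donor photobleaching drops both to background.  Gaussian noise is added
    per frame; true bleach frames are recorded in ``metadata``.
    """
    params.validate()
    rng = rng_from_seed(params.seed)
    n = params.n_frames
    dt = params.frame_period
    bck = params.background_mean
    bright = params.donor_brightness
    e = params.fret_efficiency_true

    acc_frame, acc_t = _draw_bleach_frame(params.acceptor_bleach_rate, dt, rng)
    if params.accepted_fixture:
        don_frame, _ = _draw_bleach_frame(params.donor_bleach_rate, dt, rng,
                                          after=acc_t if acc_frame is not None else 0.0)
    else:
        don_frame, _ = _draw_bleach_frame(params.donor_bleach_rate, dt, rng)

    donor = np.empty(n)
    acceptor = np.empty(n)
    af = n if acc_frame is None else min(acc_frame, n)
    df = n if don_frame is None else min(don_frame, n)
    for i in range(n):
        donor_alive = i < df
        acceptor_alive = i < af
        if donor_alive and acceptor_alive:
            donor[i] = bck + bright * (1.0 - e)
            acceptor[i] = bck + bright * e
        elif donor_alive:
            donor[i] = bck + bright
            acceptor[i] = bck
        else:
            donor[i] = bck
            acceptor[i] = bck

    if params.noise_sd > 0:
        donor = donor + rng.normal(0.0, params.noise_sd, size=n)
        acceptor = acceptor + rng.normal(0.0, params.noise_sd, size=n)

    time = np.arange(n) * dt
    meta = {
        "acceptor_bleach_frame": acc_frame if (acc_frame is not None and acc_frame < n) else None,
        "donor_bleach_frame": don_frame if (don_frame is not None and don_frame < n) else None,
        "fret_efficiency_true": e,
    }
    return IntensityTrace(time=time, donor=donor, acceptor=acceptor,
                          frame_period=dt, metadata=meta)


def sample_mixture(spec: MixtureSpec) -> list[np.ndarray]:
    """Draw replicate lists of per-molecule FRET efficiencies.

    Component membership is multinomial on the weights; values are Gaussian
    with sigma derived from the FWHM width.  Values are deliberately not
    truncated to [0, 1]: measured efficiencies scatter outside the unit
    interval and the histogram range accommodates them.
    """
    spec.validate()
    rng = rng_from_seed(spec.seed)
    means = np.array([c[0] for c in spec.components])
    sigmas = np.array([fwhm_to_sigma(c[1]) for c in spec.components])
    weights = np.array([c[2] for c in spec.components])
    out = []
    for _ in range(spec.n_replicates):
        idx = rng.choice(len(means), size=spec.n_per_replicate, p=weights)
        vals = rng.normal(means[idx], sigmas[idx]) if spec.n_per_replicate else np.empty(0)
        out.append(np.asarray(vals, dtype=float))
    return out


def sample_condition_set(
    condition_weights: dict[str, tuple[float, float, float]] | None = None,
    means: tuple[float, float, float] = STUDY_MEANS,
    widths: tuple[float, float, float] = STUDY_WIDTHS,
    n_per_replicate: int = 200,
    n_replicates: int = 3,
    seed: int | None = None,
) -> dict[str, list[np.ndarray]]:
    """Per-condition replicate efficiency samples for the six-condition design."""
    if condition_weights is None:
        condition_weights = STUDY_CONDITION_WEIGHTS
    rng = rng_from_seed(seed)
    out: dict[str, list[np.ndarray]] = {}
    for name, w in condition_weights.items():
        comps = [(m, fw, wt) for m, fw, wt in zip(means, widths, w) if wt > 0]
        total = sum(c[2] for c in comps)
        comps = [(m, fw, wt / total) for m, fw, wt in comps]
        spec = MixtureSpec(components=comps, n_per_replicate=n_per_replicate,
                           n_replicates=n_replicates,
                           seed=int(rng.integers(0, 2**31 - 1)))
        out[name] = sample_mixture(spec)
    return out


def generate_titration(spec: TitrationSpec) -> TitrationSeries:
    """Forward-evaluate the tight-binding quadratic and add optional noise."""
    spec.validate()
    s = np.asarray(spec.concentrations, dtype=float)
    f = tight_binding_model(spec.F0, spec.Bmax, spec.E0, spec.KD, s)
    if spec.noise_sd > 0:
        rng = rng_from_seed(spec.seed)
        f = f + rng.normal(0.0, spec.noise_sd, size=s.shape)
    return TitrationSeries(s=s, F=f, E0=spec.E0)


def generate_decay(spec: DecaySpec) -> KineticTrace:
    """Evaluate F(t) = offset + sum A_i exp(-k_i t) on a regular grid."""
    spec.validate()
    t = np.arange(0.0, spec.duration + 0.5 * spec.dt, spec.dt)
    f = np.full_like(t, spec.offset)
    for k, a in zip(spec.rates, spec.amplitudes):
        f = f + a * np.exp(-k * t)
    if spec.noise_sd > 0:
        rng = rng_from_seed(spec.seed)
        f = f + rng.normal(0.0, spec.noise_sd, size=t.shape)
    return KineticTrace(time=t, F=f)
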