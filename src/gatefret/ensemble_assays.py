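"""Ensemble-level fits: tight binding, stopped-flow exponentials, conversions.

Binding between the channel and the motor is measured at concentrations
comparable to K_D, so ligand depletion matters and the isotherm is the
quadratic ("tight-binding") solution of the binding equilibrium:

    F(s) = F0 - Bmax * (E0 + s + KD - sqrt((E0 + s + KD)^2 - 4*E0*s)) / (2*E0)

with E0 the fixed binding partner and s the titrated species (both nM here).
Stopped-flow nucleotide-release traces are fitted to one or two exponentials,
optionally with a rate fixed; when individual rates would be spurious the
time to 50% completion (t_1/2) of the fitted curve is reported instead.
Small conversions: the ensemble proximity ratio F_A/(F_D+F_A), steady-state
ATPase turnover from NADH absorbance slopes, and Forster-law distance from
efficiency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import optimize

from gatefret._util import (
    FitFailureError,
    InvalidInputError,
    InvalidParameterError,
    rng_from_seed,
)

__all__ = [
    "TitrationSeries", "BindingFit", "KineticTrace", "ExponentialFit",
    "FretCalibration", "AtpaseAssay",
    "tight_binding_model", "fit_tight_binding", "fit_exponentials",
    "proximity_ratio", "atpase_turnover", "efret_to_distance",
]


@dataclass
class TitrationSeries:
    """Titration of ligand s (nM) against fluorescence F, with the fixed
    partner at concentration E0 (nM)."""

    s: np.ndarray
    F: np.ndarray
    E0: float

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.s.shape != self.F.shape:
            raise InvalidInputError("s and F must have equal length")
        if np.any(self.s < 0):
            raise InvalidInputError("concentrations must be non-negative")
        if self.E0 <= 0:
            raise InvalidParameterError("E0 must be positive")


@dataclass
class BindingFit:
    F0: float
    Bmax: float
    KD: float
    stderr: dict = field(default_factory=dict)
    rss: float = 0.0
    kd_identifiable: bool = True


@dataclass
class KineticTrace:
    """Time course of fluorescence (stopped-flow style)."""

    time: np.ndarray
    F: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.time.shape != self.F.shape:
            raise InvalidInputError("time and F must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise InvalidInputError("time must be strictly increasing")


@dataclass
class ExponentialFit:
    rates: np.ndarray
    amplitudes: np.ndarray
    offset: float
    t_half: float
    stderr: dict = field(default_factory=dict)
    rss: float = 0.0

    @property
    def normalised_amplitudes(self) -> np.ndarray:
        """Amplitudes scaled so the total amplitude is 1."""
        total = self.amplitudes.sum()
        if total == 0:
            raise InvalidInputError("total amplitude is zero; cannot normalise")
        return self.amplitudes / total


@dataclass
class FretCalibration:
    """Forster radius of the dye pair (6 nm for the pair used here)."""

    R0: float = 6.0

    def __post_init__(self):
        if self.R0 <= 0:
            raise InvalidParameterError("R0 must be positive")


@dataclass
class AtpaseAssay:
    """Coupled-assay slope in delta-A340 per minute plus calibration constants."""

    slope: float
    enzyme_conc: float              # M
    epsilon_NADH: float = 6220.0    # 1/M at 340 nm
    path_length: float = 1.0        # cm

    def __post_init__(self):
        if self.enzyme_conc <= 0:
            raise InvalidInputError("enzyme concentration must be positive")
        if self.epsilon_NADH <= 0 or self.path_length <= 0:
            raise InvalidParameterError("epsilon and path length must be positive")


def tight_binding_model(F0, Bmax, E0, KD, s):
    """Quadratic ligand-depletion isotherm, elementwise over s (nM)."""
    if E0 <= 0:
        raise InvalidParameterError("E0 must be positive")
    s = np.asarray(s, dtype=float)
    b = E0 + s + KD
    disc = b * b - 4.0 * E0 * s
    if np.any(disc < -1e-9 * np.maximum(b * b, 1.0)):
        raise FloatingPointError("negative discriminant in tight-binding model")
    bound = (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * E0)
    return F0 - Bmax * bound


def fit_tight_binding(series: TitrationSeries, n_starts: int = 5,
                      seed: int | None = 0) -> BindingFit:
    """Weighted-free nonlinear least squares of the tight-binding isotherm.

    F0, Bmax and KD float; E0 is fixed at the series value.  Multi-start with
    seeded jittered initialisations; asymptotic standard errors reported.
    Degenerate flat data yield Bmax ~ 0 and ``kd_identifiable = False``.
    """
    s, f, e0 = series.s, series.F, series.E0
    if len(np.unique(s)) < 4:
        raise InvalidInputError("need at least 4 distinct concentrations")
    f0_init = float(f[np.argmin(s)])
    span = float(f0_init - f.min()) if f0_init >= f.min() else float(f0_init - f.max())
    half = f0_init - 0.5 * span
    below = s[f <= half] if span >= 0 else s[f >= half]
    kd_init = float(np.median(below)) if below.size else float(np.median(s[s > 0]) or 1.0)
    kd_init = max(kd_init, 1e-3)

    def residual(p):
        return tight_binding_model(p["F0"].value, p["Bmax"].value, e0,
                                   p["KD"].value, s) - f

    rng = rng_from_seed(seed)
    best = None
    for start in range(n_starts):
        p = lmfit.Parameters()
        jf = 1.0 if start == 0 else float(np.exp(rng.normal(0, 0.1)))
        jk = 1.0 if start == 0 else float(np.exp(rng.normal(0, 0.5)))
        p.add("F0", value=f0_init * jf if f0_init != 0 else 0.0)
        p.add("Bmax", value=span * jf)
        p.add("KD", value=kd_init * jk, min=0.0)
        try:
            res = lmfit.minimize(residual, p, method="leastsq")
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise FitFailureError("tight-binding fit failed to converge")

    kd = float(best.params["KD"].value)
    bmax = float(best.params["Bmax"].value)
    identifiable = abs(bmax) > 1e-3 * max(abs(f).max(), 1e-12)
    if s.max() < kd and identifiable:
        warnings.warn("titration range does not bracket the fitted KD; "
                      "the estimate is an extrapolation")
    stderr = {k: (best.params[k].stderr if best.params[k].stderr is not None else np.nan)
              for k in ("F0", "Bmax", "KD")}
    return BindingFit(F0=float(best.params["F0"].value), Bmax=bmax, KD=kd,
                      stderr=stderr, rss=float(best.chisqr),
                      kd_identifiable=bool(identifiable))


def _exp_model(t, offset, rates, amps):
    out = np.full_like(t, offset, dtype=float)
    for k, a in zip(rates, amps):
        out = out + a * np.exp(-k * t)
    return out


def fit_exponentials(trace: KineticTrace, n_components: int = 1,
                     fixed_rates: dict[int, float] | None = None,
                     n_starts: int = 5, seed: int | None = 0) -> ExponentialFit:
    """Fit offset + sum A_i exp(-k_i t), optionally with some rates fixed.

    ``fixed_rates`` maps component index -> rate held constant (used when a
    contaminating species' rate is known independently).  t_1/2 is the time
    at which the fitted curve reaches 50% of its total change, found by
    bisection on the fitted model rather than on the raw data.
    """
    if n_components not in (1, 2):
        raise InvalidParameterError("n_components must be 1 or 2")
    fixed_rates = fixed_rates or {}
    t, f = trace.time, trace.F
    span = float(f[0] - f[-1])
    k0 = 1.0 / max(t[-1] / 3.0, 1e-12)

    def residual(p):
        rates = [p[f"k_{i}"].value for i in range(n_components)]
        amps = [p[f"A_{i}"].value for i in range(n_components)]
        return _exp_model(t, p["offset"].value, rates, amps) - f

    rng = rng_from_seed(seed)
    best = None
    for start in range(n_starts):
        p = lmfit.Parameters()
        p.add("offset", value=float(f[-1]))
        for i in range(n_components):
            if i in fixed_rates:
                p.add(f"k_{i}", value=float(fixed_rates[i]), vary=False)
            else:
                spread = 10.0 ** i
                jk = 1.0 if start == 0 else float(np.exp(rng.normal(0, 1.0)))
                p.add(f"k_{i}", value=k0 * spread * jk, min=1e-9)
            p.add(f"A_{i}", value=span / n_components)
        try:
            res = lmfit.minimize(residual, p, method="leastsq")
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise FitFailureError("exponential fit failed to converge")

    rates = np.array([best.params[f"k_{i}"].value for i in range(n_components)])
    amps = np.array([best.params[f"A_{i}"].value for i in range(n_components)])
    offset = float(best.params["offset"].value)
    t_half = _t_half(rates, amps)
    stderr = {name: (best.params[name].stderr if best.params[name].stderr is not None
                     else np.nan) for name in best.params}
    return ExponentialFit(rates=rates, amplitudes=amps, offset=offset,
                          t_half=t_half, stderr=stderr, rss=float(best.chisqr))


def _t_half(rates, amps) -> float:
    """Time at which sum A_i exp(-k_i t) has decayed to half its initial value."""
    total = amps.sum()
    if total == 0:
        return math.nan

    def completion(t):
        return 1.0 - _exp_model(np.array([t]), 0.0, rates, amps)[0] / total

    hi = 2.0 * math.log(2.0) / rates.min()
    while completion(hi) < 0.5:
        hi *= 2.0
        if hi > 1e12:
            return math.nan
    return float(optimize.brentq(lambda t: completion(t) - 0.5, 0.0, hi))


def proximity_ratio(F_D, F_A):
    """Ensemble FRET proxy: F_A / (F_D + F_A)."""
    fd = np.asarray(F_D, dtype=float)
    fa = np.asarray(F_A, dtype=float)
    total = fd + fa
    if np.any(total <= 0):
        raise InvalidInputError("F_D + F_A must be positive")
    out = fa / total
    return float(out) if out.ndim == 0 else out


def atpase_turnover(assay: AtpaseAssay) -> float:
    """ATP turnover (per minute per enzyme) from the NADH-coupled assay slope."""
    return assay.slope / (assay.epsilon_NADH * assay.path_length * assay.enzyme_conc)


def efret_to_distance(E: float, cal: FretCalibration = FretCalibration()) -> float:
    """Dye-dye distance (nm) from efficiency via the Forster law r = R0*(1/E - 1)^(1/6)."""
    if not 0.0 < E < 1.0:
        raise ValueError("E must lie strictly within (0, 1)")
    return cal.R0 * (1.0 / E - 1.0) ** (1.0 / 6.0)
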