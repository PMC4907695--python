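"""Shared numerical conventions and small helpers."""

from __future__ import annotations

import math

import numpy as np

# Gaussian peak widths are quoted as full width at half maximum throughout
# (e.g. the closed-state peak: mean 0.76, width 0.24).  sigma = FWHM / (2*sqrt(2 ln 2)).
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def fwhm_to_sigma(width: float) -> float:
    """Convert a full-width-at-half-maximum to a Gaussian standard deviation."""
    return float(width) * FWHM_TO_SIGMA


def sigma_to_fwhm(sigma: float) -> float:
    return float(sigma) / FWHM_TO_SIGMA


def rng_from_seed(seed) -> np.random.Generator:
    """One explicit generator per call; no global state."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class InvalidParameterError(ValueError):
    """A spec/parameter object violates its invariants."""


class InvalidInputError(ValueError):
    """Input data violate a precondition (shape, ordering, emptiness)."""


class FitFailureError(RuntimeError):
    """A nonlinear fit failed to converge."""

    def __init__(self, message: str, stage: int | None = None):
        super().__init__(message)
        self.stage = stage


class InsufficientDataError(ValueError):
    """Too few observations to perform the requested estimate."""


class LookupError_(KeyError):
    """A named chain/residue/atom is absent from a structure."""
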