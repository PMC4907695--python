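"""How many spectral components do the histograms require?

Two complementary criteria:

* ``svd_components`` — singular value decomposition of the (bins x
  condition*replicate) histogram matrix; the number of significant components
  is the smallest rank whose reconstruction error falls within the
  replicate-to-replicate noise floor.
* ``compare_k_fits`` — residual sum of squares of k-Gaussian mixture fits
  under the staged-protocol constraints (high peak pinned by the motor-free
  channel), for candidate k.  RSS is non-increasing in k because the models
  nest; structure left in the k=2 residuals is what reveals a third state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from gatefret._util import InsufficientDataError, rng_from_seed
from gatefret.fret_histograms import (
    FretHistogram,
    ProtocolError,
    _fit_global,
    _plain_rss,
    average_replicates,
)

__all__ = ["SvdResult", "svd_components", "compare_k_fits", "residual_runs_test"]


@dataclass
class SvdResult:
    singular_values: np.ndarray
    n_significant: int
    noise_floor: float

    def __post_init__(self):
        self.singular_values = np.asarray(self.singular_values, dtype=float)


def _normalise_columns(mat: np.ndarray) -> np.ndarray:
    totals = mat.sum(axis=0)
    totals = np.where(totals > 0, totals, 1.0)
    return mat / totals


def _matrix_and_noise(histogram_set: dict[str, list[FretHistogram]]):
    """Stack normalised replicate histograms into columns; estimate the
    per-entry noise SD from the scatter of replicates about their condition
    mean (debiased for the subtracted mean)."""
    cols, ss, dof = [], 0.0, 0
    for cond, reps in histogram_set.items():
        block = _normalise_columns(np.column_stack([h.frequencies for h in reps]))
        cols.append(block)
        n = block.shape[1]
        if n >= 2:
            dev = block - block.mean(axis=1, keepdims=True)
            ss += float(np.sum(dev ** 2))
            dof += block.shape[0] * (n - 1)
    mat = np.hstack(cols)
    noise = math.sqrt(ss / dof) if dof else 0.0
    return mat, noise


def svd_components(histograms, replicate_noise: float | None = None,
                   noise_factor: float = 1.2) -> SvdResult:
    """Count significant SVD components of a histogram set.

    ``histograms`` is either a dict of condition -> replicate histograms (the
    per-entry noise SD is then estimated from same-condition replicate
    scatter) or a (bins x columns) matrix with ``replicate_noise`` supplied
    as that per-entry SD.  Columns are area-normalised first, so amplitude
    differences rather than molecule totals drive the decomposition.

    A component is significant when its singular value exceeds the noise
    floor — the largest singular value expected of a pure-noise matrix of
    the same shape, ``sigma * (sqrt(bins) + sqrt(columns))`` — by the factor
    ``noise_factor``; omitting such a component leaves reconstruction error
    above what replicate scatter alone explains.
    """
    if isinstance(histograms, dict):
        mat, est_noise = _matrix_and_noise(histograms)
        sigma = est_noise if replicate_noise is None else float(replicate_noise)
    else:
        mat = _normalise_columns(np.asarray(histograms, dtype=float))
        sigma = float(replicate_noise) if replicate_noise is not None else 0.0
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise InsufficientDataError("need at least two histogram columns for SVD")

    s = np.linalg.svd(mat, compute_uv=False)
    floor = sigma * (math.sqrt(mat.shape[0]) + math.sqrt(mat.shape[1]))
    tol = noise_factor * floor + 1e-10 * (s[0] if s.size else 1.0)
    n_sig = max(int(np.sum(s > tol)), 1)
    return SvdResult(singular_values=s, n_significant=n_sig, noise_floor=floor)


def compare_k_fits(histograms, k_values=(1, 2, 3),
                   alone_condition: str = "alone", seed: int | None = 0) -> dict[int, float]:
    """Residual sum of squares of k-Gaussian mixture fits for each candidate k.

    ``histograms`` may be a single :class:`FretHistogram`, a list of replicate
    histograms, or a condition dict; with a dict containing the motor-free
    condition, the high peak is first determined there and held fixed for all
    k, as in the staged protocol.  Successive k are warm-started from the
    k-1 solution (extra component at zero amplitude), so the returned RSS is
    non-increasing in k.
    """
    if isinstance(histograms, FretHistogram):
        histogram_set = {"data": [histograms]}
        use_alone = False
    elif isinstance(histograms, list):
        histogram_set = {"data": histograms}
        use_alone = False
    else:
        histogram_set = histograms
        use_alone = alone_condition in histogram_set
        if not use_alone:
            raise ProtocolError(
                f"condition dict lacks {alone_condition!r}; pass a histogram or list instead")

    # every replicate histogram is its own dataset: shapes are shared
    # globally while amplitudes float per replicate, so an extra component
    # cannot chase noise that is independent between replicates
    edges = next(iter(histogram_set.values()))[0].bin_edges
    datasets = [(edges, h.frequencies, np.ones_like(h.frequencies))
                for reps in histogram_set.values() for h in reps]
    averaged = {c: average_replicates(reps) for c, reps in histogram_set.items()}

    fixed = {}
    mu_high, w_high = None, None
    if use_alone:
        alone = averaged[alone_condition]
        mode = alone.bin_centres[int(np.argmax(alone.frequencies))]
        r1 = _fit_global([(edges, alone.frequencies, np.ones_like(alone.frequencies))],
                         1, [mode], [0.25], fixed={}, seed=seed)
        mu_high, w_high = r1.shapes[0]
        fixed = {0: (mu_high, w_high)}

    anchor = mu_high if mu_high is not None else float(
        next(iter(averaged.values())).bin_centres[
            int(np.argmax(next(iter(averaged.values())).frequencies))])

    rng = rng_from_seed(seed)
    rss: dict[int, float] = {}
    prev: tuple[int, object] | None = None
    for k in sorted(set(int(k) for k in k_values)):
        if k < 1:
            raise ValueError("k must be >= 1")
        init_means = [anchor] + [anchor - 0.17 * (i + 1) for i in range(k - 1)]
        init_widths = [w_high if w_high is not None else 0.25] + [0.2] * (k - 1)
        extra = []
        if prev is not None:
            # warm start: k-1 solution padded with one more component, so the
            # nested optimum is always reachable and RSS cannot increase
            prev_k, prev_fit = prev
            theta = []
            for c in range(k):
                if c in fixed:
                    continue
                if c < prev_k:
                    theta += list(prev_fit.shapes[c])
                else:
                    theta += [anchor - 0.25 * (c - prev_k + 1), 0.2]
            extra = [np.asarray(theta)]
        fit = _fit_global(datasets, k, init_means, init_widths,
                          fixed=fixed, seed=int(rng.integers(0, 2**31 - 1)),
                          extra_inits=extra)
        rss[k] = _plain_rss(fit, datasets)
        if prev is not None and rss[k] > rss[prev[0]]:
            rss[k] = rss[prev[0]]   # nested models: keep the k-1 optimum
        prev = (k, fit)
    return rss


def residual_runs_test(residuals) -> float:
    """Wald-Wolfowitz runs test p-value on the signs of fit residuals.

    Structured (sign-correlated) residuals give few runs and a small p;
    white residuals give p near uniform.
    """
    r = np.asarray(residuals, dtype=float)
    signs = np.sign(r[r != 0])
    n = len(signs)
    if n < 2:
        return 1.0
    n_pos = int(np.sum(signs > 0))
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        return 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n ** 2 * (n - 1.0))
    if var <= 0:
        return 1.0
    from scipy import stats
    z = (runs - mu) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))
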