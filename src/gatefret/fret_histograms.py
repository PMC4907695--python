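"""FRET-efficiency histograms and the staged constrained mixture fit.

Histograms of per-molecule efficiencies are built per replicate, averaged bin
by bin (mean +- SEM), and described by a mixture of Gaussian components —
closed, part-open and open conformations of the lateral gate.  The global fit
runs in four stages:

1. a single Gaussian is fitted to the 'alone' condition (channel without the
   motor), pinning the position and width of the high-FRET closed peak;
2. the whole condition set is fitted globally to three Gaussians with the
   high peak fixed and the two lower peaks shared across conditions;
3. all positions and widths are fixed and only the per-replicate amplitudes
   float (a weighted non-negative linear problem);
4. the two lower peaks are released again to confirm the shared-shape model
   is not over-constrained; disagreement beyond the parameter uncertainties
   raises a flag on the returned fit.

Widths are quoted as FWHM; amplitudes are areas (molecule counts).  Model
curves are bin-integrated Gaussians, not centre-sampled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from gatefret._util import (
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
    fwhm_to_sigma,
    rng_from_seed,
)

logger = logging.getLogger(__name__)

#: Default binning: 0.05-wide bins spanning [-0.2, 1.2].
DEFAULT_BIN_EDGES = np.linspace(-0.2, 1.2, 29)


class ProtocolError(ValueError):
    """The staged protocol's required inputs are missing (no 'alone' condition)."""


@dataclass
class FretHistogram:
    """Binned FRET-efficiency frequencies for one condition/replicate."""

    bin_edges: np.ndarray
    frequencies: np.ndarray
    condition: str = ""
    replicate: int = 0
    sem: np.ndarray | None = None
    n_out_of_range: int = 0

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.frequencies) != len(self.bin_edges) - 1:
            raise InvalidInputError("len(frequencies) must equal len(bin_edges) - 1")
        if np.any(self.frequencies < 0):
            raise InvalidInputError("frequencies must be non-negative")

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> float:
        return float(self.frequencies.sum())


@dataclass
class GaussianComponent:
    """One mixture component: mean, FWHM width, and amplitude (area)."""

    mean: float
    width: float
    amplitude: float = 0.0

    @property
    def sigma(self) -> float:
        return fwhm_to_sigma(self.width)


@dataclass
class MixtureFit:
    """Result of the staged global fit.

    ``components`` are sorted by decreasing mean (closed, part-open, open).
    ``condition_amplitudes`` maps condition -> per-replicate amplitude matrix
    (n_replicates x n_components); ``rss_per_stage`` records the residual sum
    of squares after each stage; ``stage4_consistent`` is False when the
    released stage-4 shapes drift outside their uncertainties.
    """

    components: list[GaussianComponent]
    condition_amplitudes: dict[str, np.ndarray]
    rss_per_stage: dict[int, float] = field(default_factory=dict)
    stage4_consistent: bool = True
    stage4_components: list[GaussianComponent] | None = None

    def mean_amplitudes(self, condition: str) -> np.ndarray:
        return self.condition_amplitudes[condition].mean(axis=0)


def build_histogram(efficiencies, bin_edges=None, condition: str = "",
                    replicate: int = 0) -> FretHistogram:
    """Count efficiencies into half-open bins [lo, hi); out-of-range values
    are dropped and their count logged."""
    if bin_edges is None:
        bin_edges = DEFAULT_BIN_EDGES
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2:
        raise InvalidParameterError("bin_edges must contain at least two edges")
    if np.any(np.diff(edges) <= 0):
        raise InvalidParameterError("bin_edges must be strictly increasing")
    vals = np.asarray(efficiencies, dtype=float)
    in_range = (vals >= edges[0]) & (vals < edges[-1])
    n_out = int(vals.size - in_range.sum())
    if n_out:
        logger.info("build_histogram(%s/%d): dropped %d value(s) outside [%g, %g)",
                    condition, replicate, n_out, edges[0], edges[-1])
    idx = np.digitize(vals[in_range], edges) - 1
    freq = np.bincount(idx, minlength=edges.size - 1).astype(float)
    return FretHistogram(bin_edges=edges, frequencies=freq, condition=condition,
                         replicate=replicate, n_out_of_range=n_out)


def average_replicates(histograms: list[FretHistogram]) -> FretHistogram:
    """Bin-by-bin mean of replicate histograms, with per-bin SEM = SD/sqrt(n)."""
    if not histograms:
        raise InvalidInputError("no histograms to average")
    edges = histograms[0].bin_edges
    for h in histograms[1:]:
        if not np.array_equal(h.bin_edges, edges):
            raise InvalidInputError("replicate histograms must share bin edges")
    mat = np.vstack([h.frequencies for h in histograms])
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return FretHistogram(bin_edges=edges, frequencies=mean,
                         condition=histograms[0].condition, sem=sem)


def histograms_from_samples(samples: dict[str, list[np.ndarray]],
                            bin_edges=None) -> dict[str, list[FretHistogram]]:
    """Bin per-condition replicate efficiency lists into histograms."""
    return {
        cond: [build_histogram(vals, bin_edges, condition=cond, replicate=i)
               for i, vals in enumerate(reps)]
        for cond, reps in samples.items()
    }


def _bin_gaussian(edges: np.ndarray, mean: float, width: float) -> np.ndarray:
    """Fraction of a unit-area Gaussian falling in each bin."""
    sigma = fwhm_to_sigma(width)
    return np.diff(stats.norm.cdf((edges - mean) / sigma))


def mixture_curve(edges: np.ndarray, components: list[GaussianComponent],
                  amplitudes=None) -> np.ndarray:
    """Bin-integrated model histogram for a set of components."""
    if amplitudes is None:
        amplitudes = [c.amplitude for c in components]
    out = np.zeros(len(edges) - 1)
    for comp, a in zip(components, amplitudes):
        out += a * _bin_gaussian(edges, comp.mean, comp.width)
    return out


def _weights(hist: FretHistogram, count_floor: float) -> np.ndarray:
    # Counting-statistics weights: var(count) ~ count, floored so empty bins
    # still constrain the fit.  Replicate SEMs are too noisy at n_rep = 3 to
    # serve as weights directly.
    return 1.0 / np.sqrt(np.maximum(hist.frequencies, count_floor))


# Tiny ridge on the amplitudes of non-fixed components.  When a released
# component collapses onto the fixed closed-state peak the amplitude split is
# exactly degenerate; the ridge tie-breaks it toward the constrained peak
# while biasing well-determined amplitudes by well under 0.1%.
AMPLITUDE_RIDGE = 3e-3

_MU_BOUNDS = (-0.2, 1.2)
# widths narrower than one histogram bin are unphysical (instrument-limited)
_W_BOUNDS = (0.05, 1.0)


@dataclass
class _GlobalFit:
    """Internal result of a global mixture fit (variable projection)."""

    shapes: list[tuple[float, float]]          # (mean, FWHM) per component
    amplitudes: list[np.ndarray]               # per dataset, length k
    chisqr: float                              # weighted objective incl. ridge
    shape_stderr: list[tuple[float, float]]    # (se_mu, se_w); nan when fixed


def _assemble_shapes(theta, k, fixed):
    shapes, it = [], iter(theta)
    for c in range(k):
        shapes.append(fixed[c] if c in fixed else (next(it), next(it)))
    return shapes


def _profiled_amplitudes(datasets, shapes, fixed):
    """Optimal non-negative amplitudes for fixed shapes (weighted, ridged)."""
    k = len(shapes)
    pen = np.diag([0.0 if c in fixed else AMPLITUDE_RIDGE for c in range(k)])
    amps, residuals = [], []
    for edges, freq, wts in datasets:
        design = np.column_stack([_bin_gaussian(edges, m, w) for m, w in shapes])
        a_aug = np.vstack([design * wts[:, None], pen])
        b_aug = np.concatenate([freq * wts, np.zeros(k)])
        a, _ = optimize.nnls(a_aug, b_aug)
        amps.append(a)
        residuals.append(a_aug @ a - b_aug)
    return amps, np.concatenate(residuals)


def _fit_global(datasets, k, init_means, init_widths,
                fixed: dict[int, tuple[float, float]],
                seed=None, n_starts: int = 5,
                extra_inits: list[np.ndarray] | None = None) -> _GlobalFit:
    """Weighted global mixture fit by variable projection.

    The per-dataset amplitudes are linear parameters and are profiled out
    with non-negative least squares at every step, leaving a small bounded
    optimisation over the free component means and widths (multi-start with
    seeded jitters; ``fixed`` maps component index -> (mean, width) held
    constant).
    """
    rng = rng_from_seed(seed)
    free = [c for c in range(k) if c not in fixed]
    x0, lo, hi = [], [], []
    for c in free:
        x0 += [float(init_means[c]), float(init_widths[c])]
        lo += [_MU_BOUNDS[0], _W_BOUNDS[0]]
        hi += [_MU_BOUNDS[1], _W_BOUNDS[1]]
    x0, lo, hi = np.array(x0), np.array(lo), np.array(hi)

    def objective(theta):
        shapes = _assemble_shapes(theta, k, fixed)
        _, resid = _profiled_amplitudes(datasets, shapes, fixed)
        return resid

    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        jit = x0.copy()
        jit[0::2] += rng.normal(0.0, 0.05, size=len(free))
        jit[1::2] *= np.exp(rng.normal(0.0, 0.25, size=len(free)))
        starts.append(np.clip(jit, lo, hi))
    for ini in extra_inits or []:
        starts.append(np.clip(np.asarray(ini, dtype=float), lo, hi))

    best = None
    for x in starts:
        if len(x) == 0:   # every shape fixed: amplitudes only
            amps, resid = _profiled_amplitudes(datasets,
                                               _assemble_shapes([], k, fixed), fixed)
            return _GlobalFit(shapes=_assemble_shapes([], k, fixed),
                              amplitudes=amps,
                              chisqr=float(np.sum(resid ** 2)),
                              shape_stderr=[(np.nan, np.nan)] * k)
        try:
            res = optimize.least_squares(lambda t: objective(t), x,
                                         bounds=(lo, hi), x_scale="jac")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailureError("global mixture fit failed to converge")

    shapes = _assemble_shapes(best.x, k, fixed)
    amps, resid = _profiled_amplitudes(datasets, shapes, fixed)
    chisqr = float(np.sum(resid ** 2))

    # asymptotic SEs of the free shape parameters from the VARPRO Jacobian
    stderr = [(np.nan, np.nan)] * k
    try:
        jac = best.jac
        n_amp = sum(len(a) for a in amps)
        dof = max(1, jac.shape[0] - jac.shape[1] - n_amp)
        cov = np.linalg.pinv(jac.T @ jac) * (chisqr / dof)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
        for i, c in enumerate(free):
            stderr[c] = (float(ses[2 * i]), float(ses[2 * i + 1]))
    except Exception:
        pass
    return _GlobalFit(shapes=shapes, amplitudes=amps, chisqr=chisqr,
                      shape_stderr=stderr)


def _plain_rss(fit: _GlobalFit, datasets) -> float:
    """Unweighted data-only residual sum of squares of a global fit."""
    rss = 0.0
    for (edges, freq, _), amps in zip(datasets, fit.amplitudes):
        model = np.zeros_like(freq)
        for (m, w), a in zip(fit.shapes, amps):
            model += a * _bin_gaussian(edges, m, w)
        rss += float(np.sum((model - freq) ** 2))
    return rss


def _amplitude_nnls(hist: FretHistogram, components: list[GaussianComponent],
                    count_floor: float) -> tuple[np.ndarray, float]:
    """Weighted non-negative least-squares amplitudes for fixed shapes."""
    design = np.column_stack([_bin_gaussian(hist.bin_edges, c.mean, c.width)
                              for c in components])
    w = _weights(hist, count_floor)
    # ridge rows break exact degeneracy toward the first (closed) component
    pen = np.diag([0.0] + [AMPLITUDE_RIDGE] * (design.shape[1] - 1))
    a_aug = np.vstack([design * w[:, None], pen])
    b_aug = np.concatenate([hist.frequencies * w, np.zeros(design.shape[1])])
    amps, _ = optimize.nnls(a_aug, b_aug)
    resid = design @ amps - hist.frequencies
    return amps, float(np.sum(resid ** 2))


def _prune_insignificant(fit: _GlobalFit, datasets, fixed_high, seed,
                         alpha: float = 0.01) -> list[tuple[float, float]]:
    """Backward elimination of released components that do not improve the
    global fit significantly (partial F-test).

    When the data lack a state, its released Gaussian only absorbs noise; the
    drop in chi-square it buys is then compatible with its extra parameters
    and the component is pruned — its shape is replaced by the nearest
    retained component so the stage-3 amplitude ridge routes its weight
    there.  Components representing real states raise chi-square enormously
    when removed and are always kept.
    """
    shapes = list(fit.shapes)
    chisqr = fit.chisqr
    n_points = sum(len(freq) for _, freq, _ in datasets)
    n_data = len(datasets)
    active = [c for c in range(1, len(shapes))
              if shapes[c] != shapes[0]]      # released components
    while active:
        k_eff = len(shapes)
        dof = max(1, n_points - (2 * len(active) + k_eff * n_data))
        delta_p = 2 + n_data
        f_stats = {}
        for c in active:
            reduced = [s for i, s in enumerate(shapes) if i != c]
            means = [m for m, _ in reduced]
            widths = [w for _, w in reduced]
            r = _fit_global(datasets, len(reduced), means, widths,
                            fixed={0: fixed_high}, seed=seed, n_starts=1)
            f_stats[c] = ((r.chisqr - chisqr) / delta_p) / (chisqr / dof)
        c_min = min(f_stats, key=f_stats.get)
        if f_stats[c_min] >= stats.f.ppf(1 - alpha, delta_p, dof):
            break
        # prune: collapse onto the nearest surviving component by mean
        others = [i for i in range(len(shapes)) if i != c_min]
        nearest = min(others, key=lambda i: abs(shapes[i][0] - shapes[c_min][0]))
        shapes[c_min] = shapes[nearest]
        active.remove(c_min)
        keep = [shapes[i] for i in sorted(set(range(len(shapes))) - {c_min})]
        r = _fit_global(datasets, len(keep), [m for m, _ in keep],
                        [w for _, w in keep], fixed={0: fixed_high},
                        seed=seed, n_starts=1)
        chisqr = r.chisqr
    return shapes


def fit_staged_mixture(
    histogram_set: dict[str, list[FretHistogram]],
    alone_condition: str = "alone",
    n_components: int = 3,
    count_floor: float = 1.0,
    seed: int | None = 0,
) -> MixtureFit:
    """Run the four-stage constrained global fit on a condition set.

    ``histogram_set`` maps condition name -> replicate histograms on common
    bin edges; it must contain ``alone_condition``.  Returns the shared
    component shapes, per-replicate amplitudes per condition, per-stage RSS,
    and the stage-4 over-constraint check.
    """
    if alone_condition not in histogram_set:
        raise ProtocolError(f"histogram set lacks required condition {alone_condition!r}")
    conditions = list(histogram_set)
    averaged = {c: average_replicates(histogram_set[c]) for c in conditions}
    edges = averaged[alone_condition].bin_edges

    # Stage 1: single Gaussian on the 'alone' channel pins the closed peak.
    alone = averaged[alone_condition]
    ds1 = [(edges, alone.frequencies, _weights(alone, count_floor))]
    mode = alone.bin_centres[int(np.argmax(alone.frequencies))]
    r1 = _fit_global(ds1, 1, [mode], [0.25], fixed={}, seed=seed)
    mu_high, w_high = r1.shapes[0]
    rss1 = _plain_rss(r1, ds1)

    # Stage 2: global fit, high peak fixed, lower peaks shared.
    ds2 = [(edges, averaged[c].frequencies, _weights(averaged[c], count_floor))
           for c in conditions]
    init_means = [mu_high] + [mu_high - 0.17 * (i + 1) for i in range(n_components - 1)]
    init_widths = [w_high] + [0.18, 0.30][: n_components - 1]
    r2 = _fit_global(ds2, n_components, init_means, init_widths,
                     fixed={0: (mu_high, w_high)}, seed=seed)
    rss2 = _plain_rss(r2, ds2)

    shapes = _prune_insignificant(r2, ds2, fixed_high=(mu_high, w_high), seed=seed)
    order = np.argsort([-m for m, _ in shapes])
    components = [GaussianComponent(mean=shapes[i][0], width=shapes[i][1])
                  for i in order]

    # If a released component collapsed onto an earlier one (data lacking that
    # state), merge the shapes; the amplitude ridge then routes the weight to
    # the earlier component in stage 3 instead of splitting it arbitrarily.
    profiles = [_bin_gaussian(edges, c.mean, c.width) for c in components]
    for i in range(1, n_components):
        for j in range(i):
            cos = profiles[i] @ profiles[j] / (
                np.linalg.norm(profiles[i]) * np.linalg.norm(profiles[j]))
            if cos > 0.995:
                components[i] = GaussianComponent(mean=components[j].mean,
                                                  width=components[j].width)
                profiles[i] = profiles[j]
                break

    # Stage 3: shapes frozen, per-replicate amplitudes (weighted NNLS).
    condition_amplitudes: dict[str, np.ndarray] = {}
    rss3 = 0.0
    for c in conditions:
        amps = []
        for h in histogram_set[c]:
            a, r = _amplitude_nnls(h, components, count_floor)
            amps.append(a)
            rss3 += r
        condition_amplitudes[c] = np.vstack(amps)
    for comp, mean_amp in zip(components,
                              np.mean([condition_amplitudes[c].mean(axis=0)
                                       for c in conditions], axis=0)):
        comp.amplitude = float(mean_amp)

    # Stage 4: release the lower peaks to check for over-constraint.
    s4_means = [c.mean for c in components]
    s4_widths = [c.width for c in components]
    r4 = _fit_global(ds2, n_components, s4_means, s4_widths,
                     fixed={0: (components[0].mean, components[0].width)},
                     seed=seed, n_starts=1)
    rss4 = _plain_rss(r4, ds2)
    s4_shapes = sorted(
        [(m, w, se_m, se_w)
         for (m, w), (se_m, se_w) in zip(r4.shapes, r4.shape_stderr)],
        key=lambda t: -t[0])
    stage4_components = [GaussianComponent(mean=m, width=w) for m, w, _, _ in s4_shapes]
    consistent = True
    for comp, (m4, w4, m_se, w_se) in zip(components, s4_shapes):
        m_tol = max(2.0 * (0.0 if np.isnan(m_se) else m_se), 0.05)
        w_tol = max(2.0 * (0.0 if np.isnan(w_se) else w_se), 0.3 * comp.width)
        if abs(comp.mean - m4) > m_tol or abs(comp.width - w4) > w_tol:
            consistent = False
    if not consistent:
        warnings.warn("stage-4 released fit drifts outside stage-3 uncertainties; "
                      "the shared-shape model may be over-constrained")

    return MixtureFit(
        components=components,
        condition_amplitudes=condition_amplitudes,
        rss_per_stage={1: rss1, 2: rss2, 3: rss3, 4: rss4},
        stage4_consistent=consistent,
        stage4_components=stage4_components,
    )


def orientation_correct(condition_amplitudes, alone_amplitudes) -> np.ndarray:
    """Correct amplitudes for the ~50% of channels facing away from the motor.

    Half of the 'alone' population is subtracted from each condition and the
    remainder doubled: ``corrected_i = 2*(A_i - 0.5*alone_i)``.  Negative
    results are floored at zero with a warning.  Linear, and the identity on
    the 'alone' condition itself.
    """
    a = np.asarray(condition_amplitudes, dtype=float)
    alone = np.asarray(alone_amplitudes, dtype=float)
    if a.shape != alone.shape:
        raise InvalidInputError("amplitude vectors must have matching shape")
    corrected = 2.0 * (a - 0.5 * alone)
    if np.any(corrected < 0):
        warnings.warn("orientation correction produced negative amplitudes; floored at 0")
        corrected = np.maximum(corrected, 0.0)
    return corrected


def anova_amplitudes(replicate_amplitudes) -> tuple[np.ndarray, np.ndarray]:
    """Per-component mean and SEM of fitted amplitudes across replicates.

    Accepts either a (n_replicates x n_components) array — one condition —
    or a dict of such arrays keyed by condition; with several conditions the
    SEM uses the pooled residual mean square of the one-way layout for each
    component, SEM = sqrt(MS_within / n_replicates).  For a dict input the
    returned mean/SEM are dicts keyed the same way.
    """
    if isinstance(replicate_amplitudes, dict):
        groups = {k: np.atleast_2d(np.asarray(v, dtype=float))
                  for k, v in replicate_amplitudes.items()}
        if any(g.shape[0] < 2 for g in groups.values()):
            raise InsufficientDataError("each condition needs >= 2 replicates")
        n_comp = next(iter(groups.values())).shape[1]
        means = {k: g.mean(axis=0) for k, g in groups.items()}
        sems = {}
        ms_within = np.empty(n_comp)
        for c in range(n_comp):
            sse = sum(np.sum((g[:, c] - g[:, c].mean()) ** 2) for g in groups.values())
            dof = sum(g.shape[0] - 1 for g in groups.values())
            ms_within[c] = sse / dof
        for k, g in groups.items():
            sems[k] = np.sqrt(ms_within / g.shape[0])
        return means, sems

    mat = np.atleast_2d(np.asarray(replicate_amplitudes, dtype=float))
    if mat.shape[0] < 2:
        raise InsufficientDataError("at least two replicates required")
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    return mean, sem


def compute_anisotropy(I_par, I_perp, G: float = 1.0,
                       wavelengths=None, window=None) -> float:
    """Steady-state fluorescence anisotropy with G-factor correction.

    r = (I_par - G*I_perp) / (I_par + 2*G*I_perp).  With spectra
    (``wavelengths`` given) the anisotropy is computed per point and averaged
    over ``window = (lo, hi)`` nm.
    """
    ipar = np.asarray(I_par, dtype=float)
    iperp = np.asarray(I_perp, dtype=float)
    total = ipar + 2.0 * G * iperp
    if np.any(total <= 0):
        raise InvalidInputError("total intensity I_par + 2*G*I_perp must be positive")
    r = (ipar - G * iperp) / total
    if wavelengths is not None and window is not None:
        wl = np.asarray(wavelengths, dtype=float)
        mask = (wl >= window[0]) & (wl <= window[1])
        if not np.any(mask):
            raise InvalidInputError("emission window contains no spectral points")
        return float(np.mean(np.atleast_1d(r)[mask]))
    return float(r) if np.ndim(r) == 0 else r
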