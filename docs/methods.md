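# Methods

This note records the models the package implements, the choices made where
the underlying experimental protocol left the design open, and what the
synthetic-data tests do and do not demonstrate.

## Conventions

* **Widths are FWHM.** Every Gaussian "width" at the interface (component
  widths, the kinetic-simulation noise width) is a full width at half
  maximum; internally σ = width / (2√(2 ln 2)). Generator and fitter share
  the convention, so recovery tests are convention-invariant.
* **Units.** Concentrations in nM in the binding module, times in seconds,
  intensities in camera counts per frame, atomic distances in Å with
  lateral-gate summaries in nm.
* **Randomness.** Every stochastic routine takes an explicit seed and builds
  one `numpy` generator from it; nothing touches global state. Identical
  seed + parameters give bit-identical output, which the suite asserts for
  the full pipeline.

## Trace selection and efficiency estimation

A valid particle carries exactly one donor and one acceptor, certified by
sequential single-step photobleaching: one downward acceptor step, an
anti-correlated upward donor step within ±1 frame of it, and a later single
downward donor step. Donor-first traces are rejected (reason codes, not
errors), as are multi-step channels and traces without the anti-correlated
rise.

The step detector is iterative binary segmentation: a segment splits at the
least-squares single change point when the level change exceeds
`threshold` (default 4) × a robust noise SD (MAD of first differences
scaled by 0.6745·√2); minimum segment length 5 frames. It is deterministic
and agrees with an exhaustive single-change-point scan on single-step
traces, which the suite verifies. The anti-correlation criterion — donor
rise ≥ 30% of the acceptor drop — tolerates noise while excluding
uncorrelated events; both criteria are invariant under uniform intensity
scaling. Segment means exclude 2 frames at each boundary because the step
frame integrates both levels.

The efficiency E = 1 − (I_DA − I_bck)/(I_D − I_bck) needs no channel
sensitivity or quantum-yield corrections and is deliberately not clipped to
[0, 1]: noise legitimately scatters estimates outside the unit interval and
the histogram range (−0.2 to 1.2, 0.05 bins) accommodates that.

## The staged constrained global fit

Model curves are bin-integrated area-normalised Gaussians times an area
amplitude — not centre-sampled — so wide bins introduce no discretisation
bias. The four stages:

1. single Gaussian on the motor-free condition pins (μ, w) of the closed
   peak;
2. global three-Gaussian fit over all conditions with the closed peak fixed
   and the two lower peaks shared;
3. all shapes frozen; per-replicate amplitudes by weighted non-negative
   least squares;
4. the lower peaks released again; if the released shapes drift outside
   their asymptotic uncertainties the fit is flagged as over-constrained.

Numerical choices:

* **Variable projection.** Amplitudes are linear parameters, so they are
  profiled out by NNLS at every objective evaluation, leaving a bounded
  4-parameter optimisation over the free means and widths (trust-region
  least squares, Jacobian scaling, 5 seeded multi-starts). This is both
  faster and far more reliable than optimising shapes and amplitudes
  jointly: the joint problem has spurious basins that trap trust-region
  steps even on noiseless data.
* **Weights.** Per-bin weights are counting-statistics weights
  1/√max(count, 1). Replicate SEMs at three replicates are themselves
  ~50%-noisy and make poor weights; counting weights recovered the broad
  open component about twice as precisely in benchmark runs.
* **Amplitude ridge.** A tiny ridge (3×10⁻³) on the amplitudes of non-fixed
  components breaks the exact degeneracy that appears when a released
  component collapses onto the fixed closed peak, routing the shared weight
  to the constrained component. It biases well-determined amplitudes by
  well under 0.1%.
* **Component pruning.** After stage 2, each released component must justify
  itself by a partial F-test at α = 0.01 (backward elimination): a component
  whose removal does not significantly worsen the global fit is collapsed
  onto its nearest retained neighbour. On data genuinely containing three
  states the test never fires (removing a real component raises chi-square
  enormously); on data lacking a state it stops that state's Gaussian from
  absorbing noise.
* **Width bounds.** Fitted FWHMs are bounded below by one bin width (0.05):
  narrower features cannot represent a conformational state given the
  shot-noise-limited peak widths (≥ 0.16) and would only chase single-bin
  fluctuations.

**Estimator behaviour.** At the study's data size (three replicates of 200
molecules per condition, six conditions) the closed and part-open means are
recovered with SD ≈ 0.005 and negligible bias. The broad open component is
harder: its asymptotic SE is ≈ 0.023, and in roughly one seed in five the
global optimum sits on a secondary ridge near μ ≈ 0.40 with a narrower
width — a genuine feature of the likelihood at this sample size, not an
optimiser failure (the suite checks the optimum found beats the true
parameters in chi-square there). The acceptance script therefore reports
the **median** fitted means over seven independently seeded study sets,
which is robust to that heavy tail; single-set fits are what the unit tests
exercise.

## Orientation correction, ANOVA, anisotropy

Roughly half the reconstituted channels face away from the motor and can
never respond to it; their signature is the motor-free amplitude pattern.
The correction subtracts half of the "alone" amplitudes from each condition
and doubles the remainder — linear, the identity on the "alone" condition
itself, with negative results floored at zero under a warning. Amplitude
statistics across replicates use a one-way layout: SEM per component is
√(MS_within/n), which reduces to SD/√n for a single group. Anisotropy uses
the standard steady-state form r = (I∥ − G·I⊥)/(I∥ + 2·G·I⊥), averaged over
stated emission windows when spectra are supplied.

## SVD component counting

Histogram columns (one per condition × replicate) are area-normalised so
amplitude patterns, not molecule totals, drive the decomposition. The
per-entry noise SD σ is estimated from replicate scatter about condition
means (debiased for the subtracted mean). A component is significant when
its singular value exceeds 1.2 × σ(√bins + √columns) — the largest singular
value expected of a same-shaped pure-noise matrix (the random-matrix edge).
A global reconstruction-RMS criterion was rejected because it dilutes a
weak-but-real component's energy over every matrix entry and saturates;
the singular-value test detects exactly the component whose omission leaves
reconstruction error above what replicate scatter explains. `compare_k_fits`
complements it with residual sums of squares of k-Gaussian global fits to
the replicate histograms (shapes shared, amplitudes per replicate, closed
peak pinned by the motor-free condition); successive k are warm-started
from the k−1 solution, so RSS is non-increasing by construction.

## Two-state ratchet kinetics

The channel alternates between closed (high FRET, 0.76) and open (low FRET,
0.45). Exit from closed is ADP release (k_cat = 0.27 s⁻¹, rate-limiting);
exit from open is ATP hydrolysis and phosphate release (k_cleave =
11.5 s⁻¹), giving a stationary closed-state occupancy of
k_cleave/(k_cat + k_cleave) ≈ 0.977. Dwells are exact exponential variates
rounded **up** to the 1 ms grid (minimum one step), so recorded dwells sum
exactly to the discretised total time; the ≤ 0.5 ms rounding bias is
negligible against both rates. The trajectory starts closed (ADP-bound),
the state ADP release makes rate-limiting. Camera emulation adds Gaussian
noise per 1 ms step (σ from the 0.24 FWHM of the closed peak — noise is
added first, then averaged) and boxcar-averages over non-overlapping 200 ms
windows, so post-average noise SD is σ/√200. Dwell-rate recovery excludes
the censored first and last dwells; rate = 1/mean with SE = rate/√n. The
acceptance run uses a 6000 s trajectory (~1600 dwells per state, relative
SE ≈ 2.5%); simulation cost is negligible.

## Ensemble fits

The tight-binding quadratic is evaluated through the numerically guarded
discriminant and fitted with F0, Bmax, K_D floating and E0 fixed
(multi-start Levenberg–Marquardt; asymptotic SEs). Flat titrations return
Bmax ≈ 0 with `kd_identifiable = False` rather than an arbitrary K_D.
Exponential fits honour externally fixed rates (used when a contaminating
species' rate is known) and report t_1/2 by bisection on the fitted curve,
not the raw data, because individual rates of a poorly separated double
exponential are unstable while the half-completion time is not.

## Structure metrics

Geometry only: Euclidean Cβ–Cβ distances (Cα fallback for glycine, logged),
lateral-gate widths over the TM2/TM7 pairs 124/275, 127/278, 130/282
(channel numbering of the thermophilic complex) reported in nm, and minimum
side-chain heavy-atom distances. First model of a PDB file; alternate
locations resolved by highest occupancy, ties toward 'A'. All metrics are
rigid-motion invariant by construction and by test.

## What the synthetic data do and do not show

The generators reproduce the statistical structure the analysis assumes:
piecewise-constant bleaching traces with additive Gaussian detector noise,
Gaussian mixtures of efficiencies, exponential dwells, exact isotherms and
decays. The six-condition study set uses fixed mixing weights chosen to
mirror the described condition dependence — motor-free and ADP-bound
channels almost entirely closed, the ATP ground-state analogue (AMPPNP)
populating the open state, and ATP-turnover conditions populating the
part-open state — with 200 molecules per replicate, three replicates.

Not emulated: dye photophysics (blinking, spectral cross-talk), shot-noise
intensity statistics (noise is additive Gaussian; the real noise model is
unstated), raw TIRF images and spot extraction, and liposome occupancy
statistics. Passing tests therefore demonstrate correctness of the
analysis chain and its statistical behaviour under the assumed model, not
robustness to instrument artefacts those effects introduce.

## Problem sizes

Defaults were chosen as the sizes a desk-scale study of this system would
use: 200 molecules × 3 replicates per condition for histogram work, 600 s
simulated trajectories for histogram emulation and 2000–6000 s for rate
recovery, 20-point titrations, 50–100-run Monte-Carlo checks in the test
suite.
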