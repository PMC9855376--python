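# Methods

## The measurement being emulated

A single-molecule break junction (SMBJ) run repeatedly drives a gold tip
into a gold substrate until the current preamplifier saturates, then
retracts it at a constant speed while recording current at fixed bias,
stopping when the current reaches the preamplifier floor (~10 pA). With
thiolated DNA in the cell, a minority of retraction events trap a molecule
between the electrodes; those traces hold a conductance plateau at the
molecule's junction conductance before breaking down. All conductances are
handled dimensionlessly as G/G0, with G0 = 2e²/h computed from physical
constants (≈ 77.48 µS); plateau positions, spreads and noise are expressed
on the log10 scale ("decades").

The analysis chain is: screen traces for plateaus → accumulate the
selected traces' samples into a semi-log histogram → fit Gaussian peaks in
log scale → assign peaks to conformations → (optionally) track the
quadruplex/duplex peak-amplitude ratio across a concentration titration.

## Synthetic trace model

Each trace is sampled on a uniform distance grid
(retraction_rate / sampling_rate per sample; defaults 80 nm/s at 40 kHz,
i.e. 2 pm/sample) between a saturation ceiling and a noise floor.

* **Tunneling events** (probability 1 − p_junction): log10 G(d) =
  log10(ceiling) − β·d, truncated at the floor. β defaults to 6
  decades/nm, a typical vacuum-gap decay in aqueous SMBJ work.
* **Junction events**: a species is drawn from the capture weights (below);
  its plateau level is drawn from Normal(μ, σ_between) and its length from
  Normal(length_mean, length_sd) truncated > 0. The trace decays to the
  plateau, holds it for the drawn length, then decays to the floor; the
  trace ends at the first sample at/below the floor, clamped to it.
* **Plateau tilt**: real plateaus sag slightly as the junction is
  stretched; a plateau_slope (default −0.3 decades/nm) is applied
  *centred* on the drawn level, so the plateau's mean log-conductance
  equals the level and the tilt broadens peaks without biasing their
  centres.
* **Noise**: i.i.d. Gaussian noise (default 0.05 decades SD) is added to
  every sample in log space; samples are then clipped to
  [floor, ceiling], so the window-containment invariant holds exactly.
* **Floor and bias**: the bias is not a measured quantity here; the
  default 0.1 V is typical for SMBJ and makes the 10 pA floor equal
  1e-10 S ≈ 1.29e-6 G0, just below the analysis window. The floor default
  is derived from the bias at construction, so changing the bias moves the
  floor consistently.

Default plateau geometry (length 0.3 ± 0.1 nm, σ_between 0.15 decades,
noise 0.05 decades) was chosen once so that composite-histogram peaks come
out a few tenths of a decade wide, the visual width of published semi-log
SMBJ histograms.

### Capture model

No functional form for junction probability versus concentration is
established for this system; the generator adopts a compressive power law:
the weight of species *i* among junction events is
(affinity_i · c_i)^α, normalised, with α = 0.08 by default. The small
exponent is a modelling assumption, not a claim about the chemistry: it is
the regime in which a species at a 10⁻⁹ concentration ratio still forms
~18% of junctions, which is what lets a titration spanning ~16 orders of
magnitude of concentration ratio keep both peaks detectable. α is a
config knob (`capture_alpha`).

Parallel-topology quadruplexes get zero capture weight: with both thiol
linkers on one end they cannot bridge two electrodes. The environment
switch implements the potassium effect — under 100 mM KCl every
antiparallel quadruplex is converted to the parallel topology (hence no
junctions, no peak), and duplex species may carry a slightly shifted
KCl-specific plateau level (`mu_kcl`).

p_junction defaults to 0.125 so that, after screening losses, the
end-to-end selection fraction lands inside the 10–15% band observed in
these experiments.

## Trace screening

Two criteria, both evaluated over a log-conductance window (default
[−5.5, −1.0], below saturation and above the floor):

1. an OLS line fit of log10 G against distance; traces with RMS residual
   **below** `residual_threshold` are rejected (pure tunneling is an almost
   exact line);
2. the tallest bin of the per-trace histogram (same half-open binning as
   the composite histogram, default 40 bins/decade) must hold at least
   `amplitude_threshold` samples (a plateau concentrates samples into one
   bin).

The residual metric is fixed as RMSE in decades. The thresholds are not
physically derivable; they were calibrated once, in-repo, against the
generator defaults to `residual_threshold = 0.10` decades and
`amplitude_threshold = 15` counts. At these values the two populations are
cleanly separable: tunneling traces show residuals ≤ 0.056 decades and
spike counts ≤ 11, junction traces ≥ 0.06 / ≥ 6 with ≥ 98% joint recall,
giving a ~12.5% default selection fraction with a false-positive rate
indistinguishable from zero (and exactly zero when noise is disabled).

## Histogramming and peak fitting

The composite histogram sums per-sample bin assignments of all selected
traces over half-open bins (total counts = in-window samples, a conserved
quantity the tests check). Peaks are fit as a sum of k Gaussians in
(bin centre, count) space by nonlinear least squares (SciPy trust-region
with positivity/width bounds), initialised at the k most prominent local
maxima of the lightly smoothed counts separated by ≥ 0.5 decades; fewer
separable maxima than k is an error rather than a silent merge.

Selected traces contribute not only their plateau but also their
tunneling-decay segments, which deposit a nearly flat pedestal of a few
samples per bin per trace across the whole window. A **constant offset
term is therefore part of the default fit model**; without it one Gaussian
broadens to absorb the pedestal and two-peak centres are badly biased
(single-peak centres survive, but widths inflate). Fitted amplitudes are
heights above the pedestal. A Poisson-weighted objective
(`poisson_weighted=True`) and an offset-free model (`baseline=False`) are
available.

Repeat statistics follow the experimental convention: peak positions from
N independent measurements (seeded repeats) are matched by sorted order —
the optimal one-to-one matching for 1-D positions — and summarised as mean
± sample standard deviation on the linear G0 scale.

## Conformation assignment and titration

The default reference table carries the two single-conformation controls —
duplex 3.03e-4 G0 and G-quadruplex 3.77e-3 G0 — with a 0.35-decade
tolerance: wide enough to cover the observed spread of duplex
(1.6–3.4e-4 G0) and quadruplex (3.5–3.8e-3 G0) values, far below the
~1.1-decade separation between classes. Assignment is one-to-one, greedy
by log-distance, ties broken toward the lower-conductance reference.

The titration runs the full pipeline at each (c_quad, c_duplex) grid point
(default: 9 log-spaced points from 2 fM to 0.45 µM against a fixed
0.45 µM, both directions), averaged over 2 seeded repeats per point. A
peak counts as detected when its fitted amplitude exceeds 5× the Poisson
noise of a typical bin (5·√median nonzero count); a "5× the median count"
rule would be meaningless here because the median bin *is* the tunneling
pedestal. Stage failures at a grid point (e.g. nothing selected under
KCl) flag the point rather than aborting the grid.

## Determinism and seeds

Every stochastic component draws from a NumPy `Generator`. One master seed
deterministically derives per-repeat / per-grid-point seeds via
`SeedSequence.spawn` (all derived seeds < 2³¹), so ensembles are bitwise
reproducible across runs and the serialised pipeline report is
byte-identical under a fixed seed. The trace container format writes 9
significant digits with stable ordering, so serialisation is also
byte-deterministic.

## Problem sizes

Default analyses use 5000-trace ensembles (matching experimental practice);
the titration uses 2000–3000 traces per repeat per grid point, enough that
both peaks clear the detection criterion at every ratio while a full
two-direction grid completes in well under a minute per repeat set.

## What the generator does and does not emulate

Emulated: semi-log-linear tunneling decays; species-specific plateau
levels with between-trace spread; plateau length variability and tilt; the
preamplifier noise floor and saturation ceiling; junction formation rates;
concentration-dependent species capture; the KCl topology switch.

Not emulated: multi-molecule junctions and multi-step traces; distance
drift, snap-back and piezo nonlinearity; correlated (1/f) current noise;
conductance dependence on stretching beyond the linear tilt; binding
kinetics (the capture model is an equilibrium stand-in); any structural or
electronic-structure physics (no transport calculation links sequence to
conductance — plateau levels are inputs, not predictions). Passing tests
therefore demonstrate that the *analysis chain* recovers what the
generator put in under realistic trace statistics; they do not validate
the conductance values themselves, which enter as reference parameters.

## Known limitations

* The Gaussian-plus-constant model ignores the slight pedestal ramp near
  the window edges; with peaks ≥ 0.5 decades from an edge the induced
  centre bias is below the seed-to-seed scatter (~0.01 decades).
* The capture exponent α controls the shape of the titration curve; the
  package makes no claim that 0.08 matches the chemistry, only that the
  qualitative behaviour (both species detectable over a huge ratio range,
  amplitude ratio monotone in concentration ratio) is reproduced.
* `summarize_repeats` requires the same number of peaks in every repeat;
  repeats that lose a peak must be handled upstream (the pipeline reports
  them as such instead of summarising).
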