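# Methods

## Scientific setting

Lecithin-cholesterol acyltransferase (LCAT) esterifies cholesterol on HDL
particles. Small-molecule positive allosteric modulators (PAMs) bind its
membrane-binding domain (MBD) and shift it away from the lid that gates the
active site. In MD simulations this repositioning is captured by a single
scalar: the α-carbon distance between CYS50 and ASN65 of the MBD. The larger
the equilibrium CYS50–ASN65 distance a bound compound induces, the more it
activates the enzyme in vitro, and the relationship is well described by a
straight line over the activity range of known activators. `lcatpam`
implements the quantitative machinery around that observation: distance
extraction and summarization from trajectories, the linear
distance-to-activity calibration with prediction intervals, the staged
virtual-screen triage that precedes MD, the enzyme-kinetics workup of the
two fluorescence assays used for validation, and the ANOVA + Dunnett
statistics applied to triplicate parameters.

## Distance biomarker and summarization

Coordinates are held in ångström (PDB convention); distances are reported in
nm by default, with a unit tag on every series and summary, and
nm/ångström mixing is refused rather than silently converted. The metric is
the plain Euclidean CA–CA distance per frame; for single-atom groups this
equals the minimum inter-group distance of standard MD tooling.

Two summarization schemes reduce correlated trajectory data to mean ± SEM:

* **Block averaging** (`block_summary`): one long run is split into
  `n_blocks` contiguous blocks of equal frame count (default 10, the
  "1 µs split into ten 100 ns sequences" protocol); the SEM is the n−1
  sample SD of block means over √n. Remainder frames on non-divisible
  splits are assigned to the final block — documented rather than dropped.
* **Replicate analysis** (`replicate_summary`): several independent runs are
  each averaged over an analysis window and the SEM is taken across
  replicate means. The default window is the second half of each run (the
  "last 100 ns of 200 ns" protocol).

Windows are half-open `[t_start, t_end)` so "the last 100 ns" is
unambiguous; the helper used for "to the end" nudges the bound past the
final timestamp so the last frame is kept. SEM across replicates (rather
than pooling frames) is the deliberate choice: replicate means are the
independent observations; frames within a replicate are autocorrelated.

## Activity calibration

`ActivityCalibration` regresses activity (percent of the no-PAM control;
100% = control) on the mean distance by unweighted ordinary least squares.
Both axes carry SEMs in real data, but an errors-in-variables treatment
would add estimator variance that the few-point calibrations here cannot
support; inverse-variance weighting by the activity SEMs is available via
`weighted=True`. Predictions carry t-based prediction intervals on n−2
degrees of freedom, computed from the residual SE and the leverage of the
new point; a perfect-line calibration collapses the interval to the point
prediction. Ranking flags a candidate as a predicted activator when its
predicted activity reaches the control level (100%, configurable).

## Virtual-screen triage

Filters run in a fixed order: charge → mass window → docking score. A
compound failing several criteria is labelled by the first stage it fails;
the surviving count is order-independent. The mass window passes 100–600
g/mol inclusively (the protocol removes "below 100" and "above 600");
the score stage passes SP scores ≤ −7.0 (more negative = better). Charge
assignment at the prepared protonation state is upstream of this package;
records carry a precomputed boolean. Masses may be derived from Hill
formulas using IUPAC standard atomic weights. Manual scaffold-diversity
picking is replaced by a deterministic surrogate: best XP score per
diversity group, ties broken lexicographically — reproducible, and
documented as a surrogate rather than a reconstruction.

## Kinetics

Fluorescence is converted to rate as
`(signal − background) / standard-curve slope / time` (µM h⁻¹). The
standard curve is fitted with an intercept but only its slope is used;
background subtraction therefore stays explicit instead of being absorbed
into the intercept. Negative net signals clip to zero rate with a flag.

Michaelis–Menten fits use Levenberg–Marquardt least squares with
Vmax₀ = 1.2·max(v), Km₀ = the substrate level nearest half-max, relative
tolerance 1e-10, and standard errors from the Jacobian at the solution; a
Km at ≤1e-6 µM or ≥100·max(S) raises a boundary warning. Catalytic
efficiency is k_cat/K_m with k_cat = Vmax/[E]; the molar enzyme
concentration is a user input (converting a mass concentration needs the
enzyme's molecular weight), and all percent-change outputs are defined to
be independent of it. Percent changes vs. control follow the
round-half-away-from-zero-to-nearest-10% convention used when quoting
activity increases in prose; the raw value is available with
`round_to=None`.

Dose–response uses the 4-parameter logistic on log10 concentration.
Zero-dose wells inform the bottom initialization but are excluded from the
log-scale regression; the bottom is free by default with a `fix_bottom`
option. A response whose per-dose means span less than the effect
tolerance (5 percentage points by default) is flagged `no_effect` with an
undefined EC50 — the negative-control behaviour — rather than forcing an
unidentifiable fit. EC50 outside the tested range raises an extrapolation
warning. Triplicates are fitted per replicate and summarized as mean ± SEM
of parameters (one curve per assay run); a pooled fit sits behind a flag.

## Statistics

One-way ANOVA is followed by two-tailed Dunnett comparisons against the
designated control, with pooled within-group variance (homogeneity
assumed; a >10-fold variance ratio triggers an advisory warning). Adjusted
p-values come from the equicorrelated multivariate-t distribution evaluated
by scipy's seeded numeric integrator; the single-treatment case reduces
exactly to the pooled two-sample t-test and is computed in closed form.
Adjusted p-values are constrained to be at least the unadjusted t p-value,
which the mathematics requires and integrator noise could otherwise
violate at the 1e-3 level. Stars follow the strict thresholds *p<0.05,
**p<0.01, ***p<0.001. `per_stratum_comparisons` runs the ANOVA + Dunnett
pair independently within each stratum (each substrate-concentration
point, or each kinetic parameter), matching the per-point testing design.

## Synthetic data

The generators define the conditions under which the pipeline is validated:

* **Trajectories**: the CYS50–ASN65 distance follows a stationary
  Ornstein–Uhlenbeck process — the minimal stationary model with tunable
  mean, variance and correlation time — discretized exactly
  (`d_{t+dt} = µ + (d_t−µ)e^{−dt/τ} + σ√(1−e^{−2dt/τ})·z`), not by Euler
  stepping. Defaults: 2.0 nm mean, 0.1 nm SD, 5 ns correlation time, five
  replicates of 2000 frames at 0.1 ns — the shape of the replicate-MD
  protocol. Frames hold two pseudo-residues (CYS 50 at the origin, ASN 65
  on the x-axis), so rigid-body invariance tests can transform frames
  independently of the generator. What this does *not* emulate: real
  protein dynamics have multi-timescale correlations, rare pose
  transitions (the reorientation seen for glucose-binding compounds), and
  non-Gaussian excursions; passing tests demonstrate the correctness of
  the summarization arithmetic and its statistical calibration for
  stationary data, not robustness to metastable switching.
* **Kinetic plates**: well signal = background + slope·v(S)·time + Gaussian
  noise with SD a fraction of Vmax (2% default), triplicates, the
  DHE well concentrations (0, 6.4, 9.6, 14.4, 21.6, 32.5, 50.6 µM), a
  noiseless standard-curve block, and exact background wells. Generating
  truth defaults to the tabulated reference parameters (Vmax 8.66 µM h⁻¹,
  Km 11.59 µM). Real plates add pipetting error correlated within dilution
  series, fluorescence drift and inner-filter effects, none of which are
  modelled.
* **Dose–response**: 4PL truth at the titration concentrations
  (0.001–10 µM), default EC50 0.1 µM, top 250%, bottom 100%, Hill 1.
* **Compound libraries**: uniform masses over 50–700 g/mol (wider than the
  filter window so both tails are exercised), Bernoulli charges, Gaussian
  SP scores with correlated XP scores; expected stage counts are
  recomputed by direct enumeration, independently of the filter code.

All randomness flows from one integer seed through `SeedSequence`
spawning; identical specs and seeds give identical outputs.

## Problem sizes and numerical choices

The validation suite uses deliberately chosen sizes: 500 seeded
regressions (50 points each) for slope-recovery and interval-coverage
rates — 50 points keeps the t(n−2) pivot's 3-SE tail below 0.5%, so the
≥99% recovery criterion is meaningful; 2000 null simulations (6 treatments
× triplicates) for the familywise error rate, giving a ±0.015 band at
roughly three binomial SDs; 200 seeded datasets for Michaelis–Menten and
EC50 recovery under noise. Optimizer tolerances are 1e-10 (MM) and 1e-12
(4PL) on LM steps; grid-search-plus-polish oracles in the tests check the
fitted optima through an independent optimizer route.

## Known limitations

* The calibration is linear by construction and validated only within the
  distance range of the calibration compounds; extrapolation widens the
  prediction interval but the linearity assumption itself is untested
  outside that range.
* Dunnett p-values inherit scipy's integrator accuracy (~1e-3); tests and
  documentation use a 0.005 tolerance.
* The screen consumes precomputed docking scores and charge flags; no
  structural perception is performed.
* Absolute agreement with published fitted parameters cannot be checked
  without the underlying raw plates; the package validates by
  recovery-from-known-truth instead.
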