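# Methods

This note records the models implemented in `doughrheo`, the numerical
choices behind them, what the synthetic generators do and do not
emulate, and the known limitations.

## Squeezing-flow kinematics and sign convention

Lubricated squeezing flow compresses a cylindrical sample between
lubricated plates at constant platen speed, approximating frictionless
equibiaxial extension.  The classical formulas carry minus signs (the
height decreases), which would make compressive strain negative; since
every downstream regression uses magnitudes, the package stores
positive magnitudes throughout: ε_b = ½ ln(h₀/h_t), ε̇_b = v/(2 h_t),
η_b\* = σ/ε̇_b.  This is a pure convention with no effect on any slope
or index.

Units are SI internally (m, N, Pa, s); geometry is accepted in the
units instruments report (mm, mm/s) and converted once at the boundary.

Trace cleaning: samples before the force first exceeds a noise floor
(default 0.01 N) are treated as instrument settle and dropped, as are
samples below a height floor (default 2 mm, i.e. the protocol's 90 %
endpoint, beyond which lubrication typically fails).  Both floors are
parameters of `process_trace`.

## Interpolation at target deformations

Stress and rate are interpolated at grid deformations linearly in
(ε_b, ln σ) and (ε_b, ln ε̇_b).  For constant-speed kinematics
ln ε̇_b is exactly linear in ε_b (ε̇_b = v·e^{2ε_b}/(2h₀)), and for the
constitutive family σ = C·ε̇^m·e^{S·ε_b} so is ln σ, so log-space
interpolation is exact on the model class rather than second-order.
Targets outside a trace's observed strain range are flagged per target,
not raised.

## The strain-hardening cascade

1. per grid deformation (default 0.3–1.0 in steps of 0.1), ordinary
   least squares of log₁₀ σ on log₁₀ ε̇_b across the platen speeds
   (≥ 3 distinct speeds required; unreachable deformations are dropped
   with a warning);
2. each per-deformation line is evaluated at the target strain rate
   (defaults 0.01 and 1.00 s⁻¹, configurable).  Rates outside a
   deformation's observed span are extrapolated and flagged — the fast
   target genuinely lies above the slowest test's span, so the
   procedure implies extrapolation by construction;
3. the SHI is the OLS slope of ln σ (natural log) on ε_b over the
   grid; SHI > 1 sets the strain-hardening flag.

OLS is unweighted everywhere.  Base-10 logs are used for log-log fits
(slopes are base-invariant) and the natural log where the SHI's
definition prescribes ln σ.

On σ = C·ε̇^m·e^{S·ε_b} the cascade is exact: every per-deformation
slope equals m and the recovered SHI equals S to machine precision,
independent of speed set and grid.  This is the package's primary
oracle, and why the synthetic generator uses that family.

The strain-hardening criterion is implemented on the SHI itself
(slope of ln σ on ε_b at constant rate > 1); an alternative
double-logarithmic form of the criterion sometimes quoted in the
literature would use a different abscissa and is deliberately not used.

## Power-law fits and standard errors

Both G\*(ω) = A_f·ω^(1/z) and η_b(ε̇) = K·ε̇^(n−1) are fitted as
straight lines in log₁₀–log₁₀ space.  Linearisation is exact on the
model class (noise-free data give R²_adj = 1 identically), keeps the
estimator closed-form, and matches how such fits are usually reported;
the multiplicative (lognormal) noise model also becomes additive in
log space.  Standard errors: slope errors map directly (z via
δz = δslope/slope², n via δn = δslope); intercept errors map to the
prefactor by the delta method (δA = ln 10 · A · δintercept).

Frequency sweeps recorded in Hz are converted to angular frequency
ω = 2πf before fitting, since the power law is defined on ω.  A
`FrequencySweep(angular=True)` flag admits already-angular (or
deliberately raw-Hz) data; the choice shifts A_f by a factor
(2π)^(1/z) and leaves z unchanged.

## Error propagation

`propagate_error` implements first-order Gaussian propagation with
independent measurands: std² = Σᵢ (∂f/∂xᵢ)² stdᵢ².  Partials are
central finite differences with relative step 1e−6 (absolute floor
1e−12) so that f can be an arbitrary callable; covariance terms are out
of scope.  Against analytic partials the finite-difference results
agree to < 1e−6 relative on products, quotients, powers and logs.

## Fermentation models

dV_rel/dt is estimated with `numpy.gradient` (second-order central
differences in the interior, one-sided at the ends; exact on linear
trajectories).  The Bloksma rate divides by V_rel; the van Vliet rate
divides by 3(V_rel−1) and is genuinely singular at V_rel = 1, so such
points are flagged NaN rather than clipped — a trajectory legitimately
starts gas-free.  The algebraic ratio 3(V_rel−1)/V_rel between the two
models holds elementwise to derivative accuracy and is used as an
internal consistency check.

## Protein-network morphometrics

Binarisation defaults to a global Otsu threshold (a fixed threshold is
available); blank images yield an empty mask with a warning.  The mask
is thinned with a topology-preserving medial-axis skeletonisation.

Junction/endpoint classification required three robustness refinements
beyond naive 8-neighbour counting, all addressing artifacts of thinning
thick ribbons rather than real topology:

- terminal twigs of ≤ 3 px ending in a junction are pruned (corner
  artifacts of thinning; genuine branches are far longer than the
  strand width);
- pixels wedged entirely between junction candidates are absorbed into
  the junction cluster (the inner pixel of a diagonal staircase
  corner);
- an 8-connected cluster of ≥ 3-neighbour pixels counts as a junction
  only if it joins ≥ 3 distinct branch segments — a staircase corner
  of a diagonal line also produces ≥ 3-neighbour pixels but joins only
  two, and is a turn.

Skeleton length counts adjacent pixel pairs, diagonal steps weighted
√2.  Strand width is defined operationally as protein area divided by
total skeleton length — exact for a ribbon of constant width, and the
natural estimator when only a width "of a continuous strand" is
specified.  Vessel length is reported both as the per-image total
(headline) and as the mean junction-free segment length, since
published tables are ambiguous between the two readings; the printed
magnitudes (thousands of µm per image) indicate totals.

Lacunarity is the gliding-box statistic Λ(r) = 1 + var/mean² of box
mass over all fully contained r×r boxes (stride 1), averaged over
dyadic sizes {2, 4, …, ≤ min dim/2}.  Λ ≥ 1 always, Λ = 1 iff box mass
is constant; for an i.i.d. Bernoulli(p) mask Λ(r) = 1 + (1−p)/(p r²),
which the implementation reproduces within sampling error.  Note this
Λ ≥ 1 convention differs from the scaled lacunarity some vessel-analysis
GUIs print (values < 1), so absolute values are not comparable across
tools — percent changes are.

Because the segmentation/skeleton pipeline of the original GUI tooling
is unspecified, absolute metric values on real micrographs will differ
from that tooling; comparisons should be within-pipeline.  Pixel size
is a required input; a 225 µm field imaged at 1024² px gives the
default 0.22 µm/px.

## Synthetic data: what it emulates, and what not

- `simulate_lsf_trace`: constant-speed platen kinematics with stress
  from σ = C·ε̇^m·e^{S·ε_b} and mean-one lognormal multiplicative
  noise.  Defaults (C = 8000 Pa, m = 0.25, S = 2, five speeds 0.1–10
  mm/s, 20 → 2 mm, 45 mm plates) give biaxial viscosities of order
  1e4–1e6 Pa·s and SHI in the 1–3 band, the magnitudes typical of
  wheat dough.  The family is chosen to make the cascade exact, so
  parameter recovery is a sharp correctness test; it does not emulate
  thixotropy, slip, or lubrication failure.
- `simulate_frequency_sweep`: G\* = A_f·ω^(1/z) over log-spaced
  0.1–10 Hz with lognormal noise.  Real dough shows mild deviations
  from a pure power law; those are not modelled.
- `simulate_volume_trajectory`: exponential (constant Bloksma rate) or
  logistic (proofing-like rise to a plateau) V_rel(t), with defaults in
  the 1e−4–1e−3 s⁻¹ strain-rate decade.  No gas-cell coalescence or
  disproportionation.
- `simulate_network_image`: branched strand trees of straight segments
  on the 8 compass directions (segment length 16–30 px, width 3 px,
  branch probability 0.45 at ± 90°, ± 45° trunk turns), rasterised at
  30/200 background/foreground grey with Gaussian noise σ = 8.
  Segments sharing a node are constrained to ≥ 90° separation and all
  strands keep a clearance margin (width + 3 px), because closer
  geometry merges the rasterised ribbons and makes the recorded truth
  unrecoverable in principle.  Junction/endpoint counts and the
  noise-free mask are recorded as ground truth; topology recovery is
  exact on hundreds of seeds.  Real gluten networks have curved,
  variable-width, touching strands — the generator tests the
  morphometric machinery, not the difficulty of real segmentation.

Every simulator is a pure function of (parameters, seed) and
bit-reproducible.  Passing tests on synthetic data therefore
demonstrate correctness of the analysis chain on its model class and
calibrated behaviour under multiplicative noise; they do not certify
accuracy on real instrument traces or micrographs, which add the
unmodelled effects above.

## Problem sizes and defaults

Simulated traces default to 1000 samples per stroke; recovery studies
use 200 replicates for fit calibration and 100 images for topology
checks — sizes at which the reported medians and coverages are stable
to well under their tolerance margins.  The acceptance script mirrors
these sizes and derives all its randomness from the single `--seed`
argument.

## Known limitations

- No friction/lubrication correction in the squeezing-flow analysis;
  heavily under-lubricated tests violate the biaxial assumption.
- The SHI's slow-rate value involves flagged extrapolation below the
  slowest test's rate span at large deformations; this mirrors the
  standard procedure but inflates its uncertainty.
- Error propagation ignores covariances between measurands.
- Lacunarity and the other absolute morphometrics are
  convention-dependent; compare percent changes, not absolute values,
  across pipelines.
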