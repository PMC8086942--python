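# Methods

## Scientific setting

In the Fontan (total cavopulmonary) circulation the inferior vena cava
(IVC) and the hepatic veins (HV) drain through an extracardiac conduit
directly into the pulmonary arteries.  A balanced *hepatic flow
distribution* (HFD) — the share of hepatic-venous blood reaching the left
versus right lung — protects against pulmonary arteriovenous
malformations.  HFD is conventionally quantified by seeding tracer
particles uniformly over the Fontan conduit cross-section and counting
pulmonary arrivals, which silently assumes hepatic blood is uniformly
distributed over that cross-section.  Conduit flow, however, is laminar,
so the HV and IVC streams may stay segregated.  This package quantifies
(i) the degree of mixing between labelled HV and IVC streams at two
conduit cross-sections and (ii) the disagreement between the conventional
(conduit-seeded) and direct (HV-seeded) HFD estimates, on synthetic,
analytically controllable flow fields that stand in for patient-specific
CFD solutions.  Externally computed velocity fields can also be ingested
(legacy-ASCII VTK structured points) and run through the identical
analysis.

## Synthetic flow model

The conduit is a square duct, cross-section [-a, a]^2, length L, with
anatomical axes x (right to left), y (posterior to anterior), z (caudal to
cranial).  The velocity field is

    w(x, y, t) = w0 cos(pi x / 2a) cos(pi y / 2a) q(t)
    q(t)       = 1 + (P/2) sin(2 pi t / T)

together with a blinking transverse stirring field that alternates every
half-period tau between an x-shear u = eps w0 sin(pi y / a + phi) and a
y-shear v = eps w0 sin(pi x / a + phi'), with phases drawn once per
virtual patient.  Because u depends only on y, v only on x and w not on z,
the field is exactly divergence-free; q has unit mean so P is precisely
the pulsatility (Q_max - Q_min)/Q_mean.  eps = 0 yields perfectly
segregated parallel streams; eps > 0 produces chaotic transverse stirring
with known qualitative ground truth.

Default parameters (duct units: lengths in units of a, times in seconds):

| parameter | default | meaning |
|---|---|---|
| a | 1 | duct half-width (unit of length) |
| L | 20 | duct length; axis transit takes 2 cardiac cycles |
| w0 | 10 a/s | peak axial velocity |
| T | 1.0 s | cardiac period |
| n_steps | 100 | flow time steps per cycle |
| P | 0.55 | conduit pulsatility (measured conduit range 0.53-0.66) |
| eps | 0.15 | stirring amplitude, fraction of w0 |
| tau | 0.5 s | blink half-period |
| s | 0.5 | LPA share of pulmonary outflow |
| Q_IVC, Q_HV | 3.0, 1.5 l/min | cohort-mean caval and hepatic flows |
| n_hv | 7500 | HV particles released per time step |

Flow rates enter only through the released particle ratio
n_IVC = round(n_hv Q_IVC / Q_HV) and the cohort generator (Q_IVC ~
N(3.0, 0.7), Q_HV ~ N(1.5, 0.6) truncated positive, s ~ U(0.3, 0.7),
eps ~ U(0, 0.3)).  HV inflow is modelled as labelled rectangular
sub-regions ("ostia") of the caudal release plane, with particles
apportioned by area (largest-remainder rounding) and placed uniformly per
region; the IVC occupies a separate labelled region.  The default
geometry puts two HV ostia in the posterior half and the IVC anteriorly;
ostia areas and placement are free parameters of the virtual patient.

The pulmonary split is represented kinematically: a threshold x_split is
solved (bisection on the quadrature of the time-mean axial flux, relative
tolerance 1e-8) such that the flux fraction with x > x_split equals s;
particles exiting the cranial end are classified LPA/RPA by their exit-x
against this threshold.  For the product-cosine profile the closed form
x_split = (2a/pi) asin(1 - 2s) provides an independent oracle used in
tests.

## Particle tracing

Pathlines integrate dx/dt = v(x, t) with classical RK4, `substeps`
integrator substeps per flow time step.  The blinking regime is frozen per
substep at the substep midpoint: the stirring field is piecewise constant
in time, and evaluating a stage exactly on a regime switch would otherwise
degrade the scheme to first order at switches.  Blink half-periods should
remain integer multiples of the substep for the same reason (all defaults
satisfy this).  Step-halving then moves cranial crossing coordinates by
< 1e-4 a in stirred fields (verified in tests), so production runs use
1-2 substeps per time step where the default of 10 would be wasteful;
the tests state the substep count they use.

Plane transections are detected per substep segment by linear
interpolation in z, only in the caudal-to-cranial (+z) direction (the
synthetic field has w >= 0, so conduit flow never reverses; retrograde
crossings in external fields are ignored as delivered flow is what is
counted).  A crossing is assigned to the time step containing the
segment's end sample; a sample exactly on the plane counts once.  Repeated
crossings of one pathline are counted per event.

Particles terminate on outlet exit (z >= L, exit position interpolated to
the outlet plane), on leaving the cross-sectional domain, or at the
tracking horizon.  The stirring field does not vanish on the side walls,
so wall escape is genuine advection in this model; escaped particles are
clamped to the wall, flagged `out_of_domain`, excluded from all counts and
reported (a warning fires above 1%).  Under strong stirring this loss is
substantial (tens of percent) — see Limitations.

A fused single-pass numba kernel implements the RK4 substep for the
synthetic duct field; it is bit-compatible with the generic
field-interface path (cross-checked in the suite) and exists purely for
throughput.  External (VTK-interpolated) fields always use the generic
path.

## Mixing quantification

Per the release schedule, n_hv HV particles (plus the proportional IVC
count) are released every time step for five cardiac cycles; transections
with the caudal plane (default z = 0.1 L, just above the HV/IVC
confluence) and the cranial plane (0.9 L, just below the pulmonary
bifurcation) are binned by time phase of the fifth cycle, by quadrant
(left/right x anterior/posterior, boundaries to the positive side) and by
source label.  For each phase and quadrant with HV fraction f_s against
the cross-section fraction f_g, the mixing index is the tent ratio

    M = min(f_s / f_g, (1 - f_s) / (1 - f_g)),

which is exactly 1 when the quadrant reproduces the global ratio and
exactly 0 when the quadrant is single-label.  Phases where a quadrant is
empty or the cross-section is single-label are undefined and excluded
(and counted).  The cross-section M of a phase is the
transection-count-weighted mean over defined quadrants (unweighted
available); M_average is the arithmetic mean over defined phases.
Categories: [0, 0.1) none, [0.1, 0.3) poor, [0.3, 0.5) mild, [0.5, 0.7)
moderate, [0.7, 0.9) good, [0.9, 1] uniform (half-open on the left; the
verbal ranges overlap at the edges so a convention was required).

Finite transection counts bias M_average downward by approximately
2.25 E|f_s - f_g| per phase (the tent's mean slope at f_g = 1/3), i.e.
O(1/sqrt(count per quadrant)); comparisons between configurations should
therefore hold the release count fixed.

## HFD quantification

Three seeding strategies are compared under one velocity field and equal
per-step release budgets, released every time step of one cardiac cycle
and tracked for 5-12 cycles with early stop once 99% of particles are
resolved: direct HV seeding (area-proportional over the ostia; a
flux-weighted option exists for sensitivity analysis), and uniform
unlabelled seeding over the caudal or cranial conduit cross-section (the
conventional method).  HFD = 100 P_LPA / (P_LPA + P_RPA) over resolved
particles; unresolved particles (still active at the horizon, or lost
through a wall) are excluded from the denominator and always reported.
With eps = 0 the expected direct-method HFD is the analytic area fraction
of the ostia lying left of x_split (streamlines are straight), giving an
exact recovery target within the binomial sampling interval.

## Agreement statistics

Method agreement across a cohort uses the classical panel: paired t-test;
Bland-Altman mean difference with limits of agreement (mean +/- 1.96
sample SD); intraclass correlation, two-way mixed effects, single measure,
absolute agreement (the standard form for a fixed set of measurement
methods; the consistency variant is available); and the mean absolute
difference with a +/- 1.96 SEM interval, where the SEM is that of the
absolute differences.  M_average across the four quadrants is compared by
one-way repeated-measures ANOVA (subjects as blocks) with Tukey HSD post
hoc tests on the studentized-range distribution using the RM residual
mean square.  t-tests, Pearson correlations and distributions come from
scipy; ICC and the RM-ANOVA are computed via pingouin and cross-checked
against the mean-squares formulas in the suite.  Zero-variance degenerate
inputs return flagged limit values (p in {0, 1}, ICC NaN) rather than
raising, so cohort loops never abort.

## Reproducibility

All stochastic stages draw from per-stage substreams of the
configuration's single seed (stage name hashed into a SeedSequence), so
identical configurations give byte-identical outputs and stages can be
re-run in isolation.  Pipeline runs write a manifest with the
configuration hash, seed, per-stage runtimes, warnings and SHA-256 of
every output file.

## What the synthetic data do and do not emulate

Emulated: labelled HV/IVC co-flow in a conduit, laminar parabolic-like
profiles, pulsatile waveforms with the measured pulsatility, a prescribed
pulmonary flux split, tunable transverse mixing spanning segregated to
strongly stirred, per-time-step particle release schedules and the full
counting machinery.  Not emulated: patient geometry (curvature,
non-circular lumina, the actual bifurcation), secondary flows driven by
that geometry, non-Newtonian rheology, respiratory modulation, and
vessel-wall compliance.  Passing tests therefore validate the
*measurement machinery* (tracing, transection counting, the index, the
HFD estimators, the statistics) and its analytic ground-truth behaviour —
not the physiological magnitudes of any real cohort, which require
patient-specific CFD input (ingestable via the VTK reader).

## Limitations

* The blinking stirring field does not satisfy no-slip on the side walls,
  so strong stirring expels a large fraction of particles, which are
  terminated and excluded.  Long-residence survivors concentrate near the
  stirring field's node lines, which places the two labels in distinct
  structures; as a consequence the cycle-averaged cross-section mixing
  index saturates around 0.85-0.9 at the cranial plane even under the
  strongest stirring examined — the "uniform mixing" bin (> 0.9) is at
  the very edge of what this mechanism can produce.  This mirrors, in
  exaggerated form, the physical observation that wall-bounded laminar
  stirring homogenizes slowly.
* Mixing is assessed at quadrant scale only; finer-scale segregation is
  invisible to the index.
* The kinematic outlet-split model routes particles by a single exit-x
  threshold; it conserves the prescribed flux split but has no pulmonary
  geometry.
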