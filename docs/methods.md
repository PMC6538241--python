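# Methods

This note documents the models, algorithms and numerical choices behind
`discmech`, and what its verification suite does and does not demonstrate.

## Simulated motion-segment mechanics

### Constitutive law for cyclic curves

The loading limbs of the simulated force-displacement (and torque-rotation)
curves follow a **logistic-blended trilinear stiffness law**.  The local
stiffness is

k(x) = k_nz + (k_c − k_nz)·σ(s·(c − w − x)) + (k_t − k_nz)·σ(s·(x − c − w)),

where σ is the logistic function, `c` the neutral-zone (NZ) centre, `w` its
half width, `k_nz`, `k_c`, `k_t` the NZ, compressive-flank and tensile-flank
stiffnesses and `s` the transition sharpness (1/mm or 1/deg).  The response
is its exact integral (softplus form), so the true NZ region, NZ stiffness
and flank stiffnesses are known in closed form — the reason this law was
chosen over tracing representative experimental curves.  The 10–90% width
of one blending transition is `ln(81)/s`.

Hysteresis is modelled as a constant response offset between the
sweep-toward-tension and sweep-toward-compression limbs (the simplest form
that produces a closed loop); viscoelastic rate dependence, creep and
preload transients are deliberately not modelled.  Noise is additive i.i.d.
Gaussian on the measured channel only — the primary axis is servo-
controlled and treated as exact — matching the behaviour of
displacement/rotation-controlled test rigs.

The displacement sweep is a cosine in time (uniform sampling, default
400 samples/cycle, 20 cycles at 0.1 Hz), sized by numerically inverting the
response law so the loading limbs reach exactly the protocol's effective
stress limits (+0.25 / −0.50 MPa) times the disc cross-sectional area
(default: circular, 20 mm diameter, 314.16 mm²).  Torsion sweeps ±4° with
the clockwise/counterclockwise limb stiffnesses independently settable.

Default truth parameters are representative of an intact bovine caudal
segment: axial NZ stiffness 25 N/mm, compressive flank 220 N/mm, tensile
flank 120 N/mm, NZ length 0.6 mm, hysteresis 12 N; torsion 300/320 N·mm/deg
flanks, NZ 40 N·mm/deg over 2°.  Transition sharpness defaults (100/mm
axial, 25/deg torsion) keep the blend a small perturbation of the trilinear
law — the 10–90% transition is ~7–9% of the NZ length — so "the NZ
boundary" remains a meaningful concept; much softer blends make the plateau
interior curvature-dominated and the truth NZ ill-defined.

### Failure ramps

Compression-to-failure is a monotone 2 mm/min displacement ramp whose
stress rises smoothly (sin² toe) to a known peak, drops by a prescribed
fraction over a short displacement window, and then either **rebounds**
(herniation: the extruded nucleus unloads partially and stress re-rises as
the endplates approach) or declines without recovery (endplate fracture).

### Endplate profiles and cohorts

Endplate pairs are point polylines with parabolic convexity bulging into
the disc; the gap is constructed so its exact lateral average equals the
requested mean height, and digitization is emulated by seeded jitter of the
sampling abscissae.  The cohort generator draws per-specimen percent
changes ~ Normal(mean%, SD%) applied multiplicatively to intact baselines;
its default exercise reproduces a +6.96 ± 5.93% compressive-stiffness
change distribution at the observed defect-group scale.

## Analysis algorithms

### Cycle segmentation

Cycles are delimited by extrema of the primary channel (not by nominal
frequency), so records with drift still segment correctly; record
boundaries count as extrema of the appropriate sign.  A trailing partial
cycle is rejected unless the closing peak recovers ≥ 90% of the opening
amplitude, in which case the previous complete cycle is used.  Sign
convention: tension and counterclockwise positive; all stiffnesses are
reported as positive magnitudes.

### Limb stiffness

Each loading limb spans a full extreme-to-extreme sweep, so "top 20% of the
loading-portion points" is ranked by load in the limb's own direction
(most negative force for the compressive/clockwise limb, most positive for
tensile/counterclockwise), rounded up to at least 3 points, then fitted by
ordinary least squares.

### Neutral zone

The NZ search runs over the loading traversal spanning both limbs, with
each candidate region confined to a single limb:

1. **Seed**: OLS slope of every contiguous 15-point window (rolling-sum
   formulation, O(n)); the seed is the window of minimal |slope|.  Ties are
   broken by the window whose centre is nearest the response zero-crossing,
   then by lowest start index.
2. **Expansion**: alternate sides, adding one point at a time; an expansion
   is accepted while the refitted standard error stays within 10% of the
   seed window's.  A side that fails may be retried after the other side
   grows (the refit changes), so the search stops only when neither side
   can be extended.
3. The NZ length is the primary-axis extent of the accepted region; the NZ
   stiffness is the magnitude of its refitted slope.

Two numerical choices matter and are configurable:

- **Expansion statistic** (`se_kind`): the default is the regression's
  *residual* standard error.  The slope standard error is offered as an
  alternative but behaves pathologically as a stopping statistic with a
  fixed baseline: it scales as 1/√Sxx and therefore *falls* as the window's
  x-spread grows, so under measurement noise the 10% bound never trips and
  the "NZ" swallows the entire limb (≈350% stiffness error at 1%-of-range
  noise in our experiments).  The residual SE stays flat inside a straight
  region and jumps at a stiffness transition, which is the behaviour the
  stopping rule needs.
- **Baseline floors**: the seed SE is floored at (a) a robust ambient-noise
  estimate, median|Δ²y|/(0.6745·√6) — second differences cancel locally
  linear trends — and (b) a measurement-resolution floor, default 0.1% of
  the response range (representative of load-cell readout accuracy).
  Without (a), a seed window whose local noise happens to fit unusually
  well stops the expansion immediately (a noisy straight line would return
  a 15-point NZ instead of the whole line); without (b), noise-free records
  sit at float-rounding SE and can never expand.

**Known bias**: because the stopping rule reacts only after the residual SE
has grown 10%, the accepted region systematically (i) stops a fraction of
a transition width short of the plateau edge on noise-free data — so the
recovered NZ length is accurate to about one transition width per boundary —
and (ii) admits a few transition points under noise, biasing NZ stiffness
upward; at 1%-of-range force noise the median NZ-stiffness error is ≈15%
while both limb stiffnesses stay within ≈2–4%.  Users comparing groups
should rely on the paired intact/treated normalization, which cancels most
of this bias.

### Geometry and failure

Disc height is the mean vertical (axis-aligned) separation of the two
polylines, linearly interpolated on a dense common grid (1000 points,
configurable) over their lateral overlap, times the mm/pixel scale; mean
*normal* distance is deliberately not used since disc height is defined
along the spinal axis.  Cross-sectional area is circular from one diameter
(caudal discs are near-circular) or elliptical from two.  Height loss uses
the pre-test radiograph for the strain denominator.

The failure peak is the first local stress maximum followed by a ≥10%
relative drop before the stress next exceeds that maximum (the operational
replacement for the visual/video confirmation used in the laboratory);
stress is pre-smoothed by a centred 5-sample moving mean (1 disables) and
peaks below 10% of the record's stress maximum are ignored, since relative
drops are meaningless near zero load.  Mode classification — rebound above
5% of peak after the drop ⇒ herniation, otherwise endplate — is a
curve-shape heuristic and is flagged as such in every result.

### Study pipeline

`run_study` is a pure function of (design, protocol, seed): per specimen it
generates and analyzes intact axial + torsion records, applies the group's
truth perturbation, re-generates and re-analyzes, normalizes treated/intact
per parameter (ratios and percent change are both emitted; a zero intact
value marks that ratio undefined without failing the specimen), simulates
the radiographic height measurement, and runs the terminal failure ramp on
the treated state only, matching the experimental sequence.  Group
summaries report mean ± sample SD (SD undefined at n = 1).  Inferential
statistics (ANOVA, post-hoc tests, outlier removal) are intentionally out
of scope — the summary table is the hand-off to any statistics package.

## What the verification shows — and does not

The acceptance statistics (see `scripts/acceptance.py`) are computed on
synthetic data whose truth is known exactly.  Problem sizes were chosen so
the whole suite runs in seconds on one CPU: 200 curves for the seed-window
oracle, 50 randomized truths per channel for zero-noise recovery, 100 seeds
at the 1%-noise operating point (50 per level for the monotonicity sweep),
50 ramps per failure mode, n = 10 for the injected-effect cohort and
n = 10 000 for the percent-change convergence check.

Passing them demonstrates that the algorithms recover what they are defined
to recover under the stated noise model.  It does **not** demonstrate
performance on real laboratory records, which contain viscoelastic drift,
preload transients, quantization, and curve shapes outside the trilinear
family; nor can the heuristic failure-mode call be validated against video
ground truth here.  The NZ algorithm settings (15-point window, 10% SE
growth) originate from calibration against manual observer determinations
on laboratory curves, which cannot be re-derived from synthetic data; they
are exposed as parameters (`--window`, `--se-growth`) rather than re-tuned.

## Open choices resolved

- Sampling rate of the test system is not standardized; 400 samples/cycle
  is the configurable default (each limb holds ≥ 100 points, comfortably
  above the 15-point window).
- Torque range is read from the loading limbs' endpoints by default;
  `torque_range_limb="unloading"` swaps the traversal.
- The normalization scale (ratio vs percent of intact) is display
  convention; both are emitted.
- Units are fixed throughout: mm, N, MPa, degrees, N·mm, N·mm/deg; all
  pixel→mm conversion happens at the geometry I/O boundary.
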