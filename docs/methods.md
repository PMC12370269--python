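# Methods

## Shape representation and file dialect

All surfaces live on a cylindrical lattice: `n_slices` horizontal slices
(slice 0 distal-most, axial heights in mm strictly increasing) each sampled
at `n_theta` equal angles, storing the surface radius in mm. The default
lattice (90 slices × 120 angles, 3° spacing) satisfies the clinical sampling
convention of at most 3° angular spacing on at least 90 slices. θ = 0 is
anterior; θ increases toward the lateral side of a *right* limb, and left
limbs are mirrored on alignment (θ → 360 − θ) so all internal processing
uses a single right-limb frame. The z origin is the distal end.

Scans are persisted in an AAOP-style plain-text dialect (header line,
dimensions, side, landmark records, then one line per slice). This dialect
is this package's own: it is *AAOP-style*, documented in
`socketgen.aop_io.write_aop`, and makes no claim of byte compatibility with
commercial CAD exports, whose record layout is not public. Round-trip
fidelity (read∘write identity to 1e-6 mm) is what the toolkit guarantees
and tests.

Meshing closes the sampled side wall with triangle-fan caps at both ends,
giving a watertight 2-manifold with 2·n_theta·(n_slices−1) + 2·n_theta
triangles. Mesh volume and watertightness are computed with trimesh; STL
bytes are written directly (fixed zero header) so identical inputs give
identical files. The polygonal volume underestimates the smooth solid of
revolution by a factor sin(Δθ)/Δθ ≈ 1 − Δθ²/6; at 1° sampling this is
5 × 10⁻⁵, well inside the 0.1% tolerance used in the geometry checks.

## Statistical shape model

Correspondence is carried by the lattice itself: after alignment
(mirror → rotate the patellar-tendon landmark to θ = 0 → zero the distal
end → resample to the reference slice/angle counts over the scan's own
length), equal grid indices mean equal proportional anatomical position.
No nonrigid registration is performed — the cylindrical sampling already
provides a shared parameterization, and rotation by whole grid steps is
exact (an integer column roll), which the alignment tests exploit.

Because slices are index-matched proportionally, overall limb length would
otherwise vanish from the model; it is appended as one extra scalar column
to the PCA data vector, so the model spans size as well as shape. PCA is
computed by thin SVD of the centered data matrix on raw radii in mm
(covariance, not correlation): modes and mode scores stay in mm, directly
comparable with rectification magnitudes. The retained mode count is either
requested explicitly or chosen as the smallest count reaching a cumulative
eigenvalue fraction (default 0.95); the number of modes the original
clinical model retained is not known, so this is exposed as configuration.

## Rectification model

Each of the 7 local features is a spatial template: a separable raised
cosine in (wrapped angular distance, axial distance) with value 1 at the
anchor landmark and exactly 0 outside its half-width/half-height support.
Bilateral features (paratibial, supracondylar) are single scalars whose
template is the pointwise maximum of the two anchor bumps; the distal-end
build is an axial cap profile (weight 1 at the distal end across all
angles). Default footprints, configurable per call:

| feature            | half-width | half-height |
|--------------------|-----------:|------------:|
| patella tendon bar | 25°        | 15 mm       |
| paratibial         | 20°        | 40 mm       |
| fibula head        | 20°        | 20 mm       |
| distal tibia       | 25°        | 20 mm       |
| anterior tibia     | 15°        | 60 mm       |
| supracondylar      | 30°        | 20 mm       |
| distal end (cap)   | —          | 25 mm       |

These footprints are plausible clinical defaults, not measured values;
every numeric test controls its own kernel layout.

A socket is `s · (limb + Σ_f m_f K_f)` with `s = √(1 + v)`: scaling radii
by s multiplies the enclosed volume of the capped solid exactly by s²
(a linear scale in x and y only), so v is the signed volume-change
fraction. Carves are constrained ≤ 0, builds ≥ 0, |v| < 0.5. The scale is
applied *after* the local offsets; fixing this order is what makes
extraction well-posed.

Extraction inverts the map by alternating (a) a bounded-variable least
squares fit (scipy `lsq_linear`) of the kernel fields to the de-scaled
difference `socket/ŝ − limb`, each coefficient constrained to its feasible
sign, and (b) a volume-matching update `ŝ ← √(V_socket / V(limb + Σ m̂ K))`.
The fixed point converges in a handful of iterations (tolerance 1e-12 on
s) and recovers noiseless designs to machine precision — also for the
default overlapping footprints, since the templates are linearly
independent; the overlap bound asserted in tests (≤5% relative error) is
deliberately conservative. Magnitudes below 1e-12 are snapped to zero so
exact round trips report exact zeros.

## Design evidence model

Per feature f, an independent Bayesian linear regression of the extracted
magnitude on: intercept, standardized age and time since amputation,
gender (reference: man, the majority class), reason for amputation one-hot
(reference: infection/diabetic foot, the most common cause), and the
standardized leading mode scores. Conjugate normal–inverse-gamma prior:
zero-mean ridge with unit prior precision on standardized columns
(1e-6 on the intercept, i.e. effectively unpenalized) and a weak
Inv-Gamma(1e-3, 1e-3) variance prior. Posteriors are closed-form
(multivariate t for β, Student-t posterior predictive), which keeps the
pipeline deterministic; the closed form is cross-validated against a long
ensemble-MCMC run in the test suite. Independence across features is the
simplest faithful structure; a multivariate (correlated-feature) extension
would slot behind the same interface.

Point predictions are clipped to each feature's feasible sign range;
predictive intervals are reported *unclipped* so they remain honest about
the model's uncertainty near the boundary. Clipping at prediction rather
than in the likelihood keeps the model linear-Gaussian; when the training
magnitudes sit well inside their sign ranges (as clinical rectifications
do) the approximation is excellent, and the parameter-recovery tests use
exactly that regime so credible-interval coverage reflects the inference
rather than boundary misspecification.

Standardization constants are computed once at fit time and stored, so the
predict-time encoding is identical by construction; an unseen category at
predict time maps to the reference level with a logged warning.

## Synthetic data: what it emulates and what it does not

`generate_limb` builds a radius field from a linearly tapered profile
(taper = distal/proximal radius ratio), a rounded distal cap over the
bottom quarter (bulbosity 1 = no narrowing), an elliptical cross-section
factor (1 + e·cos 2θ), Gaussian bumps (SD 12° × 12 mm) at the nine
canonical landmark sites, and optional low-order Fourier surface noise.
Landmark sites are fixed fractions of limb length at fixed angles (e.g.
patellar tendon at 0.85 L anterior, fibular head at 0.80 L, 100° lateral),
snapped to the nearest grid node so bump peaks are exact at the landmark.

Cohort covariates mirror the demographic structure of a UK limb-fitting
population: 16/17 men, age normal(63, 14) clipped to [30, 90] years, time
since amputation lognormal with median 4 years, amputation reasons in
proportion 6:4:3:3:1:1:1 (infection/diabetic foot, dysvascularity, trauma,
critical limb-threatening ischemia, sepsis, neuropathy, osteomyelitis),
activity levels mostly A2–A3. Shape parameters are uniform over plausible
transtibial ranges (length 130–220 mm, proximal radius 45–62 mm, taper
0.65–0.95) with a weak configurable covariate coupling (default: older
age → slightly more cylindrical; longer time since amputation → slightly
slimmer). All values are set once as defaults and fully configurable.

The expert rule (`ExpertRule.default()`) uses intercepts of −3 to −4 mm
for carves, +2.5 to +5 mm for builds and −5% volume, small covariate and
shape effects (±0.3–0.5 mm per SD), and 0.5 mm feature noise (0.01 for the
volume fraction) — typical rectification depths with a realistic scatter.

What the generator does **not** emulate: scanner noise and mesh artefacts,
soft-tissue mechanics, non-smooth or free-form rectifications, per-side
asymmetric paratibial/supracondylar work, and any nonlinearity in expert
practice. Passing tests therefore demonstrate that the pipeline recovers a
*linear* expert policy from smooth parametric limbs — the intended
algorithmic contract — not that it matches any individual clinician on
real scans.

Comfort scores are simulated on a 0.5-point grid (clipped to [0, 10]) with
a shared within-subject component (correlation 0.7) between the two
sockets of a pair; the 0.5 resolution is an inference from the granularity
of reported score differences, and both it and the correlation are
configurable.

## Trial statistics

The Wilcoxon signed-rank test drops zero differences (the original
zero-handling rule; the variant is an explicit argument), uses
tie-averaged ranks, and computes the two-sided exact p by dynamic-
programming convolution over the doubled-rank multiset whenever ≤ 12
nonzero differences remain (exact rational arithmetic, so ties cost
nothing), otherwise a tie-corrected normal approximation. The normal
deviate Z is always computed and feeds the standard effect size
r = |Z|/√n — the usual convention for this statistic. Bootstrap CIs are
percentile intervals of the sample median, seeded and vectorized.

The noninferiority sample size iterates n upward, evaluating the power of
the one-sided paired t-test (reject H0: mean difference ≤ −margin) from
the noncentral t distribution with noncentrality (Δ + margin)/(σ_d/√n).
The population comfort-score SD is interpreted as *per condition*, so the
within-pair difference SD is σ·√2 under independence; with margin 1.21,
σ = 1.2, α = 0.05 this gives n = 19 at power 0.9 (power 0.8955 at n = 18,
0.9104 at n = 19) — the interpretation consistent with the published
design; treating σ as the difference SD would give a much smaller n. Pair
classification against the margin treats the boundary |d| = 1.21 as
"the same" (inclusive).

## Numerical choices and problem sizes

- Alignment interpolation is linear in z and in wrapped θ; rotation by
  whole grid steps and mirroring are exact index permutations.
- Eigenvalue/mode sign is fixed only up to ±; tests compare by |cosine|.
- Extraction tolerances: 1e-12 on the volume scale fixed point, ≤ 50
  iterations, 1e-12 zero-snap on magnitudes.
- Over-carving (non-positive socket radius) raises an error naming the
  dominant carve and grid location rather than clamping silently.
- Simulation sizes in the test suite are desk-scale defaults: the
  end-to-end check trains on 120 synthetic limb–socket pairs (the
  historical archive held 163) and evaluates 200 held-out patients;
  credible-interval coverage uses 200 replicate fits at n = 500; the
  sample-size cross-check uses 50,000 Monte-Carlo trials; bootstrap
  coverage uses 1,000 simulated samples × 2,000 resamples.

## Known limitations

- The brim is a single horizontal trim height, not a 3D contour.
- Paratibial and supracondylar rectifications are bilateral scalars;
  per-side magnitudes would need a kernel-spec split (supported by the
  template machinery but not exposed as a default).
- The evidence model is linear with independent features and sign-clipping
  at prediction; truncated likelihoods or multivariate residual structure
  are out of scope.
- The AAOP-style dialect is internal; importing real clinical exports
  would require a format bridge.
- Mode-score predictors are those of the synthetic shape distribution;
  on real scans the number of informative modes, and hence the regression
  dimensionality, would differ.
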