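# Methods

This note documents the models behind `bgvbq`, the defaults that matter,
and what the synthetic phantom does and does not establish.

## Signal model and estimators

The forward model for the weighted volumes is the steady-state spoiled
gradient echo. Two amplitude forms are implemented: the exact form
`A sin(a)(1−E)/(1−cos(a)E)` with `E = exp(−TR·R1)`, and the rational
small-angle/short-TR approximation `A·a·TR·R1/(a²/2 + TR·R1)`; echo decay
multiplies either by `exp(−TE·R2*)`. MT-weighted volumes always use the
rational form with the per-excitation saturation δ added to the
denominator, because the MT-saturation estimator inverts exactly that form
and no closed steady state with an MT pulse is available. Consequently the
noiseless rational-mode round trip (synthesis → estimation) is exact to
machine precision — this is a designed property used as a test anchor, not
a claim about scanner data. Synthesizing in exact-SPGR mode instead leaves
the known small-angle bias: over R1 ∈ [0.5, 1.5] s⁻¹ at the default
protocol the R1 error stays below 1.5%, which the tests verify against the
closed-form forward evaluation.

Estimation details:

- R2* uses ordinary least squares on log signals. The default fits the
  eight PDw echoes only and extrapolates each contrast to TE = 0 with its
  own slope; a joint mode (one common slope, per-contrast intercepts) is
  available since which echoes fed the published R2* maps is not specified.
- Flip angles are converted to radians at protocol load; all formulas work
  in radians and seconds. B1 enters only as the effective flip `a = f·α`.
  The optional residual MT-saturation correction
  `δ·(1−0.4)/(1−0.4·f)` is off by default: when the supplied B1 map is the
  true one, the effective-flip inversion is already exact, and the
  empirical correction is intended for the case where δ was computed with
  nominal angles.
- Invalid voxels (non-positive signals, vanishing denominators, negative
  rates) become NaN and leave the shared mask; downstream extraction and
  statistics skip them.
- Smoothing offers plain Gaussian convolution (σ = FWHM/2.355 per axis)
  and the tissue-weighted variant G(w·m)/G(w) with the quotient masked
  where the smoothed weight drops below 0.05. The pipeline defaults do not
  smooth before extraction — parcel means over homogeneous phantom regions
  would be unaffected — but the operation is exposed and tested because
  voxel-wise analyses of real maps use it at 6 mm FWHM.

## Phantom

The atlas is a 48×56×48 grid at 1 mm isotropic resolution: a bilateral
tripartite seed nucleus of 36 voxels per hemisphere (three 12-voxel slabs —
motor posterolateral, associative central, limbic anteromedial), six
125-voxel circuit-partner blocks per hemisphere (posterior putamen and
thalamus: motor; dorsal pallidum and caudate: associative; anterior putamen
and ventral pallidum: limbic), six cortical target slabs (M1, SMA, superior
frontal, middle frontal, anterior cingulate, orbitofrontal) plus
hippocampus and amygdala blocks, and a brain filler region. Regions are
axis-aligned blocks; only adjacency, sizes and circuit membership are meant
to be realistic, not shapes or cortical folding.

Between-subject covariance follows a single-factor Gaussian model per
(circuit, parameter): region value = μ + λσz_circuit + √(1−λ²)σε, so the
cross-region correlation of two regions in one circuit converges to
λ_a·λ_b. The magnitude of shared variation within a circuit is not an
empirical estimate — no published value exists — so λ defaults to 0.7
within circuits and 0 across circuits, chosen once as a value that makes
within-circuit covariance clearly detectable at n = 101 without being
degenerate. Seed-subregion population means and SDs default to the
published subregion table (MT in %, R1 and R2* in s⁻¹); partner and
cortical regions carry plausible grey/deep-grey values fixed in
`DEFAULT_REGION_PARAMS`. Within-region voxel texture is Gaussian with SD
2% of the region mean; acquisition noise is additive Gaussian with SD 0.5
signal units against a TE=0 amplitude of roughly 80 (SNR ≳ 150), small
enough that the log-linear R2* fit's noise bias is negligible relative to
the 3·SD/√n acceptance band. Noise is Gaussian rather than Rician: at
these SNRs the difference is immaterial and the estimators assume no noise
floor. Age (uniform 40–71 years) and sex (Bernoulli, 64/101 female) are
generated with zero effect on tissue values by default; an optional age
slope exists to exercise covariate adjustment.

Fiber pathways are capsule-shaped tubes along polyline centerlines; voxels
inside a tube carry the local tangent and the tube's volume fraction (two
slots per voxel, a third overlap is an error). Two geometric rules keep
the default phantom clean. First, inside the seed nucleus a tube paints
only voxels of its own source subregion — a seed voxel's orientations
represent that voxel's efferents, and without this rule a tube hugging one
slab would recruit its 1-voxel-distant neighbours. Second, the segments
past the first bend are wider (2.8 mm vs 2.0 mm radius) so that
streamlines launched off-axis survive the 45° elbows; near the seed the
narrow radius keeps the three class pathways disjoint. Each subregion
connects to one primary cortical target of its class (M1, superior
frontal, anterior cingulate); the remaining targets exist with zero
default connectivity, which is sufficient for class-level aggregation.

## Tracking

The engine follows the reference probabilistic-tractography conventions:
nearest-voxel orientation lookup with continuous positions, per-step
compartment choice proportional to volume fractions, angular Gaussian
perturbation (SD = dispersion, standing in for the sampled orientation
posterior of a fitted diffusion model — fitting that posterior from raw
DWI is out of scope), sign alignment with the previous direction, and
termination on mask exit, missing orientations, or cosine between
successive directions below the curvature threshold (0.2 ≈ 78.5°).
Tracts launch bidirectionally from uniformly jittered start points inside
each seed voxel (5,000 per voxel by default); a tract counts toward a
target if any point of either propagation enters it, with no early
stopping, and each target at most once per tract. Orientations are axial:
the engine canonicalizes the stored sign before perturbing, which makes
counts exactly invariant to flipping every vector in the field.

One behavioural subtlety matters for interpreting fractions: the
compartment is re-drawn at every step, so a voxel holding two strongly
bent orientations ends a fraction of streamlines by the curvature rule
rather than splitting them binomially. The branch-ratio tests therefore
construct bifurcations where geometry guarantees a single draw at the
branch voxel; real branch voxels sit between these idealizations.

## Parcellation

Raw counts are summed into class maps before z-scoring (the alternative —
z-scoring per target, then summing — is rejected because normalization is
applied to the three built class maps). Z-scores use the population-SD
convention (divide by N), fixed here since no convention is published;
constant maps are flagged degenerate and zeroed. Winner-takes-all stores
both the subtracted exclusive values e_c = z_c − Σ_{c'≠c} z_{c'} and the
labels; for any number of classes the argmax of e_c equals the argmax of
z_c (the subtraction adds a class-independent constant), so both readings
agree and both are emitted. Exact ties (measure-zero with real counts)
stay unassigned and are excluded from seed-value extraction. The bipartite
variant merges limbic and associative z maps by voxel-wise mean, keeping
the merged map on the same scale as the motor map. Group parcels average
subject z maps voxel-wise on the shared grid — phantom subjects need no
spatial registration.

## Covariance statistics

Seed values are parcel means pooled across hemispheres (a per-side mode
exists; the published choice is ambiguous). The design is
[seed, age centered, sex, intercept] with the contrast on the seed column.
Fits are per-modality OLS; the block-diagonal multi-modality structure is
provided because it reproduces the separate-fit betas exactly, and the
implementation asserts that equivalence on every call rather than assuming
it. Per-block REML nonsphericity estimation is not replicated — with
per-modality OLS and per-modality variance the inference is the separate
analysis, which is the documented justification for the concatenated
design in the first place.

Family-wise error control replaces random-field theory (whose smoothness
estimation is meaningless on piecewise-constant phantoms) with the
max-statistic permutation test: the seed regressor is residualized against
the nuisance columns (Freedman–Lane), permuted, and the maximum |t| over
the search mask builds the null; corrected p = (1 + #{maxT_b ≥ |t|}) /
(n_perm + 1), 1,000 permutations by default. This is a deliberate
methodological substitution with its own calibration test: under a λ = 0
null the family-wise error rate over 200 simulated cohorts at α = 0.05
falls within [0.02, 0.08]. Bonferroni is available as a second method;
survival is boundary-inclusive (a voxel exactly at α survives). An
auxiliary uncorrected p < 0.001 trend mask is always emitted. Peaks are
reported per 26-connected cluster of surviving voxels in world mm.

The covariance calibration and detection studies sample voxel matrices
directly from the cohort model (region value + voxel noise) rather than
rendering and re-fitting MRI volumes for hundreds of cohorts; estimator
exactness is established separately by the recovery study, so the direct
path changes nothing statistically while keeping the suites tractable.
The end-to-end pipeline (`bgvbq run`) does propagate fitted-map values
into its covariance stage.

## Subregion statistics

The three-subregion comparison is a one-way repeated-measures ANOVA with
subject as blocking factor, F on (2, 2(n−1)) degrees of freedom — subjects
contribute all three subregions, so the repeated-measures form is the
defensible reading; an independent-groups option exists for comparison.
Pairwise contrasts are two-tailed paired t-tests reported at raw p with no
multiplicity adjustment, and summary tables use the sample-SD (n−1)
convention. Degenerate inputs (zero within-subject error, zero-variance
differences) are flagged rather than silently propagated.

## Study scales and seeds

The seeded experiments in `bgvbq.study` use: 101 map subjects and 13
tractography subjects (the two-cohort structure of the source design), 200
streamline samples per voxel for parcel derivation (the parcel is already
exact at dispersion 0, where the acceptance pipeline derives it — this
isolates map-recovery error from parcellation error), 200 null cohorts ×
200 permutations for FWE calibration, and 100 replicates for the subregion
ordering study. A single root seed fans out to per-stage integer seeds via
`SeedSequence`, so stages are independently reproducible and all results
are bit-identical for a fixed seed.

## Limitations

Phantom regions are homogeneous blocks: there is no partial voluming, no
cortical folding, no susceptibility gradients, and no spatial registration
step — passing tests demonstrate the correctness of the estimators,
tracker, parcellation and inference machinery under the stated generative
model, not robustness to the artifacts of real acquisitions. The
streamline dispersion model is a single global angular SD, not a fitted
orientation posterior. Group analyses assume a shared grid. The
exact-SPGR forward mode exists only for PDw/T1w; MT-weighted synthesis is
rational-only by construction.
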