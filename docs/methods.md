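# Methods

## The data model

An individual's moveable digit is recorded as a dorsal profile projected
onto its output-lever reference axis `L2M`: 18 stations, equally spaced
from the digit tip (station 1, pinned at the origin) to the condyle
(station 18 at `x = L2M`), with signed heights in µm relative to the
axis. Equal spacing is the registration that makes profiles comparable
across species after scaling to a common `L2M`; it is also what gives
the contrast centres their station interpretation. Raw drawn polylines
are standardized by linear interpolation at the 18 stations
(`standardize_profile`), which is idempotent on already-standard input.

Angles are degrees in every file and user-facing output, radians
internally. Station indexing is 1-based everywhere, matching the
anatomical numbering x₁…x₁₈ — slope angle `phi[k]` (0-based array) is
the increment ending at profile station k + 2.

## Closed-form chelal geometry

`VR = L1U/L2M` is the chelal velocity ratio (ideal mechanical
advantage). Input-force proxies assume either pennate muscle packing
(`F1P = k_p·CHI·CLI`) or circular packing (`F1C = k_c·CHI²`); output
forces premultiply by VR and the two assumptions are averaged. The
proportionality constants default to 1: the analysis only ever uses
force ratios and orderings, never absolute newtons. The tip diameter at
δ µm behind the point is `2δ·tan(tip_angle/2)`; taking that diameter as
the depth of the dentition base plate inverts the saw-depth relation
`W ≈ base/(1 − 1/b)` to the ventral-curvature estimate
`b = W/(W − base)`. The lever classifier calls class 3 (cutting) for α
above a configurable threshold, default 90°: typical crushing designs
sit around 90° with cutting taxa elevated, but no universal numeric
cutoff exists, so the threshold is configuration, not doctrine.
The tip-force proxy `VR·CHI²` is provided for per-individual plots of
`(tip diameter)⁴` against load; note that the flexural-rigidity argument
behind it is stated both as `∝ 1/d⁴` and as `F2_tip ∝ d⁴` in the
literature this follows — the implementation exposes the `F2 ∝ d⁴`
relation actually used in the regression displays.

## The contrast battery

Profiles are reduced to 17 slope angles φ. The battery consumes the
first nine (stations 2–10, the tooth row): one breasting contrast
`a = (1,1,1,−2,−2,−2,1,1,1)/√18`, four banded six-station module rows
`b1–b4` scaled 1/√12, and seven second-difference rows `c1–c7` scaled
1/√6. The scalings make the twelve scalars comparable (each scaled row
has unit sum of squares). Contrasts are applied to φ (the angle
transform of the raw slopes g): angles are bounded and scale-free under
joint µm rescaling of x and y, and every row sums to zero so a constant
slope offset cancels. Sign convention: negative scalar = apparent peak
(tooth), positive = gullet. Structurally the b rows are binomial
combinations of adjacent c rows (`b_k = c_k + 3c_{k+1} + 3c_{k+2} +
c_{k+3}` unscaled), which the suite verifies as a regression test.

Species calls use a null band `± t(df, 0.975)·s/√n` around zero, with
`s` the pooled one-way-ANOVA residual SD per contrast across all taxa
(one shared grey zone per contrast, the display convention the analysis
mirrors); per-taxon bands and a Bonferroni correction across the twelve
contrasts exist behind flags but are off by default, since no
multiple-testing correction is applied in the source workflow.
Replicate samples of one species that call opposite band sides flag a
contrast as under-dispersed (`replicate_consistency`); the package
reports the flags and leaves any widening to the analyst — no automatic
inflation factor is defensible without a model of between-sample
variation. A caller-supplied tooth-row end index below station 10
attaches a `short_tooth_row` warning flag rather than an error: the
comparison may still be wanted, but the contrast inputs extend past the
mastication surface.

## Ω matrices

A cohort's Ω is the averaged SSCP of its height vectors over stations
2–18 (the pinned tip is excluded to keep full rank; 20 individuals >
17 coordinates). SSCP is about zero, not the cohort mean: profiles are
registered to a common origin and axis, so the raw cross-products carry
the mean shape as well as its variation; a mean-centred variant and the
n−1 divisor are available behind flags for sensitivity analysis. If a
degenerate cohort breaks positive-definiteness, a diagonal jitter of
1e−8 × trace/dim is added and recorded on the result. Replicate
samples merge by the Riemannian (Fréchet) consensus — the geodesic
midpoint for two inputs.

## SPD geometry

The affine-invariant metric `d(A,B) = ‖log(A^{−1/2}BA^{−1/2})‖_F` and
geodesic `γ(t) = A^{1/2}(A^{−1/2}BA^{−1/2})^t A^{1/2}` are computed via
eigendecompositions of symmetrized inputs with eigenvalues floored at
1e−12 × the largest; every log/exp/power output is re-symmetrized.
These guards let the pipeline survive condition numbers of 1e8 (a
stress fixture in the suite) — the regime where naive implementations
of interpolation and distance routines break. Geodesics are discretized
at m = 201 parameters; point-to-geodesic distances scan the
discretization and refine with a bounded scalar minimization between
the best sample's neighbours (tolerance 1e−6 in t). Whether the
original analyses used true orthogonal projection or an
endpoint-constrained distance is not recorded; the refined minimum over
the full segment is this package's choice. The Fréchet mean iterates
the tangent-space average from the arithmetic initialization,
converging when the tangent-mean norm drops below 1e−10 (cap 200
iterations; non-convergence is flagged, not silently accepted).
Relative eigenvectors of a pair (A, B) are the eigenpairs of
`A^{−1/2}BA^{−1/2}` sorted by descending eigenvalue and mapped back
through `A^{1/2}`, giving one loading per measurement position;
eigenvalue ties at 1 (B = A) are flagged degenerate.

## TRANSECT

dsigma is the mean affine-invariant distance between independent
replicate cohorts of the same species; the critical (on-transit) radius
is 1.645·dsigma, the one-sided 95% normal quantile on that noise scale.
Endpoint selection takes the maximal remaining pairwise distance. This
rule is the package's reconstruction: it is the only simple selection
consistent with a strictly decreasing sequence of extracted path
lengths, which the extraction then guarantees on any input. Members
(distance ≤ critical) and endpoints are removed after each path —
membership is always judged among taxa *remaining* at that stage — and
leftover taxa are singletons. Ties in the maximal distance break
lexicographically (within 1e−12 relative, since exact float ties do not
occur) and are logged on the result. Taxa on a path are ordered by
their nearest-point parameter t*.

## Manifold summaries

MDS is classical (Torgerson) scaling — deterministic, and exact on
Euclidean-realizable inputs — rather than a stress minimiser; the
negative-eigenvalue mass is reported and flagged above 50%. Sign
convention: the first label's coordinates are made nonnegative. PGA
log-maps all matrices to the tangent space at their Fréchet mean, where
the affine-invariant inner product is Frobenius, and takes the SVD of
the centred tangent vectors. Single-link clustering delegates to the
standard linkage algorithm; groups cut at the critical value are
provably the connected components of the thresholded distance graph,
and merge heights equal sorted minimum-spanning-tree edge weights —
both are oracle tests in the suite. Dendrograms export as ultrametric
Newick trees.

## Synthetic cohorts

`SpeciesTemplate` emulates what the analysis assumes about real
cohorts: 20 adult females per sample; a tip wedge dipping to a
mastication plateau ~7 µm below the axis (giving a derived tip angle
near 53°, in the observed range); a logistic ascending-ramus rise to
the basal height after the tooth row ends at station 10 (e_index,
allowed 8–12); optional breasting swell and local Gaussian asperity
modules (positive amplitude = tooth); and i.i.d. Gaussian station noise
of SD 1.5 µm on a default `L2M` of 170 µm (station spacing 10 µm).
AR(1)-correlated and heavy-tailed noise exist behind flags; the true
within-species station covariance of real material is unknown, so
independent stations are the default. Companion measures derive from
the template (VR 0.5, CHI/CLI as fractions of L2M) with 3%
multiplicative jitter. Replicate templates are sampled twice
independently, exactly as duplicate field samples would be.

What the generator does *not* emulate: digitization error correlated
along the drawing, allometry within a cohort, asymmetric or discrete
(rather than smoothed Gaussian) teeth, and between-sample ecological
variation beyond fresh noise draws. Passing recovery tests therefore
demonstrates that the estimators recover the structure they model, not
that real material satisfies that model.

Profile-level templates cannot be planted exactly on an affine-invariant
geodesic (a cohort's Ω is approximately μμᵀ + σ²I, and that family is
not a geodesic), so transect ground truth uses `spd_community`: taxa
planted in commuting (diagonal-log) SPD coordinates — where geodesics
are exact log-space segments — with symmetric tangent noise of scale
τ = 0.02 per cohort. The planted layout puts the main pair 10 critical
radii apart, the midpoint member's noise displacement near 0.4 radii,
the second pair 4 radii long and 3.5 radii off the first geodesic, and
the singleton 2.6 radii off the second geodesic: every margin is ≥ 3
noise SDs, so recovery failures are rare but not impossible — which is
what the 45-of-50-seeds acceptance bound reflects.

## Problem sizes and numerical checks

The default verification runs use: 1000 random SPD pairs (dim 2–17) for
the distance closed form at 1e−8; 100 geodesic speed checks at 1e−6; 50
seeds of the planted six-taxon transect community; 100 seeds of
three-taxon contrast communities (20 individuals each) for
sign-recovery and the flat-cohort coverage rate; and 30 random ≤8-taxon
fixtures for the exact single-link/MST identity. A genuinely flat,
noise-free cohort yields exactly all-level calls (zero scalars, zero
band); under station noise each call is a two-sided 5% test, so the
level-call rate on featureless cohorts is checked against a binomial
envelope around the nominal 95%, not against "always level", which no
correct implementation could deliver.

## Known limitations

* Transects are geometric paths in Ω space, not phylogenies; the method
  cannot distinguish reversion from independent reappearance.
* No Procrustes superimposition: registration is entirely by the
  L2M-axis convention, so axis-location error propagates into heights.
* Contrast centres assume the tooth row reaches station 10; species
  with short tooth rows are flagged, not rescaled.
* The lever-class threshold is a configuration default, not an
  empirical boundary.
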