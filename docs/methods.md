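# Methods

## Estimators

**Univariate K.** For n particle coordinates x_i inside a rectangular window
of area A, K(r) = A n⁻² Σ_{i≠j} w_ij 1(‖x_i − x_j‖ ≤ r) with an inclusive
indicator, Euclidean distances, and the isotropic edge weight w_ij: the
reciprocal of the fraction of the circumference of the circle centered at
x_i with radius ‖x_i − x_j‖ that lies inside the window. The weight is
computed in closed form for a rectangle from the per-edge exterior arcs
2·arccos(d_e/r) with right-angle corner overlaps removed by
inclusion–exclusion; circles that exit through two *opposite* edges (only
possible when r exceeds half the window span, i.e. never on the default
1 µm² window with the 240-nm grid) fall back to uniform sampling of 4,096
circumference angles. Pair weights are evaluated only for pairs with
d ≤ max(r), and K over the whole grid is accumulated by sorting pair
distances and cumulative-summing weights, making a 1,000-simulation
envelope on a 250-point pattern a sub-second operation. The transform
L(r) − r = √(K(r)/π) − r is zero under CSR, positive for clustering.

**Bivariate K.** With n_b big-gold and n_s small-gold points,
K_bs sums over ordered (big, small) pairs with the weight centered on the
big point, K_sb symmetrically with centers on the small points, and
K_biv(r) = (n_b + n_s)⁻¹ [n_b K_sb + n_s K_bs], which is exactly invariant
under channel relabeling. L_biv(r) − r is the same transform.

**Radius grid.** 1–240 nm in 1-nm increments by default; any strictly
increasing positive grid is accepted.

## Monte-Carlo standardization

Envelopes are *pointwise* per-radius quantiles (numpy's interpolated
order-statistic quantile) over seeded null simulations, not global
max-deviation bands: standardized values are read at "the corresponding
value of r". The univariate null is binomial CSR conditioned on the
observed count n — each image's envelope reflects its own labeling count —
at level 0.99 with 1,000 simulations by default. Radii where the envelope
quantile is ≤ 10⁻⁹ nm are flagged undefined and excluded from peaks and
integrals: at very small r most null curves equal −r exactly and division
would flip signs or blow up. Standardization preserves sign (values below
the envelope stay negative); the expected coverage of an interpolated
m-simulation quantile is k/(m+1) ≈ 94.9% at m = 1000 and level 0.95,
a sub-percent conditioning accepted as-is.

The bivariate null (level 0.95) holds the big channel fixed and redraws the
small channel as CSR with its observed count. This tests cross-channel
association without assuming the big channel is itself CSR. It does not
preserve the small channel's *internal* clustering; a toroidal-shift null
(`null="toroidal"`), which does, is available when both channels are
strongly self-clustered and the CSR-small null would be anticonservative.

**LBI.** The trapezoidal integral of the standardized bivariate curve over
the closed band [10, 110] nm on the 1-nm grid. The closed reading of the
band is deliberate: a curve held exactly at its envelope then integrates to
exactly 100, the documented CI reference; a half-open band would move that
constant off 100. Negative LBI indicates segregation. Significance is the
rank of the observed LBI among the null simulations' LBIs, p =
(1 + #{null ≥ obs}) / (1 + n_sims); one batch of null simulations supplies
both the envelope and the null LBI distribution, mirroring how a single
1,000-simulation run is used for both normalization and ranking.

## L_max and its two flavors

The headline statistic is the peak of the *standardized* curve (ties broken
toward the smaller radius), read against the CI line at 1. The peak of the
*raw* L(r) − r curve is exposed alongside it (`raw_lmax`, `lmax_raw`
column) because the two answer different questions. Independent thinning
(incomplete antibody labeling) preserves K(r) in expectation exactly, so
the raw peak is the labeling-density-invariant measure of clustering
extent; the standardized peak divides by an envelope whose width scales
roughly like 1/n, so it necessarily shrinks as labeling drops. The
thinning-invariance test therefore asserts <10% variation of the *raw*
peak across 30/60/100% labeling efficiencies (expected retained n ≥ 50),
while group comparisons and significance calls use the standardized peak.

## Group comparison

Per-image standardized L_max values are summarized as unweighted mean ± SEM
over images (replicate membrane sheets are the experimental unit; an
n-weighted mean would let brightly labeled sheets dominate). Two conditions
are compared by a permutation bootstrap: T = |mean L_max(A) − mean
L_max(B)|, image-to-group assignments permuted with group sizes fixed,
p = (1 + #{T* ≥ T}) / (1 + n_boot) with n_boot = 1000, so the smallest
attainable p is 1/1001 and p ∈ (0, 1]. The exact resampling statistic used
by the original spatial-statistics literature for replicated patterns is
not fully specified there; this permutation scheme is the package's own
concrete choice, and an integrated-squared-difference whole-curve statistic
(`statistic="curve_integral"`) is provided as an alternative. Envelopes are
memoized by point count (`EnvelopeCache`), with each count's simulations
seeded by (base_seed, n) so results are independent of evaluation order.

## Oligomer populations

Particles within the threshold (default 15 nm) are linked and connected
components of the proximity graph define oligomers (single linkage —
chains count as one cluster, matching how visibly chained gold particles
read). Complete linkage is available (`method="complete"`). Component
sizes map to monomer / dimer / trimer / multimer (≥4); distributions are
reported both as cluster counts and as particle fractions (the axis
convention of published population histograms is ambiguous, so both are
emitted; plots default to particle fractions).

## Synthetic generators

The Thomas process (Poisson parents, Poisson(μ) offspring, isotropic
Gaussian(σ) displacement) is the clustered reference because its K is
closed-form: K(r) = πr² + (1 − e^{−r²/(4σ²)})/κ, giving an independent
oracle for the whole estimator stack and a least-squares route to recover
(κ, σ) from pooled K̂ curves. Parents are simulated in the window expanded
by 4σ so boundary clusters are not truncated (the estimator edge-corrects;
the generator should not add its own edge artifact). Defaults κ = 5×10⁻⁵
nm⁻² (50 parents/µm²), μ = 5, σ = 10 nm give ~250 points/µm² and cluster
radii of tens of nm, matching realistic immunogold densities and the
length scales at which standardized curves peak.

Count-conditioned variants (the curvature-response mixture and the
two-channel generators) fix the total in-window count and redraw
out-of-window offspring, so experimental contrasts differ in organization
rather than labeling density. The curvature-response generator places a
Binomial(n_total, φ) subset as cluster offspring and the rest uniformly:
φ = 0 is exactly CSR, φ = 1 fully clustered, and mean L_max rises
monotonically with φ. Two-channel modes: `colocalized` draws both channels
from one shared parent set; `independent` uses two independent parent
sets; `segregated` rejects small-channel candidates within 3σ of any
big-channel parent (a hard-core exclusion chosen for simplicity — it
produces an unambiguous LBI depression, not a calibrated biological
repulsion strength). Labeling thinning retains each point independently
with the given efficiency. All generators take explicit seeds and are
bit-reproducible; none models membrane mechanics — they emulate the
statistical structure the estimators assume, nothing more.

What the generators do *not* emulate: digitization error in particle
coordinates, antibody-size displacement between gold and epitope, steric
exclusion between gold particles, or spatially varying labeling
efficiency. Passing tests therefore validate the estimators and their
calibration on ideal point processes, not robustness to those acquisition
artifacts.

## Auxiliary metrics

R_q is the RMS height deviation after mean-subtraction ("mean image data
plane"); best-fit-plane leveling is available for tilted scans. FRET
efficiency uses the standard donor-lifetime form E = 1 − τ_DA/τ_D (the
assumed formula; τ_DA > τ_D warns rather than errors so dose series keep
their unphysical points visible). The nanobar end region is the two
half-disc caps (radius 125 nm); the center region is the axial central
rectangle sized to the *same total area* as the caps (half-length
πR²/2W ≈ 98 nm at defaults), removing area-imbalance bias from the
end/center ratio — the center extent is a package choice, as the source
protocol does not define it. Background subtraction is grayscale
morphological opening with a disc of the given radius (default 3 px), the
deterministic 2-D analogue of rolling-ball filtering; z-stacks default to
average projection. SPR records are assembled into RU_S/RU_L isotherms
sorted by concentration within vesicle-diameter groups; no binding model
is fitted.

## Problem sizes and numerical checks

Test-suite simulation sizes are chosen so Monte-Carlo error sits well
inside each asserted tolerance: 500 simulations for the analytic-K checks
(SE ≈ 0.5% of the target at r = 50 nm), 200 per thinning level, 500
same-generator comparisons for bootstrap type-I calibration, 100
replicates for power, and 30 pooled images for σ recovery. Envelope
coverage is asserted on the mean over independent envelope replicates
because a single 1,000-simulation envelope's quantile carries ~0.7 pp
Monte-Carlo error, comparable to the asserted band. Estimator-vs-oracle
comparisons are exact to 10⁻⁹ relative; closed-form edge weights agree
with a 10⁵-sample circumference oracle to 10⁻³ relative, and the 4,096-
angle fallback to its own ~2/4096 resolution.

## Known limitations

- Window placement within micrographs is upstream; patterns are taken as
  given inside their region.
- Only rectangular windows are supported.
- The bivariate CSR-small null can be anticonservative when the small
  channel is strongly self-clustered; use the toroidal null and interpret
  LBI comparatively in that regime.
- Oligomer classes count gold particles, not proteins: labeling
  stoichiometry and efficiency are not deconvolved.
- Inhomogeneous-intensity K variants, pair-correlation functions, and 3-D
  extensions are out of scope.
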