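# Methods

This note documents the models, numerical choices and known limitations of
the package, stage by stage.

## Vegetation scenes and the construction oracle

Synthetic scenes are built directly on the 0.5 m voxel lattice rather than
by simulating trees. Each stratum receives a requested number of
disc-shaped patches of vegetated columns; patches are non-overlapping
across the *whole* scene and separated by at least two empty columns, so
8-connected component labelling can never merge them and patch counts are
exact by construction. Within a patch column, the stratum's voxel cells are
filled to the requested occupancy fraction (at least one voxel per column,
so a patch's footprint is exactly its column set). Every occupied voxel
emits ≥ 1 point placed uniformly inside the cell with a 10⁻⁴ margin from
cell faces, so voxelization recovers the constructed occupancy exactly.
The generator records occupancy and patch layout; this record is the
"scene oracle" the tests compare against.

Defaults and their reasoning:

- `plot_radius` defaults to 250 m, the survey's LiDAR disc. The oracle
  sweeps in the tests and the acceptance script use 8–14 m discs purely to
  keep 1,000-scene suites fast; the construction is scale-free.
- `point_density` defaults to 4 pts/m², the survey instrument's floor.
- `ground_relief_amplitude` defaults to 0 (flat terrain). Terrain relief
  makes the DTM an interpolation, which is tested separately against an
  analytic tilted plane with tolerance; flat terrain keeps the oracle exact
  end to end. No terrain statistics are claimed for real sites.
- `noise_fraction` defaults to 0.001: a trace of points below ground and
  far above the canopy, exercising the outlier filters.
- Canopy voxels are generated in [25, 35) m; the canopy stratum itself is
  open-ended upward.

What the scenes do **not** emulate: return-intensity, occlusion (real
LiDAR undersamples sub-canopy strata), scan-angle effects, and spatially
correlated terrain error. Passing the oracle suite therefore demonstrates
correctness of the metric computations, not robustness to sensor physics.

## Height normalization and outlier filtering

The terrain model is inverse-distance-weighted interpolation over the
`knn = 10` nearest ground points (power 2). If the cloud carries no ground
classification, ground is seeded deterministically as the lowest point per
2 m × 2 m cell. After normalization, points below 0 m are dropped. High
outliers are dropped above a cap whose default is the fixed 70 m ceiling
of the vertical profile: vegetation above 70 m carries no information for
any metric here, and a fixed cap cannot clip genuinely sparse canopy. An
adaptive alternative (`z_cap="auto"`: 99.9th percentile + 5 m) is
available but can remove real returns when less than ~0.1% of points are
canopy. Ground returns are excluded from voxel occupancy so that occupancy
measures vegetation; otherwise every ground column would register in the
understory and fuse its patches.

## Voxel metrics

Half-open intervals are used everywhere — voxel cells `[a, a+0.5)`, strata
`[0,5), [5,15), [15,25), [25,∞)`, profile bins `[k, k+1)` — so no voxel is
double-counted and `Total_A` partitions exactly into the four strata. The
voxel lattice is anchored on the absolute 0.5 m grid (the bounding box
floor snapped to the lattice), which makes binning deterministic and
independent of jitter in the cloud extent. Patch counts use queen's-case
(8-) connectivity, the default of common landscape-metrics tooling;
`Vert_V` is the sample variance (denominator 69) of the full fixed 70-bin
profile including zero bins, so plots of different heights are measured on
the same support.

## Hierarchical distance sampling

Counts are modelled per distance bin. With individuals uniform by area on
the disc and half-normal detection, the latent-abundance model thins to
independent Poisson bin counts with mean λ·π_k, where

π_k = 2σ² (e^{−a²/2σ²} − e^{−b²/2σ²}) / R²

(the closed-form area-weighted integral; written via `expm1` for numerical
stability at large σ). This marginalized likelihood is the sampler's
default; a literal "evaluate g at the bin distance" dialect is available
for comparison, and a brute-force latent-N summation validates the
identity in the tests. The detection scale uses a log link, guaranteeing
σ > 0.

Priors (the original analysis reports none): Normal(0, 2) hypermeans,
half-Normal(0, 1) hyper-SDs, Normal(0, 1) observer effects. Inference is
an adaptive Metropolis-within-Gibbs sampler written for this model:
species coefficients update column-wise with per-(species, coefficient)
adapted random-walk scales and per-species acceptance (the likelihood
factorizes over species), hypermeans are conjugate Normal draws, hyper-SDs
and observer effects use log- and identity-scale Metropolis steps. Two
chains by default; split-R̂ and bulk ESS (via arviz) are reported and
R̂ ≥ 1.05 raises a convergence warning rather than failing silently. The
detection intercept and observer effects are additively confounded by
design (as in any observer-effect detection model); their sum is well
identified and the priors resolve the split, but their individual chains
mix more slowly than the rest.

N̂ per plot × species is the posterior mean of
(observed total + λ·(1 − Σ_k π_k)) — the observed individuals plus the
expected undetected mass — evaluated on the 250 m disc. Post-processing
zeroes species outside the plot's domain range pool, zeroes N̂ < 0.95, and
flags presence at N̂ ≥ 0.95; the filter and threshold commute and the
operation is idempotent.

Habitat covariates are deliberately excluded from both model equations:
community hyperparameters would otherwise drag all species toward a shared
habitat response.

## Trait space and functional diversity

Gower distances are range-normalized per axis, averaged within the five
trait categories, then combined across categories by weights; proportional
axes (diet, foraging) are treated as quantitative rather than collapsed to
binary guilds. Category weights can be optimized to equalize category
contributions — the contribution of a category is the Pearson correlation
of its distance matrix with the combined matrix, and the objective is the
standard deviation of those contributions. The optimizer is a seeded
random-restart search with multiplicative local refinement (300 objective
evaluations by default): only the objective is prescribed by the balancing
method; the search strategy is this package's choice, kept deliberately
simple and deterministic.

PCoA is classical scaling (double-centering and symmetric
eigendecomposition). Negative eigenvalues — expected, since Gower
distances are generally non-Euclidean — are dropped, not corrected
(no Cailliez/Lingoes), and the fraction of absolute eigenvalue mass lost
is recorded. Space quality is tracked as RMSD between original and
embedded distances for 1–10 axes; four axes are retained by default.

FRic/FEve/FDiv follow the Villéger definitions. For assemblages with
S ≤ 4 species the hull is computed in the subset's own principal subspace
of dimension min(4, S − 1) (1-D hulls degrade to ranges), mirroring the
behaviour of the standard FD tooling; assemblages with S < 2 (S < 3 for
FEve/FDiv) yield missing values with a recorded reason, never errors.
Community PC means are weighted by post-threshold N̂.

## Phylogenetic metrics and nulls

Faith's PD sums the branch lengths of the minimal subtree spanning an
assemblage's tips, including the path to the root by default (the common
toolkit convention; a rootless variant is available). MPD is the
unweighted mean patristic distance over unordered tip pairs. Because
verbal definitions of "mean distance between closest relatives" actually
describe MNTD, that index is provided as a separate, clearly named
function. Tree-based observed values are summarized as the mean across the
tree sample.

Null communities preserve each plot's richness and abundance multiset and
draw occupants uniformly from the plot's domain pool ("pool resampling").
A checkerboard-swap variant that additionally preserves species occurrence
frequencies is available behind a flag; pool resampling is the default
because richness preservation and range constraints are the only
constraints the SES definition here requires. SES = (obs − null mean)/null
SD; degenerate null distributions (zero SD) yield missing values with a
reason. With trees, each null replicate is evaluated on each tree — 100
replicates × 100 trees = 10,000 evaluations per plot.

One calibration subtlety: for a single tree, the null distribution of a
tree metric such as MPD is skewed by that tree's shape, and the skew is
shared by every plot, so the across-plot mean SES of self-null data does
not converge to zero with more plots. Averaging the observed metric over a
tree sample and crossing nulls with trees — what the engine does — removes
the shared component; the self-null check in the acceptance suite uses
eight trees and centers within ±0.05 across seeds.

## Mixed models and comparison

The twelve candidate models are fixed covariate combinations of
environment (TempRange, Elevation, Latitude), habitat composition
(Total_A, Can_A, Sub_A, Mid_A, Und_A) and configuration (Total_C, Can_C,
Sub_C, Mid_C, Und_C, Vert_V), all with site random intercepts. Covariates
are centered and scaled; a |r| ≥ 0.7 correlation screen is reported, not
auto-applied, since the model set itself embodies the collinearity
decisions (the Full model keeps Total_A, its twin drops it). Families:
Poisson (log link) for richness, Beta (logit mean, precision φ) for FEve —
boundary values squeezed by (y(n−1)+½)/n — Gaussian otherwise. Priors:
Normal(0, 5) intercepts, Normal(0, 2) slopes, half-Normal(0, 2) scales,
Gamma(2, 0.1) Beta precision.

Gaussian fits use conjugate Gibbs draws for coefficients and site effects
with Metropolis steps on the scales; Poisson/Beta fits are fully adaptive
Metropolis (component-wise coefficients, per-site intercepts). Pointwise
log-likelihoods are conditional on the site effects, matching the default
of mainstream mixed-model LOO workflows.

PSIS-LOO elpd comes from arviz; the pairwise SE against the best model
uses the pointwise-difference formulation, and the top set contains every
model within 3×SE of the best (the best always included). Consensus
classes per covariate: *solid star* — every model containing it estimates
a same-signed 95% CI excluding zero; *open star* — the best model does and
at least half the top-set models containing it agree; otherwise the
pooled posterior draws of the top-set models containing the covariate
decide positive/negative/null.

## Pipeline and reproducibility

Stages communicate only through plain files (XYZ, CSV, Newick, JSON), so
any stage can be replaced by real data. The run manifest records SHA-256
hashes of all artifacts, seeds, versions and stage timings; replaying a
config with the same seeds reproduces every hash bit-exactly. Validation
is fail-fast: a disabled stage with missing outputs, or outputs whose
hashes contradict the recorded manifest, refuses to run.

Problem sizes in the shipped test and acceptance suites are the package's
own choices for a single-CPU workflow: 8–14 m scene discs for the
1,000-scene oracle sweep, 60 plots × 20 species for hyperparameter
coverage (3 replicates), 385 observations for LOO recovery (10
simulations), and a 12-plot / 8-species demo scenario whose abundance
intercept (β₀ hypermean 1.5) is set high enough that hull-based FD metrics
are defined at nearly every plot.

## Known limitations

- The distance-sampling sampler is random-walk based; for communities far
  larger than a few hundred species a gradient-based sampler would mix
  better. Convergence is always diagnosed and flagged.
- Counts are modelled as independent Poisson bins (exact under the
  uniform-by-area assumption); a multinomial-conditional formulation is
  not implemented.
- The bird placement model is spatially uniform within plots; no
  clustering, movement or double-counting processes.
- FRic on near-degenerate point sets depends on qhull's tolerance;
  degeneracies are reported as missing, not repaired.
- The Beta family squeeze introduces an O(1/n) bias at the boundaries,
  standard but worth remembering with few plots.
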