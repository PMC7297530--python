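# Methods

## Data model and units

Annotations enter as webKnossos-style NML skeletons: trees of nodes and
edges, with per-node comments carrying all semantic labels. Two comment
dialects are accepted on input (inline attributes and a trailing
`<comments>` block); the writer emits inline comments because node ids
are only unique per tree, which makes a document-global comment block
ambiguous. Coordinates are voxel-indexed (0-based, corner-anchored) at
parse time and converted once to physical units: each axis is scaled by
its voxel size, the cutting axis additionally by a thickness-correction
factor (default 1.0; 1.49 for datasets whose nominal section thickness
underestimates the true one, judged from soma ellipticity). All
downstream geometry is in µm. Cortical depth of a point is the
per-dataset pia offset plus its depth-axis coordinate; the offsets are
dataset metadata, not file content.

The annotation vocabulary, written by the generator and parsed back into
`DendriteAnnotation` objects: `soma`, `trunk origin` (proximal end of a
deep-layer AD with no soma in the volume), `main bifurcation`,
`spine neck` (nodes of a neck side-branch) and per-synapse tokens
(`shaft synapse`, `spine synapse #k`, `secondary spine synapse #k`,
`spine neck synapse`), `;`-separated when a node carries several. Spine
synapses are referenced at their shaft attachment node so that every
synapse has a well-defined arc position on the pruned (spine-neck-free)
skeleton; `#k` preserves spine identity for double-innervation counts.

## Morphometry

Shaft path length removes spine necks and sums Euclidean edge lengths.
Analysis windows are closed intervals of arc distance from the reference
node (soma, else trunk origin); an edge contributes the overlap of its
arc span with the window, which is exact on a tree. The default window is
±10 µm around the main bifurcation. Dendrite surface area is the open
cylinder π·L·d̄ with d̄ the mean of diameter samples interpolated on a
2.5 µm arc grid (explicit samples take precedence over node radii; the
mean is unweighted — whether a length-weighted mean is preferable is
untested and flagged as a sensitivity question). Soma size is the
equal-volume sphere diameter (abc)^(1/3) of the axis-aligned ellipsoid;
trunk calibre is the equal-area circle diameter √(major·minor) of an
annotated elliptical cross-section ~50 µm from the soma; synaptic
interface area is the ellipse π·(major/2)·(minor/2) of two annotated
axes.

Main-bifurcation detection honours an annotated override; otherwise it
returns the most proximal degree-≥3 node whose two largest daughter
subtrees have total path lengths within a relative tolerance (default
0.5) of each other — a deterministic reduction of the qualitative
"two daughter branches of similar thickness and angle" criterion.

## Synapse quantification

Identity rule: shaft, spine-neck and secondary-spine synapses are
putative inhibitory; primary spine innervations are excitatory. A
double-innervated spine therefore contributes one excitatory and one
inhibitory count. `DensityResult` carries the shaft-only tally
separately from the full putative-inhibitory tally because population
"shaft density" statements refer to the former.

Two averaging conventions are computed and labelled: per-dendrite means
(mean of per-dendrite densities/fractions) and pooled statistics (sum of
counts over summed lengths). They differ whenever dendrites vary in
size; neither is "the" fraction.

Distance profiles bin synapses by path distance to soma in 10 µm
half-open bins; bins with fewer than four synapses are merged
proximal-first (a deficient bin joins its proximal neighbour group if one
exists, otherwise it is held and merged distally; a deficient trailing
remainder joins the last group). The direction of "immediate neighbour"
merging was an open choice; proximal-first is deterministic and isolated
in `merge_low_count_bins` for sensitivity checks.

Cortical-depth profiles partition reconstructions into 100 µm virtual
tangential sections, pool counts and path lengths per section, and
attach a percentile bootstrap CI (default 10,000 resamples) with the
dendrite as resampling unit.

## Axon analysis

Axons are classified excitatory iff a strict majority (> 0.5) of their
output synapses lies on single-innervated spines; exactly 0.5 resolves
to putative inhibitory. The per-structure excitatory fraction of
shaft-seeded axons feeds the identity correction: a fraction f of
shaft-derived inhibitory counts moves to the excitatory tally
(double-spine contributions untouched), after which densities and
fractions are recomputed.

Innervation profiles are per-axon 8-category fraction vectors with the
seed synapse excluded. The conditional matrix reports per-seed-group
means of the L2-AD and DL-AD fractions plus the AD-restricted
renormalization (axons without AD synapses are excluded there, as
averages are undefined on empty sets). Multiplicity statistics count
synapses per distinct AD target; the binarized preference collapses each
distinct AD to one hit.

The specificity test concatenates the two groups' fraction vectors,
redraws groups of the original sizes (no stratification) 10,000 times
and reports, per category, the fraction of resampled |mean differences|
at least as large as the observed one — a two-sided reading of "more
extreme", chosen as the conservative interpretation. Significance uses
α/m with m = 8. The (1+k)/(1+B) p-value convention is reported alongside
the plain k/B one; the plain one is the default. Cross-region
consistency reports the CV (sample SD of the four region means over
their mean, in %) per target, a Wilks-lambda multivariate location test
over the six retained categories (AIS and glia excluded: too few
synapses, near-singular covariance), and Bonferroni-corrected per-target
one-way ANOVAs only when the omnibus rejects.

## Cell-type models

Layer assignment is a half-open interval lookup on soma depth (boundaries
are dataset-specific configuration; boundary values belong to the deeper
layer); ADs without a soma in the volume are "deep layer". Layer-2
marginal neurons are flagged when the soma→bifurcation chord deviates
from the pia normal by more than a threshold (default 60°); chords under
5 µm are refused.

L5 subtypes are found by average-linkage agglomerative clustering of the
z-scored 4-D feature space (soma equivalent diameter, MB depth, oblique
count, trunk diameter); the metric (cosine, Euclidean, correlation,
city-block) is selected by cophenetic correlation, and a warning is
logged when cosine — the metric expected to be most consistent — does
not win (on the generator's default blobs, correlation and cosine are
nearly tied and either may be selected; the partition is essentially
identical). Features are standardized before cosine clustering because
the raw units are incommensurate; this was an open design choice.
The cluster with the larger mean soma diameter is labelled thick-tufted.
Thick-tuftedness is PC 1 of the (standardized) feature matrix with its
sign fixed to correlate positively with soma diameter, making scores
deterministic.

Fits: the exponential-with-offset model y = c + a·e^(bx) is fitted by
nonlinear least squares with c₀ = min(y), a₀ = max(y) − c₀ and b₀ from a
log-linear regression of y − c₀ (offset boundable to [0, 1] for
fractions; constant data short-circuits to a = 0, R² = 0). The
linear-fraction model (a·x+b)/(c·x+d) is fitted from two starts (linear
numerator; reciprocal-regression denominator); the model is only
identified up to a common scale, so the raw solution is reported
together with a d = 1 normalization, and fits whose denominator changes
sign inside the data range are rejected. R² is 1 − SS_res/SS_tot
throughout (0 for constant data). Fraction prediction from density
models computes Î/(Î+Ê) with the non-modelled component held at its
mean and reports the R² of prediction against observation.

## Synthetic data generator

The generator is the package's definition of the study conditions; every
default is a population value the analysis is expected to recover.

Geometry: each cell is a straight trunk (soma or trunk origin → main
bifurcation) plus a symmetric Y of two tuft branches, structural nodes
every 1 µm, spine necks as 1-node side branches. Trunk lengths are
cell-type-specific (L2 ≈ 41 ± 8 µm — placing the modelled MB inhibitory
fraction near its observed L2 value — L5tt ≈ 300 µm, etc.); layer-2
marginal neurons get a pia-parallel trunk. Main-bifurcation depths
scatter around 15 µm below the dataset face.

Synapses: independent Poisson processes along arc length, piecewise
constant per 1 µm subinterval, with three compartments — the ±10 µm MB
window at per-type (inhibitory shaft, excitatory spine) rates
(L2: 0.42/0.84; DL: 0.22/2.16; L5tt: 0.133/1.40; L5st: 0.107/0.59 per
µm), the distal tuft beyond 30 µm past the MB, and the remaining trunk,
where the total MB rate is split by the exponential distance model
f(d) = 1.57·e^(−0.047·d) + 0.1 (clipped to [0, 1]), making rates
continuous at the window boundary. Each synapse is inserted as its own
node at its exact continuous arc position, so realized densities are
unbiased estimates of the configured rates at any node spacing — the
discretization that would otherwise inflate a closed 30 µm window by one
grid node is avoided by construction. The L2 excitatory window rate
0.84/µm is a calibration choice (it puts the per-dendrite mean fraction
near one third given 0.42/µm inhibitory), not an observed value. Distal
tuft shaft rates are calibrated so the *total* putative-inhibitory rate
(shaft + neck 0.01/µm + double-spine secondaries) over the total rate
equals the target distal fractions (22.5% L5tt, 31.3% L5st, 11.4% L2,
10.2% L3). Double-spine rates: 6.4% (L2), 3.5% (DL), 5% otherwise.

Axons: per axon, the number of output synapses is Poisson(15) truncated
at ≥ 6; the AD-targeted count is Binomial(n, 0.203); AD synapses are
grouped into connections with multiplicity distribution
(0.77, 0.17, 0.04, 0.02) over 1–4 synapses, each connection hitting the
seed's own AD type with probability (1+s)/2 (default s = 0.548, i.e.
77.4% same-type) and a distinct AD id; non-AD synapses draw from a fixed
category mix dominated by single spines and other shafts with AIS and
glia rare. Because multiplicities are capped by the remaining AD budget
of small axons, the realized mean synapses-per-target (~1.2) sits
slightly below the distribution mean (1.31); the mean per-axon AD
*fraction* is exact by construction. A separate calibration population
generates the bimodal single-spine-fraction mixture for identity
estimation, with shaft-seeded axons excitatory at per-structure mixing
rates (L5st: 0.44 in L1, 0.60 in L2; 0.05 otherwise).

L5 morphology: two 4-D Gaussians (7:11 mixing) separated mainly in soma
diameter, MB depth and oblique count; excitatory density follows
0.44·PC1 + 1.4 (noise SD 0.25) and the inhibitory fraction
(0.043·PC1+0.13)/(0.58·PC1+1.40) (noise SD 0.02), with inhibitory
density implied by I = E·f/(1−f). Distance-model samples draw d_MB
uniformly over 10–330 µm with fraction noise SD 0.12.

What the generator does **not** emulate: realistic 3-D axon
trajectories (axon outputs are tabular), curved or branching trunks,
annotation errors and proofreading disagreements, spatial correlations
between synapses (placement is Poisson; an overdispersion hook exists
but is off), and image-derived quantities. Passing recovery tests
therefore demonstrates correctness of the measurement pipeline under
rate-like placement, not robustness to annotation noise.

## Problem sizes and numerical choices

Default study sizes mirror the populations the statistics were designed
for: 41+41 main-bifurcation maps, 92+91 seeded axons, 18 L5 cells,
16 distal tuft branches, 81 distance-model points. The test suite runs
recovery checks at these sizes (seconds each) and the bootstrap type-I
simulation at 1000 replicates with 2000 resamples per test; the
acceptance script regenerates everything in well under a minute.
Bootstrap and generator randomness flow from a single seed via
`numpy.random.SeedSequence`-derived child seeds. Ties and degenerate
inputs fail loudly: zero shaft length, empty axon output lists, identical
feature vectors and sign-changing denominators raise typed errors rather
than returning silent NaNs.

## Known limitations

* The conditional-innervation model treats connection multiplicity as
  independent of target type; empirical multiplicity may covary with
  seed type.
* The MB window uses a single global half-width; real windows were
  bounding boxes, so path-window and box-window lengths can differ on
  curved dendrites (the generator's dendrites are straight, hiding this).
* The MANOVA-based consistency test assumes multivariate normality of
  compositional fractions; it is reported as "not applicable" when the
  covariance is singular rather than being replaced by a permutation
  scheme.
* Surface-area densities require diameter annotations; node radii are a
  stand-in of unvalidated accuracy.
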