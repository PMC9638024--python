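# Methods

## Problem and model

Dual-color PD-PALM imaging of a membrane region yields a table of
localized molecules, each with a planar position (nm) and a channel
identity (CH_A = EP2 receptor, CAGE 500 dye; CH_B = oxytocin receptor,
CAGE 552 dye). The scientific question is how the receptor population
partitions into monomers, homomers and heteromers, and with what
per-species stoichiometry. `palmcensus` implements the quantification
chain from the localization table onward; raw-image fitting, drift
correction and microscope control are out of scope.

Coordinates are nanometers with the origin at the lower-left corner of
the region of interest (ROI), y increasing upward; only inter-point
distances matter downstream, so the convention is internal but fixed.
ROI boundaries are closed: a localization exactly on the edge is valid,
avoiding silent data loss on exported windows. The default ROI is
7000 × 7000 nm, the standard imaging window.

## Association census

**Same-channel discounting (10 nm, strict).** Two same-channel
localizations closer than 10 nm cannot be distinguished as separate
receptors; keeping both would overestimate association. Violating
pairs are scanned in ascending (low id, high id) order and the
higher-id member of each still-live pair is removed. "Within 10 nm" is
read strictly: a pair at exactly 10 nm survives. One pass suffices —
the operation is idempotent and leaves no violating pair (property- and
brute-force-tested). Removal (not averaging) is used because the
discounted point is treated as a duplicate detection, not a second
molecule. The resulting effective localization precision is 20 nm.

**Neighbor graph (50 nm, closed).** An edge joins any two surviving
localizations, regardless of channel, at Euclidean distance ≤ 50 nm.
The implementation uses a k-d tree but is tested to match the
brute-force all-pairs definition exactly, including ties at the radius.

**Group extraction with exclusion.** Once an associating group is
found, its members are excluded from further searches, so groups
partition the field (asserted on every run). Two readings of the
underlying second-order neighborhood analysis are provided, because its
exact grouping depth is defined in an external tool rather than
specified here:

- `full_closure` (default): groups are connected components of the
  graph — the unique order-independent reading consistent with the
  exclusion rule;
- `second_order`: a seed (lowest unassigned id) grows by at most two
  breadth levels before exclusion. This variant can depend on seed
  order; `order_robustness()` reports the fraction of localizations
  whose group changes under a reversed seed order (0 for well-separated
  complexes, regression-tested).

Both radii are monotone: enlarging the search radius never splits a
group (tested).

**Taxonomy.** A group with counts (n_A, n_B) is a monomer (size 1), a
homo- or hetero- dimer/trimer/tetramer/pentamer (size 2–5, hetero iff
both channels present), or a higher-order aggregate (size ≥ 6). The
boundary at 6 follows the contrast between low-order oligomers (2–5
receptors), which are density-robust, and larger aggregates, which are
density-driven; a group of exactly 6 is classified higher-order.
Heteromer stoichiometries are rendered `"<n_A>EP2:<n_B>OTR"`.

**Per-field metrics.** The heteromer burden uses *molecules* as the
denominator (percentage of all receptors found in heteromeric groups);
the composition table uses *heteromeric groups* (percentage of total
heteromers); stoichiometry breakdowns use the groups of their own size
class. Metrics with an empty denominator are reported absent, never as
0. Whether the molecule-denominator metric should instead be computed
per channel and averaged is not defined by the source material; the
joint-denominator reading is used here.

**Statistics.** Fields (cells) are first averaged within an
experiment; mean ± SEM are computed across experiment means, so n is
the number of independent experiments. SEM is absent for a single
experiment. Conditions are compared with the unpaired two-tailed
Student's t test (pooled variance, df = n₁+n₂−2, via
`scipy.stats.ttest_ind`); Welch's test is available behind a flag.
Zero pooled variance or n < 2 raises rather than returning a number.

## Synthetic data generator

The generator emulates the acquisition: complex centroids from a
homogeneous Poisson process at `complex_density` per µm² over the ROI;
species drawn by mixture fraction; each protomer displaced uniformly in
a disc of radius `intra_spacing` around its centroid, then perturbed by
isotropic Gaussian noise `loc_sigma`, then kept with probability
`detection_prob`. Ground truth maps every emitted localization to its
complex and species. Identical configs (including seed) give
byte-identical output; per-field substreams derive from
`(seed, field index)`.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| ROI | 7000 × 7000 nm | standard imaging window |
| `loc_sigma` | 8.5 nm | FWHM-style precision 2.355·σ ≈ 20 nm, the stated effective precision |
| `intra_spacing` | 15 nm | no intra-complex geometry is published; a 15 nm disc keeps true complexes well inside the 50 nm search radius |
| `complex_density` | 1.0 /µm² | no per-ROI densities are published; 1/µm² (~49 complexes, ~65–90 molecules per ROI) is a realistic sparse-expression regime, and the CSR control curve covers the density sensitivity |
| `detection_prob` | 1.0 | labeling efficiency was ~1 dye per antibody; thinning available for sensitivity analyses |
| `min_separation` | off (150 nm in benchmarks) | hard-core thinning guarantees "well-separated" complexes where the benchmark requires it |

Edge handling: centroids are drawn in the full ROI; a protomer whose
displacement + noise lands outside is re-drawn (rejection resampling),
preserving molecule counts near edges.

**What is deliberately not emulated:** fluorophore photophysics
(blinking, re-appearances), antibody labeling stoichiometry, membrane
topography (3D). A consequence matters for benchmarking: two genuinely
distinct same-channel protomers of one complex can land closer than
10 nm, and the discounting step — correctly — removes one. *Recovery is
therefore defined against the post-discounting truth*: a group is
correct when it equals the set of surviving localizations of one
planted complex. A green recovery test establishes that grouping and
classification are exact on resolvable data; it does not establish that
the census can see below the 10 nm resolution limit (nothing can, by
construction). Class-fraction recovery is additionally benchmarked
against the *planted* (pre-discounting) mix: with the default geometry
the discounting bias stays within ±3 percentage points per class,
dominated by heterotetramers (3 same-channel protomers in one 15 nm
disc) losing a protomer.

**CSR control.** Pure-monomer simulations across a density grid give
the spurious-association curve: the percentage of molecules in apparent
2–5-mers and ≥6-mers under complete spatial randomness. Spurious
≥6-mers rise steeply with density (near 0% at 10 molecules/µm², ~27% at
200/µm² with default radii), reproducing the rationale for treating
higher-order aggregates as density artifacts while analyzing low-order
oligomers for composition.

## Pose topology and clustering

Docking solutions are rigid transforms (R, t) of a mobile protomer
against a fixed membrane-embedded target; both share the membrane
frame, normal = +z. Per pose:

- tilt = arccos(n · R n) ∈ [0, π] — rotations about the normal give
  tilt 0 for any structure (tested);
- z-offset = |(R c + t − c)_z| for the Cα centroid c.

A pose passes iff tilt ≤ 0.4 rad and z-offset ≤ 6.0 Å (both
deliberately permissive). Filtering first truncates to the 4000
best-scored solutions, then applies the topology test, preserving score
order. Whether tilt should be defined on the principal axis of the
transmembrane bundle rather than the global +z is not specified; the
+z convention is used and stated.

**RMSD convention.** Pairwise Cα-RMSD is computed in the common frame
of the fixed target *without re-superposition*, because all solutions
share the immobile protomer; "superimposed" is read as "placed in the
common frame". Under this convention a pure relative translation d has
RMSD exactly ‖d‖, which the tests exploit.

**QT-like clustering (3.0 Å).** Iteratively, the unassigned pose with
the most unassigned within-threshold neighbours (ties: lowest pose id,
for determinism) becomes a cluster centre; it and its neighbours are
removed. Cluster populations are non-increasing in extraction order.
Clusters partition the pose set and every member lies within the
threshold of its centre (both tested, plus equivalence with an
exhaustive greedy oracle on ≤ 12-pose sets and planted-cluster recovery
at > 2× threshold separation). The downstream visual inspection of
cluster centres and the quantitative membrane-topology reliability
score used to rank clusters are human/undefined steps and are out of
scope; populations and pass rates are reported instead. Iterated
assembly from dimers to tetramers is likewise out of scope: the module
consumes pose lists for any fixed structure pair.

## Numerical choices

- Distance ties: merge radius strict (<), search radius and RMSD
  threshold closed (≤); stated once here and tested.
- Localization CSVs are written with 17 significant digits and read
  with round-trip float parsing, so write∘read is the identity.
- All stochastic code uses `numpy.random.Generator` seeded via
  `SeedSequence`; no global RNG state.
- The t statistic is undefined (raises) for degenerate samples rather
  than returning NaN.

## Known limitations

- The biological percentages reported for the real receptor system
  (~13% heteromers, etc.) cannot be reproduced: the raw imaging data
  are not deposited. They appear nowhere as test oracles.
- The depth-2 `second_order` grouping is one plausible reading of the
  original (externally defined) analysis; `full_closure` is the
  order-independent default and the two are compared via
  `order_robustness` rather than silently conflated.
- The simulator's Poisson/hard-core placement ignores membrane
  microdomains; real fields may be locally denser than any single
  density setting, which is why the CSR curve is provided as a
  sensitivity analysis rather than a calibration.
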