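# Methods

This note documents the models and procedures implemented in `axonstat`:
what is computed, under which assumptions, which defaults were chosen where
the design was open, and what the synthetic data do and do not establish.

## Skeletons and units

A traced neurite is an undirected tree of 3D nodes.  Coordinates are
0-based voxel indices; a voxel scale (nm per voxel along x, y, z) carries
the anisotropic sampling of serial-section EM — the default scale is
(20, 20, 40) nm, i.e. 20 nm in-plane resolution and 40 nm section
thickness.  All geometry is computed in nanometres after conversion
(nm = voxel × scale) and reported in the unit stated per function;
consequently every nm-valued output scales linearly with the voxel scale.
Per-node radii are stored in nm directly (not voxels), because radii
measured on anisotropic voxels have no single natural voxel unit.

The NML dialect is pinned (`things/thing/nodes|edges|comments`); annotation
tags ride in node comments as `key=value` pairs joined by `;`, with a bare
token extending the previous value so that vesicle-diameter lists read
naturally (`vesicle_diam_nm=48;50;45`).  The tag vocabulary (varicosity,
vesicle_diam_nm, mito_start/mito_end, contact_point, swelling, soma) is a
convention of this package: annotation comment syntaxes vary between
projects, so one is fixed and documented.  Unknown keys are preserved on
round trip but ignored.  Group and compartment metadata travel in a sidecar
JSON manifest keyed by thing id — NML has no standard slot for them.
`parse_nml ∘ write_nml` is the identity on valid records; every input
either yields valid records or a typed error, never a silently partial
record.

Mitochondrion segments are encoded by `mito_start=<i>` / `mito_end=<i>`
tags on the two end nodes; the chain is the unique tree path between them,
and its length is the polyline length of that chain (not the end-to-end
Euclidean distance), matching how lengths are measured by stepping nodes
along the organelle's long axis.

## Morphometry

* **Cable length** — sum of Euclidean edge lengths (µm).
* **Geodesic distance** — length along the unique tree path (nm).  Tested
  against a generic weighted shortest-path search on random trees.
* **Branch count** — Σ over nodes of max(0, degree − 2).  This extends the
  intuitive "number of bifurcations" to higher-degree nodes, which the
  field rarely defines; a degree-4 node counts as two branch events.
* **Varicosity detection** — on the diameter profile of each maximal
  unbranched segment, a node is flagged when its diameter ≥ `fold` × the
  minimum diameter within a trailing+leading `window`; maximal flagged runs
  closer than `min_separation` merge and each run reports its peak.
  Defaults: fold = 2, window = 1 µm, min_separation = 0.5 µm.  Two
  operational definitions circulate — a ~3-fold rise relative to the
  thinnest stretch of the axon, and a ≥ 2-fold rise within ~1 µm — and the
  ≥ 2-fold-in-1-µm form is implemented as the default because it is a
  local, protocol-like rule; both `fold` and `window` are configuration.
  The 0.5 µm merge radius keeps sub-µm neighbouring varicosities separate
  (they occur under the log-normal spacing model) while still fusing
  jagged single peaks.
* **Inter-varicosity distances** — geodesic distances between *consecutive*
  varicosities in axon order (order = geodesic distance from the root, the
  soma-tagged node or lowest id).  Whether "distances between varicosity
  pairs" means consecutive or all pairs is ambiguous in common usage;
  consecutive is the default and `all_pairs=True` is available.
* **Dendrite diameter** — arithmetic mean of three orthogonal chord
  measurements (nm).

## Varicosity typing

Types from vesicle diameters: I (no vesicles), II (only small-bin,
26–67 nm), III (only large-bin, 90–238 nm), IV (both bins occupied).
Diameters in the 67–90 nm gap or beyond 238 nm do not vote; a non-empty
varicosity whose every vesicle is out-of-bin is left unassigned with a
warning rather than forced into a type.  A single in-bin vesicle of the
minority class suffices for type IV by default (`min_minority_count = 1`);
no minimum count is established in the field, so it is configuration.
Classification is deterministic and order-independent.

Pooled type frequencies are computed over **all** classified varicosities
of all axons.  Per-axon eligibility (≥ 3 classified varicosities) applies
only to the exceedance/null analysis, not to pooling.

## The organization null model

The question: do individual axons carry more same-type varicosities than
expected if each axon sampled types independently from the population?

Statistic: the exceedance count C(T, k) = number of eligible axons with
strictly more than k type-T varicosities, for k = 1 … k_max.

Null: hold each axon's varicosity count n_a fixed; draw its types iid from
the pooled frequencies f (estimated once from all classified varicosities,
then held fixed — a plug-in null with no resampling of f).

* Monte Carlo route: M = 100,000 trials; per trial each axon receives n_a
  fresh draws and C is tallied exactly as for the data;
  p = Pr(C_sim ≥ C_obs).  The `geq` tail is the default: the observed value
  acts as a cutoff on the simulated count distribution; `gt` is available.
  A Monte Carlo p of exactly 0 is rendered "< 1/M" in display output; the
  raw 0 is kept in machine output.
* Exact route: q_a = P(Binomial(n_a, f_T) > k); C is Poisson-binomial
  (q_1 … q_A).  The mass function is computed by the standard dynamic
  programme (fold one axon at a time into the running pmf, O(A²) total) and
  tails are read off it.  The DP tail is clipped to [0, 1] to absorb
  accumulated float error (~1e-16).

The exact route is an analytic oracle for the simulation: for every cell
|p_mc − p_exact| is bounded by Monte Carlo error (≈ 4·sqrt(p(1−p)/M)),
which the acceptance suite verifies over randomized instances, and the DP
itself is verified against full enumeration on tiny instances.  Because the
p-value is a discrete function of C, the test's true size at α = 0.05 is
the "achievable size" — the null mass of the rejection region — typically
below 0.05; calibration is asserted against that quantity, not against
nominal α.

Interpretation caveat: C(T, k) is informative when k is commensurate with
the per-axon varicosity counts.  If axons carry many varicosities
(n_a ≫ k), low-k cells saturate under both null and alternative, and
type persistence shows up at large k (or even as *deficits* at low k,
since clustering inflates the variance of per-axon counts).  Choose k_max
with the composition of the dataset in mind.

## Group statistics

Mann-Whitney U, two-tailed, reported as U = min(U_x, U_y).  The exact null
distribution of U is used when min(n_x, n_y) ≤ 8 and the pooled sample is
tie-free; otherwise the normal approximation with tie correction and
continuity correction.  The two-tailed p doubles the smaller one-tail mass,
capped at 1.  The computation is delegated to scipy's implementation, which
follows exactly these conventions; the test suite checks it against a full
enumeration oracle for all tie-free size pairs up to 7×7.

Mean ± SEM uses the (n−1)-denominator standard deviation; SEM is flagged
undefined (NaN) for n < 2.  The log-normal fit is maximum likelihood:
μ = mean of logs, σ = population (ML) standard deviation of logs, with Q-Q
pairs against fitted quantiles for inspection.

Sampling units mirror the study design: densities are per-axon values;
mitochondrial lengths are per-structure values; dendritic comparisons use
the ratio mitochondrion length (nm) / dendrite diameter (nm).  Animal-level
nesting is **not** modelled (data from the two animals per group are
pooled) — a documented limitation, not an oversight.  No multiple-testing
correction is applied across metrics by default.

## The synthetic-data generator

The generator defines the study conditions under which everything is
tested.  Per axon:

* **Backbone** — persistent 3D random walk, 1 µm steps (direction blends
  90% previous direction with 10% fresh isotropic noise), trunk length
  ~ Uniform(50, 250) µm.  Branch events form a Poisson process at rate λ_b
  per µm over all grown cable; each event attaches a subtree whose length
  is drawn from the same length distribution scaled by 0.3 per generation
  (keeping trees compact and the branching process subcritical).  Event
  nodes — varicosity peaks, swellings, mitochondrion endpoints, contact
  points — are inserted at their exact arclengths by splitting walk edges:
  the measured structures (mitochondria ≈ 0.36 µm, sub-µm spacings) are
  smaller than the step size and would be unrepresentable on the 1 µm node
  grid alone.
* **Varicosities** — placed sequentially along the trunk with log-normal
  spacing (default median 4 µm, σ_log = 0.8; no published spacing
  parameters exist, so these are package defaults and fully configurable).
  Node radii encode a 100 nm baseline diameter with 300 nm peaks at
  varicosities — the 3-fold bump geometry the 2-fold detector must recover.
* **Types** — first varicosity ~ Multinomial(f) with
  f = (156, 101, 78, 75)/410, the empty/small/large/mixed composition of
  the reference dataset; each subsequent repeats the previous type with
  probability ρ (first-order Markov), else draws fresh from f.  ρ = 0 is
  the iid null.  A mixture mode (each axon tilts f toward a dominant type
  with weight w) is the alternative "axon classes" hypothesis; both reduce
  to iid at ρ = 0 / w = 0.  The sampler consumes two uniforms per position
  regardless of ρ, so sequences with the same seed are coupled across ρ
  (common random numbers) — raising ρ only converts fresh draws into
  repeats, which makes power curves in ρ directly comparable.
* **Vesicles** — counts are truncated normals (min 1): small ≈ 30.1 ± 32,
  large ≈ 9.2 ± 7; mixed varicosities ≈ 28.2 ± 42 small plus 6.9 ± 8
  large (SDs derived from reported SEMs × √n).  Diameters are truncated
  normals confined to their bin (small: mean 48, SD 8 nm on [26, 67];
  large: mean 133, SD 25 nm on [90, 238]); the truncation guarantees that
  classification recovers the generating type exactly, which is what the
  fidelity tests assert.  Truncated normals were chosen over log-normals
  because only means and SEMs are reported and the bins enforce support.
* **Mitochondria, swellings, contacts** — Poisson per µm over all cable.
  Mitochondrion lengths are log-normal with (mean, SD) per condition:
  DA axons 0.36 ± 0.13 µm saline, 0.79 ± 0.64 µm cocaine (SDs from
  SEM × √n); segments are laid down within one walk segment so the chain
  length equals the drawn length exactly.  Swelling diameters are
  log-normal with mean 2.2 µm, SD 1.4 µm (positive support without the
  truncation bias a clipped normal would add to the mean).  Contact points
  are Bernoulli axo-axonic with p = 0.83 (saline) / 0.77 (cocaine).

Group presets (per µm): branch rate 0.01 saline / 0.04 cocaine; swelling
rate 0 / 0.04; mitochondrion rate 0.14 / 0.16; contact rate 0.2 in both.
Chemical-synapse (CS) axons carry mitochondria with a **single pooled mean**
(0.72 ± 0.51 µm) in both groups: the study conditions state no cocaine
effect on CS-axon mitochondria, and planting the two near-identical
reported group means as true effects would manufacture a detectable
difference at the generator's mitochondrion counts.  Dendrite presets draw
a per-cell diameter and scale mitochondrion length by the target
length/diameter ratio (MSN dendrites 1.39 saline / 3.0 cocaine; VTA DA
dendrites 1.74 / 1.85); the soma preset uses 2.46 / 2.78 µm lengths.  The
VTA presets keep the reported per-group point estimates even though the
underlying study found those contrasts null — at large simulated n a
comparison on them may reject; only the CS-axon contrast is asserted null
in the acceptance suite.

Seeds: one master seed; per-axon child seeds spawned deterministically via
a seed sequence.  Identical config + seed regenerates byte-identical NML,
manifests and ground truth.

### What the generator does and does not emulate

It reproduces the *statistical* structure the analysis consumes: rates per
µm, length distributions, type frequencies and their serial dependence,
vesicle-size bins, group contrasts and their directions.  It does not
emulate: images or voxel volumes; biological branching morphology (no
tortuosity realism, no boundary effects of a finite imaging volume);
partial annotation (every planted structure is annotated, whereas real
annotators see fragments — which is why real axons of 50–250 µm carried
only ~5 recorded varicosities each, while fully annotated synthetic axons
of that length carry ~30); annotator noise or disagreement; animal-level
clustering.  Passing tests therefore demonstrate correctness of the
*computations* under known conditions, not robustness to the annotation
noise of real volumes.

Two estimator facts follow from full annotation and matter when reading
recovery numbers.  (1) Branch-rate recovery uses the pooled ratio
(total branches / total cable), which converges to λ_b as cable grows; the
per-axon mean of ratios is biased low here because each branch event adds
its own subtree cable to its axon's denominator.  (2) Group comparisons on
synthetic data run at larger per-structure n than the study reported, so
p-values are smaller than the reported ones; only directions and
null-consistency are asserted.

## Problem sizes in the test and acceptance suites

Oracle equivalence runs 10 randomized instances at M = 100,000 trials;
exact-vs-enumeration runs on ≤ 4 axons × ≤ 4 varicosities; calibration uses
500 replicate datasets of 75 axons at the reference composition (checked
against the discrete achievable size with an exact Poisson-binomial 99%
band); power uses 200 shared-seed replicates per ρ ∈ {0, 0.2, 0.4, 0.6,
0.8}; geometry oracles use 100 random trees of ≤ 50 nodes (all pairs);
Mann-Whitney exactness enumerates all tie-free size pairs ≤ 7 × 7;
parameter recovery uses the full 44/41-axon study plus 30/57 CS axons.
These sizes make each property statistically decisive while the whole
suite stays fast.  One numerical note: the Monte Carlo agreement band
4·sqrt(p(1−p)/M) is floored at 5/M, because within ~1e-5 of p ∈ {0, 1} the
band is narrower than the estimator's own 1/M step.

## Known limitations

* Mouse-level nesting is not modelled; per-axon and per-structure values
  are treated as exchangeable within group.
* The varicosity detector assumes a reasonably sampled radius profile;
  profiles shorter than the window return no detections (with a warning).
* The exceedance statistic tests marginal per-axon counts, not literal
  runs or spatial adjacency; a run-length statistic would have different
  power against ordered alternatives.
* The annotation-tag vocabulary is a package convention; real Knossos
  projects will need their comment strings mapped onto it.
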