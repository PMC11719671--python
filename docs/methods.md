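# Methods

## The assay and its parameters

An aortic ring assay embeds a ~1 mm arterial explant in a gel; over roughly a
week, microvessels sprout from the ring's outer edge and branch into a
network. `angioring` quantifies one explant at one timepoint by a fixed
registry of parameters in four subindex categories:

| category | parameters | units |
|---|---|---|
| explant | migration, circumference | fraction, µm |
| pattern | vessel_structure (% primary vessels), loop_count | %, count |
| network_properties | max_radial_outgrowth, max_initial_vessel_length, total_vessel_length, mean_vessel_length, speed_mean_initial_length, speed_max_initial_length | µm, µm/day |
| sprouting | vessel_density, branch_count, mean_branch_length, junctions_per_vessel | count/mm, count, µm, count |

Twelve of these are measurable on a single image; the two growth speeds
compare consecutive imaging sessions of the same ring, use the exact elapsed
time between them, and are attributed to the later day of each interval.
`vessel_count` and `junction_count` are exposed by the same operations as
auxiliary values (the scored registry uses their normalised companions,
density per mm of ring circumference and junctions per initial vessel, which
are comparable across rings of different size).

Definitions that need precision beyond the visual ones:

* **Maximum radial outgrowth** is the largest *perpendicular* distance from
  any vessel tip (branch tips included) to the ring's outer boundary — the
  shortest point-to-boundary distance, which formalises "measured at a right
  angle from the ring edge". It is always ≤ the longest path length, because
  vessels may curve tangentially.
* **Junctions** are distinct attachment nodes where at least one branch
  originates. Because tracing is done in continuous coordinates, attachment
  points closer than a merge tolerance (default 5 µm, roughly the precision
  of manual tracing) are a single junction. A point where two branches share
  one attachment counts once.
* **Loops** are independent cycles of the undirected segment graph that run
  through at least three distinct segments; a branch that leaves its parent
  and fuses straight back onto it (a two-segment circuit) is not a loop. The
  count is the number of such cycles in a fundamental cycle basis of the
  merged junction graph; in these sparse, nearly planar networks the
  fundamental cycles coincide with the circuits one counts visually.
* **Missing vs. zero.** A ring without branches has *no* mean branch length;
  a non-migrated ring has *no* length metrics. These are reported as missing
  (NaN/empty CSV cell), never as zero — averaging zeros would conflate
  absence of vessels with short vessels. Counts, by contrast, are genuinely
  zero. Group aggregation skips missing values.

The junction/loop machinery is one shared geometric graph: every segment is
split at its own endpoints, its children's attachment points and any
anastomosing tip; split points within the merge tolerance become one node;
chain edges remember which segment they belong to. Junctions, loops and the
round-trip contract below are all defined on this graph.

## The Angiogenic Activity Index

For each scored parameter, with treatment values T and control values C at
an early and a late day of treatment (defaults 4 and 7),

    AAI = ((T_late − T_early) − (C_late − C_early)) / (C_late − C_early).

Zero means control-like change, +1 a doubled control change, −1 no change
under treatment. The index is a ratio of differences, hence invariant to
affine rescaling of a parameter's units, and needs no orientation flip for
parameters that decrease with angiogenic activity: if the control change is
negative (e.g. the primary-vessel percentage falls as branching proceeds), a
larger decrease under treatment still scores positive. An explicit
per-parameter orientation (±1) is available in the configuration for users
who disagree with that convention.

Category subindices are weighted aggregates, by default the *literal* form
(1/n)·Σ wᵢ·AAIᵢ with predictive-importance weights wᵢ (default 1): with
weights above 1 the subindex can leave [−1, 1], which is what lets strongly
pro-angiogenic samples score above 1. A weight-normalised variant
(Σ wᵢ·AAIᵢ / Σ wᵢ) is provided for sensitivity analysis. The final AAI is
the plain mean of the available subindices.

Two aggregation modes: `per_donor` (default) computes the AAI per donor
against that donor's own control rings and then averages across donors;
`pooled` takes group means over all rings first. Reports record which mode
was used.

**Degenerate controls.** If the control group did not change between the two
scoring days, the AAI of that parameter is undefined. The default policy is
to raise an error naming the parameter — silently dividing by a tiny control
change would manufacture arbitrarily large indices. An `epsilon` policy
(substitute a configured small change) and a `drop` policy (exclude the
parameter with a logged warning) are available. Degeneracy can also be
judged *relatively*: with `degenerate_rel_tol` > 0, a control change smaller
than that fraction of the control level counts as degenerate too — a
control that moved by well under its measurement scatter cannot normalise a
treatment effect, and dividing by it manufactures arbitrarily large
indices. The library default is 0 (exact zeros only);
`AaiConfig.simulation_default()` uses `drop` with a 2% relative threshold
and removes `migration` from the scored set, because in the simulator every
ring sprouts by day 4 and the control migration fraction cannot change.
Ring circumference is a covariate of the explant, not a scored parameter,
in every configuration.

## Mask extraction

`extract_network` replaces manual tracing for inputs that arrive as a binary
vessel mask plus ring mask with a known pixel size. Pipeline: topological
thinning (scikit-image); pixel classification by 8-neighbour count
(endpoint 1, path 2, node ≥ 3); node-cluster labelling; node-to-node path
tracing; spur pruning below 20 µm (and removal of tiny ring-edge stubs the
thinning leaves along the explant boundary); then hierarchy reconstruction.

Hierarchy reconstruction traces each vessel *eagerly* from its origin to its
tip: at a junction, the outgoing path most collinear with the arrival
direction (turn ≤ 35°, directions estimated over ~12-pixel chords because
single-step directions quantise to 45° multiples) continues the same vessel;
a vessel that arrives at a junction with no collinear continuation simply
ends there and claims nothing, so a through-vessel later crosses that node
intact. Remaining unclaimed paths become branches of the vessel owning their
node, in the order the nodes were reached from the ring. Paths whose
proximal end touches the ring are initial vessels; when two paths share one
ring contact the longer is the initial and the other its branch. Closed
circuits anchored on a single node are traced as three chained branches — a
circle is by definition at least three interconnected vessels.

Two raster-specific corrections: (1) thinning retracts a skeleton by up to
the local half-width at free ends, so each endpoint is extended along its
own direction to the mask's cap edge minus the local half-width (distance
transform), and initial vessels are extended back to the ring boundary;
(2) an anastomosing tip is displaced a few pixels by the junction cluster,
so tips within 4 pixels of another segment are snapped exactly onto it, and
a branch whose tip lands back on its own parent (a node-less arch formed by
a tip-to-tip fusion) is split at its apex into two branches.

**Round-trip contract.** For networks that are *well separated* —
`is_well_separated` checks segment lengths above the pruning scale, mutual
node separation, junctions clear of the ring edge, one attaching branch per
junction, a minimum clearance between non-adjacent segments, no branch
curling back to graze its own parent, and anastomoses only within one
initial vessel's tree (a fusion bridging two trees has no recoverable
origination direction) — rendering at 2 µm/px followed by extraction
recovers vessel, branch, junction and loop counts exactly and lengths to
within 5% (observed ≤ ~4%; lengths are measured on chord-resampled
polylines, every third skeleton pixel, which removes the staircase bias of
8-connected chains). Networks violating these conditions are still
extracted, but counts may differ by the ambiguity of the configuration —
exactly as two human tracers would disagree on them.

## The outgrowth simulator

The generator is phenomenological: it reproduces the observable kinetics of
explant outgrowth, not endothelial biology. One ring's trajectory:

* **Seeding.** Initial vessels appear by a Poisson process spread uniformly
  over the assay horizon, at uniform angles on the ring; `seed_density`
  (vessels per mm ring circumference, default 7/mm) is the expected
  *final-day* density, so the vessel count and density rise over the
  observation days, as they do in the assay.
* **Elongation.** Tips advance at `elongation`·exp(−`elongation_decay`·t)
  (defaults 160 µm/day, 0.15/day) with Gaussian direction jitter
  (20°/√day); growth visibly slows between days 4 and 7. Tips that would
  grow into the explant are deflected outward.
* **Branching.** Branch events follow a Poisson process with intensity
  `branching_rate` (default 1.5 events per mm vessel per day) times the
  current total vessel length, starting after `branch_onset_day`
  (default 1.0 — the initial sprouting phase produces primary vessels only,
  so day-1 snapshots are 100% primary). Branches deviate ±30–90° from the
  parent direction and then grow by the same law.
* **Anastomosis.** An active tip within `capture_radius` (20 µm) of another
  vessel fuses onto the nearest point of it, forward of the tip's heading,
  with per-step probability `anastomosis_prob` (0.25); fusion stops the tip
  and closes a loop when target and tip share a tree.
* A treatment multiplier scales elongation and branching rate; multiplier 1
  reproduces control statistics in distribution.

Defaults were calibrated to the scale of a day-14 chick aorta explant in
matrigel: ring radius 540 µm (circumference ≈ 3.4 mm), day-7 maximum
initial lengths around 700 µm, tens of initial vessels, and on the order of
50–100 branches per ring, with loop counts rising steeply under a
pro-angiogenic treatment. Time stepping is 0.25 day; snapshots at the
observation days share one growing geometry, so later days contain earlier
days exactly (monotone growth). Each ring draws from its own substream
keyed by (seed, group, donor, ring): identical seeds give identical output,
and changing the ring count never perturbs existing rings.

What the generator does *not* emulate: chemotactic guidance, vessel
calibre/lumen, regression, matrix heterogeneity, imaging artefacts in the
masks, or inter-donor biological variability beyond independent sampling.
Passing tests therefore certify the measurement and scoring machinery on
networks with known ground truth — not that real micrographs are segmented
correctly upstream, which is outside this package's scope.

## Calibration and problem sizes

The end-to-end checks run at these sizes, chosen to keep the whole suite in
a few CPU-minutes while keeping Monte-Carlo noise within the margins they
test: the AAI null calibration and multiplier sweep use 50 rings per group
with pooled aggregation (null |final AAI| < 0.15 at the suite's fixed seed;
final AAI strictly increasing over multipliers 0.5/1.0/1.5/2.0). In these
runs `mean_vessel_length` is regularly excluded by the relative degeneracy
guard: its control change between days 4 and 7 is tiny because newly
spawned branches offset tip elongation (the assay shows the same saturation
of mean lengths), making its AAI denominator ill-conditioned. Oracle
equivalence uses 100
random networks of ≤ 20 segments built constructively so every count is
known without measurement; the raster round trip uses 20 well-separated
networks at 2 µm/px (counts exact, lengths within 5%); the seeding
expectation uses 200 rings (within 3 standard errors).

## Numerical choices and edge cases

* Merge tolerance 5 µm for junction identity; ties in the cycle basis do
  not arise at that tolerance under the separation conditions above.
* Continuation threshold 35°: below the simulator's minimum branch angle
  (30° by default, 40° in round-trip configurations) with margin for
  direction-estimation noise.
* Empty networks: migration 0, counts 0, length metrics missing; quantify
  never raises on a non-migrated ring.
* ΔC = 0 handling is a policy, never silent (see above).
* Reports print 3 significant figures; JSON retains full precision.
* CSV round trips are byte-stable (fixed float formatting).

## Known limitations

* Loop counting via a cycle basis can in principle differ from a visual
  count on dense, highly anastomosed networks where minimal cycles are not
  unique; at assay-realistic densities this was not observed.
* The extractor consumes binary masks only; segmentation of raw brightfield
  micrographs is upstream and deliberately out of scope.
* 2-D only: overlapping vessels in a thick gel project onto crossings that
  violate well-separatedness and are resolved heuristically.
* The growth-speed parameters require at least two imaging sessions; tables
  built from single-day data simply lack those rows, and the AAI then scores
  the remaining parameters.
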