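# Methods

## The retrieval model

A database holds N image patches, each represented by eight embedding
vectors — one per element of the dihedral group D4 (rotations by 0/90/180/
270°, indices 0–3, and the horizontal mirror followed by the same rotations,
indices 4–7).  All embeddings are L2-normalized so ranking by L2 distance is
scale-free across embedders.  A query is embedded once (orientation 0);
retrieval scans all 8N stored vectors, keeps each patch's minimum-distance
orientation, applies exclusions, and greedily enforces spatial diversity in
rank order: a candidate is dropped if its base-frame center lies strictly
within `diversity_radius` (default 1,000 px, Euclidean) of an
already-accepted result **on the same slide** — cross-slide distances are
undefined, so the rule is per-slide.  The filters consume an enlarged
candidate pool (10·k, doubling on shortfall) so k survivors normally exist;
if the database is exhausted first, the result list carries a `shortfall`
flag.

Coordinates are 0-based, top-left origin, half-open rectangles, stored in
the base (highest-magnification) frame; patches extracted at lower
magnification carry a `scale` factor mapping level pixels to base pixels.
Incomplete boundary tiles are dropped, never padded.

## Search index

Both search routes are exact.  `brute_force_knn` is the oracle: a full
distance scan ordered by (distance, record id, orientation) — the tie rule
is total, so results are platform-independent.  The k-d tree uses
median splits on the widest-spread axis and stops at ≤ 40 points per leaf or
depth 6 (both honored as stopping rules; they are redundant for correctness,
which branch-and-bound guarantees regardless).  Queries prune a subtree only
when the distance from the query to its bounding box strictly exceeds the
current k-th best distance, so boundary ties are always visited; both routes
compute distances with the same float64 accumulation over float32 storage
and therefore agree bit-for-bit.

## Embedders

The deep network that motivates the embedder contract is out of scope; the
contract (`embed_pixels` on a 224 × 224 RGB array) lets any vector-valued
image function plug in.  Every embedder input passes through one resize
contract: inputs must be 200–400 px per side and are resized to 224 × 224 by
**corner-aligned** bilinear interpolation (constants and linear ramps are
reproduced exactly, endpoints preserved; 224 px inputs pass through
unchanged, making the operation idempotent).  Corner alignment was chosen
over pixel-center alignment because it makes the resize analytically
predictable, which the test oracles exploit.

### Default engine: histogram descriptor

Raw feature (176 values): 16-bin intensity histograms per RGB channel
(area-normalized) concatenated with magnitude-weighted gradient-orientation
histograms (8 bins) over a 4 × 4 grid.  Two deliberate choices:

* Cell histograms are normalized by cell **area**, not total gradient
  energy: per-area gradient energy carries the texture's dominant spatial
  frequency, which energy normalization would cancel (a 1/32 factor keeps
  the block on the same scale as the intensity histograms).
* Angle bins are offset by half a bin width so axis-aligned gradient angles
  fall in bin interiors, making the eight dihedral transforms permute bins
  exactly.

The 176 raw values are projected to `output_dim` (default 128, must be a
multiple of 8) by a fixed seeded Gaussian matrix that is **group-averaged**
over D4: the projection intertwines the permutation action on raw features
with a regular-representation permutation of output coordinates.
Consequently embedding a rotated/mirrored patch permutes output coordinates
— an isometry — and the min-over-orientations distance used in search is
*exactly* invariant: querying any dihedral transform of a patch returns the
same result set.  A plain random projection would only give approximate
invariance and fails the orientation-invariance suite; this is the one place
the artifact's design departs from the simplest possible descriptor, and it
is what makes the eight-orientation database semantics testable rather than
merely heuristic.

### SIFT bag-of-visual-words baseline

Local SIFT descriptors (scikit-image) from a training set are clustered by
seeded k-means into a codebook (default 128 words, matching the default
engine's dimension; the aggregation scheme is this package's choice — the
classical baseline it models never specified one).  A patch embeds as the
L2-normalized histogram of nearest codewords; zero detected keypoints map to
the all-zero vector (a defined, distance-neutral fallback).  The codebook is
persisted beside the database manifest so queries reuse the identical
vocabulary.

## Evaluation machinery

Patches carry one flat label set: histologic features as plain strings,
organ and grade as `organ=`/`grade=` prefixed labels.  Match predicates
(feature, feature+organ, grade, grade+feature) operate on these channels; a
"hit" requires non-empty intersection of the relevant label sets, because
annotations are non-exhaustive and patches may legitimately carry several
features.  The top-5 score is the percentage of queries with ≥ 1 hit among
five results (empty result lists are misses).  Confusion entry (i, j) is the
fraction of class-i queries whose top-5 contains a class-j result; rows need
not sum to 1, and the diagonal equals the per-class top-5 score under
class-membership matching.

Balanced subsampling draws exact per-class counts without replacement, with
database and query patches from disjoint slide sets (a seeded greedy split
assigns just enough slides to the query pool to cover every class).

Statistics follow the study protocol: McNemar for paired binary metrics
(exact binomial when the discordant count b+c < 25 — the switch point is
this package's choice — chi-square with continuity correction otherwise;
p = 1 when b+c = 0), two-sided Mann–Whitney U for non-binary metrics (exact
enumeration when both samples are ≤ 20 and tie-free, normal approximation
with tie correction otherwise), Clopper–Pearson (beta-quantile) intervals
for binomial scores, and mean ± 1.96 SE for averaged rubric scores.

## Rater studies

Each query shows exactly four results, all from one hidden source: the
engine, or — with per-query Bernoulli probability 0.25, so arm counts are
approximate by design — uniform random retrieval.  The blinded export holds
query/result references and blank score columns only; the keyed answer file
re-joins losslessly on query id.  Rubrics: binary feature match (100 iff
feature sets intersect); 3-way organ match (100/0/"unclear", unclear results
leave the denominator and are reported as a fraction); and a 0/25/50/75/100
match-quality ladder over tumor presence, grade agreement and feature
overlap.  The human criterion "look visually different" at the ladder's
bottom rung is operationalized as an empty feature intersection — a
computable surrogate for automated self-tests; human raters remain free to
judge.  Study averages are flat means over all rated results (queries are
not reweighted).

## Synthetic world

The generator stands in for annotated whole-slide images.  Each texture
class is isotropic ring band-pass noise with a class-specific radial
frequency, log-spaced around a shared base (0.12 cycles/px, bandwidth 0.03)
with spread proportional to `separability`; at separability 0 every class
uses the same filter, so classes are exchangeable by construction.
Frequency was chosen as the class cue — rather than band *orientation* —
because orientation cues are ambiguous in an eight-orientation database (a
rotated class-A patch would imitate a class-B angle), and the retrieval
semantics demand that rotation never changes a patch's class.  "Organ"
applies a fixed hue palette (channel gains); "grade" adds an ordered density
of dark blobs.  Recorded labels are corrupted symmetrically with probability
1 − `label_purity` (default 0.7, mirroring the ~70% annotation purity of
real studies); ground truth is retained separately.  Patches are spread
round-robin over ≥ 8 synthetic slides on a 2,048 px grid, so the 1,000 px
diversity rule never suppresses legitimate distinct results and
slide-disjoint splits always exist.  Synthetic slides are x40/x20/x10/x5
pyramids with class textures painted into rectangles; annotation rectangles
are the painted regions shrunk to 80% of their area (centered), mirroring
the ~80% annotation coverage requested of annotators.

What a green test does *not* establish: the textures are stationary,
isotropic and noise-free compared to tissue; there is no stain variation,
no spatial correlation between neighboring patches' content, and class
structure is one-dimensional (frequency).  Synthetic results validate the
pipeline's mechanics and calibration, not absolute retrieval accuracy on
histology.

## Defaults and scaling in the test suite

Deployment-mirroring defaults: patch 300 px, embedding dim 128, k 5,
diversity radius 1,000 px, k-d tree leaf 40 / depth 6, random arm fraction
0.25, label purity 0.7.  The test and acceptance suites run fixtures at
224 px (the resize contract's identity point, keeping orientation tests
bit-exact and the suite fast), with clean labels (`purity = 1.0`) in the
separability sweeps to isolate retrieval behaviour from label noise, and
with per-class counts in the tens rather than thousands; study *arithmetic*
(45,000/9,000, 87,000/14,500, 40,000/8,000) is still exercised at full scale
on label-only records.  Published headline accuracies from slide-image
studies depend on a proprietary embedder and real tissue and are
deliberately not reproduction targets.

## Known limitations

* The k-d tree is single-machine and exact; distributed sharding and
  approximate hash-table hybrids are out of scope.
* The SIFT baseline's separability on synthetic band-pass textures is
  weaker than on real tissue structure; it is a baseline, not a reference.
* Inter-rater agreement statistics are not implemented.
* Proprietary whole-slide formats are not read; pyramids are represented as
  per-level image arrays/files.
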