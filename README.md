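# histosearch

Reverse image search for histopathology patches.

Pathologists often reason by analogy: "what does this region look like, and
where have I seen it before?"  `histosearch` implements the machinery behind
that workflow as content-based image retrieval over patch embeddings.  Image
patches (300 × 300 px RGB by default) are compressed to 128-dimensional
embedding vectors; because tissue has no preferred orientation, each stored
patch contributes **eight** vectors — one per element of the dihedral group
D4 (4 rotations × optional mirror).  A query patch is embedded once and its
k nearest stored vectors under L2 distance are retrieved through an exact
k-d tree (leaf size 40, depth 6), then filtered so that

* each distinct patch appears once, at its best-matching orientation, and
* no two results on the same slide lie within 1,000 px of each other
  (spatial diversity).

The package also ships the full evaluation machinery used to judge such a
system — balanced study designs, the top-5 score (fraction of queries whose
five results contain ≥ 1 correct match), class confusion matrices,
Clopper–Pearson intervals, McNemar and Mann–Whitney tests — plus blinded
rater-study tooling (randomized engine-vs-random assignment, 0–100 scoring
rubrics, blinded export / keyed re-join) and a seeded synthetic texture
generator so every part runs without any slide data.

The deep-ranking network used in production systems is deliberately **not**
included: any function mapping a 224 × 224 RGB array to a fixed-length
vector can stand behind the embedder contract.  Two embedders ship here: a
deterministic handcrafted descriptor (`HistogramEmbedder`, the default) and
a SIFT bag-of-visual-words baseline (`SiftBovwEmbedder`).

## Worked example

```python
from histosearch import (FixtureSpec, generate_patch_set, EmbeddingDatabase,
                         default_embedder, query, QueryOptions)

spec = FixtureSpec(n_classes=3, patches_per_cell=20, patch_size=224,
                   separability=2.0, label_purity=1.0, seed=7)
patches, truth = generate_patch_set(spec)

embedder = default_embedder()                       # 128-d, deterministic
db = EmbeddingDatabase.from_patches(patches, embedder)
db.build_index()                                    # exact k-d tree

results = query(db, embedder, patches[0],
                QueryOptions(k=5, exclude_self=True))
for r in results:
    print(r.rank, r.meta.slide_id, sorted(r.labels), round(r.distance, 4))
```

prints

```
1 synthslide5 ['tex0'] 0.1801
2 synthslide2 ['tex0'] 0.1863
3 synthslide3 ['tex0'] 0.1961
4 synthslide6 ['tex0'] 0.1963
5 synthslide7 ['tex0'] 0.2007
```

The query patch belongs to texture class `tex0`; all five retrieved patches
share that class, each from a different slide, ranked by increasing L2
distance between L2-normalized embeddings.  Querying any rotated or
mirrored copy of the same patch returns the same five patches: the
database's eight stored orientations plus the default embedder's
group-averaged projection make retrieval exactly orientation-invariant.

The same pipeline is available from the shell:

```bash
histosearch simulate --classes 3 --per-cell 20 --size 224 --seed 7 --out patches/
histosearch build    --patches patches/ --out db/
histosearch query    --db db/ --image patches/patch000000.png --k 5
histosearch evaluate --patches patches/ --db-per-class 8 --query-per-class 4 \
                     --engines default,random --seed 0 --report report.json
```

## Evaluation studies

`histosearch.evaluation` reproduces the standard study designs for this
kind of system: an organ-specific design (9 histologic features × 5,000
database / 1,000 query patches each), a multi-organ design (prostate,
breast, colon × 10 features, 29 valid cells × 3,000 / 500) and a
Gleason-grading design (NT/GP3/GP4/GP5 × 10,000 / 2,000), with balanced
slide-disjoint subsampling, per-class and overall top-5 scores, confusion
matrices and paired significance tests.  `histosearch.rater_study` builds
blinded prospective studies in which ~25% of queries are silently answered
by uniform random retrieval as a negative control.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch
at a desk scale: it generates a seeded 4-class texture world, builds the
orientation-augmented database, scores the default engine against the
random control in a balanced study (with McNemar comparison), runs a
blinded rater-style study with automated rubric scoring, and writes its
result object to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
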