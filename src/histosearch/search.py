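"""User-facing query pipeline.

A query is answered in five steps: embed orientation 0 of the (resized)
query patch; retrieve an enlarged candidate pool of nearest vectors over all
stored orientations; keep only each distinct patch's best orientation;
apply exclusions (the query itself and/or its slide); then greedily enforce
spatial diversity — walking candidates in rank order, drop any whose
base-frame center lies within ``diversity_radius`` pixels (Euclidean, same
slide) of an already-accepted result.  The first k survivors are returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .embedding import Embedder
from .imaging import Patch
from .index import EmbeddingDatabase, PatchMeta, brute_force_knn

__all__ = ["QueryOptions", "SearchResult", "SearchResultList", "query", "random_retrieval"]


@dataclass(frozen=True)
class QueryOptions:
    """Retrieval knobs; defaults follow the deployed system.

    ``diversity_radius`` is measured between patch centers in base-frame
    pixels, within a slide only (cross-slide distances are undefined).
    ``candidate_pool`` is the initial k-NN pool the dedup/diversity filters
    consume; it grows (doubling) on shortfall until the database is exhausted.
    """

    k: int = 5
    diversity_radius: float = 1000.0
    exclude_query_slide: bool = False
    exclude_self: bool = False
    candidate_pool: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.diversity_radius < 0:
            raise ValueError(
                f"diversity_radius must be >= 0, got {self.diversity_radius}"
            )


@dataclass(frozen=True)
class SearchResult:
    """One retrieved patch: best orientation, distance, and 1-based rank."""

    meta: PatchMeta
    orientation: int
    distance: float
    rank: int

    @property
    def record_id(self) -> int:
        return self.meta.record_id

    @property
    def labels(self) -> frozenset[str]:
        return self.meta.labels


class SearchResultList(list):
    """Ranked results; ``shortfall`` marks fewer than k survivors."""

    shortfall: bool = False


def _check_embedder(db: EmbeddingDatabase, embedder: Embedder) -> None:
    spec = embedder.spec
    if (
        spec["name"] != db.embedder_spec.get("name")
        or spec["output_dim"] != db.embedder_spec.get("output_dim")
    ):
        raise ValueError(
            f"query embedder {spec['name']}/{spec['output_dim']} does not match "
            f"database embedder {db.embedder_spec.get('name')}"
            f"/{db.embedder_spec.get('output_dim')}"
        )


def query(
    db: EmbeddingDatabase,
    embedder: Embedder,
    query_patch: Patch,
    options: QueryOptions | None = None,
) -> SearchResultList:
    """Retrieve the k most similar stored patches for a query patch.

    Only orientation 0 of the query is embedded: the database already stores
    all 8 dihedral orientations of every patch, so querying a rotated or
    mirrored copy reaches the same records through a different stored
    orientation.  Exactly one result is returned per distinct patch (its
    minimum-distance orientation).
    """
    options = options or QueryOptions()
    _check_embedder(db, embedder)
    vector = embedder.embed_query(query_patch.pixels)

    n_vectors = db.n_vectors
    pool = options.candidate_pool or 10 * options.k
    while True:
        pool = min(pool, n_vectors)
        neighbours = (
            db.index.query(vector, pool)
            if db.index is not None
            else brute_force_knn(db, vector, pool)
        )
        results = _filter(db, neighbours, query_patch, options)
        if len(results) >= options.k or pool >= n_vectors:
            break
        pool *= 2

    out = SearchResultList(results[: options.k])
    out.shortfall = len(out) < options.k
    return out


def _filter(db, neighbours, query_patch, options) -> list[SearchResult]:
    seen: set[int] = set()
    accepted: list[SearchResult] = []
    centers_by_slide: dict[str, list[tuple[float, float]]] = {}
    query_ref = query_patch.ref
    for record_id, orientation, distance in neighbours:
        if record_id in seen:
            continue  # keep only the best orientation per distinct patch
        seen.add(record_id)
        meta = db.metas[record_id]
        if options.exclude_self and meta.ref == query_ref:
            continue
        if options.exclude_query_slide and meta.slide_id == query_patch.slide_id:
            continue
        cx, cy = meta.center
        too_close = any(
            math.hypot(cx - ax, cy - ay) < options.diversity_radius
            for ax, ay in centers_by_slide.get(meta.slide_id, ())
        )
        if too_close:
            continue
        accepted.append(
            SearchResult(
                meta=meta,
                orientation=orientation,
                distance=distance,
                rank=len(accepted) + 1,
            )
        )
        centers_by_slide.setdefault(meta.slide_id, []).append((cx, cy))
        if len(accepted) >= options.k:
            break
    return accepted


def random_retrieval(db: EmbeddingDatabase, k: int, seed: int) -> SearchResultList:
    """Negative-control engine: k distinct patches sampled uniformly.

    Sampling is without replacement and seeded; distances are unset (NaN)
    because no similarity computation takes place.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(db):
        raise ValueError(f"cannot draw {k} distinct patches from {len(db)}")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(db), size=k, replace=False)
    out = SearchResultList(
        SearchResult(meta=db.metas[int(r)], orientation=0, distance=float("nan"), rank=i + 1)
        for i, r in enumerate(picks)
    )
    return out
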