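"""Embedding database: storage, brute-force search oracle, exact k-d tree.

A database holds N patch records, each with 8 orientation-tagged embedding
vectors, flattened to an ``(8N, dim)`` matrix for search.  Two k-NN routes
exist: :func:`brute_force_knn` (the oracle, a full distance scan) and
:class:`KdTree` (axis-aligned median splits, branch-and-bound with
bounding-box pruning — exact, so the two must agree on every instance).
Ties are broken by ``(record id, orientation)`` ascending so result order is
total and platform-independent.

On disk a database is a directory: ``manifest.json`` (format version,
embedder spec, shapes), ``patches.tsv`` (one row per record), and
``embeddings.f32`` (row-major little-endian float32, shape ``(8N, dim)``),
plus ``codebook.f32`` when the embedder carries a fitted vocabulary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .embedding import N_ORIENTATIONS, Embedder, EmbeddingRecord
from .imaging import Patch

__all__ = [
    "DatabaseFormatError",
    "PatchMeta",
    "Neighbor",
    "NeighborList",
    "KdTreeParams",
    "KdTree",
    "EmbeddingDatabase",
    "l2_distance",
    "brute_force_knn",
    "build_kdtree",
    "kdtree_knn",
    "save_database",
    "load_database",
]

FORMAT_VERSION = 1


class DatabaseFormatError(RuntimeError):
    """Persisted database is corrupt or from an incompatible version."""


@dataclass(frozen=True)
class PatchMeta:
    """Searchable metadata of one stored patch (pixels are not retained)."""

    record_id: int
    slide_id: str
    x: float
    y: float
    w: float
    h: float
    magnification: str
    labels: frozenset[str]

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def ref(self) -> tuple[str, float, float, str]:
        return (self.slide_id, self.x, self.y, self.magnification)


class Neighbor(NamedTuple):
    record_id: int
    orientation: int
    distance: float


class NeighborList(list):
    """Ranked neighbours; ``truncated`` flags k exceeding the vector count."""

    truncated: bool = False


def l2_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two equal-dimension vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def _distances(points: np.ndarray, query: np.ndarray) -> np.ndarray:
    # Shared by the oracle and the k-d tree so both produce bit-identical
    # distances (float64 accumulation over float32 storage).
    diff = points.astype(np.float64) - query.astype(np.float64)
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


@dataclass(frozen=True)
class KdTreeParams:
    """Stopping rules for tree construction (defaults follow deployment)."""

    leaf_size: int = 40
    max_depth: int = 6

    def __post_init__(self) -> None:
        if self.leaf_size < 1:
            raise ValueError(f"leaf_size must be >= 1, got {self.leaf_size}")
        if self.max_depth < 1:
            raise ValueError(f"max_depth must be >= 1, got {self.max_depth}")


class _Node:
    __slots__ = ("indices", "axis", "left", "right", "lo", "hi", "depth")

    def __init__(self, indices, depth, lo, hi):
        self.indices = indices  # None for internal nodes
        self.depth = depth
        self.lo = lo  # bounding box, per-dimension minima
        self.hi = hi
        self.axis = None
        self.left = None
        self.right = None


class KdTree:
    """Exact k-NN over the flattened vector matrix.

    Median splits along the widest-spread axis; a node becomes a leaf when it
    holds at most ``leaf_size`` points or sits at ``max_depth``.  Queries are
    branch-and-bound: a subtree is pruned only when the distance from the
    query to its bounding box strictly exceeds the current k-th best
    distance, so ties at the boundary are always visited and results match
    the brute-force oracle exactly.
    """

    def __init__(self, points: np.ndarray, params: KdTreeParams | None = None) -> None:
        self.points = np.ascontiguousarray(points, dtype=np.float32)
        if self.points.ndim != 2 or not len(self.points):
            raise ValueError("k-d tree needs a non-empty (n, dim) matrix")
        self.params = params or KdTreeParams()
        self.root = self._build(np.arange(len(self.points)), depth=0)

    def _build(self, indices: np.ndarray, depth: int) -> _Node:
        pts = self.points[indices]
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        node = _Node(None, depth, lo, hi)
        if len(indices) <= self.params.leaf_size or depth >= self.params.max_depth:
            node.indices = indices
            return node
        axis = int(np.argmax(hi - lo))
        order = np.argsort(pts[:, axis], kind="stable")
        mid = len(indices) // 2
        node.axis = axis
        node.left = self._build(indices[order[:mid]], depth + 1)
        node.right = self._build(indices[order[mid:]], depth + 1)
        return node

    # -- introspection used by structural tests ---------------------------

    def leaves(self) -> list[_Node]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.indices is not None:
                out.append(node)
            else:
                stack.extend((node.left, node.right))
        return out

    @property
    def depth(self) -> int:
        return max(leaf.depth for leaf in self.leaves())

    # -- search ------------------------------------------------------------

    def query(self, query_vector: np.ndarray, k: int) -> NeighborList:
        query_vector = np.asarray(query_vector, dtype=np.float64)
        if query_vector.shape != (self.points.shape[1],):
            raise ValueError(
                f"query dimension {query_vector.shape} does not match "
                f"index dimension ({self.points.shape[1]},)"
            )
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        truncated = k > len(self.points)
        k_eff = min(k, len(self.points))
        # Worst-first pool of (distance, flat index); full tuple comparisons
        # implement the (record, orientation) tie rule via the flat index.
        best: list[tuple[float, int]] = []

        def bbox_min_dist(node: _Node) -> float:
            delta = np.maximum(node.lo - query_vector, 0.0) + np.maximum(
                query_vector - node.hi, 0.0
            )
            return float(np.sqrt(np.sum(delta**2)))

        def visit(node: _Node) -> None:
            if node.indices is not None:
                dists = _distances(self.points[node.indices], query_vector)
                for d, idx in zip(dists, node.indices):
                    cand = (float(d), int(idx))
                    if len(best) < k_eff:
                        _heap_push(best, cand)
                    elif cand < best[0]:
                        _heap_replace(best, cand)
                return
            children = [node.left, node.right]
            children.sort(key=bbox_min_dist)
            for child in children:
                if len(best) < k_eff or bbox_min_dist(child) <= best[0][0]:
                    visit(child)

        visit(self.root)
        ranked = sorted(best)
        out = NeighborList(
            Neighbor(idx // N_ORIENTATIONS, idx % N_ORIENTATIONS, d)
            for d, idx in ranked
        )
        out.truncated = truncated
        return out


def _heap_push(heap: list, item: tuple) -> None:
    # Max-heap on (distance, flat index): store as-is, sift on inverted order.
    heap.append(item)
    i = len(heap) - 1
    while i > 0:
        parent = (i - 1) // 2
        if heap[parent] < heap[i]:
            heap[parent], heap[i] = heap[i], heap[parent]
            i = parent
        else:
            break


def _heap_replace(heap: list, item: tuple) -> None:
    heap[0] = item
    i, n = 0, len(heap)
    while True:
        left, right = 2 * i + 1, 2 * i + 2
        largest = i
        if left < n and heap[left] > heap[largest]:
            largest = left
        if right < n and heap[right] > heap[largest]:
            largest = right
        if largest == i:
            return
        heap[i], heap[largest] = heap[largest], heap[i]
        i = largest


class EmbeddingDatabase:
    """Persisted collection of embedding records plus optional search index."""

    def __init__(self, embedder_spec: dict, output_dim: int) -> None:
        self.embedder_spec = dict(embedder_spec)
        self.output_dim = int(output_dim)
        self.metas: list[PatchMeta] = []
        self._vectors: list[np.ndarray] = []
        self._matrix: np.ndarray | None = None
        self.index: KdTree | None = None
        self.codebook: np.ndarray | None = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_patches(
        cls, patches: list[Patch], embedder: Embedder
    ) -> "EmbeddingDatabase":
        """Embed every patch (all 8 orientations) into a fresh database."""
        db = cls(embedder.spec, embedder.output_dim)
        if getattr(embedder, "codebook", None) is not None:
            db.codebook = np.asarray(embedder.codebook)
        for patch in patches:
            db.add(patch, embedder.embed_patch(patch))
        return db

    def add(self, patch: Patch, record: EmbeddingRecord) -> int:
        if record.output_dim != self.output_dim:
            raise ValueError(
                f"record dim {record.output_dim} != database dim {self.output_dim}"
            )
        record_id = len(self.metas)
        x, y, w, h = patch.base_footprint
        self.metas.append(
            PatchMeta(
                record_id=record_id,
                slide_id=patch.slide_id,
                x=x,
                y=y,
                w=w,
                h=h,
                magnification=patch.magnification,
                labels=patch.labels,
            )
        )
        self._vectors.append(record.vectors)
        self._matrix = None
        self.index = None
        return record_id

    def add_record(self, meta: PatchMeta, vectors: np.ndarray) -> int:
        """Append a record from pre-computed vectors (no pixels involved)."""
        vectors = np.asarray(vectors, dtype=np.float32)
        if vectors.shape != (N_ORIENTATIONS, self.output_dim):
            raise ValueError(
                f"expected ({N_ORIENTATIONS}, {self.output_dim}) vectors, "
                f"got {vectors.shape}"
            )
        record_id = len(self.metas)
        self.metas.append(
            PatchMeta(
                record_id=record_id,
                slide_id=meta.slide_id,
                x=meta.x,
                y=meta.y,
                w=meta.w,
                h=meta.h,
                magnification=meta.magnification,
                labels=meta.labels,
            )
        )
        self._vectors.append(vectors)
        self._matrix = None
        self.index = None
        return record_id

    # -- views ---------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.metas)

    @property
    def n_vectors(self) -> int:
        return len(self.metas) * N_ORIENTATIONS

    @property
    def vectors(self) -> np.ndarray:
        """(N, 8, dim) float32 stack of all records."""
        return self.flat_vectors.reshape(len(self.metas), N_ORIENTATIONS, -1)

    @property
    def flat_vectors(self) -> np.ndarray:
        """(8N, dim) matrix; row ``8*r + o`` is record r, orientation o."""
        if self._matrix is None:
            if not self._vectors:
                raise ValueError("database is empty")
            self._matrix = np.ascontiguousarray(
                np.concatenate(self._vectors, axis=0), dtype=np.float32
            )
        return self._matrix

    def build_index(self, params: KdTreeParams | None = None) -> KdTree:
        self.index = KdTree(self.flat_vectors, params)
        return self.index

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        matrix = self.flat_vectors
        manifest = {
            "format_version": FORMAT_VERSION,
            "embedder": self.embedder_spec,
            "n_records": len(self.metas),
            "n_orientations": N_ORIENTATIONS,
            "output_dim": self.output_dim,
        }
        if self.codebook is not None:
            manifest["codebook_shape"] = list(self.codebook.shape)
            self.codebook.astype("<f4").tofile(path / "codebook.f32")
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        pd.DataFrame(
            {
                "record_id": [m.record_id for m in self.metas],
                "slide_id": [m.slide_id for m in self.metas],
                "x": [m.x for m in self.metas],
                "y": [m.y for m in self.metas],
                "w": [m.w for m in self.metas],
                "h": [m.h for m in self.metas],
                "magnification": [m.magnification for m in self.metas],
                "labels": [";".join(sorted(m.labels)) for m in self.metas],
            }
        ).to_csv(path / "patches.tsv", sep="\t", index=False)
        matrix.astype("<f4").tofile(path / "embeddings.f32")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingDatabase":
        path = Path(path)
        try:
            manifest = json.loads((path / "manifest.json").read_text())
        except FileNotFoundError as exc:
            raise DatabaseFormatError(f"no manifest.json under {path}") from exc
        if manifest.get("format_version") != FORMAT_VERSION:
            raise DatabaseFormatError(
                f"unsupported format version {manifest.get('format_version')!r}; "
                f"this build reads version {FORMAT_VERSION}"
            )
        n_records = int(manifest["n_records"])
        dim = int(manifest["output_dim"])
        db = cls(manifest["embedder"], dim)
        raw = np.fromfile(path / "embeddings.f32", dtype="<f4")
        expected = n_records * N_ORIENTATIONS * dim
        if raw.size != expected:
            raise DatabaseFormatError(
                f"embeddings.f32 holds {raw.size} values, expected {expected} "
                f"({n_records} records x {N_ORIENTATIONS} orientations x {dim})"
            )
        table = pd.read_csv(
            path / "patches.tsv", sep="\t", keep_default_na=False, dtype={"labels": str}
        )
        if len(table) != n_records:
            raise DatabaseFormatError(
                f"patches.tsv holds {len(table)} rows, manifest says {n_records}"
            )
        for row in table.itertuples(index=False):
            labels = frozenset(l for l in str(row.labels).split(";") if l)
            db.metas.append(
                PatchMeta(
                    record_id=int(row.record_id),
                    slide_id=str(row.slide_id),
                    x=float(row.x),
                    y=float(row.y),
                    w=float(row.w),
                    h=float(row.h),
                    magnification=str(row.magnification),
                    labels=labels,
                )
            )
        matrix = raw.reshape(n_records * N_ORIENTATIONS, dim)
        db._vectors = [
            matrix[i * N_ORIENTATIONS : (i + 1) * N_ORIENTATIONS]
            for i in range(n_records)
        ]
        db._matrix = np.ascontiguousarray(matrix)
        shape = manifest.get("codebook_shape")
        if shape:
            db.codebook = np.fromfile(path / "codebook.f32", dtype="<f4").reshape(
                shape
            ).astype(np.float64)
        return db


def brute_force_knn(
    db: EmbeddingDatabase, query_vector: np.ndarray, k: int
) -> NeighborList:
    """Exact k-NN by full scan — the oracle the k-d tree must reproduce.

    Returns the k globally smallest distances over all 8N vectors, ascending,
    ties broken by (record id, orientation).  ``k`` beyond the vector count
    returns everything with ``truncated`` set.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not len(db):
        raise ValueError("database is empty")
    query_vector = np.asarray(query_vector, dtype=np.float64)
    flat = db.flat_vectors
    if query_vector.shape != (flat.shape[1],):
        raise ValueError(
            f"query dimension {query_vector.shape} does not match "
            f"database dimension ({flat.shape[1]},)"
        )
    dists = _distances(flat, query_vector)
    order = np.lexsort(
        (np.arange(len(dists)) % N_ORIENTATIONS, np.arange(len(dists)) // N_ORIENTATIONS, dists)
    )
    truncated = k > len(dists)
    top = order[: min(k, len(dists))]
    out = NeighborList(
        Neighbor(int(i) // N_ORIENTATIONS, int(i) % N_ORIENTATIONS, float(dists[i]))
        for i in top
    )
    out.truncated = truncated
    return out


def build_kdtree(db: EmbeddingDatabase, params: KdTreeParams | None = None) -> KdTree:
    """Build (and attach) the accelerated index over a database."""
    return db.build_index(params)


def kdtree_knn(index: KdTree, query_vector: np.ndarray, k: int) -> NeighborList:
    """Exact k-NN through the tree; contractually identical to brute force."""
    return index.query(query_vector, k)


def save_database(db: EmbeddingDatabase, path: str | Path) -> None:
    db.save(path)


def load_database(path: str | Path) -> EmbeddingDatabase:
    return EmbeddingDatabase.load(path)
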