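"""Pluggable patch embedders.

The production system this package models compressed each 300x300 RGB patch
into eight 128-dimensional vectors (one per dihedral orientation) with a
proprietary deep ranking network.  That network is deliberately not part of
this artifact: any function mapping a 224x224 RGB array to a fixed-length
vector can stand behind the :class:`Embedder` contract.  Two concrete
embedders ship here:

* :class:`HistogramEmbedder` — a deterministic handcrafted descriptor
  (per-channel intensity histograms plus gridded gradient-orientation
  histograms, seeded random projection to the target dimension).  The
  default engine.
* :class:`SiftBovwEmbedder` — the classical baseline: local SIFT descriptors
  quantized against a seeded k-means codebook, the patch embedding being the
  normalized codeword histogram (bag of visual words).

All embeddings are L2-normalized so that L2 ranking is scale-free across
embedders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.color import rgb2gray
from skimage.feature import SIFT
from sklearn.cluster import KMeans

from .imaging import Patch, orient_pixels, resize_for_embedding

__all__ = [
    "NotFittedError",
    "EmbeddingRecord",
    "Embedder",
    "HistogramEmbedder",
    "SiftBovwEmbedder",
    "default_embedder",
    "sift_bovw_embedder",
    "storage_reduction_factor",
]

N_ORIENTATIONS = 8

#: Fixed seed of the HistogramEmbedder's random projection; part of the
#: embedder definition, not a tunable.
_PROJECTION_SEED = 20190719


class NotFittedError(RuntimeError):
    """An embedder requiring fitting (codebook) was used before fitting."""


@dataclass(frozen=True)
class EmbeddingRecord:
    """Eight orientation-tagged embedding vectors for one stored patch.

    ``patch_ref`` is ``(slide_id, x, y, magnification)``; ``vectors`` has
    shape ``(8, output_dim)`` with orientation ``i`` on row ``i``.
    """

    patch_ref: tuple[str, float, float, str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=np.float32)
        if vectors.ndim != 2 or vectors.shape[0] != N_ORIENTATIONS:
            raise ValueError(
                f"expected ({N_ORIENTATIONS}, dim) vectors, got {vectors.shape}"
            )
        if not np.all(np.isfinite(vectors)):
            raise ValueError("embedding vectors must be finite")
        object.__setattr__(self, "vectors", vectors)

    @property
    def output_dim(self) -> int:
        return self.vectors.shape[1]


def _l2_normalize(vector: np.ndarray) -> np.ndarray:
    norm = float(np.linalg.norm(vector))
    if norm > 0:
        vector = vector / norm
    return vector.astype(np.float32)


class Embedder:
    """Contract every embedder satisfies.

    Subclasses implement :meth:`embed_pixels` on a single 224x224 RGB array;
    the base class handles the orientation loop, the resize contract and
    L2 normalization.
    """

    name: str = "abstract"
    output_dim: int
    deterministic: bool = True

    @property
    def spec(self) -> dict:
        """Manifest-serializable description of the embedder."""
        return {
            "name": self.name,
            "output_dim": int(self.output_dim),
            "deterministic": bool(self.deterministic),
            "parameters": self.parameters(),
        }

    def parameters(self) -> dict:
        return {}

    def embed_pixels(self, pixels: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def embed_query(self, pixels: np.ndarray) -> np.ndarray:
        """Embed a query patch (orientation 0 only), resized and normalized."""
        return _l2_normalize(self.embed_pixels(resize_for_embedding(pixels)))

    def embed_patch(self, patch: Patch) -> EmbeddingRecord:
        """Embed all eight dihedral orientations of a stored patch."""
        w, h = patch.size
        if w != h:
            raise ValueError(f"database patches must be square, got {(w, h)}")
        vectors = np.stack(
            [
                _l2_normalize(
                    self.embed_pixels(
                        resize_for_embedding(orient_pixels(patch.pixels, i))
                    )
                )
                for i in range(N_ORIENTATIONS)
            ]
        )
        return EmbeddingRecord(patch_ref=patch.ref, vectors=vectors)


def _d4_multiplication_table() -> np.ndarray:
    """mul[a][b] = index of (transform a after transform b)."""
    marker = np.arange(48).reshape(4, 4, 3)
    oriented = [orient_pixels(marker, i) for i in range(8)]
    mul = np.zeros((8, 8), dtype=int)
    for a in range(8):
        for b in range(8):
            composed = orient_pixels(orient_pixels(marker, b), a)
            mul[a][b] = next(
                c for c in range(8) if np.array_equal(composed, oriented[c])
            )
    return mul


class HistogramEmbedder(Embedder):
    """Deterministic handcrafted descriptor, the default engine.

    The raw feature concatenates 16-bin intensity histograms per RGB channel
    (48 values, area-normalized) with magnitude-weighted gradient-orientation
    histograms (8 bins, offset by half a bin so dihedral transforms map bins
    onto bins exactly) on a 4x4 spatial grid (128 values).  Cell histograms
    are normalized by cell *area*, not by total gradient energy: the
    per-area energy scale carries the texture's dominant spatial frequency,
    which energy normalization would cancel.

    The 176 raw values are mapped to ``output_dim`` by a fixed seeded
    Gaussian projection that is *group-averaged* over the 8 dihedral
    transforms, so embedding a rotated or mirrored patch permutes output
    coordinates: distances between same-transform pairs are exactly
    preserved, which in turn makes the search module's min-over-orientations
    distance — and hence retrieval — exactly orientation-invariant.
    ``output_dim`` must be a multiple of 8 (the output carries a copy of the
    regular representation of the dihedral group).
    """

    name = "default"

    def __init__(
        self,
        output_dim: int = 128,
        intensity_bins: int = 16,
        grid: int = 4,
        orientation_bins: int = 8,
    ) -> None:
        if output_dim < 8 or output_dim % 8:
            raise ValueError(
                f"output_dim must be a positive multiple of 8, got {output_dim}"
            )
        self.output_dim = int(output_dim)
        self.intensity_bins = int(intensity_bins)
        self.grid = int(grid)
        self.orientation_bins = int(orientation_bins)
        self._raw_dim = 3 * self.intensity_bins + self.grid**2 * self.orientation_bins
        self._feature_perms = self._derive_feature_permutations()
        self.output_perms = self._output_permutations()
        rng = np.random.default_rng(_PROJECTION_SEED)
        p0 = rng.standard_normal((self._raw_dim, self.output_dim)) / np.sqrt(
            self._raw_dim
        )
        # Intertwining average: P = mean_a P0[fperm_a][:, operm_a] satisfies
        # raw_features(T x) @ P == (raw_features(x) @ P)[operm_T].
        projection = np.zeros_like(p0)
        for a in range(8):
            projection += p0[self._feature_perms[a]][:, self.output_perms[a]]
        self._projection = projection / 8.0

    def parameters(self) -> dict:
        return {
            "intensity_bins": self.intensity_bins,
            "grid": self.grid,
            "orientation_bins": self.orientation_bins,
            "projection_seed": _PROJECTION_SEED,
        }

    def _raw_features(self, pixels: np.ndarray) -> np.ndarray:
        pixels = np.asarray(pixels, dtype=np.float64)
        features = []
        n_px = pixels.shape[0] * pixels.shape[1]
        for c in range(3):
            hist, _ = np.histogram(
                pixels[:, :, c], bins=self.intensity_bins, range=(0.0, 256.0)
            )
            features.append(hist / n_px)
        gray = pixels.mean(axis=2)
        gy, gx = np.gradient(gray)
        magnitude = np.hypot(gx, gy)
        # Half-bin offset keeps axis-aligned gradient angles off bin edges,
        # so the 8 dihedral transforms permute bins without edge effects.
        angle = np.mod(
            np.arctan2(gy, gx) - np.pi / self.orientation_bins, 2.0 * np.pi
        )
        h, w = gray.shape
        rows = np.linspace(0, h, self.grid + 1).astype(int)
        cols = np.linspace(0, w, self.grid + 1).astype(int)
        for i in range(self.grid):
            for j in range(self.grid):
                cell = np.s_[rows[i] : rows[i + 1], cols[j] : cols[j + 1]]
                hist, _ = np.histogram(
                    angle[cell],
                    bins=self.orientation_bins,
                    range=(0.0, 2.0 * np.pi),
                    weights=magnitude[cell],
                )
                n_cell = (rows[i + 1] - rows[i]) * (cols[j + 1] - cols[j])
                # 1/32 balances gradient magnitudes against the O(1)
                # intensity-histogram block in the shared projection.
                features.append(hist / (32.0 * max(n_cell, 1)))
        return np.concatenate(features)

    def _derive_feature_permutations(self) -> np.ndarray:
        """perms[o] with raw_features(T_o x)[p] == raw_features(x)[perms[o][p]].

        Derived empirically on a fixed random image: intensity histograms are
        transform-invariant (identity block); each gradient (cell, bin)
        coordinate of the transformed image is matched to its unique source
        coordinate by value.
        """
        rng = np.random.default_rng(_PROJECTION_SEED + 1)
        probe = rng.integers(0, 256, size=(32, 32, 3)).astype(np.float64)
        f0 = self._raw_features(probe)
        n_int = 3 * self.intensity_bins
        perms = np.zeros((8, self._raw_dim), dtype=int)
        scale = np.abs(f0).max()
        for o in range(8):
            fo = self._raw_features(orient_pixels(probe, o))
            perms[o, :n_int] = np.arange(n_int)
            for p in range(n_int, self._raw_dim):
                diffs = np.abs(f0 - fo[p])
                q = int(np.argmin(diffs))
                if diffs[q] > 1e-9 * max(scale, 1.0):
                    raise AssertionError(
                        f"feature permutation for orientation {o} not exact "
                        f"(residual {diffs[q]:.2e} at coordinate {p})"
                    )
                perms[o, p] = q
            if len(set(perms[o, n_int:].tolist())) != self._raw_dim - n_int:
                raise AssertionError(
                    f"feature permutation for orientation {o} is not a bijection"
                )
        return perms

    def _output_permutations(self) -> np.ndarray:
        """Regular-representation action on output coordinates (blocks of 8)."""
        mul = _d4_multiplication_table()
        m = self.output_dim // 8
        perms = np.zeros((8, self.output_dim), dtype=int)
        for o in range(8):
            for g in range(8):
                for j in range(m):
                    perms[o, g * m + j] = mul[g][o] * m + j
        return perms

    def embed_pixels(self, pixels: np.ndarray) -> np.ndarray:
        return self._raw_features(pixels) @ self._projection


class SiftBovwEmbedder(Embedder):
    """SIFT bag-of-visual-words baseline.

    Local SIFT descriptors from a training set are clustered with seeded
    k-means into a ``codebook_size``-word vocabulary (default 128, matching
    the embedding dimension of the default engine).  A patch is embedded as
    the L2-normalized histogram of its descriptors' nearest codewords; a
    patch with no detected keypoints maps to the all-zero vector.
    """

    name = "sift_bovw"

    def __init__(self, codebook_size: int = 128, seed: int = 0) -> None:
        if codebook_size < 2:
            raise ValueError(f"codebook_size must be >= 2, got {codebook_size}")
        self.output_dim = int(codebook_size)
        self.seed = int(seed)
        self.codebook: np.ndarray | None = None

    def parameters(self) -> dict:
        return {"codebook_size": self.output_dim, "seed": self.seed}

    @property
    def is_fitted(self) -> bool:
        return self.codebook is not None

    @staticmethod
    def _descriptors(pixels: np.ndarray) -> np.ndarray:
        gray = rgb2gray(np.clip(np.asarray(pixels, dtype=np.float64) / 255.0, 0, 1))
        sift = SIFT()
        try:
            sift.detect_and_extract(gray)
        except RuntimeError:  # skimage raises when no keypoints survive
            return np.empty((0, 128))
        return np.asarray(sift.descriptors, dtype=np.float64)

    def fit(self, training_patches: list[Patch]) -> "SiftBovwEmbedder":
        """Build the codebook from the training patches' SIFT descriptors."""
        stacks = [
            d
            for p in training_patches
            for d in [self._descriptors(resize_for_embedding(p.pixels))]
            if len(d)
        ]
        descriptors = np.vstack(stacks) if stacks else np.empty((0, 128))
        if len(descriptors) < self.output_dim:
            raise ValueError(
                f"codebook of size {self.output_dim} needs at least "
                f"{self.output_dim} SIFT descriptors; training patches "
                f"yielded {len(descriptors)}"
            )
        kmeans = KMeans(
            n_clusters=self.output_dim, random_state=self.seed, n_init=4
        ).fit(descriptors)
        self.codebook = np.asarray(kmeans.cluster_centers_, dtype=np.float64)
        return self

    @classmethod
    def from_codebook(cls, codebook: np.ndarray, seed: int = 0) -> "SiftBovwEmbedder":
        """Rebuild an embedder from a persisted codebook (query-side reuse)."""
        codebook = np.asarray(codebook, dtype=np.float64)
        embedder = cls(codebook_size=codebook.shape[0], seed=seed)
        embedder.codebook = codebook
        return embedder

    def codeword_histogram(self, pixels: np.ndarray) -> np.ndarray:
        """Raw (unnormalized) codeword counts; entries sum to keypoint count."""
        if self.codebook is None:
            raise NotFittedError(
                "SIFT bag-of-visual-words embedder used before fit(); "
                "fit a codebook or load one with from_codebook()"
            )
        descriptors = self._descriptors(pixels)
        counts = np.zeros(self.output_dim, dtype=np.float64)
        if len(descriptors):
            words = np.argmin(cdist(descriptors, self.codebook), axis=1)
            counts += np.bincount(words, minlength=self.output_dim)
        return counts

    def embed_pixels(self, pixels: np.ndarray) -> np.ndarray:
        return self.codeword_histogram(pixels)


def default_embedder(dim: int = 128) -> HistogramEmbedder:
    """The deterministic default engine at the standard 128 dimensions."""
    return HistogramEmbedder(output_dim=dim)


def sift_bovw_embedder(
    training_patches: list[Patch], codebook_size: int = 128, seed: int = 0
) -> SiftBovwEmbedder:
    """Fit the SIFT bag-of-visual-words baseline on ``training_patches``."""
    return SiftBovwEmbedder(codebook_size=codebook_size, seed=seed).fit(
        training_patches
    )


def storage_reduction_factor(
    patch_side: int = 300, channels: int = 3, output_dim: int = 128
) -> float:
    """Raw pixel values per patch divided by stored embedding values.

    At the defaults (300x300x3 pixels, 8 orientations x 128 values) this is
    ~264, i.e. a ~260-fold dimensionality reduction.
    """
    return (patch_side * patch_side * channels) / (N_ORIENTATIONS * output_dim)
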