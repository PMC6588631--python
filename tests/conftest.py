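import numpy as np
import pytest

from histosearch.embedding import HistogramEmbedder, EmbeddingRecord, N_ORIENTATIONS
from histosearch.imaging import Patch
from histosearch.index import EmbeddingDatabase, PatchMeta
from histosearch.synthetic import FixtureSpec, generate_patch_set


@pytest.fixture(scope="session")
def default_emb() -> HistogramEmbedder:
    return HistogramEmbedder()


@pytest.fixture(scope="session")
def fixture_patches():
    """48 well-separated texture patches: 4 classes x 12, clean labels.

    224 px so the embedding resize is an exact no-op, keeping the suite fast
    and orientation tests bit-exact.
    """
    spec = FixtureSpec(
        n_classes=4,
        patches_per_cell=12,
        patch_size=224,
        separability=2.0,
        label_purity=1.0,
        seed=2,
    )
    patches, truth = generate_patch_set(spec)
    return patches, truth


@pytest.fixture(scope="session")
def fixture_db(fixture_patches, default_emb) -> EmbeddingDatabase:
    patches, _ = fixture_patches
    db = EmbeddingDatabase.from_patches(patches, default_emb)
    db.build_index()
    return db


def make_vector_db(
    n_records: int,
    dim: int,
    seed: int,
    n_slides: int = 4,
    labels_cycle: tuple = (),
    spacing: float = 5000.0,
) -> EmbeddingDatabase:
    """Database of random unit vectors with synthetic metadata (no pixels)."""
    rng = np.random.default_rng(seed)
    db = EmbeddingDatabase({"name": "synthetic-vectors", "output_dim": dim}, dim)
    for i in range(n_records):
        vectors = rng.standard_normal((N_ORIENTATIONS, dim))
        vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
        labels = (
            frozenset({labels_cycle[i % len(labels_cycle)]}) if labels_cycle else frozenset()
        )
        meta = PatchMeta(
            record_id=i,
            slide_id=f"slide{i % n_slides}",
            x=(i // n_slides) * spacing,
            y=float(i % n_slides),
            w=300.0,
            h=300.0,
            magnification="10x",
            labels=labels,
        )
        db.add_record(meta, vectors)
    return db


def make_patch(pixels: np.ndarray, slide_id: str = "s0", origin=(0.0, 0.0), labels=()):
    return Patch(
        slide_id=slide_id,
        origin=origin,
        magnification="10x",
        pixels=pixels,
        labels=frozenset(labels),
    )
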