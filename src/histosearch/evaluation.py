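"""Large-scale quantitative study harness.

Retrieval accuracy is measured with the *top-5 score*: the percentage of
queries whose five results contain at least one correct match under the
active match predicate (histologic feature, feature+organ, grade, or
grade+feature).  Patches carry a flat label set in which histologic features
are plain strings while organ and grade ride dedicated prefixes
(``organ=prostate``, ``grade=GP3``), so one label channel flows through the
database TSV unchanged.

Class-balanced databases and query sets are drawn without replacement, with
database and query patches taken from disjoint slide sets (mirroring the
deployed studies, whose query slides were separate from database slides).

Statistics follow the study protocol: McNemar for paired binary metrics,
Mann-Whitney U for non-binary ones, Clopper-Pearson intervals for binomial
scores and mean +/- 1.96 SE otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .embedding import Embedder
from .imaging import Patch
from .index import EmbeddingDatabase
from .search import QueryOptions, SearchResult, query, random_retrieval

__all__ = [
    "ORGAN_PREFIX",
    "GRADE_PREFIX",
    "HISTOLOGIC_FEATURES",
    "GLEASON_CATEGORIES",
    "feature_labels",
    "organ_of",
    "grade_of",
    "MATCH_PREDICATES",
    "StudyDesign",
    "organ_specific_design",
    "multi_organ_design",
    "gleason_design",
    "balanced_subsample",
    "hit_vector",
    "top5_score",
    "confusion_matrix",
    "EngineResult",
    "EvaluationReport",
    "run_study",
    "mcnemar_test",
    "mann_whitney_u",
    "clopper_pearson_ci",
    "normal_ci",
    "random_top5_expected",
]

ORGAN_PREFIX = "organ="
GRADE_PREFIX = "grade="

#: The ten histologic feature categories used across the deployed studies.
HISTOLOGIC_FEATURES = (
    "artery",
    "capillary",
    "fat",
    "lymphatic vessel",
    "lymphocyte",
    "nerve",
    "normal epithelium",
    "smooth muscle",
    "stroma",
    "vein",
)

#: Non-tumor plus the three Gleason growth patterns, ordered by severity.
GLEASON_CATEGORIES = ("NT", "GP3", "GP4", "GP5")


def feature_labels(labels: frozenset[str]) -> frozenset[str]:
    """Histologic-feature subset of a label set (prefixes stripped out)."""
    return frozenset(
        l for l in labels if not l.startswith((ORGAN_PREFIX, GRADE_PREFIX))
    )


def organ_of(labels: frozenset[str]) -> str | None:
    for l in labels:
        if l.startswith(ORGAN_PREFIX):
            return l[len(ORGAN_PREFIX) :]
    return None


def grade_of(labels: frozenset[str]) -> str | None:
    for l in labels:
        if l.startswith(GRADE_PREFIX):
            return l[len(GRADE_PREFIX) :]
    return None


def _feature_match(q: frozenset[str], r: frozenset[str]) -> bool:
    return bool(feature_labels(q) & feature_labels(r))


def _feature_organ_match(q: frozenset[str], r: frozenset[str]) -> bool:
    organ_q, organ_r = organ_of(q), organ_of(r)
    return _feature_match(q, r) and organ_q is not None and organ_q == organ_r


def _gleason_match(q: frozenset[str], r: frozenset[str]) -> bool:
    grade_q, grade_r = grade_of(q), grade_of(r)
    return grade_q is not None and grade_q == grade_r


def _gleason_feature_match(q: frozenset[str], r: frozenset[str]) -> bool:
    return _gleason_match(q, r) and _feature_match(q, r)


MATCH_PREDICATES: dict[str, Callable[[frozenset, frozenset], bool]] = {
    "feature": _feature_match,
    "feature_organ": _feature_organ_match,
    "gleason": _gleason_match,
    "gleason_feature": _gleason_feature_match,
}


# --------------------------------------------------------------------------
# study designs


@dataclass(frozen=True)
class StudyDesign:
    """One balanced retrieval study: classes and per-class sample counts.

    A *class* is the frozenset of labels a patch must carry to belong to it
    (e.g. ``{"artery", "organ=prostate"}``).  Combinations that never occur
    (prostate lymphocyte) are simply absent from ``classes``.
    """

    name: str
    classes: tuple[frozenset[str], ...]
    db_per_class: int
    query_per_class: int
    predicate: str = "feature"

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("design needs at least one class")
        if self.db_per_class < 1 or self.query_per_class < 1:
            raise ValueError("per-class counts must be positive")
        if self.predicate not in MATCH_PREDICATES:
            raise ValueError(f"unknown match predicate {self.predicate!r}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def database_total(self) -> int:
        return self.n_classes * self.db_per_class

    @property
    def query_total(self) -> int:
        return self.n_classes * self.query_per_class

    def class_of(self, labels: frozenset[str]) -> frozenset[str] | None:
        """First class whose required labels the patch carries, else None."""
        for cls in self.classes:
            if cls <= labels:
                return cls
        return None

    def class_name(self, cls: frozenset[str]) -> str:
        return "|".join(sorted(cls))


def organ_specific_design(
    db_per_class: int = 5000, query_per_class: int = 1000
) -> StudyDesign:
    """Prostate-only study over 9 histologic features.

    No lymphocytes were found in the prostate slides, so that category is
    absent and 9 of the 10 features remain; at the defaults this is a
    45,000-patch database and 9,000 queries.
    """
    features = tuple(f for f in HISTOLOGIC_FEATURES if f != "lymphocyte")
    classes = tuple(
        frozenset({f, ORGAN_PREFIX + "prostate"}) for f in features
    )
    return StudyDesign("organ-specific", classes, db_per_class, query_per_class, "feature")


def multi_organ_design(
    db_per_class: int = 3000, query_per_class: int = 500
) -> StudyDesign:
    """Prostate/breast/colon study over 10 features per organ.

    The prostate-lymphocyte combination is excluded (none found), leaving 29
    feature-organ cells: 87,000 database patches and 14,500 queries at the
    defaults.
    """
    classes = []
    for organ in ("prostate", "breast", "colon"):
        for feature in HISTOLOGIC_FEATURES:
            if organ == "prostate" and feature == "lymphocyte":
                continue
            classes.append(frozenset({feature, ORGAN_PREFIX + organ}))
    return StudyDesign(
        "multi-organ", tuple(classes), db_per_class, query_per_class, "feature_organ"
    )


def gleason_design(
    db_per_class: int = 10000, query_per_class: int = 2000
) -> StudyDesign:
    """Prostate Gleason-grading study over NT/GP3/GP4/GP5.

    40,000 database patches and 8,000 queries at the defaults.
    """
    classes = tuple(frozenset({GRADE_PREFIX + g}) for g in GLEASON_CATEGORIES)
    return StudyDesign("gleason", classes, db_per_class, query_per_class, "gleason")


def balanced_subsample(
    patches: Sequence,
    design: StudyDesign,
    seed: int,
    require_disjoint_slides: bool = True,
) -> tuple[list, list]:
    """Draw the design's balanced database and query sets without replacement.

    Slides are first split (seeded shuffle) into a query pool just large
    enough to cover every class's query count and a database pool with the
    rest, so the two sets share no slide.  Each item needs only ``labels``
    and ``slide_id`` attributes; pixels are not touched, so label-only
    records work for design-count checks.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[frozenset, list] = {cls: [] for cls in design.classes}
    for patch in patches:
        cls = design.class_of(frozenset(patch.labels))
        if cls is not None:
            by_class[cls].append(patch)

    if require_disjoint_slides:
        # Per-slide class tallies let the greedy split run in O(slides).
        slide_counts: dict[str, dict[frozenset, int]] = {}
        for cls, plist in by_class.items():
            for p in plist:
                slide_counts.setdefault(p.slide_id, {}).setdefault(cls, 0)
                slide_counts[p.slide_id][cls] += 1
        slides = sorted(slide_counts)
        order = rng.permutation(len(slides))
        query_slides: set[str] = set()
        covered = {cls: 0 for cls in design.classes}
        for i in order:
            if all(n >= design.query_per_class for n in covered.values()):
                break
            slide = slides[i]
            query_slides.add(slide)
            for cls, n in slide_counts[slide].items():
                covered[cls] += n
    else:
        query_slides = set()

    db_set: list = []
    query_set: list = []
    for cls in design.classes:
        plist = by_class[cls]
        if require_disjoint_slides:
            q_pool = [p for p in plist if p.slide_id in query_slides]
            d_pool = [p for p in plist if p.slide_id not in query_slides]
        else:
            order = rng.permutation(len(plist))
            plist = [plist[i] for i in order]
            q_pool = plist[: design.query_per_class]
            d_pool = plist[design.query_per_class :]
        for pool, count, role, target in (
            (q_pool, design.query_per_class, "query", query_set),
            (d_pool, design.db_per_class, "database", db_set),
        ):
            if len(pool) < count:
                raise ValueError(
                    f"class {design.class_name(cls)} has only {len(pool)} "
                    f"{role} patches, {count - len(pool)} short of the "
                    f"required {count}"
                )
            picks = rng.choice(len(pool), size=count, replace=False)
            target.extend(pool[int(i)] for i in picks)
    return db_set, query_set


# --------------------------------------------------------------------------
# scoring


def hit_vector(
    results_per_query: Sequence[Sequence[SearchResult]],
    query_labels: Sequence[frozenset[str]],
    match_predicate: str | Callable = "feature",
) -> np.ndarray:
    """Boolean per query: does the top-5 hold at least one correct match?"""
    if isinstance(match_predicate, str):
        match_predicate = MATCH_PREDICATES[match_predicate]
    if len(results_per_query) != len(query_labels):
        raise ValueError("results and query labels differ in length")
    hits = np.zeros(len(query_labels), dtype=bool)
    for i, (results, labels) in enumerate(zip(results_per_query, query_labels)):
        labels = frozenset(labels)
        hits[i] = any(match_predicate(labels, r.labels) for r in results)
    return hits


def top5_score(
    results_per_query: Sequence[Sequence[SearchResult]],
    query_labels: Sequence[frozenset[str]],
    match_predicate: str | Callable = "feature",
) -> float:
    """Percentage of queries with >= 1 correct result in their top 5.

    An empty result list counts as a miss.
    """
    for results in results_per_query:
        if len(results) > 5:
            raise ValueError("top-5 score expects at most 5 results per query")
    hits = hit_vector(results_per_query, query_labels, match_predicate)
    return 100.0 * float(hits.mean()) if len(hits) else 0.0


def confusion_matrix(
    results_per_query: Sequence[Sequence[SearchResult]],
    query_labels: Sequence[frozenset[str]],
    design: StudyDesign,
) -> pd.DataFrame:
    """Class-by-class retrieval confusion.

    Entry (i, j) is the fraction of class-i queries whose top-5 contains at
    least one class-j result.  Rows need not sum to 1 (a query's five
    results can span several classes) and the diagonal is, by construction,
    the per-class top-5 score under class-membership matching.
    """
    names = [design.class_name(c) for c in design.classes]
    counts = pd.DataFrame(0.0, index=names, columns=names)
    totals = pd.Series(0, index=names, dtype=int)
    for results, labels in zip(results_per_query, query_labels):
        q_cls = design.class_of(frozenset(labels))
        if q_cls is None:
            continue
        q_name = design.class_name(q_cls)
        totals[q_name] += 1
        hit_classes = {
            design.class_name(cls)
            for r in results
            for cls in [design.class_of(r.labels)]
            if cls is not None
        }
        for name in hit_classes:
            counts.loc[q_name, name] += 1.0
    nonzero = totals.replace(0, 1)
    return counts.div(nonzero, axis=0)


# --------------------------------------------------------------------------
# statistics


def mcnemar_test(hits_a: Sequence[bool], hits_b: Sequence[bool]) -> float:
    """Paired McNemar test on two engines' per-query hit vectors.

    Exact binomial on the discordant pairs when there are fewer than 25 of
    them, chi-square with continuity correction otherwise.  No discordant
    pairs means the engines are indistinguishable: p = 1.
    """
    hits_a = np.asarray(hits_a, dtype=bool)
    hits_b = np.asarray(hits_b, dtype=bool)
    if hits_a.shape != hits_b.shape:
        raise ValueError("paired hit vectors must have equal length")
    b = int(np.sum(hits_a & ~hits_b))
    c = int(np.sum(~hits_a & hits_b))
    if b + c == 0:
        return 1.0
    table = [[0, b], [c, 0]]  # only the off-diagonal enters the test
    result = _sm_mcnemar(table, exact=(b + c < 25), correction=True)
    return float(min(result.pvalue, 1.0))


def mann_whitney_u(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U test between two independent score samples.

    Exact enumeration for small tie-free samples (both n <= 20), normal
    approximation with tie correction otherwise.  Identical constant samples
    give p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not len(a) or not len(b):
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    return float(
        sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def clopper_pearson_ci(
    successes: int, n: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must be in [0, {n}], got {successes}")
    lower = 0.0 if successes == 0 else float(
        sps.beta.ppf(alpha / 2, successes, n - successes + 1)
    )
    upper = 1.0 if successes == n else float(
        sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    )
    return (lower, upper)


def normal_ci(values: Sequence[float]) -> tuple[float, float]:
    """Mean +/- 1.96 standard errors, for non-binary score averages."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("normal CI needs at least 2 values")
    mean = float(values.mean())
    half = 1.96 * float(values.std(ddof=1)) / math.sqrt(len(values))
    return (mean - half, mean + half)


def random_top5_expected(n_classes: int, k: int = 5) -> float:
    """Closed-form top-5 score of uniform retrieval on balanced classes.

    With C balanced single-label classes and k independent uniform draws the
    chance of at least one class match is 1 - ((C-1)/C)^k, as a percentage.
    """
    return 100.0 * (1.0 - ((n_classes - 1) / n_classes) ** k)


# --------------------------------------------------------------------------
# study runner


@dataclass
class EngineResult:
    """One engine's scores on a study."""

    engine: str
    score: float
    ci: tuple[float, float]
    n_queries: int
    per_class: dict[str, float]
    confusion: pd.DataFrame
    hits: np.ndarray

    def to_dict(self) -> dict:
        return {
            "engine": self.engine,
            "top5_score": self.score,
            "clopper_pearson_95": list(self.ci),
            "n_queries": self.n_queries,
            "per_class_top5": self.per_class,
            "confusion_matrix": {
                "classes": list(self.confusion.index),
                "rows": [list(map(float, row)) for _, row in self.confusion.iterrows()],
            },
        }


@dataclass
class EvaluationReport:
    """All engines' results on one study plus pairwise McNemar tests."""

    design_name: str
    predicate: str
    n_queries: int
    engines: dict[str, EngineResult]
    mcnemar: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "design": self.design_name,
            "match_predicate": self.predicate,
            "n_queries": self.n_queries,
            "engines": {name: res.to_dict() for name, res in sorted(self.engines.items())},
            "mcnemar_p": dict(sorted(self.mcnemar.items())),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def run_study(
    engines: dict[str, tuple[EmbeddingDatabase, Embedder] | str],
    query_patches: Sequence[Patch],
    design: StudyDesign,
    seed: int = 0,
    options: QueryOptions | None = None,
) -> EvaluationReport:
    """Score one or more engines on an identical query set.

    ``engines`` maps a name either to ``(database, embedder)`` or to the
    string ``"random"`` (uniform retrieval from the first real engine's
    database).  Query slides are excluded from retrieval by default, matching
    the deployed studies whose query slides were disjoint from the database.
    All engines must search databases over the same patch set.
    """
    options = options or QueryOptions(k=5, exclude_query_slide=True)
    real = {n: e for n, e in engines.items() if e != "random"}
    if not real and any(e == "random" for e in engines.values()):
        raise ValueError("the random engine needs a real engine's database")
    sizes = {len(db) for db, _ in real.values()}
    if len(sizes) > 1:
        raise ValueError(f"engines search databases of different sizes: {sizes}")

    query_labels = [frozenset(p.labels) for p in query_patches]
    rng = np.random.default_rng(seed)
    results: dict[str, EngineResult] = {}
    for name, engine in sorted(engines.items()):
        if engine == "random":
            db = next(iter(real.values()))[0]
            seeds = rng.integers(0, 2**31 - 1, size=len(query_patches))
            per_query = [
                random_retrieval(db, min(options.k, len(db)), int(s)) for s in seeds
            ]
        else:
            db, embedder = engine
            if db.index is None:
                db.build_index()
            per_query = [query(db, embedder, p, options) for p in query_patches]
        hits = hit_vector(per_query, query_labels, design.predicate)
        score = 100.0 * float(hits.mean())
        confusion = confusion_matrix(per_query, query_labels, design)
        per_class = {name_: float(100.0 * confusion.loc[name_, name_]) for name_ in confusion.index}
        lo, hi = clopper_pearson_ci(int(hits.sum()), len(hits))
        results[name] = EngineResult(
            engine=name,
            score=score,
            ci=(100.0 * lo, 100.0 * hi),
            n_queries=len(hits),
            per_class=per_class,
            confusion=confusion,
            hits=hits,
        )

    tests: dict[str, float] = {}
    names = sorted(results)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            tests[f"{a}_vs_{b}"] = mcnemar_test(results[a].hits, results[b].hits)
    return EvaluationReport(
        design_name=design.name,
        predicate=design.predicate,
        n_queries=len(query_patches),
        engines=results,
        mcnemar=tests,
    )
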