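"""Blinded prospective-study machinery.

In the deployed prospective studies pathologists rated search results without
knowing whether each query's results came from the retrieval engine or from
random selection (the negative control, ~25% of queries; all four results of
a query share one source).  This module builds the randomized assignments,
writes the blinded rater-facing export and its keyed answer file, applies the
scoring rubrics, and aggregates scores per source group.

Rubrics (all scores on a 0-100 scale):

* binary feature match — 100 iff the query and result share at least one
  histologic feature;
* 3-way organ match — 100 / 0 / "unclear" (unclear results are excluded
  from the match denominator, their fraction reported separately);
* overall match quality — a 0/25/50/75/100 ladder over tumor presence,
  grade agreement and feature overlap.  The human criterion "look visually
  different" is operationalized for automated scoring as an empty feature
  intersection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .embedding import Embedder
from .evaluation import feature_labels, grade_of, normal_ci
from .imaging import Patch
from .index import EmbeddingDatabase
from .search import QueryOptions, SearchResult, query, random_retrieval

__all__ = [
    "RESULTS_PER_QUERY",
    "RaterAssignment",
    "make_assignments",
    "export_blinded",
    "export_answer_key",
    "rejoin_with_key",
    "binary_feature_score",
    "organ_match_score",
    "match_quality_score",
    "labels_for_scoring",
    "aggregate_scores",
]

#: Every query shows the rater exactly four results.
RESULTS_PER_QUERY = 4


@dataclass(frozen=True)
class RaterAssignment:
    """One query's four results and their (hidden) source."""

    query_id: int
    query_patch: Patch
    results: tuple[SearchResult, ...]
    source: str  # "engine" | "random"; never written to the rater export

    def __post_init__(self) -> None:
        if len(self.results) != RESULTS_PER_QUERY:
            raise ValueError(
                f"each query must carry exactly {RESULTS_PER_QUERY} results, "
                f"got {len(self.results)}"
            )
        if self.source not in ("engine", "random"):
            raise ValueError(f"unknown source {self.source!r}")


def make_assignments(
    query_patches: Sequence[Patch],
    db: EmbeddingDatabase,
    embedder: Embedder,
    random_fraction: float = 0.25,
    seed: int = 0,
    options: QueryOptions | None = None,
) -> list[RaterAssignment]:
    """Assign each query independently to the engine or the random control.

    Assignment is per-query Bernoulli(``random_fraction``), so final group
    counts are approximate, as in the deployed studies.  Engine queries get
    the search pipeline's top four results; control queries get four patches
    drawn uniformly from the same database.
    """
    if not 0.0 <= random_fraction <= 1.0:
        raise ValueError(f"random_fraction must be in [0, 1], got {random_fraction}")
    options = options or QueryOptions(k=RESULTS_PER_QUERY, exclude_query_slide=True)
    if options.k != RESULTS_PER_QUERY:
        raise ValueError(f"rater studies use k={RESULTS_PER_QUERY}")
    rng = np.random.default_rng(seed)
    assignments = []
    for qid, patch in enumerate(query_patches):
        use_random = rng.random() < random_fraction
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if use_random:
            results = random_retrieval(db, RESULTS_PER_QUERY, sub_seed)
            source = "random"
        else:
            results = query(db, embedder, patch, options)
            if len(results) < RESULTS_PER_QUERY:
                raise ValueError(
                    f"query {qid} returned only {len(results)} results; "
                    f"database too small or filters too strict"
                )
            source = "engine"
        assignments.append(
            RaterAssignment(
                query_id=qid,
                query_patch=patch,
                results=tuple(results),
                source=source,
            )
        )
    return assignments


def _ref_string(slide_id: str, x: float, y: float, magnification: str) -> str:
    return f"{slide_id}:{x:g}:{y:g}:{magnification}"


def _assignment_frame(assignments: Sequence[RaterAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        row = {
            "query_id": a.query_id,
            "query_ref": _ref_string(*a.query_patch.ref),
        }
        for i, r in enumerate(a.results, start=1):
            row[f"result_{i}"] = _ref_string(*r.meta.ref)
            row[f"score_{i}"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def export_blinded(assignments: Sequence[RaterAssignment], path: str | Path) -> pd.DataFrame:
    """Write the rater-facing TSV: refs and blank score columns, no source."""
    frame = _assignment_frame(assignments)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def export_answer_key(assignments: Sequence[RaterAssignment], path: str | Path) -> pd.DataFrame:
    """Write the keyed answer TSV carrying each query's hidden source."""
    frame = pd.DataFrame(
        {
            "query_id": [a.query_id for a in assignments],
            "source": [a.source for a in assignments],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
    return frame


def rejoin_with_key(export_path: str | Path, key_path: str | Path) -> pd.DataFrame:
    """Re-join a (scored) blinded export with its answer key on query id."""
    export = pd.read_csv(export_path, sep="\t")
    key = pd.read_csv(key_path, sep="\t")
    return export.merge(key, on="query_id", validate="one_to_one")


# --------------------------------------------------------------------------
# scoring rubrics


def binary_feature_score(
    query_features: frozenset[str] | set[str],
    result_features: frozenset[str] | set[str],
) -> int:
    """100 iff the two patches share at least one histologic feature."""
    return 100 if set(query_features) & set(result_features) else 0


def organ_match_score(
    query_organ: str | None, result_organ: str | None, unclear: bool = False
) -> int | str:
    """3-way organ rubric: 100 / 0 / ``"unclear"``.

    ``unclear`` models the rater being unable to call the result's organ
    site; such results leave the match denominator.
    """
    if unclear or result_organ is None or query_organ is None:
        return "unclear"
    return 100 if query_organ == result_organ else 0


def match_quality_score(query_labels: dict, result_labels: dict) -> int:
    """Overall 0-100 match quality in 25-point steps.

    Each side is ``{"tumor": bool, "grade": str | None, "features": set}``;
    grade is required whenever tumor is true.  The ladder:

    * 0   — tumor presence mismatches and no feature overlap (the automated
            surrogate for "look visually different");
    * 25  — tumor presence mismatches but features overlap;
    * 50  — tumor presence matches but the grades differ;
    * 75  — grades match, or both patches are non-tumor;
    * 100 — as 75, plus at least one shared histologic feature.
    """
    for side, labels in (("query", query_labels), ("result", result_labels)):
        if labels["tumor"] and labels.get("grade") is None:
            raise ValueError(f"{side} patch is tumor but carries no grade")
    q_feat = set(query_labels.get("features", ()))
    r_feat = set(result_labels.get("features", ()))
    overlap = bool(q_feat & r_feat)
    if query_labels["tumor"] != result_labels["tumor"]:
        return 25 if overlap else 0
    if query_labels["tumor"] and query_labels["grade"] != result_labels["grade"]:
        return 50
    return 100 if overlap else 75


def labels_for_scoring(labels: frozenset[str]) -> dict:
    """Convert a patch's flat label set into match-quality rubric inputs.

    The non-tumor grade category ("NT") maps to ``tumor=False``.
    """
    grade = grade_of(labels)
    tumor = grade is not None and grade != "NT"
    return {
        "tumor": tumor,
        "grade": grade if tumor else None,
        "features": set(feature_labels(labels)),
    }


def aggregate_scores(
    scored: Sequence[tuple[str, int | str]],
) -> dict[str, dict]:
    """Average individual result scores within each source group.

    ``scored`` holds ``(source, score)`` per rated result, the score being a
    number or ``"unclear"``.  The final average is the flat mean over all
    rated results in the group (queries are not reweighted); "unclear"
    results leave the denominator and are reported as a fraction.  A group
    with any unscored (None) result raises.
    """
    groups: dict[str, list] = {}
    for i, (source, score) in enumerate(scored):
        if score is None:
            raise ValueError(f"result {i} (source {source}) is unscored")
        groups.setdefault(source, []).append(score)
    out: dict[str, dict] = {}
    for source, values in sorted(groups.items()):
        numeric = [float(v) for v in values if v != "unclear"]
        n_unclear = len(values) - len(numeric)
        entry: dict = {
            "n": len(numeric),
            "unclear_fraction": n_unclear / len(values) if values else 0.0,
        }
        if numeric:
            entry["mean"] = float(np.mean(numeric))
            entry["ci"] = normal_ci(numeric) if len(numeric) >= 2 else (
                entry["mean"],
                entry["mean"],
            )
        out[source] = entry
    return out
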