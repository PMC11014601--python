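"""Relative feature importance for the tree backend.

Raw per-iteration feature scores from the gradient-boosted-tree model are
normalized to proportions (each iteration's scores divided by their total,
so they express importance relative to every other feature), averaged
across CV iterations, and ranked.  Features scoring 0 in every iteration
are excluded.  Each pair-vector column originates from either the
metabolite block or the pathway block; the same atom color can appear in
both, so a reported feature carries the rank of its counterpart in the
other block when that counterpart exists and was itself included.  A
feature's *associated pathways* are the categories whose raw summed count
for that atom color is positive — i.e. some member metabolite contains the
substructure.

Importance is defined only for the tree backend; the perceptron exposes no
comparable per-feature score and requesting it raises
:class:`~pathpairs.exceptions.UnsupportedOperationError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError, UnsupportedOperationError
from .matrix import FeatureMatrix

__all__ = ["ImportanceReport", "relative_importance", "associated_pathways",
           "paired_ranks"]


@dataclass
class ImportanceReport:
    """Ranked mean relative importances over included features.

    ``table`` columns: feature_id, origin, mean_importance, rank, and (after
    :func:`paired_ranks`) pathway_rank / metabolite_rank; importances of
    included features sum to 1 within each iteration before averaging, so
    the mean_importance column itself sums to 1.
    """

    table: pd.DataFrame
    n_iterations: int
    n_excluded: int

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        if "associated_pathways" in out.columns:
            out["associated_pathways"] = out["associated_pathways"].map(
                lambda s: ";".join(sorted(s)) if isinstance(s, (set, frozenset)) else s
            )
        out.to_csv(path, sep="\t", index=False)


def relative_importance(
    raw_scores_per_iteration: Sequence[np.ndarray],
    feature_schema: Sequence[tuple[str, str]],
    exponential: bool = False,
) -> ImportanceReport:
    """Normalize, average and rank per-iteration feature scores.

    Per iteration, scores are turned into proportions over all features
    (or, with ``exponential=True``, into an exponential softmax); features
    with raw score 0 in every iteration are excluded; the rest are ranked
    1..K by descending mean, ties broken by column order.
    """
    if len(raw_scores_per_iteration) == 0:
        raise ValueError("need at least one iteration of scores")
    S = np.vstack([np.asarray(s, dtype=np.float64) for s in raw_scores_per_iteration])
    if S.shape[1] != len(feature_schema):
        raise SchemaError("score width does not match feature schema")
    if np.any(S < 0):
        raise ValueError("raw importance scores must be non-negative")
    if exponential:
        # exp-softmax over all features, per iteration
        E = np.exp(S - S.max(axis=1, keepdims=True))
        P = E / E.sum(axis=1, keepdims=True)
    else:
        totals = S.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        P = S / totals
    # exp(0) > 0, so the zero-exclusion rule only applies to proportions
    included = (
        np.arange(S.shape[1]) if exponential else np.flatnonzero(S.sum(axis=0) > 0)
    )
    mean = P[:, included].mean(axis=0)
    order = np.lexsort((included, -mean))  # descending mean, column order ties
    table = pd.DataFrame(
        {
            "feature_id": [feature_schema[included[i]][1] for i in order],
            "origin": [feature_schema[included[i]][0] for i in order],
            "mean_importance": mean[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    return ImportanceReport(table, S.shape[0], S.shape[1] - len(included))


def associated_pathways(
    feature_id: str, raw_pathway_sums: FeatureMatrix
) -> set[str]:
    """Pathway categories in which the atom color occurs at all.

    Judged on the *raw* (pre-normalization) pathway sums: a positive summed
    count means at least one member metabolite contains the substructure.
    """
    try:
        j = raw_pathway_sums.feature_ids.index(feature_id)
    except ValueError:
        raise SchemaError(f"feature {feature_id!r} not in the pathway-sum matrix")
    col = raw_pathway_sums.values[:, j]
    return {raw_pathway_sums.row_ids[i] for i in np.flatnonzero(col > 0)}


def paired_ranks(report: ImportanceReport) -> ImportanceReport:
    """Attach the counterpart rank from the other block for each feature.

    A pathway feature's ``pathway_rank`` is its own rank and its
    ``metabolite_rank`` is the rank of the same atom color among the
    metabolite-block features (and vice versa).  Counterparts missing from
    the report — de-duplicated away, or scoring 0 in every iteration — are
    left unavailable (NA).
    """
    t = report.table
    by_key = {(o, f): r for o, f, r in zip(t.origin, t.feature_id, t["rank"])}
    pathway_rank, metabolite_rank = [], []
    for origin, fid, rank in zip(t.origin, t.feature_id, t["rank"]):
        other = "pathway" if origin == "metabolite" else "metabolite"
        counterpart = by_key.get((other, fid))
        if origin == "pathway":
            pathway_rank.append(rank)
            metabolite_rank.append(counterpart)
        else:
            metabolite_rank.append(rank)
            pathway_rank.append(counterpart)
    out = t.copy()
    out["pathway_rank"] = pd.array(pathway_rank, dtype="Int64")
    out["metabolite_rank"] = pd.array(metabolite_rank, dtype="Int64")
    return ImportanceReport(out, report.n_iterations, report.n_excluded)


def check_importance_backend(backend: str) -> None:
    """Raise for backends without per-feature scores."""
    if backend != "gbt":
        raise UnsupportedOperationError(
            "feature importance is only available for the tree backend (gbt)"
        )
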