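"""Feature matrices of atom-color substructure counts and their transforms.

A metabolite is represented by the counts of *atom colors* — string-encoded
descriptions of an atom plus its bonded neighborhood — found in its molecular
structure.  Each atom color has a *bond inclusion level*: 0 is the bare
element, higher levels add progressively more bonded context.  A pathway
category is represented by summing the count vectors of its member
metabolites.  Because categories differ in membership size, raw sums are not
comparable across categories; they are normalized within each bond level by
dividing every count by the total count of all atom colors of that level
(a proportion), which makes a category with 1,486 members comparable to one
with 611.  Metabolite rows are normalized with the identical rule.

This module holds the container types (:class:`FeatureMatrix`,
:class:`PathwayCatalog`, :class:`DedupMap`, :class:`ScaleParams`) and the
matrix-level operations: pathway aggregation, per-bond-level normalization,
exact column de-duplication, and min-max scaling, plus HDF5/CSV/JSON/TSV I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .exceptions import (
    DegeneratePathwayError,
    EmptyInputError,
    MembershipError,
    MetadataError,
    SchemaError,
)

__all__ = [
    "FeatureMatrix",
    "PathwayCatalog",
    "DedupMap",
    "ScaleParams",
    "aggregate_pathway_features",
    "normalize_within_bond_level",
    "deduplicate_columns",
    "minmax_fit",
    "minmax_apply",
]


@dataclass
class FeatureMatrix:
    """Entries x features table of non-negative finite values.

    Parameters
    ----------
    row_ids
        Unique entry identifiers (metabolite or pathway ids).
    feature_ids
        Unique column identifiers (atom-color strings, or latent indices
        after encoding).
    values
        2-D float array, shape ``(len(row_ids), len(feature_ids))``.
    bond_levels
        Optional per-column bond-inclusion level (non-negative ints).
        ``None`` for matrices where the notion no longer applies
        (e.g. auto-encoded latents).
    """

    row_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    bond_levels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.row_ids = [str(r) for r in self.row_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise SchemaError("values must be a 2-D array")
        if self.values.shape != (len(self.row_ids), len(self.feature_ids)):
            raise SchemaError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.feature_ids)} columns"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise SchemaError("duplicate row ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise SchemaError("duplicate feature ids")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError("values must be finite")
        if np.any(self.values < 0):
            raise SchemaError("values must be non-negative")
        if self.bond_levels is not None:
            self.bond_levels = np.asarray(self.bond_levels, dtype=np.int64)
            if self.bond_levels.shape != (len(self.feature_ids),):
                raise SchemaError("bond_levels must have one entry per column")
            if np.any(self.bond_levels < 0):
                raise SchemaError("bond levels must be >= 0")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def row_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.row_ids)}

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            list(self.row_ids),
            list(self.feature_ids),
            self.values.copy(),
            None if self.bond_levels is None else self.bond_levels.copy(),
        )

    # ------------------------------------------------------------------ I/O
    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("row_ids", data=np.array(self.row_ids, dtype="S"))
            f.create_dataset("feature_ids", data=np.array(self.feature_ids, dtype="S"))
            if self.bond_levels is not None:
                f.create_dataset("bond_levels", data=self.bond_levels)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "FeatureMatrix":
        with h5py.File(path, "r") as f:
            values = f["values"][...]
            row_ids = [r.decode() for r in f["row_ids"][...]]
            feature_ids = [c.decode() for c in f["feature_ids"][...]]
            bond_levels = f["bond_levels"][...] if "bond_levels" in f else None
        return cls(row_ids, feature_ids, values, bond_levels)

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        """Write values with a header of feature ids; bond levels go to a
        sidecar ``<path>.bond_levels.tsv`` of (feature_id, bond_level)."""
        df = pd.DataFrame(self.values, index=self.row_ids, columns=self.feature_ids)
        df.to_csv(path, sep=sep, index_label="id")
        if self.bond_levels is not None:
            side = Path(str(path) + ".bond_levels.tsv")
            pd.DataFrame(
                {"feature_id": self.feature_ids, "bond_level": self.bond_levels}
            ).to_csv(side, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = ",") -> "FeatureMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        bond_levels = None
        side = Path(str(path) + ".bond_levels.tsv")
        if side.exists():
            meta = pd.read_csv(side, sep="\t", dtype={"feature_id": str})
            lookup = dict(zip(meta["feature_id"], meta["bond_level"]))
            try:
                bond_levels = np.array([lookup[str(c)] for c in df.columns])
            except KeyError as e:  # pragma: no cover - malformed sidecar
                raise MetadataError(f"sidecar missing bond level for column {e}")
        return cls(
            [str(r) for r in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(),
            bond_levels,
        )


@dataclass
class PathwayCatalog:
    """Ordered pathway categories, each with its set of member metabolites."""

    pathways: list[tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        norm: list[tuple[str, frozenset[str]]] = []
        seen: set[str] = set()
        for pid, members in self.pathways:
            pid = str(pid)
            if pid in seen:
                raise SchemaError(f"duplicate pathway id {pid!r}")
            seen.add(pid)
            norm.append((pid, frozenset(str(m) for m in members)))
        self.pathways = norm

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "PathwayCatalog":
        return cls([(k, frozenset(v)) for k, v in d.items()])

    @property
    def pathway_ids(self) -> list[str]:
        return [p for p, _ in self.pathways]

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)

    def members(self, pathway_id: str) -> frozenset[str]:
        for pid, members in self.pathways:
            if pid == pathway_id:
                return members
        raise SchemaError(f"unknown pathway id {pathway_id!r}")

    def validate_against(self, metab: FeatureMatrix) -> None:
        known = set(metab.row_ids)
        for pid, members in self.pathways:
            if not members:
                raise DegeneratePathwayError(f"pathway {pid!r} has no members")
            missing = members - known
            if missing:
                raise MembershipError(
                    f"pathway {pid!r} references unknown metabolites: "
                    f"{sorted(missing)[:5]}"
                )

    def to_json(self, path: str | Path) -> None:
        d = {pid: sorted(members) for pid, members in self.pathways}
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PathwayCatalog":
        d = json.loads(Path(path).read_text())
        return cls.from_dict(d)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (pid, m) for pid, members in self.pathways for m in sorted(members)
        ]
        pd.DataFrame(rows, columns=["pathway_id", "metabolite_id"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PathwayCatalog":
        df = pd.read_csv(path, sep="\t", dtype=str)
        order: dict[str, set[str]] = {}
        for pid, mid in zip(df["pathway_id"], df["metabolite_id"]):
            order.setdefault(pid, set()).add(mid)
        return cls.from_dict(order)


@dataclass
class DedupMap:
    """Reversible record of column de-duplication.

    ``kept`` lists retained column indices (original positions, in order);
    ``alias_of`` maps each removed column index to the kept index carrying
    identical values.  Applying the map to the reduced matrix reconstructs
    the original bit-exactly.
    """

    kept: list[int]
    alias_of: dict[int, int]

    def __post_init__(self) -> None:
        kept_set = set(self.kept)
        if kept_set & set(self.alias_of):
            raise SchemaError("a column cannot be both kept and aliased")
        for removed, target in self.alias_of.items():
            if target not in kept_set:
                raise SchemaError(
                    f"alias target {target} of removed column {removed} not kept"
                )

    @property
    def n_original(self) -> int:
        return len(self.kept) + len(self.alias_of)

    def restore(self, reduced: FeatureMatrix, original_feature_ids: Sequence[str],
                original_bond_levels: np.ndarray | None = None) -> FeatureMatrix:
        """Reconstruct the pre-dedup matrix from the reduced one."""
        if reduced.n_features != len(self.kept):
            raise SchemaError("reduced matrix width does not match kept columns")
        pos_of_kept = {orig: j for j, orig in enumerate(self.kept)}
        cols = np.empty((reduced.n_rows, self.n_original), dtype=reduced.values.dtype)
        for orig in range(self.n_original):
            src = pos_of_kept[orig] if orig in pos_of_kept else pos_of_kept[self.alias_of[orig]]
            cols[:, orig] = reduced.values[:, src]
        return FeatureMatrix(
            list(reduced.row_ids), list(original_feature_ids), cols, original_bond_levels
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"kept": self.kept,
                 "alias_of": {str(k): v for k, v in self.alias_of.items()}}
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DedupMap":
        d = json.loads(Path(path).read_text())
        return cls(list(d["kept"]), {int(k): v for k, v in d["alias_of"].items()})


@dataclass
class ScaleParams:
    """Per-feature observed minima and maxima for min-max scaling."""

    feature_ids: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=np.float64)
        self.maxs = np.asarray(self.maxs, dtype=np.float64)
        if np.any(self.maxs < self.mins):
            raise SchemaError("max < min in scale parameters")


def aggregate_pathway_features(
    metab: FeatureMatrix, catalog: PathwayCatalog
) -> FeatureMatrix:
    """Sum member-metabolite count vectors into one row per pathway category.

    The resulting cell (p, f) is the number of occurrences of atom color *f*
    across all metabolites in category *p*.
    """
    catalog.validate_against(metab)
    idx = metab.row_index()
    rows = np.empty((catalog.n_pathways, metab.n_features), dtype=np.float64)
    for i, (pid, members) in enumerate(catalog.pathways):
        member_rows = [idx[m] for m in sorted(members)]
        rows[i] = metab.values[member_rows].sum(axis=0)
    return FeatureMatrix(
        catalog.pathway_ids, list(metab.feature_ids), rows,
        None if metab.bond_levels is None else metab.bond_levels.copy(),
    )


def normalize_within_bond_level(m: FeatureMatrix) -> FeatureMatrix:
    """Convert counts to per-row proportions within each bond-inclusion level.

    For each row and each bond level, every value is divided by the total of
    all values of that level in that row; a level whose total is zero stays
    all-zero.  E.g. a carbon count of 1,000 out of a 10,000 elemental total
    becomes 0.1.  Idempotent, and invariant to rescaling any one (row, level)
    group by a positive constant.
    """
    if m.bond_levels is None:
        raise MetadataError("normalization requires per-column bond levels")
    out = m.values.astype(np.float64).copy()
    for level in np.unique(m.bond_levels):
        cols = m.bond_levels == level
        totals = out[:, cols].sum(axis=1, keepdims=True)
        nz = totals[:, 0] > 0
        out[np.ix_(nz, cols)] /= totals[nz]
    return FeatureMatrix(list(m.row_ids), list(m.feature_ids), out, m.bond_levels.copy())


def deduplicate_columns(
    m: FeatureMatrix, tolerance: float = 0.0
) -> tuple[FeatureMatrix, DedupMap]:
    """Drop columns whose value vectors duplicate an earlier column.

    The first occurrence (in column order) is kept.  With the default
    ``tolerance=0`` equality is exact bitwise comparison — appropriate because
    normalized values are exact ratios computed identically for identical
    count columns.  A positive tolerance switches to per-element absolute
    comparison.
    """
    if m.n_features == 0:
        raise EmptyInputError("cannot de-duplicate an empty matrix")
    kept: list[int] = []
    alias_of: dict[int, int] = {}
    if tolerance == 0.0:
        seen: dict[bytes, int] = {}
        cols = np.ascontiguousarray(m.values.T)
        for j in range(m.n_features):
            key = cols[j].tobytes()
            if key in seen:
                alias_of[j] = seen[key]
            else:
                seen[key] = j
                kept.append(j)
    else:
        for j in range(m.n_features):
            match = None
            for k in kept:
                if np.all(np.abs(m.values[:, j] - m.values[:, k]) <= tolerance):
                    match = k
                    break
            if match is None:
                kept.append(j)
            else:
                alias_of[j] = match
    reduced = FeatureMatrix(
        list(m.row_ids),
        [m.feature_ids[j] for j in kept],
        m.values[:, kept],
        None if m.bond_levels is None else m.bond_levels[kept],
    )
    return reduced, DedupMap(kept, alias_of)


def minmax_fit(m: FeatureMatrix) -> ScaleParams:
    """Record per-feature minima and maxima."""
    return ScaleParams(
        list(m.feature_ids), m.values.min(axis=0), m.values.max(axis=0)
    )


def minmax_apply(m: FeatureMatrix, p: ScaleParams) -> FeatureMatrix:
    """Scale each feature to (x - min) / (max - min); constant features map to 0."""
    if list(m.feature_ids) != list(p.feature_ids):
        raise SchemaError("scale parameters were fit on different columns")
    span = p.maxs - p.mins
    safe = np.where(span > 0, span, 1.0)
    out = (m.values - p.mins) / safe
    out[:, span == 0] = 0.0
    out = np.clip(out, 0.0, None)
    return FeatureMatrix(
        list(m.row_ids), list(m.feature_ids), out,
        None if m.bond_levels is None else m.bond_levels.copy(),
    )
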