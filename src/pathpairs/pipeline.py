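"""End-to-end feature engineering: counts in, paired feature blocks out.

Order of operations: sum member-metabolite counts into raw pathway vectors,
normalize both blocks within each bond-inclusion level, then de-duplicate
the pathway columns (pathway categories are few, so many columns coincide
exactly after normalization).  The de-duplicated pathway block feeds the
classifier directly; the *non*-de-duplicated block — which shares its width
with the metabolite block — feeds the auto-encoder when encoded features
are requested.
"""

from __future__ import annotations

from dataclasses import dataclass

from .encoder import EncoderModel, EncoderTrainConfig, encode_block, fit_autoencoder
from .matrix import (
    DedupMap,
    FeatureMatrix,
    PathwayCatalog,
    aggregate_pathway_features,
    deduplicate_columns,
    minmax_apply,
    minmax_fit,
    normalize_within_bond_level,
)

__all__ = ["FeatureSets", "build_feature_sets", "EncodedSets", "build_encoded_sets"]


@dataclass
class FeatureSets:
    """All feature matrices derived from one (counts, catalog) input."""

    metabolite: FeatureMatrix        # normalized metabolite block
    pathway: FeatureMatrix           # normalized, de-duplicated pathway block
    pathway_full: FeatureMatrix      # normalized pathway block, pre-dedup
    pathway_raw_sums: FeatureMatrix  # raw summed counts (importance attribution)
    dedup_map: DedupMap


def build_feature_sets(
    metab_counts: FeatureMatrix,
    catalog: PathwayCatalog,
    dedup_tolerance: float = 0.0,
) -> FeatureSets:
    """Aggregate, normalize and de-duplicate in the canonical order."""
    raw_sums = aggregate_pathway_features(metab_counts, catalog)
    pathway_full = normalize_within_bond_level(raw_sums)
    metabolite = normalize_within_bond_level(metab_counts)
    pathway, dmap = deduplicate_columns(pathway_full, tolerance=dedup_tolerance)
    return FeatureSets(metabolite, pathway, pathway_full, raw_sums, dmap)


@dataclass
class EncodedSets:
    """Auto-encoded counterparts of the two blocks, plus the fitted model."""

    metabolite: FeatureMatrix
    pathway: FeatureMatrix
    model: EncoderModel


def build_encoded_sets(
    sets: FeatureSets,
    ratio: float = 0.1,
    train_cfg: EncoderTrainConfig | None = None,
) -> EncodedSets:
    """Fit the auto-encoder on both blocks stacked and encode each block.

    The stack pairs the metabolite block with the pre-dedup pathway block so
    widths agree; both are min-max scaled feature-wise (parameters fit on
    the stack) before training, and the latent outputs are min-max scaled
    again inside :func:`~pathpairs.encoder.encode_block`.
    """
    import numpy as np

    m, p = sets.metabolite, sets.pathway_full
    stacked = FeatureMatrix(
        [f"m::{r}" for r in m.row_ids] + [f"p::{r}" for r in p.row_ids],
        list(m.feature_ids),
        np.vstack([m.values, p.values]),
        None,
    )
    scale = minmax_fit(stacked)
    stacked_scaled = minmax_apply(stacked, scale)
    model = fit_autoencoder(stacked_scaled, ratio=ratio, train_cfg=train_cfg)
    m_scaled = minmax_apply(
        FeatureMatrix(m.row_ids, m.feature_ids, m.values, None), scale
    )
    p_scaled = minmax_apply(
        FeatureMatrix(p.row_ids, p.feature_ids, p.values, None), scale
    )
    return EncodedSets(
        encode_block(model, m_scaled), encode_block(model, p_scaled), model
    )
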