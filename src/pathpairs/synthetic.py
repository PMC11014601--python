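"""Seeded synthetic metabolite matrices and pathway catalogs.

The generator emulates the statistical structure the pair-classification
method assumes: sparse non-negative substructure-count columns grouped into
bond-inclusion levels, and overlapping pathway memberships drawn so that
roughly 10% of metabolite-pathway pairs are positive (the imbalance of the
KEGG-derived benchmark).  Each pathway category owns a disjoint *signature*
set of features whose count rates are elevated for its member metabolites;
``signal_strength`` dials that elevation from chance-level (0) to easily
learnable.  :func:`planted_separable` builds the deterministic extreme: one
designated feature per pathway that is nonzero exactly for that pathway's
members, so labels are a function of the pair features and a correct
pipeline can reach MCC 1 in-sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError
from .matrix import FeatureMatrix, PathwayCatalog

__all__ = ["SynthConfig", "generate", "planted_separable"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults give a small but learnable benchmark-like
    fixture (~300 metabolites, 6 pathway categories, 200 count features,
    ~10.6% positive pairs)."""

    n_metabolites: int = 300
    n_pathways: int = 6
    n_features: int = 200
    n_bond_levels: int = 3
    signature_size: int = 10
    signal_strength: float = 5.0
    membership_probability: float = 0.106
    base_rate: float = 1.0
    count_distribution: str = "poisson"  # or "negative_binomial"
    nb_dispersion: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_metabolites, self.n_pathways, self.n_features,
               self.n_bond_levels) < 1:
            raise ConfigError("all dimensions must be positive")
        if self.signature_size * self.n_pathways > self.n_features:
            raise ConfigError(
                "signatures need signature_size * n_pathways <= n_features"
            )
        if not 0.0 <= self.membership_probability <= 1.0:
            raise ConfigError("membership_probability must lie in [0, 1]")
        if self.signal_strength < 0 or self.base_rate < 0:
            raise ConfigError("rates must be >= 0")
        if self.count_distribution not in ("poisson", "negative_binomial"):
            raise ConfigError(
                f"unknown count distribution {self.count_distribution!r}"
            )


def _draw_counts(
    rng: np.random.Generator, rates: np.ndarray, cfg: SynthConfig
) -> np.ndarray:
    if cfg.count_distribution == "poisson":
        return rng.poisson(rates)
    # negative binomial with mean = rate, dispersion r: p = r / (r + mean)
    r = cfg.nb_dispersion
    p = r / (r + np.maximum(rates, 1e-12))
    return rng.negative_binomial(r, p)


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


def _memberships(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    """Independent Bernoulli membership matrix; every pathway is guaranteed at
    least one member (an empty category is a degenerate input downstream)."""
    member = rng.random((cfg.n_metabolites, cfg.n_pathways)) < cfg.membership_probability
    for j in range(cfg.n_pathways):
        if not member[:, j].any():
            member[rng.integers(cfg.n_metabolites), j] = True
    return member


def generate(cfg: SynthConfig) -> tuple[FeatureMatrix, PathwayCatalog]:
    """Draw a seeded (metabolite matrix, pathway catalog) fixture.

    Counts are Poisson (or negative-binomial) with rate ``base_rate``,
    multiplied by ``1 + signal_strength`` on the signature features of each
    pathway the metabolite belongs to.  Bond levels are assigned round-robin
    over columns.  Metabolites with zero memberships are kept — they
    contribute all-negative pairs, as in the real catalog.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    member = _memberships(rng, cfg)
    rates = np.full((cfg.n_metabolites, cfg.n_features), cfg.base_rate)
    for j in range(cfg.n_pathways):
        sig = slice(j * cfg.signature_size, (j + 1) * cfg.signature_size)
        rates[member[:, j], sig] *= 1.0 + cfg.signal_strength
    counts = _draw_counts(rng, rates, cfg)
    bond_levels = np.arange(cfg.n_features) % cfg.n_bond_levels
    mids = _ids("M", cfg.n_metabolites)
    matrix = FeatureMatrix(
        mids, _ids("F", cfg.n_features), counts.astype(np.float64), bond_levels
    )
    catalog = PathwayCatalog(
        [
            (f"P{j:02d}", frozenset(mids[i] for i in np.flatnonzero(member[:, j])))
            for j in range(cfg.n_pathways)
        ]
    )
    return matrix, catalog


def planted_separable(cfg: SynthConfig) -> tuple[FeatureMatrix, PathwayCatalog]:
    """Fixture whose labels are a deterministic function of the pair features.

    The designated feature of pathway *j* (the first column of its signature
    block) is strictly positive for exactly the members of *j* and zero for
    everyone else, so for every pair, label = 1 iff the metabolite's
    designated feature for that pathway is > 0.  All other columns are zero:
    the designated columns are the sole signal carriers, both for telling
    pathways apart (through the pathway block) and for deciding membership
    (through the metabolite block), so tree feature importance must
    concentrate on them.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    member = _memberships(rng, cfg)
    counts = np.zeros((cfg.n_metabolites, cfg.n_features))
    for j in range(cfg.n_pathways):
        d = j * cfg.signature_size  # designated column for pathway j
        in_p = member[:, j]
        counts[in_p, d] = 1.0 + rng.poisson(cfg.base_rate, int(in_p.sum()))
    bond_levels = np.arange(cfg.n_features) % cfg.n_bond_levels
    mids = _ids("M", cfg.n_metabolites)
    matrix = FeatureMatrix(
        mids, _ids("F", cfg.n_features), counts, bond_levels
    )
    catalog = PathwayCatalog(
        [
            (f"P{j:02d}", frozenset(mids[i] for i in np.flatnonzero(member[:, j])))
            for j in range(cfg.n_pathways)
        ]
    )
    return matrix, catalog


def designated_feature(cfg: SynthConfig, pathway_index: int) -> str:
    """Feature id of the planted designated column for one pathway."""
    return f"F{pathway_index * cfg.signature_size:05d}"
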