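"""Modified-SMOTEbagging: rebalancing imbalanced hairpin training data.

The minority (pre-miRNA) class is augmented with SMOTE at a fixed 50% rate
(synthetic samples interpolated between a minority sample and one of its k
nearest minority neighbors), then the two negative pools are undersampled
to the augmented minority size, yielding one 'miRNA vs ncRNA' subset and
``n_pseudo_subsets`` (default 3) 'miRNA vs pseudo-hairpin' subsets — four
exactly class-balanced training subsets under the defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass(frozen=True)
class RebalanceConfig:
    """smote_rate — fraction of minority size synthesized (0.5 ⇒ 1000
    positives gain 500 synthetics); k_neighbors — SMOTE neighborhood;
    n_pseudo_subsets — number of pseudo-hairpin subsets alongside the
    single ncRNA subset."""

    smote_rate: float = 0.5
    k_neighbors: int = 5
    n_pseudo_subsets: int = 3

    def __post_init__(self) -> None:
        if self.smote_rate < 0:
            raise ValueError("smote_rate must be >= 0")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_pseudo_subsets < 0:
            raise ValueError("n_pseudo_subsets must be >= 0")


def smote(
    minority: np.ndarray,
    rate: float = 0.5,
    k: int = 5,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Synthesize ``floor(rate * n)`` minority samples.

    Seed samples are drawn without replacement; each synthetic point is
    x + u·(nn − x) with u ~ Uniform(0, 1) and nn one of x's k nearest
    minority neighbors.  Neighbor search is Euclidean on per-column
    z-standardized values (interpolation itself is affine-invariant, so the
    synthetic points live in the original feature space).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    minority = np.asarray(minority, dtype=float)
    n = len(minority)
    if n <= k:
        raise ValueError(
            f"minority size {n} must exceed k={k} nearest neighbors; use a smaller k"
        )
    n_syn = int(rate * n)
    if n_syn == 0:
        return np.empty((0, minority.shape[1]))

    mu = minority.mean(axis=0)
    sd = minority.std(axis=0)
    sd[sd == 0.0] = 1.0
    std = (minority - mu) / sd
    nn = NearestNeighbors(n_neighbors=k + 1).fit(std)
    _, neigh = nn.kneighbors(std)
    neigh = neigh[:, 1:]  # drop self

    seeds = rng.choice(n, size=n_syn, replace=n_syn > n)
    out = np.empty((n_syn, minority.shape[1]))
    for row, i in enumerate(seeds):
        j = neigh[i, rng.integers(k)]
        u = rng.random()
        out[row] = minority[i] + u * (minority[j] - minority[i])
    return out


def undersample(
    majority: np.ndarray,
    target_n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``target_n`` majority samples, without replacement when the pool
    suffices, otherwise with replacement (with a warning)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    majority = np.asarray(majority, dtype=float)
    if len(majority) == 0:
        raise ValueError("majority pool is empty")
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    if len(majority) >= target_n:
        idx = rng.choice(len(majority), size=target_n, replace=False)
    else:
        warnings.warn(
            f"majority pool ({len(majority)}) smaller than target ({target_n}); "
            "sampling with replacement",
            stacklevel=2,
        )
        idx = rng.choice(len(majority), size=target_n, replace=True)
    return majority[idx]


@dataclass(frozen=True)
class Subset:
    """One class-balanced training subset."""

    X_pos: np.ndarray
    X_neg: np.ndarray
    neg_source: str  # 'ncrna' or 'pseudo'
    synthetic_mask: np.ndarray  # True where the positive row is SMOTE-synthetic

    @property
    def n(self) -> int:
        return len(self.X_pos)


@dataclass(frozen=True)
class SubsetBundle:
    """The balanced subsets emitted by modified-SMOTEbagging."""

    subsets: tuple[Subset, ...]
    config: RebalanceConfig = field(default_factory=RebalanceConfig)

    def __len__(self) -> int:
        return len(self.subsets)


def build_subsets(
    positives: np.ndarray,
    neg_ncrna: np.ndarray,
    neg_pseudo: np.ndarray,
    config: RebalanceConfig = RebalanceConfig(),
    rng: np.random.Generator | int | None = None,
) -> SubsetBundle:
    """Run modified-SMOTEbagging over the three pools.

    SMOTE runs once, globally, before subset formation; each subset pairs
    the augmented positives with an independent undersample of its negative
    pool (pseudo subsets may overlap — with defaults 3×1500 > 4000 forces
    it).  Negatives are matched to the post-SMOTE minority size.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    positives = np.asarray(positives, dtype=float)
    if config.smote_rate > 0:
        synthetic = smote(positives, rate=config.smote_rate, k=config.k_neighbors, rng=rng)
    else:
        synthetic = np.empty((0, positives.shape[1]))
    augmented = np.vstack([positives, synthetic])
    mask = np.zeros(len(augmented), dtype=bool)
    mask[len(positives):] = True
    target = len(augmented)

    subsets = [
        Subset(
            X_pos=augmented,
            X_neg=undersample(np.asarray(neg_ncrna, dtype=float), target, rng),
            neg_source="ncrna",
            synthetic_mask=mask,
        )
    ]
    for _ in range(config.n_pseudo_subsets):
        subsets.append(
            Subset(
                X_pos=augmented,
                X_neg=undersample(np.asarray(neg_pseudo, dtype=float), target, rng),
                neg_source="pseudo",
                synthetic_mask=mask,
            )
        )
    return SubsetBundle(subsets=tuple(subsets), config=config)
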