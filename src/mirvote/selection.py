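"""Filter feature selection: CFS merit with GA search, ReliefF, InfoGain.

Correlation-based feature selection scores a subset S of k features by

    merit(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)

where r̄_cf is the mean feature–class symmetrical uncertainty and r̄_ff the
mean pairwise feature–feature symmetrical uncertainty over S: a good subset
correlates with the class while staying internally non-redundant.
Continuous features are discretized by Fayyad–Irani recursive MDL cuts
before any entropy is computed.  The search over subsets is a seeded
genetic algorithm over bit-mask chromosomes.

The package also ships the 20-feature default selection produced by this
procedure on the original training corpus
(:data:`DEFAULT_SELECTED_FEATURES`); classification defaults to it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .features import resolve_feature_name

__all__ = [
    "DEFAULT_SELECTED_FEATURES",
    "mdl_discretize",
    "discretize",
    "symmetrical_uncertainty",
    "CorrelationCache",
    "cfs_merit",
    "GAConfig",
    "ga_search",
    "relieff",
    "info_gain",
    "SelectionResult",
]

#: The default feature subset used for classification (CFS + GA on the
#: original training corpus), canonical registry spellings.
DEFAULT_SELECTED_FEATURES: tuple[str, ...] = tuple(
    resolve_feature_name(n)
    for n in (
        "Prob", "MFEI1", "zG", "zP", "zQ", "dH/Loop", "Tm/Loop", "AU/L",
        "Avg_BP_loop", "MFEI5", "SC", "SC×dP", "SC×MFE/Mean_dG",
        "SC×dP/(1−dP)", "SC/nonBP_A", "Non_BPP", "A(((", "G(..", "C...",
        "ProbPair4",
    )
)


# ---------------------------------------------------------------------------
# entropy machinery (base-2 throughout)
# ---------------------------------------------------------------------------


def _entropy(labels: np.ndarray) -> float:
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _conditional_entropy(x: np.ndarray, y: np.ndarray) -> float:
    total = 0.0
    n = len(x)
    for v in np.unique(x):
        mask = x == v
        total += mask.sum() / n * _entropy(y[mask])
    return total


def _information_gain(x: np.ndarray, y: np.ndarray) -> float:
    return _entropy(y) - _conditional_entropy(x, y)


def mdl_discretize(values: Sequence[float], labels: Sequence) -> np.ndarray:
    """Fayyad–Irani recursive minimum-description-length cut points.

    Returns an ascending array of cut values (midpoints); an empty array
    means the MDL criterion rejected every cut (e.g. constant columns or
    class-uninformative features collapse to a single bin).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(values, kind="mergesort")
    v, y = values[order], labels[order]
    cuts: list[float] = []
    _mdl_recurse(v, y, cuts)
    return np.array(sorted(cuts))


def _mdl_recurse(v: np.ndarray, y: np.ndarray, cuts: list[float]) -> None:
    n = len(v)
    if n < 2:
        return
    base_ent = _entropy(y)
    k = len(np.unique(y))
    if k < 2:
        return

    best_gain, best_idx = 0.0, -1
    best_stats = None
    for i in range(1, n):
        if v[i] == v[i - 1]:
            continue
        left, right = y[:i], y[i:]
        e1, e2 = _entropy(left), _entropy(right)
        gain = base_ent - (i / n) * e1 - ((n - i) / n) * e2
        if gain > best_gain:
            best_gain, best_idx = gain, i
            best_stats = (e1, e2, len(np.unique(left)), len(np.unique(right)))
    if best_idx < 0:
        return
    e1, e2, k1, k2 = best_stats
    delta = math.log2(3**k - 2) - (k * base_ent - k1 * e1 - k2 * e2)
    threshold = (math.log2(n - 1) + delta) / n
    if best_gain <= threshold:
        return
    cuts.append((v[best_idx - 1] + v[best_idx]) / 2.0)
    _mdl_recurse(v[:best_idx], y[:best_idx], cuts)
    _mdl_recurse(v[best_idx:], y[best_idx:], cuts)


def discretize(values: Sequence[float], cuts: np.ndarray) -> np.ndarray:
    """Bin values by the given ascending cut points (no cuts → single bin)."""
    return np.digitize(np.asarray(values, dtype=float), cuts)


def symmetrical_uncertainty(a: Sequence, b: Sequence) -> float:
    """SU(a, b) = 2·IG(a; b) / (H(a) + H(b)) over discretized columns;
    0 when both entropies vanish."""
    a = np.asarray(a)
    b = np.asarray(b)
    ha, hb = _entropy(a), _entropy(b)
    if ha + hb == 0.0:
        return 0.0
    ig = ha - _conditional_entropy(b, a)
    return float(2.0 * ig / (ha + hb))


# ---------------------------------------------------------------------------
# CFS merit + GA search
# ---------------------------------------------------------------------------


@dataclass
class CorrelationCache:
    """Precomputed symmetrical uncertainties for CFS.

    ``r_cf[k]`` is SU(feature_k, class); ``r_ff[k, l]`` the symmetric
    feature–feature SU matrix.  Built from a numeric table after MDL
    discretization against the class labels.
    """

    feature_names: tuple[str, ...]
    r_cf: np.ndarray
    r_ff: np.ndarray

    @classmethod
    def from_table(cls, table: pd.DataFrame, labels: Sequence) -> "CorrelationCache":
        y = np.asarray(labels)
        names = tuple(table.columns)
        disc = np.empty((len(table), len(names)), dtype=int)
        for k, name in enumerate(names):
            cuts = mdl_discretize(table[name].to_numpy(), y)
            disc[:, k] = discretize(table[name].to_numpy(), cuts)
        n = len(names)
        r_cf = np.array([symmetrical_uncertainty(disc[:, k], y) for k in range(n)])
        r_ff = np.zeros((n, n))
        for k in range(n):
            for l in range(k + 1, n):
                su = symmetrical_uncertainty(disc[:, k], disc[:, l])
                r_ff[k, l] = r_ff[l, k] = su
        return cls(feature_names=names, r_cf=r_cf, r_ff=r_ff)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def cfs_merit(subset: Sequence, cache: CorrelationCache) -> float:
    """CFS merit of a feature subset (names or indices); empty subset → 0."""
    if len(subset) == 0:
        return 0.0
    if isinstance(next(iter(subset)), str):
        name_to_idx = {n: i for i, n in enumerate(cache.feature_names)}
        idx = np.array([name_to_idx[s] for s in subset])
    else:
        idx = np.asarray(list(subset), dtype=int)
    k = len(idx)
    rcf = cache.r_cf[idx].mean()
    if k == 1:
        return float(rcf)
    sub = cache.r_ff[np.ix_(idx, idx)]
    rff = sub[np.triu_indices(k, 1)].mean()
    return float(k * rcf / math.sqrt(k + k * (k - 1) * rff))


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm search settings (Weka-era conventions)."""

    population_size: int = 20
    generations: int = 50
    crossover_prob: float = 0.6
    mutation_prob: float = 0.033
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one feature-selection run."""

    method: str
    selected: tuple[str, ...]
    merit: float = 0.0
    weights: Optional[Mapping[str, float]] = None
    config: Optional[Mapping] = None

    def to_json(self) -> str:
        payload = {
            "method": self.method,
            "selected": list(self.selected),
            "merit": self.merit,
            "weights": dict(self.weights) if self.weights is not None else None,
            "config": dict(self.config) if self.config is not None else None,
        }
        return json.dumps(payload, indent=2)


def ga_search(
    cache: CorrelationCache,
    config: GAConfig = GAConfig(),
) -> SelectionResult:
    """Search feature subsets by a seeded GA maximizing CFS merit.

    Bit-mask chromosomes, fitness-proportional (roulette) selection,
    single-point crossover, per-bit mutation, elitism; the best subset ever
    evaluated is returned (not merely the final population's best).
    """
    rng = np.random.default_rng(config.seed)
    n = cache.n_features
    pop = rng.random((config.population_size, n)) < 0.5

    def fitness(mask: np.ndarray) -> float:
        idx = np.flatnonzero(mask)
        return cfs_merit(idx, cache)

    best_mask, best_fit = None, -1.0

    for _ in range(config.generations):
        fits = np.array([fitness(m) for m in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = pop[gen_best].copy()

        # roulette selection probabilities
        total = fits.sum()
        probs = fits / total if total > 0 else np.full(len(pop), 1.0 / len(pop))

        elite_idx = np.argsort(fits)[::-1][: config.elitism]
        new_pop = [pop[i].copy() for i in elite_idx]
        while len(new_pop) < config.population_size:
            pa, pb = rng.choice(len(pop), size=2, p=probs)
            a, b = pop[pa].copy(), pop[pb].copy()
            if rng.random() < config.crossover_prob and n > 1:
                point = int(rng.integers(1, n))
                a[point:], b[point:] = b[point:].copy(), a[point:].copy()
            for child in (a, b):
                flip = rng.random(n) < config.mutation_prob
                child[flip] = ~child[flip]
                if len(new_pop) < config.population_size:
                    new_pop.append(child)
        pop = np.array(new_pop)

    fits = np.array([fitness(m) for m in pop])
    gen_best = int(np.argmax(fits))
    if fits[gen_best] > best_fit:
        best_fit = float(fits[gen_best])
        best_mask = pop[gen_best].copy()

    selected = tuple(
        cache.feature_names[i] for i in np.flatnonzero(best_mask)
    )
    return SelectionResult(
        method="cfs_ga", selected=selected, merit=best_fit, config=asdict(config)
    )


# ---------------------------------------------------------------------------
# ReliefF and InfoGain rankers
# ---------------------------------------------------------------------------


def relieff(
    table: pd.DataFrame,
    labels: Sequence,
    k_neighbors: int = 10,
    m_samples: Optional[int] = None,
    seed: int = 0,
) -> SelectionResult:
    """ReliefF feature weights (k nearest hits/misses, range-normalized
    diffs, miss contributions weighted by class priors).  Returns features
    ranked by descending weight."""
    X = table.to_numpy(dtype=float)
    y = np.asarray(labels)
    n, d = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ReliefF requires at least two classes")
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}

    rng = np.random.default_rng(seed)
    m = n if m_samples is None else min(m_samples, n)
    sample_idx = rng.choice(n, size=m, replace=False)

    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0.0] = 1.0  # constant features contribute zero diff anyway

    weights = np.zeros(d)
    for i in sample_idx:
        diffs = np.abs(X - X[i]) / span
        dist = diffs.sum(axis=1)
        dist[i] = np.inf
        for c in classes:
            mask = y == c
            idx_c = np.flatnonzero(mask)
            order = idx_c[np.argsort(dist[idx_c], kind="mergesort")]
            neigh = order[: min(k_neighbors, len(order))]
            if len(neigh) == 0:
                continue
            contrib = diffs[neigh].mean(axis=0)
            if c == y[i]:
                weights -= contrib / m
            else:
                weights += priors[c] / (1.0 - priors[y[i]]) * contrib / m

    w = {name: float(weights[k]) for k, name in enumerate(table.columns)}
    ranked = tuple(sorted(w, key=lambda f: w[f], reverse=True))
    return SelectionResult(
        method="relieff",
        selected=ranked,
        weights=w,
        config={"k_neighbors": k_neighbors, "m_samples": m, "seed": seed},
    )


def info_gain(table: pd.DataFrame, labels: Sequence) -> SelectionResult:
    """Information gain IG(class; feature) per feature after MDL
    discretization, ranked descending."""
    y = np.asarray(labels)
    w: dict[str, float] = {}
    for name in table.columns:
        col = table[name].to_numpy(dtype=float)
        disc = discretize(col, mdl_discretize(col, y))
        w[name] = float(_information_gain(disc, y))
    ranked = tuple(sorted(w, key=lambda f: w[f], reverse=True))
    return SelectionResult(method="info_gain", selected=ranked, weights=w)
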