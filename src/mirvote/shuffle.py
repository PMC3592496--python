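"""Dinucleotide-preserving shuffling and shuffle-cohort statistics.

Shuffled sequences preserve the exact mono- and dinucleotide multisets of
the original (Altschul–Erickson Eulerian-walk construction), so shuffle
cohorts provide the null distributions behind the z-score features
(zG, zP, zQ, zD, zF) and the mean shuffle MFE (Mean_dG).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional

import numpy as np

from .structure import FoldBackend, FoldResult, RnaSequence, default_backend

_MAX_ARBORESCENCE_TRIES = 1000


def dinucleotide_shuffle(
    seq: RnaSequence, rng: np.random.Generator | int | None = None
) -> RnaSequence:
    """Return a sequence with identical dinucleotide (hence mononucleotide)
    counts, uniformly sampled via the Altschul–Erickson construction.

    Deterministic for a fixed ``rng`` seed.  Degenerate sequences with a
    single possible arrangement (e.g. homopolymers, length < 3) are
    returned unchanged.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    s = seq.residues
    n = len(s)
    if n < 3 or len(set(s)) == 1:
        return RnaSequence(id=seq.id, residues=s)

    # multigraph: one edge per adjacent dinucleotide
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    first, last = s[0], s[-1]
    vertices = sorted(edges)

    # pick per-vertex "last edges" forming an arborescence into the terminal
    # vertex; rejection-sample until the walk-to-terminal check passes
    for _ in range(_MAX_ARBORESCENCE_TRIES):
        last_edge: dict[str, str] = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        if all(_reaches(v, last, last_edge) for v in last_edge):
            break
    else:  # pragma: no cover - bounded retries on tiny alphabets
        raise RuntimeError("failed to sample a valid shuffle arborescence")

    # shuffle the remaining edges; the chosen last edge goes at the end
    pools: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_edge:
            pool.remove(last_edge[v])
        perm = rng.permutation(len(pool))
        pool = [pool[i] for i in perm]
        if v in last_edge:
            pool.append(last_edge[v])
        pools[v] = pool

    # Eulerian walk from the original start vertex
    out = [first]
    pos = {v: 0 for v in vertices}
    v = first
    for _ in range(n - 1):
        nxt = pools[v][pos[v]]
        pos[v] += 1
        out.append(nxt)
        v = nxt
    shuffled = "".join(out)
    return RnaSequence(id=seq.id, residues=shuffled)


def _reaches(v: str, terminal: str, last_edge: Mapping[str, str]) -> bool:
    seen = set()
    while v != terminal:
        if v in seen or v not in last_edge:
            return False
        seen.add(v)
        v = last_edge[v]
    return True


def zscore(observed: float, mean: float, sd: float) -> float:
    """(observed − mean)/sd, with the convention 0 when sd == 0."""
    if sd == 0.0:
        return 0.0
    return (observed - mean) / sd


@dataclass(frozen=True)
class ShuffleCohort:
    """Folded statistics over a cohort of dinucleotide shuffles.

    ``samples`` maps statistic name → per-shuffle values; ``mean_dG`` is the
    mean shuffle MFE (kcal/mol under the Vienna backend, reduced units under
    the reference backend).  Standard deviations are sample sd (ddof=1).
    """

    n_shuffles: int
    samples: Mapping[str, np.ndarray]
    mean_dG: float

    def mean(self, name: str) -> float:
        return float(np.mean(self.samples[name]))

    def sd(self, name: str) -> float:
        x = self.samples[name]
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    def z(self, name: str, observed: float) -> float:
        """z-score of an observed value against this cohort."""
        return zscore(observed, self.mean(name), self.sd(name))


def build_cohort(
    seq: RnaSequence,
    n_shuffles: int = 100,
    statistics: Optional[Mapping[str, Callable[[FoldResult], float]]] = None,
    rng: np.random.Generator | int | None = None,
    backend: Optional[FoldBackend] = None,
    temperature: float = 37.0,
    partition: bool = True,
) -> ShuffleCohort:
    """Shuffle ``seq`` ``n_shuffles`` times, fold each shuffle once, and
    record each named statistic plus the shuffle MFEs.

    Statistics are callables over a :class:`FoldResult`.  The shuffle MFE is
    always recorded (under key ``"mfe"``) and averaged into ``mean_dG``.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    backend = backend or default_backend()
    statistics = dict(statistics or {})

    records: dict[str, list[float]] = {name: [] for name in statistics}
    records.setdefault("mfe", [])
    for k in range(n_shuffles):
        shuf = dinucleotide_shuffle(seq, rng)
        try:
            fr = backend.fold(shuf, temperature=temperature, partition=partition)
        except Exception as exc:
            raise RuntimeError(f"folding failed on shuffle {k} of {seq.id!r}") from exc
        records["mfe"].append(fr.mfe)
        for name, fn in statistics.items():
            if name == "mfe":
                continue
            records[name].append(float(fn(fr)))
    samples = {name: np.asarray(vals, dtype=float) for name, vals in records.items()}
    return ShuffleCohort(
        n_shuffles=n_shuffles,
        samples=samples,
        mean_dG=float(np.mean(samples["mfe"])),
    )
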