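"""Self-containment (SC): structural robustness of a hairpin to flanking context.

A sequence is folded alone to obtain its reference structure, then embedded
between random flanking contexts and refolded; the SC score is the mean
fraction of reference base pairs retained across contexts.  Genuine
pre-miRNA hairpins keep their stem pairing when surrounded by arbitrary
sequence (SC near 1), whereas incidental hairpins are easily invaded by
alternative pairings with the flanks (SC well below 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .structure import FoldBackend, RnaSequence, SecondaryStructure, default_backend

_BASES = "ACGU"


@dataclass(frozen=True)
class SCConfig:
    """Parameters of the random-context embedding.

    n_contexts
        Number of independent random contexts R (>= 1).
    flank_len
        Flank length f (nt) appended on each side.
    context_model
        ``"dinucleotide"`` — flanks sampled from a first-order Markov chain
        fitted (with add-one smoothing) to the candidate's dinucleotide
        counts, avoiding composition-driven artifacts; or ``"uniform"`` —
        i.i.d. uniform over ACGU.
    """

    n_contexts: int = 20
    flank_len: int = 100
    context_model: str = "dinucleotide"

    def __post_init__(self) -> None:
        if self.n_contexts < 1:
            raise ValueError("n_contexts must be >= 1")
        if self.flank_len < 0:
            raise ValueError("flank_len must be >= 0")
        if self.context_model not in ("dinucleotide", "uniform"):
            raise ValueError(f"unknown context model {self.context_model!r}")


@dataclass(frozen=True)
class SCResult:
    """SC score in [0, 1] and the per-context pair fidelities it averages."""

    sc: float
    fidelities: tuple[float, ...] = field(default=())


def pair_fidelity(
    reference: SecondaryStructure, embedded: SecondaryStructure, offset: int
) -> float:
    """Fraction of reference base pairs (i, j) that the embedded fold pairs
    as (i+offset, j+offset).  A reference with no pairs scores 0 by
    convention.  Raises ``ValueError`` if the embedded structure does not
    cover the shifted reference span.
    """
    ref_pairs = reference.pairs
    if offset < 0 or offset + reference.length > embedded.length:
        raise ValueError(
            f"embedded structure (length {embedded.length}) does not cover the "
            f"reference span at offset {offset}"
        )
    if not ref_pairs:
        return 0.0
    kept = sum(1 for (i, j) in ref_pairs if embedded.partner(i + offset) == j + offset)
    return kept / len(ref_pairs)


def _markov_sampler(residues: str):
    """First-order Markov model of the candidate with add-one smoothing."""
    counts = np.ones((4, 4))
    idx = {b: k for k, b in enumerate(_BASES)}
    for a, b in zip(residues, residues[1:]):
        counts[idx[a], idx[b]] += 1
    trans = counts / counts.sum(axis=1, keepdims=True)
    start = np.array([residues.count(b) for b in _BASES], dtype=float) + 1.0
    start /= start.sum()

    def sample(length: int, rng: np.random.Generator) -> str:
        if length == 0:
            return ""
        out = [int(rng.choice(4, p=start))]
        for _ in range(length - 1):
            out.append(int(rng.choice(4, p=trans[out[-1]])))
        return "".join(_BASES[k] for k in out)

    return sample


def self_containment(
    seq: RnaSequence,
    config: SCConfig = SCConfig(),
    backend: Optional[FoldBackend] = None,
    rng: np.random.Generator | int | None = None,
    temperature: float = 37.0,
) -> SCResult:
    """Compute the SC score of ``seq`` under ``config``.

    The candidate is folded alone (reference), then for each of R seeded
    random contexts embedded between flanks of length f, the concatenation
    folded, and the pair fidelity at offset f recorded; SC is the mean
    fidelity.  Deterministic given the rng seed.  A candidate whose
    standalone MFE structure has no pairs scores SC = 0.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    backend = backend or default_backend()

    reference = backend.fold(seq, temperature=temperature, partition=False).structure
    if reference.tot_bp == 0:
        return SCResult(sc=0.0, fidelities=tuple(0.0 for _ in range(config.n_contexts)))

    if config.context_model == "dinucleotide":
        sample_flank = _markov_sampler(seq.residues)
    else:
        def sample_flank(length: int, r: np.random.Generator) -> str:
            return "".join(_BASES[k] for k in r.integers(0, 4, size=length))

    fidelities = []
    for c in range(config.n_contexts):
        left = sample_flank(config.flank_len, rng)
        right = sample_flank(config.flank_len, rng)
        embedded_seq = RnaSequence(
            id=f"{seq.id}|ctx{c}", residues=left + seq.residues + right
        )
        embedded = backend.fold(
            embedded_seq, temperature=temperature, partition=False
        ).structure
        fidelities.append(pair_fidelity(reference, embedded, offset=len(left)))
    return SCResult(sc=float(np.mean(fidelities)), fidelities=tuple(fidelities))
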