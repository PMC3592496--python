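"""Synthetic hairpin simulator and the pseudo-hairpin candidate filter.

The simulator emulates the composition of the original training corpus:

* positives ("mirna") — pre-miRNA-like hairpins: long near-complementary
  stems (25–40 bp) perturbed by occasional mismatches and bulges, closed by
  a short loop; these fold into deep, context-robust stems (low MFE, high
  self-containment).
* "pseudo" negatives — pseudo-hairpin-like decoys: random sequences with
  protein-coding-like composition (GC 0.52) whose lengths track the
  positive length distribution, rejection-sampled through the candidate
  filter (≥ 18 bp of stem, MFE ≤ −18 kcal/mol) so every emitted record is
  a *hard* negative, exactly like the published negative set construction.
* "ncrna" negatives — moderately structured hairpins, 70–150 nt, with
  weaker stems (10–15 bp, higher mismatch rate) and unpaired tails,
  standing in for tRNA/snoRNA-like structured non-coding RNA.

Default pool sizes are 1000 / 754 / 4000 (≈ 1:4.75 positive:negative), the
class balance of the original corpus; all counts scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .structure import FoldBackend, FoldResult, RnaSequence, default_backend

_BASES = "ACGU"
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class FilterCriteria:
    """The pseudo-hairpin candidate criteria: length window, minimum stem
    base pairs, maximum (most positive allowed) folding free energy."""

    min_stem_bp: int = 18
    max_mfe: float = -18.0
    min_len: int = 60
    max_len: int = 150

    def __post_init__(self) -> None:
        if self.min_stem_bp < 1:
            raise ValueError("min_stem_bp must be >= 1")


def pseudo_hairpin_filter(
    seq: RnaSequence, fold: FoldResult, criteria: FilterCriteria = FilterCriteria()
) -> tuple[bool, list[str]]:
    """Apply the candidate filter; returns (passed, violated-criteria)."""
    reasons = []
    if not criteria.min_len <= len(seq) <= criteria.max_len:
        reasons.append(
            f"length {len(seq)} outside [{criteria.min_len}, {criteria.max_len}]"
        )
    if fold.structure.tot_bp < criteria.min_stem_bp:
        reasons.append(
            f"stem has {fold.structure.tot_bp} bp < {criteria.min_stem_bp} required"
        )
    if fold.mfe > criteria.max_mfe:
        reasons.append(f"MFE {fold.mfe:.2f} above maximum {criteria.max_mfe:.2f}")
    return (not reasons, reasons)


@dataclass(frozen=True)
class SimConfig:
    """Simulator composition and per-class hairpin generator settings.

    Stem lengths are in base pairs, loops in nt; ``mismatch_rate`` /
    ``bulge_rate`` perturb the 3' arm away from perfect complementarity.
    The default gap between positive stems (25–40 bp) and ncRNA-like stems
    (10–15 bp) is the class-separation dial.
    """

    n_mirna: int = 1000
    n_ncrna: int = 754
    n_pseudo: int = 4000
    mirna_stem: tuple[int, int] = (25, 40)
    mirna_loop: tuple[int, int] = (4, 8)
    mirna_mismatch_rate: float = 0.05
    mirna_bulge_rate: float = 0.02
    ncrna_stem: tuple[int, int] = (10, 15)
    ncrna_loop: tuple[int, int] = (6, 12)
    ncrna_mismatch_rate: float = 0.15
    ncrna_len: tuple[int, int] = (70, 150)
    gc: float = 0.5
    pseudo_gc: float = 0.52
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    max_attempts_per_record: int = 200


@dataclass(frozen=True)
class SimRecord:
    id: str
    residues: str
    label: str  # 'positive' | 'negative'
    tag: str    # 'mirna' | 'ncrna' | 'pseudo'


@dataclass(frozen=True)
class DatasetManifest:
    """Simulated (or loaded) dataset: records plus provenance."""

    records: tuple[SimRecord, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record ids must be unique")
        for r in self.records:
            if r.tag == "mirna" and r.label != "positive":
                raise ValueError(f"record {r.id}: mirna tag requires positive label")

    def sequences(self) -> list[RnaSequence]:
        return [RnaSequence(id=r.id, residues=r.residues) for r in self.records]

    def labels(self) -> np.ndarray:
        return np.array([1 if r.label == "positive" else 0 for r in self.records])

    def tags(self) -> np.ndarray:
        return np.array([r.tag for r in self.records], dtype=object)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G U
    return "".join(np.array(list("ACGU"))[rng.choice(4, size=length, p=p)])


def _make_hairpin(
    rng: np.random.Generator,
    stem_bp: int,
    loop_len: int,
    mismatch_rate: float,
    bulge_rate: float,
    gc: float,
) -> str:
    arm5 = _random_seq(rng, stem_bp, gc)
    arm3 = []
    for base in reversed(arm5):
        comp = _COMP[base]
        if rng.random() < mismatch_rate:
            comp = _BASES[rng.integers(4)]
        arm3.append(comp)
        if rng.random() < bulge_rate:
            arm3.append(_BASES[rng.integers(4)])
    loop = _random_seq(rng, loop_len, 0.4)
    return arm5 + loop + "".join(arm3)


def simulate_dataset(
    config: SimConfig = SimConfig(),
    seed: int = 0,
    backend: Optional[FoldBackend] = None,
) -> DatasetManifest:
    """Generate a labeled synthetic dataset under ``config``.

    Pseudo-hairpin records are rejection-sampled through
    :func:`pseudo_hairpin_filter` (so every emitted pseudo record passes
    it); if a record cannot be produced within
    ``config.max_attempts_per_record`` attempts a ``RuntimeError`` suggests
    relaxing the criteria.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    backend = backend or default_backend()
    records: list[SimRecord] = []

    for k in range(config.n_mirna):
        stem = int(rng.integers(config.mirna_stem[0], config.mirna_stem[1] + 1))
        loop = int(rng.integers(config.mirna_loop[0], config.mirna_loop[1] + 1))
        seq = _make_hairpin(
            rng, stem, loop, config.mirna_mismatch_rate, config.mirna_bulge_rate,
            config.gc,
        )
        records.append(SimRecord(f"mir_{k:05d}", seq, "positive", "mirna"))

    pos_lengths = [len(r.residues) for r in records] or [80]

    for k in range(config.n_ncrna):
        stem = int(rng.integers(config.ncrna_stem[0], config.ncrna_stem[1] + 1))
        loop = int(rng.integers(config.ncrna_loop[0], config.ncrna_loop[1] + 1))
        core = _make_hairpin(rng, stem, loop, config.ncrna_mismatch_rate, 0.05, config.gc)
        total = int(rng.integers(config.ncrna_len[0], config.ncrna_len[1] + 1))
        pad = max(total - len(core), 0)
        left = int(rng.integers(0, pad + 1))
        seq = _random_seq(rng, left, config.gc) + core + _random_seq(rng, pad - left, config.gc)
        records.append(SimRecord(f"ncrna_{k:05d}", seq, "negative", "ncrna"))

    crit = config.criteria
    for k in range(config.n_pseudo):
        for attempt in range(config.max_attempts_per_record):
            length = int(pos_lengths[rng.integers(len(pos_lengths))])
            length = int(np.clip(length, crit.min_len, crit.max_len))
            seq = _random_seq(rng, length, config.pseudo_gc)
            rna = RnaSequence(id=f"pseudo_{k:05d}", residues=seq)
            fr = backend.fold(rna, partition=False)
            passed, _ = pseudo_hairpin_filter(rna, fr, crit)
            if passed:
                records.append(SimRecord(rna.id, seq, "negative", "pseudo"))
                break
        else:
            raise RuntimeError(
                "rejection sampling of pseudo-hairpins exhausted "
                f"{config.max_attempts_per_record} attempts; relax FilterCriteria"
            )

    return DatasetManifest(
        records=tuple(records),
        provenance={
            "simulator": "mirvote",
            "seed": seed,
            "n_mirna": config.n_mirna,
            "n_ncrna": config.n_ncrna,
            "n_pseudo": config.n_pseudo,
        },
    )
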