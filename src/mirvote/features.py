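"""The 125-feature catalog for candidate pre-miRNA hairpins.

Five groups (19 sequence + 30 structure + 32 base-pair + 32 triplet +
12 self-containment-derived = 125 features).  103 of them are the classic
catalog accumulated by earlier hairpin classifiers (miPred/microPred
lineage: MFE indices, shuffle z-scores, ensemble diversity/entropy,
triplet sequence-structure elements, ...); the remaining 22 are the
robustness-oriented additions built on the SC score and loop-normalized
thermodynamics.

Every division is guarded: a zero denominator yields feature value 0, so
all features are finite for any input the simulator or a user can supply.

The registry (:func:`catalog`) is the single source of truth for feature
names, group membership, ordering and novelty flags; feature tables are
always emitted in registry order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .selfcontainment import SCConfig, SCResult, self_containment
from .shuffle import ShuffleCohort, build_cohort
from .structure import (
    FoldBackend,
    FoldResult,
    MeltEstimate,
    RnaSequence,
    default_backend,
    estimate_melt,
)

CATALOG_VERSION = "1.0"

_BASES = "ACGU"
_PATTERNS = ("(((", "((.", "(..", "(.(", ".((", ".(.", "..(", "...")


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    group: str  # sequence | structure | basepair | triplet | sc
    novel: bool
    description: str = ""


def _seq_specs() -> list[FeatureSpec]:
    names = ["Len", "%G+C", "%A+U"] + [
        f"%{a}{b}" for a in _BASES for b in _BASES
    ]
    return [FeatureSpec(n, "sequence", False) for n in names]


def _structure_specs() -> list[FeatureSpec]:
    classic = [
        "MFE", "efe", "MFEI1", "MFEI2", "MFEI3", "MFEI4", "dG", "dQ", "dD",
        "dF", "Prob", "zG", "zQ", "zD", "zF", "nefe", "Freq", "diff", "dH",
        "dH/L", "dS", "dS/L", "Tm", "Tm/L",
    ]
    novel = ["MFEI5", "MFE/Mean_dG", "dH/loop", "dS/loop", "Tm/Loop", "dQ/Loop"]
    return [FeatureSpec(n, "structure", False) for n in classic] + [
        FeatureSpec(n, "structure", True) for n in novel
    ]


def _basepair_specs() -> list[FeatureSpec]:
    classic = (
        ["dP", "zP", "div", "tot_bp", "stem", "loop", "A-U/L", "G-U/L", "G-C/L",
         "%A-U/Stem", "%G-C/Stem", "%G-U/Stem"]
        + [f"Probpair{b}" for b in range(1, 11)]
        + ["Avg_BP_stem", "NonBP_A", "NonBP_C", "NonBP_G", "NonBP_U", "Non_BPP"]
    )
    novel = ["%A-U/BP", "%C-G/BP", "%G-U/BP", "Avg_BP_Loop"]
    return [FeatureSpec(n, "basepair", False) for n in classic] + [
        FeatureSpec(n, "basepair", True) for n in novel
    ]


def _triplet_specs() -> list[FeatureSpec]:
    return [
        FeatureSpec(f"{b}{p}", "triplet", False)
        for b in _BASES
        for p in _PATTERNS
    ]


def _sc_specs() -> list[FeatureSpec]:
    names = [
        "SC", "SC/tot_bp", "SC/Len", "SCxMFE/Mean_dG", "SCxdP", "SCxzG",
        "SC/(1-dP)", "SCxdP/(1-dP)", "SC/NonBP_A", "SC/NonBP_C", "SC/NonBP_G",
        "SC/NonBP_U",
    ]
    return [FeatureSpec(n, "sc", True) for n in names]


_CATALOG: tuple[FeatureSpec, ...] = tuple(
    _seq_specs() + _structure_specs() + _basepair_specs() + _triplet_specs() + _sc_specs()
)
_BY_NAME: dict[str, FeatureSpec] = {s.name: s for s in _CATALOG}
assert len(_BY_NAME) == 125, "feature registry must contain 125 unique names"

FEATURE_NAMES: tuple[str, ...] = tuple(s.name for s in _CATALOG)
GROUP_SIZES: dict[str, int] = {
    g: sum(1 for s in _CATALOG if s.group == g)
    for g in ("sequence", "structure", "basepair", "triplet", "sc")
}


def catalog() -> tuple[FeatureSpec, ...]:
    """The full ordered feature registry (125 specs)."""
    return _CATALOG


def feature_spec(name: str) -> FeatureSpec:
    return _BY_NAME[resolve_feature_name(name)]


def _normalize_key(name: str) -> str:
    key = (
        name.replace("×", "x")
        .replace("−", "-")
        .replace("–", "-")
        .replace(" ", "")
        .lower()
    )
    return key


_ALIASES: dict[str, str] = {_normalize_key(n): n for n in FEATURE_NAMES}
# spellings used when the selected feature list is quoted in prose
_ALIASES.update(
    {
        _normalize_key("AU/L"): "A-U/L",
        _normalize_key("GU/L"): "G-U/L",
        _normalize_key("GC/L"): "G-C/L",
        _normalize_key("dH/Loop"): "dH/loop",
        _normalize_key("dS/Loop"): "dS/loop",
        _normalize_key("Avg_BP_loop"): "Avg_BP_Loop",
        _normalize_key("SC/nonBP_A"): "SC/NonBP_A",
        _normalize_key("SC/nonBP_C"): "SC/NonBP_C",
        _normalize_key("SC/nonBP_G"): "SC/NonBP_G",
        _normalize_key("SC/nonBP_U"): "SC/NonBP_U",
        _normalize_key("SC*dP"): "SCxdP",
        _normalize_key("SC*zG"): "SCxzG",
        _normalize_key("SC*MFE/Mean_dG"): "SCxMFE/Mean_dG",
        _normalize_key("SC*dP/(1-dP)"): "SCxdP/(1-dP)",
    }
)
_ALIASES.update({_normalize_key(f"ProbPair{b}"): f"Probpair{b}" for b in range(1, 11)})


def resolve_feature_name(name: str) -> str:
    """Map a feature name (including case/punctuation variants) to its
    canonical registry name; raises ``KeyError`` for unknown names."""
    key = _normalize_key(name)
    if key not in _ALIASES:
        raise KeyError(f"unknown feature name {name!r}")
    return _ALIASES[key]


def _g(num: float, den: float) -> float:
    """Guarded division: 0 whenever the denominator is 0."""
    return num / den if den != 0.0 else 0.0


# ---------------------------------------------------------------------------
# group extractors
# ---------------------------------------------------------------------------


def sequence_features(seq: RnaSequence) -> dict[str, float]:
    """19 sequence-composition features: length, %G+C, %A+U and the 16
    overlapping dinucleotide percentages (of L−1 dinucleotides)."""
    s = seq.residues
    L = len(s)
    out = {"Len": float(L)}
    out["%G+C"] = 100.0 * (s.count("G") + s.count("C")) / L
    out["%A+U"] = 100.0 * (s.count("A") + s.count("U")) / L
    n_di = L - 1
    counts: dict[str, int] = {}
    for a, b in zip(s, s[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    for a in _BASES:
        for b in _BASES:
            out[f"%{a}{b}"] = _g(100.0 * counts.get(a + b, 0), n_di)
    return out


def _pair_prob_upper(fold: FoldResult) -> np.ndarray:
    if fold.pair_prob is None:
        n = fold.structure.length
        return np.zeros((n, n))
    return np.triu(fold.pair_prob, k=1)


def _ensemble_entropy(fold: FoldResult) -> float:
    """−Σ_{i<j} p_ij ln p_ij (natural log; 0·ln0 = 0)."""
    p = _pair_prob_upper(fold)
    mask = p > 0
    return float(-(p[mask] * np.log(p[mask])).sum())


def _ensemble_diversity(fold: FoldResult) -> float:
    """Σ_{i<j} 2 p_ij (1 − p_ij): expected base-pair distance to the ensemble."""
    p = _pair_prob_upper(fold)
    return float((2.0 * p * (1.0 - p)).sum())


def _fiedler(fold: FoldResult) -> float:
    """Second-smallest Laplacian eigenvalue of the bonding graph
    (backbone edges plus MFE base-pair edges); a compactness measure."""
    n = fold.structure.length
    if n < 2:
        return 0.0
    adj = np.zeros((n, n))
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1.0
    for i, j in fold.structure.pairs:
        adj[i - 1, j - 1] = adj[j - 1, i - 1] = 1.0
    lap = np.diag(adj.sum(axis=1)) - adj
    eig = np.linalg.eigvalsh(lap)
    return float(eig[1])


def _mfe_pair_probs(fold: FoldResult) -> np.ndarray:
    if fold.pair_prob is None or fold.structure.tot_bp == 0:
        return np.zeros(0)
    return np.array([fold.pair_prob[i - 1, j - 1] for i, j in fold.structure.pairs])


def cohort_statistics() -> Mapping[str, callable]:
    """The per-shuffle statistics required by the z-score features."""
    return {
        "mfe": lambda fr: fr.mfe,
        "tot_bp": lambda fr: float(fr.structure.tot_bp),
        "entropy": _ensemble_entropy,
        "diversity": _ensemble_diversity,
        "fiedler": _fiedler,
    }


def structure_features(
    seq: RnaSequence,
    fold: FoldResult,
    melt: MeltEstimate,
    cohort: ShuffleCohort,
) -> dict[str, float]:
    """30 thermodynamic / ensemble features (MFE indices, z-scores, melting
    quantities and their loop-normalized variants)."""
    L = float(len(seq))
    st = fold.structure
    gc_pct = 100.0 * (seq.residues.count("G") + seq.residues.count("C")) / L
    dG = fold.mfe / L
    ent = _ensemble_entropy(fold)
    div = _ensemble_diversity(fold)
    fied = _fiedler(fold)
    dQ = ent / L
    dD = div / L
    dF = fied / L
    mfe_probs = _mfe_pair_probs(fold)
    out = {
        "MFE": fold.mfe,
        "efe": fold.efe,
        "MFEI1": _g(dG, gc_pct),
        "MFEI2": _g(dG, st.n_stems),
        "MFEI3": _g(dG, st.n_loops),
        "MFEI4": _g(fold.mfe, st.tot_bp),
        "dG": dG,
        "dQ": dQ,
        "dD": dD,
        "dF": dF,
        "Prob": float(mfe_probs.mean()) if mfe_probs.size else 0.0,
        "zG": cohort.z("mfe", fold.mfe),
        "zQ": cohort.z("entropy", ent),
        "zD": cohort.z("diversity", div),
        "zF": cohort.z("fiedler", fied),
        "nefe": fold.efe / L,
        "Freq": fold.freq_mfe,
        "diff": abs(fold.mfe - fold.efe) / L,
        "dH": melt.dH,
        "dH/L": melt.dH / L,
        "dS": melt.dS,
        "dS/L": melt.dS / L,
        "Tm": melt.Tm,
        "Tm/L": melt.Tm / L,
        "MFEI5": _g(dG, st.tot_bp),
        "MFE/Mean_dG": _g(fold.mfe, cohort.mean_dG),
        "dH/loop": _g(melt.dH, st.n_loops),
        "dS/loop": _g(melt.dS, st.n_loops),
        "Tm/Loop": _g(melt.Tm, st.n_loops),
        "dQ/Loop": _g(dQ, st.n_loops),
    }
    return out


_PAIR_TYPE = {
    frozenset("AU"): "A-U",
    frozenset("GC"): "G-C",
    frozenset("GU"): "G-U",
}


def basepair_features(
    seq: RnaSequence, fold: FoldResult, cohort: ShuffleCohort
) -> dict[str, float]:
    """32 base-pairing features: pairing propensity and its z-score,
    ensemble diversity, stem/loop counts, pair-type compositions, MFE-pair
    probability histogram, and unpaired-residue counts."""
    s = seq.residues
    L = float(len(s))
    st = fold.structure
    type_counts = {"A-U": 0, "G-C": 0, "G-U": 0}
    for i, j in st.pairs:
        type_counts[_PAIR_TYPE[frozenset((s[i - 1], s[j - 1]))]] += 1

    mfe_probs = _mfe_pair_probs(fold)
    bins = np.zeros(10)
    if mfe_probs.size:
        # bin b covers ((b-1)/10, b/10]
        idx = np.ceil(mfe_probs * 10.0).astype(int)
        idx = np.clip(idx, 1, 10)
        for b in idx:
            bins[b - 1] += 1
        bins /= mfe_probs.size

    paired_pos = {i for pair in st.pairs for i in pair}
    nonbp = {b: 0 for b in _BASES}
    for pos, base in enumerate(s, start=1):
        if pos not in paired_pos:
            nonbp[base] += 1

    out = {
        "dP": st.tot_bp / L,
        "zP": cohort.z("tot_bp", float(st.tot_bp)),
        "div": _ensemble_diversity(fold),
        "tot_bp": float(st.tot_bp),
        "stem": float(st.n_stems),
        "loop": float(st.n_loops),
        "A-U/L": type_counts["A-U"] / L,
        "G-U/L": type_counts["G-U"] / L,
        "G-C/L": type_counts["G-C"] / L,
        "%A-U/Stem": _g(type_counts["A-U"], st.n_stems),
        "%G-C/Stem": _g(type_counts["G-C"], st.n_stems),
        "%G-U/Stem": _g(type_counts["G-U"], st.n_stems),
    }
    for b in range(1, 11):
        out[f"Probpair{b}"] = float(bins[b - 1])
    out.update(
        {
            "Avg_BP_stem": _g(st.tot_bp, st.n_stems),
            "NonBP_A": float(nonbp["A"]),
            "NonBP_C": float(nonbp["C"]),
            "NonBP_G": float(nonbp["G"]),
            "NonBP_U": float(nonbp["U"]),
            "Non_BPP": (L - 2.0 * st.tot_bp) / L,
            "%A-U/BP": _g(100.0 * type_counts["A-U"], st.tot_bp),
            "%C-G/BP": _g(100.0 * type_counts["G-C"], st.tot_bp),
            "%G-U/BP": _g(100.0 * type_counts["G-U"], st.tot_bp),
            "Avg_BP_Loop": _g(st.tot_bp, st.n_loops),
        }
    )
    return out


def triplet_features(seq: RnaSequence, fold: FoldResult) -> dict[str, float]:
    """32 triplet sequence-structure elements: for every interior position,
    the paired-status pattern of (i−1, i, i+1) — with ')' folded onto '(' —
    keyed by the middle nucleotide; values are counts normalized by L−2."""
    s = seq.residues
    L = len(s)
    out = {f"{b}{p}": 0.0 for b in _BASES for p in _PATTERNS}
    if L < 3:
        return out
    db = fold.structure.dot_bracket.replace(")", "(")
    for i in range(1, L - 1):
        pattern = db[i - 1 : i + 2]
        out[f"{s[i]}{pattern}"] += 1.0
    for key in out:
        out[key] /= L - 2
    return out


def sc_features(
    sc: SCResult,
    structure_values: Mapping[str, float],
    basepair_values: Mapping[str, float],
    L: int,
) -> dict[str, float]:
    """12 structural-robustness features: SC and its composites with
    base-pairing and shuffle-normalized quantities."""
    v = sc.sc
    dP = basepair_values["dP"]
    return {
        "SC": v,
        "SC/tot_bp": _g(v, basepair_values["tot_bp"]),
        "SC/Len": v / L,
        "SCxMFE/Mean_dG": v * structure_values["MFE/Mean_dG"],
        "SCxdP": v * dP,
        "SCxzG": v * structure_values["zG"],
        "SC/(1-dP)": _g(v, 1.0 - dP),
        "SCxdP/(1-dP)": _g(v * dP, 1.0 - dP),
        "SC/NonBP_A": _g(v, basepair_values["NonBP_A"]),
        "SC/NonBP_C": _g(v, basepair_values["NonBP_C"]),
        "SC/NonBP_G": _g(v, basepair_values["NonBP_G"]),
        "SC/NonBP_U": _g(v, basepair_values["NonBP_U"]),
    }


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the full extraction pipeline.

    temperature — folding temperature in °C; n_shuffles — shuffle cohort
    size behind the z-score features and Mean_dG; melt_t2 — upper
    temperature of the melting finite difference; sc — self-containment
    embedding parameters.
    """

    temperature: float = 37.0
    n_shuffles: int = 100
    melt_t2: float = 67.0
    sc: SCConfig = field(default_factory=SCConfig)

    def scaled(self, n_shuffles: int, n_contexts: int, flank_len: int) -> "FeatureConfig":
        """Convenience: a cheaper configuration for small-scale runs."""
        return replace(
            self,
            n_shuffles=n_shuffles,
            sc=replace(self.sc, n_contexts=n_contexts, flank_len=flank_len),
        )


@dataclass(frozen=True)
class FeatureVector:
    """The 125 named feature values for one hairpin."""

    sequence_id: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_NAMES:
            raise ValueError("feature vector must carry all 125 registry names in order")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.sequence_id)

    def __getitem__(self, name: str) -> float:
        return self.values[resolve_feature_name(name)]


def extract_all(
    seq: RnaSequence,
    backend: Optional[FoldBackend] = None,
    config: FeatureConfig = FeatureConfig(),
    seed: int | None = 0,
) -> FeatureVector:
    """Extract the full 125-feature vector for one sequence.

    Orchestrates fold → melting estimate → shuffle cohort → SC → the five
    feature groups.  Deterministic for a fixed seed, backend and config.
    """
    backend = backend or default_backend()
    ss = np.random.SeedSequence(seed)
    rng_cohort, rng_sc = [np.random.default_rng(c) for c in ss.spawn(2)]
    try:
        fr = backend.fold(seq, temperature=config.temperature, partition=True)
        melt = estimate_melt(
            seq, backend=backend, t1=config.temperature, t2=config.melt_t2
        )
        cohort = build_cohort(
            seq,
            n_shuffles=config.n_shuffles,
            statistics=cohort_statistics(),
            rng=rng_cohort,
            backend=backend,
            temperature=config.temperature,
        )
        sc = self_containment(
            seq, config=config.sc, backend=backend, rng=rng_sc,
            temperature=config.temperature,
        )
    except Exception as exc:
        raise RuntimeError(f"feature extraction failed for {seq.id!r}") from exc

    sv = structure_features(seq, fr, melt, cohort)
    bv = basepair_features(seq, fr, cohort)
    values: dict[str, float] = {}
    values.update(sequence_features(seq))
    values.update(sv)
    values.update(bv)
    values.update(triplet_features(seq, fr))
    values.update(sc_features(sc, sv, bv, len(seq)))
    ordered = {name: float(values[name]) for name in FEATURE_NAMES}
    return FeatureVector(sequence_id=seq.id, values=ordered)


def extract_table(
    sequences: Sequence[RnaSequence],
    backend: Optional[FoldBackend] = None,
    config: FeatureConfig = FeatureConfig(),
    seed: int | None = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Extract features for many sequences into a DataFrame (rows indexed by
    sequence id, columns in registry order).  Each sequence gets an
    independent child seed derived from ``seed``."""
    backend = backend or default_backend()
    children = np.random.SeedSequence(seed).spawn(len(sequences))
    rows = []
    iterator = enumerate(sequences)
    for k, seq in iterator:
        child_seed = int(children[k].generate_state(1)[0] % (2**31))
        rows.append(extract_all(seq, backend=backend, config=config, seed=child_seed))
        if progress and (k + 1) % 50 == 0:  # pragma: no cover
            print(f"  extracted {k + 1}/{len(sequences)}")
    frame = pd.DataFrame(
        [r.values for r in rows], index=[r.sequence_id for r in rows]
    )
    frame.index.name = "id"
    return frame[list(FEATURE_NAMES)]
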