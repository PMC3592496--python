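"""Secondary-structure engine: folding backends, dot-bracket parsing, melting estimates.

The module exposes a pluggable folding contract (:class:`FoldBackend`) with two
implementations:

* :class:`ViennaBackend` — adapter to the ViennaRNA thermodynamic folder
  (McCaskill partition function, Turner energies).  This is the production
  backend for real feature extraction.
* :class:`ReferenceBackend` — a bundled, fully self-contained model:
  base-pair maximization with an energy of −1 unit per Watson–Crick or G–U
  pair, minimum hairpin loop of 3, and an exact inside/outside partition
  function over the same nested-structure ensemble (kT = 1 unit).  Its output
  is verifiable against brute-force structure enumeration, which makes it the
  oracle backend for tests; it is not meant for biological inference.

Coordinates are 1-based in pair tables; dot-bracket strings run 5'→3'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Protocol, runtime_checkable

import numpy as np

MIN_LOOP = 3  # minimum unpaired residues enclosed by a hairpin pair
_MIN_FOLDABLE = MIN_LOOP + 2

_VALID = frozenset("ACGU")
_CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)


def normalize_residues(residues: str) -> str:
    """Uppercase and map DNA thymine to uracil."""
    return residues.upper().replace("T", "U")


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence over {A, C, G, U}.

    ``residues`` is normalized (uppercase, T→U) on construction; any residue
    outside the alphabet raises ``ValueError`` naming the offending 1-based
    positions.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        norm = normalize_residues(self.residues)
        bad = [i + 1 for i, c in enumerate(norm) if c not in _VALID]
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: invalid residues at positions {bad[:10]}"
            )
        if len(norm) < 1:
            raise ValueError(f"sequence {self.id!r}: empty sequence")
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _CANONICAL_PAIRS


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested secondary structure.

    ``pair_table[i-1]`` is the 1-based partner of position ``i`` (0 when
    unpaired).  ``loop_sizes`` lists the lengths of maximal unpaired runs
    that are flanked by paired positions on both sides (hairpin loops,
    bulges, interior-loop sides and multiloop segments each count once);
    dangling ends are not loops.
    """

    dot_bracket: str
    pair_table: tuple[int, ...]
    tot_bp: int
    n_stems: int
    n_loops: int
    loop_sizes: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.dot_bracket)

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        """Base pairs (i, j), 1-based, i < j, in 5'→3' order of i."""
        return tuple(
            (i + 1, j) for i, j in enumerate(self.pair_table) if j > i + 1
        )

    def partner(self, i: int) -> int:
        """1-based partner of 1-based position ``i`` (0 if unpaired)."""
        return self.pair_table[i - 1]


class DotBracketError(ValueError):
    pass


def parse_dot_bracket(db: str) -> SecondaryStructure:
    """Parse a Vienna dot-bracket string into a :class:`SecondaryStructure`.

    Raises :class:`DotBracketError` with the 1-based index of the first
    unbalanced bracket.  Only '(', '.', ')' are accepted (no pseudoknots).
    """
    stack: list[int] = []
    table = [0] * len(db)
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise DotBracketError(f"unmatched ')' at position {idx + 1}")
            i = stack.pop()
            table[i] = idx + 1
            table[idx] = i + 1
        elif ch != ".":
            raise DotBracketError(f"invalid character {ch!r} at position {idx + 1}")
    if stack:
        raise DotBracketError(f"unmatched '(' at position {stack[-1] + 1}")
    return _structure_from_table(db, tuple(table))


def _structure_from_table(db: str, table: tuple[int, ...]) -> SecondaryStructure:
    n = len(db)
    pairs = [(i + 1, j) for i, j in enumerate(table) if j > i + 1]
    tot_bp = len(pairs)

    # stems: maximal runs of stacked pairs, (i, j) stacking on (i+1, j-1)
    pair_set = set(pairs)
    n_stems = sum(1 for (i, j) in pairs if (i - 1, j + 1) not in pair_set)

    # loops: maximal unpaired runs bounded by paired positions on both sides
    loop_sizes: list[int] = []
    paired = [j != 0 for j in table]
    run = 0
    seen_paired = False
    for k in range(n):
        if paired[k]:
            if run and seen_paired:
                loop_sizes.append(run)
            run = 0
            seen_paired = True
        else:
            run += 1
    return SecondaryStructure(
        dot_bracket=db,
        pair_table=table,
        tot_bp=tot_bp,
        n_stems=n_stems,
        n_loops=len(loop_sizes),
        loop_sizes=tuple(loop_sizes),
    )


def render_dot_bracket(pair_table: tuple[int, ...]) -> str:
    """Render a pair table back to dot-bracket (inverse of parsing)."""
    out = []
    for i, j in enumerate(pair_table):
        if j == 0:
            out.append(".")
        elif j > i + 1:
            out.append("(")
        else:
            out.append(")")
    return "".join(out)


@dataclass(frozen=True)
class FoldResult:
    """Folding output for one sequence at one temperature.

    ``pair_prob`` is the symmetric base-pair probability matrix (0-based
    numpy indexing; entry [i, j] is the probability that residues i+1 and
    j+1 pair in the Boltzmann ensemble); it is ``None`` when the backend was
    asked for the MFE structure only.
    """

    structure: SecondaryStructure
    mfe: float
    efe: float
    freq_mfe: float
    temperature: float
    pair_prob: Optional[np.ndarray] = field(default=None, repr=False)


@dataclass(frozen=True)
class MeltEstimate:
    """Two-temperature finite-difference melting estimate (kcal/mol, K)."""

    dH: float
    dS: float
    Tm: float


@runtime_checkable
class FoldBackend(Protocol):
    def fold(
        self, seq: RnaSequence, temperature: float = 37.0, partition: bool = True
    ) -> FoldResult:
        ...


def _trivial_fold(seq: RnaSequence, temperature: float, partition: bool) -> FoldResult:
    n = len(seq)
    structure = _structure_from_table("." * n, tuple([0] * n))
    prob = np.zeros((n, n)) if partition else None
    return FoldResult(
        structure=structure,
        mfe=0.0,
        efe=0.0,
        freq_mfe=1.0,
        temperature=temperature,
        pair_prob=prob,
    )


class ReferenceBackend:
    """Exact base-pair-maximization folding model (see module docstring).

    Energy of a structure is −1 unit per canonical pair; kT is 1 unit, so
    the Boltzmann weight of a structure with b pairs is e^b.  The partition
    function and pair probabilities are computed with inside/outside
    recursions over the nested ensemble with minimum loop ``MIN_LOOP``.
    Temperature does not enter the energy model, so results are
    temperature-independent (dS = 0 in melting estimates by construction).
    The outside recursion is O(L^4); the backend is intended for short
    sequences (tests, oracles), not genome-scale use.
    """

    pair_energy = -1.0

    def fold(
        self, seq: RnaSequence, temperature: float = 37.0, partition: bool = True
    ) -> FoldResult:
        n = len(seq)
        if n < _MIN_FOLDABLE:
            return _trivial_fold(seq, temperature, partition)
        s = seq.residues
        ok = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + MIN_LOOP + 1, n):
                ok[i, j] = can_pair(s[i], s[j])

        db, mfe = self._nussinov(n, ok)
        structure = parse_dot_bracket(db)
        if not partition:
            return FoldResult(structure, mfe, mfe, 1.0, temperature, None)

        Z, Zb = self._inside(n, ok)
        total = Z[0][n - 1] if n else 1.0
        prob = self._outside(n, ok, Z, Zb, total)
        efe = -math.log(total)
        freq = math.exp(-mfe) / total
        freq = min(freq, 1.0)
        return FoldResult(structure, mfe, efe, freq, temperature, prob)

    # -- minimum free energy ------------------------------------------------

    def _nussinov(self, n: int, ok: np.ndarray) -> tuple[str, float]:
        best = np.zeros((n, n), dtype=np.int32)
        for span in range(MIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                v = best[i + 1, j] if i + 1 <= j else 0
                for k in range(i + MIN_LOOP + 1, j + 1):
                    if ok[i, k]:
                        inner = best[i + 1, k - 1] if i + 1 <= k - 1 else 0
                        rest = best[k + 1, j] if k + 1 <= j else 0
                        v = max(v, 1 + inner + rest)
                best[i, j] = v
        table = [0] * n
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if i >= j or j - i <= MIN_LOOP:
                continue
            if best[i, j] == (best[i + 1, j] if i + 1 <= j else 0):
                stack.append((i + 1, j))
                continue
            for k in range(i + MIN_LOOP + 1, j + 1):
                if ok[i, k]:
                    inner = best[i + 1, k - 1] if i + 1 <= k - 1 else 0
                    rest = best[k + 1, j] if k + 1 <= j else 0
                    if best[i, j] == 1 + inner + rest:
                        table[i] = k + 1
                        table[k] = i + 1
                        stack.append((i + 1, k - 1))
                        stack.append((k + 1, j))
                        break
        n_pairs = int(best[0, n - 1])
        return render_dot_bracket(tuple(table)), self.pair_energy * n_pairs if n_pairs else 0.0

    # -- partition function -------------------------------------------------

    @staticmethod
    def _w() -> float:
        return math.e  # Boltzmann weight of one pair: e^{-(-1)/1}

    def _inside(self, n: int, ok: np.ndarray):
        w = self._w()
        Z = [[1.0] * n for _ in range(n)]   # Z[i][j]: subsequence i..j, empty=1
        Zb = [[0.0] * n for _ in range(n)]  # Zb[i][j]: i pairs j
        for span in range(1, n):
            for i in range(0, n - span):
                j = i + span
                if ok[i, j]:
                    inner = Z[i + 1][j - 1] if i + 1 <= j - 1 else 1.0
                    Zb[i][j] = w * inner
                total = Z[i + 1][j] if i + 1 <= j else 1.0
                for k in range(i + MIN_LOOP + 1, j + 1):
                    if ok[i, k]:
                        rest = Z[k + 1][j] if k + 1 <= j else 1.0
                        total += Zb[i][k] * rest
                Z[i][j] = total
        return Z, Zb

    def _outside(self, n: int, ok, Z, Zb, total: float) -> np.ndarray:
        w = self._w()

        def z(i: int, j: int) -> float:
            return 1.0 if i > j else Z[i][j]

        # Q[i][j]: weight of all configurations outside (i, j) given that
        # (i, j) pairs, excluding the (i, j) pair weight itself.  Summed over
        # the innermost pair (h, l) enclosing (i, j); by innermost-ness the
        # gap splits into two independent segments.
        Q = np.zeros((n, n))
        order = sorted(
            ((i, j) for i in range(n) for j in range(i + MIN_LOOP + 1, n) if ok[i, j]),
            key=lambda ij: ij[0] - ij[1],  # widest spans first
        )
        for i, j in order:
            acc = z(0, i - 1) * z(j + 1, n - 1)
            for h in range(0, i):
                for l in range(j + 1, n):
                    if ok[h, l]:
                        acc += w * Q[h, l] * z(h + 1, i - 1) * z(j + 1, l - 1)
            Q[i, j] = acc
        prob = np.zeros((n, n))
        for i, j in order:
            p = Zb[i][j] * Q[i, j] / total
            prob[i, j] = prob[j, i] = p
        return prob


class ViennaBackend:
    """Adapter to the ViennaRNA thermodynamic folding engine.

    Energies are Turner kcal/mol; the partition function and base-pair
    probabilities come from ViennaRNA's McCaskill implementation.  The
    ``RNA`` Python bindings are imported lazily so the rest of the package
    works without them.
    """

    def __init__(self) -> None:
        try:
            import RNA  # type: ignore
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "ViennaRNA python bindings (module 'RNA') are required for "
                "ViennaBackend; install the viennarna package or use "
                "ReferenceBackend"
            ) from exc
        self._RNA = RNA

    def fold(
        self, seq: RnaSequence, temperature: float = 37.0, partition: bool = True
    ) -> FoldResult:
        n = len(seq)
        if n < _MIN_FOLDABLE:
            return _trivial_fold(seq, temperature, partition)
        RNA = self._RNA
        md = RNA.md()
        md.temperature = temperature
        fc = RNA.fold_compound(seq.residues, md)
        db, mfe = fc.mfe()
        structure = parse_dot_bracket(db)
        if not partition:
            return FoldResult(structure, float(mfe), float(mfe), 1.0, temperature, None)
        fc.exp_params_rescale(mfe)
        _, efe = fc.pf()
        efe = float(min(efe, mfe))  # guard float round-off on unstructured input
        bpp = np.array(fc.bpp())[1:, 1:]  # strip ViennaRNA's 1-based padding
        prob = bpp + bpp.T
        # Boltzmann frequency of the MFE structure from the energy gap
        kt = 0.0019872041 * (273.15 + temperature)  # kcal/(mol K) * T
        freq = float(min(math.exp((efe - mfe) / kt), 1.0))
        return FoldResult(structure, float(mfe), efe, freq, temperature, prob)


_DEFAULT_BACKEND: Optional[FoldBackend] = None


def get_backend(name: str = "vienna") -> FoldBackend:
    """Return a folding backend by name ('vienna' or 'reference')."""
    if name == "vienna":
        return ViennaBackend()
    if name == "reference":
        return ReferenceBackend()
    raise ValueError(f"unknown folding backend {name!r}")


def default_backend() -> FoldBackend:
    """Module-level cached ViennaRNA backend (falls back to the reference
    model only if the bindings are missing)."""
    global _DEFAULT_BACKEND
    if _DEFAULT_BACKEND is None:
        try:
            _DEFAULT_BACKEND = ViennaBackend()
        except ImportError:  # pragma: no cover
            _DEFAULT_BACKEND = ReferenceBackend()
    return _DEFAULT_BACKEND


def fold(
    seq: RnaSequence,
    temperature: float = 37.0,
    backend: Optional[FoldBackend] = None,
    partition: bool = True,
) -> FoldResult:
    """Fold a sequence with the given backend (default: ViennaRNA)."""
    backend = backend or default_backend()
    return backend.fold(seq, temperature=temperature, partition=partition)


def estimate_melt(
    seq: RnaSequence,
    backend: Optional[FoldBackend] = None,
    t1: float = 37.0,
    t2: float = 67.0,
) -> MeltEstimate:
    """Two-temperature finite-difference estimate of folding dH, dS and Tm.

    dS = −(mfe(T2) − mfe(T1)) / (T2 − T1) in kcal/(mol·K) (temperatures in
    °C differ by the same amount as in K), dH = mfe(T1) + T1[K]·dS, and
    Tm = dH/dS when dS ≠ 0, else 0.  A backend with temperature-independent
    energies yields an all-zero estimate apart from dH = mfe.
    """
    if not t1 < t2:
        raise ValueError("require t1 < t2")
    backend = backend or default_backend()
    m1 = backend.fold(seq, temperature=t1, partition=False).mfe
    m2 = backend.fold(seq, temperature=t2, partition=False).mfe
    dS = -(m2 - m1) / (t2 - t1)
    dH = m1 + (t1 + 273.15) * dS
    Tm = dH / dS if dS != 0.0 else 0.0
    return MeltEstimate(dH=dH, dS=dS, Tm=Tm)
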