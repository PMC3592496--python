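"""Dot-bracket parsing, the reference folding model vs brute force, melting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirvote.structure import (
    DotBracketError,
    FoldResult,
    ReferenceBackend,
    RnaSequence,
    estimate_melt,
    parse_dot_bracket,
    render_dot_bracket,
)

from conftest import boltzmann_summary, random_rna


class TestRnaSequence:
    def test_normalizes_dna_and_case(self):
        seq = RnaSequence("s", "acgT")
        assert seq.residues == "ACGU"

    def test_rejects_invalid_residues_with_positions(self):
        with pytest.raises(ValueError, match=r"positions \[3\]"):
            RnaSequence("s", "ACXG")


class TestParseDotBracket:
    @pytest.mark.parametrize(
        "db, tot_bp, n_stems, n_loops, loop_sizes",
        [
            ("((((....))))", 4, 1, 1, (4,)),
            ("............", 0, 0, 0, ()),
            ("((..((....))))", 4, 2, 2, (2, 4)),
            # the inter-hairpin segment is flanked by paired positions on
            # both sides, so it counts as a loop; dangling ends never do
            ("(((...)))...(((...)))", 6, 2, 3, (3, 3, 3)),
            ("..(((...))).", 3, 1, 1, (3,)),
        ],
    )
    def test_counting_conventions(self, db, tot_bp, n_stems, n_loops, loop_sizes):
        st_ = parse_dot_bracket(db)
        assert st_.tot_bp == tot_bp
        assert st_.n_stems == n_stems
        assert st_.n_loops == n_loops
        assert st_.loop_sizes == loop_sizes

    @pytest.mark.parametrize("db, pos", [("(((..", 3), ("..)..", 3), ("(.))", 4)])
    def test_unbalanced_reports_index(self, db, pos):
        with pytest.raises(DotBracketError, match=str(pos)):
            parse_dot_bracket(db)

    def test_pair_table_symmetric(self):
        st_ = parse_dot_bracket("((..((....))))")
        for i, j in st_.pairs:
            assert st_.partner(j) == i

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_round_trip_on_folded_structures(self, seed):
        rng = np.random.default_rng(seed)
        s = random_rna(rng, int(rng.integers(5, 25)))
        fr = ReferenceBackend().fold(RnaSequence("r", s), partition=False)
        db = fr.structure.dot_bracket
        assert render_dot_bracket(fr.structure.pair_table) == db
        assert parse_dot_bracket(db).pair_table == fr.structure.pair_table


class TestReferenceBackend:
    def test_canonical_hairpin(self, reference_backend):
        fr = reference_backend.fold(RnaSequence("h", "GGGAAACCC"))
        assert fr.structure.dot_bracket == "(((...)))"
        assert fr.mfe == -3.0
        assert fr.efe <= -3.0
        assert 0.0 < fr.freq_mfe <= 1.0

    def test_unpairable_sequence(self, reference_backend):
        fr = reference_backend.fold(RnaSequence("a", "AAAAAAA"))
        assert fr.structure.dot_bracket == "......."
        assert fr.structure.tot_bp == 0
        assert fr.mfe == 0.0
        assert fr.freq_mfe == 1.0

    def test_too_short_sequence_gives_empty_structure(self, reference_backend):
        fr = reference_backend.fold(RnaSequence("s", "GGCC"))
        assert fr.structure.tot_bp == 0 and fr.mfe == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed, reference_backend):
        """MFE, ensemble free energy, pair probabilities and MFE-structure
        frequency all agree with exhaustive structure enumeration."""
        rng = np.random.default_rng(seed)
        s = random_rna(rng, int(rng.integers(8, 17)))
        oracle = boltzmann_summary(s)
        fr = reference_backend.fold(RnaSequence("r", s))
        assert fr.mfe == oracle["mfe"]
        assert fr.efe == pytest.approx(oracle["efe"], abs=1e-10)
        assert np.allclose(fr.pair_prob, oracle["prob"], atol=1e-10)
        assert fr.freq_mfe == pytest.approx(oracle["freq_mfe"], abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_efe_never_above_mfe(self, seed, reference_backend):
        rng = np.random.default_rng(100 + seed)
        s = random_rna(rng, int(rng.integers(6, 30)))
        fr = reference_backend.fold(RnaSequence("r", s))
        assert fr.efe <= fr.mfe + 1e-12
        assert (fr.pair_prob.sum(axis=1) <= 1.0 + 1e-9).all()


class TestViennaBackend:
    def test_basic_invariants(self, vienna_backend):
        rng = np.random.default_rng(3)
        for _ in range(3):
            s = random_rna(rng, 60)
            fr = vienna_backend.fold(RnaSequence("v", s))
            assert fr.efe <= fr.mfe + 1e-9
            assert 0.0 < fr.freq_mfe <= 1.0
            assert np.allclose(fr.pair_prob, fr.pair_prob.T)
            assert (fr.pair_prob.sum(axis=1) <= 1.0 + 1e-6).all()

    def test_strong_stem_has_low_mfe(self, vienna_backend):
        fr = vienna_backend.fold(
            RnaSequence("v", "GGGGGGGGGGGGAAAACCCCCCCCCCCC"), partition=False
        )
        assert fr.mfe < -18.0
        assert fr.structure.tot_bp >= 10


class _StubMeltBackend:
    """Fixed MFE per temperature, for finite-difference arithmetic checks."""

    def __init__(self, mfes):
        self.mfes = mfes

    def fold(self, seq, temperature=37.0, partition=True):
        st_ = parse_dot_bracket("." * len(seq))
        return FoldResult(st_, self.mfes[temperature], self.mfes[temperature], 1.0,
                          temperature, None)


class TestEstimateMelt:
    def test_finite_difference_arithmetic(self):
        backend = _StubMeltBackend({37.0: -10.0, 67.0: -7.0})
        melt = estimate_melt(RnaSequence("m", "ACGUACGU"), backend=backend)
        assert melt.dS == pytest.approx(-0.1)
        assert melt.dH == pytest.approx(-10.0 + 310.15 * -0.1)
        assert melt.Tm == pytest.approx(melt.dH / melt.dS)
        assert melt.Tm > 0

    def test_temperature_independent_backend_gives_zero_entropy(self):
        backend = _StubMeltBackend({37.0: -5.0, 67.0: -5.0})
        melt = estimate_melt(RnaSequence("m", "ACGUACGU"), backend=backend)
        assert melt.dS == 0.0 and melt.Tm == 0.0

    def test_reference_backend_is_temperature_independent(self, reference_backend):
        melt = estimate_melt(RnaSequence("m", "GGGAAACCC"), backend=reference_backend)
        assert melt.dS == 0.0 and melt.Tm == 0.0 and melt.dH == -3.0

    def test_requires_increasing_temperatures(self, reference_backend):
        with pytest.raises(ValueError):
            estimate_melt(RnaSequence("m", "GGGAAACCC"), backend=reference_backend,
                          t1=67.0, t2=37.0)
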