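"""Feature registry integrity and group extraction arithmetic."""

import numpy as np
import pytest

from mirvote.features import (
    FEATURE_NAMES,
    GROUP_SIZES,
    FeatureConfig,
    basepair_features,
    catalog,
    extract_all,
    resolve_feature_name,
    sc_features,
    sequence_features,
    structure_features,
    triplet_features,
)
from mirvote.selection import DEFAULT_SELECTED_FEATURES
from mirvote.selfcontainment import SCResult
from mirvote.shuffle import ShuffleCohort
from mirvote.structure import (
    FoldResult,
    MeltEstimate,
    RnaSequence,
    parse_dot_bracket,
)


def make_fold(db: str, mfe: float = -10.0, efe: float = None, pair_prob=None,
              freq: float = 0.5) -> FoldResult:
    st = parse_dot_bracket(db)
    n = len(db)
    if pair_prob is None:
        pair_prob = np.zeros((n, n))
        for i, j in st.pairs:
            pair_prob[i - 1, j - 1] = pair_prob[j - 1, i - 1] = 0.9
    return FoldResult(st, mfe, efe if efe is not None else mfe - 1.0, freq, 37.0,
                      pair_prob)


def make_cohort(mfes, tot_bps=None) -> ShuffleCohort:
    mfes = np.asarray(mfes, dtype=float)
    samples = {
        "mfe": mfes,
        "tot_bp": np.asarray(tot_bps if tot_bps is not None else mfes * 0, float),
        "entropy": np.zeros_like(mfes),
        "diversity": np.zeros_like(mfes),
        "fiedler": np.zeros_like(mfes),
    }
    return ShuffleCohort(n_shuffles=len(mfes), samples=samples,
                         mean_dG=float(mfes.mean()))


class TestRegistry:
    def test_counts(self):
        specs = catalog()
        assert len(specs) == 125
        assert GROUP_SIZES == {
            "sequence": 19, "structure": 30, "basepair": 32, "triplet": 32, "sc": 12,
        }
        assert sum(s.novel for s in specs) == 22
        assert sum(not s.novel for s in specs) == 103
        assert len({s.name for s in specs}) == 125

    def test_key_names_present(self):
        for name in ("MFEI1", "MFEI5", "MFE/Mean_dG", "dQ/Loop", "Probpair4",
                     "A(((", "U...", "SCxdP/(1-dP)", "Non_BPP", "Avg_BP_Loop"):
            assert name in FEATURE_NAMES

    def test_default_selection_resolves(self):
        assert len(DEFAULT_SELECTED_FEATURES) == 20
        for name in DEFAULT_SELECTED_FEATURES:
            assert name in FEATURE_NAMES

    @pytest.mark.parametrize(
        "alias, canonical",
        [("AU/L", "A-U/L"), ("ProbPair4", "Probpair4"), ("dH/Loop", "dH/loop"),
         ("SC×dP/(1−dP)", "SCxdP/(1-dP)"), ("sc/nonbp_a", "SC/NonBP_A"),
         ("Avg_BP_loop", "Avg_BP_Loop")],
    )
    def test_alias_normalization(self, alias, canonical):
        assert resolve_feature_name(alias) == canonical

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            resolve_feature_name("MFEI9")


class TestSequenceFeatures:
    def test_gc_content(self):
        v = sequence_features(RnaSequence("s", "GGCC"))
        assert v["%G+C"] == 100.0 and v["%A+U"] == 0.0

    def test_homopolymer_dinucleotides(self):
        v = sequence_features(RnaSequence("s", "AAAA"))
        assert v["%AA"] == 100.0
        assert sum(v[f"%{a}{b}"] for a in "ACGU" for b in "ACGU") == 100.0

    def test_acgu_dinucleotides(self):
        v = sequence_features(RnaSequence("s", "ACGU"))
        assert v["Len"] == 4
        for name in ("%AC", "%CG", "%GU"):
            assert v[name] == pytest.approx(100.0 / 3)

    def test_single_residue_guards(self):
        v = sequence_features(RnaSequence("s", "A"))
        assert v["%AA"] == 0.0 and v["%A+U"] == 100.0


class TestStructureFeatures:
    def test_mfe_indices(self):
        seq = RnaSequence("s", "GC" * 35)  # L=70, %G+C=100
        fold = make_fold("(" * 30 + "." * 10 + ")" * 30, mfe=-35.0)
        melt = MeltEstimate(dH=-40.0, dS=-0.1, Tm=400.0)
        cohort = make_cohort([-20.0, -25.0, -30.0])
        v = structure_features(seq, fold, melt, cohort)
        assert v["dG"] == pytest.approx(-0.5)
        assert v["MFEI1"] == pytest.approx(-0.5 / 100.0)
        assert v["MFEI4"] == pytest.approx(-35.0 / 30)
        assert v["MFEI5"] == pytest.approx(-0.5 / 30)
        assert v["MFE/Mean_dG"] == pytest.approx(-35.0 / -25.0)
        assert v["dH/loop"] == pytest.approx(-40.0)
        assert v["Tm/Loop"] == pytest.approx(400.0)

    def test_unpaired_guards(self):
        seq = RnaSequence("s", "AUAUAUAUAU")
        fold = make_fold("." * 10, mfe=0.0, efe=0.0, freq=1.0)
        melt = MeltEstimate(0.0, 0.0, 0.0)
        cohort = make_cohort([0.0, 0.0])
        v = structure_features(seq, fold, melt, cohort)
        assert v["MFEI4"] == 0.0 and v["dQ"] == 0.0 and v["dD"] == 0.0
        assert v["MFEI2"] == 0.0 and v["MFEI3"] == 0.0

    def test_constant_cohort_zscores(self):
        seq = RnaSequence("s", "GGGAAACCC")
        fold = make_fold("(((...)))", mfe=-3.0)
        cohort = make_cohort([-3.0, -3.0, -3.0])
        v = structure_features(seq, fold, MeltEstimate(0, 0, 0), cohort)
        assert v["zG"] == 0.0
        assert v["MFE/Mean_dG"] == pytest.approx(1.0)


class TestBasepairFeatures:
    def test_pairing_propensities(self):
        seq = RnaSequence("s", "G" * 30 + "AAAAAAAAAA" + "C" * 30)
        fold = make_fold("(" * 30 + "." * 10 + ")" * 30, mfe=-30.0)
        v = basepair_features(seq, fold, make_cohort([0, 0]))
        assert v["dP"] == pytest.approx(30 / 70)
        assert v["Non_BPP"] == pytest.approx(10 / 70)
        assert v["%C-G/BP"] == 100.0 and v["%A-U/BP"] == 0.0
        assert v["tot_bp"] == 30 and v["stem"] == 1 and v["loop"] == 1
        assert v["Avg_BP_Loop"] == 30.0

    def test_probpair_bins_partition_pairs(self):
        seq = RnaSequence("s", "GGGGGAAAACCCCC")
        st = parse_dot_bracket("(((((....)))))")
        n = 14
        prob = np.zeros((n, n))
        values = [0.05, 0.15, 0.35, 0.95, 1.0]
        for (i, j), p in zip(st.pairs, values):
            prob[i - 1, j - 1] = prob[j - 1, i - 1] = p
        fold = FoldResult(st, -5.0, -5.5, 0.5, 37.0, prob)
        v = basepair_features(seq, fold, make_cohort([0, 0]))
        bins = [v[f"Probpair{b}"] for b in range(1, 11)]
        assert sum(bins) == pytest.approx(1.0)
        assert v["Probpair1"] == pytest.approx(1 / 5)   # 0.05
        assert v["Probpair2"] == pytest.approx(1 / 5)   # 0.15
        assert v["Probpair4"] == pytest.approx(1 / 5)   # 0.35
        assert v["Probpair10"] == pytest.approx(2 / 5)  # 0.95, 1.0

    def test_nonbp_counts_by_base(self):
        seq = RnaSequence("s", "GGGGGAAAACCCCC")
        fold = make_fold("(((((....)))))", mfe=-5.0)
        v = basepair_features(seq, fold, make_cohort([0, 0]))
        assert v["NonBP_A"] == 4 and v["NonBP_G"] == 0 and v["NonBP_C"] == 0


class TestTripletFeatures:
    def test_all_paired_pattern(self):
        seq = RnaSequence("s", "AAA")
        from mirvote.structure import SecondaryStructure
        st = SecondaryStructure("(((", (0, 0, 0), 0, 0, 0, ())
        fold = FoldResult(st, 0.0, 0.0, 1.0, 37.0, None)
        v = triplet_features(seq, fold)
        assert v["A((("] == 1.0
        assert sum(v.values()) == pytest.approx(1.0)

    def test_middle_base_keys_unpaired(self):
        seq = RnaSequence("s", "GAC")
        fold = make_fold("...", mfe=0.0)
        v = triplet_features(seq, fold)
        assert v["A..."] == 1.0

    def test_close_brackets_fold_onto_open(self):
        seq = RnaSequence("s", "GGGAAACCC")
        fold = make_fold("(((...)))", mfe=-3.0)
        v = triplet_features(seq, fold)
        assert sum(v.values()) == pytest.approx(1.0)
        assert v["C((("] > 0  # positions inside the closing arm map to '('

    def test_short_sequence_all_zero(self):
        seq = RnaSequence("s", "AC")
        fold = make_fold("..", mfe=0.0)
        assert sum(triplet_features(seq, fold).values()) == 0.0


class TestScFeatures:
    def _deps(self, sc, dP, tot_bp, L, mean_ratio=1.0, zG=0.0, nonbp=None):
        nonbp = nonbp or {"A": 1.0, "C": 2.0, "G": 0.0, "U": 4.0}
        structure_values = {"MFE/Mean_dG": mean_ratio, "zG": zG}
        basepair_values = {
            "dP": dP, "tot_bp": float(tot_bp),
            "NonBP_A": nonbp["A"], "NonBP_C": nonbp["C"],
            "NonBP_G": nonbp["G"], "NonBP_U": nonbp["U"],
        }
        return sc_features(SCResult(sc=sc), structure_values, basepair_values, L)

    def test_composites(self):
        v = self._deps(sc=0.9, dP=0.5, tot_bp=20, L=80)
        assert v["SCxdP"] == pytest.approx(0.45)
        assert v["SC/(1-dP)"] == pytest.approx(1.8)
        assert v["SCxdP/(1-dP)"] == pytest.approx(0.9)
        assert v["SC/tot_bp"] == pytest.approx(0.045)
        assert v["SC/Len"] == pytest.approx(0.9 / 80)
        assert v["SC/NonBP_G"] == 0.0  # guarded zero denominator

    def test_sc_zero_zeroes_everything(self):
        v = self._deps(sc=0.0, dP=0.4, tot_bp=10, L=60, mean_ratio=2.0, zG=-3.0)
        assert all(val == 0.0 for val in v.values())

    def test_scaled_example(self):
        v = self._deps(sc=0.8, dP=0.25, tot_bp=20, L=80)
        assert v["SC/tot_bp"] == pytest.approx(0.04)
        assert v["SC/Len"] == pytest.approx(0.01)


class TestExtractAll:
    def test_full_vector_reference_backend(self, reference_backend):
        cfg = FeatureConfig(n_shuffles=4).scaled(n_shuffles=4, n_contexts=3,
                                                 flank_len=8)
        seq = RnaSequence("hp", "GGGGGAAAAACCCCCAAAA")
        fv = extract_all(seq, backend=reference_backend, config=cfg, seed=2)
        vals = np.array(list(fv.values.values()))
        assert len(vals) == 125
        assert np.all(np.isfinite(vals))
        assert tuple(fv.values.keys()) == FEATURE_NAMES
        assert fv["SC"] > 0

    def test_deterministic(self, reference_backend):
        cfg = FeatureConfig().scaled(n_shuffles=3, n_contexts=2, flank_len=5)
        seq = RnaSequence("hp", "GGGGAAAACCCC")
        a = extract_all(seq, backend=reference_backend, config=cfg, seed=9)
        b = extract_all(seq, backend=reference_backend, config=cfg, seed=9)
        assert a.values == b.values
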