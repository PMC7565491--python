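import numpy as np
import pytest

from crpkit.annotation import (
    ANTIMICROBIAL_LIKE,
    TRYPSIN_INHIBITOR_LIKE,
    AlignmentResult,
    ClassificationError,
    PatternError,
    TopologyError,
    classify_p1,
    frequency_matrix,
    loop_pattern,
    needle_align,
    nj_tree,
    putative_connectivity,
)
from crpkit.chem import AlphabetError
from crpkit.synthetic import CrpSpec, gen_crp, mutate

from conftest import CITCOL2, CITCOL8, CITCOLS, MCOTI_III, REFERENCE_CRPS


class TestLoopPattern:
    def test_citcol8(self):
        p = loop_pattern(CITCOL8)
        assert (p.prefix_len, p.loops, p.suffix_len) == (5, (6, 5, 3, 1, 10), 3)

    def test_mcoti_iii(self):
        p = loop_pattern(MCOTI_III)
        assert (p.prefix_len, p.loops, p.suffix_len) == (3, (6, 5, 3, 1, 5), 1)

    def test_adjacent_cysteines(self):
        p = loop_pattern("CC")
        assert (p.prefix_len, p.loops, p.suffix_len) == (0, (0,), 0)

    def test_too_few_cys(self):
        with pytest.raises(PatternError):
            loop_pattern("ACA")

    def test_reconstruction_bijective(self):
        rng = np.random.default_rng(3)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(200):
            seq = "".join(rng.choice(alphabet, size=rng.integers(5, 60)))
            if seq.count("C") < 2:
                continue
            p = loop_pattern(seq)
            assert p.reconstruct_length() == len(seq)
            assert [seq[i] for i in p.cys_positions] == ["C"] * p.n_cys
            rebuilt = [i for i, ch in enumerate(seq) if ch == "C"]
            assert list(p.cys_positions) == rebuilt


class TestClassifyP1:
    def test_citcol8_phe_antimicrobial(self):
        c = classify_p1(CITCOL8)
        assert c.p1_residue == "F" and c.label == ANTIMICROBIAL_LIKE

    def test_mcoti_arg_inhibitor(self):
        c = classify_p1(MCOTI_III)
        assert c.p1_residue == "R" and c.label == TRYPSIN_INHIBITOR_LIKE

    def test_all_citcols_antimicrobial(self):
        for _, seq in CITCOLS.values():
            assert classify_p1(seq).label == ANTIMICROBIAL_LIKE

    def test_short_loop1_errors(self):
        with pytest.raises(ClassificationError):
            classify_p1("CACAA")


class TestConnectivity:
    def test_citcol2_residue_indices(self):
        conn = putative_connectivity(loop_pattern(CITCOL2))
        assert conn.pairs == ((1, 4), (2, 5), (3, 6))
        assert conn.residue_pairs == ((2, 19), (9, 21), (15, 32))

    def test_toy_six_cys(self):
        conn = putative_connectivity(loop_pattern("CACACACACAC".replace("CA", "CA")))
        assert conn.pairs == ((1, 4), (2, 5), (3, 6))

    def test_four_cys_unsupported(self):
        with pytest.raises(TopologyError):
            putative_connectivity(loop_pattern("CACACA"))


class TestNeedleAlign:
    def test_self_alignment(self):
        r = needle_align(CITCOL8, CITCOL8)
        assert r.identity_pct == 100.0 and r.gaps_pct == 0.0

    @pytest.mark.parametrize("acc", sorted(REFERENCE_CRPS))
    def test_printed_similarities(self, acc):
        seq, printed = REFERENCE_CRPS[acc]
        r = needle_align(CITCOL8, seq)
        assert round(r.similarity_pct, 1) == printed

    def test_symmetry(self):
        for seq, _ in REFERENCE_CRPS.values():
            a = needle_align(CITCOL8, seq)
            b = needle_align(seq, CITCOL8)
            assert a.score == b.score
            assert a.similarity_pct == b.similarity_pct
            assert (a.aligned_a, a.aligned_b) == (b.aligned_b, b.aligned_a)

    def test_identity_below_similarity(self):
        r = needle_align(CITCOL8, MCOTI_III)
        assert r.identity_pct <= r.similarity_pct <= 100.0

    def test_nonstandard_residue(self):
        with pytest.raises(AlphabetError):
            needle_align("ACDB", "ACD")

    def test_empty_sequence(self):
        with pytest.raises(ValueError):
            needle_align("", "ACD")


class TestFrequencyMatrix:
    def test_citcol_panel_conservation(self):
        longest = max(len(s) for _, s in CITCOLS.values())
        aligned = [s.rjust(longest, "-") for _, s in CITCOLS.values()]
        freq = frequency_matrix(aligned)
        # shared 35-residue core: every column single-residue except the
        # three substitution sites (S/Y, W/K, D/N)
        core_cols = range(longest - 35, longest)
        variable = [
            c for c in core_cols
            if not np.isclose(freq.iloc[c].max(), 1.0)
        ]
        offset = longest - 35
        assert variable == [offset + 9, offset + 13, offset + 19]
        sy = freq.iloc[offset + 19]
        assert sy["Y"] == pytest.approx(5 / 8) and sy["S"] == pytest.approx(3 / 8)

    def test_columns_sum_to_one(self):
        freq = frequency_matrix(["AC-", "AG-", "ACA", "ACC"])
        assert np.allclose(freq.sum(axis=1), 1.0)

    def test_single_sequence_all_one(self):
        freq = frequency_matrix([CITCOL8])
        assert np.allclose(freq.max(axis=1), 1.0)

    def test_even_split(self):
        freq = frequency_matrix(["A"] * 4 + ["G"] * 4)
        assert freq.iloc[0]["A"] == pytest.approx(0.5)
        assert freq.iloc[0]["G"] == pytest.approx(0.5)

    def test_ragged_input(self):
        with pytest.raises(ValueError):
            frequency_matrix(["AC", "A"])


class TestNjTree:
    def test_three_equidistant_leaves(self):
        tree = nj_tree({"a": "AAAAA", "b": "GGGGG", "c": "TTTTT"})
        lengths = sorted(t.length for t in tree.tips())
        assert lengths == pytest.approx([0.5, 0.5, 0.5])

    def test_too_few_sequences(self):
        with pytest.raises(ValueError):
            nj_tree({"a": "AA", "b": "GG"})

    def test_planted_families_separate(self):
        spec_a = CrpSpec(p1_policy="aromatic")
        spec_b = CrpSpec(p1_policy="basic")
        founders = {"A": gen_crp(spec_a, 1, seed=1)[0][1],
                    "B": gen_crp(spec_b, 1, seed=2)[0][1]}
        seqs = {}
        for fam, founder in founders.items():
            for i in range(5):
                seqs[f"{fam}{i}"] = mutate(founder, rate=0.1, seed=100 + i)
        tree = nj_tree(seqs)
        dm = tree.tip_tip_distances()
        for name in seqs:
            others = [o for o in seqs if o != name]
            nearest = min(others, key=lambda o: dm[name, o])
            assert nearest[0] == name[0]

    def test_citcols_monophyletic_vs_mcoti(self):
        seqs = {name: seq for name, (_, seq) in CITCOLS.items()}
        seqs["MCoTI-III"] = MCOTI_III
        tree = nj_tree(seqs)
        dm = tree.tip_tip_distances()
        citcol_names = [n for n in seqs if n.startswith("citcol")]
        max_within = max(
            dm[a, b] for a in citcol_names for b in citcol_names if a != b
        )
        min_out = min(dm[n, "MCoTI-III"] for n in citcol_names)
        assert max_within < min_out
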