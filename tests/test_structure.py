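"""Mock predictor contract, change frequencies, structural classification."""

import numpy as np
import pytest

import stokeshift as ss
from stokeshift.io import TRACKS, TRACK_ALPHABETS, StructureAnnotation
from stokeshift.structure import (
    annotate_library,
    change_frequency,
    classify_structural_branches,
    mock_predictor,
)


class TestMockPredictor:
    def test_deterministic(self):
        seq = "MKVLITGASGFIGSHLVDRLM"
        a, b = mock_predictor(seq), mock_predictor(seq)
        assert a == b

    def test_alphabets_and_length(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        anno = mock_predictor(seq)
        for track in TRACKS:
            assert len(anno.track(track)) == len(seq)
            assert set(anno.track(track)) <= set(TRACK_ALPHABETS[track])

    def test_point_substitution_is_local(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list(ss.io.AMINO_ACIDS), size=60))
            pos = int(rng.integers(60))
            alt = "W" if seq[pos] != "W" else "Y"
            seq2 = seq[:pos] + alt + seq[pos + 1 :]
            a1, a2 = mock_predictor(seq), mock_predictor(seq2)
            for track in TRACKS:
                diffs = [
                    i for i, (x, y) in enumerate(zip(a1.track(track), a2.track(track)))
                    if x != y
                ]
                assert len(diffs) <= 5
                assert all(abs(i - pos) <= 2 for i in diffs)

    def test_homopolymer_constant_interior(self):
        anno = mock_predictor("A" * 30)
        for track in TRACKS:
            interior = anno.track(track)[2:-2]
            assert len(set(interior)) == 1


class TestAnnotateLibrary:
    def test_one_annotation_per_sequence(self):
        lib = ss.AncestralLibrary("n", ["ACDEF"], "altall")
        assert len(annotate_library(lib, mock_predictor)) == 1

    def test_duplicates_predicted_once(self):
        calls = []

        def counting(seq):
            calls.append(seq)
            return mock_predictor(seq)

        lib = ss.AncestralLibrary("n", ["ACDEF", "ACDEF", "ACDEW"], "altall")
        annos = annotate_library(lib, counting)
        assert len(annos) == 3 and len(calls) == 2

    def test_length_mismatch_names_node(self):
        def broken(seq):
            return mock_predictor(seq[:-1])

        lib = ss.AncestralLibrary("nodeX", ["ACDEF"], "altall")
        with pytest.raises(Exception, match="nodeX"):
            annotate_library(lib, broken)


def anno(ss3: str) -> StructureAnnotation:
    """Annotation with a chosen ss3 string; other tracks constant."""
    n = len(ss3)
    return StructureAnnotation("O" * n, ss3, "C" * n, "B" * n)


class TestChangeFrequency:
    def test_identical_singletons_zero(self):
        assert change_frequency([anno("HHEC")], [anno("HHEC")], "ss3") == 0.0

    def test_fully_different_pair_one(self):
        assert change_frequency([anno("HHHH")], [anno("EEEE")], "ss3") == 1.0

    def test_cross_pair_mean_by_hand(self):
        # 2 x 3 libraries of 4-symbol strings: mean of the 6 pairwise
        # mismatch fractions, enumerated by hand
        parents = [anno("HHEC"), anno("HEEC")]
        children = [anno("HHEC"), anno("CHEC"), anno("EEEE")]
        fractions = []
        for p in parents:
            for c in children:
                fractions.append(
                    np.mean([x != y for x, y in zip(p.ss3, c.ss3)])
                )
        expected = float(np.mean(fractions))
        assert change_frequency(parents, children, "ss3") == pytest.approx(expected)

    def test_symmetric_and_order_invariant(self):
        pa = [anno("HHEC"), anno("HEEC")]
        ca = [anno("CHEC"), anno("EEEE")]
        f1 = change_frequency(pa, ca, "ss3")
        f2 = change_frequency(ca, pa, "ss3")
        f3 = change_frequency(pa[::-1], ca[::-1], "ss3")
        assert f1 == pytest.approx(f2) == pytest.approx(f3)

    def test_singletons_equal_hamming(self):
        a, b = anno("HHEECC"), anno("HCEHCC")
        ham = np.mean([x != y for x, y in zip(a.ss3, b.ss3)])
        assert change_frequency([a], [b], "ss3") == pytest.approx(ham)

    def test_length_mismatch_rejected(self):
        with pytest.raises(Exception, match="length"):
            change_frequency([anno("HH")], [anno("HHH")], "ss3")


class TestStructuralClassification:
    def test_all_zero_frequencies_unflagged_same_quartile(self):
        freqs = {t: {("r", f"n{i}"): 0.0 for i in range(5)} for t in TRACKS}
        dfs = classify_structural_branches(freqs)
        for t in TRACKS:
            assert set(dfs[t]["quartile"]) == {"Q2"}
            assert not dfs[t]["flag"].any()

    def test_distinct_frequencies_one_per_quartile(self):
        freqs = {t: {("r", f"n{i}"): i / 10 for i in range(4)} for t in TRACKS}
        dfs = classify_structural_branches(freqs)
        assert sorted(dfs["ss3"]["quartile"]) == ["Q1", "Q2", "Q3", "Q4"]

    def test_five_metric_quartiles_jointly_emitted(self, jtt, gamma6):
        from conftest import shift_replicate
        from stokeshift.pipeline import assemble_branch_table

        rep = shift_replicate(8, jtt, gamma6, n_taxa=8, length=80)
        table = assemble_branch_table(rep["epistasis"], rep["structural"])
        for metric in ss.io.METRICS:
            assert f"quartile_{metric}" in table.df.columns
        inner_rows = table.df.dropna(subset=["ss3"])
        assert len(inner_rows) > 0
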