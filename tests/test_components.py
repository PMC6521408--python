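"""Container and decoy-population operation tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from decoytools.components import (DesignTable, MutationSpec,
                                   ReferenceSequence, SelectionRange,
                                   deduplicate_identifiers, get_sequence,
                                   generate_mutant_variants,
                                   generate_wt_reversions, merge_experiments,
                                   mutation_tokens)


# -- references --------------------------------------------------------------

class TestReferenceSequences:
    def test_identity_storage(self, small_table):
        small_table.add_reference_sequence("A", "AAAA")
        assert small_table.get_reference("A").sequence == "AAAA"
        assert small_table.get_reference("A").shift == 1

    def test_length_mismatch_names_both_lengths(self, small_table):
        with pytest.raises(ValueError, match="5.*4|4.*5"):
            small_table.add_reference_sequence("A", "AAAAA")

    def test_unknown_chain_errors(self, small_table):
        with pytest.raises(KeyError, match="B"):
            small_table.add_reference_sequence("B", "AAAA")

    def test_replacement_is_last_write_wins(self, small_table):
        small_table.add_reference_sequence("A", "AAAA")
        small_table.add_reference_sequence("A", "CCCC")
        assert small_table.get_reference("A").sequence == "CCCC"

    def test_reference_survives_pandas_ops(self, small_table):
        small_table.add_reference_sequence("A", "AAAA")
        sub = small_table.sort_values("score").head(2)
        assert sub.get_reference("A").sequence == "AAAA"


# -- sequence access ---------------------------------------------------------

class TestGetSequence:
    def test_returns_verbatim(self, small_table):
        assert get_sequence(small_table.iloc[1], "A") == "CAAA"
        assert small_table.get_sequence("A", 0) == "AAAA"

    def test_missing_chain_lists_available(self, small_table):
        with pytest.raises(KeyError, match="available chains.*A"):
            get_sequence(small_table.iloc[0], "B")

    def test_gaps_not_stripped(self):
        t = DesignTable({"description": ["d"], "sequence_A": ["M-V"]})
        assert t.get_sequence("A") == "M-V"


# -- selection by residues ---------------------------------------------------

class TestGetSequenceWith:
    PAIRS = [(1, "C"), (3, "C")]

    def test_half_confidence_selects_carriers(self, small_table):
        out = small_table.get_sequence_with("A", self.PAIRS, confidence=0.5)
        assert list(out["description"]) == ["d2", "d3"]

    def test_invert_is_complement(self, small_table):
        out = small_table.get_sequence_with("A", self.PAIRS, confidence=0.5,
                                            invert=True)
        assert list(out["description"]) == ["d1"]

    def test_not_any_selection(self):
        # confidence 1/len(pairs) with invert selects rows carrying none of
        # the listed residues
        t = DesignTable({
            "description": ["a", "b", "c"],
            "sequence_A": ["AAAA", "CAAA", "GGGG"],
        })
        pairs = [(1, "C"), (2, "A"), (3, "A"), (4, "A")]
        out = t.get_sequence_with("A", pairs, confidence=0.25, invert=True)
        assert list(out["description"]) == ["c"]

    def test_empty_pairs_and_bad_confidence_error(self, small_table):
        with pytest.raises(ValueError):
            small_table.get_sequence_with("A", [])
        with pytest.raises(ValueError):
            small_table.get_sequence_with("A", self.PAIRS, confidence=1.5)

    def test_partition_property(self, rng):
        # select(invert=False) and select(invert=True) partition the table
        letters = np.array(list("ACDE"))
        for _ in range(25):
            n, L = rng.integers(5, 30), rng.integers(4, 12)
            seqs = ["".join(rng.choice(letters, size=L)) for _ in range(n)]
            t = DesignTable({"description": [f"d{i}" for i in range(n)],
                             "sequence_A": seqs})
            pairs = [(int(p) + 1, str(rng.choice(letters)))
                     for p in rng.choice(L, size=3, replace=False)]
            conf = float(rng.choice([0.34, 0.5, 1.0]))
            keep = t.get_sequence_with("A", pairs, confidence=conf)
            drop = t.get_sequence_with("A", pairs, confidence=conf,
                                       invert=True)
            assert len(keep) + len(drop) == n
            assert set(keep.index).isdisjoint(drop.index)


# -- mutation bookkeeping ----------------------------------------------------

class TestIdentifyMutants:
    def test_single_substitution_token(self):
        t = DesignTable({"description": ["d"], "sequence_A": ["ACAA"]})
        t.add_reference_sequence("A", "AAAA")
        out = t.identify_mutants("A")
        assert out["mutant_count_A"].iloc[0] == 1
        assert out["mutants_A"].iloc[0] == "A2C"
        assert out["mutant_positions_A"].iloc[0] == "2"

    def test_identity_has_no_mutations(self):
        t = DesignTable({"description": ["d"], "sequence_A": ["AAAA"]})
        t.add_reference_sequence("A", "AAAA")
        out = t.identify_mutants("A")
        assert out["mutant_count_A"].iloc[0] == 0
        assert out["mutants_A"].iloc[0] == ""

    def test_shifted_numbering_yields_p46g(self):
        # proline at reference position 46 mutated to glycine
        ref = "MKPV"
        t = DesignTable({"description": ["d"], "sequence_A": ["MKGV"]})
        t.add_reference_sequence("A", ref, shift=44)
        out = t.identify_mutants("A")
        assert out["mutants_A"].iloc[0] == "P46G"

    def test_gap_counts_as_mutation(self):
        t = DesignTable({"description": ["d"], "sequence_A": ["A-AA"]})
        t.add_reference_sequence("A", "AAAA")
        assert t.identify_mutants("A")["mutant_count_A"].iloc[0] == 1

    def test_requires_reference(self, small_table):
        with pytest.raises(KeyError, match="add_reference_sequence"):
            small_table.identify_mutants("A")

    def test_count_is_hamming_distance(self, rng):
        letters = np.array(list("ACDEFG"))
        ref = "".join(rng.choice(letters, size=20))
        for _ in range(20):
            seq = "".join(rng.choice(letters, size=20))
            t = DesignTable({"description": ["d"], "sequence_A": [seq]})
            t.add_reference_sequence("A", ref)
            expected = sum(a != b for a, b in zip(ref, seq))
            assert t.identify_mutants("A")["mutant_count_A"].iloc[0] \
                == expected


class TestGenerateMutantVariants:
    def test_four_positions_two_options_gives_sixteen(self):
        template = "M" * 50
        t = DesignTable({"description": ["tmpl"], "sequence_A": [template]})
        t.add_reference_sequence("A", template)
        specs = [MutationSpec(p, ("M", o))
                 for p, o in zip((34, 35, 46, 47), "LEGK")]
        out = t.generate_mutant_variants("A", specs)
        assert len(out) == 16
        assert out["is_template"].sum() == 1
        assert template in set(out["sequence_A"])
        assert len(set(out["sequence_A"])) == 16

    def test_degenerate_single_option(self):
        t = DesignTable({"description": ["tmpl"], "sequence_A": ["AAAA"]})
        out = t.generate_mutant_variants("A", [MutationSpec(2, "A")])
        assert len(out) == 1
        assert out["sequence_A"].iloc[0] == "AAAA"

    def test_product_matches_exhaustive_enumeration(self):
        template = "AAAAAA"
        t = DesignTable({"description": ["tmpl"], "sequence_A": [template]})
        specs = [MutationSpec(2, "CD"), MutationSpec(5, "EFG")]
        out = t.generate_mutant_variants("A", specs)
        expected = set()
        for c1, c2 in itertools.product("CD", "EFG"):
            s = list(template)
            s[1], s[4] = c1, c2
            expected.add("".join(s))
        assert set(out["sequence_A"]) == expected
        assert len(out) == 6
        # variants differ from template only at the listed positions
        for seq in out["sequence_A"]:
            diffs = {i + 1 for i, (a, b) in enumerate(zip(template, seq))
                     if a != b}
            assert diffs <= {2, 5}

    def test_duplicate_positions_error(self, small_table):
        with pytest.raises(ValueError, match="duplicate"):
            generate_mutant_variants(small_table.iloc[0], "A",
                                     [MutationSpec(1, "A"),
                                      MutationSpec(1, "C")])

    def test_option_outside_alphabet_errors(self):
        with pytest.raises(ValueError, match="alphabet"):
            MutationSpec(1, "AZ")

    def test_identifiers_derive_from_template(self, small_table):
        out = generate_mutant_variants(small_table.iloc[0], "A",
                                       [MutationSpec(1, "AC")])
        assert all(d.startswith("d1_v") for d in out["description"])


class TestGenerateWtReversions:
    def _table(self, seq, ref="AAAAAA"):
        t = DesignTable({"description": ["d"], "sequence_A": [seq]})
        t.add_reference_sequence("A", ref)
        return t

    def test_two_mutations_give_four_sequences(self):
        out = self._table("ACADAA").generate_wt_reversions("A")
        assert len(out) == 4
        assert "ACADAA" in set(out["sequence_A"])  # unreverted
        assert "AAAAAA" in set(out["sequence_A"])  # fully reverted

    def test_identity_gives_single_sequence(self):
        out = self._table("AAAAAA").generate_wt_reversions("A")
        assert len(out) == 1

    def test_key_residue_restriction(self):
        # 3 mutations, selection covering exactly one of them -> 2 sequences;
        # oracle: exhaustive enumeration over the full 2^3 set
        t = self._table("CAADAF")
        full = t.generate_wt_reversions("A")
        assert len(full) == 8
        restricted = t.generate_wt_reversions("A", key_residues="4")
        expected = {s for s in full["sequence_A"]
                    if s[0] == "C" and s[5] == "F"}
        assert set(restricted["sequence_A"]) == expected
        assert len(restricted) == 2

    def test_requires_reference(self, small_table):
        with pytest.raises(KeyError):
            small_table.generate_wt_reversions("A")


class TestMakeResfile:
    def test_resfile_dialect(self, tmp_path):
        t = DesignTable({"description": ["d"],
                         "sequence_A": ["ACA" + "A" * 42 + "G" + "A" * 4]})
        ref = "AAA" + "A" * 42 + "P" + "A" * 4
        t.add_reference_sequence("A", ref)
        out = t.make_resfile("A", path_pattern=str(tmp_path / "{description}.resfile"))
        body = (tmp_path / "d.resfile").read_text()
        assert body == "NATAA\nstart\n2 A PIKAA C\n46 A PIKAA G\n"
        assert out["resfile_A"].iloc[0].endswith("d.resfile")

    def test_no_mutations_header_and_start_only(self, tmp_path):
        t = DesignTable({"description": ["d"], "sequence_A": ["AAAA"]})
        t.add_reference_sequence("A", "AAAA")
        t.make_resfile("A", path_pattern=str(tmp_path / "{description}.resfile"))
        assert (tmp_path / "d.resfile").read_text() == "NATAA\nstart\n"

    def test_custom_header(self, tmp_path):
        t = DesignTable({"description": ["d"], "sequence_A": ["CAAA"]})
        t.add_reference_sequence("A", "AAAA")
        t.make_resfile("A", header="ALLAA",
                       path_pattern=str(tmp_path / "{description}.resfile"))
        assert (tmp_path / "d.resfile").read_text().startswith("ALLAA\n")

    def test_unwritable_path_errors(self):
        t = DesignTable({"description": ["d"], "sequence_A": ["CAAA"]})
        t.add_reference_sequence("A", "AAAA")
        with pytest.raises(OSError):
            t.make_resfile("A", path_pattern="/proc/none/{description}.resfile")


# -- slicing & quantile filtering --------------------------------------------

class TestSliceRegion:
    def _table(self, length=60):
        seq = "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(length))
        t = DesignTable({"description": ["d"], "sequence_A": [seq]})
        t.add_reference_sequence("A", seq)
        return t

    def test_window_21_56(self):
        out = self._table().slice_region(21, 56)
        assert len(out.get_sequence("A")) == 36
        assert out.get_reference("A").shift == 21

    def test_identity_window(self):
        t = self._table()
        out = t.slice_region(1, 60)
        assert out.get_sequence("A") == t.get_sequence("A")

    def test_single_position(self):
        assert len(self._table().slice_region(5, 5).get_sequence("A")) == 1

    def test_idempotence_with_preserved_labels(self):
        t = self._table()
        once = t.slice_region(21, 56)
        twice = once.slice_region(21, 56)
        assert once.get_sequence("A") == twice.get_sequence("A")
        assert twice.get_reference("A").shift == 21

    def test_labels_preserved_in_mutation_numbering(self):
        t = self._table()
        sliced = t.slice_region(21, 56)
        seq = sliced.get_sequence("A")
        mutated = "G" + seq[1:] if seq[0] != "G" else "A" + seq[1:]
        t2 = DesignTable({"description": ["m"], "sequence_A": [mutated]})
        ref = sliced.get_reference("A")
        t2.add_reference_sequence("A", ref.sequence, shift=ref.shift)
        out = t2.identify_mutants("A")
        assert out["mutant_positions_A"].iloc[0] == "21"

    def test_out_of_range_reports_valid_span(self):
        with pytest.raises(IndexError, match="1-60"):
            self._table().slice_region(0, 61)


class TestFilterQuantile:
    def test_top_five_percent(self, rng):
        scores = rng.permutation(np.linspace(-400, -200, 100))
        t = DesignTable({"score": scores,
                         "description": [f"d{i}" for i in range(100)]})
        out = t.filter_quantile("score", 0.05)
        threshold = pd.Series(scores).quantile(0.05)
        assert 3 <= len(out) <= 5
        assert (out["score"] < threshold).all()

    def test_higher_is_better(self):
        t = DesignTable({"score": [1.0, 2.0, 3.0, 4.0],
                         "description": list("abcd")})
        out = t.filter_quantile("score", 0.3, lower_is_better=False)
        assert list(out["description"]) == ["d"]

    def test_all_equal_scores_select_nothing(self):
        t = DesignTable({"score": [1.0] * 5, "description": list("abcde")})
        assert len(t.filter_quantile("score", 0.05)) == 0

    def test_non_numeric_term_errors(self, small_table):
        with pytest.raises(TypeError):
            small_table.filter_quantile("description", 0.05)


# -- merging -----------------------------------------------------------------

class TestMergeExperiments:
    def test_shared_ids_union_of_columns(self):
        ids = [f"d{i}" for i in range(10)]
        a = DesignTable({"description": ids, "score": range(10)})
        b = DesignTable({"description": ids, "cav_vol": range(10)})
        out = merge_experiments([a, b])
        assert len(out) == 10
        assert {"score", "cav_vol"} <= set(out.columns)

    def test_disjoint_ids_empty_join(self):
        a = DesignTable({"description": ["a"], "score": [1]})
        b = DesignTable({"description": ["b"], "score": [2]})
        assert len(merge_experiments([a, b])) == 0

    def test_labelled_concatenation(self):
        labels = ["no_target", "static", "pack", "packmin"]
        tables = [DesignTable({"description": [f"{lab}_{i}" for i in range(5)],
                               "score": range(5)}) for lab in labels]
        out = merge_experiments(tables, labels=labels)
        assert len(out) == 20
        assert sorted(out["experiment"].unique()) == sorted(labels)

    def test_collision_suffixes_deterministic(self):
        ids = ["d1", "d2"]
        a = DesignTable({"description": ids, "score": [1, 2]})
        b = DesignTable({"description": ids, "score": [3, 4]})
        out = merge_experiments([a, b])
        assert "score" in out.columns and "score_2" in out.columns

    def test_missing_identifier_errors(self):
        with pytest.raises(KeyError):
            merge_experiments([DesignTable({"x": [1]})])


# -- casting & misc ----------------------------------------------------------

def test_cast_roundtrip_preserves_cells(small_table, tmp_path):
    plain = pd.DataFrame(small_table)
    path = tmp_path / "t.csv"
    plain.to_csv(path, index=False)
    back = DesignTable(pd.read_csv(path))
    pd.testing.assert_frame_equal(pd.DataFrame(back), plain)


def test_selection_range_grammar():
    sel = SelectionRange("43-64")
    assert sel.lo == 43 and sel.hi == 64 and len(sel) == 22
    sel = SelectionRange("1,3-5,9")
    assert sel.positions() == (1, 3, 4, 5, 9)
    assert SelectionRange("43–64").positions() == SelectionRange("43-64").positions()
    with pytest.raises(ValueError):
        SelectionRange("9-3")


def test_deduplicate_identifiers():
    t = DesignTable({"description": ["d", "d", "e"], "score": [1, 2, 3]})
    out = deduplicate_identifiers(t)
    assert list(out["description"]) == ["d", "d_r2", "e"]


def test_mutation_tokens_shift():
    assert mutation_tokens("AP", "AG", shift=45) == [(46, "P46G")]
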