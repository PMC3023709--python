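"""Hybrid-property featurization: translation, C/T/D, AAC, filtering.

The anchor is a 50-residue reference sequence whose hydrophobicity
translation and every C/T/D value were checked by hand; the brute-force
property test then confirms the vectorized path on random sequences.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protfun import (
    HYDROPHOBICITY,
    N_FEATURES,
    ProteinRecord,
    aac_features,
    composition_features,
    dedupe_vectors,
    distribution_features,
    distribution_landmarks,
    fallback_residue_annotation,
    feature_names,
    featurize,
    featurize_all,
    transition_counts,
    transition_features,
    translate_sequence,
)
from protfun.alphabets import DEFAULT_ALPHABETS, SECONDARY_STRUCTURE, SOLVENT_ACCESSIBILITY
from protfun.errors import DegenerateInputError, MissingAnnotationError
from protfun.io import CANONICAL_AA

from conftest import REF_SEQ, REF_TRANSLATION


class TestTranslation:
    def test_reference_sequence_translates_exactly(self, ref_record):
        assert translate_sequence(ref_record, HYDROPHOBICITY) == REF_TRANSLATION

    def test_single_group_sequence(self):
        rec = ProteinRecord(id="a", sequence="AAAA")
        assert translate_sequence(rec, HYDROPHOBICITY) == "NNNN"

    def test_direct_lookup(self):
        rec = ProteinRecord(id="a", sequence="RC")
        assert translate_sequence(rec, HYDROPHOBICITY) == "PH"

    def test_noncanonical_residues_dropped_from_translation(self):
        rec = ProteinRecord(id="a", sequence="RXC")
        assert translate_sequence(rec, HYDROPHOBICITY) == "PH"

    def test_annotation_backed_requires_annotation(self):
        rec = ProteinRecord(id="a", sequence="MSDK")
        with pytest.raises(MissingAnnotationError):
            translate_sequence(rec, SECONDARY_STRUCTURE)

    def test_annotation_backed_uses_labels(self):
        rec = ProteinRecord(id="a", sequence="MSXK",
                            residue_annotations={"secondary_structure": "HECC"})
        # the label aligned with the noncanonical X drops with it
        assert translate_sequence(rec, SECONDARY_STRUCTURE) == "HEC"


class TestComposition:
    def test_reference_counts_and_percents(self):
        t = REF_TRANSLATION
        assert (t.count("H"), t.count("N"), t.count("P")) == (10, 16, 24)
        np.testing.assert_allclose(
            composition_features(t, HYDROPHOBICITY), [20.0, 32.0, 48.0]
        )

    def test_single_group(self):
        np.testing.assert_allclose(
            composition_features("HHHH", HYDROPHOBICITY), [100.0, 0.0, 0.0]
        )

    def test_uniform_thirds(self):
        np.testing.assert_allclose(
            composition_features("HNP", HYDROPHOBICITY), [100 / 3] * 3
        )

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            composition_features("", HYDROPHOBICITY)


class TestTransition:
    def test_reference_transition_counts(self):
        counts, k = transition_counts(REF_TRANSLATION)
        assert k == 31
        assert counts[frozenset("HN")] == 8
        assert counts[frozenset("NP")] == 16
        assert counts[frozenset("HP")] == 7

    def test_reference_percentages(self):
        np.testing.assert_allclose(
            transition_features(REF_TRANSLATION, HYDROPHOBICITY),
            [100 * 8 / 31, 100 * 16 / 31, 100 * 7 / 31],
        )

    def test_no_transitions_all_zero(self):
        np.testing.assert_allclose(
            transition_features("HHHH", HYDROPHOBICITY), [0.0, 0.0, 0.0]
        )

    def test_two_transitions_same_pair(self):
        np.testing.assert_allclose(
            transition_features("HNH", HYDROPHOBICITY), [100.0, 0.0, 0.0]
        )


class TestDistribution:
    def test_reference_h_landmarks(self):
        assert distribution_landmarks(REF_TRANSLATION, "H") == (1, 10, 18, 37, 46)

    def test_reference_d_rows(self):
        d = distribution_features(REF_TRANSLATION, HYDROPHOBICITY)
        np.testing.assert_allclose(d[0:5], [2, 20, 36, 74, 92])    # H
        np.testing.assert_allclose(d[5:10], [4, 28, 54, 78, 98])   # N
        np.testing.assert_allclose(d[10:15], [6, 24, 44, 64, 100]) # P

    def test_ceiling_quantile_convention(self):
        # positions 1..4 of the only group: indices ceil(1), ceil(2), ceil(3), 4
        d = distribution_features("HHHH", HYDROPHOBICITY)
        np.testing.assert_allclose(d[0:5], [25, 25, 50, 75, 100])

    def test_absent_group_is_all_zero(self):
        d = distribution_features("HHHH", HYDROPHOBICITY)
        np.testing.assert_allclose(d[5:15], np.zeros(10))

    def test_tuples_non_decreasing(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = "".join(rng.choice(list("HNP"), size=rng.integers(1, 60)))
            d = distribution_features(s, HYDROPHOBICITY).reshape(3, 5)
            for row in d:
                assert all(a <= b for a, b in zip(row, row[1:]))


class TestAAC:
    def test_single_residue(self):
        v = aac_features(ProteinRecord(id="a", sequence="AAAA"))
        assert v[CANONICAL_AA.index("A")] == 100.0
        assert v.sum() == pytest.approx(100.0)

    def test_hand_count(self):
        v = aac_features(ProteinRecord(id="a", sequence="ACDE"))
        for aa in "ACDE":
            assert v[CANONICAL_AA.index(aa)] == 25.0

    def test_noncanonical_excluded_from_both_sides(self):
        v = aac_features(ProteinRecord(id="a", sequence="AXA"))
        assert v[CANONICAL_AA.index("A")] == 100.0

    def test_all_noncanonical_rejected(self):
        with pytest.raises(DegenerateInputError):
            aac_features(ProteinRecord(id="a", sequence="XXX"))


class TestFeaturize:
    def test_length_and_block_sizes(self, ref_record):
        names = feature_names()
        assert len(names) == N_FEATURES == 132
        blocks = ("hydrophobicity", "secondary_structure",
                  "solvent_accessibility", "vdw_volume", "polarity",
                  "polarizability", "aac")
        sizes = [sum(1 for n in names if n.split(".")[0] == b) for b in blocks]
        assert sizes == [21, 21, 7, 21, 21, 21, 20]

    def test_values_are_percent_bounded(self, ref_record):
        v = featurize(ref_record, allow_fallback=True)
        assert ((v >= 0) & (v <= 100)).all()

    def test_deterministic(self, ref_record):
        v1 = featurize(ref_record, allow_fallback=True)
        v2 = featurize(ref_record, allow_fallback=True)
        assert (v1 == v2).all()

    def test_c_blocks_sum_to_100(self, ref_record):
        v = featurize(ref_record, allow_fallback=True)
        for prop in ("hydrophobicity", "vdw_volume", "polarity", "polarizability"):
            c = v[[n for n in v.index if n.startswith(f"{prop}.C.")]]
            assert c.sum() == pytest.approx(100.0, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(alphabet=CANONICAL_AA, min_size=1, max_size=200))
    def test_matches_brute_force_oracle(self, seq):
        """Full vector equals an independent single-pass recomputation."""
        rec = ProteinRecord(id="x", sequence=seq)
        v = featurize(rec, allow_fallback=True)
        expected = []
        for alph in DEFAULT_ALPHABETS:
            g = translate_sequence(rec, alph, allow_fallback=True)
            L = len(g)
            groups = alph.groups
            C = [100 * g.count(x) / L for x in groups]
            diff = [(a, b) for a, b in zip(g, g[1:]) if a != b]
            K = len(diff)
            T = [100 * sum(1 for a, b in diff if {a, b} == set(p)) / K if K else 0.0
                 for p in alph.pairs]
            D = []
            for x in groups:
                pos = [i + 1 for i, ch in enumerate(g) if ch == x]
                if not pos:
                    D += [0.0] * 5
                else:
                    n = len(pos)
                    idx = [1, math.ceil(0.25 * n), math.ceil(0.5 * n),
                           math.ceil(0.75 * n), n]
                    D += [100 * pos[i - 1] / L for i in idx]
            if len(groups) == 2:
                expected += [C[0]] + T + D[:5]
            else:
                expected += C + T + D
        expected += [100 * seq.count(aa) / len(seq) for aa in CANONICAL_AA]
        np.testing.assert_allclose(v.to_numpy(), expected, atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.text(alphabet=CANONICAL_AA, min_size=5, max_size=80),
           st.randoms(use_true_random=False))
    def test_permutation_preserves_c_and_aac(self, seq, rnd):
        perm = list(seq)
        rnd.shuffle(perm)
        rec1 = ProteinRecord(id="a", sequence=seq)
        rec2 = ProteinRecord(id="b", sequence="".join(perm))
        v1 = featurize(rec1, allow_fallback=True)
        v2 = featurize(rec2, allow_fallback=True)
        keep = [n for n in v1.index
                if n.startswith(("hydrophobicity.C", "vdw_volume.C",
                                 "polarity.C", "polarizability.C", "aac."))]
        np.testing.assert_allclose(v1[keep], v2[keep], atol=1e-9)


class TestFallbacks:
    def test_shapes_and_alphabets(self):
        rec = ProteinRecord(id="a", sequence="AAAAAAAAA")
        ss = fallback_residue_annotation(rec, "secondary_structure", quiet=True)
        acc = fallback_residue_annotation(rec, "solvent_accessibility", quiet=True)
        assert len(ss) == len(acc) == 9
        assert set(ss) <= set("HEC") and set(acc) <= set("BX")

    def test_deterministic(self):
        rec = ProteinRecord(id="a", sequence="MSDKPDMAEIEK")
        for prop in ("secondary_structure", "solvent_accessibility"):
            a = fallback_residue_annotation(rec, prop, quiet=True)
            b = fallback_residue_annotation(rec, prop, quiet=True)
            assert a == b

    def test_poly_isoleucine_is_buried(self):
        # Kyte-Doolittle hydropathy of I is 4.5 > 0 in every window
        rec = ProteinRecord(id="a", sequence="IIIIIIIIIIII")
        acc = fallback_residue_annotation(rec, "solvent_accessibility", quiet=True)
        assert acc == "B" * 12


class TestDedupe:
    @staticmethod
    def _table(ids, vectors):
        import pandas as pd
        return pd.DataFrame(vectors, index=ids)

    def test_conflicting_functions_all_removed(self):
        t = self._table(["p1", "p2"], [[1.0, 2.0], [1.0, 2.0]])
        ann = {"p1": frozenset({1}), "p2": frozenset({2})}
        kept, removed = dedupe_vectors(t, ann)
        assert len(kept) == 0
        assert {pid for pid, _ in removed} == {"p1", "p2"}

    def test_identical_functions_keep_one(self):
        t = self._table(["p2", "p1"], [[1.0, 2.0], [1.0, 2.0]])
        ann = {"p1": frozenset({1, 7}), "p2": frozenset({1, 7})}
        kept, removed = dedupe_vectors(t, ann)
        assert list(kept.index) == ["p1"]  # lexicographically smallest id
        assert removed == [("p2", "duplicate of p1")]

    def test_distinct_vectors_untouched(self):
        t = self._table(["p1", "p2"], [[1.0, 2.0], [3.0, 4.0]])
        ann = {"p1": frozenset({1}), "p2": frozenset({2})}
        kept, removed = dedupe_vectors(t, ann)
        assert len(kept) == 2 and removed == []


def test_length_one_sequence_featurizes():
    """A single-residue protein yields D = 100 for its one occupied group."""
    rec = ProteinRecord(id="a", sequence="M")
    v = featurize(rec, allow_fallback=True)
    assert len(v) == 132
    np.testing.assert_allclose(
        v[[f"hydrophobicity.D.H.{lm}" for lm in
           ("first", "q25", "q50", "q75", "q100")]],
        [100.0] * 5,
    )


def test_featurize_all_stacks_rows(ref_record):
    other = ProteinRecord(id="o", sequence="ACDEFGHIKLMNPQRSTVWY")
    table = featurize_all([ref_record, other], allow_fallback=True)
    assert table.shape == (2, 132)
    assert list(table.index) == ["ref", "o"]
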