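import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycorbf import features
from glycorbf.features import (
    binary_fscore_from_counts,
    encode_blosum62,
    encode_saaps,
    fscore,
    positional_residue_fscores,
    property_fscore,
    read_aaindex,
    read_property_tsv,
)
from glycorbf.saap_discovery import SAAP
from glycorbf.sequence_io import AMINO_ACIDS, NEGATIVE, POSITIVE, TERMINAL, SiteFragment


def frag(window, label=POSITIVE, pid="P", pos=50):
    n = (len(window) - 1) // 2
    return SiteFragment(pid, pos, window[n], window, label)


class TestEncodeBlosum62:
    def test_deployed_window_length_609(self):
        window = "A" * 14 + "S" + "G" * 14
        assert encode_blosum62(window).shape == (29 * 21,)

    def test_identical_windows_identical_vectors(self):
        a = encode_blosum62("AST" + TERMINAL + "G")
        b = encode_blosum62("AST" + TERMINAL + "G")
        assert np.array_equal(a, b)

    def test_all_terminal_window_hits_only_21st_slots(self):
        v = encode_blosum62(TERMINAL * 5)
        assert v.sum() == 5
        assert np.array_equal(np.flatnonzero(v), 20 + 21 * np.arange(5))

    def test_amino_acid_rows_normalized_to_unit_interval(self):
        for aa in AMINO_ACIDS:
            v = encode_blosum62(aa)
            assert v[20] == 0.0
            assert v[:20].min() >= 0.0 and v[:20].max() <= 1.0
        # global min-max: some residue attains 0 and some attains 1
        stacked = np.array([encode_blosum62(aa)[:20] for aa in AMINO_ACIDS])
        assert stacked.min() == 0.0 and stacked.max() == 1.0

    def test_injective_on_windows(self):
        vectors = {encode_blosum62(aa).tobytes() for aa in AMINO_ACIDS + TERMINAL}
        assert len(vectors) == 21

    def test_symbol_outside_alphabet_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            encode_blosum62("AB")


class TestFScore:
    def test_two_point_worked_example(self):
        assert fscore([0, 2], [-1, 1]) == pytest.approx(0.125)

    def test_equal_multisets_zero(self):
        assert fscore([1.0, 2.0, 3.0], [3.0, 1.0, 2.0]) == 0.0

    def test_zero_variance_conventions(self):
        assert fscore([1, 1], [0, 0]) == math.inf
        assert fscore([1, 1], [1, 1]) == 0.0

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            fscore([1.0], [0.0, 1.0])

    @given(
        pos=st.lists(st.floats(-50, 50), min_size=2, max_size=12),
        neg=st.lists(st.floats(-50, 50), min_size=2, max_size=12),
        a=st.floats(0.1, 8),
        b=st.floats(-10, 10),
    )
    @settings(max_examples=80, deadline=None)
    def test_label_swap_and_affine_invariance(self, pos, neg, a, b):
        base = fscore(pos, neg)
        assert fscore(neg, pos) == pytest.approx(base, rel=1e-9, abs=1e-12)
        scaled = fscore([a * x + b for x in pos], [a * x + b for x in neg])
        if math.isfinite(base):
            assert scaled == pytest.approx(base, rel=1e-6, abs=1e-9)
        else:
            assert scaled == base

    def test_binary_count_form_matches_direct_evaluation(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n_pos, n_neg = rng.integers(2, 40, size=2)
            c_pos, c_neg = rng.integers(0, n_pos + 1), rng.integers(0, n_neg + 1)
            direct = fscore(
                [1.0] * c_pos + [0.0] * (n_pos - c_pos),
                [1.0] * c_neg + [0.0] * (n_neg - c_neg),
            )
            fast = binary_fscore_from_counts(int(c_pos), int(n_pos), int(c_neg), int(n_neg))
            if math.isfinite(direct):
                assert fast == pytest.approx(direct, abs=1e-12, rel=1e-12)
            else:
                assert fast == direct


class TestPositionalResidueFscores:
    def test_perfectly_separating_indicator_attains_maximum(self):
        pos = [frag("APSGA"), frag("CPSAC"), frag("DPSGD"), frag("EPSAE")]
        neg = [frag("AGSGA", NEGATIVE), frag("CASAC", NEGATIVE),
               frag("DWSGD", NEGATIVE), frag("EYSAE", NEGATIVE)]
        scores = positional_residue_fscores(pos + neg)
        top = max(scores.values(), key=lambda v: v.fscore)
        assert scores[(-1, "P")].fscore == top.fscore
        assert top.fscore == math.inf  # perfect separation, zero variance

    def test_absent_residue_scores_zero(self):
        pos = [frag("APSGA"), frag("CPSAC")]
        neg = [frag("AGSGA", NEGATIVE), frag("CASAC", NEGATIVE)]
        scores = positional_residue_fscores(pos + neg)
        assert scores[(-2, "W")].fscore == 0.0

    def test_center_position_excluded(self):
        pos = [frag("APSGA"), frag("CPSAC")]
        neg = [frag("AGTGA", NEGATIVE), frag("CATAC", NEGATIVE)]
        scores = positional_residue_fscores(pos + neg)
        assert all(p != 0 for p, _ in scores)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            positional_residue_fscores([frag("APSGA"), frag("CPSAC")])

    def test_permuted_labels_below_permutation_null(self):
        rng = np.random.default_rng(42)
        aas = list(AMINO_ACIDS)

        def random_frags(labels):
            return [
                frag("".join(rng.choice(aas, 4)) + "S" + "".join(rng.choice(aas, 4)),
                     label, pid=f"P{i}", pos=10)
                for i, label in enumerate(labels)
            ]

        labels = [POSITIVE] * 15 + [NEGATIVE] * 60
        base = random_frags(labels)

        def max_f(frags):
            return max(v.fscore for v in positional_residue_fscores(frags).values())

        import dataclasses
        null = []
        for _ in range(200):
            perm = list(labels)
            rng.shuffle(perm)
            null.append(max_f([dataclasses.replace(f, label=l)
                               for f, l in zip(base, perm)]))
        observed = list(labels)
        rng.shuffle(observed)
        obs = max_f([dataclasses.replace(f, label=l) for f, l in zip(base, observed)])
        assert obs <= np.quantile(null, 0.99)


class TestEncodeSaaps:
    saap = SAAP(3, "T", 9, ("E", "T"), 0.071)

    def window(self, at3, at9):
        chars = ["A"] * 29
        chars[14] = "S"
        chars[14 + 3] = at3
        chars[14 + 9] = at9
        return "".join(chars)

    def test_anchor_and_first_partner_match(self):
        assert encode_saaps(self.window("T", "E"), [self.saap]) == [1.0]

    def test_anchor_fails(self):
        assert encode_saaps(self.window("A", "E"), [self.saap]) == [0.0]

    def test_second_partner_member_matches(self):
        assert encode_saaps(self.window("T", "T"), [self.saap]) == [1.0]

    def test_output_is_binary_with_one_bit_per_pair(self):
        saaps = [self.saap, SAAP(-2, "A", 5, ("G",), 0.01)]
        bits = encode_saaps(self.window("T", "E"), saaps)
        assert bits.shape == (2,)
        assert set(bits) <= {0.0, 1.0}

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            encode_saaps("ASA", [self.saap])


class TestPropertyFscore:
    pos = [frag("APSGA"), frag("CPSAC"), frag("DPSGD")]
    neg = [frag("AGSGA", NEGATIVE), frag("CASAC", NEGATIVE), frag("DWSGD", NEGATIVE)]

    def test_constant_property_scores_zero_everywhere(self):
        table = {aa: 2.5 for aa in AMINO_ACIDS}
        scores = property_fscore(self.pos + self.neg, table)
        assert all(v == 0.0 for v in scores.values())

    def test_indicator_property_reproduces_residue_fscore(self):
        table = {aa: float(aa == "P") for aa in AMINO_ACIDS}
        scores = property_fscore(self.pos + self.neg, table)
        residue = positional_residue_fscores(self.pos + self.neg)
        assert scores[-1] == pytest.approx(residue[(-1, "P")].fscore)

    def test_affine_rescaling_leaves_fscores_unchanged(self):
        rng = np.random.default_rng(1)
        table = {aa: float(v) for aa, v in zip(AMINO_ACIDS, rng.normal(size=20))}
        base = property_fscore(self.pos + self.neg, table)
        shifted = {aa: 3.0 * v - 7.0 for aa, v in table.items()}
        # affine invariance holds per position when the terminal symbol (fixed
        # at 0 in both tables) does not appear, as here
        rescaled = property_fscore(self.pos + self.neg, shifted)
        for p in base:
            assert rescaled[p] == pytest.approx(base[p], rel=1e-9, abs=1e-12)

    def test_missing_amino_acid_rejected(self):
        table = {aa: 1.0 for aa in AMINO_ACIDS if aa != "W"}
        with pytest.raises(ValueError, match="W"):
            property_fscore(self.pos + self.neg, table)


def test_aaindex_flat_file_and_tsv_parsing(tmp_path):
    aaindex = tmp_path / "aaindex1"
    aaindex.write_text(
        "H FAKE010101\n"
        "D A synthetic test scale\n"
        "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n"
        "     1.0     2.0     3.0     4.0     5.0     6.0     7.0     8.0     9.0    10.0\n"
        "    11.0    12.0    13.0    14.0    15.0    16.0    17.0    18.0    19.0    20.0\n"
        "//\n"
    )
    tables = read_aaindex(aaindex)
    assert tables["FAKE010101"]["A"] == 1.0
    assert tables["FAKE010101"]["V"] == 20.0
    assert len(tables["FAKE010101"]) == 20

    tsv = tmp_path / "prop.tsv"
    tsv.write_text("".join(f"{aa}\t{i}\n" for i, aa in enumerate(AMINO_ACIDS)))
    table = read_property_tsv(tsv)
    assert table["A"] == 0.0 and len(table) == 20
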