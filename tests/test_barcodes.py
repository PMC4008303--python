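"""Barcode design, decoding and misassignment geometry.

Expected values for the decoder and the channel probability come from
brute-force oracles defined here (full enumeration of all 4^L words), kept
independent of the vectorized implementation they check.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sasiseq.barcodes import (
    Barcode,
    BarcodeSet,
    ChannelModel,
    DesignConstraints,
    DesignExhaustedError,
    count_misassigned_perturbations,
    decode_batch,
    decode_index,
    design_barcode_set,
    encode_seq,
    min_errors_to_misassign,
    misassignment_probability,
    read_barcode_set,
    validate_set,
    write_barcode_set,
)

BASES = "ACGT"


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def oracle_decode(word: str, codewords: list[str], max_correct: int = 1):
    """Brute-force nearest-codeword scan (N counts as mismatch to all)."""
    dists = [sum(1 for x, y in zip(word, c) if x != y or x not in BASES) for c in codewords]
    dmin = min(dists)
    within = [i for i, d in enumerate(dists) if d <= max_correct]
    if dmin == 0:
        return "perfect", dists.index(0)
    if len(within) == 1:
        return "corrected", within[0]
    if len(within) > 1:
        return "ambiguous", None
    return "unassigned", None


def oracle_misassignment(codewords: list[str], p: float, max_correct: int = 1) -> float:
    """Exhaustive channel sum over every length-L word (L small)."""
    L = len(codewords[0])
    total = 0.0
    for ci in codewords:
        for word in itertools.product(BASES, repeat=L):
            w = "".join(word)
            k = hamming(w, ci)
            prob = (p / 3) ** k * (1 - p) ** (L - k)
            near_other = any(
                hamming(w, cj) <= max_correct for cj in codewords if cj != ci
            )
            if near_other:
                total += prob
    return total / len(codewords)


class TestDesign:
    def test_perfect_three_base_repetition_geometry(self):
        s = design_barcode_set(3, 3, 4, DesignConstraints.none(), seed=1)
        report = validate_set(s)
        assert len(s) == 4
        assert report.min_distance == 3
        assert report.duplicate_pairs == 0

    def test_distance_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            design_barcode_set(1, 2, 2, DesignConstraints.none())

    def test_contradictory_gc_range_rejected(self):
        with pytest.raises(ValueError):
            DesignConstraints(gc_fraction_range=(0.8, 0.2))

    def test_exhaustion_reports_partial_set(self):
        # a (2,2) quaternary code holds at most 4 words; asking for 20 fails
        with pytest.raises(DesignExhaustedError) as exc:
            design_barcode_set(2, 2, 20, DesignConstraints.none(), seed=1)
        partial = exc.value.partial
        assert 1 <= len(partial) < 20
        assert validate_set(partial).min_distance >= 2

    def test_deterministic_per_seed(self):
        a = design_barcode_set(6, 3, 30, DesignConstraints.none(), seed=9)
        b = design_barcode_set(6, 3, 30, DesignConstraints.none(), seed=9)
        c = design_barcode_set(6, 3, 30, DesignConstraints.none(), seed=10)
        assert a.sequences == b.sequences
        assert a.sequences != c.sequences

    def test_constraints_respected(self):
        cons = DesignConstraints(gc_fraction_range=(0.4, 0.6), max_homopolymer_run=2)
        s = design_barcode_set(8, 3, 20, cons, seed=4)
        for bc in s:
            gc = sum(c in "GC" for c in bc.sequence) / 8
            assert 0.4 <= gc <= 0.6
            assert all(
                len(list(g)) <= 2 for _, g in itertools.groupby(bc.sequence)
            )
        assert not validate_set(s, cons).constraint_violations

    def test_forbidden_suffix_excluded(self):
        cons = DesignConstraints(gc_fraction_range=(0, 1), max_homopolymer_run=99,
                                 forbidden_suffixes=("T",))
        s = design_barcode_set(5, 2, 30, cons, seed=1)
        assert all(not bc.sequence.endswith("T") for bc in s)


class TestValidate:
    def test_duplicates_counted(self):
        s = BarcodeSet.from_sequences(["AAA", "AAA"])
        report = validate_set(s)
        assert report.duplicate_pairs == 1
        assert report.min_distance == 0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            BarcodeSet.from_sequences([])


@pytest.fixture(scope="module")
def tetra():
    return BarcodeSet.from_sequences(["AAA", "CCC", "GGG", "TTT"], 3)


class TestDecode:
    def test_perfect_corrected_unassigned(self, small_set):
        cw = small_set.barcodes[6]
        res0 = decode_index(cw.sequence, small_set)
        assert (res0.status, res0.barcode_id, res0.distance) == ("perfect", cw.id, 0)
        one_off = "G" + cw.sequence[1:] if cw.sequence[0] != "G" else "T" + cw.sequence[1:]
        res = decode_index(one_off, small_set)
        assert (res.status, res.barcode_id, res.distance) == ("corrected", cw.id, 1)
        # two substitutions against a d=5 set fall outside every radius-1 ball
        two = list(cw.sequence)
        two[0] = "G" if two[0] != "G" else "T"
        two[5] = "G" if two[5] != "G" else "T"
        res2 = decode_index("".join(two), small_set)
        assert res2.status == "unassigned"
        # confirmed by the brute-force oracle
        assert oracle_decode("".join(two), small_set.sequences)[0] == "unassigned"

    def test_n_counts_as_mismatch_everywhere(self, tetra):
        assert decode_index("NAA", tetra).status == "corrected"
        assert decode_index("NNA", tetra).status == "unassigned"

    def test_wrong_length_raises(self, tetra):
        with pytest.raises(ValueError):
            decode_index("AAAA", tetra)

    def test_batch_tolerates_wrong_length(self, tetra):
        status, bid, _ = decode_batch(["AAA", "AAAA"], tetra)
        assert bid[0] == 1 and status[1] == 2  # second unassigned

    def test_ambiguous_only_on_malformed_sets(self):
        bad = BarcodeSet.from_sequences(["AAA", "AAC"])
        assert decode_index("AAG", bad).status == "ambiguous"

    @settings(deadline=None, max_examples=40)
    @given(st.data())
    def test_decoder_matches_bruteforce_on_random_words(self, data):
        rng_words = st.text(alphabet="ACGT", min_size=5, max_size=5)
        codewords = data.draw(
            st.lists(rng_words, min_size=2, max_size=6, unique=True)
        )
        bset = BarcodeSet.from_sequences(codewords)
        word = data.draw(st.text(alphabet="ACGTN", min_size=5, max_size=5))
        got = decode_index(word, bset)
        want_status, want_idx = oracle_decode(word, codewords)
        assert got.status == want_status
        if want_idx is not None and want_status in ("perfect", "corrected"):
            assert got.barcode_id == want_idx + 1

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_ball_disjointness_no_ambiguity_for_d3_sets(self, seed):
        """Radius-1 balls of a d>=3 set are disjoint, so the decoder can
        never report ambiguity."""
        s = design_barcode_set(5, 3, 10, DesignConstraints.none(), seed=seed)
        assert validate_set(s).min_distance >= 3
        words = np.random.default_rng(seed).integers(0, 4, size=(300, 5)).astype(np.uint8)
        status, _, _ = decode_batch(words, s)
        assert not (status == 3).any()


class TestMisassignment:
    def test_min_errors_tetra_code(self):
        s = BarcodeSet.from_sequences(["AAA", "CCC", "GGG", "TTT"], 3)
        assert min_errors_to_misassign(s, 1) == 2
        # enumeration agrees: no 1-error word misassigns, some 2-error word does
        bad1, _ = count_misassigned_perturbations(s, 1, 1)
        bad2, _ = count_misassigned_perturbations(s, 2, 1)
        assert bad1 == 0 and bad2 > 0

    def test_single_codeword_undefined(self):
        with pytest.raises(ValueError):
            min_errors_to_misassign(BarcodeSet.from_sequences(["AAAA"]))

    def test_equals_min_distance_minus_correction_radius(self, small_set):
        assert (
            min_errors_to_misassign(small_set, 1)
            == validate_set(small_set).min_distance - 1
        )

    def test_two_codeword_closed_form(self):
        """P(land within 1 of the other codeword) for {AAA, CCC} at p:
        7(p/3)^3 + 3(1-p)(p/3)^2, cross-checked by exhaustive channel sum."""
        s = BarcodeSet.from_sequences(["AAA", "CCC"], 3)
        p = 0.01
        got = misassignment_probability(s, ChannelModel(p))
        closed = 7 * (p / 3) ** 3 + 3 * (1 - p) * (p / 3) ** 2
        assert got == pytest.approx(closed, rel=1e-12)
        assert got == pytest.approx(oracle_misassignment(["AAA", "CCC"], p), rel=1e-12)
        assert got == pytest.approx(3.33e-5, rel=0.01)

    def test_single_codeword_probability_zero(self):
        s = BarcodeSet.from_sequences(["ACGT"])
        assert misassignment_probability(s, ChannelModel(0.1)) == 0.0

    @pytest.mark.parametrize("seed", [11, 12])
    def test_matches_exhaustive_oracle_small_sets(self, seed):
        s = design_barcode_set(4, 3, 5, DesignConstraints.none(), seed=seed)
        p = 0.05
        got = misassignment_probability(s, ChannelModel(p))
        want = oracle_misassignment(s.sequences, p)
        assert got == pytest.approx(want, rel=1e-10)

    def test_monotone_in_error_rate(self, small_set):
        probs = [
            misassignment_probability(small_set, ChannelModel(p))
            for p in (0.0, 0.001, 0.01, 0.1)
        ]
        assert probs == sorted(probs)
        assert probs[0] == 0.0


def test_tsv_round_trip(tmp_path, small_set):
    path = tmp_path / "set.tsv"
    write_barcode_set(small_set, path)
    back = read_barcode_set(path)
    assert back.sequences == small_set.sequences
    assert back.ids == small_set.ids
    assert back.declared_min_distance == small_set.declared_min_distance


def test_barcode_validation():
    with pytest.raises(ValueError):
        Barcode(1, "ACGX")
    with pytest.raises(ValueError):
        Barcode(0, "ACGT")
    assert (encode_seq("ACGTN") == np.array([0, 1, 2, 3, 4], dtype=np.uint8)).all()
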