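"""Target scanner: pairing geometry, positional rules, duplex energies."""

import itertools

import numpy as np
import pytest

from budmir.config import ScanRules
from budmir.targets import (
    STACK_DG,
    check_positional_rules,
    duplex_mfe,
    evaluate_site,
    mismatch_vector,
    perfect_mfe,
    predict_targets,
    relative_mfe,
    _revcomp,
)

MIRNA21 = "TGACAGAAGAGAGTGAGCACA"


def _vec(length, mm_positions):
    v = [False] * length
    for p in mm_positions:
        v[p - 1] = True
    return v


def _pairing_oracle(mirna, site):
    """Independent antiparallel Watson-Crick pairing check."""
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    m = mirna.upper().replace("U", "T")
    s = site.upper().replace("U", "T")
    L = len(m)
    return [(m[i], s[L - 1 - i]) not in wc for i in range(L)]


class TestMismatchVector:
    def test_perfect_complement_all_match(self):
        site = _revcomp(MIRNA21)
        assert mismatch_vector(MIRNA21, site) == [False] * 21

    def test_single_substitution_maps_to_mirna_position(self):
        site = list(_revcomp(MIRNA21))
        # miRNA position 10 pairs with site index L-10 (0-based)
        j = 21 - 10
        site[j] = next(b for b in "ACGT"
                       if b != site[j] and b != {"A": "T", "T": "A",
                                                 "G": "C", "C": "G"}[MIRNA21[9]])
        vec = mismatch_vector(MIRNA21, "".join(site))
        assert vec == _vec(21, [10])

    def test_exhaustive_length3_agrees_with_pairing_oracle(self):
        for m in map("".join, itertools.product("ACGT", repeat=3)):
            for s in map("".join, itertools.product("ACGT", repeat=3)):
                assert mismatch_vector(m, s) == _pairing_oracle(m, s)

    def test_gu_wobble_flag_turns_wobble_into_match(self):
        # miRNA G against site T is a wobble pair
        vec_strict = mismatch_vector("G" * 12, "T" * 12)
        vec_wobble = mismatch_vector("G" * 12, "T" * 12, gu_wobble_is_match=True)
        assert vec_strict == [True] * 12
        assert vec_wobble == [False] * 12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mismatch_vector("ACGT", "ACG")


class TestPositionalRules:
    @pytest.mark.parametrize("mm_positions,expected", [
        ([], True),
        ([15], True),
        ([1], True),          # position 1 is unconstrained
        ([3], True),          # one mismatch in 2-9 allowed
        ([3, 7], False),      # two in 2-9
        ([10], False),        # central window
        ([11], False),
        ([13, 14, 15], False),  # three consecutive
        ([12, 14, 16, 18], True),   # four in 3' half, non-consecutive
        ([12, 14, 16, 18, 20], False),  # five in 3' half
        ([1, 2], True),       # run of two crossing position 1 is fine
    ])
    def test_rule_table(self, mm_positions, expected):
        assert check_positional_rules(_vec(21, mm_positions)) is expected

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError):
            check_positional_rules(_vec(11, []))

    def test_consecutive_run_can_cross_windows(self):
        # 9,10 is a run of two (allowed) but position 10 breaks the window
        assert check_positional_rules(_vec(21, [9, 10])) is False
        # 1,2,3 is a run of three crossing the unconstrained position 1
        assert check_positional_rules(_vec(21, [1, 2, 3])) is False


class TestDuplexEnergy:
    def test_perfect_complement_is_strictly_negative(self):
        e = duplex_mfe(MIRNA21, _revcomp(MIRNA21), [False] * 21)
        assert e < 0

    def test_all_mismatch_site_is_zero(self):
        vec = [True] * 21
        assert duplex_mfe(MIRNA21, "A" * 21, vec) == 0.0

    def test_stack_table_is_strand_symmetric(self):
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for dinuc, dg in STACK_DG.items():
            flipped = comp[dinuc[1]] + comp[dinuc[0]]
            assert STACK_DG[flipped] == dg

    def test_mismatches_never_strengthen_the_duplex(self):
        perfect = perfect_mfe(MIRNA21)
        site = _revcomp(MIRNA21)
        for positions in itertools.chain(
                itertools.combinations(range(1, 22), 1),
                itertools.combinations(range(1, 22), 2)):
            vec = _vec(21, positions)
            e = duplex_mfe(MIRNA21, site, vec)
            assert abs(e) <= abs(perfect) + 1e-12


class TestRelativeMfe:
    def test_boundaries(self):
        assert relative_mfe(-30.0, -30.0) == 1.0
        assert relative_mfe(0.0, -30.0) == 0.0
        assert relative_mfe(-21.0, -30.0) == pytest.approx(0.70)

    def test_boundary_site_passes_with_ge_semantics(self):
        assert relative_mfe(-21.0, -30.0) >= ScanRules().min_relative_mfe

    def test_nonnegative_perfect_rejected(self):
        with pytest.raises(ValueError):
            relative_mfe(-5.0, 0.0)


class TestPredictTargets:
    def test_planted_perfect_site_found_once(self):
        rng = np.random.default_rng(0)
        tx = "".join(rng.choice(list("ACGT"), size=200))
        tx = tx[:50] + _revcomp(MIRNA21) + tx[50 + 21:]
        sites = predict_targets({"vvi-miR156a": MIRNA21}, {"TX1": tx})
        exact = [s for s in sites if s.start == 51]
        assert len(exact) == 1
        assert exact[0].mm_count == 0
        assert exact[0].relative_mfe == pytest.approx(1.0)

    def test_empty_transcriptome_rejected(self):
        with pytest.raises(ValueError):
            predict_targets({"m": MIRNA21}, {})

    def test_wobble_flag_never_decreases_passing_sites(self):
        rng = np.random.default_rng(1)
        mirna = "".join(rng.choice(list("ACGT"), size=21))
        txs = {f"T{i}": "".join(rng.choice(list("ACGT"), size=300))
               for i in range(5)}
        # plant a few imperfect sites
        for i, tid in enumerate(txs):
            body = list(txs[tid])
            site = list(_revcomp(mirna))
            site[3] = "A" if site[3] != "A" else "C"
            body[40:40 + 21] = site
            txs[tid] = "".join(body)
        strict = predict_targets({"m": mirna}, txs, ScanRules())
        wobble = predict_targets({"m": mirna}, txs,
                                 ScanRules(gu_wobble_is_match=True))
        strict_keys = {(s.mirna_id, s.transcript_id, s.start) for s in strict}
        wobble_keys = {(s.mirna_id, s.transcript_id, s.start) for s in wobble}
        assert strict_keys <= wobble_keys

    def test_tightening_rules_never_adds_sites(self, synth_ref,
                                               synth_transcriptome):
        transcriptome, _ = synth_transcriptome
        mirnas = {k: v for k, v in list(synth_ref.items())[:6]}
        loose = predict_targets(mirnas, transcriptome,
                                ScanRules(max_mm_12_end=4))
        tight = predict_targets(mirnas, transcriptome,
                                ScanRules(max_mm_12_end=2))
        loose_keys = {(s.mirna_id, s.transcript_id, s.start) for s in loose}
        tight_keys = {(s.mirna_id, s.transcript_id, s.start) for s in tight}
        assert tight_keys <= loose_keys

    def test_output_sorted(self, synth_ref, synth_transcriptome):
        transcriptome, _ = synth_transcriptome
        sites = predict_targets(synth_ref, transcriptome)
        keys = [(s.mirna_id, s.transcript_id, s.start) for s in sites]
        assert keys == sorted(keys)
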