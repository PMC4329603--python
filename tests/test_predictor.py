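"""Cleavage-site relocation, transit score, and the four-class decision."""

import numpy as np
import pandas as pd
import pytest

from plastidfind import (
    AMINO_ACIDS,
    WINDOW_COLUMNS,
    PredictionClass,
    ScoringMatrix,
    SignalPResult,
    classify,
    predict_cleavage_site,
    transit_peptide_score,
    window_score,
)
from plastidfind.predictor import (
    predictions_to_tsv_lines,
    read_predictions,
    write_predictions,
)

from conftest import (
    oracle_relocate,
    oracle_window_score,
    random_matrix,
    random_sequence,
)


def toy_matrix(entries: dict[tuple[int, str], float]) -> ScoringMatrix:
    df = pd.DataFrame(
        0.0, index=list(AMINO_ACIDS), columns=list(WINDOW_COLUMNS)
    )
    for (col, aa), v in entries.items():
        df.at[aa, col] = v
    return ScoringMatrix(df)


class TestWindowScore:
    def test_all_x_window_scores_zero_and_complete(self):
        m = toy_matrix({(1, "F"): 2.0})
        seq = "X" * 40
        assert window_score(seq, 10, m) == (0.0, True)

    def test_single_matrix_entry(self):
        m = toy_matrix({(1, "F"): 2.0})
        seq = "A" * 9 + "F" + "A" * 30  # F at position 10
        score, complete = window_score(seq, 10, m)
        assert score == pytest.approx(2.0) and complete

    def test_truncated_upstream_window_is_incomplete(self):
        m = toy_matrix({(-1, "A"): 1.0, (-5, "A"): 1.0})
        seq = "A" * 30
        score, complete = window_score(seq, 2, m, columns=(-5, -4, -3, -2, -1))
        assert score == pytest.approx(1.0)  # only column -1 is addressable
        assert not complete

    def test_mature_start_below_two_rejected(self):
        m = toy_matrix({})
        with pytest.raises(ValueError):
            window_score("A" * 30, 1, m)

    def test_agrees_with_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            m = random_matrix(rng)
            seq = random_sequence(rng, int(rng.integers(10, 80)))
            ms = int(rng.integers(2, len(seq) + 5))
            got = window_score(seq, ms, m)
            want = oracle_window_score(seq, ms, m.values, WINDOW_COLUMNS)
            assert got[0] == pytest.approx(want[0], abs=1e-9)
            assert got[1] == want[1]


class TestCleavageSiteRelocation:
    def test_all_zero_matrix_ties_break_to_offset_zero(self):
        m = toy_matrix({})
        site, offset, scores = predict_cleavage_site("A" * 50, 20, m)
        assert (site, offset) == (20, 0)
        assert scores == (0.0,) * 5

    def test_single_f_two_positions_upstream_wins(self):
        m = toy_matrix({(1, "F"): 5.0})
        # SignalP says mature start 20; the only F sits at position 18
        seq = "A" * 17 + "F" + "A" * 32
        site, offset, scores = predict_cleavage_site(seq, 20, m)
        assert (site, offset) == (18, -2)
        assert max(scores) == pytest.approx(5.0)

    def test_canonical_motif_stays_at_signalp_site(self, trained_matrix, spec):
        from plastidfind.simulate import TRANSIT_COMPOSITION, _draw

        rng = np.random.default_rng(5)
        # signal peptide ending ...ASA | FAP + transit-like downstream
        seq = "M" + "L" * 12 + "ASA" + "FAP" + _draw(rng, TRANSIT_COMPOSITION, 40)
        site, offset, _ = predict_cleavage_site(seq, 17, trained_matrix)
        assert (site, offset) == (17, 0)

    def test_tie_breaking_prefers_smallest_then_upstream_offset(self):
        m = toy_matrix({(1, "F"): 5.0})
        # F at positions 19 and 21 -> offsets -1 and +1 tie; upstream wins the
        # |offset| tie only after magnitude: -1 beats +1
        seq = "A" * 18 + "F" + "A" + "F" + "A" * 29
        site, offset, _ = predict_cleavage_site(seq, 20, m)
        assert (site, offset) == (19, -1)

    def test_agrees_with_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            m = random_matrix(rng)
            seq = random_sequence(rng, int(rng.integers(30, 90)))
            ms = int(rng.integers(2, len(seq) - 5))
            got = predict_cleavage_site(seq, ms, m)
            want = oracle_relocate(seq, ms, m.values)
            assert got[0] == want[0] and got[1] == want[1]
            assert np.allclose(got[2], want[2], atol=1e-9)

    def test_core5_mode_scores_only_core_columns(self):
        m = toy_matrix({(10, "F"): 5.0, (1, "W"): 1.0})
        seq = "A" * 14 + "W" + "A" * 7 + "F" + "A" * 20  # W at 15, F at 23
        # full25: column +10 sees the F for offset 0 (pos 15+10-1=24)? no ->
        # construct directly: at offset -1 site=14 col +10 -> pos 23 = F
        site_full, off_full, _ = predict_cleavage_site(seq, 15, m, "full25")
        site_core, off_core, _ = predict_cleavage_site(seq, 15, m, "core5")
        assert off_full == -1  # pulled by the distant +10 column
        assert off_core == 0  # core window ignores column +10


class TestTransitScore:
    def test_excludes_cleavage_site_columns(self):
        m = toy_matrix({(-1, "A"): 4.0, (1, "F"): 3.0, (2, "A"): 1.0})
        seq = "A" * 19 + "FA" + "A" * 25  # mature start 20
        score, complete = transit_peptide_score(seq, 20, m)
        assert score == pytest.approx(4.0)  # 3 (F at +1) + 1 (A at +2); not -1
        assert complete

    def test_short_downstream_region_zero_filled(self):
        m = toy_matrix({(1, "F"): 3.0, (20, "A"): 2.0})
        seq = "A" * 19 + "F" + "A" * 11  # only 12 residues downstream
        score, complete = transit_peptide_score(seq, 20, m)
        assert score == pytest.approx(3.0)
        assert not complete


def _scenario(signalp_positive, plus1_in_set, offset_zero, score_above):
    """Build (sequence, signalp, matrix) realizing one decision-table branch."""
    site = 15
    target = site if offset_zero else site + 1
    seq = ["G"] * 60
    m = {(-5, "C"): 5.0}  # offset anchor, outside the transit window
    seq[(target - 5) - 1] = "C"
    seq[target - 1] = "F" if plus1_in_set else "A"
    m[(4, "H")] = 3.0 if score_above else 1.0
    seq[(target + 3) - 1] = "H"
    sp = (
        SignalPResult("s", True, site)
        if signalp_positive
        else SignalPResult("s", False)
    )
    return "".join(seq), sp, toy_matrix(m)


DECISION_TABLE = [
    (sp, p1, off0, hi)
    for sp in (True, False)
    for p1 in (True, False)
    for off0 in (True, False)
    for hi in (True, False)
]


@pytest.mark.parametrize("signalp_positive,plus1_in_set,offset_zero,score_above",
                         DECISION_TABLE)
def test_decision_table(signalp_positive, plus1_in_set, offset_zero, score_above):
    """All 16 branch combinations map to the mandated class."""
    seq, sp, m = _scenario(signalp_positive, plus1_in_set, offset_zero, score_above)
    record = classify(seq, sp, m)
    if not signalp_positive:
        expected = PredictionClass.NOT_PLASTID_SP_NEGATIVE
    elif not plus1_in_set:
        expected = PredictionClass.NOT_PLASTID_SP_POSITIVE
    elif offset_zero and score_above:
        expected = PredictionClass.PLASTID_HIGH
    else:
        expected = PredictionClass.PLASTID_LOW
    assert record.prediction is expected
    if signalp_positive:
        assert record.offset == (0 if offset_zero else 1)
        assert len(record.candidate_scores) == 5
        assert record.cleavage_score == max(record.candidate_scores)
    else:
        assert record.transit_score is None and record.offset is None


class TestClassifyDetails:
    def test_transit_score_exactly_two_is_low_confidence(self):
        seq, sp, _ = _scenario(True, True, True, True)
        m = toy_matrix({(-5, "C"): 5.0, (4, "H"): 2.0})
        record = classify(seq, sp, m)
        assert record.transit_score == pytest.approx(2.0)
        assert record.prediction is PredictionClass.PLASTID_LOW

    def test_transit_score_just_above_two_is_high_confidence(self):
        seq, sp, _ = _scenario(True, True, True, True)
        m = toy_matrix({(-5, "C"): 5.0, (4, "H"): 2.01})
        record = classify(seq, sp, m)
        assert record.prediction is PredictionClass.PLASTID_HIGH

    def test_monotonicity_in_transit_score(self):
        """Raising the transit score never demotes a plastid record."""
        seq, sp, _ = _scenario(True, True, True, True)
        ranks = []
        for weight in (0.0, 1.0, 2.0, 2.5, 4.0):
            m = toy_matrix({(-5, "C"): 5.0, (4, "H"): weight})
            record = classify(seq, sp, m)
            assert record.prediction in (
                PredictionClass.PLASTID_LOW, PredictionClass.PLASTID_HIGH
            )
            ranks.append(record.prediction is PredictionClass.PLASTID_HIGH)
        assert ranks == sorted(ranks)  # once high, stays high

    def test_translation_invariance(self, trained_matrix):
        rng = np.random.default_rng(3)
        seq = random_sequence(rng, 80, x_prob=0.0)
        base = classify(seq, SignalPResult("s", True, 20), trained_matrix)
        shifted = classify(
            "GG" + seq, SignalPResult("s", True, 22), trained_matrix
        )
        assert shifted.prediction is base.prediction
        assert shifted.asafind_mature_start == base.asafind_mature_start + 2
        assert shifted.offset == base.offset
        assert shifted.transit_score == pytest.approx(base.transit_score, abs=1e-9)

    def test_stop_character_truncates_with_warning(self, trained_matrix):
        seq = "M" + "L" * 15 + "ASAFAP" + "S" * 30 + "*" + "F" * 10
        with pytest.warns(UserWarning, match="stop character"):
            record = classify(seq, SignalPResult("s", True, 20), trained_matrix)
        assert record.prediction is not None

    def test_plus1_residue_taken_from_relocated_site(self):
        m = toy_matrix({(1, "F"): 5.0})
        seq = "A" * 17 + "F" + "A" * 40  # F at 18; SignalP site 20 has A
        record = classify(seq, SignalPResult("s", True, 20), m)
        assert record.plus1_residue == "F"
        assert record.offset == -2
        # relocated +1 is F but offset != 0 -> low confidence at best
        assert record.prediction in (
            PredictionClass.PLASTID_LOW, PredictionClass.PLASTID_HIGH
        )
        assert record.prediction is PredictionClass.PLASTID_LOW


class TestPredictionIO:
    def test_tsv_round_trip(self, benchmark, trained_matrix, tmp_path):
        from plastidfind import classify_all

        records, sps, _ = benchmark
        subset = records[:20] + records[-20:]
        ids = {sid for sid, _ in subset}
        preds = classify_all(subset, [r for r in sps if r.id in ids], trained_matrix)
        path = tmp_path / "pred.tsv"
        write_predictions(preds, path)
        again = read_predictions(path)
        assert len(again) == len(preds)
        for a, b in zip(preds, again):
            assert a.id == b.id and a.prediction is b.prediction
            assert a.offset == b.offset
            if a.transit_score is None:
                assert b.transit_score is None
            else:
                assert b.transit_score == pytest.approx(a.transit_score, abs=1e-6)

    def test_labels_serialized_verbatim(self):
        assert str(PredictionClass.PLASTID_HIGH) == "plastid, high confidence"
        assert str(PredictionClass.NOT_PLASTID_SP_NEGATIVE) == (
            "not plastid, SignalP negative"
        )
        lines = predictions_to_tsv_lines(
            [
                __import__("plastidfind").PredictionRecord(
                    id="x", prediction=PredictionClass.NOT_PLASTID_SP_POSITIVE
                )
            ]
        )
        assert lines[1].endswith("not plastid, SignalP positive")
        assert "\t.\t" in lines[1]  # absent values serialized as '.'
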