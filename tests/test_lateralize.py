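"""Consensus lateralization, concordance and the usefulness binomial test."""

from math import comb

import numpy as np
import pytest

from ictolat import (
    classify_concordance,
    patient_consensus,
    reproduce_table3,
    seizure_consensus,
    usefulness_binomial_test,
)
from ictolat.ictogenicity import NIResult
from ictolat.lateralize import (
    SeizurePrediction,
    load_patient_table,
    surgery_hemisphere_of,
)
from ictolat.rois import ROI_LABELS


def _ni(top_roi, value=0.9, others=0.1):
    ni = np.full(15, others)
    ni[ROI_LABELS.index(top_roi)] = value
    return NIResult(
        ni=ni, bni_pre=0.5, bni_post=0.5 * (1 - ni), k_star=1.0,
        n_realizations=1, roi_labels=ROI_LABELS,
    )


def _seizure(roi, n_segments=1):
    return SeizurePrediction(
        seizure_id="s", per_segment_top_roi=[roi] * n_segments, seizure_roi=roi
    )


class TestSeizureConsensus:
    def test_unanimous(self):
        pred = seizure_consensus([_ni("Insula right")] * 3)
        assert pred.seizure_roi == "Insula right"
        assert pred.n_segments == 3

    def test_mode(self):
        segs = [_ni("Insula left"), _ni("Insula left"), _ni("Supramarginal right")]
        assert seizure_consensus(segs).seizure_roi == "Insula left"

    def test_tie_broken_by_mean_ni(self):
        # A and B each top one segment; A has higher mean NI overall
        a = _ni("Insula left", value=0.8, others=0.05)
        b = _ni("Supramarginal right", value=0.6, others=0.05)
        assert seizure_consensus([a, b]).seizure_roi == "Insula left"

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            seizure_consensus([])


class TestPatientConsensus:
    def test_two_winning_rois_same_hemisphere(self):
        # two candidate regions tied, both right-hemisphere -> "right"
        seizures = [
            _seizure("Superior parietal right"),
            _seizure("Superior parietal right"),
            _seizure("Supramarginal right"),
            _seizure("Supramarginal right"),
        ]
        pred = patient_consensus(seizures)
        assert pred.predicted == "right"
        assert set(pred.winning_rois) == {
            "Superior parietal right", "Supramarginal right",
        }

    def test_split_across_hemispheres_inconclusive(self):
        # five seizures, five distinct ROIs in both hemispheres
        rois = [
            "Insula left", "Insula right", "Parahippocampal left",
            "Supramarginal right", "Superior temporal left",
        ]
        pred = patient_consensus([_seizure(r) for r in rois])
        assert pred.predicted == "inconclusive"

    def test_single_seizure_unanimous(self):
        pred = patient_consensus([_seizure("Parahippocampal left")])
        assert pred.predicted == "left"

    def test_midline_winner_alone_is_inconclusive(self):
        pred = patient_consensus([_seizure("Precuneus"), _seizure("Precuneus")])
        assert pred.predicted == "inconclusive"

    def test_midline_excluded_from_hemisphere_vote(self):
        pred = patient_consensus([_seizure("Precuneus"), _seizure("Insula left")])
        assert pred.predicted == "left"


class TestClassifyConcordance:
    @pytest.mark.parametrize(
        "pred, surgery, engel, expect_cls, expect_useful",
        [
            ("right", "right", "Ia", "C", True),   # agrees with working surgery
            ("left", "right", "Ia", "D", False),   # disagrees with working surgery
            ("inconclusive", "right", "IIa", "I", True),
            ("left", "left", "IIa", "C", False),   # agrees with failed surgery
            ("right", "left", "IIIa", "D", True),
            ("inconclusive", "none", "Ia", "I", True),
        ],
    )
    def test_cells(self, pred, surgery, engel, expect_cls, expect_useful):
        rec = classify_concordance(pred, surgery, engel)
        assert rec.classification == expect_cls
        assert rec.useful is expect_useful

    def test_unknown_engel_rejected(self):
        with pytest.raises(ValueError, match="Engel"):
            classify_concordance("left", "left", "IV")

    def test_surgery_hemisphere_parsing(self):
        assert surgery_hemisphere_of("temporal right") == "right"
        assert surgery_hemisphere_of("frontal left") == "left"
        assert surgery_hemisphere_of("none (no MRI)") == "none"


class TestBinomialTest:
    def test_matches_exact_tail(self):
        recs = [
            classify_concordance("left", "left", "Ia") for _ in range(12)
        ] + [classify_concordance("right", "left", "Ia") for _ in range(3)]
        p = usefulness_binomial_test(recs)
        assert p == pytest.approx(576 / 32768, abs=1e-12)

    def test_all_successes(self):
        recs = [classify_concordance("left", "left", "Ia") for _ in range(15)]
        assert usefulness_binomial_test(recs) == pytest.approx(2.0**-15)

    def test_zero_successes_gives_one(self):
        recs = [classify_concordance("right", "left", "Ia") for _ in range(8)]
        assert usefulness_binomial_test(recs) == pytest.approx(1.0)

    @pytest.mark.parametrize("n,k", [(5, 3), (10, 10), (12, 7), (15, 12)])
    def test_agrees_with_enumeration_oracle(self, n, k):
        """Brute force: P(X>=k) summed over all 2^n equally likely outcomes."""
        recs = [classify_concordance("left", "left", "Ia") for _ in range(k)] + [
            classify_concordance("right", "left", "Ia") for _ in range(n - k)
        ]
        tail = sum(
            1 for m in range(2**n) if bin(m).count("1") >= k
        ) / 2**n
        assert usefulness_binomial_test(recs) == pytest.approx(tail, abs=1e-12)
        assert tail == pytest.approx(
            sum(comb(n, j) for j in range(k, n + 1)) / 2**n
        )


class TestReproduceTable3:
    def test_counts_and_pvalue(self):
        summary = reproduce_table3()
        assert summary["good_outcome"] == {"C": 6, "D": 2, "I": 2}
        assert summary["bad_outcome"]["C"] == 1
        assert summary["bad_outcome"] == {"C": 1, "D": 2, "I": 2}
        assert summary["n_useful"] == 12
        assert summary["n_patients"] == 15
        assert summary["p_value"] == pytest.approx(576 / 32768, abs=1e-12)
        assert round(summary["p_value"], 2) == 0.02

    def test_recomputed_cdi_matches_printed_column(self):
        table = load_patient_table()
        summary = reproduce_table3(table)
        recomputed = {r.patient_id: r.classification for r in summary["records"]}
        for _, row in table.iterrows():
            assert recomputed[row["patient_id"]] == row["printed_cdi"]

    def test_counts_conserve(self):
        summary = reproduce_table3()
        for stratum in ("good_outcome", "bad_outcome"):
            counts = summary[stratum]
            assert counts["C"] + counts["D"] + counts["I"] in (5, 10)
        useful = sum(r.useful for r in summary["records"])
        not_useful = sum(not r.useful for r in summary["records"])
        assert useful + not_useful == summary["n_patients"]

    def test_malformed_row_names_patient(self):
        table = load_patient_table()
        table.loc[0, "engel"] = "V"
        with pytest.raises(ValueError, match="FR 115"):
            reproduce_table3(table)
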