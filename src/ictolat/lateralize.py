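"""Consensus lateralization, concordance bookkeeping and the usefulness test.

The node-ictogenicity stage yields one NI vector per 16-s segment. The
prediction is built hierarchically:

* **segment** — the ROI with maximal NI;
* **seizure** — the modal top-ROI across the seizure's segments (ties go to
  the ROI with the higher mean NI over the seizure, then to canonical
  order with a warning);
* **patient** — the most frequent seizure-level ROI; the prediction is the
  winning ROI's hemisphere. When the most frequent ROIs span both
  hemispheres, or only fused midline ROIs win (they carry no
  lateralization information), the prediction is *inconclusive*.

Each patient's prediction is compared with the hemisphere actually operated
on: concordant (C), discordant (D) or inconclusive (I). A prediction is
deemed *potentially useful* when it either agrees with a surgery that
worked (C with good Engel outcome), disagrees with or abstains on a surgery
that failed (D or I with bad outcome), or abstains on a good outcome (I —
no harm done). The only harmful cells are D-with-good-outcome and
C-with-bad-outcome. Whether the observed number of useful predictions
beats a coin-flip predictor is assessed with a one-sided exact binomial
test.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .ictogenicity import NIResult
from .rois import HEMISPHERE_OF_ROI, ROI_LABELS, hemisphere_of

GOOD_ENGEL = frozenset({"Ia", "Ib"})
BAD_ENGEL = frozenset({"IIa", "IIIa"})


@dataclass
class SeizurePrediction:
    """Per-seizure consensus over segment-level top-NI ROIs."""

    seizure_id: str
    per_segment_top_roi: list[str]
    seizure_roi: str

    @property
    def n_segments(self) -> int:
        return len(self.per_segment_top_roi)


@dataclass
class PatientPrediction:
    """Patient-level vote tally and the resulting lateralization."""

    patient_id: str
    votes: dict[str, int]
    predicted: str  # "left" | "right" | "inconclusive"
    winning_rois: list[str]


@dataclass
class ConcordanceRecord:
    """One patient's prediction vs the performed surgery."""

    patient_id: str
    outcome_class: str  # "good" | "bad"
    surgery_hemisphere: str  # "left" | "right" | "none"
    classification: str  # "C" | "D" | "I"
    useful: bool


def seizure_consensus(
    ni_per_segment: list[NIResult],
    roi_labels: tuple[str, ...] = ROI_LABELS,
    seizure_id: str = "",
) -> SeizurePrediction:
    """Reduce a seizure's segment NI vectors to a single candidate ROI."""
    if not ni_per_segment:
        raise ValueError("need at least one segment")
    tops = [roi_labels[r.top_roi()[0]] for r in ni_per_segment]
    counts = Counter(tops)
    top_count = max(counts.values())
    tied = sorted(
        (roi for roi, c in counts.items() if c == top_count),
        key=roi_labels.index,
    )
    if len(tied) == 1:
        winner = tied[0]
    else:
        mean_ni = {
            roi: float(
                np.mean([r.ni[roi_labels.index(roi)] for r in ni_per_segment])
            )
            for roi in tied
        }
        best = max(mean_ni.values())
        still_tied = [roi for roi in tied if best - mean_ni[roi] < 1e-12]
        if len(still_tied) > 1:
            warnings.warn(
                f"seizure {seizure_id or '?'}: mean-NI tie between "
                f"{still_tied}; keeping canonical order",
                stacklevel=2,
            )
        winner = still_tied[0]
    return SeizurePrediction(
        seizure_id=seizure_id, per_segment_top_roi=tops, seizure_roi=winner
    )


def patient_consensus(
    seizures: list[SeizurePrediction],
    hemisphere_of_roi: dict[str, str] = HEMISPHERE_OF_ROI,
    patient_id: str = "",
) -> PatientPrediction:
    """Vote across seizures and lateralize, or declare the case inconclusive."""
    if not seizures:
        raise ValueError("need at least one seizure")
    votes = Counter(s.seizure_roi for s in seizures)
    top = max(votes.values())
    winners = sorted(roi for roi, c in votes.items() if c == top)
    hemis = {
        hemisphere_of_roi[roi]
        for roi in winners
        if hemisphere_of_roi[roi] != "midline"
    }
    predicted = hemis.pop() if len(hemis) == 1 else "inconclusive"
    return PatientPrediction(
        patient_id=patient_id,
        votes=dict(votes),
        predicted=predicted,
        winning_rois=winners,
    )


def classify_concordance(
    predicted: PatientPrediction | str,
    surgery_hemisphere: str,
    outcome: str,
    patient_id: str = "",
) -> ConcordanceRecord:
    """Label a prediction C/D/I against the operated hemisphere.

    ``outcome`` is the Engel class (Ia/Ib good, IIa/IIIa bad). A surgery
    hemisphere of "none" (no post-surgical localization available) is
    classified I regardless of the prediction.
    """
    pred = predicted.predicted if isinstance(predicted, PatientPrediction) else predicted
    if isinstance(predicted, PatientPrediction) and not patient_id:
        patient_id = predicted.patient_id
    if outcome in GOOD_ENGEL:
        outcome_class = "good"
    elif outcome in BAD_ENGEL:
        outcome_class = "bad"
    else:
        raise ValueError(f"unknown Engel label: {outcome!r}")
    if surgery_hemisphere not in ("left", "right", "none"):
        raise ValueError(f"bad surgery hemisphere: {surgery_hemisphere!r}")
    if pred == "inconclusive" or surgery_hemisphere == "none":
        cls = "I"
    elif pred == surgery_hemisphere:
        cls = "C"
    elif pred in ("left", "right"):
        cls = "D"
    else:
        raise ValueError(f"bad prediction: {pred!r}")
    useful = not (
        (cls == "D" and outcome_class == "good")
        or (cls == "C" and outcome_class == "bad")
    )
    return ConcordanceRecord(
        patient_id=patient_id,
        outcome_class=outcome_class,
        surgery_hemisphere=surgery_hemisphere,
        classification=cls,
        useful=useful,
    )


def usefulness_binomial_test(
    records: list[ConcordanceRecord], p0: float = 0.5
) -> float:
    """One-sided exact binomial tail P(X >= k | n, p0), k = useful count."""
    if not records:
        raise ValueError("need at least one record")
    k = sum(r.useful for r in records)
    n = len(records)
    return float(binomtest(k, n, p0, alternative="greater").pvalue)


# --- study-metadata bookkeeping ----------------------------------------------


def surgery_hemisphere_of(localization: str) -> str:
    """Extract 'left'/'right' from a surgery-localization string, else 'none'."""
    loc = localization.lower()
    if "left" in loc:
        return "left"
    if "right" in loc:
        return "right"
    return "none"


def load_patient_table(path=None) -> pd.DataFrame:
    """Load the packaged study metadata table (or a user CSV like it).

    Columns: patient_id, gender, age, implantation, focus_ieeg,
    surgery_localization, engel, n_seizures, prediction, printed_cdi.
    """
    if path is None:
        with resources.files("ictolat.data").joinpath("table3.csv").open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def reproduce_table3(table: pd.DataFrame | None = None) -> dict:
    """Recompute the concordance bookkeeping from the patient table.

    For each of the 15 patients the C/D/I label is recomputed from the
    framework prediction versus the operated hemisphere, then stratified by
    outcome class; the summary also reports the number of potentially
    useful predictions and the binomial p-value against a coin-flip
    predictor.
    """
    if table is None:
        table = load_patient_table()
    required = {"patient_id", "engel", "surgery_localization", "prediction"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")

    records: list[ConcordanceRecord] = []
    for _, row in table.iterrows():
        try:
            rec = classify_concordance(
                str(row["prediction"]).strip(),
                surgery_hemisphere_of(str(row["surgery_localization"])),
                str(row["engel"]).strip(),
                patient_id=str(row["patient_id"]),
            )
        except ValueError as exc:
            raise ValueError(f"malformed row for {row['patient_id']!r}: {exc}") from exc
        records.append(rec)

    def _counts(cls_records):
        c = Counter(r.classification for r in cls_records)
        return {"C": c.get("C", 0), "D": c.get("D", 0), "I": c.get("I", 0)}

    good = [r for r in records if r.outcome_class == "good"]
    bad = [r for r in records if r.outcome_class == "bad"]
    return {
        "records": records,
        "good_outcome": _counts(good),
        "bad_outcome": _counts(bad),
        "n_patients": len(records),
        "n_useful": sum(r.useful for r in records),
        "p_value": usefulness_binomial_test(records),
    }


def lateralize_patient(
    ni_by_seizure: dict[str, list[NIResult]], patient_id: str = ""
) -> PatientPrediction:
    """Full consensus chain from per-segment NI vectors grouped by seizure."""
    seizures = [
        seizure_consensus(segs, seizure_id=sid)
        for sid, segs in ni_by_seizure.items()
    ]
    return patient_consensus(seizures, patient_id=patient_id)


__all__ = [
    "SeizurePrediction",
    "PatientPrediction",
    "ConcordanceRecord",
    "seizure_consensus",
    "patient_consensus",
    "classify_concordance",
    "usefulness_binomial_test",
    "surgery_hemisphere_of",
    "load_patient_table",
    "reproduce_table3",
    "lateralize_patient",
    "hemisphere_of",
]
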