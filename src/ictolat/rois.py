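"""Canonical region-of-interest (ROI) scheme used throughout the package.

The analysis works on 15 cortical ROIs drawn from the Desikan-Killiany atlas,
chosen to cover the default mode, salience and frontoparietal control
networks. Because 19-channel scalp EEG cannot resolve left from right close
to the brain's midline, five midline region pairs are fused into single
bilateral ROIs; the remaining ten ROIs come in left/right pairs and are the
only ones that can carry lateralization information.

The canonical order (top-to-bottom of the scheme, left before right) is fixed
here once and used for every 15-row matrix in the package.
"""

from __future__ import annotations

#: Canonical ROI labels, fixed order. Midline (fused) ROIs carry no hemisphere.
ROI_LABELS: tuple[str, ...] = (
    "Medial orbitofrontal",
    "Rostral anterior cingulate",
    "Rostral middle frontal",
    "Precuneus",
    "Parahippocampal left",
    "Parahippocampal right",
    "Supramarginal left",
    "Supramarginal right",
    "Superior temporal left",
    "Superior temporal right",
    "Caudal anterior cingulate",
    "Insula left",
    "Insula right",
    "Superior parietal left",
    "Superior parietal right",
)

N_ROIS = len(ROI_LABELS)

#: hemisphere per ROI: "left" | "right" | "midline"
HEMISPHERE_OF_ROI: dict[str, str] = {
    label: (
        "left"
        if label.endswith(" left")
        else "right" if label.endswith(" right") else "midline"
    )
    for label in ROI_LABELS
}

MIDLINE_ROIS: tuple[str, ...] = tuple(
    r for r in ROI_LABELS if HEMISPHERE_OF_ROI[r] == "midline"
)
LATERAL_ROIS: tuple[str, ...] = tuple(
    r for r in ROI_LABELS if HEMISPHERE_OF_ROI[r] != "midline"
)

ROI_INDEX: dict[str, int] = {label: i for i, label in enumerate(ROI_LABELS)}


def hemisphere_of(roi: str) -> str:
    """Return 'left', 'right' or 'midline' for a canonical ROI label."""
    try:
        return HEMISPHERE_OF_ROI[roi]
    except KeyError:
        raise KeyError(f"unknown ROI label: {roi!r}") from None
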