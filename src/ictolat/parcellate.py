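"""Collapse source time series into one representative series per ROI.

Smoothness-constrained inverse solutions make neighbouring sources highly
correlated, so each ROI is summarized by the first principal component of
its member sources' time series — the single series accounting for maximal
spatial variance within the region. The PC sign is mathematically
arbitrary, but a global flip shifts the instantaneous phase by pi and would
corrupt downstream cross-ROI phase differences; the sign is therefore fixed
so the component correlates non-negatively with the ROI-mean time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inverse import Leadfield
from .rois import HEMISPHERE_OF_ROI, ROI_LABELS


@dataclass
class ROITimeSeries:
    """15 x samples matrix of ROI component series in canonical order."""

    data: np.ndarray
    fs: float
    roi_labels: tuple[str, ...] = ROI_LABELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.roi_labels):
            raise ValueError("row count must match the ROI label count")

    @property
    def hemisphere_of_roi(self) -> tuple[str, ...]:
        return tuple(HEMISPHERE_OF_ROI[r] for r in self.roi_labels)


def _first_pc(x: np.ndarray) -> np.ndarray:
    """Leading principal-component time course of a sources x samples block.

    Rows are mean-centered; the component is the projection onto the
    leading eigenvector of the source-by-source covariance, sign-fixed
    against the ROI mean.
    """
    xc = x - x.mean(axis=1, keepdims=True)
    if xc.shape[0] == 1:
        comp = xc[0].copy()
    else:
        cov = (xc @ xc.T) / max(xc.shape[1] - 1, 1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        v = eigvecs[:, -1]  # eigenvector of the largest eigenvalue
        comp = v @ xc
    mean_ts = xc.mean(axis=0)
    if np.dot(comp, mean_ts) < 0:
        comp = -comp
    return comp


def parcellate_first_pc(
    src: np.ndarray, lf: Leadfield, fs: float = 256.0
) -> ROITimeSeries:
    """First-PC parcellation of a sources x samples matrix into 15 ROI rows."""
    src = np.asarray(src, dtype=float)
    if src.shape[0] != lf.n_sources:
        raise ValueError(
            f"source matrix has {src.shape[0]} rows, leadfield has "
            f"{lf.n_sources} sources"
        )
    rows = []
    for roi in ROI_LABELS:
        members = lf.sources_in_roi(roi)
        if members.size == 0:
            raise ValueError(f"ROI {roi!r} has no sources")
        rows.append(_first_pc(src[members]))
    return ROITimeSeries(data=np.vstack(rows), fs=fs)
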