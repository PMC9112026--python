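"""Periventricular distance bands.

Builds the cohort-consensus ventricle mask, assigns each supratentorial WM
voxel its Euclidean distance (mm) to the closest ventricle voxel, and labels
one-mm bands 1..30 by rounding distances to the nearest integer.  The band
adjacent to the ventricles is excluded from metric computation by default to
limit partial-volume contamination, and infratentorial regions never enter
the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "BandLabelMap",
    "build_consensus_ventricle_mask",
    "distance_to_ventricles",
    "label_bands",
    "round_half_away_from_zero",
]

log = logging.getLogger(__name__)


def round_half_away_from_zero(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (1.5 → 2, 2.5 → 3).

    Distances are non-negative here, but the convention is kept general.
    Chosen over banker's rounding so tie handling is uniform across bands.
    """
    x = np.asarray(x)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class BandLabelMap:
    """Integer band labels on the supratentorial WM.

    ``labels`` is 0 outside the analysis domain and b ∈ 1..n_bands where the
    rounded mm distance to the ventricles equals b.  Band 1 voxels stay in
    the map (for visualization) even when ``excluded_band_1`` is set; the
    metrics module honours the flag.
    """

    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    n_bands: int = 30
    excluded_band_1: bool = True

    @property
    def retained_bands(self) -> np.ndarray:
        """Band indices that enter metric computation, in increasing order."""
        present = np.unique(self.labels[self.labels > 0])
        if self.excluded_band_1:
            present = present[present != 1]
        return present


def build_consensus_ventricle_mask(
    ventricle_masks,
    infratentorial_mask: np.ndarray | None = None,
    threshold: float = 0.5,
) -> np.ndarray:
    """Average per-subject ventricle masks and threshold at p = 50%.

    A voxel belongs to the consensus mask iff its across-subject frequency is
    >= ``threshold`` (inclusive).  The infratentorial portion is removed
    afterwards (third/fourth ventricles sit too close to the outer brainstem
    for meaningful distance bands).
    """
    masks = [np.asarray(m, dtype=bool) for m in ventricle_masks]
    if not masks:
        raise ValueError("need at least one ventricle mask")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("ventricle masks must share one grid")

    freq = np.mean(np.stack(masks), axis=0)
    consensus = freq >= threshold
    if infratentorial_mask is not None:
        consensus &= ~np.asarray(infratentorial_mask, dtype=bool)
    if not consensus.any():
        raise ValueError("consensus ventricle mask empty")
    return consensus


def distance_to_ventricles(
    ventricle_mask: np.ndarray,
    voxel_size_mm,
) -> np.ndarray:
    """Centre-to-centre Euclidean distance (mm) to the nearest ventricle voxel.

    Returned for every grid voxel (callers mask to the supratentorial WM);
    ventricle voxels themselves get 0.  Anisotropic voxel sizes are honoured
    through the distance-transform sampling.
    """
    ventricle_mask = np.asarray(ventricle_mask, dtype=bool)
    if not ventricle_mask.any():
        raise ValueError("ventricle mask is empty")
    sampling = tuple(float(v) for v in np.broadcast_to(voxel_size_mm, (3,)))
    return ndimage.distance_transform_edt(~ventricle_mask, sampling=sampling)


def label_bands(
    distance_mm: np.ndarray,
    supratentorial_wm: np.ndarray,
    voxel_size_mm,
    n_bands: int = 30,
    exclude_band_1: bool = True,
    rounding: str = "half_away_from_zero",
) -> BandLabelMap:
    """Label one-mm distance bands 1..n_bands on the supratentorial WM.

    band(r) = round(d(r)); voxels rounding to 0 (inside/adjacent-half of the
    ventricle wall) or beyond ``n_bands`` are labelled 0.  ``rounding``
    selects the tie rule: "half_away_from_zero" (default; 1.5 mm → band 2)
    or "half_even" (banker's rounding).
    """
    supratentorial_wm = np.asarray(supratentorial_wm, dtype=bool)
    if rounding == "half_away_from_zero":
        band = round_half_away_from_zero(distance_mm)
    elif rounding == "half_even":
        band = np.rint(distance_mm)
    else:
        raise ValueError(f"unknown rounding mode: {rounding!r}")

    labels = band.astype(np.int32)
    labels[~supratentorial_wm] = 0
    labels[(labels < 1) | (labels > n_bands)] = 0

    counts = np.bincount(labels.ravel(), minlength=n_bands + 1)
    log.debug("band voxel counts: %s", counts[1:].tolist())
    return BandLabelMap(
        labels=labels,
        voxel_size_mm=tuple(float(v) for v in np.broadcast_to(voxel_size_mm, (3,))),
        n_bands=n_bands,
        excluded_band_1=exclude_band_1,
    )
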