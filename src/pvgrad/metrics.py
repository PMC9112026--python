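"""Per-band z-score metrics and band-pair gradients.

For each retained distance band b, compartment (NAWM or lesion) and z
threshold τ ∈ {0,1,2,3}, the table records

* ``mean_abs_z_above_tau`` — mean |z| over compartment voxels with |z| > τ;
* ``suprathreshold_volume_fraction`` — count of those voxels normalized by
  the band's total supratentorial-WM voxel count, so NAWM and lesion
  fractions of one band are comparable and sum to at most 1;
* ``suprathreshold_volume_mm3`` — the same count in mm³ (unnormalized);
* ``lesion_volume_in_band_mm3`` — total lesion volume in the band
  (τ-independent; the "lesion probability" profile);
* ``mean_z`` — signed mean z over all valid compartment voxels in the band
  (τ-independent; unbiased estimate of the injected abnormality profile).

Gradients between a band pair are the inner-band metric minus the
outer-band metric divided by the mm distance between the bands, so a
periventricular-dominant abnormality yields a positive gradient.

NAWM is the WM mask minus the lesion mask dilated by a 3×3×3 cube; the
dilation exists only to carve NAWM — lesion metrics use the undilated mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .bands import BandLabelMap

__all__ = [
    "GradientValue",
    "make_nawm_mask",
    "compute_band_metrics",
    "compute_gradient",
    "compute_gradients",
    "reported_to_bin",
    "DEFAULT_BAND_PAIRS",
    "DEFAULT_TAUS",
]

log = logging.getLogger(__name__)

DEFAULT_BAND_PAIRS = ((1, 2), (1, 5), (1, 10), (1, 20), (1, 30))
DEFAULT_TAUS = (0.0, 1.0, 2.0, 3.0)

_METRIC_COLUMNS = {
    "mean_abs_z": "mean_abs_z_above_tau",
    "volume_fraction": "suprathreshold_volume_fraction",
    "suprathreshold_volume_mm3": "suprathreshold_volume_mm3",
    "lesion_volume": "lesion_volume_in_band_mm3",
    "mean_z": "mean_z",
}


@dataclass
class GradientValue:
    """Metric difference between an inner and outer band per mm."""

    subject_id: str | None
    compartment: str
    metric: str
    band_inner: int
    band_outer: int
    bin_inner: int
    bin_outer: int
    tau: float
    value: float


def make_nawm_mask(wm_mask: np.ndarray, lesion_mask: np.ndarray) -> np.ndarray:
    """Normal-appearing WM: WM minus the cube-dilated (radius 1) lesion mask."""
    wm_mask = np.asarray(wm_mask, dtype=bool)
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if wm_mask.shape != lesion_mask.shape:
        raise ValueError(
            f"grid mismatch: WM {wm_mask.shape} vs lesions {lesion_mask.shape}"
        )
    if not lesion_mask.any():
        return wm_mask.copy()
    dilated = ndimage.binary_dilation(lesion_mask, structure=np.ones((3, 3, 3), bool))
    return wm_mask & ~dilated


def compute_band_metrics(
    zmap,
    bands: BandLabelMap,
    nawm_mask: np.ndarray,
    lesion_mask: np.ndarray | None = None,
    taus=DEFAULT_TAUS,
    subject_id: str | None = None,
    use_abs: bool = True,
) -> pd.DataFrame:
    """Long-format per-(band, compartment, τ) metric table for one subject.

    Band 1 is kept in the table with ``band_excluded=True`` when the label
    map flags it, so visualization and the literal band-pair mode can still
    reach it; analysis code filters on the flag.  ``use_abs=False`` switches
    the thresholded metrics to the signed convention (z > τ only), since
    tissue damage prolongs T1.
    """
    z = zmap.z
    valid = zmap.valid_mask
    labels = bands.labels
    if z.shape != labels.shape or z.shape != np.asarray(nawm_mask).shape:
        raise ValueError("z map, band labels and masks must share one grid")
    nawm_mask = np.asarray(nawm_mask, dtype=bool)
    if lesion_mask is None:
        lesion_mask = np.zeros_like(nawm_mask)
    lesion_mask = np.asarray(lesion_mask, dtype=bool)

    voxvol = float(np.prod(bands.voxel_size_mm))
    n_bands = bands.n_bands
    minlength = n_bands + 1

    band_total = np.bincount(labels.ravel(), minlength=minlength)[: minlength]
    zmag = np.abs(z) if use_abs else z

    rows = []
    for compartment, cmask in (("NAWM", nawm_mask), ("lesion", lesion_mask)):
        sel = cmask & valid & (labels > 0)
        lab_sel = labels[sel]
        z_sel = zmag[sel]
        zsigned_sel = z[sel]
        n_comp = np.bincount(lab_sel, minlength=minlength)
        sum_signed = np.bincount(lab_sel, weights=zsigned_sel, minlength=minlength)
        lesion_in_band = np.bincount(
            labels[lesion_mask & (labels > 0)].ravel(), minlength=minlength
        )
        for tau in taus:
            above = z_sel > tau
            n_above = np.bincount(lab_sel[above], minlength=minlength)
            sum_above = np.bincount(
                lab_sel[above], weights=np.abs(zsigned_sel[above]), minlength=minlength
            )
            for b in range(1, n_bands + 1):
                nb = int(band_total[b])
                na = int(n_above[b])
                rows.append(
                    {
                        "subject_id": subject_id,
                        "compartment": compartment,
                        "band": b,
                        "tau": float(tau),
                        "n_voxels_band": nb,
                        "n_voxels_compartment": int(n_comp[b]),
                        "n_voxels_above": na,
                        "mean_abs_z_above_tau": (sum_above[b] / na) if na else 0.0,
                        "suprathreshold_volume_fraction": (na / nb) if nb else np.nan,
                        "suprathreshold_volume_mm3": na * voxvol,
                        "lesion_volume_in_band_mm3": float(lesion_in_band[b]) * voxvol,
                        "mean_z": (sum_signed[b] / n_comp[b]) if n_comp[b] else np.nan,
                        "band_excluded": bool(bands.excluded_band_1 and b == 1),
                    }
                )
    return pd.DataFrame(rows)


def reported_to_bin(reported: int, bands: BandLabelMap, mode: str = "retained") -> int:
    """Map a reported band index to a mm bin.

    mode="retained": reported index k is the k-th retained band after band-1
    exclusion (reported 1 → 2 mm bin), capped at the outermost band since a
    bin beyond n_bands does not exist.  mode="literal": the mm bin as
    printed.
    """
    if mode == "literal" or not bands.excluded_band_1:
        return int(reported)
    if mode == "retained":
        return int(min(reported + 1, bands.n_bands))
    raise ValueError(f"unknown band index mode: {mode!r}")


def compute_gradient(
    metrics: pd.DataFrame,
    band_inner: int,
    band_outer: int,
    metric: str,
    tau: float,
    compartment: str,
    bands: BandLabelMap | None = None,
    band_index_mode: str = "retained",
) -> GradientValue:
    """Gradient of one metric between a reported band pair for one subject.

    ``metrics`` must be a single-subject table from
    :func:`compute_band_metrics`.  A missing band metric yields a NaN value
    (logged), never an exception, so cohort loops keep going.
    """
    if band_outer <= band_inner:
        raise ValueError("band_outer must exceed band_inner")
    column = _METRIC_COLUMNS[metric]
    if bands is not None:
        bin_inner = reported_to_bin(band_inner, bands, band_index_mode)
        bin_outer = reported_to_bin(band_outer, bands, band_index_mode)
    else:
        bin_inner, bin_outer = int(band_inner), int(band_outer)

    sub_ids = metrics["subject_id"].unique()
    subject_id = sub_ids[0] if len(sub_ids) == 1 else None

    def _lookup(b):
        sel = metrics[
            (metrics["compartment"] == compartment)
            & (metrics["band"] == b)
            & (metrics["tau"] == float(tau))
        ]
        if len(sel) != 1 or not np.isfinite(sel[column].iloc[0]):
            return np.nan
        return float(sel[column].iloc[0])

    m_in, m_out = _lookup(bin_inner), _lookup(bin_outer)
    if not (np.isfinite(m_in) and np.isfinite(m_out)):
        log.warning(
            "missing %s metric for bins %d-%d (%s, tau=%s); gradient is NaN",
            metric, bin_inner, bin_outer, compartment, tau,
        )
        value = np.nan
    else:
        value = (m_in - m_out) / float(bin_outer - bin_inner)
    return GradientValue(
        subject_id=subject_id,
        compartment=compartment,
        metric=metric,
        band_inner=int(band_inner),
        band_outer=int(band_outer),
        bin_inner=bin_inner,
        bin_outer=bin_outer,
        tau=float(tau),
        value=value,
    )


def compute_gradients(
    metrics: pd.DataFrame,
    bands: BandLabelMap,
    pairs=DEFAULT_BAND_PAIRS,
    metric_names=("mean_abs_z", "volume_fraction"),
    taus=DEFAULT_TAUS,
    compartments=("NAWM", "lesion"),
    band_index_mode: str = "retained",
) -> pd.DataFrame:
    """Gradient table over all (compartment, metric, pair, τ) combinations.

    ``metrics`` may contain several subjects; gradients are computed per
    subject.  Uses vectorized lookups (the scalar :func:`compute_gradient`
    is the reference path, exercised in tests for equivalence).
    """
    bin_map = {
        p: (
            reported_to_bin(p[0], bands, band_index_mode),
            reported_to_bin(p[1], bands, band_index_mode),
        )
        for p in pairs
    }
    rows = []
    for sid, sub in metrics.groupby("subject_id", dropna=False, sort=False):
        # pivot: (compartment, tau, band) -> metric columns
        idx = sub.set_index(["compartment", "tau", "band"])
        for compartment in compartments:
            for metric in metric_names:
                column = _METRIC_COLUMNS[metric]
                for tau in taus:
                    for (r_in, r_out) in pairs:
                        b_in, b_out = bin_map[(r_in, r_out)]
                        try:
                            m_in = idx.at[(compartment, float(tau), b_in), column]
                            m_out = idx.at[(compartment, float(tau), b_out), column]
                            value = (m_in - m_out) / float(b_out - b_in)
                        except KeyError:
                            value = np.nan
                        rows.append(
                            {
                                "subject_id": sid,
                                "compartment": compartment,
                                "metric": metric,
                                "pair": f"{r_in}-{r_out}",
                                "band_inner": r_in,
                                "band_outer": r_out,
                                "bin_inner": b_in,
                                "bin_outer": b_out,
                                "tau": float(tau),
                                "value": value,
                            }
                        )
    return pd.DataFrame(rows)
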