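"""Single-subject voxel-wise z-score maps.

z(r) = (T1(r) − E[T1](r)) / RMSE(r), where the expectation and RMSE come
from the normative atlas evaluated at the subject's age and sex.  Prolonged
T1 (demyelination, axonal loss, oedema) gives positive z.  Voxels outside
the atlas fit mask, or where the model RMSE is zero (degenerate constant
training data), are flagged missing rather than set to 0 or ±inf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["ZScoreMap", "compute_zscore_map"]

log = logging.getLogger(__name__)


@dataclass
class ZScoreMap:
    """Standardized T1 deviation map; ``z`` is NaN outside ``valid_mask``."""

    z: np.ndarray
    valid_mask: np.ndarray


def compute_zscore_map(t1_map: np.ndarray, atlas, age: float, sex) -> ZScoreMap:
    """Z-score one subject's T1 map against a fitted normative atlas."""
    t1_map = np.asarray(t1_map, dtype=np.float64)
    if t1_map.shape != atlas.fit_mask_.shape:
        raise ValueError(
            f"grid mismatch: T1 map has shape {t1_map.shape}, "
            f"atlas grid is {atlas.fit_mask_.shape}"
        )
    expected = atlas.predict(age, sex)
    valid = atlas.fit_mask_ & (atlas.rmse_ > 0)
    n_degenerate = int(atlas.fit_mask_.sum() - valid.sum())
    if n_degenerate:
        log.warning(
            "%d fit-mask voxels have zero model RMSE and are flagged missing",
            n_degenerate,
        )
    z = np.full(t1_map.shape, np.nan)
    z[valid] = (t1_map[valid] - expected[valid]) / atlas.rmse_[valid]
    return ZScoreMap(z=z, valid_mask=valid)
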