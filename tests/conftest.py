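"""Shared fixtures: phantom geometries and a fitted healthy atlas.

Session-scoped because geometry construction and cohort generation are the
expensive steps; everything downstream treats them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from pvgrad import (
    default_truth,
    distance_to_ventricles,
    fit_atlas,
    generate_cohort,
    label_bands,
    make_phantom_geometry,
)

#: cohort-scale grid: same anatomy in mm as the 96^3/1 mm standard phantom,
#: sampled at 2 mm to keep cohort simulations fast.
SMALL_SHAPE, SMALL_VOX = (48, 48, 48), (2.0, 2.0, 2.0)


@pytest.fixture(scope="session")
def standard_geometry():
    """The 96^3 / 1 mm phantom on which all 30 one-mm bands are realizable."""
    return make_phantom_geometry((96, 96, 96), (1.0, 1.0, 1.0), seed=7)


@pytest.fixture(scope="session")
def small_geometry():
    return make_phantom_geometry(SMALL_SHAPE, SMALL_VOX, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_geometry):
    return default_truth(small_geometry, seed=7)


@pytest.fixture(scope="session")
def small_distance(small_geometry):
    return distance_to_ventricles(
        small_geometry.ventricles, small_geometry.voxel_size_mm
    )


@pytest.fixture(scope="session")
def small_bands(small_geometry, small_distance):
    return label_bands(
        small_distance, small_geometry.supratentorial_wm, small_geometry.voxel_size_mm
    )


@pytest.fixture(scope="session")
def tiny_geometry():
    """Coarse 20^3 / 4 mm phantom for Monte-Carlo-heavy generator checks."""
    return make_phantom_geometry((20, 20, 20), (4.0, 4.0, 4.0), seed=7, n_bands=8)


@pytest.fixture(scope="session")
def hc_cohort(small_geometry, small_truth):
    """A healthy cohort matching the reference study's HC count (n=92)."""
    return generate_cohort(small_geometry, small_truth, n_hc=92, seed=11)


@pytest.fixture(scope="session")
def hc_atlas(small_geometry, hc_cohort):
    subjects = hc_cohort.subjects
    maps = [hc_cohort.t1_maps[sid] for sid in subjects["subject_id"]]
    return fit_atlas(maps, subjects, fit_mask=small_geometry.brain)


def assert_band_metrics_match_loop(table, z, labels, nawm, lesions, vx, taus):
    """Compare a metric table against a per-voxel python loop, all cells."""
    import pytest

    voxvol = float(np.prod(vx))
    n_bands = int(labels.max())
    for compartment, cmask in (("NAWM", nawm), ("lesion", lesions)):
        for b in range(1, n_bands + 1):
            for tau in taus:
                n_band = n_comp = n_above = n_lesion = 0
                s_above = 0.0
                for idx in np.ndindex(z.shape):
                    if labels[idx] != b:
                        continue
                    n_band += 1
                    if lesions[idx]:
                        n_lesion += 1
                    if not cmask[idx] or not np.isfinite(z[idx]):
                        continue
                    n_comp += 1
                    if abs(z[idx]) > tau:
                        n_above += 1
                        s_above += abs(z[idx])
                row = table[
                    (table.compartment == compartment)
                    & (table.band == b)
                    & (table.tau == tau)
                ].iloc[0]
                assert row.n_voxels_band == n_band
                assert row.n_voxels_compartment == n_comp
                assert row.n_voxels_above == n_above
                assert row.mean_abs_z_above_tau == pytest.approx(
                    s_above / n_above if n_above else 0.0
                )
                if n_band:
                    assert row.suprathreshold_volume_fraction == pytest.approx(
                        n_above / n_band
                    )
                else:
                    assert np.isnan(row.suprathreshold_volume_fraction)
                assert row.suprathreshold_volume_mm3 == pytest.approx(n_above * voxvol)
                assert row.lesion_volume_in_band_mm3 == pytest.approx(n_lesion * voxvol)


def brute_force_distance(ventricle_mask: np.ndarray, voxel_size_mm) -> np.ndarray:
    """All-pairs minimum Euclidean distance oracle (test-side reference)."""
    vx = np.asarray(voxel_size_mm, dtype=float)
    vent_idx = np.argwhere(ventricle_mask) * vx
    out = np.empty(ventricle_mask.shape)
    for idx in np.ndindex(ventricle_mask.shape):
        diff = vent_idx - np.asarray(idx) * vx
        out[idx] = np.sqrt((diff**2).sum(axis=1).min())
    return out
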