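"""NAWM morphology, per-band suprathreshold metrics, band-pair gradients."""

import numpy as np
import pandas as pd
import pytest

from pvgrad import compute_band_metrics, compute_gradient, compute_gradients, make_nawm_mask
from pvgrad.bands import BandLabelMap
from pvgrad.metrics import reported_to_bin
from pvgrad.zscore import ZScoreMap


def band_map(labels, vx=(1.0, 1.0, 1.0), n_bands=None, excluded=True):
    labels = np.asarray(labels, dtype=np.int32)
    return BandLabelMap(
        labels=labels,
        voxel_size_mm=vx,
        n_bands=n_bands or max(int(labels.max()), 1),
        excluded_band_1=excluded,
    )


def zmap_of(z):
    z = np.asarray(z, dtype=float)
    return ZScoreMap(z=z, valid_mask=np.isfinite(z))


class TestNawm:
    def test_empty_lesions_give_full_wm(self):
        wm = np.random.default_rng(0).random((6, 6, 6)) < 0.5
        np.testing.assert_array_equal(make_nawm_mask(wm, np.zeros_like(wm)), wm)

    def test_single_lesion_voxel_removes_27_cube(self):
        wm = np.ones((7, 7, 7), bool)
        lesion = np.zeros_like(wm)
        lesion[3, 3, 3] = True
        nawm = make_nawm_mask(wm, lesion)
        # independent neighborhood enumeration
        removed = {
            (3 + di, 3 + dj, 3 + dk)
            for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
        }
        for idx in np.ndindex(7, 7, 7):
            assert nawm[idx] == (idx not in removed)

    def test_lesions_covering_wm_leave_empty_nawm(self):
        wm = np.ones((4, 4, 4), bool)
        nawm = make_nawm_mask(wm, wm)
        assert not nawm.any()
        # downstream metrics are flagged missing, not an error
        labels = np.ones((4, 4, 4), np.int32) * 2
        table = compute_band_metrics(
            zmap_of(np.ones((4, 4, 4))), band_map(labels), nawm, wm, taus=(0,)
        )
        nawm_row = table[(table.compartment == "NAWM") & (table.band == 2)].iloc[0]
        assert nawm_row.n_voxels_compartment == 0
        assert np.isnan(nawm_row.mean_z)
        assert nawm_row.mean_abs_z_above_tau == 0.0


class TestBandMetrics:
    def test_uniform_band(self):
        """All |z| = 3 at tau=2: mean 3.0, fraction 1.0."""
        z = np.full((3, 3, 3), 3.0)
        labels = np.full((3, 3, 3), 5, np.int32)
        table = compute_band_metrics(
            zmap_of(z), band_map(labels), np.ones((3, 3, 3), bool), taus=(2,)
        )
        row = table[(table.compartment == "NAWM") & (table.band == 5)].iloc[0]
        assert row.mean_abs_z_above_tau == pytest.approx(3.0)
        assert row.suprathreshold_volume_fraction == pytest.approx(1.0)

    def test_mixed_band_arithmetic(self):
        """10 voxels: 5 at |z|=2.5, 5 at 0.5; tau=2 -> n=5, mean 2.5, frac 0.5."""
        z = np.zeros((10, 1, 1))
        z[:5] = 2.5
        z[5:] = 0.5
        labels = np.full((10, 1, 1), 4, np.int32)
        table = compute_band_metrics(
            zmap_of(z), band_map(labels), np.ones((10, 1, 1), bool), taus=(2,)
        )
        row = table[(table.compartment == "NAWM") & (table.band == 4)].iloc[0]
        assert row.n_voxels_above == 5
        assert row.mean_abs_z_above_tau == pytest.approx(2.5)
        assert row.suprathreshold_volume_fraction == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_loop_oracle(self, seed):
        """Vectorized table equals a per-voxel python loop on random 8^3 data."""
        rng = np.random.default_rng(seed)
        shape = (8, 8, 8)
        z = rng.standard_normal(shape) * 2
        z[rng.random(shape) < 0.1] = np.nan
        labels = rng.integers(0, 6, shape).astype(np.int32)
        nawm = rng.random(shape) < 0.6
        lesions = rng.random(shape) < 0.15
        vx = (1.0, 1.5, 2.0)
        taus = (0.0, 1.0, 2.0, 3.0)
        bm = band_map(labels, vx=vx, n_bands=5)
        table = compute_band_metrics(zmap_of(z), bm, nawm, lesions, taus=taus)

        voxvol = 1.0 * 1.5 * 2.0
        for compartment, cmask in (("NAWM", nawm), ("lesion", lesions)):
            for b in range(1, 6):
                for tau in taus:
                    n_band = n_comp = n_above = n_lesion = 0
                    s_above = s_signed = 0.0
                    for idx in np.ndindex(shape):
                        if labels[idx] != b:
                            continue
                        n_band += 1
                        if lesions[idx]:
                            n_lesion += 1
                        if not cmask[idx] or not np.isfinite(z[idx]):
                            continue
                        n_comp += 1
                        s_signed += z[idx]
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
                    assert row.lesion_volume_in_band_mm3 == pytest.approx(
                        n_lesion * voxvol
                    )
                    if n_comp:
                        assert row.mean_z == pytest.approx(s_signed / n_comp)

    def test_tau_monotonicity_and_fraction_bounds(self):
        rng = np.random.default_rng(9)
        shape = (8, 8, 8)
        z = rng.standard_normal(shape) * 2
        labels = rng.integers(0, 6, shape).astype(np.int32)
        table = compute_band_metrics(
            zmap_of(z), band_map(labels, n_bands=5),
            rng.random(shape) < 0.7, rng.random(shape) < 0.2,
        )
        frac = table["suprathreshold_volume_fraction"]
        assert ((frac >= 0) & (frac <= 1) | frac.isna()).all()
        for _, grp in table.groupby(["compartment", "band"]):
            ordered = grp.sort_values("tau")["n_voxels_above"].to_numpy()
            assert (np.diff(ordered) <= 0).all()
        above = table[table.n_voxels_above > 0]
        assert (above.mean_abs_z_above_tau >= above.tau).all()


class TestGradients:
    def _metric_table(self, values_by_band, tau=2.0, compartment="NAWM"):
        rows = []
        for b, v in values_by_band.items():
            rows.append(
                {
                    "subject_id": "p0",
                    "compartment": compartment,
                    "band": b,
                    "tau": tau,
                    "mean_abs_z_above_tau": v,
                    "suprathreshold_volume_fraction": v / 10.0,
                    "suprathreshold_volume_mm3": v,
                    "lesion_volume_in_band_mm3": v,
                    "mean_z": v,
                    "band_excluded": b == 1,
                }
            )
        return pd.DataFrame(rows)

    def test_gradient_arithmetic(self):
        table = self._metric_table({2: 2.0, 10: 1.0})
        g = compute_gradient(
            table, 2, 10, "mean_abs_z", 2.0, "NAWM", band_index_mode="literal"
        )
        assert g.value == pytest.approx((2.0 - 1.0) / 8.0)

    def test_constant_metric_gives_zero_gradient(self):
        table = self._metric_table({b: 1.7 for b in range(1, 31)})
        for outer in (2, 5, 10, 20, 30):
            g = compute_gradient(table, 1, outer, "mean_abs_z", 2.0, "NAWM",
                                 band_index_mode="literal")
            assert g.value == pytest.approx(0.0)

    def test_missing_band_gives_nan(self):
        table = self._metric_table({2: 2.0})
        g = compute_gradient(table, 2, 10, "mean_abs_z", 2.0, "NAWM",
                             band_index_mode="literal")
        assert np.isnan(g.value)

    def test_reported_to_bin_mapping(self):
        bm = band_map(np.full((2, 2, 2), 30, np.int32), n_bands=30, excluded=True)
        assert reported_to_bin(1, bm, "retained") == 2
        assert reported_to_bin(20, bm, "retained") == 21
        assert reported_to_bin(30, bm, "retained") == 30  # capped at outermost
        assert reported_to_bin(1, bm, "literal") == 1
        bm_keep = band_map(np.full((2, 2, 2), 30, np.int32), n_bands=30, excluded=False)
        assert reported_to_bin(1, bm_keep, "retained") == 1

    def test_vectorized_equals_scalar_path(self):
        rng = np.random.default_rng(3)
        table = pd.concat(
            [
                self._metric_table(
                    {b: rng.random() * 3 for b in range(1, 31)}, tau=t, compartment=c
                )
                for t in (0.0, 2.0)
                for c in ("NAWM", "lesion")
            ],
            ignore_index=True,
        )
        bm = band_map(np.full((2, 2, 2), 30, np.int32), n_bands=30)
        grads = compute_gradients(
            table, bm, pairs=((1, 2), (1, 10)), metric_names=("mean_abs_z",),
            taus=(0.0, 2.0),
        )
        for _, row in grads.iterrows():
            ref = compute_gradient(
                table, row.band_inner, row.band_outer, row.metric, row.tau,
                row.compartment, bands=bm,
            )
            assert row.value == pytest.approx(ref.value, rel=1e-12)

    def test_gradient_scales_linearly_with_z(self):
        rng = np.random.default_rng(4)
        shape = (8, 8, 8)
        z = rng.standard_normal(shape)
        labels = rng.integers(1, 6, shape).astype(np.int32)
        nawm = np.ones(shape, bool)
        bm = band_map(labels, n_bands=5, excluded=False)
        c = 3.0
        g1 = compute_gradients(
            compute_band_metrics(zmap_of(z), bm, nawm, taus=(0.0,)),
            bm, pairs=((1, 4),), metric_names=("mean_z",), taus=(0.0,),
            compartments=("NAWM",),
        )
        g2 = compute_gradients(
            compute_band_metrics(zmap_of(c * z), bm, nawm, taus=(0.0,)),
            bm, pairs=((1, 4),), metric_names=("mean_z",), taus=(0.0,),
            compartments=("NAWM",),
        )
        assert g2.value.iloc[0] == pytest.approx(c * g1.value.iloc[0], rel=1e-10)
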