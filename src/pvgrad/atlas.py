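"""Voxel-wise normative T1 atlas.

Per voxel r inside the fit mask, the healthy reference is an ordinary
least-squares fit of T1 on an intercept, sex (male = 1, female = 0), age
centred at the healthy-cohort mean, and centred age squared:

    E[T1](r) = beta0(r) + beta_sex(r)*sex + beta_age(r)*age_c + beta_age2(r)*age_c**2

with the per-voxel residual RMSE stored alongside the coefficients.  The
atlas is the fitted healthy reference against which single-subject z-score
maps are computed.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import read_volume, write_volume

__all__ = [
    "NormativeT1Atlas",
    "fit_atlas",
    "predict_t1",
    "save_atlas",
    "load_atlas",
    "encode_sex",
]

_FORMAT_VERSION = 1
_COEF_NAMES = ("beta0", "beta_sex", "beta_age", "beta_age2", "rmse")


def encode_sex(sex) -> float:
    """Map a sex label to the model coding: male = 1, female = 0."""
    if isinstance(sex, str):
        s = sex.strip().lower()
        if s in ("male", "m", "1"):
            return 1.0
        if s in ("female", "f", "0"):
            return 0.0
        raise ValueError(f"unrecognized sex value: {sex!r}")
    v = float(sex)
    if v not in (0.0, 1.0):
        raise ValueError(f"sex must be male/female or 0/1, got {sex!r}")
    return v


class NormativeT1Atlas(BaseEstimator):
    """Voxel-wise OLS normative model of healthy T1.

    Parameters
    ----------
    age_center : float or None
        Centering constant (years) for the age covariate.  None (default)
        uses the mean age of the fitting cohort; the constant used is stored
        in ``age_center_`` and always reapplied at prediction time.
    rmse_dof : {"residual", "n"}
        Denominator of the residual variance: residual degrees of freedom
        n − 4 (default, unbiased) or n.

    Attributes
    ----------
    beta0_, beta_sex_, beta_age_, beta_age2_ : ndarray
        Coefficient maps (ms; ms/year, ms/year² for the age terms), NaN
        outside ``fit_mask_``.
    rmse_ : ndarray
        Per-voxel residual RMSE (ms), NaN outside ``fit_mask_``.
    age_center_ : float
    n_subjects_ : int
    fit_mask_ : ndarray of bool
    """

    def __init__(self, age_center: float | None = None, rmse_dof: str = "residual"):
        self.age_center = age_center
        self.rmse_dof = rmse_dof

    # ------------------------------------------------------------------ fit
    def fit(self, t1_maps, subjects, fit_mask: np.ndarray | None = None):
        """Fit the per-voxel model on a healthy cohort.

        Parameters
        ----------
        t1_maps : sequence of 3D arrays or array of shape (n, \\*grid)
            One T1 map (ms) per subject, all on one grid.
        subjects : DataFrame or sequence of mappings
            Must provide ``age`` (years) and ``sex`` per subject, in the same
            order as ``t1_maps``.
        fit_mask : bool array, optional
            Voxels to fit; defaults to voxels where any subject is nonzero.
        """
        if self.rmse_dof not in ("residual", "n"):
            raise ValueError("rmse_dof must be 'residual' or 'n'")
        maps = np.stack([np.asarray(m, dtype=np.float64) for m in t1_maps])
        n = maps.shape[0]
        if n < 5:
            raise ValueError(
                "insufficient degrees of freedom: need >= 5 subjects for the "
                "4-coefficient model"
            )
        subjects = pd.DataFrame(subjects)
        if len(subjects) != n:
            raise ValueError("subjects table and t1_maps length mismatch")

        ages = subjects["age"].to_numpy(dtype=float)
        sexes = np.array([encode_sex(s) for s in subjects["sex"]])
        if len(np.unique(sexes)) == 1:
            warnings.warn(
                "all fitting subjects share one sex; the sex coefficient is "
                "not identifiable and the design is rank-deficient",
                UserWarning,
            )

        center = float(np.mean(ages)) if self.age_center is None else float(self.age_center)
        ac = ages - center
        X = np.column_stack([np.ones(n), sexes, ac, ac**2])

        rank = np.linalg.matrix_rank(X)
        if rank < 4:
            bad = []
            if np.ptp(sexes) == 0:
                bad.append("sex")
            if np.ptp(ac) == 0:
                bad.extend(["age", "age2"])
            raise ValueError(
                "rank-deficient design matrix (rank "
                f"{rank} < 4); collinear columns: {', '.join(bad) or 'unknown'}"
            )

        if fit_mask is None:
            fit_mask = np.any(maps != 0, axis=0)
        fit_mask = np.asarray(fit_mask, dtype=bool)
        if fit_mask.shape != maps.shape[1:]:
            raise ValueError(
                f"fit_mask shape {fit_mask.shape} does not match map grid "
                f"{maps.shape[1:]}"
            )

        Y = maps[:, fit_mask]  # (n, V)
        XtX = X.T @ X
        beta = np.linalg.solve(XtX, X.T @ Y)  # (4, V)
        resid = Y - X @ beta
        dof = n - 4 if self.rmse_dof == "residual" else n
        rmse = np.sqrt(np.sum(resid**2, axis=0) / dof)

        def _full(v):
            out = np.full(fit_mask.shape, np.nan)
            out[fit_mask] = v
            return out

        self.beta0_ = _full(beta[0])
        self.beta_sex_ = _full(beta[1])
        self.beta_age_ = _full(beta[2])
        self.beta_age2_ = _full(beta[3])
        self.rmse_ = _full(rmse)
        self.age_center_ = center
        self.n_subjects_ = n
        self.fit_mask_ = fit_mask
        return self

    # -------------------------------------------------------------- predict
    def predict(self, age: float, sex, voxel: tuple[int, int, int] | None = None):
        """Expected T1 (ms) for given covariates.

        Returns the full map (NaN outside the fit mask) or, if ``voxel`` is
        given, the scalar prediction at that voxel (NaN if outside the mask).
        """
        check_is_fitted(self, "beta0_")
        ac = float(age) - self.age_center_
        s = encode_sex(sex)
        pred = (
            self.beta0_
            + self.beta_sex_ * s
            + self.beta_age_ * ac
            + self.beta_age2_ * ac**2
        )
        if voxel is None:
            return pred
        return float(pred[tuple(voxel)])

    def zscore(self, t1_map: np.ndarray, age: float, sex):
        """Z-score map of one subject against this atlas (see zscore module)."""
        from .zscore import compute_zscore_map

        return compute_zscore_map(t1_map, self, age, sex)


# ---------------------------------------------------------------- functions

def fit_atlas(t1_maps, subjects, fit_mask=None, age_center=None, rmse_dof="residual"):
    """Functional wrapper over :class:`NormativeT1Atlas`.fit."""
    return NormativeT1Atlas(age_center=age_center, rmse_dof=rmse_dof).fit(
        t1_maps, subjects, fit_mask=fit_mask
    )


def predict_t1(atlas: NormativeT1Atlas, age: float, sex, voxel=None):
    """Expected T1 from a fitted atlas (map, or scalar at ``voxel``)."""
    return atlas.predict(age, sex, voxel=voxel)


def save_atlas(atlas: NormativeT1Atlas, path) -> None:
    """Write the atlas as five NIfTI volumes plus a JSON metadata file.

    Coefficient maps are stored at full float64 precision so a round trip is
    bit-exact.
    """
    check_is_fitted(atlas, "beta0_")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {
        "beta0": atlas.beta0_,
        "beta_sex": atlas.beta_sex_,
        "beta_age": atlas.beta_age_,
        "beta_age2": atlas.beta_age2_,
        "rmse": atlas.rmse_,
        "fit_mask": atlas.fit_mask_.astype(np.uint8),
    }
    for name, arr in arrays.items():
        dtype = np.uint8 if name == "fit_mask" else np.float64
        write_volume(arr, path / f"{name}.nii.gz", dtype=dtype)
    meta = {
        "format_version": _FORMAT_VERSION,
        "age_center": atlas.age_center_,
        "n_subjects": atlas.n_subjects_,
        "rmse_dof": atlas.rmse_dof,
        "sex_coding": {"male": 1, "female": 0},
    }
    (path / "atlas.json").write_text(json.dumps(meta, indent=2))


def load_atlas(path) -> NormativeT1Atlas:
    """Load an atlas written by :func:`save_atlas`."""
    path = Path(path)
    meta_path = path / "atlas.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"incomplete atlas: missing atlas.json in {path}")
    meta = json.loads(meta_path.read_text())
    version = meta.get("format_version")
    if version != _FORMAT_VERSION:
        raise ValueError(
            f"atlas format version mismatch: file has {version}, "
            f"reader supports {_FORMAT_VERSION}"
        )
    missing = [
        name for name in (*_COEF_NAMES, "fit_mask")
        if not (path / f"{name}.nii.gz").exists()
    ]
    if missing:
        raise FileNotFoundError(f"incomplete atlas: missing map(s) {missing} in {path}")

    atlas = NormativeT1Atlas(rmse_dof=meta.get("rmse_dof", "residual"))
    volumes = {
        name: read_volume(path / f"{name}.nii.gz")[0]
        for name in (*_COEF_NAMES, "fit_mask")
    }
    atlas.beta0_ = volumes["beta0"]
    atlas.beta_sex_ = volumes["beta_sex"]
    atlas.beta_age_ = volumes["beta_age"]
    atlas.beta_age2_ = volumes["beta_age2"]
    atlas.rmse_ = volumes["rmse"]
    atlas.fit_mask_ = volumes["fit_mask"].astype(bool)
    atlas.age_center_ = float(meta["age_center"])
    atlas.n_subjects_ = int(meta["n_subjects"])
    return atlas
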