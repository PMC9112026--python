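"""Synthetic 3D phantom cohorts for the periventricular T1-gradient pipeline.

The generator produces healthy-control and patient T1 maps on a shared grid
(the synthetic analogue of a study-specific template space) with the
statistical structure the downstream analysis assumes:

* healthy T1 varies voxel-wise as a linear function of sex, centred age and
  centred age squared, plus independent Gaussian residual noise;
* patients carry a diffuse abnormality field whose magnitude decays
  exponentially with the Euclidean distance from the lateral ventricles,
  plus focal lesions whose per-band occurrence rate decays with the same
  distance;
* disability (EDSS) is a noisy, quantized monotone function of each
  patient's true injected gradient severity.

Anatomy is deliberately schematic — nested ellipsoids — because every
downstream operation (distance transforms, band labelling, masked
regressions) is geometry-agnostic, and ellipsoids make the realizability of
all 30 one-mm bands provable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhantomGeometry",
    "SyntheticTruth",
    "SyntheticCohort",
    "make_phantom_geometry",
    "default_truth",
    "generate_healthy_subject",
    "generate_patient_subject",
    "generate_cohort",
]

#: EDSS baseline per group, matching the cohorts' reported medians
#: (early ~2.0, progressive ~5.5).
EDSS_GROUP_BASE = {"earlyMS": 2.0, "progressiveMS": 5.5}

#: Multiplier applied to the per-subject severity draw per group, so the
#: progressive cohort carries a stronger injected gradient on average.
SEVERITY_GROUP_SCALE = {"earlyMS": 1.0, "progressiveMS": 2.0}


@dataclass(frozen=True)
class PhantomGeometry:
    """Tissue masks of one synthetic head on a common grid.

    All masks are boolean arrays of shape ``grid_shape``.  ``supratentorial_wm``
    is ``wm & ~infratentorial`` and is the analysis domain of the band
    extraction.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    brain: np.ndarray
    wm: np.ndarray
    gm: np.ndarray
    ventricles: np.ndarray
    infratentorial: np.ndarray
    supratentorial_wm: np.ndarray

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class SyntheticTruth:
    """Ground-truth generative parameters, kept for recovery tests.

    Coefficient fields are in ms (per year, per year² for the age terms);
    distances in mm.  ``gradient_amplitude_ms`` is the diffuse abnormality
    amplitude at zero distance from the ventricles for a severity-1 subject.
    """

    beta0_field: np.ndarray
    beta_sex_field: np.ndarray
    beta_age_field: np.ndarray
    beta_age2_field: np.ndarray
    noise_sigma: np.ndarray
    age_center_years: float = 37.0
    gradient_amplitude_ms: float = 60.0
    gradient_decay_mm: float = 10.0
    affected_fraction: float = 0.7
    lesion_rate_scale: float = 6.0
    lesion_decay_mm: float = 10.0
    lesion_radius_mm: float = 2.5
    lesion_t1_elevation_ms: float = 350.0
    edss_coupling_slope: float = 1.5
    edss_noise_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gradient_decay_mm <= 0:
            raise ValueError("gradient_decay_mm must be positive")
        if self.lesion_decay_mm <= 0:
            raise ValueError("lesion_decay_mm must be positive")


@dataclass
class SyntheticCohort:
    """One generated cohort: demographics plus per-subject volumes."""

    subjects: pd.DataFrame
    t1_maps: dict[str, np.ndarray]
    lesion_masks: dict[str, np.ndarray]
    severities: dict[str, float] = field(default_factory=dict)


def _ellipsoid(coords: list[np.ndarray], center_mm, semi_mm) -> np.ndarray:
    rho2 = sum(((c - c0) / s) ** 2 for c, c0, s in zip(coords, center_mm, semi_mm))
    return rho2 <= 1.0


def make_phantom_geometry(
    grid_shape=(96, 96, 96),
    voxel_size_mm=(1.0, 1.0, 1.0),
    seed: int = 0,
    n_bands: int = 30,
) -> PhantomGeometry:
    """Build the nested-ellipsoid phantom anatomy.

    The main head ellipsoid holds a thin GM rim, WM filling the interior,
    and two lateral-ventricle ellipsoids near the centre; a disjoint inferior
    blob is labelled infratentorial (with a small fourth-ventricle component
    inside it).  ``seed`` jitters the ellipsoid centres by up to one voxel so
    different seeds give slightly different anatomies.

    Raises
    ------
    ValueError
        If the grid cannot realize ``n_bands`` one-mm distance bands in the
        supratentorial WM; the message names the maximum realizable band.
    """
    from scipy import ndimage

    grid_shape = tuple(int(n) for n in grid_shape)
    voxel_size_mm = tuple(float(v) for v in np.broadcast_to(voxel_size_mm, (3,)))
    if any(n <= 0 for n in grid_shape) or any(v <= 0 for v in voxel_size_mm):
        raise ValueError("grid_shape and voxel_size_mm must be positive")

    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-1.0, 1.0, size=(4, 3)) * np.asarray(voxel_size_mm)

    # mm coordinates relative to the grid centre
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * v
        for n, v in zip(grid_shape, voxel_size_mm)
    ]
    coords = list(np.meshgrid(*coords, indexing="ij"))
    half = [n * v / 2.0 for n, v in zip(grid_shape, voxel_size_mm)]

    head_center = np.array([0.0, 0.0, 0.10 * half[2]]) + jitter[0]
    head_semi = (0.90 * half[0], 0.92 * half[1], 0.78 * half[2])
    rho2 = sum(
        ((c - c0) / s) ** 2 for c, c0, s in zip(coords, head_center, head_semi)
    )
    head = rho2 <= 1.0
    interior = rho2 <= 0.90**2  # GM rim ≈ 2–4 mm thick

    scale = min(half) / 48.0  # anatomy expressed relative to a 96 mm head
    lat_semi = (4.0 * scale, 10.0 * scale, 4.0 * scale)
    lat_z = head_center[2] + 2.0 * scale
    vent_left = _ellipsoid(
        coords, (head_center[0] - 7.0 * scale + jitter[1][0], head_center[1], lat_z), lat_semi
    )
    vent_right = _ellipsoid(
        coords, (head_center[0] + 7.0 * scale + jitter[2][0], head_center[1], lat_z), lat_semi
    )

    infra_center = (
        head_center[0] + jitter[3][0],
        head_center[1] - 0.20 * half[1],
        -0.62 * half[2],
    )
    infra = _ellipsoid(
        coords, infra_center, (0.30 * half[0], 0.30 * half[1], 0.18 * half[2])
    )
    vent_fourth = _ellipsoid(coords, infra_center, (2.5 * scale,) * 3)

    ventricles = vent_left | vent_right | vent_fourth
    brain = head | infra
    wm = (interior | infra) & ~ventricles
    gm = head & ~interior & ~infra & ~ventricles
    supratentorial_wm = wm & ~infra

    if not ventricles.any():
        raise ValueError("ventricle mask empty: grid too coarse for the anatomy")

    dist = ndimage.distance_transform_edt(~ventricles, sampling=voxel_size_mm)
    max_band = int(np.floor(dist[supratentorial_wm].max() + 0.5)) if supratentorial_wm.any() else 0
    if max_band < n_bands:
        raise ValueError(
            f"grid too small to realize {n_bands} distance bands: "
            f"max realizable band {max_band} < {n_bands}"
        )

    return PhantomGeometry(
        grid_shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        brain=brain,
        wm=wm,
        gm=gm,
        ventricles=ventricles,
        infratentorial=infra,
        supratentorial_wm=supratentorial_wm,
    )


def default_truth(geometry: PhantomGeometry, seed: int = 0, **overrides) -> SyntheticTruth:
    """Ground-truth coefficient fields with smooth spatial variation.

    Tissue means follow typical 3 T values (WM ≈ 850 ms, GM ≈ 1400 ms,
    CSF/ventricles ≈ 3500 ms); low-frequency sinusoidal modulation keeps the
    coefficient fields non-constant so per-voxel fits are informative.
    Keyword overrides replace any :class:`SyntheticTruth` field.
    """
    shape = geometry.grid_shape
    ii, jj, kk = np.meshgrid(
        *[np.linspace(0.0, np.pi, n) for n in shape], indexing="ij"
    )
    wave = np.sin(ii) * np.cos(2 * jj) + 0.5 * np.cos(kk)

    beta0 = np.zeros(shape)
    beta0[geometry.wm] = 850.0
    beta0[geometry.gm] = 1400.0
    beta0[geometry.ventricles] = 3500.0
    beta0[geometry.brain] += 30.0 * wave[geometry.brain]

    beta_sex = np.where(geometry.brain, 12.0 + 4.0 * wave, 0.0)
    beta_age = np.where(geometry.brain, 1.6 + 0.4 * wave, 0.0)
    beta_age2 = np.where(geometry.brain, 0.02 + 0.005 * wave, 0.0)
    sigma = np.where(geometry.brain, 30.0 + 5.0 * np.cos(ii), 0.0)

    params = dict(
        beta0_field=beta0,
        beta_sex_field=beta_sex,
        beta_age_field=beta_age,
        beta_age2_field=beta_age2,
        noise_sigma=sigma,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticTruth(**params)


def _sex_code(sex) -> int:
    if isinstance(sex, str):
        s = sex.strip().lower()
        if s in ("male", "m", "1"):
            return 1
        if s in ("female", "f", "0"):
            return 0
        raise ValueError(f"unrecognized sex value: {sex!r}")
    return int(sex)


def model_surface(truth: SyntheticTruth, age: float, sex, brain: np.ndarray) -> np.ndarray:
    """Noise-free expected T1 map for given covariates (0 outside brain)."""
    ac = float(age) - truth.age_center_years
    t1 = (
        truth.beta0_field
        + truth.beta_sex_field * _sex_code(sex)
        + truth.beta_age_field * ac
        + truth.beta_age2_field * ac**2
    )
    return np.where(brain, t1, 0.0)


def generate_healthy_subject(
    geometry: PhantomGeometry,
    truth: SyntheticTruth,
    record,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One healthy T1 map: model surface plus per-voxel Gaussian noise.

    ``record`` is any mapping with ``age`` and ``sex`` entries (a cohort-table
    row works).  ``rng`` defaults to a stream derived from ``truth.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    t1 = model_surface(truth, record["age"], record["sex"], geometry.brain)
    noise = rng.standard_normal(geometry.grid_shape) * truth.noise_sigma
    return np.where(geometry.brain, t1 + noise, 0.0)


def _seed_lesions(
    geometry: PhantomGeometry,
    truth: SyntheticTruth,
    distance_mm: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spherical lesions with per-band Poisson counts decaying with distance."""
    lesions = np.zeros(geometry.grid_shape, dtype=bool)
    band = np.floor(distance_mm + 0.5).astype(int)
    coords_mm = [
        (np.arange(n) - (n - 1) / 2.0) * v
        for n, v in zip(geometry.grid_shape, geometry.voxel_size_mm)
    ]
    grids = np.meshgrid(*coords_mm, indexing="ij")
    domain = geometry.supratentorial_wm
    max_band = int(band[domain].max()) if domain.any() else 0
    for b in range(1, max_band + 1):
        in_band = domain & (band == b)
        n_vox = int(in_band.sum())
        if n_vox == 0:
            continue
        rate = truth.lesion_rate_scale * np.exp(-b / truth.lesion_decay_mm)
        n_lesions = rng.poisson(rate)
        if n_lesions == 0:
            continue
        idx = np.flatnonzero(in_band.ravel())
        centers = rng.choice(idx, size=min(n_lesions, n_vox), replace=False)
        for c in centers:
            cidx = np.unravel_index(c, geometry.grid_shape)
            c_mm = [g[cidx] for g in grids]
            r2 = sum((g - cm) ** 2 for g, cm in zip(grids, c_mm))
            lesions |= r2 <= truth.lesion_radius_mm**2
    return lesions & geometry.wm


def generate_patient_subject(
    geometry: PhantomGeometry,
    truth: SyntheticTruth,
    record,
    distance_mm: np.ndarray,
    rng: np.random.Generator | None = None,
    severity: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One patient T1 map and lesion mask.

    On top of the healthy model surface, a diffuse abnormality
    ``severity · A · exp(−d/λ)`` is added on a random ``affected_fraction``
    subset of the supratentorial WM, focal lesions are seeded with a
    distance-decaying per-band Poisson rate and receive a fixed additional T1
    elevation, and Gaussian residual noise is added everywhere in brain.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    if severity is None:
        scale = SEVERITY_GROUP_SCALE.get(record.get("group", "earlyMS"), 1.0)
        severity = scale * rng.uniform(0.5, 1.5)

    t1 = model_surface(truth, record["age"], record["sex"], geometry.brain)

    affected = geometry.supratentorial_wm & (
        rng.random(geometry.grid_shape) < truth.affected_fraction
    )
    injected = np.where(
        affected,
        severity * truth.gradient_amplitude_ms * np.exp(-distance_mm / truth.gradient_decay_mm),
        0.0,
    )

    lesions = _seed_lesions(geometry, truth, distance_mm, rng)
    noise = rng.standard_normal(geometry.grid_shape) * truth.noise_sigma
    t1 = t1 + injected + lesions * truth.lesion_t1_elevation_ms + noise
    return np.where(geometry.brain, t1, 0.0), lesions


def _quantize_edss(x: np.ndarray | float) -> np.ndarray | float:
    return np.clip(np.round(np.asarray(x) * 2.0) / 2.0, 0.0, 10.0)


def generate_cohort(
    geometry: PhantomGeometry,
    truth: SyntheticTruth,
    n_hc: int,
    n_early: int = 0,
    n_progressive: int = 0,
    seed: int = 0,
    distance_mm: np.ndarray | None = None,
) -> SyntheticCohort:
    """Generate a full cohort reproducibly from one seed.

    Ages are drawn Normal(37, 10) truncated to [18, 80] and sexes
    Bernoulli(0.37 male), mirroring the healthy reference cohort the model
    is calibrated for.  EDSS for patients is the group baseline plus
    ``edss_coupling_slope`` times the subject's injected-gradient severity
    plus Gaussian noise, quantized to the ordinal 0–10 scale in 0.5 steps.

    Per-subject RNG streams are spawned from ``(seed, subject index)`` so
    growing the cohort never reshuffles earlier subjects.
    """
    if n_hc < 5:
        raise ValueError(
            "insufficient degrees of freedom: need at least 5 healthy controls "
            "for the 4-coefficient normative model"
        )
    if (n_early + n_progressive) > 0 and distance_mm is None:
        from .bands import distance_to_ventricles

        distance_mm = distance_to_ventricles(
            geometry.ventricles, geometry.voxel_size_mm
        )

    groups = (
        ["HC"] * n_hc + ["earlyMS"] * n_early + ["progressiveMS"] * n_progressive
    )
    streams = np.random.SeedSequence(seed).spawn(len(groups))

    rows = []
    t1_maps: dict[str, np.ndarray] = {}
    lesion_masks: dict[str, np.ndarray] = {}
    severities: dict[str, float] = {}
    for i, (group, ss) in enumerate(zip(groups, streams)):
        rng = np.random.default_rng(ss)
        sid = f"{group}{i:03d}"
        age = float(np.clip(rng.normal(37.0, 10.0), 18.0, 80.0))
        sex = "male" if rng.random() < 0.37 else "female"
        record = {"subject_id": sid, "age": age, "sex": sex, "group": group}
        if group == "HC":
            t1_maps[sid] = generate_healthy_subject(geometry, truth, record, rng)
            record["edss"] = np.nan
        else:
            severity = SEVERITY_GROUP_SCALE[group] * rng.uniform(0.5, 1.5)
            t1, lesions = generate_patient_subject(
                geometry, truth, record, distance_mm, rng, severity=severity
            )
            t1_maps[sid] = t1
            lesion_masks[sid] = lesions
            severities[sid] = severity
            edss = (
                EDSS_GROUP_BASE[group]
                + truth.edss_coupling_slope * severity
                + rng.normal(0.0, truth.edss_noise_sd)
            )
            record["edss"] = float(_quantize_edss(edss))
        rows.append(record)

    subjects = pd.DataFrame(rows, columns=["subject_id", "age", "sex", "group", "edss"])
    return SyntheticCohort(
        subjects=subjects,
        t1_maps=t1_maps,
        lesion_masks=lesion_masks,
        severities=severities,
    )
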