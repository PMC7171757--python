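"""Synthetic dual-sequence MR cohorts with texture-driven survival.

Every downstream stage of the pipeline (extraction, clustering, selection,
modeling, evaluation) is testable on cohorts produced here, without any
external data.

Model
-----
* Each patient carries two ellipsoidal ROIs (``tumor``, ``node``) on a
  shared grid, imaged on two sequences (``T1CE``, ``T2``) with different
  structure mean intensities.
* In-ROI texture is a Gaussian random field: white noise smoothed by a
  Gaussian kernel whose width is the patient's latent correlation length
  (voxels), standardized, and scaled by the patient's latent contrast.
  Latents are drawn uniformly over the spec ranges, per structure.
* Survival: proportional hazards on the *standardized* latents with a
  Weibull baseline (shape 1 = exponential, the default):
  ``T = scale * (E / exp(eta))**(1/shape)`` with ``E ~ Exp(1)`` and
  ``eta = sum_k beta[endpoint][latent_k] * z_k``.
* Censoring: one administrative censoring time per patient, uniform on
  ``(0, c_max)`` with ``c_max`` calibrated so the expected censored
  fraction over the cohort equals ``censoring_rate``.
* Default endpoint coupling: LC is driven by the tumor latents; RC, DMFS
  and OS by the node latents.

All randomness flows from ``CohortSpec.seed`` through one child stream per
patient, so a cohort is bit-reproducible and individual patients are
invariant to cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, TypeVar

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .errors import ConfigurationError
from .features import extract_all
from .io import ImageVolume, RoiMask

__all__ = [
    "ENDPOINTS",
    "LATENT_NAMES",
    "default_effect_sizes",
    "CohortSpec",
    "SyntheticPatient",
    "generate_cohort",
    "cohort_feature_table",
    "cohort_outcomes",
    "generate_feature_cohort",
    "split_cohort",
    "write_cohort",
]

ENDPOINTS = ("LC", "RC", "DMFS", "OS")
LATENT_NAMES = ("tumor_corr_length", "tumor_contrast", "node_corr_length", "node_contrast")

#: Interquartile range of a standardized uniform variable: a coefficient of
#: log(3)/1.732 on a standardized latent gives a hazard ratio of 3 across
#: the latent's IQR.
_UNIFORM_IQR_Z = math.sqrt(12.0) / 2.0

_STRUCTURE_MEANS = {
    "T1CE": {"tumor": 120.0, "node": 100.0},
    "T2": {"tumor": 80.0, "node": 110.0},
}
_BACKGROUND_MEAN = {"T1CE": 60.0, "T2": 40.0}
_CONTRAST_INTENSITY_SCALE = 10.0  # intensity units per unit latent contrast


def default_effect_sizes(beta: float = 0.7) -> dict[str, dict[str, float]]:
    """Endpoint -> latent -> log-hazard coefficient, with the default
    coupling (tumor latents drive LC; node latents drive RC/DMFS/OS).

    ``beta = 0.7`` corresponds to a hazard ratio exp(0.7 * sqrt(12)/2) ~ 3.4
    across the latent's interquartile range.
    """
    return {
        "LC": {"tumor_corr_length": beta, "tumor_contrast": beta},
        "RC": {"node_corr_length": beta, "node_contrast": beta},
        "DMFS": {"node_corr_length": beta, "node_contrast": beta},
        "OS": {"node_corr_length": beta, "node_contrast": beta},
    }


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; identical specs (including
    ``seed``) generate bit-identical cohorts."""

    n_patients: int = 93
    volume_shape: tuple[int, int, int] = (20, 96, 64)
    voxel_spacing_mm: tuple[float, float, float] = (5.0, 1.0, 1.0)
    roi_radius_range_mm: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"tumor": (12.0, 22.0), "node": (6.0, 11.0)}
    )
    texture_corr_length_range: tuple[float, float] = (0.5, 2.5)
    texture_contrast_range: tuple[float, float] = (0.5, 3.0)
    n_sequences: int = 2
    baseline_hazard_scale: float = 60.0
    weibull_shape: float = 1.0  # 1.0 = exponential baseline
    effect_sizes: Mapping[str, Mapping[str, float]] = field(default_factory=default_effect_sizes)
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError(f"n_patients must be >= 2, got {self.n_patients}")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigurationError(
                f"censoring_rate must be in [0, 1), got {self.censoring_rate}")
        if self.baseline_hazard_scale <= 0 or self.weibull_shape <= 0:
            raise ConfigurationError("baseline_hazard_scale and weibull_shape must be positive")
        for ep, betas in self.effect_sizes.items():
            for name, b in betas.items():
                if name not in LATENT_NAMES:
                    raise ConfigurationError(f"unknown latent parameter {name!r} in effect_sizes")
                if not math.isfinite(b):
                    raise ConfigurationError(f"effect size for {ep}/{name} is not finite")
        # every ellipsoid (largest radius) must fit inside the volume
        half_extent_mm = [
            (n - 3) / 2.0 * s for n, s in zip(self.volume_shape, self.voxel_spacing_mm)
        ]
        for structure, (rmin, rmax) in self.roi_radius_range_mm.items():
            if rmin <= 0 or rmax < rmin:
                raise ConfigurationError(
                    f"roi_radius_range_mm[{structure!r}] must be positive and ordered")
            # structures sit side by side along y, so each may use half the y extent
            limits = (half_extent_mm[0], half_extent_mm[1] / 2.0, half_extent_mm[2])
            if rmax > min(limits):
                raise ConfigurationError(
                    f"roi_radius_range_mm[{structure!r}] max {rmax} mm does not fit "
                    f"inside volume_shape {self.volume_shape} at spacing "
                    f"{self.voxel_spacing_mm}")

    @property
    def sequences(self) -> tuple[str, ...]:
        return ("T1CE", "T2")[: self.n_sequences]


@dataclass
class SyntheticPatient:
    patient_id: str
    volumes: dict[str, ImageVolume]
    masks: dict[str, RoiMask]
    latent_params: dict[str, float]
    outcomes: dict[str, tuple[float, int]]  # endpoint -> (time_months, event)


def _standardized_latent(value: float, rng_range: tuple[float, float]) -> float:
    lo, hi = rng_range
    if hi == lo:
        return 0.0
    return (value - (lo + hi) / 2.0) / ((hi - lo) / math.sqrt(12.0))


def _ellipsoid_mask(shape: Sequence[int], center: Sequence[float],
                    radius_mm: float, spacing: Sequence[float]) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    d2 = sum(((g - c) * s / radius_mm) ** 2 for g, c, s in zip(grids, center, spacing))
    return d2 <= 1.0


def _gaussian_field(rng: np.random.Generator, shape: Sequence[int], corr_length: float) -> np.ndarray:
    """Smoothed, standardized white noise (unit variance over the volume)."""
    noise = rng.standard_normal(shape)
    fieldv = ndimage.gaussian_filter(noise, sigma=corr_length, mode="reflect")
    sd = fieldv.std()
    return (fieldv - fieldv.mean()) / (sd if sd > 0 else 1.0)


def _linear_predictors(spec: CohortSpec, latents: list[dict[str, float]]) -> np.ndarray:
    """eta[patient, endpoint] from standardized latents and effect sizes."""
    ranges = {
        "tumor_corr_length": spec.texture_corr_length_range,
        "node_corr_length": spec.texture_corr_length_range,
        "tumor_contrast": spec.texture_contrast_range,
        "node_contrast": spec.texture_contrast_range,
    }
    eta = np.zeros((len(latents), len(ENDPOINTS)))
    for i, lat in enumerate(latents):
        for j, ep in enumerate(ENDPOINTS):
            for name, beta in spec.effect_sizes.get(ep, {}).items():
                eta[i, j] += beta * _standardized_latent(lat[name], ranges[name])
    return eta


def _calibrate_censoring_horizon(rates: np.ndarray, target: float) -> float:
    """Upper bound c of the uniform censoring distribution such that the
    expected censored fraction over all (patient, endpoint) exponential
    rates equals *target*."""

    def censored_fraction(c: float) -> float:
        lc = rates * c
        return float(np.mean(np.where(lc > 1e-12, -np.expm1(-lc) / np.maximum(lc, 1e-12), 1.0)))

    lo, hi = 1e-6, 1e-6
    # censored_fraction is decreasing in c from 1 to 0
    hi = 1.0
    while censored_fraction(hi) > target and hi < 1e9:
        hi *= 4.0
    return float(optimize.brentq(lambda c: censored_fraction(c) - target, lo, hi, xtol=1e-9))


def _survival_times(spec: CohortSpec, eta: np.ndarray,
                    unit_exp: np.ndarray, unit_cens: np.ndarray) -> list[dict[str, tuple[float, int]]]:
    """Event/censoring assembly. ``unit_exp`` is Exp(1) per patient per
    endpoint, ``unit_cens`` is U(0,1) per patient (shared follow-up end)."""
    k = spec.weibull_shape
    times = spec.baseline_hazard_scale * (unit_exp / np.exp(eta)) ** (1.0 / k)
    if spec.censoring_rate > 0:
        if k != 1.0:
            # effective exponential rate matching each Weibull mean
            rates = 1.0 / np.maximum(
                spec.baseline_hazard_scale * math.gamma(1 + 1 / k) * np.exp(-eta / k), 1e-12)
        else:
            rates = np.exp(eta) / spec.baseline_hazard_scale
        c_max = _calibrate_censoring_horizon(rates.ravel(), spec.censoring_rate)
        cens = c_max * unit_cens
    else:
        cens = np.full(unit_cens.shape, np.inf)
    out = []
    for i in range(eta.shape[0]):
        rec = {}
        for j, ep in enumerate(ENDPOINTS):
            t_event = times[i, j]
            t = min(t_event, cens[i])
            rec[ep] = (max(float(t), 1e-6), int(t_event <= cens[i]))
        out.append(rec)
    return out


def generate_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Generate ``spec.n_patients`` synthetic patients.

    Deterministic in ``spec`` (including the seed); the true log-hazard of
    every patient is the linear combination of the standardized latents
    with ``spec.effect_sizes``.
    """
    root = np.random.SeedSequence(spec.seed)
    streams = [np.random.default_rng(s) for s in root.spawn(spec.n_patients)]
    structures = list(spec.roi_radius_range_mm)

    latents: list[dict[str, float]] = []
    unit_exp = np.empty((spec.n_patients, len(ENDPOINTS)))
    unit_cens = np.empty(spec.n_patients)
    geometry: list[dict[str, np.ndarray]] = []
    fields: list[dict[tuple[str, str], np.ndarray]] = []

    ny = spec.volume_shape[1]
    centers_y = {"tumor": ny * 0.3, "node": ny * 0.72}

    for i, rng in enumerate(streams):
        lat: dict[str, float] = {}
        for structure in structures:
            lat[f"{structure}_corr_length"] = float(rng.uniform(*spec.texture_corr_length_range))
            lat[f"{structure}_contrast"] = float(rng.uniform(*spec.texture_contrast_range))
        latents.append(lat)

        masks: dict[str, np.ndarray] = {}
        for structure in structures:
            r = float(rng.uniform(*spec.roi_radius_range_mm[structure]))
            center = (
                spec.volume_shape[0] / 2.0 + rng.uniform(-0.5, 0.5),
                centers_y[structure] + rng.uniform(-0.5, 0.5),
                spec.volume_shape[2] / 2.0 + rng.uniform(-0.5, 0.5),
            )
            m = _ellipsoid_mask(spec.volume_shape, center, r, spec.voxel_spacing_mm)
            if not m.any():
                raise ConfigurationError(
                    f"roi_radius_range_mm[{structure!r}]: radius {r:.2f} mm produced an "
                    f"empty mask at spacing {spec.voxel_spacing_mm}; increase the minimum "
                    f"radius or reduce the voxel spacing")
            masks[structure] = m
        geometry.append(masks)

        f: dict[tuple[str, str], np.ndarray] = {}
        for seq in spec.sequences:
            for structure in structures:
                f[(seq, structure)] = _gaussian_field(
                    rng, spec.volume_shape, lat[f"{structure}_corr_length"])
        fields.append(f)

        unit_exp[i] = rng.exponential(1.0, size=len(ENDPOINTS))
        unit_cens[i] = rng.uniform()

    eta = _linear_predictors(spec, latents)
    outcomes = _survival_times(spec, eta, unit_exp, unit_cens)

    patients = []
    width = max(3, len(str(spec.n_patients)))
    for i, rng in enumerate(streams):
        volumes = {}
        for seq in spec.sequences:
            img = np.full(spec.volume_shape, _BACKGROUND_MEAN[seq])
            img = img + 5.0 * rng.standard_normal(spec.volume_shape)
            for structure in structures:
                m = geometry[i][structure]
                contrast = latents[i][f"{structure}_contrast"]
                img[m] = (
                    _STRUCTURE_MEANS[seq][structure]
                    + _CONTRAST_INTENSITY_SCALE * contrast * fields[i][(seq, structure)][m]
                )
            volumes[seq] = ImageVolume(img, spec.voxel_spacing_mm, seq)
        masks = {
            structure: RoiMask(geometry[i][structure], structure)
            for structure in structures
        }
        patients.append(SyntheticPatient(
            patient_id=f"P{i + 1:0{width}d}",
            volumes=volumes,
            masks=masks,
            latent_params=latents[i],
            outcomes=outcomes[i],
        ))
    return patients


def cohort_feature_table(patients: Sequence[SyntheticPatient], n_levels: int = 64) -> pd.DataFrame:
    """Patients x features table with columns
    ``<structure>_<sequence>_<family>_<feature>`` (172 per patient)."""
    rows = {}
    for p in patients:
        per_structure = extract_all(p.volumes, p.masks, n_levels)
        row = {}
        for structure in sorted(per_structure):
            for name, val in per_structure[structure].items():
                row[f"{structure}_{name}"] = val
        rows[p.patient_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "patient_id"
    return table


def cohort_outcomes(patients: Sequence[SyntheticPatient]) -> pd.DataFrame:
    """Long-format outcome table: patient_id, endpoint, time_months, event."""
    rows = []
    for p in patients:
        for ep, (t, e) in p.outcomes.items():
            rows.append({"patient_id": p.patient_id, "endpoint": ep,
                         "time_months": t, "event": e})
    return pd.DataFrame(rows, columns=["patient_id", "endpoint", "time_months", "event"])


def generate_feature_cohort(n_patients: int, n_features: int,
                            effect_sizes: Mapping[str, float],
                            censoring_rate: float, seed: int,
                            feature_corr: float = 0.2,
                            baseline_hazard_scale: float = 60.0,
                            endpoint: str = "OS") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fast tabular cohort bypassing image synthesis.

    Features are jointly Gaussian with exchangeable pairwise correlation
    ``feature_corr`` (one shared factor); the log-hazard is linear in the
    features named in ``effect_sizes`` with an exponential baseline.
    Feature names are ``f01 .. fNN``.
    """
    if n_patients <= 0 or n_features <= 0:
        raise ConfigurationError("n_patients and n_features must be positive")
    if not 0.0 <= censoring_rate < 1.0:
        raise ConfigurationError(f"censoring_rate must be in [0, 1), got {censoring_rate}")
    if not 0.0 <= feature_corr < 1.0:
        raise ConfigurationError(f"feature_corr must be in [0, 1), got {feature_corr}")
    width = max(2, len(str(n_features)))
    names = [f"f{j + 1:0{width}d}" for j in range(n_features)]
    unknown = set(effect_sizes) - set(names)
    if unknown:
        raise ConfigurationError(f"effect_sizes name unknown features: {sorted(unknown)}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shared = rng.standard_normal((n_patients, 1))
    x = math.sqrt(feature_corr) * shared + math.sqrt(1 - feature_corr) * rng.standard_normal(
        (n_patients, n_features))
    table = pd.DataFrame(x, columns=names)
    table.index = [f"P{i + 1:03d}" for i in range(n_patients)]
    table.index.name = "patient_id"

    beta = np.array([effect_sizes.get(nm, 0.0) for nm in names])
    eta = x @ beta
    t_event = baseline_hazard_scale * rng.exponential(1.0, n_patients) / np.exp(eta)
    if censoring_rate > 0:
        rates = np.exp(eta) / baseline_hazard_scale
        c_max = _calibrate_censoring_horizon(rates, censoring_rate)
        cens = c_max * rng.uniform(size=n_patients)
    else:
        cens = np.full(n_patients, np.inf)
    time = np.maximum(np.minimum(t_event, cens), 1e-6)
    event = (t_event <= cens).astype(int)
    outcomes = pd.DataFrame({
        "patient_id": table.index,
        "endpoint": endpoint,
        "time_months": time,
        "event": event,
    })
    return table, outcomes


T = TypeVar("T")


def split_cohort(patients: Sequence[T], train_fraction: float, seed: int) -> tuple[list[T], list[T]]:
    """Simple (non-stratified) random split into training and validation.

    Training size is ``round(train_fraction * n)``; the two parts are
    disjoint and exhaustive.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(patients)
    n_train = int(round(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ConfigurationError(
            f"train_fraction {train_fraction} yields an empty split for n={n}")
    order = np.random.default_rng(np.random.SeedSequence(seed)).permutation(n)
    train_idx = np.sort(order[:n_train])
    val_idx = np.sort(order[n_train:])
    return [patients[i] for i in train_idx], [patients[i] for i in val_idx]


def write_cohort(patients: Sequence[SyntheticPatient], out_dir) -> None:
    """Persist a cohort as NIfTI volumes/masks plus an outcomes CSV."""
    from pathlib import Path

    from .io import write_mask, write_outcomes, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in patients:
        for seq, vol in p.volumes.items():
            write_volume(vol, out / f"{p.patient_id}_{seq}.nii.gz")
        for structure, mask in p.masks.items():
            spacing = next(iter(p.volumes.values())).voxel_spacing_mm
            write_mask(mask, spacing, out / f"{p.patient_id}_{structure}_mask.nii.gz")
    write_outcomes(cohort_outcomes(patients), out / "outcomes.csv")
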