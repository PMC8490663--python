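"""Synthetic test universe: phantom template, atlas bundle, tumors, cohorts.

Everything downstream of image acquisition can be exercised without any
real data: a small RAS+ template centered on the world origin, mirrored
cuboid parcels for each panel structure, Gaussian-profile tract probability
maps whose above-threshold volume is known analytically, ellipsoid tumors
digitized on voxel centers, and cohorts whose clinical covariates follow
configurable group effects.

The phantom is a scaled-down head: a 64 mm cube rather than a 180 mm brain,
with parcels and tumors shrunk accordingly. Ground-truth proximity flags are
computed from the generating geometry (analytic ellipsoid membership against
the stored label/probability arrays) independently of the overlap engine, so
the engine can be validated end-to-end against construction truth.

Determinism: one integer seed drives every draw through a single named
generator; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .atlas import AnalysisConfig, AtlasBundle, default_eloquence_panel
from .grids import BinaryMask, LabelVolume, ProbabilityVolume, VolumeGrid
from .overlap import ANY_ELOQUENT_LABEL

__all__ = [
    "SyntheticCohortSpec",
    "SimulatedCohort",
    "make_template_and_atlas",
    "make_ellipsoid_tumor",
    "simulate_cohort",
]

log = logging.getLogger(__name__)

# (y, z) slot centers in mm for the nine parcel structures; x = ±_PARCEL_X
# (left negative in RAS+), cuboid half-width _PARCEL_HALF.
_PARCEL_SLOTS: dict[str, tuple[float, float]] = {
    "Precentral cortex": (-18.0, 18.0),
    "Postcentral cortex": (0.0, 18.0),
    "Pericalcarine": (18.0, 18.0),
    "Hippocampus": (-18.0, 0.0),
    "Para hippocampal area": (0.0, 0.0),
    "Supramarginal": (18.0, 0.0),
    "Pars Triangularis": (-18.0, -18.0),
    "Pars Opercularis": (0.0, -18.0),
    "Inferior parietal": (18.0, -18.0),
}
_PARCEL_X = 14.0
_PARCEL_HALF = 4.0

# (y, z) blob centers for the tract maps; lateralized at x = ±_TRACT_X.
_TRACT_SLOTS: dict[str, tuple[float, float]] = {
    "CS": (-9.0, 9.0),
    "OR": (9.0, 9.0),
    "IFOF": (-9.0, -9.0),
    "SLF": (9.0, -9.0),
    "AF": (0.0, 26.0),
}
_TRACT_X = 14.0
_TRACT_SIGMA = 4.0  # mm; the p > 0.5 ball has radius sigma * sqrt(2 ln 2)


def make_template_and_atlas(
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: float = 1.0,
) -> AtlasBundle:
    """Build a self-consistent phantom atlas bundle.

    The grid is RAS+ and centered on the world origin. Each of the nine
    parcel structures gets a left and a right cuboid, mirror-symmetric in x
    (left at negative x); the five tracts get Gaussian blobs with peak 1.0
    (bilateral for CS and OR, left-only for SLF, AF, IFOF). Labels 1–9 are
    left structures, 101–109 their right mirrors.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 32 for s in shape):
        raise ValueError(f"shape must be ≥ (32, 32, 32), got {shape}")
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = -spacing * (np.asarray(shape) - 1) / 2.0
    template = VolumeGrid(np.zeros(shape, dtype=np.float32), affine)
    centers = template.voxel_centers_world()
    x, y, z = centers[..., 0], centers[..., 1], centers[..., 2]

    labels = np.zeros(shape, dtype=np.int32)
    label_table: dict[int, tuple[str, str]] = {}
    for idx, (name, (cy, cz)) in enumerate(_PARCEL_SLOTS.items(), start=1):
        for hemi, label_id in (("left", idx), ("right", 100 + idx)):
            cx = -_PARCEL_X if hemi == "left" else _PARCEL_X
            sel = (
                (np.abs(x - cx) <= _PARCEL_HALF)
                & (np.abs(y - cy) <= _PARCEL_HALF)
                & (np.abs(z - cz) <= _PARCEL_HALF)
            )
            labels[sel] = label_id
            label_table[label_id] = (name, hemi)

    tracts: dict[str, ProbabilityVolume] = {}
    for name, (cy, cz) in _TRACT_SLOTS.items():
        hemis = ("left", "right") if name in ("CS", "OR") else ("left",)
        for hemi in hemis:
            cx = -_TRACT_X if hemi == "left" else _TRACT_X
            r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
            prob = np.exp(-r2 / (2.0 * _TRACT_SIGMA**2)).astype(np.float32)
            tracts[f"{name}_{hemi}"] = ProbabilityVolume(
                grid=VolumeGrid(prob, affine)
            )

    panel = default_eloquence_panel(label_table)
    bundle = AtlasBundle(
        template=template,
        labels=LabelVolume(grid=VolumeGrid(labels, affine)),
        label_table=label_table,
        tracts=tracts,
        regions=tuple(panel),
    )
    bundle.validate()
    return bundle


def make_ellipsoid_tumor(
    center_mm: tuple[float, float, float],
    semi_axes_mm: tuple[float, float, float],
    template: VolumeGrid,
) -> BinaryMask:
    """Digitize an axis-aligned ellipsoid on the template's voxel centers.

    A voxel belongs to the tumor when its center satisfies
    Σ ((w_i − c_i)/s_i)² ≤ 1. Deterministic; an ellipsoid that misses every
    voxel center yields an empty mask with a warning.
    """
    semi = np.asarray(semi_axes_mm, dtype=float)
    if np.any(semi <= 0):
        raise ValueError("semi-axes must be positive")
    centers = template.voxel_centers_world()
    delta = (centers - np.asarray(center_mm, dtype=float)) / semi
    inside = (delta**2).sum(axis=-1) <= 1.0
    if not inside.any():
        log.warning("ellipsoid at %s intersects no voxel center", center_mm)
    return BinaryMask(
        grid=VolumeGrid(inside.astype(np.uint8), template.affine)
    )


def _default_groups() -> dict[str, int]:
    # cohort composition of the emulated study population
    return {
        "IDH-wt astrocytoma": 82,
        "IDH-mut astrocytoma": 67,
        "Oligodendroglioma": 73,
        "Not characterized": 55,
    }


def _default_bias() -> dict[str, dict[str, float]]:
    # per-group probability that a tumor is seeded inside the named panel
    # region; mirrors the published biological gradient (most eloquent
    # involvement in IDH wild-type astrocytoma, least in oligodendroglioma)
    return {
        "IDH-wt astrocytoma": {"Hippocampus left": 0.30, "OR left": 0.20,
                               "CS left": 0.15},
        "IDH-mut astrocytoma": {"Hippocampus left": 0.15, "CS left": 0.15,
                                "Precentral cortex left": 0.10},
        "Oligodendroglioma": {"Precentral cortex left": 0.10, "CS left": 0.10},
        "Not characterized": {"CS left": 0.10, "Hippocampus left": 0.10},
    }


def _default_kps() -> dict[str, dict[int, float]]:
    # per-group KPS distributions; P(KPS < 90) ≈ 0.49 / 0.33 / 0.29 / 0.35
    return {
        "IDH-wt astrocytoma": {60: 0.07, 70: 0.14, 80: 0.28, 90: 0.36, 100: 0.15},
        "IDH-mut astrocytoma": {70: 0.08, 80: 0.25, 90: 0.45, 100: 0.22},
        "Oligodendroglioma": {70: 0.07, 80: 0.22, 90: 0.41, 100: 0.30},
        "Not characterized": {70: 0.10, 80: 0.25, 90: 0.45, 100: 0.20},
    }


_AGE_MODEL = {
    "IDH-wt astrocytoma": (52.0, 12.0),
    "IDH-mut astrocytoma": (40.3, 11.0),
    "Oligodendroglioma": (45.6, 12.0),
    "Not characterized": (45.0, 13.0),
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generating parameters of a simulated cohort.

    ``biopsy_model`` is (β₀, β₁) for P(biopsy) = expit(β₀ + β₁·any_eloquent);
    ``presumed_given_voxel`` gives P(clinician-presumed eloquent | voxel-based
    eloquence true / false). ``seed`` is mandatory.
    """

    seed: int
    n_per_group: dict[str, int] = field(default_factory=_default_groups)
    group_location_bias: dict[str, dict[str, float]] = field(
        default_factory=_default_bias
    )
    tumor_radius_range: tuple[float, float] = (5.0, 12.0)
    biopsy_model: tuple[float, float] = (-2.6, 1.4)
    kps_model: dict[str, dict[int, float]] = field(default_factory=_default_kps)
    presumed_given_voxel: tuple[float, float] = (0.75, 0.20)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.tumor_radius_range
        if not 0 < lo <= hi:
            raise ValueError("tumor radii must be positive and ordered")
        for group, biases in self.group_location_bias.items():
            for region, p in biases.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"bias for {region!r} in {group!r} must be in [0, 1]"
                    )
        for group, dist in self.kps_model.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"KPS probabilities for {group!r} must sum to 1")


@dataclass(frozen=True)
class SimulatedCohort:
    """Masks, clinical table, and construction ground truth for one draw."""

    masks: dict[str, BinaryMask]
    clinical: pd.DataFrame
    truth: pd.DataFrame  # patient_id, region, overlap_mm3, proximal
    spec: SyntheticCohortSpec

    def true_any_eloquent(self, patient_id: str) -> bool:
        sel = (self.truth["patient_id"] == patient_id) & (
            self.truth["region"] == ANY_ELOQUENT_LABEL
        )
        return bool(self.truth.loc[sel, "proximal"].iloc[0])


def _region_members(atlas: AtlasBundle, config: AnalysisConfig) -> dict[str, np.ndarray]:
    """Boolean membership array per panel region, straight from the stored
    label/probability arrays (independent of the overlap engine)."""
    members = {}
    for region in atlas.regions:
        if region.kind == "parcellation":
            sel = np.isin(atlas.labels.data, sorted(region.label_ids))
        else:
            sel = atlas.tracts[region.tract_map_key].data > (
                config.tract_probability_threshold
            )
        members[region.display_name] = sel
    return members


def _region_center(atlas: AtlasBundle, display_name: str) -> np.ndarray:
    region = next(r for r in atlas.regions if r.display_name == display_name)
    if region.kind == "parcellation":
        sel = np.isin(atlas.labels.data, sorted(region.label_ids))
        centers = atlas.template.voxel_centers_world()
        return centers[sel].mean(axis=0)
    # Gaussian tract: its peak voxel is its center
    prob = atlas.tracts[region.tract_map_key].data
    idx = np.unravel_index(int(np.argmax(prob)), prob.shape)
    centers = atlas.template.voxel_centers_world()
    return centers[idx]


def simulate_cohort(
    spec: SyntheticCohortSpec,
    atlas: AtlasBundle,
    config: AnalysisConfig | None = None,
) -> SimulatedCohort:
    """Draw a cohort of ellipsoid tumors with clinical covariates.

    For each patient a seeding site is chosen (inside a biased panel region,
    or uniformly in the central field of view), an ellipsoid tumor is
    digitized there, and per-region ground-truth overlap volumes and
    proximity flags are computed analytically from the generating geometry.
    The surgical strategy is drawn from the stated logistic model on the
    true any-eloquent flag, and KPS from the stated per-group distributions.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(spec.seed)
    centers = atlas.template.voxel_centers_world()
    members = _region_members(atlas, config)
    voxvol = atlas.template.voxel_volume_mm3
    extent = np.abs(atlas.template.affine[:3, 3]).min()
    seed_box = 0.65 * extent

    masks: dict[str, BinaryMask] = {}
    clinical_rows = []
    truth_rows = []
    beta0, beta1 = spec.biopsy_model
    p_presumed_pos, p_presumed_neg = spec.presumed_given_voxel
    counter = 0
    for group, n in spec.n_per_group.items():
        biases = spec.group_location_bias.get(group, {})
        kps_dist = spec.kps_model.get(
            group, {70: 0.10, 80: 0.25, 90: 0.45, 100: 0.20}
        )
        kps_values = sorted(kps_dist)
        kps_probs = [kps_dist[v] for v in kps_values]
        age_mu, age_sd = _AGE_MODEL.get(group, (45.0, 13.0))
        for _ in range(n):
            counter += 1
            pid = f"P{counter:04d}"
            target = None
            for region_name, p in biases.items():
                if rng.random() < p:
                    target = region_name
                    break
            if target is not None:
                center = _region_center(atlas, target) + rng.normal(0.0, 2.0, 3)
            else:
                center = rng.uniform(-seed_box, seed_box, 3)
            semi = rng.uniform(*spec.tumor_radius_range, 3)
            delta = (centers - center) / semi
            inside = (delta**2).sum(axis=-1) <= 1.0
            masks[pid] = BinaryMask(
                grid=VolumeGrid(inside.astype(np.uint8), atlas.template.affine)
            )
            any_true = False
            for region in atlas.regions:
                ov = float(
                    np.count_nonzero(members[region.display_name] & inside) * voxvol
                )
                prox = ov >= config.overlap_threshold_mm3
                any_true = any_true or prox
                truth_rows.append(
                    {"patient_id": pid, "region": region.display_name,
                     "overlap_mm3": ov, "proximal": prox}
                )
            truth_rows.append(
                {"patient_id": pid, "region": ANY_ELOQUENT_LABEL,
                 "overlap_mm3": float("nan"), "proximal": any_true}
            )
            biopsy = rng.random() < expit(beta0 + beta1 * any_true)
            presumed = rng.random() < (
                p_presumed_pos if any_true else p_presumed_neg
            )
            kps = int(rng.choice(kps_values, p=kps_probs))
            age = int(np.clip(round(rng.normal(age_mu, age_sd)), 18, 90))
            clinical_rows.append(
                {
                    "patient_id": pid,
                    "age": age,
                    "kps": kps,
                    "surgery": "biopsy" if biopsy else "resection",
                    "presumed_eloquent": bool(presumed),
                    "molecular_subgroup": group,
                    "who_grade": int(rng.choice([2, 3], p=[0.66, 0.34])),
                }
            )
    return SimulatedCohort(
        masks=masks,
        clinical=pd.DataFrame(clinical_rows),
        truth=pd.DataFrame(truth_rows),
        spec=spec,
    )
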