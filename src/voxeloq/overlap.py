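"""Per-patient tumor/region overlap volumes and proximity flags.

The core quantity is the physical overlap between a tumor segmentation and a
region mask, both on the template grid: intersection voxel count times voxel
volume, in mm³. A region is "in proximity" when the overlap meets the
configured minimum volume (default 1 mm³, inclusive; the 10 mm³ setting is
the published sensitivity analysis). A patient is voxel-based eloquent when
any panel region is proximal.

Overlap volumes are always reported on the template grid's voxel metric,
never back-projected to native space. Multifocal tumors are used whole: all
foreground components enter the overlap computation (a log line notes
multi-component masks); largest-component selection belongs to lobe
taxonomy, not to the voxel analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ._errors import GeometryError
from .atlas import AnalysisConfig, AtlasBundle, region_mask
from .grids import BinaryMask, mask_volume_mm3, voxel_volume_mm3

__all__ = [
    "OverlapRecord",
    "PatientProfile",
    "overlap_volume",
    "proximity_flag",
    "profile_patient",
    "cohort_proximity_table",
    "profiles_to_frame",
    "round_half_up",
    "format_count_percent",
    "ANY_ELOQUENT_LABEL",
]

log = logging.getLogger(__name__)

ANY_ELOQUENT_LABEL = "Any voxel-based eloquent region"


@dataclass(frozen=True)
class OverlapRecord:
    patient_id: str
    region_name: str
    overlap_mm3: float
    tumor_mm3: float
    region_mm3: float
    proximal: bool


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    records: tuple[OverlapRecord, ...]

    @property
    def any_eloquent(self) -> bool:
        return any(r.proximal for r in self.records)


def overlap_volume(tumor: BinaryMask, region: BinaryMask) -> float:
    """Physical intersection volume of two masks on the same grid, mm³."""
    if tumor.grid.shape != region.grid.shape or not np.allclose(
        tumor.affine, region.affine, atol=1e-4
    ):
        raise GeometryError("tumor and region masks are not on the same grid")
    n = int(np.count_nonzero(np.logical_and(tumor.data, region.data)))
    return n * voxel_volume_mm3(tumor)


def proximity_flag(overlap_mm3: float, config: AnalysisConfig | None = None) -> bool:
    """True when the overlap meets the minimum volume (inclusive)."""
    config = config or AnalysisConfig()
    if overlap_mm3 < 0:
        raise ValueError("overlap volume cannot be negative")
    return overlap_mm3 >= config.overlap_threshold_mm3


def profile_patient(
    patient_id: str,
    tumor: BinaryMask,
    atlas: AtlasBundle,
    config: AnalysisConfig | None = None,
) -> PatientProfile:
    """Overlap record for every panel region, in panel order.

    All panel regions appear even when their overlap is zero.
    """
    config = config or AnalysisConfig()
    if tumor.grid.shape != atlas.template.shape or not np.allclose(
        tumor.affine, atlas.template.affine, atol=1e-4
    ):
        raise GeometryError("tumor mask is not on the template grid")
    n_components = ndimage.label(tumor.data)[1]
    if n_components > 1:
        log.info("patient %s: tumor mask has %d components; using all",
                 patient_id, n_components)
    tumor_mm3 = mask_volume_mm3(tumor)
    records = []
    for region in atlas.regions:
        rmask = region_mask(atlas, region, config)
        ov = overlap_volume(tumor, rmask)
        records.append(
            OverlapRecord(
                patient_id=patient_id,
                region_name=region.display_name,
                overlap_mm3=ov,
                tumor_mm3=tumor_mm3,
                region_mm3=mask_volume_mm3(rmask),
                proximal=proximity_flag(ov, config),
            )
        )
    return PatientProfile(patient_id=patient_id, records=tuple(records))


def profiles_to_frame(profiles: Sequence[PatientProfile]) -> pd.DataFrame:
    """Long-format table: patient_id, region, overlap_mm3, tumor_mm3,
    region_mm3, proximal."""
    rows = []
    for p in profiles:
        for r in p.records:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "region": r.region_name,
                    "overlap_mm3": r.overlap_mm3,
                    "tumor_mm3": r.tumor_mm3,
                    "region_mm3": r.region_mm3,
                    "proximal": bool(r.proximal),
                }
            )
        rows.append(
            {
                "patient_id": p.patient_id,
                "region": ANY_ELOQUENT_LABEL,
                "overlap_mm3": float("nan"),
                "tumor_mm3": (
                    p.records[0].tumor_mm3 if p.records else float("nan")
                ),
                "region_mm3": float("nan"),
                "proximal": bool(p.any_eloquent),
            }
        )
    return pd.DataFrame(rows)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention used by the cohort tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_count_percent(count: int, group_size: int) -> str:
    """Table-style cell, e.g. 108 of 277 → ``'108 (39.0)'``."""
    pct = round_half_up(100.0 * count / group_size, 1)
    return f"{count} ({pct:.1f})"


def cohort_proximity_table(
    profiles: Sequence[PatientProfile],
    grouping: Mapping[str, str] | Callable[[str], str],
) -> pd.DataFrame:
    """Per-region, per-group proximity counts and percentages.

    Rows follow panel order with the any-eloquent summary row first (the
    layout used for group-comparison tables); columns: region, group,
    group_size, count, percent, formatted.
    """
    get_group = grouping if callable(grouping) else grouping.__getitem__
    groups: dict[str, list[PatientProfile]] = {}
    for p in profiles:
        groups.setdefault(get_group(p.patient_id), []).append(p)
    if not profiles:
        raise ValueError("no profiles given")
    region_order = [ANY_ELOQUENT_LABEL] + [
        r.region_name for r in profiles[0].records
    ]
    rows = []
    for gname in groups:
        members = groups[gname]
        n = len(members)
        flags: dict[str, int] = {ANY_ELOQUENT_LABEL: sum(
            p.any_eloquent for p in members
        )}
        for p in members:
            for r in p.records:
                flags[r.region_name] = flags.get(r.region_name, 0) + int(r.proximal)
        for region in region_order:
            count = flags.get(region, 0)
            rows.append(
                {
                    "region": region,
                    "group": gname,
                    "group_size": n,
                    "count": count,
                    "percent": round_half_up(100.0 * count / n, 1),
                    "formatted": format_count_percent(count, n),
                }
            )
    df = pd.DataFrame(rows)
    df["region"] = pd.Categorical(df["region"], categories=region_order, ordered=True)
    return df.sort_values(["region", "group"], ignore_index=True)
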