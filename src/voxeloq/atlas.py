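"""Atlas bundle: parcellation, tract probability maps, and the eloquence panel.

The default panel holds the 21 regions of traditional neurosurgical interest
used for voxel-based eloquence in lower-grade glioma: nine cortical /
subcortical parcellation structures and five white-matter tracts. Seven of
the fourteen structures are analyzed on the left side only, because their
role in language is most often left-lateralized (supramarginal, pars
triangularis, pars opercularis, inferior parietal, SLF, AF, IFOF); the rest
are taken bilaterally (precentral, postcentral, pericalcarine, hippocampus,
parahippocampal, corticospinal tract, optic radiations).

A tract is present in a voxel when its atlas probability is strictly above
the configured threshold (default 0.5). Hemisphere assignment comes from the
parcellation's own label table, never from the sign of world x; a validation
pass cross-checks each labeled structure's centroid against its annotation
and warns on disagreement (in RAS+ world coordinates the left hemisphere
lies at negative x).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._errors import ConfigurationError, GeometryError
from .grids import (
    BinaryMask,
    LabelVolume,
    ProbabilityVolume,
    VolumeGrid,
    read_volume,
)

__all__ = [
    "RegionDefinition",
    "AtlasBundle",
    "AnalysisConfig",
    "default_eloquence_panel",
    "load_panel",
    "save_panel",
    "load_atlas_bundle",
    "region_mask",
    "SHORT_LABELS",
]

log = logging.getLogger(__name__)

PARCELLATION = "parcellation"
TRACT = "tract"
BOTH_SIDES = "both_sides"
LEFT_ONLY = "left_only"

#: Figure-legend short labels for each canonical region name.
SHORT_LABELS: dict[str, str] = {
    "Precentral cortex": "PreC",
    "Postcentral cortex": "PostC",
    "Pericalcarine": "PeriCal",
    "Hippocampus": "Hipp",
    "Para hippocampal area": "ParaHipp",
    "Supramarginal": "SupMarg",
    "Pars Triangularis": "ParsTri",
    "Pars Opercularis": "ParsOp",
    "Inferior parietal": "InfPar",
    "CS": "CS",
    "OR": "OR",
    "IFOF": "IFOF",
    "SLF": "SLF",
    "AF": "AF",
}

# Editorial default mapping from clinical region names to atlas structure
# names (CerebrA-style); label ids are resolved against the bundle's own
# label table, never hard-coded, so the panel survives atlas re-releases.
_ATLAS_NAME_SYNONYMS: dict[str, tuple[str, ...]] = {
    "Precentral cortex": ("precentral cortex", "precentral gyrus", "precentral"),
    "Postcentral cortex": ("postcentral cortex", "postcentral gyrus", "postcentral"),
    "Pericalcarine": ("pericalcarine", "pericalcarine cortex", "calcarine"),
    "Hippocampus": ("hippocampus",),
    "Para hippocampal area": (
        "para hippocampal area",
        "parahippocampal gyrus",
        "parahippocampal",
    ),
    "Supramarginal": ("supramarginal", "supramarginal gyrus"),
    "Pars Triangularis": ("pars triangularis",),
    "Pars Opercularis": ("pars opercularis",),
    "Inferior parietal": ("inferior parietal", "inferior parietal lobule"),
}


@dataclass(frozen=True)
class RegionDefinition:
    """One entry of the eloquence panel.

    Parcellation regions are defined by atlas structure names (resolved to
    concrete label ids against a bundle's label table via :meth:`bind`);
    tract regions name exactly one probability map.
    """

    name: str
    kind: str  # parcellation | tract
    hemisphere: str  # left | right
    eloquent_when: str  # both_sides | left_only
    atlas_names: tuple[str, ...] = ()
    label_ids: frozenset[int] = frozenset()
    tract_map_key: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (PARCELLATION, TRACT):
            raise ConfigurationError(f"unknown region kind {self.kind!r}")
        if self.hemisphere not in ("left", "right"):
            raise ConfigurationError(f"unknown hemisphere {self.hemisphere!r}")
        if self.eloquent_when not in (BOTH_SIDES, LEFT_ONLY):
            raise ConfigurationError(f"unknown eloquent_when {self.eloquent_when!r}")
        if self.kind == TRACT and not self.tract_map_key:
            raise ConfigurationError(f"tract region {self.name!r} names no map")

    @property
    def display_name(self) -> str:
        """Row label as printed in cohort tables, e.g. ``'CS left'``."""
        return f"{self.name} {self.hemisphere}"

    @property
    def short_label(self) -> str:
        """Figure-legend label with L/R suffix, e.g. ``'CS L'``."""
        return f"{SHORT_LABELS[self.name]} {self.hemisphere[0].upper()}"

    def bind(self, label_table: Mapping[int, tuple[str, str]]) -> "RegionDefinition":
        """Resolve atlas structure names to label ids for this hemisphere."""
        if self.kind != PARCELLATION:
            return self
        wanted = tuple(s.lower() for s in (self.atlas_names or ()))
        if not wanted:
            wanted = tuple(
                s.lower() for s in _ATLAS_NAME_SYNONYMS.get(self.name, (self.name,))
            )
        ids = set()
        for label_id, (label_name, hemi) in label_table.items():
            if hemi.lower() != self.hemisphere:
                continue
            norm = label_name.strip().lower()
            if any(norm == w or w in norm for w in wanted):
                ids.add(int(label_id))
        if not ids:
            raise ConfigurationError(
                f"panel region {self.display_name!r}: no label in the label "
                f"table matches any of {wanted}"
            )
        return replace(self, label_ids=frozenset(ids))


def _panel_entries() -> list[tuple[str, str, str, str]]:
    # (name, kind, hemisphere, eloquent_when) in cohort-table row order
    entries: list[tuple[str, str, str, str]] = []
    for name in ("Precentral cortex", "Postcentral cortex", "Pericalcarine",
                 "Hippocampus", "Para hippocampal area"):
        entries.append((name, PARCELLATION, "left", BOTH_SIDES))
        entries.append((name, PARCELLATION, "right", BOTH_SIDES))
    for name in ("Supramarginal", "Pars Triangularis", "Pars Opercularis",
                 "Inferior parietal"):
        entries.append((name, PARCELLATION, "left", LEFT_ONLY))
    entries.append(("CS", TRACT, "left", BOTH_SIDES))
    entries.append(("CS", TRACT, "right", BOTH_SIDES))
    entries.append(("OR", TRACT, "left", BOTH_SIDES))
    entries.append(("OR", TRACT, "right", BOTH_SIDES))
    entries.append(("IFOF", TRACT, "left", LEFT_ONLY))
    entries.append(("SLF", TRACT, "left", LEFT_ONLY))
    entries.append(("AF", TRACT, "left", LEFT_ONLY))
    return entries


def default_eloquence_panel(
    label_table: Mapping[int, tuple[str, str]] | None = None,
) -> list[RegionDefinition]:
    """The 21-region eloquence panel in cohort-table row order.

    Fourteen regions belong to bilateral pairs and seven are left-only.
    When a label table is given, parcellation regions are bound to concrete
    label ids; otherwise they stay name-based until a bundle binds them.
    """
    panel = []
    for name, kind, hemi, when in _panel_entries():
        region = RegionDefinition(
            name=name,
            kind=kind,
            hemisphere=hemi,
            eloquent_when=when,
            tract_map_key=f"{name}_{hemi}" if kind == TRACT else "",
        )
        if label_table is not None and kind == PARCELLATION:
            region = region.bind(label_table)
        panel.append(region)
    return panel


@dataclass(frozen=True)
class AnalysisConfig:
    """Every analysis tunable, with its published default.

    overlap_threshold_mm3: minimum tumor/region overlap (inclusive) counted
    as proximity; tract_probability_threshold: strict lower bound for tract
    presence in a voxel; alpha: multiplicity-adjusted significance level
    (inclusive, p ≤ alpha); kps_cutoff: Karnofsky scores below this count as
    impaired performance status.
    """

    overlap_threshold_mm3: float = 1.0
    tract_probability_threshold: float = 0.5
    alpha: float = 0.002
    kps_cutoff: int = 90

    def __post_init__(self) -> None:
        if not self.overlap_threshold_mm3 > 0:
            raise ConfigurationError("overlap_threshold_mm3 must be > 0")
        if not 0 < self.tract_probability_threshold < 1:
            raise ConfigurationError("tract_probability_threshold must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class AtlasBundle:
    """Template grid + parcellation + label table + tract maps + panel."""

    template: VolumeGrid
    labels: LabelVolume
    label_table: dict[int, tuple[str, str]]
    tracts: dict[str, ProbabilityVolume]
    regions: tuple[RegionDefinition, ...] = field(default_factory=tuple)

    def validate(self, atol: float = 1e-4) -> list[str]:
        """Check grid congruence and panel references; return warnings.

        Congruence violations and dangling references are hard errors;
        centroid/hemisphere disagreements are returned as warnings.
        """
        for name, grid in [("labels", self.labels.grid)] + [
            (f"tract {k!r}", t.grid) for k, t in self.tracts.items()
        ]:
            if grid.shape != self.template.shape or not np.allclose(
                grid.affine, self.template.affine, atol=atol
            ):
                raise GeometryError(
                    f"{name} grid is not congruent with the template: "
                    f"affine\n{grid.affine}\nvs template affine\n"
                    f"{self.template.affine}"
                )
        present = set(np.unique(self.labels.data).tolist()) - {0}
        for region in self.regions:
            if region.kind == PARCELLATION:
                missing = [i for i in region.label_ids if i not in self.label_table]
                if missing:
                    raise ConfigurationError(
                        f"panel region {region.display_name!r} references label "
                        f"ids {sorted(missing)} absent from the label table"
                    )
            else:
                if region.tract_map_key not in self.tracts:
                    raise ConfigurationError(
                        f"panel region {region.display_name!r} references tract "
                        f"map {region.tract_map_key!r} which is not in the bundle"
                    )
        warnings: list[str] = []
        centers = None
        for label_id, (name, hemi) in sorted(self.label_table.items()):
            if label_id not in present:
                continue
            if centers is None:
                centers = self.template.voxel_centers_world()
            x_mean = float(centers[self.labels.data == label_id, 0].mean())
            # RAS+: left hemisphere lies at negative world x
            expected_neg = hemi.lower() == "left"
            if (x_mean < 0) != expected_neg:
                msg = (
                    f"label {label_id} ({name!r}, {hemi}) has centroid "
                    f"x = {x_mean:.1f} mm, inconsistent with its hemisphere "
                    "annotation"
                )
                warnings.append(msg)
                log.warning(msg)
        return warnings


def load_panel(path: str | Path) -> list[RegionDefinition]:
    """Read a panel file: CSV with columns
    name,kind,hemisphere,eloquent_when,atlas_names,tract_key
    (atlas_names is ';'-separated, empty for tract regions)."""
    panel = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            panel.append(
                RegionDefinition(
                    name=row["name"],
                    kind=row["kind"],
                    hemisphere=row["hemisphere"],
                    eloquent_when=row["eloquent_when"],
                    atlas_names=tuple(
                        s for s in row.get("atlas_names", "").split(";") if s
                    ),
                    tract_map_key=row.get("tract_key", ""),
                )
            )
    return panel


def save_panel(panel: Sequence[RegionDefinition], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["name", "kind", "hemisphere", "eloquent_when", "atlas_names", "tract_key"]
        )
        for r in panel:
            writer.writerow(
                [r.name, r.kind, r.hemisphere, r.eloquent_when,
                 ";".join(r.atlas_names), r.tract_map_key]
            )
    return path


def _read_label_table(path: str | Path) -> dict[int, tuple[str, str]]:
    table: dict[int, tuple[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            table[int(row["id"])] = (row["name"], row["hemisphere"])
    return table


def load_atlas_bundle(
    template_path: str | Path,
    labels_path: str | Path,
    label_table_path: str | Path,
    tract_paths: Mapping[str, str | Path],
    panel_path: str | Path | None = None,
) -> AtlasBundle:
    """Load and validate an atlas bundle from disk.

    All grids must be congruent (identical shape, affines within 1e-4 mm);
    violations are hard errors. Panel regions are bound to label ids from the
    label table.
    """
    template = read_volume(template_path)
    labels = LabelVolume(grid=read_volume(labels_path))
    label_table = _read_label_table(label_table_path)
    tracts = {
        key: ProbabilityVolume(grid=read_volume(p)) for key, p in tract_paths.items()
    }
    panel = load_panel(panel_path) if panel_path else default_eloquence_panel()
    bound = tuple(r.bind(label_table) for r in panel)
    bundle = AtlasBundle(
        template=template,
        labels=labels,
        label_table=label_table,
        tracts=tracts,
        regions=bound,
    )
    bundle.validate()
    return bundle


def save_atlas_bundle(bundle: AtlasBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle to a directory in the standard on-disk layout.

    template.nii.gz, labels.nii.gz, label_table.csv, panel.csv and one
    tracts/<key>.nii.gz per probability map; the returned mapping can be fed
    back to :func:`load_atlas_bundle`.
    """
    from .grids import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tracts").mkdir(exist_ok=True)
    paths: dict[str, Path] = {
        "template": write_volume(bundle.template, out / "template.nii.gz"),
        "labels": write_volume(bundle.labels, out / "labels.nii.gz"),
    }
    table_path = out / "label_table.csv"
    with open(table_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "name", "hemisphere"])
        for label_id, (name, hemi) in sorted(bundle.label_table.items()):
            writer.writerow([label_id, name, hemi])
    paths["label_table"] = table_path
    paths["panel"] = save_panel(bundle.regions, out / "panel.csv")
    for key, tract in bundle.tracts.items():
        paths[f"tract:{key}"] = write_volume(tract, out / "tracts" / f"{key}.nii.gz")
    return paths


def load_atlas_bundle_dir(bundle_dir: str | Path) -> AtlasBundle:
    """Load a bundle from the directory layout written by
    :func:`save_atlas_bundle`."""
    d = Path(bundle_dir)
    tract_paths = {p.name.split(".nii")[0]: p for p in sorted((d / "tracts").glob("*.nii*"))}
    return load_atlas_bundle(
        d / "template.nii.gz",
        d / "labels.nii.gz",
        d / "label_table.csv",
        tract_paths,
        panel_path=d / "panel.csv" if (d / "panel.csv").exists() else None,
    )


def region_mask(
    atlas: AtlasBundle,
    region: RegionDefinition,
    config: AnalysisConfig | None = None,
) -> BinaryMask:
    """Binary mask of one panel region on the template grid.

    Parcellation regions select voxels whose label is in the region's id set;
    tract regions select voxels with probability strictly above the
    configured threshold.
    """
    config = config or AnalysisConfig()
    if region.kind == PARCELLATION:
        if not region.label_ids:
            region = region.bind(atlas.label_table)
        sel = np.isin(atlas.labels.data, sorted(region.label_ids))
    else:
        tract = atlas.tracts[region.tract_map_key]
        sel = tract.data > config.tract_probability_threshold
    return BinaryMask(
        grid=VolumeGrid(sel.astype(np.uint8), atlas.template.affine)
    )
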