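"""Lesion connected components, location rules and per-lesion features.

Lesions are taken as connected components of a binary mask (26-connectivity
by default) and classified by overlap with an anatomical region atlas, in
this precedence order:

1. periventricular — more than 5% of the lesion volume in direct contact
   with the lateral ventricles (contact = within a 1-voxel, 26-neighborhood
   dilation of the ventricle mask, since such lesions abut rather than
   overlap CSF);
2. juxtacortical — more than 20% of the volume touching or within cortex;
3. infratentorial — more than 50% of the volume in brainstem + cerebellum
   jointly (sub-labelled by the larger share);
4. deep white matter otherwise.

Components smaller than 27 mm^3 are excluded from feature tables.  All masks
and maps must share one voxel grid; no resampling happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LOCATIONS",
    "Thresholds",
    "RegionAtlas",
    "LesionComponent",
    "label_components",
    "classify_location",
    "summarize_lesions",
]

LOCATIONS = ("periventricular", "juxtacortical", "infratentorial", "deep_wm")

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class Thresholds:
    """Location rule thresholds (strict inequalities) and size filter."""

    periventricular: float = 0.05
    juxtacortical: float = 0.20
    infratentorial: float = 0.50
    min_volume_mm3: float = 27.0


@dataclass
class RegionAtlas:
    """Binary region masks sharing one grid with the lesion volume."""

    ventricles: np.ndarray
    cortex: np.ndarray
    brainstem: np.ndarray
    cerebellum: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        shapes = {m.shape for m in (self.ventricles, self.cortex, self.brainstem, self.cerebellum)}
        if len(shapes) != 1:
            raise ValueError("atlas masks must share one grid")
        self.ventricles = np.asarray(self.ventricles, dtype=bool)
        self.cortex = np.asarray(self.cortex, dtype=bool)
        self.brainstem = np.asarray(self.brainstem, dtype=bool)
        self.cerebellum = np.asarray(self.cerebellum, dtype=bool)

    @property
    def shape(self):
        return self.ventricles.shape

    def ventricle_contact_zone(self) -> np.ndarray:
        """Ventricle mask dilated by one voxel (26-neighborhood)."""
        return ndimage.binary_dilation(self.ventricles, structure=_STRUCT26)


@dataclass
class LesionComponent:
    id: int
    indices: tuple[np.ndarray, np.ndarray, np.ndarray]
    volume_mm3: float
    location: str | None = None
    sublocation: str | None = None
    overlap: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return len(self.indices[0])


def label_components(
    lesion_mask: np.ndarray,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    connectivity: int = 26,
) -> list[LesionComponent]:
    """Connected components of a binary 3-D mask with their volumes."""
    mask = np.asarray(lesion_mask)
    if mask.ndim != 3:
        raise ValueError("lesion mask must be 3-D")
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("lesion mask must be binary (0/1)")
    if connectivity == 26:
        structure = _STRUCT26
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    labels, n = ndimage.label(mask.astype(bool), structure=structure)
    voxel_vol = float(np.prod(voxel_size))
    out = []
    for comp_id in range(1, n + 1):
        idx = np.nonzero(labels == comp_id)
        out.append(
            LesionComponent(
                id=comp_id, indices=idx, volume_mm3=len(idx[0]) * voxel_vol
            )
        )
    return out


def classify_location(
    component: LesionComponent,
    atlas: RegionAtlas,
    thresholds: Thresholds = Thresholds(),
    _contact_zone: np.ndarray | None = None,
) -> LesionComponent:
    """Apply the location rules in precedence order; fills ``location``,
    ``sublocation`` and ``overlap`` in place and returns the component."""
    idx = component.indices
    if any(i.max(initial=0) >= s for i, s in zip(idx, atlas.shape)):
        raise ValueError("component indices outside atlas grid")
    n = component.n_voxels
    zone = atlas.ventricle_contact_zone() if _contact_zone is None else _contact_zone
    frac_vent = float(zone[idx].sum()) / n
    frac_cortex = float(atlas.cortex[idx].sum()) / n
    frac_bs = float(atlas.brainstem[idx].sum()) / n
    frac_cb = float(atlas.cerebellum[idx].sum()) / n
    component.overlap = {
        "ventricle_contact": frac_vent,
        "cortex": frac_cortex,
        "brainstem": frac_bs,
        "cerebellum": frac_cb,
    }
    if frac_vent > thresholds.periventricular:
        component.location, component.sublocation = "periventricular", None
    elif frac_cortex > thresholds.juxtacortical:
        component.location, component.sublocation = "juxtacortical", None
    elif frac_bs + frac_cb > thresholds.infratentorial:
        component.location = "infratentorial"
        component.sublocation = "brainstem" if frac_bs >= frac_cb else "cerebellum"
    else:
        component.location, component.sublocation = "deep_wm", None
    return component


def summarize_lesions(
    components: list[LesionComponent],
    metric_maps: dict[str, np.ndarray],
    atlas: RegionAtlas | None = None,
    thresholds: Thresholds = Thresholds(),
    patient_id: str = "P000",
) -> pd.DataFrame:
    """Per-lesion feature table: one row per retained component.

    Components smaller than ``thresholds.min_volume_mm3`` are dropped (a
    27 mm^3 component is retained; only strictly smaller ones are excluded).
    Each feature is the mean of the metric map over the lesion voxels.  An
    empty result is a valid table with the full header.
    """
    metric_names = list(metric_maps)
    cols = ["patient_id", "lesion_id", "location", "volume_mm3", *metric_names]
    zone = atlas.ventricle_contact_zone() if atlas is not None else None
    rows = []
    for comp in components:
        if comp.volume_mm3 < thresholds.min_volume_mm3:
            continue
        if comp.location is None:
            if atlas is None:
                raise ValueError("components lack locations and no atlas given")
            classify_location(comp, atlas, thresholds, _contact_zone=zone)
        row = {
            "patient_id": patient_id,
            "lesion_id": comp.id,
            "location": comp.location,
            "volume_mm3": comp.volume_mm3,
        }
        for name in metric_names:
            m = np.asarray(metric_maps[name], dtype=float)
            row[name] = float(np.nanmean(m[comp.indices]))
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)
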