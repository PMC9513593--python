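"""Synthetic voxelized torso phantom.

A geometric-primitive stand-in for an anthropomorphic voxel phantom:
organ-level ellipsoids, spheres and cylinders rasterized onto a voxel
grid by voxel-centre inclusion, each carrying a tissue class from a
small attenuation/uptake table.  The default body emulates a compact
adult torso plus head on a 50 x 50 x 200 grid of 4 mm voxels, with an
FDG-like activity distribution normalized to a configurable total
activity (default 21 MBq), twenty-two spherical activity lesions
(8-12 mm diameter, contrast 2.4-24 over the host organ background)
and a catalog of 23 spherical volumes of interest used by the
quantification module.

Lesions modify activity only; attenuation is that of the host organ.
Organ overlaps are resolved by list order: later organs overwrite
earlier ones (documented priority order of the default body).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .constants import ETA_307, MU_WATER_511
from .grid import Grid

__all__ = [
    "TissueTable", "Organ", "BodySpec", "Lesion", "VOI", "Phantom",
    "tissue_mu_table", "build_phantom", "embed_lesions", "define_vois",
    "default_body_spec", "default_lesion_catalog", "default_voi_catalog",
    "save_phantom_nifti", "load_phantom_nifti",
]

TISSUE_CLASSES = ("air", "lung", "adipose", "soft_tissue", "liver",
                  "blood", "brain", "bone", "bone_marrow", "water")

#: Linear attenuation coefficients at 511 keV (mm^-1), standard
#: tissue values; editable, the table is configuration not physics.
DEFAULT_MU_511 = {
    "air": 0.0, "lung": 0.0029, "adipose": 0.0090,
    "soft_tissue": 0.0096, "liver": 0.0099, "blood": 0.0099,
    "brain": 0.0099, "bone": 0.0160, "bone_marrow": 0.0098,
    "water": MU_WATER_511,
}

#: FDG-like activity concentrations in relative units (rescaled to the
#: phantom's total activity at build time).
DEFAULT_ACTIVITY = {
    "air": 0.0, "lung": 0.5, "adipose": 0.3, "soft_tissue": 1.0,
    "liver": 2.2, "blood": 1.8, "brain": 2.5, "bone": 0.5,
    "bone_marrow": 1.3, "water": 0.0,
}


@dataclass(frozen=True)
class TissueTable:
    """Per-tissue 511/307 keV attenuation and activity concentration."""

    mu_511: dict
    mu_307: dict
    activity: dict

    def __post_init__(self):
        for t in TISSUE_CLASSES:
            for d in (self.mu_511, self.mu_307, self.activity):
                if t not in d:
                    raise KeyError(f"missing tissue entry {t!r}")
        for t in TISSUE_CLASSES:
            if self.mu_511[t] < 0 or self.mu_307[t] < 0:
                raise ValueError("attenuation coefficients must be >= 0")
            if t != "air" and self.mu_307[t] < self.mu_511[t]:
                raise ValueError(f"mu_307 < mu_511 for {t}")


def tissue_mu_table(mode: str = "eta_consistent", mu_307: Optional[dict] = None,
                    mu_511: Optional[dict] = None,
                    activity: Optional[dict] = None) -> TissueTable:
    """Build the tissue table.

    ``eta_consistent`` sets ``mu_307 = eta * mu_511`` for every tissue
    (the model-matched mode); ``independent`` takes a user-supplied
    per-tissue 307 keV column for model-mismatch studies.
    """
    mu511 = dict(DEFAULT_MU_511 if mu_511 is None else mu_511)
    act = dict(DEFAULT_ACTIVITY if activity is None else activity)
    if mode == "eta_consistent":
        mu307 = {t: ETA_307 * v for t, v in mu511.items()}
    elif mode == "independent":
        if mu_307 is None:
            raise ValueError("independent mode requires a mu_307 column")
        mu307 = dict(mu_307)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TissueTable(mu_511=mu511, mu_307=mu307, activity=act)


@dataclass(frozen=True)
class Organ:
    """A geometric primitive with a tissue class.

    ``shape`` is one of ``sphere`` (size = (r,)), ``ellipsoid``
    (half-axes (a, b, c)) or ``cylinder`` (axis along z,
    size = (a, b, half_length); a == b gives a circular cylinder).
    ``activity_override`` replaces the tissue's base concentration.
    """

    name: str
    shape: str
    center: tuple
    size: tuple
    tissue: str
    activity_override: Optional[float] = None

    def bounding_box(self):
        c = np.asarray(self.center, float)
        if self.shape == "sphere":
            h = np.full(3, self.size[0])
        elif self.shape in ("ellipsoid", "cylinder"):
            h = np.asarray(self.size, float)
        else:
            raise ValueError(f"unknown shape {self.shape!r}")
        return c - h, c + h

    def mask(self, grid: Grid) -> np.ndarray:
        x, y, z = grid.voxel_centers()
        cx, cy, cz = self.center
        if self.shape == "sphere":
            r = self.size[0]
            return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r * r
        if self.shape == "ellipsoid":
            a, b, c = self.size
            return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0
        if self.shape == "cylinder":
            a, b, hz = self.size
            return (((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0) & (np.abs(z - cz) <= hz)
        raise ValueError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class BodySpec:
    organs: tuple
    total_activity_mbq: float = 21.0
    grid_shape: tuple = (50, 50, 200)
    voxel_size: float = 4.0


@dataclass(frozen=True)
class Lesion:
    center: tuple
    diameter: float
    contrast: float
    host_organ: str

    def __post_init__(self):
        if self.contrast <= 1.0:
            raise ValueError("lesion contrast must exceed 1")


@dataclass(frozen=True)
class VOI:
    center: tuple
    radius: float
    organ_label: str


@dataclass
class Phantom:
    grid: Grid
    organ_names: tuple  # index + 1 = label value; 0 is air
    labels: np.ndarray
    mu511: np.ndarray
    activity: np.ndarray
    tissue_table: TissueTable
    organ_tissue: dict
    lesions: tuple = ()
    vois: tuple = ()

    @property
    def total_activity_mbq(self) -> float:
        return float(self.activity.sum()) * self.grid.voxel_volume_ml / 1000.0

    def organ_mask(self, name: str) -> np.ndarray:
        if name not in self.organ_names:
            raise KeyError(f"unknown organ {name!r}")
        return self.labels == (self.organ_names.index(name) + 1)

    def organ_background(self, name: str) -> float:
        """Background activity concentration of an organ."""
        tissue = self.organ_tissue[name]["tissue"]
        ov = self.organ_tissue[name]["activity_override"]
        base = self.tissue_table.activity[tissue] if ov is None else ov
        return base * self.organ_tissue[name]["scale"]

    def mu307(self) -> np.ndarray:
        """307 keV mu-map via the per-tissue table (exact per label)."""
        out = np.zeros_like(self.mu511)
        for i, name in enumerate(self.organ_names):
            t = self.organ_tissue[name]["tissue"]
            m = self.labels == i + 1
            out[m] = self.tissue_table.mu_307[t]
        return out


def build_phantom(body_spec: BodySpec, voxel_size: Optional[float] = None,
                  seed: int = 0, tissue_table: Optional[TissueTable] = None) -> Phantom:
    """Rasterize a body spec onto the voxel grid.

    Deterministic given the spec (and seed, kept for interface
    stability — the rasterization itself draws no random numbers).
    Activity is rescaled so that the voxel sum matches the spec's
    total activity.  An organ extending outside the grid is an error.
    """
    del seed
    table = tissue_table or tissue_mu_table()
    vs = voxel_size or body_spec.voxel_size
    grid = Grid(shape=tuple(body_spec.grid_shape), voxel_size=vs)
    labels = np.zeros(grid.shape, dtype=np.int16)
    mu = np.zeros(grid.shape, dtype=np.float64)
    act = np.zeros(grid.shape, dtype=np.float64)
    organ_tissue = {}
    for i, organ in enumerate(body_spec.organs):
        lo, hi = organ.bounding_box()
        if not grid.contains_box(lo, hi):
            raise ValueError(f"organ {organ.name!r} extends outside the grid")
        m = organ.mask(grid)
        labels[m] = i + 1
        mu[m] = table.mu_511[organ.tissue]
        conc = (table.activity[organ.tissue] if organ.activity_override is None
                else organ.activity_override)
        act[m] = conc
        organ_tissue[organ.name] = {
            "tissue": organ.tissue,
            "activity_override": organ.activity_override,
            "scale": 1.0,
        }
    total = act.sum() * grid.voxel_volume_ml / 1000.0  # MBq
    if total > 0:
        scale = body_spec.total_activity_mbq / total
        act *= scale
        for v in organ_tissue.values():
            v["scale"] = scale
    return Phantom(grid=grid, organ_names=tuple(o.name for o in body_spec.organs),
                   labels=labels, mu511=mu, activity=act, tissue_table=table,
                   organ_tissue=organ_tissue)


def embed_lesions(phantom: Phantom, lesion_list,
                  renormalize_total: bool = True) -> Phantom:
    """Embed spherical activity lesions (voxel-centre inclusion).

    Lesion activity = contrast x host-organ background concentration;
    the mu-map is unchanged.  A lesion reaching outside its host organ
    is an error.  With ``renormalize_total`` the whole activity map is
    rescaled back to the phantom's total activity (contrasts are
    ratios and survive the rescale).
    """
    total_before = phantom.total_activity_mbq
    act = phantom.activity.copy()
    x, y, z = phantom.grid.voxel_centers()
    for les in lesion_list:
        host_mask = phantom.organ_mask(les.host_organ)
        cx, cy, cz = les.center
        r = les.diameter / 2.0
        m = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r * r
        if not m.any():
            raise ValueError(f"lesion at {les.center} covers no voxel")
        if not np.all(host_mask[m]):
            raise ValueError(
                f"lesion at {les.center} extends outside host organ {les.host_organ!r}")
        act[m] = les.contrast * phantom.organ_background(les.host_organ)
    organ_tissue = phantom.organ_tissue
    if renormalize_total and act.sum() > 0:
        k = total_before / (act.sum() * phantom.grid.voxel_volume_ml / 1000.0)
        act *= k
        organ_tissue = {name: {**v, "scale": v["scale"] * k}
                        for name, v in phantom.organ_tissue.items()}
    return replace(phantom, activity=act, lesions=tuple(lesion_list),
                   organ_tissue=organ_tissue)


def define_vois(phantom: Phantom, catalog) -> tuple:
    """Validate a VOI catalog against the phantom.

    Every voxel of each VOI sphere must carry its organ's label;
    a VOI crossing an organ boundary is an error.
    """
    x, y, z = phantom.grid.voxel_centers()
    for voi in catalog:
        m = ((x - voi.center[0]) ** 2 + (y - voi.center[1]) ** 2
             + (z - voi.center[2]) ** 2) <= voi.radius**2
        if not m.any():
            raise ValueError(f"VOI at {voi.center} covers no voxel")
        if not np.all(phantom.organ_mask(voi.organ_label)[m]):
            raise ValueError(
                f"VOI at {voi.center} crosses the boundary of {voi.organ_label!r}")
    return tuple(catalog)


def voi_mask(phantom: Phantom, voi: VOI) -> np.ndarray:
    x, y, z = phantom.grid.voxel_centers()
    return ((x - voi.center[0]) ** 2 + (y - voi.center[1]) ** 2
            + (z - voi.center[2]) ** 2) <= voi.radius**2


# ---------------------------------------------------------------------------
# Default body, lesion and VOI catalogs
# ---------------------------------------------------------------------------

def default_body_spec(total_activity_mbq: float = 21.0) -> BodySpec:
    """Compact adult torso + head on a 200 x 200 x 800 mm grid.

    List order is the overlap priority (later organs overwrite):
    subcutaneous fat < soft torso < skull < brain < ribcage < lungs
    < liver < myocardium < LV blood pool < spine < hip bones
    < hip marrow < bladder.  Structure sizes are chosen so every VOI
    interior clears the desk-scale reconstruction resolution.
    """
    organs = (
        Organ("torso_fat", "cylinder", (0, 0, -80), (88, 68, 320), "adipose"),
        Organ("torso_soft", "cylinder", (0, 0, -80), (80, 60, 320), "soft_tissue"),
        Organ("neck", "cylinder", (0, 0, 255), (45, 45, 25), "soft_tissue"),
        Organ("skull_bone", "sphere", (0, 0, 310), (84,), "bone",
              activity_override=0.7),
        Organ("brain", "sphere", (0, 0, 310), (40,), "brain"),
        Organ("ribs_outer", "cylinder", (0, 0, 130), (78, 58, 70), "bone"),
        Organ("ribs_inner", "cylinder", (0, 0, 130), (70, 50, 70), "soft_tissue"),
        Organ("lung_left", "ellipsoid", (-45, -10, 110), (32, 40, 85), "lung"),
        Organ("lung_right", "ellipsoid", (45, -10, 110), (32, 40, 85), "lung"),
        Organ("liver", "ellipsoid", (35, 10, -10), (42, 40, 55), "liver"),
        Organ("myocardium", "ellipsoid", (-18, 14, 85), (34, 34, 46), "soft_tissue",
              activity_override=3.0),
        Organ("lv_blood_pool", "ellipsoid", (-18, 14, 85), (26, 26, 38), "blood"),
        Organ("spine_bone", "cylinder", (0, -34, -60), (24, 24, 280), "bone",
              activity_override=0.9),
        Organ("hip_bone_left", "cylinder", (-40, 0, -330), (34, 34, 50), "bone",
              activity_override=0.7),
        Organ("hip_bone_right", "cylinder", (40, 0, -330), (34, 34, 50), "bone",
              activity_override=0.7),
        Organ("hip_marrow_left", "cylinder", (-40, 0, -330), (26, 26, 50), "bone_marrow"),
        Organ("hip_marrow_right", "cylinder", (40, 0, -330), (26, 26, 50), "bone_marrow"),
        Organ("bladder", "sphere", (0, 16, -252), (34,), "water",
              activity_override=10.0),
    )
    return BodySpec(organs=organs, total_activity_mbq=total_activity_mbq)


def default_lesion_catalog() -> tuple:
    """22 spherical activity lesions, 8-12 mm, contrast 2.4-24:
    5 liver, 3 per lung, 4 pelvic nodes, 4 neck nodes, 3 brain."""
    return (
        # liver (mid lobe, clear of the lung boundary; the VOIs sit in
        # the inferior lobe)
        Lesion((25, 8, 5), 12.0, 2.4, "liver"),
        Lesion((48, 12, 8), 11.0, 3.0, "liver"),
        Lesion((30, 28, -5), 10.0, 4.0, "liver"),
        Lesion((50, -8, 10), 9.0, 6.0, "liver"),
        Lesion((18, 20, 12), 8.0, 8.0, "liver"),
        # left lung
        Lesion((-45, -10, 150), 12.0, 8.0, "lung_left"),
        Lesion((-60, 8, 115), 10.0, 12.0, "lung_left"),
        Lesion((-42, -32, 65), 8.0, 24.0, "lung_left"),
        # right lung
        Lesion((45, -10, 150), 12.0, 6.0, "lung_right"),
        Lesion((55, 0, 100), 10.0, 10.0, "lung_right"),
        Lesion((40, -25, 80), 8.0, 16.0, "lung_right"),
        # pelvic nodes (soft-tissue background)
        Lesion((-28, -10, -270), 12.0, 3.0, "torso_soft"),
        Lesion((28, -10, -270), 10.0, 4.0, "torso_soft"),
        Lesion((-15, 46, -315), 9.0, 6.0, "torso_soft"),
        Lesion((15, 46, -315), 8.0, 8.0, "torso_soft"),
        # neck nodes (just below the neck/torso junction)
        Lesion((-28, 22, 213), 10.0, 4.0, "torso_soft"),
        Lesion((28, 22, 213), 9.0, 6.0, "torso_soft"),
        Lesion((-26, -6, 213), 8.0, 8.0, "torso_soft"),
        Lesion((26, -6, 213), 8.0, 12.0, "torso_soft"),
        # brain
        Lesion((0, 20, 325), 12.0, 2.4, "brain"),
        Lesion((-18, -12, 318), 10.0, 3.0, "brain"),
        Lesion((18, 4, 292), 8.0, 4.0, "brain"),
    )


def default_voi_catalog() -> tuple:
    """23 spherical VOIs on selected anatomical regions (all placed
    away from the default lesions)."""
    return (
        VOI((-52, -19, 128), 11.0, "lung_left"),
        VOI((-56, -24, 104), 9.0, "lung_left"),
        VOI((45, -8, 118), 12.0, "lung_right"),
        VOI((44, -6, 84), 11.0, "lung_right"),
        VOI((35, 5, -40), 13.0, "liver"),
        VOI((55, 15, -20), 10.0, "liver"),
        VOI((36, 9, -17), 12.0, "liver"),
        VOI((28, 22, -27), 9.0, "liver"),
        VOI((16, 8, -28), 8.0, "liver"),
        VOI((-18, 14, 85), 10.0, "lv_blood_pool"),
        VOI((0, 0, 310), 13.0, "brain"),
        VOI((0, -14, 300), 11.0, "brain"),
        VOI((0, 10, 297), 10.0, "brain"),
        VOI((0, 62, 310), 7.0, "skull_bone"),
        VOI((46, -46, 310), 8.0, "skull_bone"),
        VOI((-46, 46, 310), 8.0, "skull_bone"),
        VOI((0, -34, 40), 10.0, "spine_bone"),
        VOI((0, -34, -160), 10.0, "spine_bone"),
        VOI((-40, 0, -330), 9.0, "hip_marrow_left"),
        VOI((40, 0, -330), 9.0, "hip_marrow_right"),
        VOI((0, 16, -252), 13.0, "bladder"),
        VOI((0, 28, -150), 14.0, "torso_soft"),
        VOI((-45, -10, -180), 13.0, "torso_soft"),
    )


# ---------------------------------------------------------------------------
# Volume import/export
# ---------------------------------------------------------------------------

def _affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= grid.voxel_size
    aff[:3, 3] = grid.origin + grid.voxel_size / 2.0
    return aff


def save_phantom_nifti(phantom: Phantom, prefix) -> None:
    """Write labels, mu-map and activity as NIfTI volumes plus a JSON
    lesion/VOI catalog next to them."""
    import nibabel as nib

    aff = _affine(phantom.grid)
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.int16), aff), f"{prefix}_labels.nii.gz")
    nib.save(nib.Nifti1Image(phantom.mu511.astype(np.float32), aff), f"{prefix}_mu511.nii.gz")
    nib.save(nib.Nifti1Image(phantom.activity.astype(np.float32), aff),
             f"{prefix}_activity.nii.gz")
    meta = {
        "organ_names": list(phantom.organ_names),
        "organ_tissue": phantom.organ_tissue,
        "lesions": [vars(l) | {"center": list(l.center)} for l in phantom.lesions],
        "vois": [vars(v) | {"center": list(v.center)} for v in phantom.vois],
        "voxel_size": phantom.grid.voxel_size,
    }
    with open(f"{prefix}_catalog.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_phantom_nifti(prefix, tissue_table: Optional[TissueTable] = None) -> Phantom:
    import nibabel as nib

    with open(f"{prefix}_catalog.json") as fh:
        meta = json.load(fh)
    labels_img = nib.load(f"{prefix}_labels.nii.gz")
    labels = np.asarray(labels_img.dataobj).astype(np.int16)
    mu = np.asarray(nib.load(f"{prefix}_mu511.nii.gz").dataobj).astype(np.float64)
    act = np.asarray(nib.load(f"{prefix}_activity.nii.gz").dataobj).astype(np.float64)
    grid = Grid(shape=labels.shape, voxel_size=float(meta["voxel_size"]))
    lesions = tuple(Lesion(tuple(d["center"]), d["diameter"], d["contrast"],
                           d["host_organ"]) for d in meta["lesions"])
    vois = tuple(VOI(tuple(d["center"]), d["radius"], d["organ_label"])
                 for d in meta["vois"])
    return Phantom(grid=grid, organ_names=tuple(meta["organ_names"]), labels=labels,
                   mu511=mu, activity=act, tissue_table=tissue_table or tissue_mu_table(),
                   organ_tissue=meta["organ_tissue"], lesions=lesions, vois=vois)
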