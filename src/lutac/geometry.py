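"""Cylindrical scanner model, coincidence policy and sinogram binning.

The scanner is a cylinder of crystal rings grouped into axial *units*.
Coincidences are restricted by a maximum-unit-difference (MUD) policy:
two crystals may only form a line of response (LOR) if their axial
units are at most ``mud`` apart.  The acceptance angle implied by the
policy is measured, by convention, as ``arctan(axial span / ring
diameter)`` — the span of unit lengths the policy admits over the
detector ring diameter.  This convention reproduces the familiar
57/51/43/32/17 degree ladder of the 8-, 4-, 3-, 2- and 1-unit spans
on a 786 mm ring with 242.5 mm units.

Sinogram convention
-------------------
Transaxially, an LOR is binned by the angle of its normal
(``n_angles`` bins over half a turn) and its signed distance from the
scanner axis (``n_radial`` bins across the transaxial FOV).  Axially,
rings are mashed in groups of ``axial_mash`` and an LOR is assigned
the ordered pair of mashed-ring indices of its two endpoints, the
order fixed by the position of the endpoints along the LOR direction.
The mapping is deterministic and invertible up to mashing; the
inverse returns the representative crystal pair of the bin (central
ring of each mash group, central transaxial pair of the bin).

Desk scale
----------
A reduced-crystal variant of any geometry keeps the ring diameter,
unit structure and MUD semantics but enlarges the crystal pitch so
that sinograms stay small.  All policy and angle arithmetic is exact
in this mode; only the sampling density changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
import yaml

from .constants import C_MM_PER_PS

__all__ = [
    "ScannerGeometry",
    "EnergyWindow",
    "SinogramSpec",
    "LORTable",
    "build_lor_table",
    "build_scanner",
    "desk_variant",
    "max_acceptance_angle",
    "lor_allowed",
    "sinogram_index",
    "sinogram_index_inverse",
    "tof_threshold",
    "geometry_to_yaml",
    "geometry_from_yaml",
]

UNRESTRICTED = None  # sentinel for "no unit-difference policy"


@dataclass(frozen=True)
class EnergyWindow:
    """An energy acceptance window in keV."""

    low: float
    high: float
    label: str = ""

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"energy window requires low < high, got {self.low}..{self.high}")


#: Windows used throughout: the 511 keV emission window, the broad
#: beta window of the transmission coincidence, and the 307 keV
#: photon window (with the raised-threshold variants).
EMISSION_WINDOW = EnergyWindow(430.0, 645.0, "emission_511")
BETA_WINDOW_250 = EnergyWindow(250.0, 645.0, "beta")
BETA_WINDOW_290 = EnergyWindow(290.0, 645.0, "beta")
GAMMA_WINDOW_250 = EnergyWindow(250.0, 350.0, "gamma_307")
GAMMA_WINDOW_290 = EnergyWindow(290.0, 350.0, "gamma_307")


@dataclass(frozen=True)
class ScannerGeometry:
    """Parametrized cylindrical PET scanner.

    ``mud`` is the maximum unit difference of the coincidence policy;
    ``None`` means unrestricted (all ring combinations accepted).
    """

    ring_diameter: float = 786.0
    n_axial_units: int = 8
    unit_length: float = 242.5
    crystal_pitch_trans: float = 2.76
    crystal_pitch_axial: float = 2.76
    crystal_length: float = 18.1
    crystals_per_ring: int = 0  # 0 -> derived from pitch
    mud: Optional[int] = 4
    coincidence_window_ns: float = 6.9
    ctr_ps: float = 430.0
    energy_resolution_511: float = 0.117
    tof_bin_width_ps: float = 273.0
    transaxial_fov: float = 600.0
    name: str = ""

    def __post_init__(self):
        for f in ("ring_diameter", "unit_length", "crystal_pitch_trans",
                  "crystal_pitch_axial", "crystal_length", "transaxial_fov"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.crystals_per_ring == 0:
            n = int(round(math.pi * self.ring_diameter / self.crystal_pitch_trans))
            n -= n % 2  # even count so that diametric LORs exist
            object.__setattr__(self, "crystals_per_ring", n)
        if self.rings_per_unit < 1:
            raise ValueError("unit shorter than one crystal pitch")
        if self.mud is not None:
            if self.mud < 0:
                raise ValueError("mud must be non-negative")
            if self.mud + 1 > self.n_axial_units:
                raise ValueError(
                    f"mud={self.mud} inconsistent with {self.n_axial_units} axial units "
                    "(mud+1 must not exceed the unit count)")

    # -- derived quantities -------------------------------------------------
    @property
    def rings_per_unit(self) -> int:
        return int(round(self.unit_length / self.crystal_pitch_axial))

    @property
    def n_rings(self) -> int:
        return self.n_axial_units * self.rings_per_unit

    @property
    def axial_length(self) -> float:
        return self.n_axial_units * self.unit_length

    @property
    def ring_radius(self) -> float:
        return self.ring_diameter / 2.0

    def ring_z(self, ring) -> np.ndarray:
        """Axial coordinate of a crystal ring centre (scanner centred at z=0)."""
        ring = np.asarray(ring, dtype=float)
        pitch = self.unit_length / self.rings_per_unit
        return (ring - (self.n_rings - 1) / 2.0) * pitch

    def crystal_angle(self, itrans) -> np.ndarray:
        return (np.asarray(itrans, dtype=float) + 0.5) * (2.0 * math.pi / self.crystals_per_ring)

    def crystal_xy(self, itrans):
        a = self.crystal_angle(itrans)
        return self.ring_radius * np.cos(a), self.ring_radius * np.sin(a)

    def unit_of_ring(self, ring) -> np.ndarray:
        return np.asarray(ring) // self.rings_per_unit

    @property
    def crystal_volume_cc(self) -> float:
        return self.crystal_pitch_trans * self.crystal_pitch_axial * self.crystal_length / 1000.0

    @property
    def n_crystals(self) -> int:
        return self.n_rings * self.crystals_per_ring


_PRESETS = {
    "uexplorer": dict(n_axial_units=8, mud=4, name="uexplorer"),
    "one_meter": dict(n_axial_units=4, mud=UNRESTRICTED, name="one_meter"),
    "conventional_24cm": dict(n_axial_units=1, mud=UNRESTRICTED, name="conventional_24cm"),
}


def build_scanner(preset: Optional[str] = None, **overrides) -> ScannerGeometry:
    """Build a scanner from a preset name or explicit fields.

    Presets: ``uexplorer`` (8 units, MUD 4), ``one_meter`` (4 units,
    unrestricted) and ``conventional_24cm`` (1 unit, unrestricted).
    Keyword overrides are applied on top of the preset.
    """
    kwargs = {}
    if preset is not None:
        if preset not in _PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
        kwargs.update(_PRESETS[preset])
    kwargs.update(overrides)
    return ScannerGeometry(**kwargs)


def desk_variant(geometry: ScannerGeometry, crystals_per_ring: int = 80,
                 rings_per_unit: int = 24) -> ScannerGeometry:
    """Reduced-crystal desk-scale variant of a geometry.

    Ring diameter, unit structure and the MUD policy are preserved;
    crystal pitches are enlarged so a unit holds ``rings_per_unit``
    rings and a ring holds ``crystals_per_ring`` crystals.
    """
    return replace(
        geometry,
        crystals_per_ring=crystals_per_ring,
        crystal_pitch_trans=math.pi * geometry.ring_diameter / crystals_per_ring,
        crystal_pitch_axial=geometry.unit_length / rings_per_unit,
        name=(geometry.name + "_desk") if geometry.name else "desk",
    )


def max_acceptance_angle(geometry: ScannerGeometry) -> float:
    """Maximum LOR acceptance angle in degrees implied by the policy.

    The angle is ``arctan(span / ring_diameter)`` with the span equal
    to ``(mud+1)`` unit lengths (or the full axial length when the
    policy is unrestricted).  Rounding to whole degrees is left to the
    caller; the paper-style integer values are ``round()`` of this.
    """
    if geometry.mud is not None:
        span = (geometry.mud + 1) * geometry.unit_length
    else:
        span = geometry.n_axial_units * geometry.unit_length
    return math.degrees(math.atan2(span, geometry.ring_diameter))


def _transaxial_angle_offset(geometry, ca, cb):
    """Normal angle theta in [0, pi) and signed radial offset of a chord."""
    xa, ya = geometry.crystal_xy(ca)
    xb, yb = geometry.crystal_xy(cb)
    theta = math.atan2(yb - ya, xb - xa) + math.pi / 2.0
    theta = theta % math.pi
    n = (math.cos(theta), math.sin(theta))
    s = xa * n[0] + ya * n[1]
    if theta >= math.pi - 1e-9:
        # 0/pi branch point: pick the theta=0 branch, flip the normal
        theta -= math.pi
        s = -s
    return theta, s


def lor_allowed(geometry: ScannerGeometry, crystal_a, crystal_b,
                max_angle_deg: Optional[float] = None) -> bool:
    """Whether two crystals may form an LOR under the coincidence policy.

    Crystals are ``(ring, transaxial)`` index pairs.  The LOR must
    satisfy the MUD policy, cross the transaxial FOV and, if
    ``max_angle_deg`` is given, have a policy angle
    ``arctan(|dz| / ring_diameter)`` within it.
    """
    (ra, ca), (rb, cb) = crystal_a, crystal_b
    for r, c in ((ra, ca), (rb, cb)):
        if not (0 <= r < geometry.n_rings and 0 <= c < geometry.crystals_per_ring):
            raise IndexError(f"crystal (ring={r}, trans={c}) outside the scanner")
    if ca == cb:
        return False
    if geometry.mud is not None:
        if abs(int(geometry.unit_of_ring(ra)) - int(geometry.unit_of_ring(rb))) > geometry.mud:
            return False
    _, s = _transaxial_angle_offset(geometry, ca, cb)
    if abs(s) > geometry.transaxial_fov / 2.0:
        return False
    if max_angle_deg is not None:
        dz = abs(float(geometry.ring_z(ra)) - float(geometry.ring_z(rb)))
        if math.degrees(math.atan2(dz, geometry.ring_diameter)) > max_angle_deg + 1e-9:
            return False
    return True


def tof_threshold(geometry: ScannerGeometry, lor_length_mm: float) -> float:
    """TOF acceptance threshold (ps) for an LOR of the given
    centre-to-centre length: the flight time of the full LOR minus
    500 ps.  May be negative for short LORs (no rejection then)."""
    return lor_length_mm / C_MM_PER_PS - 500.0


@dataclass(frozen=True)
class SinogramSpec:
    """Binning of LORs into a sinogram.

    ``tof_bins == 0`` marks a non-TOF (transmission) sinogram.
    ``max_acceptance_angle`` further restricts the LOR set below what
    the MUD policy admits (used for the acceptance-angle sweeps).
    """

    n_radial: int
    n_angles: int
    axial_mash: int = 3
    angle_mash: int = 1
    max_acceptance_angle: Optional[float] = None
    tof_bins: int = 0

    def __post_init__(self):
        if self.axial_mash < 1 or self.angle_mash < 1:
            raise ValueError("mash factors must be >= 1")
        if self.tof_bins < 0:
            raise ValueError("tof_bins must be >= 0")

    @classmethod
    def for_geometry(cls, geometry: ScannerGeometry, tof: bool = False,
                     axial_mash: int = 3, angle_mash: int = 1,
                     max_acceptance_angle: Optional[float] = None) -> "SinogramSpec":
        if geometry.crystals_per_ring % angle_mash:
            raise ValueError("angle_mash must divide the crystal count")
        n_ang = geometry.crystals_per_ring // angle_mash
        # radial bin width ~ R*pi/N: below the minimum same-angle chord
        # offset spacing, so distinct crystal pairs land in distinct bins
        width = geometry.ring_radius * math.pi / geometry.crystals_per_ring
        n_rad = int(math.ceil(geometry.transaxial_fov / width)) | 1  # odd: s=0 at a bin centre
        n_tof = 0
        if tof:
            # cover arc positions over the longest policy-allowed LOR,
            # so TOF marginalization holds for every voxel on any LOR
            sigma = geometry.ctr_ps / 2.354820045030949
            if geometry.mud is not None:
                span = (geometry.mud + 1) * geometry.unit_length
            else:
                span = geometry.n_axial_units * geometry.unit_length
            if max_acceptance_angle is not None:
                span = min(span, math.tan(math.radians(max_acceptance_angle))
                           * geometry.ring_diameter)
            lmax = math.hypot(span, geometry.ring_diameter)
            tmax = lmax / C_MM_PER_PS + 3.5 * sigma
            n_tof = 2 * int(math.ceil(tmax / geometry.tof_bin_width_ps - 0.5)) + 1
        return cls(n_radial=n_rad, n_angles=n_ang, axial_mash=axial_mash,
                   angle_mash=angle_mash,
                   max_acceptance_angle=max_acceptance_angle, tof_bins=n_tof)

    def n_mashed_rings(self, geometry: ScannerGeometry) -> int:
        return (geometry.n_rings + self.axial_mash - 1) // self.axial_mash

    def representative_ring(self, geometry: ScannerGeometry, mashed: int) -> int:
        r = mashed * self.axial_mash + (self.axial_mash - 1) // 2
        return min(r, geometry.n_rings - 1)


def _canonical_sides(geometry, ca, cb, theta):
    """Order a crystal pair by position along the LOR direction."""
    d = (math.sin(theta), -math.cos(theta))
    xa, ya = geometry.crystal_xy(ca)
    xb, yb = geometry.crystal_xy(cb)
    if xa * d[0] + ya * d[1] <= xb * d[0] + yb * d[1]:
        return ca, cb
    return cb, ca


def _transaxial_bin(geometry, spec, ca, cb):
    theta, s = _transaxial_angle_offset(geometry, ca, cb)
    if abs(s) > geometry.transaxial_fov / 2.0:
        return None
    n_cry = geometry.crystals_per_ring
    step = math.pi / n_cry
    angle = (int(round(theta / step)) % n_cry) // spec.angle_mash
    width = geometry.transaxial_fov / spec.n_radial
    radial = int(round(s / width)) + spec.n_radial // 2
    radial = min(max(radial, 0), spec.n_radial - 1)
    a_first, a_second = _canonical_sides(geometry, ca, cb, theta)
    return radial, angle, a_first, a_second


class _TransaxialLookup:
    """Representative transaxial crystal pair per (angle, radial) bin."""

    _cache: dict = {}

    @classmethod
    def get(cls, geometry: ScannerGeometry, spec: SinogramSpec) -> np.ndarray:
        key = (geometry.crystals_per_ring, geometry.ring_diameter,
               geometry.transaxial_fov, spec.n_radial, spec.n_angles,
               spec.angle_mash)
        if key not in cls._cache:
            n = geometry.crystals_per_ring
            rep = -np.ones((spec.n_angles, spec.n_radial, 2), dtype=np.int32)
            for ca in range(n):
                for cb in range(ca + 1, n):
                    out = _transaxial_bin(geometry, spec, ca, cb)
                    if out is None:
                        continue
                    radial, angle, first, second = out
                    if rep[angle, radial, 0] >= 0:
                        continue  # injective by construction; keep first
                    rep[angle, radial] = (first, second)
            cls._cache[key] = rep
        return cls._cache[key]


def sinogram_index(geometry: ScannerGeometry, spec: SinogramSpec,
                   crystal_a, crystal_b):
    """Map a crystal pair to ``(radial, angle, (mashed_a, mashed_b))``.

    The mashed-ring pair is ordered by endpoint position along the LOR
    direction, so opposite obliques occupy distinct planes.
    """
    if not lor_allowed(geometry, crystal_a, crystal_b,
                       max_angle_deg=spec.max_acceptance_angle):
        raise ValueError(f"LOR {crystal_a}-{crystal_b} not allowed by the policy")
    (ra, ca), (rb, cb) = crystal_a, crystal_b
    radial, angle, first, second = _transaxial_bin(geometry, spec, ca, cb)
    ring_of = {ca: ra, cb: rb}
    mr_first = ring_of[first] // spec.axial_mash
    mr_second = ring_of[second] // spec.axial_mash
    return radial, angle, (mr_first, mr_second)


def sinogram_index_inverse(geometry: ScannerGeometry, spec: SinogramSpec,
                           radial: int, angle: int, plane):
    """Representative crystal pair of a sinogram bin."""
    rep = _TransaxialLookup.get(geometry, spec)
    first, second = rep[angle, radial]
    if first < 0:
        raise ValueError(f"empty sinogram bin (radial={radial}, angle={angle})")
    mr_first, mr_second = plane
    r1 = spec.representative_ring(geometry, mr_first)
    r2 = spec.representative_ring(geometry, mr_second)
    return (r1, int(first)), (r2, int(second))


@dataclass
class LORTable:
    """Flat table of the populated sinogram bins of a geometry.

    Each row is one (radial, angle, mashed-ring-pair) bin, represented
    by its central crystal pair.  Endpoint coordinates are stored for
    the 511 keV and 307 keV depth-of-interaction models (filled in by
    the projector module).  Reconstruction and simulation operate on
    these flat arrays; multi-bed protocols concatenate tables.
    """

    geometry: ScannerGeometry
    spec: SinogramSpec
    radial: np.ndarray
    angle: np.ndarray
    plane_a: np.ndarray
    plane_b: np.ndarray
    ring_a: np.ndarray
    ring_b: np.ndarray
    trans_a: np.ndarray
    trans_b: np.ndarray
    front_a: np.ndarray  # (n, 3) front-face centre of endpoint A
    front_b: np.ndarray
    lor_length: np.ndarray  # centre-to-centre front-face distance
    geom_weight: np.ndarray  # solid-angle/obliquity weight, unnormalized
    end511_a: Optional[np.ndarray] = None
    end511_b: Optional[np.ndarray] = None
    end307_a: Optional[np.ndarray] = None
    end307_b: Optional[np.ndarray] = None
    z_offset: float = 0.0

    def __len__(self):
        return len(self.radial)

    @property
    def n_lors(self) -> int:
        return len(self.radial)

    def subset_rows(self, n_subsets: int):
        """Row indices per subset; subsets take every n-th angle
        (projections equidistant in angle)."""
        if self.spec.n_angles % n_subsets:
            raise ValueError(f"{n_subsets} subsets do not divide {self.spec.n_angles} angles")
        return [np.nonzero(self.angle % n_subsets == s)[0] for s in range(n_subsets)]

    def tof_thresholds(self) -> np.ndarray:
        return self.lor_length / C_MM_PER_PS - 500.0

    def restrict(self, mask) -> "LORTable":
        """Sub-table of the rows selected by a boolean mask or index
        array (used to drop LORs that never cross the image grid)."""
        out = LORTable(geometry=self.geometry, spec=self.spec,
                       radial=self.radial[mask], angle=self.angle[mask],
                       plane_a=self.plane_a[mask], plane_b=self.plane_b[mask],
                       ring_a=self.ring_a[mask], ring_b=self.ring_b[mask],
                       trans_a=self.trans_a[mask], trans_b=self.trans_b[mask],
                       front_a=self.front_a[mask], front_b=self.front_b[mask],
                       lor_length=self.lor_length[mask],
                       geom_weight=self.geom_weight[mask],
                       z_offset=self.z_offset)
        for name in ("end511_a", "end511_b", "end307_a", "end307_b"):
            v = getattr(self, name)
            if v is not None:
                setattr(out, name, v[mask])
        return out

    def shifted(self, dz: float) -> "LORTable":
        """Copy of the table with all endpoints moved axially by dz
        (bed repositioning relative to the fixed phantom grid)."""
        out = LORTable(
            geometry=self.geometry, spec=self.spec,
            radial=self.radial, angle=self.angle,
            plane_a=self.plane_a, plane_b=self.plane_b,
            ring_a=self.ring_a, ring_b=self.ring_b,
            trans_a=self.trans_a, trans_b=self.trans_b,
            front_a=self.front_a + np.array([0.0, 0.0, dz]),
            front_b=self.front_b + np.array([0.0, 0.0, dz]),
            lor_length=self.lor_length, geom_weight=self.geom_weight,
            z_offset=self.z_offset + dz,
        )
        for name in ("end511_a", "end511_b", "end307_a", "end307_b"):
            v = getattr(self, name)
            if v is not None:
                setattr(out, name, v + np.array([0.0, 0.0, dz]))
        return out


def build_lor_table(geometry: ScannerGeometry, spec: SinogramSpec) -> LORTable:
    """Enumerate all populated, policy-allowed sinogram bins."""
    rep = _TransaxialLookup.get(geometry, spec)
    n_mash = spec.n_mashed_rings(geometry)
    mash_rep = np.array([spec.representative_ring(geometry, m) for m in range(n_mash)])
    mash_unit = geometry.unit_of_ring(mash_rep)
    mash_z = geometry.ring_z(mash_rep)

    # allowed mashed plane pairs (ordered)
    pa, pb = np.meshgrid(np.arange(n_mash), np.arange(n_mash), indexing="ij")
    pa, pb = pa.ravel(), pb.ravel()
    ok = np.ones(len(pa), dtype=bool)
    if geometry.mud is not None:
        ok &= np.abs(mash_unit[pa] - mash_unit[pb]) <= geometry.mud
    if spec.max_acceptance_angle is not None:
        dz = np.abs(mash_z[pa] - mash_z[pb])
        ang = np.degrees(np.arctan2(dz, geometry.ring_diameter))
        ok &= ang <= spec.max_acceptance_angle + 1e-9
    pa, pb = pa[ok], pb[ok]

    ang_idx, rad_idx = np.nonzero(rep[:, :, 0] >= 0)
    first = rep[ang_idx, rad_idx, 0]
    second = rep[ang_idx, rad_idx, 1]

    # cartesian product planes x transaxial bins
    n_t = len(ang_idx)
    n_p = len(pa)
    radial = np.tile(rad_idx, n_p).astype(np.int32)
    angle = np.tile(ang_idx, n_p).astype(np.int32)
    trans_a = np.tile(first, n_p).astype(np.int32)
    trans_b = np.tile(second, n_p).astype(np.int32)
    plane_a = np.repeat(pa, n_t).astype(np.int32)
    plane_b = np.repeat(pb, n_t).astype(np.int32)
    ring_a = mash_rep[plane_a].astype(np.int32)
    ring_b = mash_rep[plane_b].astype(np.int32)

    xa, ya = geometry.crystal_xy(trans_a)
    xb, yb = geometry.crystal_xy(trans_b)
    za = geometry.ring_z(ring_a)
    zb = geometry.ring_z(ring_b)
    front_a = np.stack([xa, ya, za], axis=1)
    front_b = np.stack([xb, yb, zb], axis=1)
    d = np.linalg.norm(front_b - front_a, axis=1)
    d_trans = np.hypot(xb - xa, yb - ya)
    cos_polar = d_trans / d
    face = geometry.crystal_pitch_trans * geometry.crystal_pitch_axial
    geom_weight = face * cos_polar / d**2

    return LORTable(
        geometry=geometry, spec=spec,
        radial=radial, angle=angle,
        plane_a=plane_a, plane_b=plane_b,
        ring_a=ring_a, ring_b=ring_b,
        trans_a=trans_a, trans_b=trans_b,
        front_a=front_a, front_b=front_b,
        lor_length=d, geom_weight=geom_weight,
    )


def concat_tables(tables) -> LORTable:
    """Concatenate LOR tables of the same geometry/spec (multi-bed
    protocols: each bed contributes its LOR set at its axial offset)."""
    tables = [t for t in tables if len(t)]
    if not tables:
        raise ValueError("no non-empty tables to concatenate")
    first = tables[0]
    kw = {}
    for name in ("radial", "angle", "plane_a", "plane_b", "ring_a", "ring_b",
                 "trans_a", "trans_b", "front_a", "front_b", "lor_length",
                 "geom_weight", "end511_a", "end511_b", "end307_a", "end307_b"):
        vals = [getattr(t, name) for t in tables]
        kw[name] = None if any(v is None for v in vals) else np.concatenate(vals)
    return LORTable(geometry=first.geometry, spec=first.spec, **kw)


def bin_crystal_pairs(geometry: ScannerGeometry, spec: SinogramSpec,
                      ring1, trans1, ring2, trans2):
    """Vectorized crystal-pair -> (radial, angle, plane_a, plane_b).

    Mirrors :func:`sinogram_index` for event batches (used by the
    scatter samplers).  Returns int arrays plus a validity mask
    (False where the pair violates FOV or MUD policy); the
    acceptance-angle restriction of ``spec`` is applied as well.
    """
    ring1 = np.asarray(ring1, dtype=np.int64)
    ring2 = np.asarray(ring2, dtype=np.int64)
    trans1 = np.asarray(trans1, dtype=np.int64)
    trans2 = np.asarray(trans2, dtype=np.int64)
    xa, ya = geometry.crystal_xy(trans1)
    xb, yb = geometry.crystal_xy(trans2)
    theta = (np.arctan2(yb - ya, xb - xa) + math.pi / 2.0) % math.pi
    s = xa * np.cos(theta) + ya * np.sin(theta)
    flip = theta >= math.pi - 1e-9
    theta = np.where(flip, theta - math.pi, theta)
    s = np.where(flip, -s, s)

    valid = trans1 != trans2
    valid &= np.abs(s) <= geometry.transaxial_fov / 2.0
    if geometry.mud is not None:
        valid &= np.abs(geometry.unit_of_ring(ring1)
                        - geometry.unit_of_ring(ring2)) <= geometry.mud
    dz = np.abs(geometry.ring_z(ring1) - geometry.ring_z(ring2))
    if spec.max_acceptance_angle is not None:
        ang = np.degrees(np.arctan2(dz, geometry.ring_diameter))
        valid &= ang <= spec.max_acceptance_angle + 1e-9

    n_cry = geometry.crystals_per_ring
    step = math.pi / n_cry
    angle = (np.round(theta / step).astype(np.int64) % n_cry) // spec.angle_mash
    width = geometry.transaxial_fov / spec.n_radial
    radial = np.clip(np.round(s / width).astype(np.int64) + spec.n_radial // 2,
                     0, spec.n_radial - 1)
    # canonical side order: position along the LOR direction
    dx, dy = np.sin(theta), -np.cos(theta)
    a_first = xa * dx + ya * dy <= xb * dx + yb * dy
    mr1 = ring1 // spec.axial_mash
    mr2 = ring2 // spec.axial_mash
    plane_a = np.where(a_first, mr1, mr2)
    plane_b = np.where(a_first, mr2, mr1)
    return radial, angle, plane_a, plane_b, valid


def lor_row_lookup(table: LORTable) -> np.ndarray:
    """Dense (angle, radial, plane_a, plane_b) -> table-row index map
    (-1 where the bin is absent from the table)."""
    spec, geom = table.spec, table.geometry
    nm = spec.n_mashed_rings(geom)
    lut = -np.ones((spec.n_angles, spec.n_radial, nm, nm), dtype=np.int64)
    lut[table.angle, table.radial, table.plane_a, table.plane_b] = \
        np.arange(len(table))
    return lut


def geometry_to_yaml(geometry: ScannerGeometry, path) -> None:
    """Serialize a geometry as a human-readable key/value config."""
    d = asdict(geometry)
    d["mud"] = "unrestricted" if geometry.mud is None else geometry.mud
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def geometry_from_yaml(path) -> ScannerGeometry:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if d.get("mud") == "unrestricted":
        d["mud"] = None
    return ScannerGeometry(**d)
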