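"""System models: Siddon ray tracing, depth-of-interaction endpoint
placement, attenuation factors and (TOF) forward/back projection.

Endpoints.  An LOR endpoint is the crystal front-face centre pushed
*outward* along the LOR (deeper into the crystal) by the mean
interaction depth of the truncated-exponential depth-of-interaction
model.  The depth depends on the photon energy through the scale
``eta`` applied to the LYSO attenuation coefficient, so transmission
(307 keV) and emission (511 keV) system matrices differ slightly.

Energy scaling.  Mu-maps are always stored at 511 keV; all 307 keV
physics multiplies line integrals by ``eta`` (a single source of
truth, see :func:`eta_transform`).

TOF.  The TOF kernel is a Gaussian whose FWHM is the coincidence
timing resolution, integrated exactly over each TOF bin and truncated
at +/-3.5 sigma (keeping the marginalization error below 1e-3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .constants import C_MM_PER_PS, ETA_307, FWHM_TO_SIGMA, MU_LYSO_511
from .geometry import LORTable, ScannerGeometry
from .grid import Grid

__all__ = [
    "DOIModel", "doi_depth", "place_endpoints", "siddon_path",
    "forward_project", "back_project", "chord_lengths",
    "tof_forward_project", "tof_back_project",
    "attenuation_factors", "eta_transform",
    "TOF_TRUNCATION_SIGMA",
]

TOF_TRUNCATION_SIGMA = 3.5


@dataclass(frozen=True)
class DOIModel:
    """Truncated-exponential depth-of-interaction model.

    ``Y`` is the depth quantile used when random sampling is disabled
    (the mean-depth surrogate); ``eta`` scales the crystal attenuation
    for sub-511 keV photons.
    """

    mu_lyso: float = MU_LYSO_511
    crystal_length: float = 18.1
    Y: float = 0.6
    eta: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.Y < 1.0):
            raise ValueError("fixed depth quantile Y must lie in (0, 1)")


def doi_depth(model: DOIModel, Y=None):
    """Interaction depth (mm from the crystal front face) at quantile Y.

    ``depth = -ln(1 - Y (1 - exp(-eta mu D))) / (eta mu)``, the
    inverse CDF of an exponential interaction law truncated at the
    crystal length D; clamped to [0, D].
    """
    y = np.asarray(model.Y if Y is None else Y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("depth quantile must lie in [0, 1]")
    mu = model.eta * model.mu_lyso
    depth = -np.log1p(-y * (-np.expm1(-mu * model.crystal_length))) / mu
    return np.clip(depth, 0.0, model.crystal_length)


def place_endpoints(table: LORTable, rng: np.random.Generator | None = None) -> LORTable:
    """Fill the 511 and 307 keV DOI-adjusted endpoints of an LOR table.

    The endpoint sits at the crystal front-face centre pushed deeper
    into the crystal along its radial axis by the interaction depth
    (the depth-of-interaction parallax: for off-centre and oblique
    LORs this shifts the effective line of response).  With ``rng``
    given, per-LOR depth quantiles are drawn uniformly (random DOI
    sampling); otherwise the fixed quantile Y=0.6 is used.
    """
    geom = table.geometry
    ang_a = geom.crystal_angle(table.trans_a)
    ang_b = geom.crystal_angle(table.trans_b)
    rad_a = np.stack([np.cos(ang_a), np.sin(ang_a), np.zeros_like(ang_a)], axis=1)
    rad_b = np.stack([np.cos(ang_b), np.sin(ang_b), np.zeros_like(ang_b)], axis=1)
    for attr_a, attr_b, eta in (("end511_a", "end511_b", 1.0),
                                ("end307_a", "end307_b", ETA_307)):
        model = DOIModel(crystal_length=geom.crystal_length, eta=eta)
        n = len(table)
        if rng is None:
            da = np.full(n, doi_depth(model))
            db = da
        else:
            da = doi_depth(model, rng.random(n))
            db = doi_depth(model, rng.random(n))
        setattr(table, attr_a, table.front_a + da[:, None] * rad_a)
        setattr(table, attr_b, table.front_b + db[:, None] * rad_b)
    return table


def _grid_args(grid: Grid):
    o = grid.origin
    nx, ny, nz = grid.shape
    return float(o[0]), float(o[1]), float(o[2]), float(grid.voxel_size), nx, ny, nz


def _as_points(p):
    p = np.ascontiguousarray(np.atleast_2d(np.asarray(p, dtype=np.float64)))
    if p.shape[1] != 3:
        raise ValueError("endpoints must be (n, 3)")
    return p


def siddon_path(p1, p2, grid: Grid):
    """Voxels crossed by the segment p1->p2 with intersection lengths.

    Returns ``(indices, lengths)`` where ``indices`` is (m, 3) voxel
    indices in traversal order and ``lengths`` their chord lengths in
    mm.  A zero-length ray is an error; a ray missing the grid
    returns empty arrays.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.allclose(p1, p2):
        raise ValueError("degenerate zero-length ray")
    ox, oy, oz, h, nx, ny, nz = _grid_args(grid)
    nb = nx + ny + nz + 4
    idx_buf = np.empty(nb, np.int64)
    len_buf = np.empty(nb, np.float64)
    m = _kernels._trace(p1[0], p1[1], p1[2], p2[0], p2[1], p2[2],
                        ox, oy, oz, h, nx, ny, nz, idx_buf, len_buf)
    flat = idx_buf[:m]
    ii = flat // (ny * nz)
    jj = (flat // nz) % ny
    kk = flat % nz
    return np.stack([ii, jj, kk], axis=1), len_buf[:m].copy()


def forward_project(vol, p1, p2, grid: Grid) -> np.ndarray:
    """Line integrals sum_j l_ij x_j (mm-weighted) for each LOR."""
    p1, p2 = _as_points(p1), _as_points(p2)
    out = np.zeros(p1.shape[0])
    _kernels.forward_kernel(np.ascontiguousarray(vol, dtype=np.float64).ravel(),
                            p1, p2, *_grid_args(grid), out)
    return out


def back_project(vals, p1, p2, grid: Grid) -> np.ndarray:
    """Adjoint of :func:`forward_project`."""
    p1, p2 = _as_points(p1), _as_points(p2)
    out = np.zeros(int(np.prod(grid.shape)))
    _kernels.back_kernel(np.ascontiguousarray(vals, dtype=np.float64),
                         p1, p2, *_grid_args(grid), out)
    return out.reshape(grid.shape)


def chord_lengths(p1, p2, grid: Grid) -> np.ndarray:
    """Length of each segment clipped to the grid bounding box."""
    p1, p2 = _as_points(p1), _as_points(p2)
    out = np.zeros(p1.shape[0])
    _kernels.chord_kernel(p1, p2, *_grid_args(grid), out)
    return out


def _tof_args(geometry: ScannerGeometry):
    sigma = geometry.ctr_ps * FWHM_TO_SIGMA
    return sigma, geometry.tof_bin_width_ps, 1.0 / C_MM_PER_PS, TOF_TRUNCATION_SIGMA


def tof_forward_project(vol, p1, p2, grid: Grid, geometry: ScannerGeometry,
                        n_tof: int) -> np.ndarray:
    """TOF-resolved line integrals, shape (n_lors, n_tof).

    The kernel centre for a voxel at signed arc distance u from the
    LOR midpoint (positive toward p2) is at time 2u/c.  Summing over
    TOF bins reproduces :func:`forward_project` up to the kernel
    truncation.
    """
    p1, p2 = _as_points(p1), _as_points(p2)
    out = np.zeros((p1.shape[0], n_tof))
    _kernels.tof_forward_kernel(np.ascontiguousarray(vol, dtype=np.float64).ravel(),
                                p1, p2, *_grid_args(grid), *_tof_args(geometry), out)
    return out


def tof_back_project(vals, p1, p2, grid: Grid, geometry: ScannerGeometry) -> np.ndarray:
    """Adjoint of :func:`tof_forward_project`."""
    p1, p2 = _as_points(p1), _as_points(p2)
    vals = np.ascontiguousarray(vals, dtype=np.float64)
    out = np.zeros(int(np.prod(grid.shape)))
    _kernels.tof_back_kernel(vals, p1, p2, *_grid_args(grid),
                             *_tof_args(geometry), out)
    return out.reshape(grid.shape)


def attenuation_factors(mu_map, p1, p2, grid: Grid, energy_mode: int = 511) -> np.ndarray:
    """Attenuation factors a_i = exp(-eta sum_j l_ij mu_j) in (0, 1].

    ``energy_mode`` 511 uses eta = 1; 307 uses eta = 1.2276 applied to
    the 511 keV mu-map (mu-maps are stored at 511 keV everywhere).
    """
    mu_map = np.asarray(mu_map, dtype=float)
    if np.any(mu_map < 0):
        raise ValueError("negative attenuation coefficients")
    if energy_mode == 511:
        eta = 1.0
    elif energy_mode == 307:
        eta = ETA_307
    else:
        raise ValueError("energy_mode must be 511 or 307")
    return np.exp(-eta * forward_project(mu_map, p1, p2, grid))


def eta_transform(mu511_map, eta: float = ETA_307, inverse: bool = False) -> np.ndarray:
    """Voxelwise energy scaling between 511 keV and 307 keV mu-maps."""
    mu511_map = np.asarray(mu511_map, dtype=float)
    if np.any(mu511_map < 0):
        raise ValueError("negative attenuation coefficients")
    return mu511_map / eta if inverse else mu511_map * eta
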