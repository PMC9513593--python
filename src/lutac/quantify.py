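"""Post-reconstruction corrections and image-quality metrics.

Conventions follow the transmission-imaging evaluation they support:
NRMSE normalizes the root-mean-square error by the *evaluated*
image's dynamic range (a configuration switch offers the conventional
ground-truth-range denominator); voxel bias is the relative error
against the ground truth; SSIM uses unit exponents on the luminance,
contrast and structure terms with a 3-D Gaussian window of sigma 1.5
voxels; VOI statistics summarize the voxel-bias distribution per
organ in boxplot form; lesion SUVmax bias is evaluated against both
the ground-truth activity map and the ground-truth-mu OSEM
reconstruction.  The SUV normalization constant cancels in every
percentage bias and is fixed to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter, uniform_filter1d

from .constants import MU_WATER_511
from .phantom import Phantom, voi_mask

__all__ = [
    "MetricPair", "MetricsReport", "water_peak_scale", "nrmse", "ssim",
    "voxel_bias", "voi_stats", "lesion_suvmax_bias",
]


@dataclass(frozen=True)
class MetricPair:
    """An evaluated volume and its ground truth on the same grid."""

    x: np.ndarray
    x_check: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        if np.shape(self.x) != np.shape(self.x_check):
            raise ValueError("evaluated and ground-truth volumes differ in shape")


@dataclass
class MetricsReport:
    """Collected metrics of one reconstruction arm."""

    nrmse_percent: Optional[float] = None
    ssim: Optional[float] = None
    voi_records: list = field(default_factory=list)
    lesion_records: list = field(default_factory=list)
    scaling_factor: float = 1.0
    extras: dict = field(default_factory=dict)

    @property
    def max_abs_mean_voi_bias(self) -> Optional[float]:
        """Headline statistic: max over organs of |mean bias|, %."""
        if not self.voi_records:
            return None
        per_organ: dict = {}
        for rec in self.voi_records:
            per_organ.setdefault(rec["organ"], []).append(rec["mean"])
        return 100.0 * max(abs(float(np.mean(v))) for v in per_organ.values())

    @property
    def within_10_percent(self) -> Optional[bool]:
        m = self.max_abs_mean_voi_bias
        return None if m is None else bool(m <= 10.0)


def water_peak_scale(mu_map, target_mu_water: float = MU_WATER_511,
                     bin_width: float = 2e-4, search_lo: float = 0.007,
                     search_hi: float = 0.012, smooth_bins: int = 3):
    """Globally rescale a mu-map so its soft-tissue histogram mode
    matches the attenuation coefficient of water.

    The voxel histogram (bin width 2e-4 mm^-1, lightly smoothed) is
    searched for its highest mode within [0.007, 0.012] mm^-1; the map
    is multiplied by target/mode.  Without a mode in the window the
    map is returned unscaled with a warning.

    Returns ``(scaled_map, factor)``.
    """
    mu_map = np.asarray(mu_map, dtype=float)
    edges = np.arange(0.0, max(mu_map.max(), search_hi) + 2 * bin_width, bin_width)
    hist, edges = np.histogram(mu_map[mu_map > 0], bins=edges)
    if smooth_bins > 1:
        hist = uniform_filter1d(hist.astype(float), smooth_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    win = (centers >= search_lo) & (centers <= search_hi)
    if not np.any(win) or hist[win].max() <= 0:
        warnings.warn("no soft-tissue mode found in the search window; "
                      "returning the map unscaled")
        return mu_map.copy(), 1.0
    mode = centers[win][np.argmax(hist[win])]
    factor = target_mu_water / mode
    return factor * mu_map, float(factor)


def nrmse(pair: MetricPair, denominator: str = "evaluated") -> float:
    """Normalized root-mean-square error in percent.

    ``denominator='evaluated'`` divides by the evaluated image's range
    (max - min); ``'ground_truth'`` uses the reference range instead.
    A constant evaluated image has no range and raises.
    """
    x = np.asarray(pair.x, float)
    xc = np.asarray(pair.x_check, float)
    if pair.mask is not None:
        x, xc = x[pair.mask], xc[pair.mask]
    rmse = float(np.sqrt(np.mean((x - xc) ** 2)))
    ref = x if denominator == "evaluated" else xc
    rng = float(ref.max() - ref.min())
    if rng == 0:
        raise ValueError("image range is zero; NRMSE undefined")
    return 100.0 * rmse / rng


def ssim(pair: MetricPair, sigma: float = 1.5, truncate: float = 3.5) -> float:
    """Structural similarity with equal (unit) weighting of the
    luminance, contrast and structure terms.

    3-D Gaussian window (sigma in voxels, reflect boundary),
    stabilizing constants C1 = (0.01 L)^2, C2 = (0.03 L)^2,
    C3 = C2/2 with L the ground-truth dynamic range; mean over voxels
    with a filter-radius strip around the edges excluded.
    """
    x = np.asarray(pair.x, float)
    y = np.asarray(pair.x_check, float)
    L = float(y.max() - y.min())
    if L == 0:
        L = max(float(x.max() - x.min()), 1e-12)
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    c3 = c2 / 2.0

    f = dict(sigma=sigma, truncate=truncate, mode="reflect")
    mx = gaussian_filter(x, **f)
    my = gaussian_filter(y, **f)
    vx = gaussian_filter(x * x, **f) - mx * mx
    vy = gaussian_filter(y * y, **f) - my * my
    cxy = gaussian_filter(x * y, **f) - mx * my
    vx = np.maximum(vx, 0.0)
    vy = np.maximum(vy, 0.0)
    sx, sy = np.sqrt(vx), np.sqrt(vy)

    lum = (2 * mx * my + c1) / (mx**2 + my**2 + c1)
    con = (2 * sx * sy + c2) / (vx + vy + c2)
    stru = (cxy + c3) / (sx * sy + c3)
    smap = lum * con * stru
    pad = int(truncate * sigma + 0.5)
    if all(s > 2 * pad for s in smap.shape):
        sl = tuple(slice(pad, s - pad) for s in smap.shape)
        smap = smap[sl]
        mask = pair.mask[sl] if pair.mask is not None else None
    else:
        mask = pair.mask
    if mask is not None:
        smap = smap[mask]
    return float(smap.mean())


def voxel_bias(pair: MetricPair) -> np.ma.MaskedArray:
    """Relative voxel-wise error (x - x_check)/x_check, masked where
    the ground truth is zero (and outside an optional mask)."""
    x = np.asarray(pair.x, float)
    xc = np.asarray(pair.x_check, float)
    invalid = xc == 0
    if pair.mask is not None:
        invalid |= ~pair.mask
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (x - xc) / np.where(invalid, 1.0, xc)
    return np.ma.MaskedArray(b, mask=invalid)


def voi_stats(bias_volume, phantom: Phantom, vois=None) -> list:
    """Boxplot statistics of the voxel-bias distribution per VOI.

    Records carry mean, median, quartiles, 1.5-IQR whiskers and the
    outlier count; aggregation across the VOIs of an organ happens in
    :class:`MetricsReport`.
    """
    vois = vois if vois is not None else phantom.vois
    records = []
    for voi in vois:
        m = voi_mask(phantom, voi)
        vals = np.asarray(bias_volume)[m]
        if isinstance(bias_volume, np.ma.MaskedArray):
            vals = bias_volume[m].compressed()
        if vals.size == 0:
            raise ValueError(f"empty VOI at {voi.center}")
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_w = vals[vals >= q1 - 1.5 * iqr].min()
        hi_w = vals[vals <= q3 + 1.5 * iqr].max()
        records.append({
            "organ": voi.organ_label, "center": tuple(voi.center),
            "n_voxels": int(vals.size), "mean": float(vals.mean()),
            "median": float(med), "q1": float(q1), "q3": float(q3),
            "whisker_lo": float(lo_w), "whisker_hi": float(hi_w),
            "n_outliers": int(np.sum((vals < q1 - 1.5 * iqr)
                                     | (vals > q3 + 1.5 * iqr))),
        })
    return records


def lesion_suvmax_bias(activity, references: dict, phantom: Phantom,
                       lesions=None, dilate_voxels: int = 1) -> list:
    """Per-lesion SUVmax percentage bias against reference volumes.

    The search region is the lesion sphere dilated by one voxel; the
    maximum is taken per image (its location may differ between
    images).  ``references`` maps a name (e.g. ``ground_truth``,
    ``gt_mu_osem``) to a reference volume.
    """
    lesions = lesions if lesions is not None else phantom.lesions
    x, yv, zv = phantom.grid.voxel_centers()
    act = np.asarray(activity, float)
    out = []
    for les in lesions:
        r = les.diameter / 2.0
        m = ((x - les.center[0]) ** 2 + (yv - les.center[1]) ** 2
             + (zv - les.center[2]) ** 2) <= r * r
        if dilate_voxels:
            m = binary_dilation(m, iterations=dilate_voxels)
        if not m.any():
            raise ValueError(f"empty lesion region at {les.center}")
        suv = float(act[m].max())
        rec = {"center": tuple(les.center), "diameter": les.diameter,
               "contrast": les.contrast, "host_organ": les.host_organ,
               "suvmax": suv}
        for name, ref in references.items():
            ref_suv = float(np.asarray(ref, float)[m].max())
            rec[f"bias_vs_{name}_percent"] = (
                100.0 * (suv - ref_suv) / ref_suv if ref_suv != 0 else np.nan)
        out.append(rec)
    return out
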