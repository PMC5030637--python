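"""Point-pattern statistics for patch landscapes.

Covers the descriptive chain applied to segmented patch rasters and to
simulated fields: boundary-to-boundary nearest-neighbour distances with
a border-validity rule, the root-sphere estimate built from them, the
radially averaged Fourier amplitude spectrum and its characteristic
length, Voronoi tessellation summaries, and closed-form maximum
likelihood fits of the Rayleigh and inverse-Gaussian families.

Wavenumbers are angular throughout: a pattern of wavelength L peaks at
k = 2 pi / L.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import ConvexHull, QhullError, Voronoi, cKDTree

from .detection import PatchSet

__all__ = [
    "SpectrumProfile",
    "VoronoiSummary",
    "DistributionFit",
    "RootSphereEstimate",
    "nnd_boundary",
    "root_sphere_estimate",
    "radial_spectrum",
    "voronoi_summary",
    "fit_rayleigh",
    "fit_inverse_gaussian",
]


# ---------------------------------------------------------------------------
# nearest-neighbour distances


def nnd_boundary(patches: PatchSet) -> pd.DataFrame:
    """Minimal boundary-to-boundary distance to any other patch.

    For each patch the distance is the minimum Euclidean distance
    between its boundary pixel centers and those of every other patch,
    in metres (``pixel_size`` scaled).  A patch is flagged ``valid``
    only if its NND does not exceed the distance from its boundary to
    the nearest image edge: otherwise a structure just off-image could
    be the true nearest neighbour and the measurement is unreliable.

    Returns a DataFrame with columns ``label``, ``nnd_m``, ``valid``.
    Needs at least two patches; fewer give an empty result.
    """
    labels = patches.table["label"].to_numpy()
    if len(labels) < 2:
        return pd.DataFrame(columns=["label", "nnd_m", "valid"])
    # one global erosion: distinct 8-connected patches never share pixels,
    # so the boundary of the union splits exactly into per-patch boundaries
    from scipy import ndimage

    li = patches.label_image
    occupied = li > 0
    inner = ndimage.binary_erosion(occupied, structure=np.ones((3, 3)), border_value=0)
    by, bx = np.nonzero(occupied & ~inner)
    owner_label = li[by, bx]
    order = np.argsort(owner_label, kind="stable")
    sorted_owner = owner_label[order]
    sorted_pts = np.column_stack([by, bx]).astype(float)[order]
    starts = np.searchsorted(sorted_owner, labels, side="left")
    ends = np.searchsorted(sorted_owner, labels, side="right")
    pts_list = [sorted_pts[s:e] for s, e in zip(starts, ends)]
    all_pts = np.concatenate(pts_list)
    owner = np.concatenate([np.full(len(p), i) for i, p in enumerate(pts_list)])
    tree = cKDTree(all_pts)
    h, w = patches.shape
    rows = []
    for i, (lab, pts) in enumerate(zip(labels, pts_list)):
        pts = pts.astype(float)
        best = np.inf
        k = min(32, len(all_pts))
        while True:
            d, idx = tree.query(pts, k=k)
            d = np.atleast_2d(d)
            idx = np.atleast_2d(idx)
            other = owner[idx] != i
            found = other.any(axis=1)
            if found.all() or k >= len(all_pts):
                masked = np.where(other, d, np.inf)
                best = float(masked.min())
                break
            k = min(2 * k, len(all_pts))
        edge = float(
            np.minimum(
                np.minimum(pts[:, 0], h - 1 - pts[:, 0]),
                np.minimum(pts[:, 1], w - 1 - pts[:, 1]),
            ).min()
        )
        rows.append(
            {
                "label": int(lab),
                "nnd_m": best * patches.pixel_size,
                "valid": best <= edge,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# root-sphere estimate


@dataclasses.dataclass(frozen=True)
class RootSphereEstimate:
    """Projected root-zone size inferred from spacing statistics."""

    radius_m: float
    area_m2: float
    area_ratio: float  # root-sphere area over mean canopy patch area


def root_sphere_estimate(
    mean_r_eq: float, mean_nnd: float, mean_area: float
) -> RootSphereEstimate:
    """Estimate the average root-sphere radius, area, and area ratio.

    If tussock spacing is set by non-overlapping root zones, half the
    mean boundary-to-boundary NND belongs to each patch, so the root
    sphere extends to ``mean_r_eq + mean_nnd / 2`` from the patch
    center; its area is that circle's, and the ratio compares it to the
    mean canopy (patch) area.
    """
    if mean_r_eq <= 0 or mean_nnd < 0 or mean_area <= 0:
        raise ValueError("means must be positive (mean_nnd may be 0)")
    radius = mean_r_eq + 0.5 * mean_nnd
    area = float(np.pi * radius**2)
    return RootSphereEstimate(radius, area, area / mean_area)


# ---------------------------------------------------------------------------
# radially averaged Fourier spectrum


@dataclasses.dataclass(frozen=True)
class SpectrumProfile:
    """Radially averaged Fourier amplitude versus angular wavenumber."""

    k: np.ndarray           # annulus centers, rad / length-unit
    amplitude: np.ndarray   # mean |FFT| over each annulus
    k_max: Optional[float]  # peak wavenumber (absent if featureless)
    characteristic_length: Optional[float]  # 2 pi / k_max


def radial_spectrum(
    data: np.ndarray,
    pixel_size: float,
    taper: Optional[str] = None,
) -> SpectrumProfile:
    """Radially averaged amplitude spectrum of a field or mask.

    Non-square input is center-cropped to the largest square (border
    effects dominate the long rectangular direction).  The mean is
    subtracted before transforming; optionally a Hann taper is applied.
    Annuli are one fundamental frequency ``2 pi / (N * pixel_size)``
    wide.  The peak search excludes the DC and fundamental annuli,
    where domain-scale trends live; a featureless (constant) input has
    no peak.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected a 2-D array")
    n = min(data.shape)
    r0 = (data.shape[0] - n) // 2
    c0 = (data.shape[1] - n) // 2
    sq = data[r0 : r0 + n, c0 : c0 + n]
    sq = sq - sq.mean()
    if taper == "hann":
        wy = np.hanning(n)
        sq = sq * wy[:, None] * wy[None, :]
    elif taper is not None:
        raise ValueError(f"unknown taper {taper!r}")
    amp = np.abs(np.fft.fft2(sq))
    freqs = 2.0 * np.pi * np.fft.fftfreq(n, d=pixel_size)
    kr = np.hypot(freqs[:, None], freqs[None, :])
    dk = 2.0 * np.pi / (n * pixel_size)
    bins = np.round(kr / dk).astype(int)
    n_bins = n // 2 + 1
    sums = np.bincount(bins.ravel(), weights=amp.ravel(), minlength=n_bins)[:n_bins]
    counts = np.bincount(bins.ravel(), minlength=n_bins)[:n_bins]
    profile = sums / np.maximum(counts, 1)
    k_centers = np.arange(n_bins) * dk
    k_max = length = None
    if n_bins > 3 and profile[2:].max() > 0:
        j = 2 + int(np.argmax(profile[2:]))
        if j < n_bins - 1:  # a peak on the Nyquist edge is not a peak
            k_max = float(k_centers[j])
            length = float(2.0 * np.pi / k_max)
    return SpectrumProfile(k_centers, profile, k_max, length)


# ---------------------------------------------------------------------------
# Voronoi tessellation


@dataclasses.dataclass(frozen=True)
class VoronoiSummary:
    """Per-cell geometry of the interior Voronoi cells.

    ``cells`` has one row per retained cell: ``point_index``,
    ``n_vertices``, ``area``.  Cells are retained only if bounded and
    with every vertex inside the analysis window, so no cell is
    distorted by the unknown exterior.
    """

    cells: pd.DataFrame
    modal_vertex_count: int
    fraction_six_sided: float
    mean_area: float
    equivalent_radius: float  # radius of the circle with the mean area


def voronoi_summary(
    centers: np.ndarray,
    window: Optional[Sequence[float]] = None,
) -> VoronoiSummary:
    """Voronoi tessellation of patch centers, summarised over interior cells.

    ``window`` is ``(min0, max0, min1, max1)`` in the same coordinates
    as ``centers``; by default the bounding box of the centers.  The
    modal vertex count of a hexagonally ordered pattern is 6.

    Raises ``ValueError`` for fewer than 4 centers or degenerate
    (collinear) input, and if no cell survives the window rule.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != 2 or len(centers) < 4:
        raise ValueError("need at least 4 planar centers")
    if window is None:
        window = (
            centers[:, 0].min(),
            centers[:, 0].max(),
            centers[:, 1].min(),
            centers[:, 1].max(),
        )
    lo0, hi0, lo1, hi1 = map(float, window)
    try:
        vor = Voronoi(centers)
    except QhullError as err:
        raise ValueError(f"degenerate center configuration: {err}") from err
    rows = []
    for pi, ri in enumerate(vor.point_region):
        region = vor.regions[ri]
        if not region or -1 in region:
            continue
        verts = vor.vertices[region]
        if not (
            (verts[:, 0] >= lo0).all()
            and (verts[:, 0] <= hi0).all()
            and (verts[:, 1] >= lo1).all()
            and (verts[:, 1] <= hi1).all()
        ):
            continue
        area = float(ConvexHull(verts).volume)  # Voronoi cells are convex
        rows.append({"point_index": pi, "n_vertices": len(region), "area": area})
    if not rows:
        raise ValueError("no bounded interior Voronoi cell inside the window")
    cells = pd.DataFrame(rows)
    mean_area = float(cells["area"].mean())
    return VoronoiSummary(
        cells=cells,
        modal_vertex_count=int(cells["n_vertices"].mode().iloc[0]),
        fraction_six_sided=float((cells["n_vertices"] == 6).mean()),
        mean_area=mean_area,
        equivalent_radius=float(np.sqrt(mean_area / np.pi)),
    )


# ---------------------------------------------------------------------------
# distribution fits


@dataclasses.dataclass(frozen=True)
class DistributionFit:
    """A closed-form maximum-likelihood fit of a named family."""

    family: str
    params: dict
    n: int
    log_likelihood: float
    ks_statistic: float


def _positive_samples(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if not np.isfinite(x).all() or (x <= 0).any():
        raise ValueError("samples must be positive and finite")
    return x


def fit_rayleigh(samples) -> DistributionFit:
    """Rayleigh MLE: sigma = sqrt(sum(x^2) / (2 n)).

    The Rayleigh family describes distances whose two Cartesian
    components are independent centred Gaussians — the classic model
    for nearest-neighbour distances in weakly interacting planar
    point patterns.
    """
    x = _positive_samples(samples)
    sigma = float(np.sqrt(np.sum(x * x) / (2.0 * len(x))))
    ll = float(sps.rayleigh.logpdf(x, scale=sigma).sum())
    ks = float(sps.kstest(x, "rayleigh", args=(0.0, sigma)).statistic)
    return DistributionFit("rayleigh", {"sigma": sigma}, len(x), ll, ks)


def fit_inverse_gaussian(samples) -> DistributionFit:
    """Inverse-Gaussian MLE: mu = mean, lambda = n / sum(1/x - 1/mu).

    Right-skewed with a sharp low-end cut-off, a common model for
    Voronoi tile areas of repulsive point patterns.  All-equal samples
    have an undefined shape parameter and raise ``ValueError``.
    """
    x = _positive_samples(samples)
    mu = float(x.mean())
    denom = float(np.sum(1.0 / x) - len(x) / mu)
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("degenerate sample: inverse-Gaussian shape undefined")
    lam = float(len(x) / denom)
    ll = float(sps.invgauss.logpdf(x, mu / lam, scale=lam).sum())
    ks = float(sps.kstest(x, "invgauss", args=(mu / lam, 0.0, lam)).statistic)
    return DistributionFit(
        "inverse-gaussian", {"mu": mu, "lambda": lam}, len(x), ll, ks
    )
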