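"""Per-particle size and shape descriptors from binary pixel masks.

A segmented particle is a single 8-connected set of pixels. From its mask
(and the underlying grayscale values) this module computes the descriptor
set used for milk-fat-globule characterization:

* circle-equivalent (CE) diameter ``2·sqrt(area/π)``;
* high-sensitivity (HS) circularity ``4π·area/perimeter²``;
* convexity (convex-hull perimeter / particle perimeter);
* solidity (particle area / convex-hull area);
* elongation ``1 − width/length`` with length the maximum Feret diameter;
* intensity mean and population standard deviation on the 0–255 scale.

Perimeter estimation
--------------------
The single most consequential numerical choice here is the perimeter
estimator: a naive count of pixel edges overestimates a digital disk's
perimeter by ~27%, which would push genuinely circular globules below the
0.920 circularity threshold. We therefore trace the outer boundary
(Moore-neighbor tracing), derive the Freeman chain code, and apply the
corner-corrected Vossepoel–Smeulders weights

    P = 0.980·N_even + 1.406·N_diag − 0.091·N_corner + π

where ``N_even`` counts axial steps, ``N_diag`` diagonal steps and
``N_corner`` chain-code direction changes. The trailing ``+π`` converts the
pixel-center contour to the half-pixel outer offset boundary (exact for
convex sets: offsetting a convex contour outward by r adds 2πr). Digital
disks of diameter 12–200 px reproduce πd within 1%; axis-aligned squares
carry a known +4% bias relative to the ideal 4a (circularity 0.82 instead
of π/4 ≈ 0.785), and thin 1-px bars underestimate their rectangle outline
by up to ~1.5 px. All convex-hull quantities apply the same half-pixel
offset so circularity, convexity and solidity are mutually consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label as sk_label

__all__ = [
    "ParticleRecord",
    "trace_boundary",
    "chain_code",
    "perimeter",
    "ce_diameter",
    "descriptors",
    "records_to_dataframe",
    "SINGLE_PIXEL_PERIMETER",
]

# Moore neighborhood in clockwise order starting north (row, col offsets).
_DIRS = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_DIR_INDEX = {d: i for i, d in enumerate(_DIRS)}

# Vossepoel–Smeulders chain-code weights and the half-pixel offset term.
_W_EVEN = 0.980
_W_DIAG = 1.406
_W_CORNER = -0.091
_OFFSET = math.pi

#: Documented perimeter of a single isolated pixel (a disk of diameter 1).
SINGLE_PIXEL_PERIMETER = math.pi


@dataclass
class ParticleRecord:
    """All measured descriptors for one segmented particle."""

    particle_id: int
    area_px: int
    area_um2: float
    perimeter_um: float
    hull_perimeter_um: float
    hull_area_um2: float
    ce_diameter_um: float
    hs_circularity: float
    convexity: float
    solidity: float
    length_um: float
    width_um: float
    elongation: float
    intensity_mean: float
    intensity_sd: float
    centroid_um: tuple[float, float]


def trace_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Trace the outer boundary of a single 8-connected component.

    Returns the closed sequence of boundary pixel coordinates (row, col)
    in clockwise order, starting from the topmost-leftmost pixel. Uses
    Moore-neighbor tracing with Jacob's stopping criterion.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise ValueError("empty mask: no foreground pixels")
    p = np.pad(mask, 1)
    rows, cols = np.nonzero(p)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost (row-major)
    if len(rows) == 1:
        return [(start[0] - 1, start[1] - 1)]

    boundary = [start]
    c = start
    b = (start[0], start[1] - 1)  # west neighbor, background by construction
    first_next: tuple[int, int] | None = None
    limit = 4 * p.size
    while True:
        bi = _DIR_INDEX[(b[0] - c[0], b[1] - c[1])]
        nxt = None
        for k in range(1, 9):
            d = _DIRS[(bi + k) % 8]
            cand = (c[0] + d[0], c[1] + d[1])
            if p[cand]:
                nxt = cand
                break
            b = cand
        if nxt is None:  # isolated pixel reachable only if len==1, handled above
            break
        if c == start and nxt == first_next:
            if len(boundary) > 1 and boundary[-1] == start:
                boundary.pop()  # closure re-appended the start pixel
            break
        c = nxt
        if first_next is None:
            first_next = c
        boundary.append(c)
        if len(boundary) > limit:
            raise RuntimeError("boundary trace failed to terminate")
    return [(r - 1, col - 1) for r, col in boundary]


def chain_code(boundary: list[tuple[int, int]]) -> list[int]:
    """Freeman chain code (0..7, clockwise from north) of a closed boundary."""
    n = len(boundary)
    if n < 2:
        return []
    codes = []
    for i in range(n):
        a = boundary[i]
        b = boundary[(i + 1) % n]
        codes.append(_DIR_INDEX[(b[0] - a[0], b[1] - a[1])])
    return codes


def _perimeter_px(boundary: list[tuple[int, int]]) -> float:
    codes = chain_code(boundary)
    if not codes:
        return SINGLE_PIXEL_PERIMETER
    arr = np.asarray(codes)
    n_diag = int(np.count_nonzero(arr % 2))
    n_even = arr.size - n_diag
    n_corner = int(np.count_nonzero(arr != np.roll(arr, 1)))
    return _W_EVEN * n_even + _W_DIAG * n_diag + _W_CORNER * n_corner + _OFFSET


def _assert_single_component(mask: np.ndarray) -> None:
    n = sk_label(mask, connectivity=2).max()
    if n == 0:
        raise ValueError("empty mask: no foreground pixels")
    if n > 1:
        raise ValueError(f"mask has {n} 8-connected components; expected exactly 1")


def perimeter(mask: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Boundary length of a single 8-connected component, in µm."""
    mask = np.asarray(mask, dtype=bool)
    _assert_single_component(mask)
    return _perimeter_px(trace_boundary(mask)) * pixel_size_um


def ce_diameter(area_um2: float) -> float:
    """Circle-equivalent diameter ``2·sqrt(area/π)`` of a projected area."""
    if area_um2 <= 0:
        raise ValueError(f"area must be positive, got {area_um2}")
    return 2.0 * math.sqrt(area_um2 / math.pi)


_HULL_AREA_OFFSET = 0.35  # px; see docstring below


def _hull_quantities(boundary_xy: np.ndarray) -> tuple[float, float]:
    """(hull perimeter, hull area) in px of the offset convex hull.

    The hull is computed on boundary pixel centers, then dilated outward:
    the perimeter by the 0.5 px offset used for the particle perimeter
    (+2π·0.5 = +π), the area by a 0.35 px offset
    (area + 0.35·perimeter + π·0.35²). The smaller area radius reflects
    that hull *vertices* are the extreme boundary centers, which for
    digitized convex shapes sit ~0.35 px inside the true boundary on
    average (calibrated on digital disks d = 25–100, where it holds
    solidity at 1.000 ± 0.006, and exact stadium hulls of two-disk
    dumbbells, error < 0.001). Degenerate (collinear) point sets fall
    back to the stadium around the longest segment.
    """
    pts = np.unique(boundary_xy, axis=0).astype(float)
    if len(pts) >= 3:
        try:
            hull = ConvexHull(pts)
            perim_c = hull.area  # in 2-D, .area is the hull perimeter
            area_c = hull.volume  # and .volume the enclosed area
            return (
                perim_c + _OFFSET,
                area_c + _HULL_AREA_OFFSET * perim_c + math.pi * _HULL_AREA_OFFSET**2,
            )
        except QhullError:
            pass  # collinear input: stadium fallback below
    # all points on a segment: offset hull is a stadium
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    length = float(d.max())
    return (
        2.0 * length + _OFFSET,
        2.0 * _HULL_AREA_OFFSET * length + math.pi * _HULL_AREA_OFFSET**2,
    )


def _principal_extents(mask: np.ndarray, boundary_xy: np.ndarray) -> tuple[float, float]:
    """(length, width) in px: caliper extents along and perpendicular to the
    principal (second-moment) axis of the particle.

    This is the instrument's length/width convention: the major axis comes
    from the pixel covariance, and length/width are the boundary-point
    extents parallel and perpendicular to it (+1 px for the half-pixel
    margin on each side). Using the principal axis rather than the maximum
    Feret direction keeps elongation at 0 for squares and at 1 − h/w for
    axis-aligned rectangles (the max Feret of a rectangle is its diagonal).
    """
    rows, cols = np.nonzero(mask)
    x = cols - cols.mean()
    y = rows - rows.mean()
    mu20, mu02, mu11 = (x * x).mean(), (y * y).mean(), (x * y).mean()
    theta = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)
    c, s = math.cos(theta), math.sin(theta)
    pts = np.asarray(boundary_xy, dtype=float)
    along = pts[:, 0] * c + pts[:, 1] * s
    across = -pts[:, 0] * s + pts[:, 1] * c
    length = float(along.max() - along.min() + 1.0)
    width = float(across.max() - across.min() + 1.0)
    return length, width


def descriptors(
    mask: np.ndarray,
    image: np.ndarray,
    pixel_size_um: float,
    particle_id: int = 0,
    origin_px: tuple[int, int] = (0, 0),
) -> ParticleRecord:
    """Compute the full descriptor record for one particle.

    Parameters
    ----------
    mask : bool array, one 8-connected component inside the image frame.
    image : grayscale array on the 0–255 scale, same shape as ``mask``.
    pixel_size_um : physical size of one pixel in µm.
    origin_px : (row, col) of the mask's origin in the full frame, so
        centroids stay in frame coordinates when working on crops.
    """
    mask = np.asarray(mask, dtype=bool)
    image = np.asarray(image)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    _assert_single_component(mask)
    vals = image[mask].astype(float)
    if vals.min() < 0 or vals.max() > 255:
        raise ValueError("image intensities must be on the 0-255 scale")

    area_px = int(mask.sum())
    area_um2 = area_px * pixel_size_um**2

    boundary = trace_boundary(mask)
    bxy = np.array([(c, r) for r, c in boundary], dtype=float)  # (x, y)
    perim_px = _perimeter_px(boundary)
    hull_perim_px, hull_area_px = _hull_quantities(bxy)
    length_px, width_px = _principal_extents(mask, bxy)
    if width_px > length_px:
        length_px, width_px = width_px, length_px

    hs_circ = min(1.0, 4.0 * math.pi * area_px / perim_px**2)
    convexity = float(np.clip(hull_perim_px / perim_px, 0.0, 1.0))
    solidity = float(np.clip(area_px / hull_area_px, 0.0, 1.0))
    elongation = float(np.clip(1.0 - width_px / length_px, 0.0, 1.0))

    rows, cols = np.nonzero(mask)
    centroid = (
        float((cols.mean() + origin_px[1] + 0.5) * pixel_size_um),
        float((rows.mean() + origin_px[0] + 0.5) * pixel_size_um),
    )
    return ParticleRecord(
        particle_id=particle_id,
        area_px=area_px,
        area_um2=area_um2,
        perimeter_um=perim_px * pixel_size_um,
        hull_perimeter_um=hull_perim_px * pixel_size_um,
        hull_area_um2=hull_area_px * pixel_size_um**2,
        ce_diameter_um=ce_diameter(area_um2),
        hs_circularity=hs_circ,
        convexity=convexity,
        solidity=solidity,
        length_um=length_px * pixel_size_um,
        width_um=width_px * pixel_size_um,
        elongation=elongation,
        intensity_mean=float(vals.mean()),
        intensity_sd=float(vals.std()),  # population (1/n) normalization
        centroid_um=centroid,
    )


#: Stable column order for particle CSV output.
PARTICLE_COLUMNS = [
    "particle_id",
    "area_px",
    "area_um2",
    "perimeter_um",
    "hull_perimeter_um",
    "hull_area_um2",
    "ce_diameter_um",
    "hs_circularity",
    "convexity",
    "solidity",
    "length_um",
    "width_um",
    "elongation",
    "intensity_mean",
    "intensity_sd",
    "centroid_x_um",
    "centroid_y_um",
]


def records_to_dataframe(records: list[ParticleRecord]) -> pd.DataFrame:
    """Flatten particle records into a DataFrame with a stable column order."""
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in dc_fields(r) if f.name != "centroid_um"}
        d["centroid_x_um"], d["centroid_y_um"] = r.centroid_um
        rows.append(d)
    return pd.DataFrame(rows, columns=PARTICLE_COLUMNS)
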