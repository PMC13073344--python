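"""Synthetic bright-field globule scenes with per-particle ground truth.

Real milk-smear micrographs are not redistributable, so every downstream
stage is exercised on generated scenes instead: fields of near-circular
globules (lognormal diameters) plus multi-globule agglomerates, rendered
dark on a light background with optional Gaussian noise.

Rendering model
---------------
Disks are rasterized by pixel-center inclusion (hard mask), so analytic
area/perimeter oracles hold exactly; an optional 1-px Gaussian edge blur
can soften edges. Globule interiors get a radial shading ramp (darkest at
the rim, brightening toward the center by ``shading_delta`` gray levels),
which mimics the bright interior of a focused fat globule and — more
importantly for testing — gives particles a nonzero internal intensity SD
(≈ shading_delta/4.24 for a full disk) so the downstream intensity-SD
quality filter is exercisable. Set ``shading_delta=0`` for flat particles.

Agglomerates are chains of overlapping disks: each subsequent disk is
placed against the previous one along a random direction at center
spacing ``(1 − overlap_fraction)·(r_prev + r_next)``. Chains with modest
overlap (≤ 0.3) reliably produce silhouettes with HS circularity below
the 0.920 individual/agglomerate boundary.

Placement uses rejection sampling: silhouettes never touch (bounding
circles kept ≥ 3 px apart), and exceeding the attempt cap raises an error
naming the crowding parameters rather than silently overlapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SceneSpec",
    "GroundTruthParticle",
    "PairedSimSpec",
    "generate_scene",
    "build_cluster",
    "generate_paired",
    "write_scene",
    "write_truth",
]

_MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    Defaults emulate the study's imaging configuration: 1.25 µm camera
    pixels behind a 20× objective (0.0625 µm at the sample plane), dark
    globules (level 80) on a calibrated light background (level 230), and
    a lognormal diameter law whose arithmetic mean matches the observed
    individual-globule mean diameter of ~4.4 µm, truncated to the
    instrument's 1.5–130 µm working range.
    """

    width_px: int = 1024
    height_px: int = 1024
    pixel_size_um: float = 0.0625
    background_level: float = 230.0
    particle_level: float = 80.0
    noise_sd: float = 0.0
    n_individuals: int = 0
    n_agglomerates: int = 0
    diameter_law: tuple[float, float] = (1.3712, 0.45)  # (mu_log, sigma_log) on µm
    diameter_range_um: tuple[float, float] = (1.5, 130.0)
    cluster_size_law: float = 0.8  # k = 2 + Poisson(rate)
    overlap_fraction: float = 0.25
    shading_delta: float = 60.0
    edge_blur_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.particle_level < self.background_level:
            raise ValueError("particle_level must be darker than background_level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in (0, 1)")
        lo, hi = self.diameter_range_um
        if not 0 < lo < hi:
            raise ValueError("diameter_range_um must satisfy 0 < low < high")


@dataclass
class GroundTruthParticle:
    particle_id: int
    true_class: str  # "individual" | "agglomerate"
    center_um: tuple[float, float]
    component_diameters_um: list[float]
    true_ce_diameter_um: float


@dataclass
class PairedSimSpec:
    """Two-method paired dataset: y = intercept + slope·x + Normal(0, noise_sd)."""

    n_samples: int = 12
    x_law: tuple = ("lognormal", 1.8, 0.35)  # ("lognormal", mu, sigma) | ("normal", m, sd) | ("uniform", lo, hi)
    slope: float = 1.0
    intercept: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _sample_diameters(rng: np.random.Generator, spec: SceneSpec, n: int) -> np.ndarray:
    """Lognormal diameters truncated to the working range by resampling."""
    mu, sigma = spec.diameter_law
    lo, hi = spec.diameter_range_um
    out = np.empty(n)
    filled = 0
    for _ in range(1000):
        if filled == n:
            break
        draws = rng.lognormal(mu, sigma, size=2 * (n - filled) + 8)
        ok = draws[(draws >= lo) & (draws <= hi)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    if filled < n:
        raise RuntimeError("diameter truncation window rejects nearly all draws")
    return out


def _cluster_offsets(
    rng: np.random.Generator | None,
    radii_px: np.ndarray,
    overlap_fraction: float,
    angles: np.ndarray | None = None,
) -> np.ndarray:
    """Chain-model disk centers (k, 2), first disk at the origin."""
    k = len(radii_px)
    if angles is None:
        if rng is None:
            raise ValueError("either rng or explicit angles required")
        angles = rng.uniform(0.0, 2.0 * math.pi, size=k - 1)
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (k - 1,):
        raise ValueError(f"expected {k - 1} chain angles, got {angles.shape}")
    centers = np.zeros((k, 2))
    for i in range(1, k):
        spacing = (1.0 - overlap_fraction) * (radii_px[i - 1] + radii_px[i])
        centers[i] = centers[i - 1] + spacing * np.array(
            [math.cos(angles[i - 1]), math.sin(angles[i - 1])]
        )
    return centers


def _render_disks(shape: tuple[int, int], centers_px: np.ndarray, radii_px: np.ndarray):
    """(mask, shading) for a union of disks; pixel-center inclusion.

    ``shading`` is the normalized interior depth in [0, 1]: 0 at the rim,
    1 at a disk center (max over member disks).
    """
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    depth = np.zeros(shape, dtype=float)
    for (cx, cy), r in zip(centers_px, radii_px):
        x0 = max(0, int(math.floor(cx - r - 1)))
        x1 = min(w, int(math.ceil(cx + r + 2)))
        y0 = max(0, int(math.floor(cy - r - 1)))
        y1 = min(h, int(math.ceil(cy + r + 2)))
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        rho = np.hypot(xx + 0.5 - cx, yy + 0.5 - cy) / r
        inside = rho <= 1.0
        mask[y0:y1, x0:x1] |= inside
        sub = depth[y0:y1, x0:x1]
        np.maximum(sub, np.where(inside, 1.0 - rho, 0.0), out=sub)
    return mask, depth


def build_cluster(
    k: int,
    diameters_px: np.ndarray | list[float],
    overlap_fraction: float,
    rng: np.random.Generator | None = None,
    angles: np.ndarray | list[float] | None = None,
) -> np.ndarray:
    """Tight silhouette mask of a chain agglomerate of ``k`` disks.

    ``diameters_px`` are the member-disk diameters in pixels; consecutive
    disks overlap with center spacing ``(1 − overlap_fraction)·(r_i + r_j)``
    along random directions (or the explicit ``angles``, length k−1).
    """
    if k < 2:
        raise ValueError("an agglomerate needs k >= 2 member disks")
    if not 0 < overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in (0, 1)")
    radii = np.asarray(diameters_px, dtype=float) / 2.0
    if radii.shape != (k,):
        raise ValueError(f"expected {k} diameters, got {radii.shape}")
    if angles is None and rng is None:
        rng = np.random.default_rng(0)
    centers = _cluster_offsets(rng, radii, overlap_fraction,
                               None if angles is None else np.asarray(angles, float))
    lo = (centers - radii[:, None]).min(axis=0) - 2.0
    centers = centers - lo
    hi = (centers + radii[:, None]).max(axis=0) + 2.0
    shape = (int(math.ceil(hi[1])), int(math.ceil(hi[0])))
    mask, _ = _render_disks(shape, centers, radii)
    return mask


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, list[GroundTruthParticle]]:
    """Render one scene; returns (uint8 image, ground-truth list).

    Deterministic given ``spec.seed``. Particle silhouettes never touch.
    """
    rng = np.random.default_rng(spec.seed)
    ps = spec.pixel_size_um
    h, w = spec.height_px, spec.width_px
    mask_total = np.zeros((h, w), dtype=bool)
    depth_total = np.zeros((h, w), dtype=float)
    placed: list[tuple[float, float, float]] = []  # (cx, cy, bounding radius) px
    truth: list[GroundTruthParticle] = []
    margin_px = 3.0  # keeps silhouettes from being even 8-adjacent

    def place(bound_r: float) -> tuple[float, float]:
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            cx = rng.uniform(bound_r + 2.0, w - bound_r - 2.0)
            cy = rng.uniform(bound_r + 2.0, h - bound_r - 2.0)
            if all(
                math.hypot(cx - px, cy - py) >= bound_r + pr + margin_px
                for px, py, pr in placed
            ):
                placed.append((cx, cy, bound_r))
                return cx, cy
        raise RuntimeError(
            f"could not place a particle of bounding radius {bound_r:.1f} px after "
            f"{_MAX_PLACEMENT_ATTEMPTS} attempts in a {w}x{h} px frame holding "
            f"{len(placed)} particles; reduce counts or diameters"
        )

    pid = 0
    for _ in range(spec.n_individuals):
        d_um = float(_sample_diameters(rng, spec, 1)[0])
        r_px = d_um / (2.0 * ps)
        if 2.0 * r_px + 6.0 > min(w, h):
            raise RuntimeError(
                f"particle of diameter {d_um:.2f} um ({2 * r_px:.0f} px) cannot fit "
                f"in a {w}x{h} px frame"
            )
        cx, cy = place(r_px)
        m, dep = _render_disks((h, w), np.array([[cx, cy]]), np.array([r_px]))
        mask_total |= m
        np.maximum(depth_total, dep, out=depth_total)
        area_px = int(m.sum())
        pid += 1
        truth.append(
            GroundTruthParticle(
                particle_id=pid,
                true_class="individual",
                center_um=(cx * ps, cy * ps),
                component_diameters_um=[d_um],
                true_ce_diameter_um=2.0 * math.sqrt(area_px * ps * ps / math.pi),
            )
        )

    for _ in range(spec.n_agglomerates):
        k = 2 + int(rng.poisson(spec.cluster_size_law))
        d_um = _sample_diameters(rng, spec, k)
        radii = d_um / (2.0 * ps)
        centers = _cluster_offsets(rng, radii, spec.overlap_fraction)
        c_mean = centers.mean(axis=0)
        bound_r = float(np.max(np.linalg.norm(centers - c_mean, axis=1) + radii))
        if 2.0 * bound_r + 6.0 > min(w, h):
            raise RuntimeError(
                f"agglomerate of bounding diameter {2 * bound_r * ps:.2f} um cannot "
                f"fit in a {w}x{h} px frame"
            )
        cx, cy = place(bound_r)
        m, dep = _render_disks((h, w), centers - c_mean + (cx, cy), radii)
        mask_total |= m
        np.maximum(depth_total, dep, out=depth_total)
        area_px = int(m.sum())
        pid += 1
        truth.append(
            GroundTruthParticle(
                particle_id=pid,
                true_class="agglomerate",
                center_um=(cx * ps, cy * ps),
                component_diameters_um=[float(v) for v in d_um],
                true_ce_diameter_um=2.0 * math.sqrt(area_px * ps * ps / math.pi),
            )
        )

    image = np.full((h, w), spec.background_level, dtype=float)
    interior = spec.particle_level + spec.shading_delta * depth_total
    image[mask_total] = interior[mask_total]
    if spec.edge_blur_px > 0:
        image = ndimage.gaussian_filter(image, spec.edge_blur_px)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    return np.clip(np.round(image), 0, 255).astype(np.uint8), truth


def generate_paired(spec: PairedSimSpec):
    """Simulate two-method paired measurements (see PairedSimSpec).

    Returns an ``agreement.PairedMeasurements``; deterministic given seed.
    """
    from .agreement import PairedMeasurements

    rng = np.random.default_rng(spec.seed)
    kind, *params = spec.x_law
    n = spec.n_samples
    if kind == "lognormal":
        x = rng.lognormal(params[0], params[1], size=n)
    elif kind == "normal":
        x = rng.normal(params[0], params[1], size=n)
    elif kind == "uniform":
        x = rng.uniform(params[0], params[1], size=n)
    else:
        raise ValueError(f"unknown x_law kind {kind!r}")
    y = spec.intercept + spec.slope * x + rng.normal(0.0, spec.noise_sd, size=n)
    ids = [f"s{i + 1}" for i in range(n)]
    return PairedMeasurements(sample_ids=ids, x=x, y=y)


def write_scene(path, image: np.ndarray) -> None:
    """Write an 8-bit grayscale scene as TIFF or PNG by extension."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, image)
    else:
        from PIL import Image

        Image.fromarray(image, mode="L").save(path)


def write_truth(path, truth: list[GroundTruthParticle]) -> None:
    """Ground-truth CSV sidecar: one row per particle.

    Columns: particle_id, true_class, center_x_um, center_y_um,
    true_ce_diameter_um, n_components, component_diameters_um
    (semicolon-separated list).
    """
    import pandas as pd

    rows = [
        {
            "particle_id": t.particle_id,
            "true_class": t.true_class,
            "center_x_um": t.center_um[0],
            "center_y_um": t.center_um[1],
            "true_ce_diameter_um": t.true_ce_diameter_um,
            "n_components": len(t.component_diameters_um),
            "component_diameters_um": ";".join(
                f"{d:.4f}" for d in t.component_diameters_um
            ),
        }
        for t in truth
    ]
    pd.DataFrame(
        rows,
        columns=[
            "particle_id",
            "true_class",
            "center_x_um",
            "center_y_um",
            "true_ce_diameter_um",
            "n_components",
            "component_diameters_um",
        ],
    ).to_csv(path, index=False)
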