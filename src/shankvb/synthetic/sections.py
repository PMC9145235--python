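"""Synthetic shank cross-section images with known ground truth.

The generator emulates iodine-stained stem CT slices at three intensity
bands — background 0, tissue 120, bundles 220 — plus additive Gaussian
noise (default sd 8), which keeps the scene separable by a single
threshold without modelling CT physics.  Section outlines follow the five
shapes seen in real shank slices: round, crescent, bell, horseshoe and
irregular (a disk perturbed by low-order radial harmonics).

Bundle placement reproduces the density gradient of real sections: a dense
annulus of small bundles in the periphery (a band of configurable width
just inside the epidermis) and sparser, larger bundles spread through the
inner zone.  Placement is dart-throwing rejection sampling with a minimum
centroid gap; infeasible requests fail loudly, naming the first bundle
that could not be placed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from ..exceptions import PackingError, ValidationError
from ..imaging import SectionImage

SHAPES = ("round", "crescent", "bell", "horseshoe", "irregular")

#: epidermis depth used when planting the peripheral annulus, mm
EZ_DEPTH_MM = 0.08
#: intensity bands (see module docstring)
BG_LEVEL, TISSUE_LEVEL, BUNDLE_LEVEL = 0, 120, 220


@dataclass(frozen=True)
class SectionShapeSpec:
    """Outline of the section: one of the five shank shapes.

    ``eccentricity`` positions the carved secondary disk (crescent/bell),
    ``notch_depth_mm``/``notch_angle_deg`` shape the horseshoe notch, and
    ``harmonic_amp`` scales the radial harmonics of the irregular outline.
    """

    shape: str = "round"
    outer_radius_mm: float = 7.0
    resolution_um: float = 13.55
    eccentricity: float = 0.9
    notch_depth_mm: float = 2.0
    notch_angle_deg: float = 70.0
    harmonic_amp: float = 0.06

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValidationError(f"shape must be one of {SHAPES}")
        if self.outer_radius_mm <= 0:
            raise ValidationError("outer_radius must be positive")
        if self.resolution_um <= 0:
            raise ValidationError("resolution must be positive")
        if self.notch_depth_mm >= self.outer_radius_mm:
            raise ValidationError("notch depth must be smaller than the radius")


@dataclass(frozen=True)
class BundleSpec:
    """Counts, sizes and spacing of the planted vascular bundles.

    Default radii come from population-median bundle areas: periphery
    bundles of equivalent radius 0.139 mm and inner bundles of 0.176 mm,
    the inner ones larger as in real sections.
    """

    pz_count: int = 100
    iz_count: int = 80
    pz_radius_mm: tuple[float, float] = (0.139, 0.020)  # mean, sd
    iz_radius_mm: tuple[float, float] = (0.176, 0.025)
    min_gap_mm: float = 0.40
    pz_band_mm: float = 1.0  # width of the peripheral annulus

    def __post_init__(self):
        if self.pz_count < 0 or self.iz_count < 0:
            raise ValidationError("bundle counts must be non-negative")
        if self.pz_radius_mm[0] <= 0 or self.iz_radius_mm[0] <= 0:
            raise ValidationError("bundle radii must be positive")
        if self.min_gap_mm <= 0 or self.pz_band_mm <= 0:
            raise ValidationError("min_gap and pz_band must be positive")


@dataclass(frozen=True)
class BundleTruth:
    """One planted bundle: centre pixel, rasterised pixel area, zone."""

    center_px: tuple[int, int]  # row, col
    radius_mm: float
    area_px: int
    zone: str  # "PZ" | "IZ"


@dataclass
class SyntheticGroundTruth:
    """Everything the generator planted, for downstream validation."""

    bundles: list[BundleTruth]
    ez_depth_mm: float
    pz_boundary_depth_mm: float  # depth of the planted PZ/IZ boundary
    section_mask: np.ndarray
    resolution_um: float
    seed: int

    @property
    def n_pz(self) -> int:
        return sum(1 for b in self.bundles if b.zone == "PZ")

    @property
    def n_iz(self) -> int:
        return sum(1 for b in self.bundles if b.zone == "IZ")

    def centroids_px(self) -> np.ndarray:
        return np.array([b.center_px for b in self.bundles], dtype=float)

    def mean_bundle_diameter_mm(self) -> float:
        return 2.0 * float(np.mean([b.radius_mm for b in self.bundles]))

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "resolution_um": self.resolution_um,
            "ez_depth_mm": self.ez_depth_mm,
            "pz_boundary_depth_mm": self.pz_boundary_depth_mm,
            "bundles": [asdict(b) for b in self.bundles],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _section_mask(spec: SectionShapeSpec, rng: np.random.Generator) -> np.ndarray:
    """Rasterise the section outline on a frame with a 20 px margin."""
    r_px = spec.outer_radius_mm * 1000.0 / spec.resolution_um
    margin = 20
    half = int(math.ceil(r_px)) + margin
    size = 2 * half
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = half - 0.5
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    if spec.shape == "round":
        mask = rr <= r_px
    elif spec.shape == "crescent":
        mask = rr <= r_px
        off = spec.eccentricity * r_px
        carve = np.hypot(dy, dx - off) <= 0.75 * r_px
        mask &= ~carve
    elif spec.shape == "bell":
        mask = rr <= r_px
        off = (1.0 + spec.eccentricity) * r_px
        carve = np.hypot(dy - off, dx) <= 1.05 * r_px  # shallow bite -> flat base
        mask &= ~carve
    elif spec.shape == "horseshoe":
        mask = rr <= r_px
        depth_px = spec.notch_depth_mm * 1000.0 / spec.resolution_um
        half_ang = math.radians(spec.notch_angle_deg) / 2.0
        notch = (np.abs(theta) <= half_ang) & (rr >= r_px - depth_px)
        mask &= ~notch
    else:  # irregular: low-order radial harmonics
        amp = rng.uniform(0.4, 1.0, 4) * spec.harmonic_amp
        phase = rng.uniform(0, 2 * math.pi, 4)
        pert = sum(
            a * np.cos((k + 2) * theta + p)
            for k, (a, p) in enumerate(zip(amp, phase))
        )
        mask = rr <= r_px * (1.0 + pert)

    # keep the largest component (carving can in principle split the shape)
    lab, n = ndimage.label(mask)
    if n == 0:
        raise ValidationError("degenerate section outline")
    if n > 1:
        mask = lab == (np.argmax(np.bincount(lab.ravel())[1:]) + 1)
    return mask


def _place_bundles(
    depth_px: np.ndarray,
    radii_px: np.ndarray,
    lo_px: np.ndarray,
    hi_px: np.ndarray,
    zone_names: list[str],
    min_gap_px: float,
    rng: np.random.Generator,
    max_attempts: int = 2000,
) -> np.ndarray:
    """Dart-throwing placement of bundle centres.

    Each bundle i gets a centre pixel with contour depth in
    [lo_px[i], hi_px[i]]; pairwise centre distances must exceed
    max(min_gap, r_i + r_j + clearance).  Raises PackingError naming the
    first unplaceable bundle.
    """
    clearance_px = 6.0
    inside = depth_px > 0
    flat_depth = depth_px[inside]
    coords = np.argwhere(inside)
    order = np.argsort(flat_depth)
    flat_depth = flat_depth[order]
    coords = coords[order]

    placed = np.empty((0, 2), float)
    placed_r = np.empty(0, float)
    centers = np.zeros((len(radii_px), 2), float)
    for i, (r_i, lo, hi) in enumerate(zip(radii_px, lo_px, hi_px)):
        j0, j1 = np.searchsorted(flat_depth, [lo, hi])
        if j1 <= j0:
            raise PackingError(
                f"bundle {i} ({zone_names[i]}, r={r_i:.1f} px): no eligible pixels"
            )
        for _ in range(max_attempts):
            c = coords[rng.integers(j0, j1)].astype(float)
            if placed.shape[0]:
                d = np.hypot(*(placed - c).T)
                gap = np.maximum(min_gap_px, placed_r + r_i + clearance_px)
                if np.any(d < gap):
                    continue
            placed = np.vstack([placed, c])
            placed_r = np.append(placed_r, r_i)
            centers[i] = c
            break
        else:
            raise PackingError(
                f"bundle {i} ({zone_names[i]}, r={r_i:.1f} px) could not be "
                f"placed after {max_attempts} attempts"
            )
    return centers


def generate_cross_section(
    shape: SectionShapeSpec,
    bundles: BundleSpec,
    seed: int,
    noise_sd: float = 8.0,
) -> tuple[SectionImage, SyntheticGroundTruth]:
    """Generate one synthetic cross-section image plus its ground truth.

    Identical seeds produce bit-identical rasters.  Periphery bundles are
    placed in the annulus between the epidermis and ``pz_band_mm`` below
    it; inner bundles uniformly in the remaining disk.
    """
    rng = np.random.default_rng(seed)
    mm_per_px = shape.resolution_um / 1000.0
    mask = _section_mask(shape, rng)
    depth_px = ndimage.distance_transform_edt(mask)

    ez_px = EZ_DEPTH_MM / mm_per_px
    band_px = bundles.pz_band_mm / mm_per_px
    boundary_px = ez_px + band_px
    max_depth = float(depth_px.max())
    if boundary_px >= max_depth and bundles.iz_count > 0:
        raise ValidationError("pz_band leaves no inner zone for this section")

    # radii, truncated to keep every bundle detectable and packable
    r_pz = np.clip(
        rng.normal(bundles.pz_radius_mm[0], bundles.pz_radius_mm[1], bundles.pz_count),
        0.06, 2.5 * bundles.pz_radius_mm[0],
    )
    r_iz = np.clip(
        rng.normal(bundles.iz_radius_mm[0], bundles.iz_radius_mm[1], bundles.iz_count),
        0.06, 2.5 * bundles.iz_radius_mm[0],
    )
    radii_mm = np.concatenate([r_pz, r_iz])
    radii_px = radii_mm / mm_per_px
    zone_names = ["PZ"] * bundles.pz_count + ["IZ"] * bundles.iz_count

    # quick area bound: reject grossly infeasible requests up front
    cum_area = np.cumsum(math.pi * radii_px**2)
    over = np.nonzero(cum_area > 0.9 * mask.sum())[0]
    if over.size:
        i = int(over[0])
        raise PackingError(
            f"bundle {i} ({zone_names[i]}): cumulative bundle area exceeds "
            "the section area"
        )

    edge_px = 2.0  # keep planted centres clear of the zone boundary
    lo = np.where(
        np.arange(len(radii_px)) < bundles.pz_count,
        np.maximum(ez_px + edge_px, radii_px + 2.0),
        np.maximum(boundary_px + edge_px, radii_px + 2.0),
    )
    hi = np.where(
        np.arange(len(radii_px)) < bundles.pz_count,
        boundary_px - edge_px,
        np.full(len(radii_px), max_depth),
    )
    centers = _place_bundles(
        depth_px, radii_px, lo, hi, zone_names,
        bundles.min_gap_mm / mm_per_px, rng,
    )

    # rasterise
    img = np.zeros(mask.shape, dtype=float)
    img[mask] = TISSUE_LEVEL
    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    truth_bundles: list[BundleTruth] = []
    for (cy, cx), r_px_i, r_mm_i, zn in zip(centers, radii_px, radii_mm, zone_names):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px_i**2
        img[disk] = BUNDLE_LEVEL
        truth_bundles.append(
            BundleTruth(
                center_px=(int(round(cy)), int(round(cx))),
                radius_mm=float(r_mm_i),
                area_px=int(disk.sum()),
                zone=zn,
            )
        )

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = SyntheticGroundTruth(
        bundles=truth_bundles,
        ez_depth_mm=EZ_DEPTH_MM,
        pz_boundary_depth_mm=EZ_DEPTH_MM + bundles.pz_band_mm,
        section_mask=mask,
        resolution_um=shape.resolution_um,
        seed=seed,
    )
    return SectionImage(pixels, shape.resolution_um), truth


def rasterize_scene(
    section_mask: np.ndarray,
    centers_px,
    radii_px,
    resolution_um: float = 13.55,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SectionImage:
    """Low-level renderer: paint explicit bundle disks on a tissue mask.

    Used to construct pathological cases (fused bundles, undersized
    bundles) that the main generator refuses to plant.
    """
    img = np.zeros(section_mask.shape, float)
    img[section_mask] = TISSUE_LEVEL
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    for (cy, cx), r in zip(centers_px, radii_px):
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = BUNDLE_LEVEL
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return SectionImage(np.clip(np.rint(img), 0, 255).astype(np.uint8), resolution_um)
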