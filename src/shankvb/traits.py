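"""The 36 cross-section traits computed from mask, zones and bundles.

Aggregation rules:

* cross-section (SZ_*) descriptors come from the tissue mask geometry;
* zone areas are pixel counts of the partition labels, zone thicknesses
  are radial measurements along rays from the section centroid;
* per-zone bundle aggregates (counts, total areas, total convex areas,
  mean convex-area ratio) run over zone-assigned bundles only;
* VB_*ave averages are unweighted means over all bundles;
* VB_LWR = VB_LAave / VB_SAave;
* SRVB = mean nearest-neighbour centroid distance / mean bundle
  equivalent diameter;
* ARIVB = mean bundle area in PZ / mean bundle area in IZ.

Zones with zero bundles report their averages as missing (NaN) and their
densities as 0; a scene with no bundles at all is an error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import registry
from .exceptions import ValidationError
from .geometry import GeometryMeasures, region_geometry
from .imaging import (
    EZ,
    IZ,
    PZ,
    BundleRegion,
    SectionImage,
    SectionMask,
    ZonePartition,
    analyze_section,
)


@dataclass
class TraitVector:
    """All 36 traits of one section; missing zone averages are NaN."""

    values: dict[str, float]

    def __post_init__(self):
        missing = set(registry.trait_names()) - set(self.values)
        if missing:
            raise ValidationError(f"trait vector incomplete: {sorted(missing)}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_series(self) -> pd.Series:
        return pd.Series({n: self.values[n] for n in registry.trait_names()})


def zone_thickness(partition: ZonePartition, zone: str, n_rays: int = 720) -> float:
    """Mean radial thickness of a zone band, in mm.

    Rays are cast from the section centroid; EZ_T and PZ_T are the mean
    radial widths of their bands, IZ_T is the mean radial distance from
    the centroid to the PZ/IZ boundary.
    """
    labels = partition.labels
    if not (labels == {"EZ": 1, "PZ": 2, "IZ": 3}[zone]).any():
        raise ValidationError(f"zone {zone} is empty in this partition")
    inside = labels > 0
    rr, cc = np.nonzero(inside)
    cy, cx = rr.mean(), cc.mean()
    mm = partition.resolution_um / 1000.0
    max_r = float(np.hypot(rr - cy, cc - cx).max()) + 2.0

    angles = np.linspace(0.0, 2.0 * math.pi, n_rays, endpoint=False)
    step = 0.5
    radii = np.arange(0.0, max_r + step, step)
    ys = np.clip(np.rint(cy + np.outer(np.sin(angles), radii)), 0,
                 labels.shape[0] - 1).astype(int)
    xs = np.clip(np.rint(cx + np.outer(np.cos(angles), radii)), 0,
                 labels.shape[1] - 1).astype(int)
    lab_ray = labels[ys, xs]  # (n_rays, n_radii)

    def last_radius(mask_row: np.ndarray) -> float:
        nz = np.nonzero(mask_row)[0]
        return radii[nz[-1]] if nz.size else np.nan

    widths = []
    for row in lab_ray:
        r_outer = last_radius(row > 0)
        r_pz = last_radius((row == 2) | (row == 3))  # outer edge of PZ band
        r_iz = last_radius(row == 3)                 # PZ/IZ boundary
        if np.isnan(r_outer):
            continue
        if zone == EZ:
            if not np.isnan(r_pz):
                widths.append(r_outer - r_pz)
        elif zone == PZ:
            if not (np.isnan(r_pz) or np.isnan(r_iz)):
                widths.append(r_pz - r_iz)
        else:
            if not np.isnan(r_iz):
                widths.append(r_iz)
    if not widths:
        raise ValidationError(f"zone {zone} not crossed by any ray")
    return float(np.mean(widths)) * mm


def _bundle_geometry(bundles, resolution_um: float) -> list[GeometryMeasures]:
    return [region_geometry(b.coords, resolution_um) for b in bundles]


def _zone_aggregates(geoms, zone_area_mm2: float) -> dict[str, float]:
    n = len(geoms)
    if n == 0:
        return {"N": 0.0, "D": 0.0, "CAR": np.nan, "CA": np.nan, "A": np.nan}
    return {
        "N": float(n),
        "D": n / zone_area_mm2 if zone_area_mm2 > 0 else 0.0,
        "CAR": float(np.mean([g.car for g in geoms])),
        "CA": float(sum(g.convex_area_mm2 for g in geoms)),
        "A": float(sum(g.area_mm2 for g in geoms)),
    }


def compute_trait_vector(
    mask: SectionMask,
    partition: ZonePartition,
    bundles,
    resolution_um: float | None = None,
) -> TraitVector:
    """Assemble the full 36-trait vector for one section.

    Every bundle must already carry a zone label (PZ or IZ).
    """
    blist = list(bundles)
    if not blist:
        raise ValidationError("no bundles: trait vector undefined")
    if any(b.zone not in (PZ, IZ) for b in blist):
        raise ValidationError("all bundles must be zone-assigned first")
    res = resolution_um if resolution_um is not None else mask.resolution_um

    sz = region_geometry(mask.mask, res)
    geoms = _bundle_geometry(blist, res)
    pz_geoms = [g for g, b in zip(geoms, blist) if b.zone == PZ]
    iz_geoms = [g for g, b in zip(geoms, blist) if b.zone == IZ]

    ez_area = partition.zone_area_mm2(EZ)
    pz_area = partition.zone_area_mm2(PZ)
    iz_area = partition.zone_area_mm2(IZ)
    pz_agg = _zone_aggregates(pz_geoms, pz_area)
    iz_agg = _zone_aggregates(iz_geoms, iz_area)

    la = float(np.mean([g.major_axis_mm for g in geoms]))
    sa = float(np.mean([g.minor_axis_mm for g in geoms]))
    vb_a = float(sum(g.area_mm2 for g in geoms))
    n_all = len(geoms)

    # separation ratio: mean NN distance over mean equivalent diameter
    cent = np.array([b.centroid for b in blist], float) * (res / 1000.0)
    if n_all >= 2:
        dists, _ = cKDTree(cent).query(cent, k=2)
        mean_nn = float(dists[:, 1].mean())
    else:
        mean_nn = np.nan
    mean_area = vb_a / n_all
    eq_diam = 2.0 * math.sqrt(mean_area / math.pi)
    srvb = mean_nn / eq_diam if eq_diam > 0 else np.nan

    pz_mean_area = pz_agg["A"] / pz_agg["N"] if pz_agg["N"] else np.nan
    iz_mean_area = iz_agg["A"] / iz_agg["N"] if iz_agg["N"] else np.nan
    arivb = pz_mean_area / iz_mean_area if iz_agg["N"] and pz_agg["N"] else np.nan

    values = {
        "SZ_SA": sz.minor_axis_mm,
        "SZ_P": sz.perimeter_mm,
        "SZ_LWR": sz.lwr,
        "SZ_LA": sz.major_axis_mm,
        "SZ_CCA": sz.circumcircle_area_mm2,
        "SZ_CA": sz.convex_area_mm2,
        "SZ_A": sz.area_mm2,
        "EZ_T": zone_thickness(partition, EZ),
        "EZ_A": ez_area,
        "PZ_VB_N": pz_agg["N"],
        "PZ_VB_D": pz_agg["D"],
        "PZ_VB_CAR": pz_agg["CAR"],
        "PZ_VB_CA": pz_agg["CA"],
        "PZ_VB_A": pz_agg["A"],
        "PZ_T": zone_thickness(partition, PZ),
        "PZ_A": pz_area,
        "IZ_VB_N": iz_agg["N"],
        "IZ_VB_D": iz_agg["D"],
        "IZ_VB_CAR": iz_agg["CAR"],
        "IZ_VB_CA": iz_agg["CA"],
        "IZ_VB_A": iz_agg["A"],
        "IZ_T": zone_thickness(partition, IZ),
        "IZ_A": iz_area,
        "VB_SAave": sa,
        "VB_Pave": float(np.mean([g.perimeter_mm for g in geoms])),
        "VB_N": float(n_all),
        "VB_LWR": la / sa,
        "VB_LAave": la,
        "VB_D": n_all / sz.area_mm2,
        "VB_CCAave": float(np.mean([g.circumcircle_area_mm2 for g in geoms])),
        "VB_CAR": float(np.mean([g.car for g in geoms])),
        "VB_CAave": float(np.mean([g.convex_area_mm2 for g in geoms])),
        "VB_Aave": float(np.mean([g.area_mm2 for g in geoms])),
        "VB_A": vb_a,
        "SRVB": srvb,
        "ARIVB": arivb,
    }
    return TraitVector(values)


def extract_traits(image: SectionImage, **pipeline_kwargs) -> TraitVector:
    """One-call pipeline: segment, detect, partition, assign, measure."""
    mask, part, det = analyze_section(image, **pipeline_kwargs)
    return compute_trait_vector(mask, part, det.bundles)


def batch_extract(images, names=None, **pipeline_kwargs) -> pd.DataFrame:
    """Trait table for several images (paths or SectionImage objects)."""
    rows = {}
    for i, im in enumerate(images):
        if not isinstance(im, SectionImage):
            im = SectionImage.from_file(im)
        name = names[i] if names is not None else f"section_{i}"
        rows[name] = extract_traits(im, **pipeline_kwargs).to_series()
    return pd.DataFrame(rows).T[registry.trait_names()]


def write_trait_table(table: pd.DataFrame, path) -> None:
    """CSV with the 36 named columns plus a sidecar JSON unit schema."""
    table.to_csv(path)
    schema = {"traits": [
        {"name": t.name, "category": t.category, "unit": t.unit,
         "description": t.description}
        for t in registry.TRAITS
    ]}
    with open(str(path) + ".schema.json", "w") as fh:
        json.dump(schema, fh, indent=1)
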