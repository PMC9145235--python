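"""Registry of the 36 cross-section phenotypic traits.

The traits describe a maize shank cross-section ("slice zone", SZ) and its
vascular bundles (VB), organised by the three functional zones of the
section: epidermis (EZ), periphery (PZ) and inner (IZ) zone.  Five
categories partition the registry: cross-section (7), epidermis (2),
periphery (7), inner (7) and vascular bundle (13).
"""

from __future__ import annotations

from dataclasses import dataclass

CATEGORIES = ("cross_section", "epidermis", "periphery", "inner", "vascular_bundle")


@dataclass(frozen=True)
class TraitDef:
    """One named trait: abbreviation, category, physical unit, description."""

    name: str
    category: str
    unit: str
    description: str


TRAITS: tuple[TraitDef, ...] = (
    # -- cross-section (7) --------------------------------------------------
    TraitDef("SZ_SA", "cross_section", "mm", "short axis length of the slice zone"),
    TraitDef("SZ_P", "cross_section", "mm", "perimeter of the slice zone"),
    TraitDef("SZ_LWR", "cross_section", "-", "length-width ratio of the slice zone"),
    TraitDef("SZ_LA", "cross_section", "mm", "long axis length of the slice zone"),
    TraitDef("SZ_CCA", "cross_section", "mm^2", "circumcircle area of the slice zone"),
    TraitDef("SZ_CA", "cross_section", "mm^2", "convex area of the slice zone"),
    TraitDef("SZ_A", "cross_section", "mm^2", "area of the slice zone"),
    # -- epidermis zone (2) -------------------------------------------------
    TraitDef("EZ_T", "epidermis", "mm", "thickness of the epidermis"),
    TraitDef("EZ_A", "epidermis", "mm^2", "area of the epidermis"),
    # -- periphery zone (7) -------------------------------------------------
    TraitDef("PZ_VB_N", "periphery", "-", "number of vascular bundles in the periphery zone"),
    TraitDef("PZ_VB_D", "periphery", "number/mm^2", "density of vascular bundles in the periphery zone"),
    TraitDef("PZ_VB_CAR", "periphery", "-", "average convex area ratio of periphery-zone bundles"),
    TraitDef("PZ_VB_CA", "periphery", "mm^2", "convex area of periphery-zone bundles"),
    TraitDef("PZ_VB_A", "periphery", "mm^2", "total area of periphery-zone bundles"),
    TraitDef("PZ_T", "periphery", "mm", "thickness of the periphery zone"),
    TraitDef("PZ_A", "periphery", "mm^2", "area of the periphery zone"),
    # -- inner zone (7) -----------------------------------------------------
    TraitDef("IZ_VB_N", "inner", "-", "number of vascular bundles in the inner zone"),
    TraitDef("IZ_VB_D", "inner", "number/mm^2", "density of vascular bundles in the inner zone"),
    TraitDef("IZ_VB_CAR", "inner", "-", "average convex area ratio of inner-zone bundles"),
    TraitDef("IZ_VB_CA", "inner", "mm^2", "convex area of inner-zone bundles"),
    TraitDef("IZ_VB_A", "inner", "mm^2", "total area of inner-zone bundles"),
    TraitDef("IZ_T", "inner", "mm", "thickness of the inner zone"),
    TraitDef("IZ_A", "inner", "mm^2", "area of the inner zone"),
    # -- vascular bundles (13) ----------------------------------------------
    TraitDef("VB_SAave", "vascular_bundle", "mm", "average short axis length of the bundles"),
    TraitDef("VB_Pave", "vascular_bundle", "mm", "average perimeter of the bundles"),
    TraitDef("VB_N", "vascular_bundle", "-", "total number of vascular bundles"),
    TraitDef("VB_LWR", "vascular_bundle", "-", "length-width ratio of the bundles (VB_LAave / VB_SAave)"),
    TraitDef("VB_LAave", "vascular_bundle", "mm", "average long axis length of the bundles"),
    TraitDef("VB_D", "vascular_bundle", "number/mm^2", "density of the vascular bundles"),
    TraitDef("VB_CCAave", "vascular_bundle", "mm^2", "average circumcircle area of the bundles"),
    TraitDef("VB_CAR", "vascular_bundle", "-", "average convex area ratio of the bundles"),
    TraitDef("VB_CAave", "vascular_bundle", "mm^2", "average convex area of the bundles"),
    TraitDef("VB_Aave", "vascular_bundle", "mm^2", "average area of the bundles"),
    TraitDef("VB_A", "vascular_bundle", "mm^2", "total area of the vascular bundles"),
    TraitDef("SRVB", "vascular_bundle", "-", "separation ratio of the bundles (mean NN distance / mean equivalent diameter)"),
    TraitDef("ARIVB", "vascular_bundle", "-", "area ratio of individual bundles (PZ mean area / IZ mean area)"),
)


def trait_names() -> list[str]:
    """All 36 trait abbreviations in registry order."""
    return [t.name for t in TRAITS]


def traits_by_category() -> dict[str, list[str]]:
    """Map each of the five categories to its trait abbreviations."""
    out: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for t in TRAITS:
        out[t.category].append(t.name)
    return out


def trait_index(name: str) -> int:
    """Position of a trait in the registry (used for deterministic ordering)."""
    for i, t in enumerate(TRAITS):
        if t.name == name:
            return i
    raise KeyError(name)


def units() -> dict[str, str]:
    return {t.name: t.unit for t in TRAITS}
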