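"""Desikan-Killiany cortical parcellation labels.

The 68-region gyral parcellation (34 regions per hemisphere) is the
standard node set for cortical-thickness covariance networks.  Region
labels follow the FreeSurfer ``aparc`` naming, suffixed with the
hemisphere (``.L`` / ``.R``).
"""

from __future__ import annotations

_DK34 = [
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
]


def desikan_killiany_68() -> list[str]:
    """Return the 68 Desikan-Killiany region labels, left hemisphere first."""
    return [f"{name}.L" for name in _DK34] + [f"{name}.R" for name in _DK34]


def generic_regions(n: int) -> list[str]:
    """Generic region labels for non-atlas synthetic networks."""
    return [f"region_{i:02d}" for i in range(n)]


def default_region_names(n_regions: int) -> list[str]:
    """DK-68 labels when the network has 68 nodes, generic labels otherwise."""
    if n_regions == 68:
        return desikan_killiany_68()
    return generic_regions(n_regions)


def hemisphere(region: str) -> str:
    """Hemisphere code ('L', 'R', or '' for generic labels)."""
    if region.endswith(".L"):
        return "L"
    if region.endswith(".R"):
        return "R"
    return ""
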