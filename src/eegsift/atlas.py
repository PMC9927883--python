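"""Desikan-Killiany cortical parcellation labels.

The 68-region atlas (34 areas per hemisphere) used to aggregate cortical
current-density time courses. Labels are the standard abbreviations with a
hemisphere suffix, e.g. ``Cu_L`` for the left cuneus.
"""

from __future__ import annotations

#: Abbreviations for the 34 Desikan-Killiany cortical areas of one hemisphere.
DK_ABBREVIATIONS: tuple[str, ...] = (
    "BSTS",  # bank of the superior temporal sulcus
    "CACC",  # caudal anterior cingulate cortex
    "CMF",   # caudal middle frontal cortex
    "Cu",    # cuneus
    "Ent",   # entorhinal cortex
    "FP",    # frontal pole
    "Fu",    # fusiform gyrus
    "IP",    # inferior parietal cortex
    "IT",    # inferior temporal cortex
    "ISC",   # isthmus of the cingulate cortex
    "LOC",   # lateral occipital cortex
    "LOF",   # lateral orbito-frontal cortex
    "Lin",   # lingual gyrus
    "MOF",   # medial orbito-frontal cortex
    "MT",    # middle temporal cortex
    "PCL",   # paracentral lobule
    "PHG",   # parahippocampal gyrus
    "POP",   # pars opercularis
    "POR",   # pars orbitalis
    "PTR",   # pars triangularis
    "PCal",  # pericalcarine cortex
    "PSC",   # postcentral gyrus
    "PCC",   # posterior cingulate cortex
    "PRC",   # precentral gyrus
    "PCu",   # precuneus
    "RAC",   # rostral anterior cingulate cortex
    "RMF",   # rostral middle frontal cortex
    "SF",    # superior frontal cortex
    "SP",    # superior parietal cortex
    "ST",    # superior temporal cortex
    "SMG",   # supramarginal gyrus
    "TP",    # temporal pole
    "TT",    # transverse temporal cortex
    "INS",   # insula
)


def make_atlas() -> list[str]:
    """Return the ordered list of 68 region labels (``<abbr>_L`` then ``<abbr>_R``).

    Left-hemisphere labels come first, in canonical abbreviation order,
    followed by the right hemisphere in the same order.
    """
    return [f"{a}_L" for a in DK_ABBREVIATIONS] + [f"{a}_R" for a in DK_ABBREVIATIONS]


def validate_region(label: str, region_labels: list[str] | tuple[str, ...]) -> None:
    """Raise ``ValueError`` if *label* is not in *region_labels*."""
    if label not in region_labels:
        raise ValueError(f"unknown atlas region label: {label!r}")
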