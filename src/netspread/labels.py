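"""Desikan-Killiany atlas labels and cortical/hemisphere helpers.

Cortical regions carry an ``lh_``/``rh_`` prefix; subcortical regions carry a
``subcort_`` prefix (optionally followed by a hemisphere tag).
"""

from __future__ import annotations

# 34 cortical parcels per hemisphere (FreeSurfer aparc naming).
DK_CORTICAL_34: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
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
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

# 9 subcortical structures per hemisphere (FreeSurfer aseg naming).
DK_SUBCORTICAL_9: tuple[str, ...] = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
    "ventraldc",
    "cerebellum",
)


def cortical_labels_68() -> list[str]:
    """The 68 cortical DK labels, left hemisphere first."""
    return [f"lh_{r}" for r in DK_CORTICAL_34] + [f"rh_{r}" for r in DK_CORTICAL_34]


def labels_86() -> list[str]:
    """68 cortical plus 18 subcortical labels."""
    sub = [f"subcort_lh_{r}" for r in DK_SUBCORTICAL_9] + [
        f"subcort_rh_{r}" for r in DK_SUBCORTICAL_9
    ]
    return cortical_labels_68() + sub


def is_cortical(label: str) -> bool:
    return label.startswith(("lh_", "rh_")) and not label.startswith("subcort_")


def hemisphere(label: str) -> str | None:
    """'lh', 'rh', or None when the label carries no hemisphere tag."""
    stripped = label[8:] if label.startswith("subcort_") else label
    if stripped.startswith("lh_"):
        return "lh"
    if stripped.startswith("rh_"):
        return "rh"
    return None


def base_region(label: str) -> str:
    """Atlas name without hemisphere or subcortical prefixes."""
    out = label
    if out.startswith("subcort_"):
        out = out[8:]
    if out.startswith(("lh_", "rh_")):
        out = out[3:]
    return out
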