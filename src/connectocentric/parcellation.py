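"""Node label sets for connectome construction.

The default atlas is the Desikan-Killiany cortical parcellation (34 parcels
per hemisphere) plus six supratentorial subcortical gray-matter structures
per hemisphere and one manually delineated piriform-cortex ROI per
hemisphere, giving 82 network nodes. Only the labels matter here — all code
paths are agnostic to node count, so finer parcellations (e.g. 164- or
214-node schemes) are supported by supplying their label list.
"""

from __future__ import annotations

DESIKAN_CORTICAL = (
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
)

SUBCORTICAL = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
)

PIRIFORM = ("piriform",)


def default_labels(n_nodes: int = 82) -> tuple[str, ...]:
    """Return ``n_nodes`` unique node labels.

    For the canonical 82-node network this is the full bilateral
    Desikan + subcortical + piriform label set. For any other size a generic
    label set is produced whose first two entries are the bilateral piriform
    ROIs, so that planted-effect defaults remain addressable.
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    if n_nodes == 82:
        names = DESIKAN_CORTICAL + SUBCORTICAL + PIRIFORM
        return tuple(f"{hemi}_{name}" for hemi in ("lh", "rh") for name in names)
    generic = [f"region_{i:03d}" for i in range(n_nodes - 2)]
    return ("lh_piriform", "rh_piriform", *generic)
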