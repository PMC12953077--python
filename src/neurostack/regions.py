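"""Region labels and feature-name registries.

Naming follows the FreeSurfer/Desikan-Killiany (DK) convention
(``Left-Hippocampus``, ``ctx-lh-superiorfrontal``).  The connectome uses
82 of the 84 DK regions: 68 cortical parcels plus 14 subcortical
gray-matter structures, excluding the left/right cerebellar cortex.
"""

from __future__ import annotations

# 34 cortical parcel names per hemisphere (DK atlas).
DK_CORTICAL_NAMES = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal",
]

CORTICAL_REGIONS = [
    f"ctx-{hemi}-{name}" for hemi in ("lh", "rh") for name in DK_CORTICAL_NAMES
]

# Subcortical gray-matter structures present as connectome nodes (7 x 2).
SUBCORTICAL_GM = [
    f"{side}-{name}"
    for side in ("Left", "Right")
    for name in ("Thalamus", "Caudate", "Putamen", "Pallidum",
                 "Hippocampus", "Amygdala", "Accumbens-area")
]

#: The 82 connectome node labels, subcortical first then cortical.
CONNECTOME_REGIONS = SUBCORTICAL_GM + CORTICAL_REGIONS
N_REGIONS = len(CONNECTOME_REGIONS)  # 82

# ---------------------------------------------------------------------------
# Morphometric (MO) feature names: 22 subcortical/ventricular/callosal
# volumes + 68 cortical thicknesses + brain parenchymal volume = 91.
# ---------------------------------------------------------------------------
VENTRICLE_VOLUMES = ["Left-Lateral-Ventricle", "Right-Lateral-Ventricle",
                     "3rd-Ventricle"]
CC_VOLUMES = ["CC_Posterior", "CC_Mid_Posterior", "CC_Central",
              "CC_Mid_Anterior", "CC_Anterior"]

#: 22 subcortical-volume (SV) features, all eTIV-normalizable volumes.
SV_FEATURES = SUBCORTICAL_GM + VENTRICLE_VOLUMES + CC_VOLUMES

#: 68 cortical-thickness (CT) features.
CT_FEATURES = list(CORTICAL_REGIONS)

#: Brain parenchymal volume (gray + white matter).
BPV_FEATURE = "BPV"

MO_FEATURES = SV_FEATURES + CT_FEATURES + [BPV_FEATURE]  # 91

# ---------------------------------------------------------------------------
# Microstructural (MS) diffusion features: 5.
# ---------------------------------------------------------------------------
MS_FEATURES = [
    "WholeBrain-MD",
    "WholeBrain-FA",
    "Left-Hippocampus-MD",
    "Right-Hippocampus-MD",
    "TBSS-Skeleton-FA",
]

#: Amyloid-beta status column, appended to every assembled feature set.
ABETA_FEATURE = "ABETA"

# ---------------------------------------------------------------------------
# Graph-theory (GT) feature names: 7 nodal metrics x 82 regions + 17 global.
# ---------------------------------------------------------------------------
NODAL_METRICS = ["CC", "DC", "EC", "CClo", "BC", "NS", "PR"]
GLOBAL_METRICS = [
    "density", "modularity", "assortativity", "transitivity",
    "global_efficiency", "CPL", "diameter", "SW", "DegEnt", "SpecRad",
    "avgDeg", "avgCC", "avgBC", "avgEC", "avgCClo", "avgNS", "avgPR",
]


def gt_feature_names(labels=None) -> list[str]:
    """Frozen GT feature-name order: metric-major nodal block then globals.

    For the default 82-region atlas this yields 7*82 + 17 = 591 names.
    """
    labels = CONNECTOME_REGIONS if labels is None else list(labels)
    nodal = [f"{m}_{r}" for m in NODAL_METRICS for r in labels]
    return nodal + list(GLOBAL_METRICS)


GT_FEATURES = gt_feature_names()  # 591

#: Feature-set tags used by FeatureTable.
TAG_MO_SV = "MO-SV"
TAG_MO_CT = "MO-CT"
TAG_MO_OTHER = "MO-other"
TAG_MS = "MS"
TAG_GT_LOCAL = "GT-local"
TAG_GT_GLOBAL = "GT-global"
TAG_ABETA = "ABETA"


def default_tags() -> dict[str, str]:
    """Map every known feature name to its set tag."""
    tags: dict[str, str] = {}
    for f in SV_FEATURES:
        tags[f] = TAG_MO_SV
    for f in CT_FEATURES:
        tags[f] = TAG_MO_CT
    tags[BPV_FEATURE] = TAG_MO_OTHER
    for f in MS_FEATURES:
        tags[f] = TAG_MS
    for m in NODAL_METRICS:
        for r in CONNECTOME_REGIONS:
            tags[f"{m}_{r}"] = TAG_GT_LOCAL
    for g in GLOBAL_METRICS:
        tags[g] = TAG_GT_GLOBAL
    tags[ABETA_FEATURE] = TAG_ABETA
    return tags
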