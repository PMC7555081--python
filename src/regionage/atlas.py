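"""Region metadata for the cortical/subcortical volume feature set.

The feature space mirrors the standard FreeSurfer outputs used in large
population-imaging studies: 34 Desikan-Killiany cortical parcels per
hemisphere (68 columns), 8 subcortical segmentations per hemisphere plus
the brain stem (17 columns), for 85 raw columns, or 43 columns after
hemisphere averaging.

``CLUSTER_OF_REGION`` records the five covariance-based groups of
hemisphere-averaged regions that the clustering stage is expected to
recover on synthetic data, and ``SUBCLUSTER3_*`` the two sub-groups of
the mixed temporo-subcortical cluster (a cortical-temporal group and a
striatal/limbic group whose strongest exposure-linked member is the
accumbens).
"""

from __future__ import annotations

import pandas as pd

# 34 Desikan-Killiany cortical parcels (per hemisphere)
CORTICAL_REGIONS: tuple[str, ...] = (
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

# 8 lateralized subcortical segmentations + midline brain stem
SUBCORTICAL_LATERAL: tuple[str, ...] = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
    "cerebellum",
)
MIDLINE_REGIONS: tuple[str, ...] = ("brainstem",)

LATERAL_REGIONS: tuple[str, ...] = CORTICAL_REGIONS + SUBCORTICAL_LATERAL
AVERAGED_REGIONS: tuple[str, ...] = LATERAL_REGIONS + MIDLINE_REGIONS  # 43

SUBCORTICAL_REGIONS: tuple[str, ...] = SUBCORTICAL_LATERAL + MIDLINE_REGIONS

#: Covariance-block membership of the 43 hemisphere-averaged regions.
#: Block 1: posterior/occipito-parietal; 2: fronto-central; 3: temporal +
#: striatal/limbic; 4: anterior cingulate & poles; 5: brain stem/cerebellar
#: and remaining basal ganglia. Sizes 7/16/11/5/4.
CLUSTER_OF_REGION: dict[str, int] = {
    # cluster 1 (7)
    "cuneus": 1,
    "isthmuscingulate": 1,
    "lateraloccipital": 1,
    "lingual": 1,
    "pericalcarine": 1,
    "precuneus": 1,
    "superiorparietal": 1,
    # cluster 2 (16)
    "caudalmiddlefrontal": 2,
    "lateralorbitofrontal": 2,
    "medialorbitofrontal": 2,
    "paracentral": 2,
    "parsopercularis": 2,
    "parsorbitalis": 2,
    "parstriangularis": 2,
    "postcentral": 2,
    "posteriorcingulate": 2,
    "precentral": 2,
    "rostralmiddlefrontal": 2,
    "superiorfrontal": 2,
    "superiortemporal": 2,
    "supramarginal": 2,
    "transversetemporal": 2,
    "insula": 2,
    # cluster 3 (11)
    "bankssts": 3,
    "fusiform": 3,
    "inferiorparietal": 3,
    "inferiortemporal": 3,
    "middletemporal": 3,
    "parahippocampal": 3,
    "thalamus": 3,
    "putamen": 3,
    "hippocampus": 3,
    "amygdala": 3,
    "accumbens": 3,
    # cluster 4 (5)
    "caudalanteriorcingulate": 4,
    "entorhinal": 4,
    "rostralanteriorcingulate": 4,
    "frontalpole": 4,
    "temporalpole": 4,
    # cluster 5 (4)
    "brainstem": 5,
    "cerebellum": 5,
    "caudate": 5,
    "pallidum": 5,
}

#: Sub-blocks of cluster 3: cortical temporal vs striatal/limbic.
SUBCLUSTER3_CORTICAL: tuple[str, ...] = (
    "inferiorparietal",
    "middletemporal",
    "inferiortemporal",
    "fusiform",
    "bankssts",
)
SUBCLUSTER3_SUBCORTICAL: tuple[str, ...] = (
    "putamen",
    "accumbens",
    "thalamus",
    "hippocampus",
    "amygdala",
    "parahippocampal",
)

#: Typical single-hemisphere volumes (mm^3) used as simulator baselines.
BASELINE_VOLUME: dict[str, float] = {
    "bankssts": 2500.0,
    "caudalanteriorcingulate": 2000.0,
    "caudalmiddlefrontal": 6300.0,
    "cuneus": 3200.0,
    "entorhinal": 1900.0,
    "frontalpole": 1200.0,
    "fusiform": 9500.0,
    "inferiorparietal": 13000.0,
    "inferiortemporal": 10500.0,
    "insula": 6800.0,
    "isthmuscingulate": 2600.0,
    "lateraloccipital": 11500.0,
    "lateralorbitofrontal": 7500.0,
    "lingual": 7000.0,
    "medialorbitofrontal": 5500.0,
    "middletemporal": 10500.0,
    "paracentral": 3600.0,
    "parahippocampal": 2100.0,
    "parsopercularis": 4600.0,
    "parsorbitalis": 2500.0,
    "parstriangularis": 3800.0,
    "pericalcarine": 2200.0,
    "postcentral": 9800.0,
    "posteriorcingulate": 3300.0,
    "precentral": 13000.0,
    "precuneus": 9800.0,
    "rostralanteriorcingulate": 2400.0,
    "rostralmiddlefrontal": 9500.0,
    "superiorfrontal": 21000.0,
    "superiorparietal": 12500.0,
    "superiortemporal": 11500.0,
    "supramarginal": 10000.0,
    "temporalpole": 2400.0,
    "transversetemporal": 1100.0,
    "thalamus": 7000.0,
    "caudate": 3500.0,
    "putamen": 5000.0,
    "pallidum": 1800.0,
    "hippocampus": 4000.0,
    "amygdala": 1600.0,
    "accumbens": 550.0,
    "cerebellum": 53000.0,
    "brainstem": 21000.0,
}


def compartment_of(region: str) -> str:
    return "subcortical" if region in SUBCORTICAL_REGIONS else "cortical"


def raw_columns(regions: tuple[str, ...] | list[str] = AVERAGED_REGIONS) -> list[str]:
    """Raw (per-hemisphere) column names for the given averaged regions."""
    cols: list[str] = []
    for r in regions:
        if r in MIDLINE_REGIONS:
            cols.append(r)
        else:
            cols.extend([f"lh_{r}", f"rh_{r}"])
    return cols


def region_metadata(columns: list[str]) -> pd.DataFrame:
    """Describe feature columns: base region name, compartment, hemisphere.

    Accepts raw (``lh_``/``rh_``-prefixed or midline) or hemisphere-averaged
    column names.
    """
    rows = []
    for c in columns:
        if c.startswith("lh_") or c.startswith("rh_"):
            hemi = "left" if c.startswith("lh_") else "right"
            name = c[3:]
        elif c in MIDLINE_REGIONS:
            hemi, name = "midline", c
        else:
            hemi, name = "both", c
        rows.append({"column": c, "region": name, "compartment": compartment_of(name), "hemisphere": hemi})
    return pd.DataFrame(rows).set_index("column")
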