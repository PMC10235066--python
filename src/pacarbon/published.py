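"""Published headline figures of the global protected-area carbon assessment.

These are the printed summary values from the global spaceborne-lidar study of
protected-area carbon effectiveness that this package's pipeline implements at
desk scale.  They are inputs for arithmetic-consistency checks (continental
additivity, percentage shares, database bookkeeping) pushed through the same
functions the pipeline uses; the pipeline itself never reads them.
"""

from __future__ import annotations

import pandas as pd

#: Additional protected-area aboveground carbon by continent, Gt (value, SE).
CONTINENT_ADDITIONAL_GT = {
    "South America": (4.94, 0.47),
    "Asia": (1.38, 0.5),
    "Africa": (1.2, 0.17),
    "North America": (0.86, 0.33),
    "Oceania": (0.65, 0.32),
    "Europe": (0.61, 0.13),
}

#: Additional PA aboveground carbon by biome, Gt (value, SE).
BIOME_ADDITIONAL_GT = {
    "Tropical and subtropical moist broadleaf forests": (5.93, 1.59),
    "Temperate broadleaf and mixed forests": (1.39, 0.64),
    "Tropical and subtropical grasslands, savannas and shrublands": (0.81, 0.31),
    "Temperate Coniferous Forest": (0.4, 0.13),
    "Tropical and subtropical dry broadleaf forests": (0.3, 0.06),
    "Mediterranean Forests, woodlands and scrubs": (0.28, 0.09),
    "Deserts and xeric shrublands": (0.25, 0.22),
    "Boreal forests/Taiga": (0.16, 0.24),
    "Temperate grasslands, savannas and shrublands": (0.05, 0.08),
    "Flooded grasslands and savannas": (0.04, 0.03),
    "Tropical and subtropical coniferous forests": (0.03, 0.03),
    "Mangroves": (0.01, 0.08),
    "Tundra": (-0.01, 0.02),
    "Montane grasslands and shrublands": (-0.01, 0.15),
}

GLOBE_ADDITIONAL_GT = 9.64       # global table value (abstract rounds to 9.65)
GLOBE_ADDITIONAL_GT_ABSTRACT = 9.65
PA_TOTAL_AGC_GT = 61.4           # total aboveground carbon inside PAs
TERRESTRIAL_AGC_GT = 235.0       # total mapped terrestrial woody carbon
BRAZIL_ADDITIONAL_GT = 3.54      # national signal dominating the global total

#: Protected-area database (Sept-2020 release) record bookkeeping.
WDPA_POLYGON_RECORDS = 240_713
WDPA_POINT_RECORDS = 22_091
WDPA_TOTAL_RECORDS = 262_804


def continental_table() -> pd.DataFrame:
    """The printed continental additional-carbon rows as a tidy frame."""
    return pd.DataFrame(
        [{"continent": k, "additional_agc_gt": v, "se_additional_agc_gt": se}
         for k, (v, se) in CONTINENT_ADDITIONAL_GT.items()])


def biome_table() -> pd.DataFrame:
    return pd.DataFrame(
        [{"biome": k, "additional_agc_gt": v, "se_additional_agc_gt": se}
         for k, (v, se) in BIOME_ADDITIONAL_GT.items()])
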