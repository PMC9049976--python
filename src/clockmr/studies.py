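"""Study-design constants for the epigenetic-clock / cancer MR analysis.

These are the published inputs the analysis is parameterised by: the
variance in each clock's age-acceleration measure explained by its
genome-wide-significant instruments, the instrument counts, the exposure
GWAS sample size, and the case/control counts of each cancer GWAS source.
They drive the power grid and the default simulation presets.
"""

from __future__ import annotations

#: exposure GWAS meta-analysis sample size (European-ancestry clock GWAS)
EXPOSURE_N = 34_710

#: proportion of trait variance explained by each clock's instruments
CLOCK_R2 = {
    "HannumAge": 0.0148,
    "IntrinsicHorvathAge": 0.0441,
    "PhenoAge": 0.0186,
    "GrimAge": 0.0047,
}

#: number of independent genome-wide-significant instruments per clock
CLOCK_N_SNPS = {
    "HannumAge": 9,
    "IntrinsicHorvathAge": 24,
    "PhenoAge": 11,
    "GrimAge": 4,
}

#: per-source case/control counts for each cancer outcome GWAS
CANCER_SOURCES: dict[str, dict[str, tuple[int, int]]] = {
    "breast": {
        "BCAC": (122_977, 105_974),
        "UK Biobank": (13_879, 198_523),
        "FinnGen": (8_401, 99_321),
    },
    "ovarian": {
        "OCAC": (25_509, 40_941),
        "UK Biobank": (1_218, 198_523),
        "FinnGen": (719, 99_321),
    },
    "prostate": {
        "PRACTICAL": (79_148, 61_106),
        "UK Biobank": (9_132, 173_493),
        "FinnGen": (6_311, 74_685),
    },
    "lung": {
        "ILCCO": (11_348, 15_861),
        "UK Biobank": (2_671, 372_016),
        "FinnGen": (1_681, 173_933),
    },
    "colorectal": {
        "GECCO": (58_131, 67_347),
        "UK Biobank": (5_657, 372_016),
        "FinnGen": (3_022, 174_006),
    },
}

#: sources pooled per cancer in the meta-analysis. Colorectal excludes
#: UK Biobank because its participants are already in the GECCO meta,
#: and double counting would overstate precision.
META_GROUPS: dict[str, list[str]] = {
    "breast": ["BCAC", "UK Biobank", "FinnGen"],
    "ovarian": ["OCAC", "UK Biobank", "FinnGen"],
    "prostate": ["PRACTICAL", "UK Biobank", "FinnGen"],
    "lung": ["ILCCO", "UK Biobank", "FinnGen"],
    "colorectal": ["GECCO", "FinnGen"],
}

#: multiple-testing family: 4 clocks x 5 cancers
FDR_FAMILY_SIZE = 20


def meta_totals(cancer: str) -> tuple[int, int]:
    """Summed (cases, controls) over the sources pooled for a cancer."""
    sources = CANCER_SOURCES[cancer]
    pooled = META_GROUPS[cancer]
    ncase = sum(sources[s][0] for s in pooled)
    ncontrol = sum(sources[s][1] for s in pooled)
    return ncase, ncontrol
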