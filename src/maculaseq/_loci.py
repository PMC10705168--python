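"""Bundled list of gene symbols previously associated with AMD risk.

Transcribed from candidate-gene and genome-wide association findings for
age-related macular degeneration (IAMDGC and related studies). Used by
:func:`maculaseq.integrate.amd_loci_annotate` to restrict result tables to
known risk loci. Symbols follow HGNC conventions where possible; the list
keeps both CDH9 and the CHD9 spelling encountered in source tables.
"""

AMD_LOCI: tuple[str, ...] = (
    "ABCA1", "ABCA7", "ABHD2", "ACAA2", "ACAD10", "ADAM19", "ADAMTS9-AS1",
    "ADAMTS9-AS2", "AFF1", "APOE", "ARHGAP21", "ARMS2", "B3GALTL", "C10orf88",
    "C2", "C3", "C4A", "C5", "C9", "CCT3", "CD46", "CD55", "CD63", "CDH7",
    "CDH9", "CETP", "CFB", "CFH", "CFHR3", "CFI", "CHD9", "CLUL1", "CNN2",
    "COL4A3", "COL5A1", "COL8A1", "CSK", "CYP24A1", "DDR1", "EXOC3L2",
    "FILIP1L", "FLT1", "GTF2A1L", "HERC2", "HLA-DQB1", "HTRA1", "IER3",
    "IGFBP7", "IL6", "ITGA7", "KMT2E", "LBP", "LIPC", "LRP2", "LRP6", "ME3",
    "MMP19", "MMP9", "MYO1E", "NLRP2", "NPLOC4", "OCA2", "PCOLCE", "PDGFB",
    "PELI3", "PILRA", "PKP2", "PLA2G12A", "PLA2G4A", "RAD51B", "RASIP1",
    "RDH5", "RGS13", "RLBP1", "ROBO1", "RORA", "RORB", "RP1L1", "RRAS",
    "SERPINA1", "SKIV2L", "SLC16A8", "SMAD3", "SPEF2", "SRPK2", "STON1",
    "STON1-GTF2A1L", "SYN3", "TGFB1", "TGFBR1", "TIMP3", "TMEM97", "TNF",
    "TNFRSF10A", "TNFRSF10B", "TRPM1", "TRPM3", "TSPAN10", "TYR", "UNC93B1",
    "VDR", "VTN", "ZBTB38", "ZNF385B",
)
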