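"""Small frozen reference snapshots used by the io layer.

``GENE_ALIAS_SNAPSHOT`` is a compact offline snapshot of frequently-seen
outdated HGNC symbols mapped to their current approved symbol, in the spirit
of nomenclature-repair tools run against a pinned database version. It is not
exhaustive; unmapped symbols pass through unchanged.

``CRAP_SYMBOLS`` lists gene symbols of ubiquitous sample-preparation
contaminants (the common Repository of Adventitious Proteins). It backs the
contaminant flag when a search-engine "Potential contaminant" column is not
available in the input table.
"""

from __future__ import annotations

#: outdated symbol -> current approved symbol (uppercase on both sides)
GENE_ALIAS_SNAPSHOT: dict[str, str] = {
    # septins were renamed SEPT* -> SEPTIN* to avoid spreadsheet date mangling
    "SEPT1": "SEPTIN1",
    "SEPT2": "SEPTIN2",
    "SEPT3": "SEPTIN3",
    "SEPT4": "SEPTIN4",
    "SEPT5": "SEPTIN5",
    "SEPT6": "SEPTIN6",
    "SEPT7": "SEPTIN7",
    "SEPT8": "SEPTIN8",
    "SEPT9": "SEPTIN9",
    "SEPT10": "SEPTIN10",
    "SEPT11": "SEPTIN11",
    "MARCH1": "MARCHF1",
    "MARCH5": "MARCHF5",
    "MARCH6": "MARCHF6",
    "MARCH7": "MARCHF7",
    "MARCH8": "MARCHF8",
    "DEC1": "DELEC1",
    "ATP5B": "ATP5F1B",
    "ATP5A1": "ATP5F1A",
    "ATP5O": "ATP5PO",
    "FAM49B": "CYRIB",
    "FAM129B": "NIBAN2",
    "C10ORF54": "VSIR",
    "GARS": "GARS1",
    "WARS": "WARS1",
    "AARS": "AARS1",
    "H2AFZ": "H2AZ1",
    "H3F3A": "H3-3A",
    "HIST1H4A": "H4C1",
    "WISP1": "CCN4",
    "CTGF": "CCN2",
    "CYR61": "CCN1",
    "AIM1": "CRYBG1",
    "GPR126": "ADGRG6",
    "KIAA0101": "PCLAF",
    "MKL1": "MRTFA",
    "WHSC1": "NSD2",
    "TMEM27": "CLTRN",
    "SQRDL": "SQOR",
    "ADSS": "ADSS2",
    "ICT1": "MRPL58",
}

#: gene symbols of common cRAP contaminant proteins
CRAP_SYMBOLS: frozenset[str] = frozenset(
    {
        # keratins (also caught by the FASTA-header rule)
        "KRT1", "KRT2", "KRT3", "KRT4", "KRT5", "KRT6A", "KRT6B", "KRT7",
        "KRT8", "KRT9", "KRT10", "KRT12", "KRT13", "KRT14", "KRT15", "KRT16",
        "KRT17", "KRT18", "KRT19", "KRT20",
        # proteases / standards spiked or introduced during preparation
        "TRYP_PIG", "TRYPSIN", "PRSS1", "PRSS2", "CTRB1", "CTRL", "PGA3",
        "LYZ", "LYSC_CHICK", "ALBU_BOVIN", "CAS1_BOVIN", "CAS2_BOVIN",
        "CASB_BOVIN", "CASK_BOVIN", "ADH1_YEAST", "BGAL_ECOLI", "GFP_AEQVI",
        "SSPA_STAAU",
    }
)
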