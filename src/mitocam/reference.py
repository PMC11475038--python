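"""Reference constants for the avian mitogenome analyses.

The 13 protein-coding genes (PCGs) of the vertebrate mitogenome, their
published CDS lengths (bp, stop codon included) in the Sturnidae sensu
lato study set, and the ten GenBank accessions of that study set. The
lengths double as the default gene sizes of the synthetic generator, so
synthetic bundles reproduce the 11,400 bp total PCG length of the real
genomes.
"""

from __future__ import annotations

# Canonical HGNC-style names, mitogenome order.
PCG_NAMES: tuple[str, ...] = (
    "MT-ND1",
    "MT-ND2",
    "MT-CO1",
    "MT-CO2",
    "MT-ATP8",
    "MT-ATP6",
    "MT-CO3",
    "MT-ND3",
    "MT-ND4L",
    "MT-ND4",
    "MT-ND5",
    "MT-ND6",
    "MT-CYB",
)

# Published per-gene CDS lengths (bp, including the stop codon); identical
# across the ten study genomes. They sum to 11,400 bp.
PCG_LENGTHS_BP: dict[str, int] = {
    "MT-ATP6": 684,
    "MT-ATP8": 168,
    "MT-CO1": 1551,
    "MT-CO2": 684,
    "MT-CO3": 786,
    "MT-CYB": 1143,
    "MT-ND1": 978,
    "MT-ND2": 1041,
    "MT-ND3": 351,
    "MT-ND4": 1380,
    "MT-ND4L": 297,
    "MT-ND5": 1818,
    "MT-ND6": 519,
}

PCG_TOTAL_BP = sum(PCG_LENGTHS_BP.values())

# GenBank accessions of the ten Sturnidae sensu lato mitogenomes.
STUDY_ACCESSIONS: tuple[str, ...] = (
    "MN356312",  # Buphagus erythrorynchus
    "BK010995",  # Mimus polyglottos
    "MN356247",  # Toxostoma redivivum
    "NC_015613",  # Acridotheres cristatellus
    "NC_015195",  # Acridotheres tristis
    "NC_020423",  # Gracupica nigricollis
    "MN356237",  # Leucopsar rothschildi
    "NC_015237",  # Spodiopsar cineraceus
    "NC_014455",  # Spodiopsar sericeus
    "NC_029360",  # Sturnus vulgaris
)
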