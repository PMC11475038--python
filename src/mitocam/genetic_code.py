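"""Genetic-code tables with their synonymous-family structure.

Codon-usage statistics (RSCU, ENC, GC3s, PR2) are all defined relative to
the partition of sense codons into synonymous families. This module wraps
the NCBI translation tables (via Biopython) and exposes that partition.

The default is translation table 2, the vertebrate mitochondrial code:
AGA/AGG join TAA/TAG as stops (60 sense codons), ATA codes Met and TGA
codes Trp. Its family-size spectrum is 12 two-fold, 6 four-fold and 2
six-fold families — no singletons — so the effective number of codons
ranges from 20 (one codon per family) to 60 (uniform usage). The standard
code (table 1) is supported for cross-checks; its maximum is the classical
61.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

VERTEBRATE_MITOCHONDRIAL = 2
STANDARD = 1


@dataclass(frozen=True)
class GeneticCode:
    """A translation table plus its synonymous-family partition.

    Attributes
    ----------
    table_id:
        NCBI translation table number.
    codon_to_aa:
        Map from each sense codon to its one-letter amino acid.
    stop_codons:
        The stop codons of the table.
    families:
        Map amino acid -> tuple of its codons (lexicographic order). The
        family tuples partition the sense codons exactly.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]
    families: dict[str, tuple[str, ...]] = field(repr=False)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if c not in self.stop_codons)

    def family_of(self, codon: str) -> tuple[str, ...]:
        """All codons synonymous with ``codon`` (including itself)."""
        return self.families[self.codon_to_aa[codon]]

    def family_size_counts(self) -> dict[int, int]:
        """Map family size k -> number of amino acids with a k-codon family."""
        counts: dict[int, int] = {}
        for codons in self.families.values():
            counts[len(codons)] = counts.get(len(codons), 0) + 1
        return counts

    @property
    def max_enc(self) -> float:
        """Theoretical ENC under perfectly uniform codon usage.

        Equals the number of sense codons (60 for table 2, 61 for table 1),
        since each k-codon family then contributes k effective codons.
        """
        return float(sum(len(c) for c in self.families.values()))

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def translate(self, codon: str) -> str:
        """One-letter amino acid, or '*' for a stop codon."""
        if codon in self.stop_codons:
            return "*"
        return self.codon_to_aa[codon]


@lru_cache(maxsize=None)
def get_code(table_id: int = VERTEBRATE_MITOCHONDRIAL) -> GeneticCode:
    """Build a :class:`GeneticCode` for an NCBI translation table."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa = dict(table.forward_table)
    stops = frozenset(table.stop_codons)
    families: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        if codon in stops:
            continue
        families.setdefault(codon_to_aa[codon], []).append(codon)
    frozen = {aa: tuple(sorted(cods)) for aa, cods in sorted(families.items())}
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=codon_to_aa,
        stop_codons=stops,
        families=frozen,
    )
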