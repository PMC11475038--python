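"""Codon aversion motifs (CAMs) and CAM-based species identification.

A gene's codon aversion motif is the set of sense codons it never uses
(equivalently, codons with RSCU = 0 on the usual counting basis, initial
and stop codons excluded). Motifs are compared as sets; the canonical text
form sorts codons lexicographically and joins them with '-'. Because the
motifs of sufficiently long mitochondrial genes turn out to be
species-specific, matching motifs against a reference panel acts as a
barcode-like identifier.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .codon_usage import CodonCounts, count_codons
from .genetic_code import GeneticCode, get_code
from .genome_io import CodingGene

logger = logging.getLogger(__name__)

#: Default eligibility threshold: genes strictly longer than 300 bp.
MIN_GENE_LENGTH = 301


@dataclass(frozen=True)
class CamMotif:
    species: str
    gene_name: str
    absent_codons: frozenset[str]

    @property
    def motif_string(self) -> str:
        return "-".join(sorted(self.absent_codons))

    def __eq__(self, other) -> bool:  # motif identity is set identity
        if not isinstance(other, CamMotif):
            return NotImplemented
        return self.absent_codons == other.absent_codons

    def __hash__(self) -> int:
        return hash(self.absent_codons)


@dataclass
class CamProfile:
    species: str
    motifs: dict[str, CamMotif]

    @property
    def aversion_count_by_aa(self) -> dict[str, int]:
        """Absent-codon counts per amino acid, aggregated over genes."""
        code = get_code()
        counts: Counter = Counter()
        for motif in self.motifs.values():
            for codon in motif.absent_codons:
                counts[code.codon_to_aa[codon]] += 1
        return dict(counts)


@dataclass
class UniquenessReport:
    genes: list[str]
    species: list[str]
    #: gene -> {(sp_a, sp_b) -> distinct?} over unordered pairs, a < b
    pairwise: dict[str, dict[tuple[str, str], bool]]
    genes_fully_distinct: list[str]
    incomparable: list[tuple[str, str, str]] = field(default_factory=list)


def aversion_set(counts: CodonCounts, code: GeneticCode | None = None) -> CamMotif:
    """The set of sense codons with zero usage (RSCU = 0)."""
    code = code or get_code()
    absent = frozenset(c for c in code.sense_codons if counts.counts.get(c, 0) == 0)
    species, gene = counts.unit
    return CamMotif(species=species, gene_name=gene, absent_codons=absent)


def eligible_genes(genes: Iterable[CodingGene] | Mapping[str, int],
                   min_length: int = MIN_GENE_LENGTH) -> list[str]:
    """Gene names whose CDS length is at least ``min_length`` bp.

    With the default threshold of 301 this retains genes "over 300 bp";
    the 13 mitochondrial PCG lengths leave 11 eligible (ATP8 and ND4L are
    too short). Accepts CodingGene objects or a {gene: length_bp} map.
    """
    if isinstance(genes, Mapping):
        lengths = dict(genes)
    else:
        lengths = {g.gene_name: len(g.cds) for g in genes}
    return sorted(name for name, bp in lengths.items() if bp >= min_length)


def build_profile(species: str, genes: Iterable[CodingGene],
                  code: GeneticCode | None = None,
                  min_length: int = MIN_GENE_LENGTH) -> CamProfile:
    """Per-gene motifs for one species, restricted to eligible genes."""
    code = code or get_code()
    genes = list(genes)
    keep = set(eligible_genes(genes, min_length))
    motifs = {}
    for g in genes:
        if g.gene_name not in keep:
            continue
        counts = count_codons(g, exclude_initial=True, exclude_stops=True, code=code)
        motifs[g.gene_name] = aversion_set(counts, code)
    return CamProfile(species=species, motifs=motifs)


def uniqueness_matrix(profiles: list[CamProfile],
                      genes: list[str] | None = None) -> UniquenessReport:
    """Pairwise motif distinctness per gene across species.

    A species pair is distinct for a gene iff their motif sets differ.
    ``genes_fully_distinct`` lists genes where every pair is distinct.
    Pairs missing the gene in either profile are marked incomparable.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    species = [p.species for p in profiles]
    if genes is None:
        genes = sorted(set().union(*(p.motifs.keys() for p in profiles)))
    by_species = {p.species: p for p in profiles}
    pairwise: dict[str, dict[tuple[str, str], bool]] = {}
    incomparable: list[tuple[str, str, str]] = []
    fully = []
    for gene in genes:
        cells: dict[tuple[str, str], bool] = {}
        all_distinct = True
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                ma = by_species[a].motifs.get(gene)
                mb = by_species[b].motifs.get(gene)
                if ma is None or mb is None:
                    incomparable.append((gene, a, b))
                    all_distinct = False
                    continue
                distinct = ma.absent_codons != mb.absent_codons
                cells[(a, b)] = distinct
                all_distinct &= distinct
        pairwise[gene] = cells
        if all_distinct and cells:
            fully.append(gene)
    for g, a, b in incomparable:
        logger.warning("gene %s missing for pair (%s, %s); marked incomparable", g, a, b)
    return UniquenessReport(genes=list(genes), species=species, pairwise=pairwise,
                            genes_fully_distinct=fully, incomparable=incomparable)


def identify_species(query: CamProfile,
                     reference: list[CamProfile]) -> list[tuple[str, int]]:
    """Rank reference species by the number of exactly matching gene motifs.

    Ties are broken by species name; a tied or below-full top score is a
    warning sign that the query species may be absent from the panel.
    """
    if not reference:
        raise ValueError("empty reference panel")
    if not query.motifs:
        logger.warning("query %s has no eligible genes", query.species)
        return []
    scores = []
    for ref in reference:
        matched = sum(
            1 for gene, motif in query.motifs.items()
            if gene in ref.motifs
            and ref.motifs[gene].absent_codons == motif.absent_codons)
        scores.append((ref.species, matched))
    scores.sort(key=lambda t: (-t[1], t[0]))
    if len(scores) > 1 and scores[0][1] == scores[1][1]:
        logger.warning("ambiguous identification: tie at %d matched genes", scores[0][1])
    return scores


def aversion_count_summary(groups: Mapping[str, list[CamProfile]]):
    """Per-group (e.g. per-family) aversion counts by amino acid.

    Returns a DataFrame with one row per (group, amino acid) and the total
    number of absent codons for that amino acid aggregated over the
    group's species and genes — the basis for comparing whether groups
    avert the same amino acids.
    """
    import pandas as pd

    rows = []
    for group, profiles in groups.items():
        agg: Counter = Counter()
        for p in profiles:
            agg.update(p.aversion_count_by_aa)
        for aa in sorted(agg):
            rows.append({"group": group, "amino_acid": aa, "absent_codons": agg[aa]})
    return pd.DataFrame(rows)
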