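"""Codon-usage statistics: RSCU, ENC, GC3s, and PR2 coordinates.

All statistics are parameterized by a :class:`~mitocam.genetic_code.GeneticCode`
so the vertebrate mitochondrial code (default) and the standard code share
one implementation.

RSCU_j = x_j / (n_i / k_i): the observed count of codon j divided by its
expected count under equal usage within its k_i-codon synonymous family.

ENC is Wright's effective number of codons generalized to an arbitrary
family-size spectrum: per family the codon homozygosity is estimated as
F = (n * sum(p_j^2) - 1) / (n - 1), class means F̄_k average the usable
families of each size k, and ENC = sum_k n_aa(k) / F̄_k (singleton classes
contribute their amino-acid count directly). Under table 2 this is
12/F̄₂ + 6/F̄₄ + 2/F̄₆, ranging from 20 to 60.

The reference ENC–GC3s curve, expected under mutational bias alone, is
ENC*(s) = 2 + s + 29 / (s² + (1 − s)²).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .genetic_code import GeneticCode, get_code
from .genome_io import CodingGene


@dataclass
class CodonCounts:
    """Codon tally for one analysis unit (a gene or a species' PCG set)."""

    unit: tuple[str, str]
    counts: Counter
    basis: str = "exclude_initial,exclude_stops"
    n_ambiguous_skipped: int = 0

    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = Counter(self.counts)
        merged.update(other.counts)
        if self.basis != other.basis:
            raise ValueError("cannot merge counts with different bases")
        unit = (self.unit[0] if self.unit[0] == other.unit[0] else "MIXED", "ALL")
        return CodonCounts(unit=unit, counts=merged, basis=self.basis,
                           n_ambiguous_skipped=self.n_ambiguous_skipped
                           + other.n_ambiguous_skipped)


@dataclass(frozen=True)
class RscuTable:
    values: dict[str, float]
    family_totals: dict[str, int]
    unused_families: frozenset[str]


@dataclass(frozen=True)
class EncResult:
    enc: float
    class_means: dict[int, float]
    gc3s: float | None
    imputed_classes: frozenset[int] = field(default_factory=frozenset)

    @property
    def imputed(self) -> bool:
        return bool(self.imputed_classes)


@dataclass(frozen=True)
class Pr2Point:
    x: float  # G3 / (G3 + C3)
    y: float  # A3 / (A3 + T3)

    @property
    def quadrant(self) -> str:
        """Quadrant relative to the (0.5, 0.5) parity center.

        II = AC bias (x < 0.5, y > 0.5); IV = TG bias (x > 0.5, y < 0.5).
        Points on an axis are reported as 'boundary'.
        """
        if self.x == 0.5 or self.y == 0.5:
            return "boundary"
        if self.y > 0.5:
            return "II" if self.x < 0.5 else "I"
        return "III" if self.x < 0.5 else "IV"


def count_codons(gene: CodingGene, exclude_initial: bool = True,
                 exclude_stops: bool = True,
                 code: GeneticCode | None = None) -> CodonCounts:
    """Tally a gene's codons on the requested basis.

    ``exclude_initial`` drops the first codon regardless of identity;
    ``exclude_stops`` drops codons that are stops under ``code``. Codons
    containing ambiguous bases are always skipped (tallied separately).
    """
    if not gene.codons:
        raise ValueError(f"{gene.species} {gene.gene_name}: no codons")
    code = code or get_code()
    counts: Counter = Counter()
    n_ambig = 0
    start = 1 if exclude_initial else 0
    for codon in gene.codons[start:]:
        if set(codon) - set("ACGT"):
            n_ambig += 1
            continue
        if exclude_stops and code.is_stop(codon):
            continue
        counts[codon] += 1
    basis = ",".join(p for p, on in
                     (("exclude_initial", exclude_initial),
                      ("exclude_stops", exclude_stops)) if on) or "all"
    return CodonCounts(unit=(gene.species, gene.gene_name), counts=counts,
                       basis=basis, n_ambiguous_skipped=n_ambig)


def count_codons_many(genes: Iterable[CodingGene], species: str = "",
                      exclude_initial: bool = True, exclude_stops: bool = True,
                      code: GeneticCode | None = None) -> CodonCounts:
    """Merged counts over several genes (species-level concatenation)."""
    parts = [count_codons(g, exclude_initial, exclude_stops, code)
             for g in genes]
    if not parts:
        raise ValueError("no genes supplied")
    merged = parts[0]
    for p in parts[1:]:
        merged = merged + p
    merged.unit = (species or merged.unit[0], "ALL")
    return merged


def rscu(counts: CodonCounts, code: GeneticCode | None = None) -> RscuTable:
    """Relative synonymous codon usage for every sense codon.

    Families with zero total get RSCU 0 for all members and are flagged
    unused; within every used family the RSCU values sum to the family
    size exactly.
    """
    code = code or get_code()
    values: dict[str, float] = {}
    totals: dict[str, int] = {}
    unused: set[str] = set()
    for aa, family in code.families.items():
        n_i = sum(counts.counts.get(c, 0) for c in family)
        totals[aa] = n_i
        if n_i == 0:
            unused.add(aa)
            for c in family:
                values[c] = 0.0
            continue
        expected = n_i / len(family)
        for c in family:
            values[c] = counts.counts.get(c, 0) / expected
    return RscuTable(values=values, family_totals=totals,
                     unused_families=frozenset(unused))


def _family_homozygosity(counts: CodonCounts, family: tuple[str, ...]) -> tuple[int, float]:
    n = sum(counts.counts.get(c, 0) for c in family)
    if n < 2:
        return n, float("nan")
    sum_p2 = sum((counts.counts.get(c, 0) / n) ** 2 for c in family)
    return n, (n * sum_p2 - 1.0) / (n - 1.0)


def enc(counts: CodonCounts, code: GeneticCode | None = None,
        impute_missing: bool = True) -> EncResult:
    """Wright's effective number of codons for the code's family spectrum.

    Families with n < 2 or a non-positive homozygosity estimate are
    excluded from their class mean. A size class left with no usable
    family is imputed at its uniform-usage expectation F̄_k = 1/k when
    ``impute_missing`` (flagged in the result), otherwise it is an error.
    """
    code = code or get_code()
    by_size: dict[int, list[float]] = {}
    n_aa_by_size: dict[int, int] = code.family_size_counts()
    for family in code.families.values():
        k = len(family)
        if k == 1:
            continue
        n, f_hat = _family_homozygosity(counts, family)
        if n >= 2 and f_hat > 0:
            by_size.setdefault(k, []).append(f_hat)
    enc_value = 0.0
    class_means: dict[int, float] = {}
    imputed: set[int] = set()
    for k, n_aa in sorted(n_aa_by_size.items()):
        if k == 1:
            enc_value += n_aa
            class_means[k] = 1.0
            continue
        usable = by_size.get(k, [])
        if usable:
            f_bar = sum(usable) / len(usable)
        elif impute_missing:
            f_bar = 1.0 / k
            imputed.add(k)
        else:
            raise ValueError(f"ENC undefined: no usable family of size {k}")
        class_means[k] = f_bar
        enc_value += n_aa / f_bar
    enc_value = min(enc_value, code.max_enc)
    return EncResult(enc=enc_value, class_means=class_means,
                     gc3s=_gc3s_or_none(counts, code),
                     imputed_classes=frozenset(imputed))


def _gc3s_or_none(counts: CodonCounts, code: GeneticCode) -> float | None:
    try:
        return gc3s(counts, code)
    except ValueError:
        return None


def gc3s(counts: CodonCounts, code: GeneticCode | None = None) -> float:
    """G+C fraction at third positions of synonymously variable codons.

    Only codons from families of size >= 2 contribute (every sense codon
    under table 2); the counting basis (initial/stop exclusion) is the one
    already baked into ``counts``.
    """
    code = code or get_code()
    gc = total = 0
    for family in code.families.values():
        if len(family) < 2:
            continue
        for codon in family:
            x = counts.counts.get(codon, 0)
            total += x
            if codon[2] in "GC":
                gc += x
    if total == 0:
        raise ValueError("GC3s undefined: no eligible codons")
    return gc / total


def expected_enc(s: float) -> float:
    """Wright's expected ENC at GC3s = s under mutational bias alone."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3s must lie in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def pr2_point(source: CodonCounts | Iterable[CodingGene],
              code: GeneticCode | None = None) -> Pr2Point:
    """Parity-rule-2 coordinates from four-fold degenerate families.

    Third-position base counts are accumulated over codons of four-fold
    families only; x = G3/(G3+C3), y = A3/(A3+T3). The neutral point is
    (0.5, 0.5); quadrant II marks an AC-ending bias, quadrant IV a
    TG-ending bias.
    """
    code = code or get_code()
    if isinstance(source, CodonCounts):
        counts = source
    else:
        counts = count_codons_many(list(source), code=code)
    third = Counter()
    for family in code.families.values():
        if len(family) != 4:
            continue
        for codon in family:
            third[codon[2]] += counts.counts.get(codon, 0)
    gc_den = third["G"] + third["C"]
    at_den = third["A"] + third["T"]
    if gc_den == 0 or at_den == 0:
        raise ValueError("PR2 coordinates undefined: empty third-position class")
    return Pr2Point(x=third["G"] / gc_den, y=third["A"] / at_den)


def enc_gc3s_table(per_unit_counts: dict[tuple[str, str], CodonCounts],
                   code: GeneticCode | None = None,
                   impute_missing: bool = True):
    """ENC/GC3s rows (one per unit) as a DataFrame, for the ENC-GC3s plot."""
    import pandas as pd

    code = code or get_code()
    rows = []
    for (species, gene), counts in per_unit_counts.items():
        res = enc(counts, code, impute_missing=impute_missing)
        rows.append({"species": species, "gene": gene, "enc": res.enc,
                     "gc3s": res.gc3s,
                     "expected_enc": expected_enc(res.gc3s)
                     if res.gc3s is not None else math.nan,
                     "imputed_classes": ",".join(map(str, sorted(res.imputed_classes)))})
    return pd.DataFrame(rows)
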