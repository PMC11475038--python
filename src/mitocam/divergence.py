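"""Cross-species divergence statistics on per-gene sequence matrices.

Mitochondrial PCGs of closely related birds share one length per gene, so
positional homology is exact and no aligner is invoked: rows of unequal
length are an error, never an implicit alignment.

Statistics: variable sites, nucleotide diversity pi (Nei's average
pairwise proportion of differing sites), transition/transversion counts,
and dN/dS by the Nei-Gojobori (1986) counting method with Jukes-Cantor
correction. NG86 is a pathway-counting approximation, not a
maximum-likelihood codon model; results carry a ``method_tag`` so they are
never mistaken for ML estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable

from .genetic_code import GeneticCode, get_code
from .genome_io import CodingGene

logger = logging.getLogger(__name__)

_TS_PAIRS = ({"A", "G"}, {"C", "T"})
_UNAMBIG = set("ACGT")


@dataclass(frozen=True)
class GeneMatrix:
    """Equal-length nucleotide rows for one gene across species."""

    gene_name: str
    species_order: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("empty matrix")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene_name}: unequal row lengths {sorted(lengths)}")
        if len(self.rows[0]) == 0:
            raise ValueError(f"{self.gene_name}: zero-length rows")
        if len(self.species_order) != len(self.rows):
            raise ValueError("species_order / rows mismatch")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class DiversityStats:
    gene_name: str
    length: int
    var_sites: int
    var_sites_percent: float
    pi: float
    ts: int
    tv: int
    ts_tv: float | None
    dn: float | None
    ds: float | None
    dn_ds: float | None
    method_tag: str = "NG86"


def build_gene_matrix(genes: Iterable[CodingGene],
                      trim_terminal_stop: bool = False,
                      code: GeneticCode | None = None) -> GeneMatrix:
    """Stack one gene's CDS across species into a matrix.

    Rows keep input order. A length mismatch raises an error naming the
    offending species (alignment is out of scope here). With
    ``trim_terminal_stop`` the final codon is removed uniformly when every
    row ends in a stop codon.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least two species")
    names = {g.gene_name for g in genes}
    if len(names) != 1:
        raise ValueError(f"mixed genes in one matrix: {sorted(names)}")
    ref_len = len(genes[0].cds)
    for g in genes[1:]:
        if len(g.cds) != ref_len:
            raise ValueError(
                f"{g.gene_name}: alignment required — {g.species} has length "
                f"{len(g.cds)}, expected {ref_len} ({genes[0].species})")
    rows = [g.cds for g in genes]
    if trim_terminal_stop:
        code = code or get_code()
        if ref_len >= 3 and ref_len % 3 == 0 and all(
                code.is_stop(r[-3:]) for r in rows):
            rows = [r[:-3] for r in rows]
    return GeneMatrix(gene_name=genes[0].gene_name,
                      species_order=tuple(g.species for g in genes),
                      rows=tuple(rows))


def variable_sites(matrix: GeneMatrix) -> tuple[int, float]:
    """Count of columns with >= 2 distinct unambiguous bases, and percent."""
    count = 0
    for j in range(matrix.length):
        column = {row[j] for row in matrix.rows} & _UNAMBIG
        if len(column) >= 2:
            count += 1
    return count, 100.0 * count / matrix.length


def _pair_diffs(a: str, b: str) -> tuple[int, int]:
    """(differing sites, comparable sites) under pairwise deletion."""
    d = comp = 0
    for x, y in zip(a, b):
        if x in _UNAMBIG and y in _UNAMBIG:
            comp += 1
            if x != y:
                d += 1
    return d, comp


def nucleotide_diversity(matrix: GeneMatrix, complete_deletion: bool = False) -> float:
    """Nei's per-site nucleotide diversity pi.

    pi = 2/(n(n-1)) * sum over pairs of (differing sites / comparable
    sites). Under the default pairwise deletion the comparable-site count
    is per pair; with ``complete_deletion`` columns containing any
    ambiguous base are removed first.
    """
    if matrix.n < 2:
        raise ValueError("pi needs >= 2 rows")
    rows = matrix.rows
    if complete_deletion:
        keep = [j for j in range(matrix.length)
                if all(r[j] in _UNAMBIG for r in rows)]
        if not keep:
            raise ValueError("pi undefined: no unambiguous columns")
        rows = tuple("".join(r[j] for j in keep) for r in rows)
    total = 0.0
    n_pairs = 0
    for a, b in combinations(rows, 2):
        d, comp = _pair_diffs(a, b)
        if comp == 0:
            raise ValueError("pi undefined: a pair shares no comparable sites")
        total += d / comp
        n_pairs += 1
    return total / n_pairs


def ts_tv(matrix: GeneMatrix) -> tuple[int, int, float | None]:
    """Transition and transversion counts over all row pairs and sites.

    A differing site with two unambiguous bases is a transition iff the
    bases are A/G or C/T. The ratio is None when no transversions exist.
    """
    ts = tv = 0
    for a, b in combinations(matrix.rows, 2):
        for x, y in zip(a, b):
            if x == y or x not in _UNAMBIG or y not in _UNAMBIG:
                continue
            if {x, y} in _TS_PAIRS:
                ts += 1
            else:
                tv += 1
    return ts, tv, (ts / tv if tv > 0 else None)


# --- Nei-Gojobori 1986 ---------------------------------------------------

_SITES_CACHE: dict[tuple[int, str], float] = {}
_PATH_CACHE: dict[tuple[int, str, str], tuple[float, float]] = {}


def _codon_sites(codon: str, code: GeneticCode) -> float:
    """Synonymous sites of one codon (nonsynonymous = 3 - result).

    Per position, the synonymous fraction among the one-step changes that
    do not create a stop codon; mutations to stops are excluded from the
    denominator so every codon contributes exactly 3 sites in total.
    """
    key = (code.table_id, codon)
    if key in _SITES_CACHE:
        return _SITES_CACHE[key]
    aa = code.codon_to_aa[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if code.is_stop(alt):
                continue
            valid += 1
            if code.codon_to_aa[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    _SITES_CACHE[key] = s
    return s


def _codon_path_diffs(c1: str, c2: str, code: GeneticCode) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Averages over all orderings of the differing positions (minimal
    mutational pathways); pathways passing through a stop codon are
    excluded, falling back to all pathways if none survive.
    """
    key = (code.table_id, c1, c2)
    if key in _PATH_CACHE:
        return _PATH_CACHE[key]
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in permutations(positions):
        current = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            if code.is_stop(nxt):
                through_stop = True
                sd = nd = 0
                break
            if code.codon_to_aa[current] == code.codon_to_aa[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not through_stop:
            paths.append((sd, nd))
    if not paths:  # every pathway crosses a stop: count all of them anyway
        for order in permutations(positions):
            current = c1
            sd = nd = 0
            for pos in order:
                nxt = current[:pos] + c2[pos] + current[pos + 1:]
                same = (code.translate(current) == code.translate(nxt))
                sd += same
                nd += not same
                current = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    _PATH_CACHE[key] = (sd, nd)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"Jukes-Cantor correction undefined at p = {p:.4f}")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pair(codons1: tuple[str, ...], codons2: tuple[str, ...],
              code: GeneticCode | None = None) -> tuple[float, float]:
    """(dN, dS) for one sequence pair by NG86 with Jukes-Cantor correction.

    Codons containing ambiguous bases in either sequence are skipped for
    this pair; internal stop codons are an error.
    """
    code = code or get_code()
    if len(codons1) != len(codons2):
        raise ValueError("codon sequences differ in length")
    s_sites = n_sites = sd = nd = 0.0
    for idx, (c1, c2) in enumerate(zip(codons1, codons2)):
        if (set(c1) | set(c2)) - _UNAMBIG:
            continue
        for row, c in ((1, c1), (2, c2)):
            if code.is_stop(c):
                raise ValueError(f"internal stop codon {c} in row {row} at codon {idx}")
        s_sites += (_codon_sites(c1, code) + _codon_sites(c2, code)) / 2.0
        n_sites += 3.0 - (_codon_sites(c1, code) + _codon_sites(c2, code)) / 2.0
        d_s, d_n = _codon_path_diffs(c1, c2, code)
        sd += d_s
        nd += d_n
    if s_sites == 0 or n_sites == 0:
        raise ValueError("NG86 undefined: no countable sites")
    return _jukes_cantor(nd / n_sites), _jukes_cantor(sd / s_sites)


def ng86_dnds(matrix: GeneMatrix,
              code: GeneticCode | None = None) -> tuple[float, float, float | None]:
    """Mean pairwise NG86 (dN, dS, dN/dS) over all row pairs.

    The final codon column is removed first when every row ends in a stop.
    Pairs whose Jukes-Cantor correction is undefined (p >= 3/4) are
    dropped with a warning.
    """
    code = code or get_code()
    if matrix.length % 3 != 0:
        raise ValueError(f"{matrix.gene_name}: length {matrix.length} not a codon multiple")
    rows = matrix.rows
    if all(code.is_stop(r[-3:]) for r in rows if set(r[-3:]) <= _UNAMBIG):
        rows = tuple(r[:-3] for r in rows)
    codon_rows = [tuple(r[i:i + 3] for i in range(0, len(r), 3)) for r in rows]
    dns, dss = [], []
    for i, j in combinations(range(len(codon_rows)), 2):
        try:
            dn, ds = ng86_pair(codon_rows[i], codon_rows[j], code)
        except ValueError as exc:
            if "Jukes-Cantor" in str(exc) or "no countable" in str(exc):
                logger.warning("%s pair (%s, %s) dropped: %s", matrix.gene_name,
                               matrix.species_order[i], matrix.species_order[j], exc)
                continue
            raise
        dns.append(dn)
        dss.append(ds)
    if not dns:
        raise ValueError(f"{matrix.gene_name}: no usable pairs for NG86")
    dn = sum(dns) / len(dns)
    ds = sum(dss) / len(dss)
    return dn, ds, (dn / ds if ds > 0 else None)


def selection_classification(dn_ds: float, tol: float = 1e-9) -> str:
    """Classify a dN/dS ratio: <1 purifying, =1 neutral, >1 positive."""
    if math.isnan(dn_ds):
        raise ValueError("dN/dS undefined")
    if abs(dn_ds - 1.0) <= tol:
        return "neutral"
    return "purifying" if dn_ds < 1.0 else "positive"


def diversity_stats(matrix: GeneMatrix, code: GeneticCode | None = None,
                    complete_deletion: bool = False,
                    codon_stats: bool = True) -> DiversityStats:
    """All per-gene divergence statistics in one pass."""
    code = code or get_code()
    var, var_pct = variable_sites(matrix)
    pi = nucleotide_diversity(matrix, complete_deletion=complete_deletion)
    ts, tv, ratio = ts_tv(matrix)
    dn = ds = dn_ds = None
    if codon_stats and matrix.length % 3 == 0:
        try:
            dn, ds, dn_ds = ng86_dnds(matrix, code)
        except ValueError as exc:
            logger.warning("%s: NG86 skipped (%s)", matrix.gene_name, exc)
    return DiversityStats(gene_name=matrix.gene_name, length=matrix.length,
                          var_sites=var, var_sites_percent=var_pct, pi=pi,
                          ts=ts, tv=tv, ts_tv=ratio, dn=dn, ds=ds, dn_ds=dn_ds)
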