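"""Synthetic multi-species mitogenome CDS sets with known ground truth.

The generator emulates the statistical structure of a small clade of
mitogenomes: 10-20 species, 13 protein-coding genes of fixed lengths,
codon usage drawn per synonymous family from a Dirichlet (lower
concentration = stronger bias = smaller ENC), a controllable third-position
GC fraction, species-specific planted aversive codons (never used, hence
recoverable as codon aversion motifs), and divergence from a common
ancestor on a star phylogeny with a controlled per-site substitution
probability and transition/transversion rate ratio kappa.

Every random stream is keyed by (seed, purpose, species, gene) through a
stable CRC-based hash, so regeneration of any part is independent of
generation order.

Ground truth is returned alongside the sequences: sampled codon profiles,
planted and realized aversion sets, and closed-form expectations for the
pairwise difference proportion and the transition/transversion densities
(the initial ATG and terminal stop are held fixed, so expectations apply
to the mutable interior, whose fraction is recorded per gene).
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .codon_aversion import aversion_set
from .codon_usage import count_codons
from .genetic_code import GeneticCode, get_code
from .genome_io import CodingGene
from .reference import PCG_LENGTHS_BP, PCG_NAMES

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}

DEFAULT_GENE_LENGTHS_CODONS = {g: bp // 3 for g, bp in PCG_LENGTHS_BP.items()}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study set (defaults = study conditions)."""

    n_species: int = 10
    gene_lengths_codons: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS_CODONS))
    table_id: int = 2
    family_concentration: float = 0.8
    gene_concentration: float = 50.0
    target_gc3: float = 0.40
    planted_aversion: dict[str, frozenset[str]] | None = None
    aversion_set_size: int = 2
    divergence_p: float = 0.05
    kappa: float = 14.0
    seed: int = 0

    @property
    def code(self) -> GeneticCode:
        return get_code(self.table_id)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(f"species_{i + 1:02d}" for i in range(self.n_species))

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if any(n < 3 for n in self.gene_lengths_codons.values()):
            raise ValueError("genes need >= 3 codons (start, body, stop)")
        if not 0.0 <= self.divergence_p < 0.75:
            raise ValueError("divergence_p must lie in [0, 0.75)")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0.0 < self.target_gc3 < 1.0:
            raise ValueError("target_gc3 must lie in (0, 1)")
        code = self.code
        if self.planted_aversion is not None:
            for sp, planted in self.planted_aversion.items():
                bad = planted & code.stop_codons
                if bad:
                    raise ValueError(f"{sp}: planted stop codons {sorted(bad)}")
                for family in code.families.values():
                    if set(family) <= planted:
                        raise ValueError(
                            f"{sp}: planted aversion covers the whole "
                            f"{code.codon_to_aa[family[0]]} family")


@dataclass
class SyntheticTruth:
    planted: dict[str, frozenset[str]]
    gene_profiles: dict[str, dict[str, dict[str, float]]]  # gene -> aa -> codon -> p
    realized_codon_counts: dict[str, dict[str, Counter]]
    realized_aversion: dict[str, dict[str, frozenset[str]]]
    mutable_fraction: dict[str, float]
    expected_diff_proportion: float  # per mutable site, between two species
    expected_ts_density: float
    expected_tv_density: float
    repairs: dict[str, int]

    @property
    def expected_ts_fraction(self) -> float:
        total = self.expected_ts_density + self.expected_tv_density
        return self.expected_ts_density / total


def _rng(seed: int, *keys: str) -> np.random.Generator:
    tag = zlib.crc32("|".join(keys).encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def default_planting(spec: SyntheticSpec) -> dict[str, frozenset[str]]:
    """Pairwise-distinct aversion sets, one per species, seeded.

    Each set draws ``aversion_set_size`` codons from distinct synonymous
    families (so no family is ever fully averted).
    """
    code = spec.code
    rng = _rng(spec.seed, "planting")
    aa_list = sorted(code.families)
    sets: dict[str, frozenset[str]] = {}
    seen: set[frozenset[str]] = set()
    for sp in spec.species_names:
        for _ in range(1000):
            aas = rng.choice(aa_list, size=spec.aversion_set_size, replace=False)
            planted = frozenset(
                str(rng.choice(code.families[aa])) for aa in aas)
            if planted not in seen and len(planted) == spec.aversion_set_size:
                seen.add(planted)
                sets[sp] = planted
                break
        else:
            raise RuntimeError("could not draw pairwise-distinct aversion sets")
    return sets


def _tilt_gc3(profiles: dict[str, np.ndarray], code: GeneticCode,
              target: float) -> dict[str, np.ndarray]:
    """Reweight GC-ending codons so the aa-uniform expected GC3 hits target."""
    fams = sorted(code.families)
    gc_mask = {aa: np.array([c[2] in "GC" for c in code.families[aa]])
               for aa in fams}

    def expected(lam: float) -> float:
        total = 0.0
        for aa in fams:
            p = profiles[aa] * np.where(gc_mask[aa], lam, 1.0)
            p = p / p.sum()
            total += p[gc_mask[aa]].sum()
        return total / len(fams)

    lo, hi = 1e-9, 1e9
    if not expected(lo) <= target <= expected(hi):
        raise ValueError(f"target_gc3 {target} unreachable")
    for _ in range(200):
        mid = (lo * hi) ** 0.5
        if expected(mid) < target:
            lo = mid
        else:
            hi = mid
    lam = (lo * hi) ** 0.5
    out = {}
    for aa in fams:
        p = profiles[aa] * np.where(gc_mask[aa], lam, 1.0)
        out[aa] = p / p.sum()
    return out


def _genome_profile(spec: SyntheticSpec) -> dict[str, np.ndarray]:
    """Genome-wide per-family codon preferences (one draw per bundle).

    Codon usage bias in a mitogenome is shared across genes — one
    mutational and selective regime shapes all 13 PCGs — so the family
    bias is drawn once at the genome level; genes then vary around it.
    """
    code = spec.code
    rng = _rng(spec.seed, "genome-profile")
    profiles = {}
    for aa in sorted(code.families):
        k = len(code.families[aa])
        profiles[aa] = (rng.dirichlet(np.full(k, spec.family_concentration))
                        if k > 1 else np.ones(1))
    return profiles


def _base_gene_profile(spec: SyntheticSpec, gene: str) -> dict[str, np.ndarray]:
    """Per-gene profile: a tight Dirichlet around the genome profile.

    ``gene_concentration`` controls cross-gene consistency (higher =
    genes more alike); the GC3 tilt is applied per gene.
    """
    code = spec.code
    genome = _genome_profile(spec)
    rng = _rng(spec.seed, "profile", gene)
    profiles = {}
    for aa in sorted(code.families):
        k = len(code.families[aa])
        if k == 1:
            profiles[aa] = np.ones(1)
            continue
        alpha = spec.gene_concentration * genome[aa] + 1e-3
        profiles[aa] = rng.dirichlet(alpha)
    return _tilt_gc3(profiles, code, spec.target_gc3)


def sample_codon_profile(spec: SyntheticSpec, species: str,
                         gene: str) -> dict[str, np.ndarray]:
    """Per-family codon probabilities for one species and gene.

    The gene's base profile (Dirichlet draw, GC3-tilted) is shared across
    species; the species' planted aversive codons are then forced to
    probability zero and each affected family renormalized. Species not in
    the planting map (including the ancestor) get the base profile.
    """
    spec.validate()
    code = spec.code
    base = _base_gene_profile(spec, gene)
    planting = (spec.planted_aversion if spec.planted_aversion is not None
                else default_planting(spec))
    planted = planting.get(species, frozenset())
    if not planted:
        return base
    out = {}
    for aa, family in sorted(code.families.items()):
        p = base[aa].copy()
        for i, codon in enumerate(family):
            if codon in planted:
                p[i] = 0.0
        if p.sum() == 0:
            raise ValueError(f"{species}: aversion covers whole {aa} family")
        out[aa] = p / p.sum()
    return out


def _draw_codons(profile: dict[str, np.ndarray], code: GeneticCode,
                 n: int, rng: np.random.Generator) -> list[str]:
    """n codons i.i.d.: family uniform over amino acids, codon per profile."""
    aas = sorted(code.families)
    fam_idx = rng.integers(0, len(aas), size=n)
    out = []
    for fi in fam_idx:
        aa = aas[fi]
        family = code.families[aa]
        ci = rng.choice(len(family), p=profile[aa])
        out.append(family[ci])
    return out


def _mutate(seq: str, p: float, kappa: float,
            rng: np.random.Generator) -> str:
    """Substitute interior sites i.i.d.; first and last codon are fixed."""
    chars = list(seq)
    lo, hi = 3, len(chars) - 3
    if hi <= lo or p == 0.0:
        return seq
    alpha = kappa / (kappa + 2.0)
    hits = np.nonzero(rng.random(hi - lo) < p)[0] + lo
    us = rng.random(len(hits))
    vs = rng.random(len(hits))
    for pos, u, v in zip(hits, us, vs):
        base = chars[pos]
        if u < alpha:
            chars[pos] = _TRANSITION[base]
        else:
            chars[pos] = _TRANSVERSIONS[base][int(v < 0.5)]
    return "".join(chars)


def _repair(codons: list[str], profile: dict[str, np.ndarray],
            code: GeneticCode, planted: frozenset[str],
            rng: np.random.Generator) -> int:
    """Fix interior codons that realize a stop or an averted codon.

    Stops get a minimal third-base edit to a sense codon (1 nt changed);
    averted codons are redrawn within their synonymous family from the
    species profile (which is zero on averted codons). Repair counts are
    returned so downstream tests can bound the perturbation they cause.
    """
    repairs = 0
    for i in range(1, len(codons) - 1):
        codon = codons[i]
        if code.is_stop(codon):
            options = [codon[:2] + b for b in "ACGT"
                       if b != codon[2] and not code.is_stop(codon[:2] + b)]
            codons[i] = options[rng.integers(0, len(options))]
            repairs += 1
            codon = codons[i]
        if codon in planted:  # redraw within the family: keeps the amino acid
            aa = code.codon_to_aa[codon]
            family = code.families[aa]
            ci = rng.choice(len(family), p=profile[aa])
            codons[i] = family[ci]
            repairs += 1
    return repairs


def _expectations(p: float, kappa: float) -> tuple[float, float, float]:
    """Closed-form per-mutable-site expectations between two star tips.

    A site differs if exactly one lineage mutated, or both did and landed
    on different bases. Transition probability per substitution is
    alpha = kappa/(kappa+2); each specific transversion has beta =
    1/(kappa+2). The two transversion partners of any base are each
    other's transition partners, which yields the both-mutated terms.
    """
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    one = 2.0 * p * (1.0 - p)
    ts = one * alpha + 2.0 * p * p * beta * beta
    tv = one * 2.0 * beta + 4.0 * p * p * alpha * beta
    return ts + tv, ts, tv


def generate_cds_set(spec: SyntheticSpec) -> tuple[
        dict[str, CodingGene], dict[str, dict[str, CodingGene]], SyntheticTruth]:
    """Generate the ancestor and all species gene sets, plus ground truth."""
    spec.validate()
    code = spec.code
    planting = (spec.planted_aversion if spec.planted_aversion is not None
                else default_planting(spec))
    gene_profiles: dict[str, dict[str, np.ndarray]] = {}
    ancestor: dict[str, CodingGene] = {}
    for gene, n_codons in sorted(spec.gene_lengths_codons.items()):
        profile = _base_gene_profile(spec, gene)
        gene_profiles[gene] = profile
        rng = _rng(spec.seed, "ancestor", gene)
        body = _draw_codons(profile, code, n_codons - 2, rng)
        codons = ["ATG"] + body + ["TAA"]
        cds = "".join(codons)
        ancestor[gene] = CodingGene(species="ancestor", gene_name=gene,
                                    cds=cds, codons=tuple(codons),
                                    has_complete_stop=True)

    species_sets: dict[str, dict[str, CodingGene]] = {}
    realized_counts: dict[str, dict[str, Counter]] = {}
    realized_aversion: dict[str, dict[str, frozenset[str]]] = {}
    repairs: dict[str, int] = {}
    for sp in spec.species_names:
        planted = planting.get(sp, frozenset())
        species_sets[sp] = {}
        realized_counts[sp] = {}
        realized_aversion[sp] = {}
        repairs[sp] = 0
        for gene in sorted(spec.gene_lengths_codons):
            rng = _rng(spec.seed, "evolve", sp, gene)
            seq = _mutate(ancestor[gene].cds, spec.divergence_p, spec.kappa, rng)
            codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
            profile = sample_codon_profile(spec, sp, gene)
            repairs[sp] += _repair(codons, profile, code, planted, rng)
            cds = "".join(codons)
            gene_obj = CodingGene(species=sp, gene_name=gene, cds=cds,
                                  codons=tuple(codons), has_complete_stop=True)
            species_sets[sp][gene] = gene_obj
            counts = count_codons(gene_obj, exclude_initial=True,
                                  exclude_stops=True, code=code)
            realized_counts[sp][gene] = Counter(counts.counts)
            realized_aversion[sp][gene] = aversion_set(counts, code).absent_codons

    diff, ts, tv = _expectations(spec.divergence_p, spec.kappa)
    mutable = {g: (3 * n - 6) / (3 * n)
               for g, n in spec.gene_lengths_codons.items()}
    truth = SyntheticTruth(
        planted={sp: frozenset(planting.get(sp, frozenset()))
                 for sp in spec.species_names},
        gene_profiles={g: {aa: dict(zip(code.families[aa], map(float, p)))
                           for aa, p in prof.items()}
                       for g, prof in gene_profiles.items()},
        realized_codon_counts=realized_counts,
        realized_aversion=realized_aversion,
        mutable_fraction=mutable,
        expected_diff_proportion=diff,
        expected_ts_density=ts,
        expected_tv_density=tv,
        repairs=repairs,
    )
    return ancestor, species_sets, truth


# --- GenBank emission ----------------------------------------------------

_MITOGENOME_ORDER = [g for g in PCG_NAMES]


def emit_records(species_sets: dict[str, dict[str, CodingGene]],
                 spec: SyntheticSpec, outdir) -> list[str]:
    """Write one GenBank flat file per species, parseable by genome_io.

    Records carry placeholder tRNA/rRNA/control-region features and all
    CDS features with field-style alias names (e.g. ``ND2``, ``CYB``) to
    exercise name normalization. MT-ND6 (when present, else the last gene)
    is placed on the light strand, stored reverse-complemented.
    """
    from pathlib import Path

    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for idx, (sp, genes) in enumerate(sorted(species_sets.items()), start=1):
        rng = _rng(spec.seed, "scaffold", sp)

        def filler(n: int) -> str:
            return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])

        gene_order = [g for g in _MITOGENOME_ORDER if g in genes]
        gene_order += [g for g in sorted(genes) if g not in gene_order]
        minus_gene = "MT-ND6" if "MT-ND6" in genes else gene_order[-1]

        chunks: list[str] = []
        features: list[SeqFeature] = []
        pos = 0

        def add(seq: str, ftype: str, quals: dict, strand: int = 1):
            nonlocal pos
            features.append(SeqFeature(
                SimpleLocation(pos, pos + len(seq), strand=strand),
                type=ftype, qualifiers=quals))
            chunks.append(seq)
            pos += len(seq)

        add(filler(70), "tRNA", {"product": ["tRNA-Phe"]})
        add(filler(975), "rRNA", {"product": ["12S ribosomal RNA"]})
        add(filler(70), "tRNA", {"product": ["tRNA-Val"]})
        add(filler(1600), "rRNA", {"product": ["16S ribosomal RNA"]})
        for gene in gene_order:
            alias = gene.removeprefix("MT-")
            cds = genes[gene].cds
            if gene == minus_gene:
                add(str(Seq(cds).reverse_complement()), "CDS",
                    {"gene": [alias]}, strand=-1)
            else:
                add(cds, "CDS", {"gene": [alias]})
            add(filler(2), "spacer", {})  # skipped by the parser
        add(filler(1200), "D-loop", {})

        features = [f for f in features if f.type != "spacer"]
        record = SeqRecord(
            Seq("".join(chunks)), id=f"SYN{idx:05d}", name=f"SYN{idx:05d}",
            description=f"synthetic mitogenome of {sp}",
            annotations={"molecule_type": "DNA", "topology": "circular",
                         "organism": sp},
            features=features)
        path = outdir / f"{sp}.gb"
        SeqIO.write([record], str(path), "genbank")
        paths.append(str(path))
    return paths
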