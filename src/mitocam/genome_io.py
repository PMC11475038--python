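"""Reading annotated mitogenomes and extracting coding sequences.

Handles GenBank flat files (via Biopython) and a plain-text alternative
(genome FASTA plus a tab-separated feature table). Coordinates are 0-based
half-open internally; GenBank's 1-based inclusive intervals are converted
at the parser boundary. Features that wrap the circular origin arrive from
Biopython as compound locations and are kept as multiple spans joined in
feature order.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import GeneticCode, get_code
from .reference import PCG_NAMES

logger = logging.getLogger(__name__)

PCG, TRNA, RRNA, CR = "PCG", "tRNA", "rRNA", "CR"


@dataclass(frozen=True)
class Feature:
    """One annotated gene/region on the heavy strand.

    ``spans`` are 0-based half-open intervals in feature order (two spans
    for origin-wrapping features of circular genomes); ``strand`` is '+'
    or '-'.
    """

    gene_name: str
    kind: str
    spans: tuple[tuple[int, int], ...]
    strand: str
    name_recognized: bool = True

    def __post_init__(self):
        if not self.spans:
            raise ValueError(f"feature {self.gene_name}: no spans")
        for s, e in self.spans:
            if not s < e:
                raise ValueError(f"feature {self.gene_name}: empty span ({s}, {e})")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.gene_name}: bad strand {self.strand!r}")
        if self.kind == PCG and self.gene_name not in PCG_NAMES:
            raise ValueError(f"unknown protein-coding gene name {self.gene_name!r}")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.spans)


@dataclass
class MitogenomeRecord:
    """A parsed mitogenome: heavy-strand sequence plus features."""

    accession: str
    species: str
    sequence: str
    features: list[Feature]

    def __post_init__(self):
        if not self.accession:
            raise ValueError("accession must be nonempty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.accession}: unexpected characters {sorted(bad)}")

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]


@dataclass(frozen=True)
class CodingGene:
    """One species' protein-coding gene in reading orientation."""

    species: str
    gene_name: str
    cds: str
    codons: tuple[str, ...]
    has_complete_stop: bool

    @property
    def n_ambiguous_codons(self) -> int:
        return sum(1 for c in self.codons if set(c) - set("ACGT"))


@dataclass(frozen=True)
class CompositionSummary:
    counts: dict[str, int]
    at_percent: float
    gc_percent: float


# --- gene-name normalization -------------------------------------------

_TRNA_BY_AA = {
    "Phe": "MT-TF", "Val": "MT-TV", "Ile": "MT-TI", "Gln": "MT-TQ",
    "Met": "MT-TM", "Trp": "MT-TW", "Ala": "MT-TA", "Asn": "MT-TN",
    "Cys": "MT-TC", "Tyr": "MT-TY", "Asp": "MT-TD", "Lys": "MT-TK",
    "Gly": "MT-TG", "Arg": "MT-TR", "His": "MT-TH", "Glu": "MT-TE",
    "Thr": "MT-TT", "Pro": "MT-TP",
}
_AA3_BY_LETTER = {
    "F": "Phe", "V": "Val", "I": "Ile", "Q": "Gln", "M": "Met", "W": "Trp",
    "A": "Ala", "N": "Asn", "C": "Cys", "Y": "Tyr", "D": "Asp", "K": "Lys",
    "G": "Gly", "R": "Arg", "H": "His", "E": "Glu", "T": "Thr", "P": "Pro",
}

_ALIASES: dict[str, str] = {}
for _i in ("1", "2", "3", "4", "4L", "5", "6"):
    for _a in (f"ND{_i}", f"NAD{_i}", f"NADH{_i}", f"NADH DEHYDROGENASE SUBUNIT {_i}",
               f"MT-ND{_i}"):
        _ALIASES[_a] = f"MT-ND{_i}"
for _i, _roman in (("1", "I"), ("2", "II"), ("3", "III")):
    for _a in (f"CO{_i}", f"COX{_i}", f"CO{_roman}", f"COX{_roman}", f"MT-CO{_i}",
               f"CYTOCHROME C OXIDASE SUBUNIT {_i}"):
        _ALIASES[_a] = f"MT-CO{_i}"
for _a in ("CYTB", "COB", "CYB", "CYT B", "MT-CYB", "CYTOCHROME B"):
    _ALIASES[_a] = "MT-CYB"
for _i in ("6", "8"):
    for _a in (f"ATP{_i}", f"ATPASE{_i}", f"ATPASE {_i}", f"ATP SYNTHASE F0 SUBUNIT {_i}",
               f"MT-ATP{_i}"):
        _ALIASES[_a] = f"MT-ATP{_i}"
for _a in ("12S", "12S RRNA", "RRNS", "S-RRNA", "RRN12", "MT-RNR1",
           "12S RIBOSOMAL RNA", "SMALL SUBUNIT RIBOSOMAL RNA"):
    _ALIASES[_a] = "MT-RNR1"
for _a in ("16S", "16S RRNA", "RRNL", "L-RRNA", "RRN16", "MT-RNR2",
           "16S RIBOSOMAL RNA", "LARGE SUBUNIT RIBOSOMAL RNA"):
    _ALIASES[_a] = "MT-RNR2"
for _a in ("D-LOOP", "DLOOP", "CONTROL REGION", "CR", "MISC_FEATURE"):
    _ALIASES[_a] = "CR"
for _aa3, _hgnc in _TRNA_BY_AA.items():
    for _a in (f"TRN{_aa3}", f"TRNA-{_aa3}", _hgnc):
        _ALIASES[_a.upper()] = _hgnc
# Duplicated-isotype tRNAs (Leu and Ser) carry an index or anticodon class.
for _a in ("TRNL1", "TRNL(UUR)", "TRNA-LEU(UUR)", "TRNL-UAA", "MT-TL1"):
    _ALIASES[_a] = "MT-TL1"
for _a in ("TRNL2", "TRNL(CUN)", "TRNA-LEU(CUN)", "TRNL-UAG", "MT-TL2"):
    _ALIASES[_a] = "MT-TL2"
for _a in ("TRNS1", "TRNS(UCN)", "TRNA-SER(UCN)", "MT-TS1"):
    _ALIASES[_a] = "MT-TS1"
for _a in ("TRNS2", "TRNS(AGY)", "TRNA-SER(AGY)", "MT-TS2"):
    _ALIASES[_a] = "MT-TS2"
# Single-letter trn aliases, e.g. trnF -> MT-TF.
for _letter, _aa3 in _AA3_BY_LETTER.items():
    for _a in (f"TRN{_letter}", f"TRNA-{_letter}"):
        _ALIASES[_a] = _TRNA_BY_AA[_aa3]


def normalize_gene_name(raw: str) -> tuple[str, bool]:
    """Normalize a gene alias to its HGNC-style mitochondrial name.

    Returns ``(name, recognized)``; unknown names are returned unchanged
    with ``recognized = False``.
    """
    if not raw:
        raise ValueError("empty gene name")
    key = raw.strip().upper()
    if key in _ALIASES:
        return _ALIASES[key], True
    return raw, False


# --- parsing ------------------------------------------------------------

_KIND_BY_FEATURE_TYPE = {"CDS": PCG, "tRNA": TRNA, "rRNA": RRNA, "D-loop": CR}


def _feature_name(seq_feature) -> str:
    for qual in ("gene", "product", "note"):
        vals = seq_feature.qualifiers.get(qual)
        if vals:
            return str(vals[0])
    return seq_feature.type


def _to_feature(seq_feature, kind: str) -> Feature:
    name, known = normalize_gene_name(_feature_name(seq_feature))
    spans = tuple((int(p.start), int(p.end)) for p in seq_feature.location.parts)
    strand = "-" if (seq_feature.location.strand or 1) < 0 else "+"
    return Feature(gene_name=name, kind=kind, spans=spans, strand=strand,
                   name_recognized=known)


def _record_from_seqrecord(rec: SeqRecord) -> MitogenomeRecord:
    features: list[Feature] = []
    for sf in rec.features:
        kind = _KIND_BY_FEATURE_TYPE.get(sf.type)
        if sf.type == "misc_feature":
            name = _feature_name(sf).strip().upper()
            if "CONTROL REGION" in name or name in ("CR", "D-LOOP"):
                kind = CR
        if kind is None:
            continue
        try:
            features.append(_to_feature(sf, kind))
        except ValueError as exc:
            logger.warning("%s: skipping feature (%s)", rec.id, exc)
    species = rec.annotations.get("organism") or rec.description or rec.id
    record = MitogenomeRecord(
        accession=rec.id or rec.name,
        species=species,
        sequence=str(rec.seq).upper(),
        features=features,
    )
    if not record.features_of_kind(PCG):
        warnings.warn(f"record {record.accession} has no CDS features")
    return record


def parse_genbank(path: str | Path) -> list[MitogenomeRecord]:
    """Parse a GenBank flat file into mitogenome records (one per LOCUS)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises various parse errors
        raise ValueError(f"{path}: not a parseable GenBank file ({exc})") from exc
    if not seq_records:
        raise ValueError(f"{path}: no GenBank records found")
    return [_record_from_seqrecord(r) for r in seq_records]


def read_fasta_with_features(fasta_path: str | Path,
                             table_path: str | Path) -> list[MitogenomeRecord]:
    """Plain-text input mode: genome FASTA plus a TSV feature table.

    The table columns are: accession, gene, kind, start, end, strand, with
    1-based inclusive coordinates (converted here) and optional extra
    ``start2``/``end2`` columns for origin-wrapping features.
    """
    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ValueError(f"{fasta_path}: no FASTA records")
    feats: dict[str, list[Feature]] = {acc: [] for acc in seqs}
    with open(table_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            acc = row["accession"]
            if acc not in seqs:
                raise ValueError(f"feature table references unknown accession {acc}")
            name, known = normalize_gene_name(row["gene"])
            spans = [(int(row["start"]) - 1, int(row["end"]))]
            if row.get("start2"):
                spans.append((int(row["start2"]) - 1, int(row["end2"])))
            feats[acc].append(Feature(gene_name=name, kind=row["kind"],
                                      spans=tuple(spans), strand=row["strand"],
                                      name_recognized=known))
    return [MitogenomeRecord(accession=acc, species=acc, sequence=seq,
                             features=feats[acc]) for acc, seq in seqs.items()]


# --- extraction and composition ----------------------------------------

def extract_cds(record: MitogenomeRecord, feature: Feature,
                code: GeneticCode | None = None) -> CodingGene:
    """Extract one PCG in reading orientation and split it into codons.

    Spans are concatenated in feature order, the result is
    reverse-complemented for '-' strand features, and a trailing partial
    codon (incomplete stops completed by polyadenylation) is dropped from
    the codon list.
    """
    if feature.kind != PCG:
        raise ValueError(f"{feature.gene_name}: not a protein-coding feature")
    code = code or get_code()
    n = len(record.sequence)
    parts = []
    for s, e in feature.spans:
        if e > n:
            raise IndexError(
                f"{record.accession} {feature.gene_name}: span ({s}, {e}) "
                f"exceeds sequence length {n}")
        parts.append(record.sequence[s:e])
    cds = "".join(parts)
    if feature.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    codons = tuple(cds[i:i + 3] for i in range(0, len(cds) - len(cds) % 3, 3))
    has_stop = bool(codons) and code.is_stop(codons[-1])
    return CodingGene(species=record.species, gene_name=feature.gene_name,
                      cds=cds, codons=codons, has_complete_stop=has_stop)


def extract_all_pcgs(record: MitogenomeRecord,
                     code: GeneticCode | None = None) -> list[CodingGene]:
    return [extract_cds(record, f, code) for f in record.features_of_kind(PCG)]


def base_composition(sequence: str) -> CompositionSummary:
    """A/C/G/T/N counts and AT%/GC% (N excluded from the denominator)."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGTN"}
    acgt = sum(counts[b] for b in "ACGT")
    if acgt == 0:
        raise ValueError("composition undefined: no unambiguous bases")
    at = 100.0 * (counts["A"] + counts["T"]) / acgt
    return CompositionSummary(counts=counts, at_percent=at, gc_percent=100.0 - at)


def organization_table(records: list[MitogenomeRecord]):
    """Per-record sizes and AT% for the genome, PCGs, rRNAs, tRNAs and CR.

    PCG length sums annotated CDS feature lengths (stop codons included);
    tRNA length sums per-feature lengths (overlaps counted per feature).
    Missing feature kinds yield empty cells.
    """
    import pandas as pd

    def _slice(record: MitogenomeRecord, feature: Feature) -> str:
        return "".join(record.sequence[s:e] for s, e in feature.spans)

    rows = []
    for rec in records:
        row: dict[str, object] = {"accession": rec.accession, "species": rec.species}
        row["genome_bp"] = len(rec.sequence)
        row["genome_at_pct"] = base_composition(rec.sequence).at_percent
        pcgs = rec.features_of_kind(PCG)
        if pcgs:
            seq = "".join(_slice(rec, f) for f in pcgs)
            row["pcg_bp"] = sum(f.length for f in pcgs)
            row["pcg_at_pct"] = base_composition(seq).at_percent
        for rnr in ("MT-RNR1", "MT-RNR2"):
            hits = [f for f in rec.features if f.gene_name == rnr]
            if hits:
                row[f"{rnr}_bp"] = hits[0].length
                row[f"{rnr}_at_pct"] = base_composition(_slice(rec, hits[0])).at_percent
        trnas = rec.features_of_kind(TRNA)
        if trnas:
            seq = "".join(_slice(rec, f) for f in trnas)
            row["trna_bp"] = sum(f.length for f in trnas)
            row["trna_at_pct"] = base_composition(seq).at_percent
        crs = rec.features_of_kind(CR)
        if crs:
            seq = "".join(_slice(rec, f) for f in crs)
            row["cr_bp"] = sum(f.length for f in crs)
            row["cr_at_pct"] = base_composition(seq).at_percent
        rows.append(row)
    return pd.DataFrame(rows)


def write_cds_fasta(genes: list[CodingGene], path: str | Path) -> None:
    """Write extracted CDS as FASTA, one record per species x gene."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.species}|{g.gene_name}\n")
            for i in range(0, len(g.cds), 70):
                fh.write(g.cds[i:i + 70] + "\n")
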