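"""End-to-end analysis pipeline: records in, report tables out.

Stages: parse -> organization table -> codon-usage statistics (RSCU,
ENC/GC3s, PR2) -> codon aversion motifs and uniqueness -> per-gene
divergence statistics -> ENC-matrix PCA. Every output is a deterministic
TSV or JSON (fixed column order, UNIX newlines, '.' decimals, stated
rounding; full-precision values in a parallel JSON), so re-running with
identical inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import codon_aversion as ca
from . import codon_usage as cu
from . import divergence as dv
from . import genome_io as gio
from . import multivariate as mv
from .genetic_code import get_code

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.5f"


@dataclass
class RunConfig:
    genbank_paths: list[str] = field(default_factory=list)
    fasta_path: str | None = None
    feature_table_path: str | None = None
    outdir: str = "mitocam_out"
    table_id: int = 2
    exclude_initial: bool = True
    exclude_stops: bool = True
    complete_deletion: bool = False
    min_gene_length: int = ca.MIN_GENE_LENGTH
    pca_scale: bool = False
    impute_enc: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def load_records(config: RunConfig) -> list[gio.MitogenomeRecord]:
    records: list[gio.MitogenomeRecord] = []
    for path in config.genbank_paths:
        records.extend(gio.parse_genbank(path))
    if config.fasta_path:
        if not config.feature_table_path:
            raise ValueError("FASTA input requires a feature table")
        records.extend(gio.read_fasta_with_features(config.fasta_path,
                                                    config.feature_table_path))
    if not records:
        raise ValueError("no input records")
    return records


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT,
              lineterminator="\n")


def _species_genes(records, code):
    """{species: {gene: CodingGene}} in input record order."""
    out: dict[str, dict[str, gio.CodingGene]] = {}
    for rec in records:
        genes = {g.gene_name: g for g in gio.extract_all_pcgs(rec, code)}
        out[rec.species] = genes
    return out


def stage_organization(records, outdir: Path) -> pd.DataFrame:
    table = gio.organization_table(records)
    _write_tsv(table, outdir / "organization.tsv")
    return table


def stage_usage(species_genes, config: RunConfig, outdir: Path):
    """RSCU per species (concatenated PCGs), ENC/GC3s per species and per
    gene, PR2 per gene across species."""
    code = get_code(config.table_id)
    per_species_counts = {}
    per_unit_counts = {}
    for sp, genes in species_genes.items():
        merged = cu.count_codons_many(
            genes.values(), species=sp, exclude_initial=config.exclude_initial,
            exclude_stops=config.exclude_stops, code=code)
        per_species_counts[sp] = merged
        per_unit_counts[(sp, "ALL")] = merged
        for gene_name, gene in genes.items():
            per_unit_counts[(sp, gene_name)] = cu.count_codons(
                gene, config.exclude_initial, config.exclude_stops, code)

    species = sorted(per_species_counts)
    rscu_rows = []
    for codon in code.sense_codons:
        row = {"codon": codon, "amino_acid": code.codon_to_aa[codon]}
        for sp in species:
            row[sp] = cu.rscu(per_species_counts[sp], code).values[codon]
        rscu_rows.append(row)
    rscu_df = pd.DataFrame(rscu_rows)
    _write_tsv(rscu_df, outdir / "rscu.tsv")

    enc_df = cu.enc_gc3s_table(
        dict(sorted(per_unit_counts.items())), code,
        impute_missing=config.impute_enc)
    _write_tsv(enc_df, outdir / "enc_gc3s.tsv")

    genes_all = sorted({g for (_, g) in per_unit_counts if g != "ALL"})
    pr2_rows = []
    for gene_name in genes_all:
        merged = None
        for sp in species:
            c = per_unit_counts.get((sp, gene_name))
            if c is None:
                continue
            merged = c if merged is None else merged + c
        try:
            pt = cu.pr2_point(merged, code)
            pr2_rows.append({"gene": gene_name, "x_g3": pt.x, "y_a3": pt.y,
                             "quadrant": pt.quadrant})
        except ValueError as exc:
            logger.warning("PR2 undefined for %s: %s", gene_name, exc)
    _write_tsv(pd.DataFrame(pr2_rows), outdir / "pr2.tsv")
    return per_unit_counts, rscu_df, enc_df


def stage_cam(species_genes, config: RunConfig, outdir: Path):
    code = get_code(config.table_id)
    profiles = [ca.build_profile(sp, genes.values(), code,
                                 min_length=config.min_gene_length)
                for sp, genes in sorted(species_genes.items())]
    genes = sorted(set().union(*(p.motifs.keys() for p in profiles))
                   ) if profiles else []
    rows = []
    for p in profiles:
        row = {"species": p.species}
        for g in genes:
            row[g] = p.motifs[g].motif_string if g in p.motifs else ""
        rows.append(row)
    _write_tsv(pd.DataFrame(rows), outdir / "cam_motifs.tsv")

    report = None
    if len(profiles) >= 2:
        report = ca.uniqueness_matrix(profiles, genes)
        payload = {
            "genes": report.genes,
            "species": report.species,
            "genes_fully_distinct": report.genes_fully_distinct,
            "distinct_pair_fraction": {
                g: (sum(cells.values()) / len(cells) if cells else None)
                for g, cells in report.pairwise.items()},
            "incomparable": [list(t) for t in report.incomparable],
        }
        with open(outdir / "uniqueness.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return profiles, report


def stage_divergence(species_genes, config: RunConfig, outdir: Path) -> pd.DataFrame:
    code = get_code(config.table_id)
    species = sorted(species_genes)
    common = sorted(set.intersection(*(set(g) for g in species_genes.values())))
    rows = []
    for gene_name in common:
        matrix = dv.build_gene_matrix(
            [species_genes[sp][gene_name] for sp in species], code=code)
        st = dv.diversity_stats(matrix, code,
                                complete_deletion=config.complete_deletion)
        rows.append(dataclasses.asdict(st))
    # Overall row: concatenated common genes, nucleotide statistics only.
    concat = [gio.CodingGene(
        species=sp, gene_name="Overall",
        cds="".join(species_genes[sp][g].cds for g in common),
        codons=(), has_complete_stop=False) for sp in species]
    matrix = dv.build_gene_matrix(concat, code=code)
    st = dv.diversity_stats(matrix, code, codon_stats=False,
                            complete_deletion=config.complete_deletion)
    overall = dataclasses.asdict(st)
    for k in ("ts", "tv", "ts_tv", "dn", "ds", "dn_ds"):
        overall[k] = None
    overall["method_tag"] = ""
    rows.append(overall)
    df = pd.DataFrame(rows)
    _write_tsv(df, outdir / "divergence.tsv")
    return df


def stage_pca(per_unit_counts, config: RunConfig, outdir: Path):
    code = get_code(config.table_id)
    per_gene_enc = {}
    for (sp, gene_name), counts in per_unit_counts.items():
        if gene_name == "ALL":
            continue
        per_gene_enc[(sp, gene_name)] = cu.enc(counts, code,
                                               impute_missing=config.impute_enc)
    matrix = mv.build_enc_matrix(per_gene_enc, impute=config.impute_enc)
    result = mv.pca_explained_variance(matrix, scale=config.pca_scale)
    _write_tsv(result.scores.rename_axis("species"), outdir / "pca_scores.tsv",
               index=True)
    _write_tsv(result.loadings.rename_axis("gene"), outdir / "pca_loadings.tsv",
               index=True)
    expl = pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(len(result.explained_variance_fraction))],
        "explained_fraction": result.explained_variance_fraction})
    _write_tsv(expl, outdir / "pca.tsv")
    return result


_PROVENANCE = {
    "organization.tsv": "genome_io.organization_table (per-record sizes and AT%)",
    "rscu.tsv": "codon_usage.rscu on per-species concatenated PCG counts",
    "enc_gc3s.tsv": "codon_usage.enc / gc3s / expected_enc per unit",
    "pr2.tsv": "codon_usage.pr2_point per gene over all species",
    "cam_motifs.tsv": "codon_aversion.build_profile (RSCU = 0 rule)",
    "uniqueness.json": "codon_aversion.uniqueness_matrix",
    "divergence.tsv": "divergence.diversity_stats per gene + nucleotide-only Overall",
    "pca_scores.tsv": "multivariate.pca_explained_variance scores",
    "pca_loadings.tsv": "multivariate.pca_explained_variance loadings",
    "pca.tsv": "multivariate.pca_explained_variance explained fractions",
}


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to MANIFEST.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest: dict = {"stages": {}, "provenance": _PROVENANCE, "warnings": []}

    def _done(stage: str, status: str = "complete") -> None:
        manifest["stages"][stage] = status

    records = load_records(config)
    code = get_code(config.table_id)
    species_genes = _species_genes(records, code)

    stage_organization(records, outdir)
    _done("organization")

    per_unit_counts, _, _ = stage_usage(species_genes, config, outdir)
    _done("usage")

    profiles, report = stage_cam(species_genes, config, outdir)
    _done("cam", "complete" if report is not None else "skipped: < 2 species")

    values: dict = {}
    if len(records) >= 2:
        div_df = stage_divergence(species_genes, config, outdir)
        _done("divergence")
        values["pi_by_gene"] = dict(zip(div_df["gene_name"], div_df["pi"]))
        pca_result = stage_pca(per_unit_counts, config, outdir)
        _done("pca")
        values["pca_explained_fraction"] = [
            float(v) for v in pca_result.explained_variance_fraction]
    else:
        msg = "skipped: single record"
        _done("divergence", msg)
        _done("pca", msg)
        manifest["warnings"].append("divergence and PCA need >= 2 records")

    with open(outdir / "values.json", "w") as fh:
        json.dump(values, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# --- CAM profile (de)serialization for the identify CLI ------------------

def profiles_to_jsonable(profiles: list[ca.CamProfile]) -> dict:
    return {p.species: {g: sorted(m.absent_codons)
                        for g, m in sorted(p.motifs.items())}
            for p in profiles}


def profiles_from_jsonable(data: dict) -> list[ca.CamProfile]:
    out = []
    for sp, motifs in data.items():
        out.append(ca.CamProfile(species=sp, motifs={
            g: ca.CamMotif(species=sp, gene_name=g,
                           absent_codons=frozenset(codons))
            for g, codons in motifs.items()}))
    return out
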