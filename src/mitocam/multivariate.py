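"""PCA of the species x gene ENC matrix.

A compact view of how codon-usage evenness varies across species: rows are
species, columns the 13 PCGs, cells the per-gene ENC. Columns are centered
(optionally unit-scaled) and decomposed by SVD; components follow a
deterministic sign convention (the loading of largest magnitude is made
positive) so outputs are stable across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_usage import EncResult


@dataclass
class EncMatrix:
    data: pd.DataFrame  # rows = species, columns = genes
    imputed_cells: list[tuple[str, str]] = field(default_factory=list)
    constant_columns: list[str] = field(default_factory=list)


@dataclass
class PcaResult:
    scores: pd.DataFrame           # species x component
    loadings: pd.DataFrame         # gene x component
    explained_variance_fraction: np.ndarray
    scaled: bool


def build_enc_matrix(per_gene_enc: dict[tuple[str, str], "EncResult | float"],
                     impute: bool = False) -> EncMatrix:
    """Assemble the species x gene ENC matrix in stable sorted order.

    A missing (species, gene) cell is an error unless ``impute``, in which
    case the gene's column mean over available species fills it (flagged).
    Constant columns are retained and flagged.
    """
    species = sorted({k[0] for k in per_gene_enc})
    genes = sorted({k[1] for k in per_gene_enc})
    values = pd.DataFrame(np.nan, index=species, columns=genes, dtype=float)
    for (sp, gene), res in per_gene_enc.items():
        values.loc[sp, gene] = res.enc if isinstance(res, EncResult) else float(res)
    imputed = [(sp, g) for sp in species for g in genes
               if np.isnan(values.loc[sp, g])]
    if imputed and not impute:
        sp, g = imputed[0]
        raise ValueError(f"missing ENC for species {sp!r}, gene {g!r}")
    for sp, g in imputed:
        values.loc[sp, g] = values[g].mean(skipna=True)
    if values.isna().any().any():
        raise ValueError("a gene has no ENC value for any species")
    if len(species) < 2 or len(genes) < 2:
        raise ValueError("ENC matrix needs >= 2 species and >= 2 genes")
    constant = [g for g in genes if values[g].nunique() == 1]
    return EncMatrix(data=values, imputed_cells=imputed, constant_columns=constant)


def pca_explained_variance(matrix: EncMatrix, scale: bool = False) -> PcaResult:
    """Center (optionally unit-scale) the ENC matrix and decompose by SVD.

    Explained fraction_i = sigma_i^2 / sum(sigma^2); the fractions are
    non-increasing and sum to 1 over all returned components.
    """
    x = matrix.data.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        nonzero = sd > 0
        x[:, nonzero] = x[:, nonzero] / sd[nonzero]
    total = float((x ** 2).sum())
    if total == 0.0:
        raise ValueError("PCA undefined: zero total variance")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # Deterministic sign: make each component's largest-magnitude loading positive.
    for i in range(len(s)):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    n_comp = len(s)
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    scores = pd.DataFrame(u * s, index=matrix.data.index, columns=comp_names)
    loadings = pd.DataFrame(vt.T, index=matrix.data.columns, columns=comp_names)
    explained = (s ** 2) / (s ** 2).sum()
    return PcaResult(scores=scores, loadings=loadings,
                     explained_variance_fraction=explained, scaled=scale)
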