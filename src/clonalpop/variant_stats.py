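"""Per-strain SNP summaries, pairwise dissimilarity and PCA of genotypes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_formats import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class StrainSNPSummary:
    """SNP and heterozygosity densities of one strain, as genome fractions."""

    strain_id: str
    total_snp_density: float
    het_snp_density: float
    het_fraction_of_snps: float


def snp_summaries(gm: GenotypeMatrix, genome_length: int) -> list[StrainSNPSummary]:
    """Total and heterozygous SNP density per strain.

    A locus counts toward a strain's total density when its dosage is
    non-missing and non-zero (the strain carries at least one alternate
    allele); it is heterozygous when 0 < dosage < ploidy.
    """
    if genome_length <= 0:
        raise ValidationError("genome_length must be positive")
    pl = gm.ploidy_vector
    nonref = (gm.dosage != MISSING) & (gm.dosage > 0)
    het = nonref & (gm.dosage < pl[None, :])
    out = []
    for j, sid in enumerate(gm.samples):
        total = nonref[:, j].sum() / genome_length
        hets = het[:, j].sum() / genome_length
        out.append(
            StrainSNPSummary(
                sid, float(total), float(hets), float(hets / total) if total else 0.0
            )
        )
    return out


def pairwise_dissimilarity(gm: GenotypeMatrix) -> np.ndarray:
    """Mean absolute difference of ploidy-scaled dosages over co-typed loci.

    ``D[i, j] = mean_l |d_li / p_i - d_lj / p_j|`` over loci typed in both
    strains; symmetric with zero diagonal.  Pairs with no co-typed loci get
    NaN.  Scaling by ploidy puts haploids and diploids on one allele-frequency
    scale.
    """
    x = gm.scaled_dosage()  # NaN where missing
    n = gm.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
            if not both.any():
                out[i, j] = out[j, i] = np.nan
                continue
            d = np.abs(x[both, i] - x[both, j]).mean()
            out[i, j] = out[j, i] = d
    return out


@dataclass
class PCAResult:
    scores: np.ndarray  # strains x components
    variance_explained: np.ndarray  # per retained component, fractions of total


def pca(gm: GenotypeMatrix, n_components: int = 2) -> PCAResult:
    """PCA of the ploidy-scaled, column-centred dosage matrix.

    Missing dosages are mean-imputed per locus; invariant loci are dropped.
    ``variance_explained`` are eigenvalue shares of the *total* variance, so
    they sum to 1 over all components.
    """
    x = gm.scaled_dosage().T  # strains x loci
    col_mean = np.nanmean(x, axis=0)
    nan_mask = np.isnan(x)
    x[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    variant = x.std(axis=0) > 0
    x = x[:, variant]
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("need at least 2 strains and 2 variant loci for PCA")
    max_comp = min(x.shape[0] - 1, x.shape[1])
    if n_components > max_comp:
        raise ValidationError(
            f"n_components {n_components} exceeds min(strains - 1, loci) = {max_comp}"
        )
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    scores = u[:, :n_components] * s[:n_components]
    return PCAResult(scores, var[:n_components] / total if total else var[:n_components])
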