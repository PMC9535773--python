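"""Ploidy classification from assembly statistics.

A strain is called haploid when its assembly is small, its gene count low and
its core-BUSCO mean copy number near 1; diploid when all three are in the
diploid band; tetraploid when assembly size and gene count sit in a band
roughly twice the diploid one.  Any strain whose criteria disagree, or with a
value between bands, is labelled ``"unclear"`` rather than forced into a
class — the same abstention the underlying survey applied to borderline
genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .io_formats import AssemblyStats


@dataclass(frozen=True)
class PloidyThresholds:
    """Band edges for the three classification criteria.

    Haploid: size < 31 Mbp, genes < 13,000, core-BUSCO copy < 1.1.
    Diploid: size > 46 Mbp, genes > 18,000, copy > 1.5.
    Tetraploid bands (size > 80 Mbp, genes > 36,000) are this module's own,
    placed midway between the observed diploid and tetraploid values, because
    the surveyed cohort contained a single tetraploid.
    """

    haploid_max_size: int = 31_000_000
    haploid_max_genes: int = 13_000
    haploid_max_copy: float = 1.1
    diploid_min_size: int = 46_000_000
    diploid_min_genes: int = 18_000
    diploid_min_copy: float = 1.5
    tetraploid_min_size: int = 80_000_000
    tetraploid_min_genes: int = 36_000

    def __post_init__(self) -> None:
        if not (
            self.haploid_max_size < self.diploid_min_size < self.tetraploid_min_size
            and self.haploid_max_genes
            < self.diploid_min_genes
            < self.tetraploid_min_genes
            and self.haploid_max_copy < self.diploid_min_copy
        ):
            raise ValidationError("ploidy bands must be ordered haploid < diploid < tetraploid")


@dataclass(frozen=True)
class PloidyCall:
    strain_id: str
    call: int | str  # 1, 2, 4 or "unclear"
    size_band: str  # "haploid" | "between" | "diploid" | "tetraploid"
    genes_band: str
    copy_band: str


def _band(value: float, hap_max: float, dip_min: float, tet_min: float | None) -> str:
    if value < hap_max:
        return "haploid"
    if tet_min is not None and value > tet_min:
        return "tetraploid"
    if value > dip_min:
        return "diploid"
    return "between"


def classify_ploidy(
    stats: AssemblyStats, thresholds: PloidyThresholds = PloidyThresholds()
) -> PloidyCall:
    """Classify one strain; all criteria must agree, otherwise ``"unclear"``.

    The copy-number criterion has no tetraploid band of its own: any copy
    number above the diploid minimum is compatible with both diploid and
    tetraploid, so the size/gene bands decide between those two.
    """
    t = thresholds
    size_band = _band(
        stats.assembly_size, t.haploid_max_size, t.diploid_min_size, t.tetraploid_min_size
    )
    genes_band = _band(
        stats.n_genes, t.haploid_max_genes, t.diploid_min_genes, t.tetraploid_min_genes
    )
    copy_band = _band(
        stats.busco_core_mean_copy, t.haploid_max_copy, t.diploid_min_copy, None
    )
    call: int | str = "unclear"
    if size_band == genes_band == "tetraploid" and copy_band == "diploid":
        call = 4
    elif size_band == genes_band == copy_band == "diploid":
        call = 2
    elif size_band == genes_band == copy_band == "haploid":
        call = 1
    return PloidyCall(stats.strain_id, call, size_band, genes_band, copy_band)


def classify_many(
    stats: Sequence[AssemblyStats], thresholds: PloidyThresholds = PloidyThresholds()
) -> list[PloidyCall]:
    return [classify_ploidy(s, thresholds) for s in stats]


def core_busco_mean_copy(
    copy_table: pd.DataFrame, strains: Sequence[str] | None = None
) -> dict[str, float]:
    """Mean copy number over core BUSCOs per strain.

    ``copy_table`` is BUSCO ids x strains (integer copy counts, 0 = absent).
    Core BUSCOs are those with copy >= 1 in *every* strain of the set; the
    returned value per strain is the arithmetic mean copy over that core set.
    """
    table = copy_table if strains is None else copy_table[list(strains)]
    if table.empty:
        raise ValidationError("empty BUSCO copy table")
    core = table.index[(table >= 1).all(axis=1)]
    if len(core) == 0:
        raise ValidationError(
            "no core BUSCOs shared by all strains; the strain set is too heterogeneous"
        )
    return table.loc[core].mean(axis=0).to_dict()
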