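"""Readers and writers for the formats the pipeline touches.

Strain metadata and assembly statistics travel as TSV, genotypes as a minimal
VCF v4.2 dialect (CHROM POS ID REF ALT QUAL FILTER INFO FORMAT + GT only),
depth as a BedGraph-like TSV, haplotype alignments as FASTA, and trees as
newick.  All genomic coordinates are 0-based half-open internally; VCF
positions are converted on read/write.

Two strain tables are shipped with the package: the 66 *Hortaea werneckii*
strains and the 48 *Aureobasidium melanogenum* strains whose genomes underpin
the analyses this package reimplements.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import Phylo, SeqIO

from .errors import ParseError, ValidationError

MISSING = -1  # sentinel for missing dosage

# ---------------------------------------------------------------------------
# strain metadata


@dataclass(frozen=True)
class StrainMeta:
    """Identity, habitat, origin and (when known) ploidy of one strain."""

    strain_id: str
    species: str = ""
    habitat: str = ""
    habitat_class: str = ""
    location: str = ""
    continent: str = ""
    ploidy_label: int | str | None = None  # 1, 2, 4, "unclear", or None


_ALLOWED_PLOIDY = {1, 2, 4}


def _parse_ploidy(text: str, row: int) -> int | str | None:
    text = text.strip()
    if not text:
        return None
    if text.lower() in {"unclear", "na", "nan"}:
        return "unclear"
    # "2(?)" marks strains whose ploidy could not be settled
    if text.endswith("(?)"):
        return "unclear"
    try:
        value = int(text)
    except ValueError:
        raise ValidationError(f"row {row}: unparseable ploidy {text!r}") from None
    if value not in _ALLOWED_PLOIDY:
        raise ValidationError(f"row {row}: ploidy {value} not in {{1, 2, 4}}")
    return value


def read_strain_table(path: str | Path, species: str = "") -> list[StrainMeta]:
    """Read a strain metadata TSV into a list of :class:`StrainMeta`.

    The header must contain at least ``strain_id``, ``habitat``, ``location``
    and ``ploidy``.  Row order is preserved; a ploidy written ``2(?)`` is
    parsed as ``"unclear"``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"strain_id", "habitat", "location", "ploidy"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"strain table missing columns: {sorted(missing)}")
    records: list[StrainMeta] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        sid = str(getattr(row, "strain_id")).strip()
        if sid in seen:
            raise ValidationError(f"duplicate strain_id {sid!r}")
        seen.add(sid)
        records.append(
            StrainMeta(
                strain_id=sid,
                species=species,
                habitat=getattr(row, "habitat", ""),
                habitat_class=getattr(row, "habitat_class", ""),
                location=getattr(row, "location", ""),
                continent=getattr(row, "continent", ""),
                ploidy_label=_parse_ploidy(getattr(row, "ploidy"), i),
            )
        )
    return records


def _packaged(name: str) -> Path:
    return Path(str(resources.files("clonalpop").joinpath("data", name)))


def load_hortaea_table() -> list[StrainMeta]:
    """The packaged *H. werneckii* strain table (66 strains)."""
    return read_strain_table(
        _packaged("hortaea_werneckii_strains.tsv"), species="Hortaea werneckii"
    )


def load_aureobasidium_table() -> list[StrainMeta]:
    """The packaged *A. melanogenum* strain table (48 strains)."""
    return read_strain_table(
        _packaged("aureobasidium_melanogenum_strains.tsv"),
        species="Aureobasidium melanogenum",
    )


def write_strain_table(records: Sequence[StrainMeta], path: str | Path) -> None:
    rows = []
    for r in records:
        ploidy = "" if r.ploidy_label is None else str(r.ploidy_label)
        rows.append(
            {
                "strain_id": r.strain_id,
                "habitat": r.habitat,
                "habitat_class": r.habitat_class,
                "location": r.location,
                "continent": r.continent,
                "ploidy": ploidy,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# assembly statistics


@dataclass(frozen=True)
class AssemblyStats:
    """Whole-assembly summary numbers used for ploidy classification."""

    strain_id: str
    assembly_size: int  # bp
    n_genes: int
    busco_core_mean_copy: float
    n_contigs: int | None = None
    n50: int | None = None

    def __post_init__(self) -> None:
        if self.assembly_size <= 0:
            raise ValidationError(f"{self.strain_id}: assembly_size must be > 0")
        if self.n_genes <= 0:
            raise ValidationError(f"{self.strain_id}: n_genes must be > 0")
        if self.busco_core_mean_copy < 0:
            raise ValidationError(f"{self.strain_id}: negative BUSCO copy number")


def read_assembly_stats(path: str | Path) -> list[AssemblyStats]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AssemblyStats(
                strain_id=str(row.strain_id),
                assembly_size=int(row.assembly_size),
                n_genes=int(row.n_genes),
                busco_core_mean_copy=float(row.busco_core_mean_copy),
                n_contigs=int(row.n_contigs) if hasattr(row, "n_contigs") else None,
                n50=int(row.n50) if hasattr(row, "n50") else None,
            )
        )
    return out


def write_assembly_stats(stats: Sequence[AssemblyStats], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "strain_id": s.strain_id,
                "assembly_size": s.assembly_size,
                "n_genes": s.n_genes,
                "busco_core_mean_copy": s.busco_core_mean_copy,
            }
            for s in stats
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype matrix


class GenotypeMatrix:
    """Loci x strains allele-dosage matrix.

    ``dosage[i, j]`` counts alternate-allele copies of strain ``j`` at locus
    ``i`` (``-1`` = missing); valid values run from 0 to the strain's ploidy.
    Positions are stored 0-based and must be strictly increasing within each
    contig.
    """

    def __init__(
        self,
        contigs: Sequence[str],
        positions: Sequence[int],
        ref: Sequence[str],
        alt: Sequence[tuple[str, ...]],
        samples: Sequence[str],
        ploidy: Mapping[str, int],
        dosage: np.ndarray,
    ) -> None:
        self.contigs = np.asarray(contigs, dtype=object)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = list(tuple(a) for a in alt)
        self.samples = list(samples)
        self.ploidy = {s: int(ploidy[s]) for s in self.samples}
        self.dosage = np.asarray(dosage, dtype=np.int16)
        self._validate()

    # -- construction helpers ------------------------------------------------

    def _validate(self) -> None:
        n_loci = len(self.positions)
        if self.dosage.shape != (n_loci, len(self.samples)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} != ({n_loci}, {len(self.samples)})"
            )
        for contig in pd.unique(self.contigs):
            pos = self.positions[self.contigs == contig]
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"positions not strictly increasing on contig {contig}"
                )
        pl = np.array([self.ploidy[s] for s in self.samples], dtype=np.int16)
        bad = (self.dosage != MISSING) & (
            (self.dosage < 0) | (self.dosage > pl[None, :])
        )
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage {self.dosage[i, j]} out of range for sample "
                f"{self.samples[j]} (ploidy {pl[j]}) at locus {i}"
            )

    # -- basic queries -------------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def biallelic(self) -> np.ndarray:
        return np.array([len(a) == 1 for a in self.alt], dtype=bool)

    @property
    def ploidy_vector(self) -> np.ndarray:
        return np.array([self.ploidy[s] for s in self.samples], dtype=np.int16)

    def het_mask(self) -> np.ndarray:
        """Boolean loci x strains mask of heterozygous calls (0 < dosage < ploidy)."""
        pl = self.ploidy_vector[None, :]
        return (self.dosage > 0) & (self.dosage < pl)

    def scaled_dosage(self) -> np.ndarray:
        """Dosage / ploidy as float, NaN where missing."""
        out = self.dosage.astype(float)
        out[self.dosage == MISSING] = np.nan
        return out / self.ploidy_vector[None, :].astype(float)

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.contigs[index],
            self.positions[index],
            self.ref[index],
            [self.alt[i] for i in np.flatnonzero(np.asarray(index))]
            if np.asarray(index).dtype == bool
            else [self.alt[i] for i in index],
            self.samples,
            self.ploidy,
            self.dosage[index],
        )


def read_genotype_vcf(path: str | Path, ploidy: Mapping[str, int]) -> GenotypeMatrix:
    """Read a minimal VCF v4.2 into a :class:`GenotypeMatrix`.

    Only the GT field is consumed.  ``ploidy`` declares each sample's ploidy;
    a GT whose allele count disagrees with it is an error.  Multiallelic
    records are retained but flagged non-biallelic.  VCF 1-based positions
    become 0-based.
    """
    contigs, positions, ref, alt, rows = [], [], [], [], []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for s in samples:
            if s not in ploidy:
                raise ValidationError(f"sample {s} missing from ploidy map")
        for rec in vf:
            alts = tuple(a for a in (rec.alts or ()) if a is not None)
            row = np.empty(len(samples), dtype=np.int16)
            for j, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or all(a is None for a in gt):
                    row[j] = MISSING
                    continue
                if len(gt) != ploidy[s]:
                    raise ValidationError(
                        f"sample {s} at {rec.chrom}:{rec.pos}: GT ploidy "
                        f"{len(gt)} != declared {ploidy[s]}"
                    )
                if any(a is None for a in gt):
                    row[j] = MISSING
                else:
                    row[j] = sum(1 for a in gt if a != 0)
            contigs.append(rec.chrom)
            positions.append(rec.pos - 1)
            ref.append(rec.ref)
            alt.append(alts)
            rows.append(row)
    dosage = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int16)
    )
    return GenotypeMatrix(contigs, positions, ref, alt, samples, ploidy, dosage)


def write_genotype_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the minimal VCF dialect read by :func:`read_genotype_vcf`."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in pd.unique(gm.contigs):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        pl = gm.ploidy_vector
        for i in range(gm.n_loci):
            alt = ",".join(gm.alt[i]) if gm.alt[i] else "."
            fields = [
                str(gm.contigs[i]),
                str(gm.positions[i] + 1),
                ".",
                str(gm.ref[i]),
                alt,
                ".",
                ".",
                ".",
                "GT",
            ]
            for j in range(gm.n_samples):
                d = gm.dosage[i, j]
                if d == MISSING:
                    fields.append("/".join(["."] * pl[j]))
                else:
                    # unphased canonical form: alts last
                    alleles = ["0"] * (pl[j] - d) + ["1"] * d
                    fields.append("/".join(alleles))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# depth tracks


@dataclass
class DepthRaw:
    """Fine-grained depth values tiling each contig (0-based half-open)."""

    contig: np.ndarray  # str per window
    start: np.ndarray
    end: np.ndarray
    depth: np.ndarray  # float, reads

    def __post_init__(self) -> None:
        self.contig = np.asarray(self.contig, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=float)
        if np.any(self.depth < 0):
            raise ValidationError("negative depth value")
        if np.any(self.end <= self.start):
            raise ValidationError("empty or inverted depth window")
        for contig in pd.unique(self.contig):
            sel = self.contig == contig
            s, e = self.start[sel], self.end[sel]
            order = np.argsort(s)
            if np.any(e[order][:-1] > s[order][1:]):
                raise ValidationError(f"overlapping depth windows on {contig}")


def read_depth_tsv(path: str | Path) -> DepthRaw:
    df = pd.read_csv(
        path, sep="\t", names=["contig", "start", "end", "depth"], comment="#"
    )
    return DepthRaw(
        df["contig"].to_numpy(dtype=object),
        df["start"].to_numpy(),
        df["end"].to_numpy(),
        df["depth"].to_numpy(dtype=float),
    )


def write_depth_tsv(raw: DepthRaw, path: str | Path) -> None:
    pd.DataFrame(
        {
            "contig": raw.contig,
            "start": raw.start,
            "end": raw.end,
            "depth": raw.depth,
        }
    ).to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# FASTA alignments


def read_fasta_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into an ordered {label: sequence} mapping."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValidationError(f"{path}: no sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValidationError(f"{path}: unequal sequence lengths {sorted(lengths)}")
    return seqs


def write_fasta_alignment(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for label, seq in seqs.items():
            fh.write(f">{label}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# newick trees


def _check_parentheses(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseError(f"unbalanced ')' at character {offset}")
    if depth != 0:
        raise ParseError(f"{depth} unclosed '(' at end of input (length {len(text)})")
    if ";" not in text:
        raise ParseError(f"missing ';' terminator at character {len(text)}")


def read_newick(text: str):
    """Parse a newick string into a ``Bio.Phylo`` tree, with strict checks."""
    _check_parentheses(text)
    try:
        tree = Phylo.read(io.StringIO(text), "newick")
    except Exception as exc:  # biopython raises several parser errors
        raise ParseError(f"newick parse failed: {exc}") from exc
    return tree


def write_newick(tree) -> str:
    """Serialise a ``Bio.Phylo`` tree to newick (12 significant digits)."""
    buf = io.StringIO()
    Phylo.write(tree, buf, "newick", format_branch_length="%.12g")
    return buf.getvalue().strip()
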