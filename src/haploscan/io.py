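"""Readers and writers for the formats the scan touches.

Conventions fixed here and used everywhere else in the package:

* Internal genomic coordinates are **1-based closed** (VCF-native). BED input
  (0-based half-open) is converted at the boundary and never leaks inward.
* Genotype calls are coded ``0`` (homozygous reference), ``1`` (homozygous
  alternate) and ``MISSING`` (= -1). Inbred strains are expected homozygous,
  so heterozygous or uncalled VCF genotypes become missing rather than a
  third allele.
* Multi-allelic and non-SNP VCF records are skipped (the scan is defined on
  bi-allelic SNPs); the number skipped is logged.

All parse failures raise :class:`FormatError` carrying file, line and reason —
readers reject rather than silently repair malformed input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("haploscan")

#: genotype code for a missing / non-homozygous call
MISSING: int = -1

_VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Malformed input file. Carries file, line (1-based, or None) and reason."""

    def __init__(self, path, reason: str, line: int | None = None):
        self.path = str(path)
        self.line = line
        self.reason = reason
        loc = f"{self.path}:{line}" if line is not None else self.path
        super().__init__(f"{loc}: {reason}")


class InputError(ValueError):
    """Inputs are well-formed but jointly unusable (e.g. no shared strains)."""


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


@dataclass
class GenotypeMatrix:
    """Ordered strains x ordered bi-allelic variants.

    ``calls`` has shape (n_variants, n_strains) with values in {0, 1, MISSING}.
    Variants must be grouped by chromosome with strictly increasing positions
    within each chromosome (chromosome order = order of first appearance).
    """

    strain_names: list[str]
    variants: list[Variant]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(set(self.strain_names)) != len(self.strain_names):
            raise ValueError("duplicate strain names")
        if self.calls.shape != (len(self.variants), len(self.strain_names)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.variants)} variants x {len(self.strain_names)} strains"
            )
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1 or missing (-1)")
        seen: dict[str, int] = {}
        last_chrom = None
        last_pos = 0
        for i, v in enumerate(self.variants):
            if v.chrom != last_chrom:
                if v.chrom in seen:
                    raise ValueError(f"variants not grouped by chromosome: {v.chrom}")
                seen[v.chrom] = i
                last_chrom, last_pos = v.chrom, 0
            if v.pos <= last_pos:
                raise ValueError(
                    f"positions not strictly increasing on {v.chrom} at index {i}"
                )
            last_pos = v.pos

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_strains(self) -> int:
        return len(self.strain_names)

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for v in self.variants:
            if not out or out[-1] != v.chrom:
                out.append(v.chrom)
        return out

    def chromosome_ranges(self) -> list[tuple[str, int, int]]:
        """Half-open variant-index range per chromosome, in matrix order."""
        ranges: list[tuple[str, int, int]] = []
        for i, v in enumerate(self.variants):
            if not ranges or ranges[-1][0] != v.chrom:
                ranges.append((v.chrom, i, i + 1))
            else:
                c, s, _ = ranges[-1]
                ranges[-1] = (c, s, i + 1)
        return ranges

    def subset_variants(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            strain_names=list(self.strain_names),
            variants=[self.variants[i] for i in idx],
            calls=self.calls[idx, :].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.strain_names == other.strain_names
            and self.variants == other.variants
            and np.array_equal(self.calls, other.calls)
        )


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from VCF or genotype TSV.

    VCF coding: homozygous reference -> 0, homozygous alternate -> 1,
    heterozygous or uncalled -> missing. Multi-allelic and non-SNP records
    are skipped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    strains = list(vcf.samples)
    if len(set(strains)) != len(strains):
        raise FormatError(path, "duplicate strain names in VCF header")
    if not strains:
        raise FormatError(path, "VCF has no sample columns")
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        codes = np.full(len(strains), MISSING, dtype=np.int8)
        for j, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # last entry is the phase flag
            if any(a < 0 for a in alleles):
                continue
            if all(a == 0 for a in alleles):
                codes[j] = 0
            elif all(a == 1 for a in alleles):
                codes[j] = 1
            # heterozygous stays missing (inbred-strain assumption)
        variants.append(Variant(rec.CHROM, rec.POS, rec.REF, alts[0]))
        rows.append(codes)
    if n_skipped:
        logger.info("%s: skipped %d multi-allelic/non-SNP records", path, n_skipped)
    calls = (
        np.vstack(rows) if rows else np.empty((0, len(strains)), dtype=np.int8)
    )
    try:
        return GenotypeMatrix(strains, variants, calls)
    except ValueError as exc:
        raise FormatError(path, str(exc)) from exc


_TSV_FIXED_COLS = ["chrom", "pos", "ref", "alt"]


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(path, "empty file", line=1)
        cols = header.split("\t")
        if cols[: len(_TSV_FIXED_COLS)] != _TSV_FIXED_COLS:
            raise FormatError(
                path, f"header must start with {_TSV_FIXED_COLS}", line=1
            )
        strains = cols[len(_TSV_FIXED_COLS) :]
        if len(set(strains)) != len(strains):
            raise FormatError(path, "duplicate strain names", line=1)
        variants: list[Variant] = []
        rows: list[list[int]] = []
        for ln, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) != len(cols):
                raise FormatError(path, f"expected {len(cols)} columns", line=ln)
            chrom, pos_s, ref, alt = fields[:4]
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(path, f"non-integer position {pos_s!r}", line=ln)
            row: list[int] = []
            for tok in fields[4:]:
                if tok == ".":
                    row.append(MISSING)
                elif tok in ("0", "1"):
                    row.append(int(tok))
                else:
                    raise FormatError(path, f"unknown allele code {tok!r}", line=ln)
            variants.append(Variant(chrom, pos, ref, alt))
            rows.append(row)
    calls = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(strains)), dtype=np.int8)
    )
    try:
        return GenotypeMatrix(strains, variants, calls)
    except ValueError as exc:
        raise FormatError(path, str(exc)) from exc


def write_genotypes(matrix: GenotypeMatrix, path, format: str = "vcf") -> Path:
    """Write a genotype matrix as VCF or TSV; output re-reads to an equal matrix."""
    if matrix.n_strains == 0:
        raise FormatError(path, "refusing to write a matrix with 0 strains")
    path = Path(path)
    if format == "vcf":
        _write_vcf(matrix, path)
    elif format == "tsv":
        _write_genotype_tsv(matrix, path)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")
    return path


_GT_STR = {0: "0/0", 1: "1/1", MISSING: "./."}


def _write_vcf(matrix: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haploscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in matrix.chromosomes():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.strain_names)
            + "\n"
        )
        for v, row in zip(matrix.variants, matrix.calls):
            gts = "\t".join(_GT_STR[int(c)] for c in row)
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


_CODE_STR = {0: "0", 1: "1", MISSING: "."}


def _write_genotype_tsv(matrix: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_FIXED_COLS + matrix.strain_names) + "\n")
        for v, row in zip(matrix.variants, matrix.calls):
            codes = "\t".join(_CODE_STR[int(c)] for c in row)
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{codes}\n")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTable:
    """Strain x timepoint x replicate trait measurements.

    Timepoint labels are stored as strings (so file round trips are exact);
    timepoint order is order of first appearance.
    """

    data: pd.DataFrame  # columns: strain, timepoint, replicate, value

    REQUIRED = ("strain", "timepoint", "replicate", "value")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["strain"] = df["strain"].astype(str)
        df["timepoint"] = df["timepoint"].astype(str)
        df["replicate"] = df["replicate"].astype(int)
        df["value"] = df["value"].astype(float)
        if df.duplicated(["strain", "timepoint", "replicate"]).any():
            dup = df[df.duplicated(["strain", "timepoint", "replicate"])].iloc[0]
            raise ValueError(
                "duplicate (strain, timepoint, replicate): "
                f"({dup.strain}, {dup.timepoint}, {dup.replicate})"
            )
        self.data = df.reset_index(drop=True)

    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.data["strain"]))

    def timepoints(self) -> list[str]:
        return list(dict.fromkeys(self.data["timepoint"]))

    def strain_means(self, timepoint) -> dict[str, float]:
        """Per-strain mean over replicates at one timepoint."""
        tp = str(timepoint)
        sub = self.data[self.data["timepoint"] == tp]
        return sub.groupby("strain", sort=False)["value"].mean().to_dict()

    def replicate_values(self, timepoint) -> pd.DataFrame:
        tp = str(timepoint)
        return self.data[self.data["timepoint"] == tp].reset_index(drop=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        a = self.data.sort_values(["strain", "timepoint", "replicate"]).reset_index(
            drop=True
        )
        b = other.data.sort_values(["strain", "timepoint", "replicate"]).reset_index(
            drop=True
        )
        if not a[["strain", "timepoint", "replicate"]].equals(
            b[["strain", "timepoint", "replicate"]]
        ):
            return False
        return bool(np.allclose(a["value"], b["value"], rtol=0, atol=0, equal_nan=True))


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype CSV/TSV with columns strain, timepoint, replicate, value."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(path, f"unparseable table: {exc}") from exc
    missing = [c for c in PhenotypeTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(path, f"missing required column(s): {', '.join(missing)}")
    for col, conv in (("replicate", int), ("value", float)):
        for i, tok in enumerate(df[col]):
            try:
                conv(tok)
            except (TypeError, ValueError):
                raise FormatError(
                    path, f"non-numeric {col} value {tok!r}", line=i + 2
                )
    df["replicate"] = df["replicate"].astype(int)
    df["value"] = df["value"].astype(float)
    try:
        return PhenotypeTable(df)
    except ValueError as exc:
        raise FormatError(path, str(exc)) from exc


def write_phenotypes(table: PhenotypeTable, path) -> Path:
    path = Path(path)
    table.data.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# gene models (BED6) and categories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene with 1-based closed coordinates and a strand-aware TSS."""

    name: str
    chrom: str
    start: int  # 1-based closed
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"start > end for gene {self.name}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


def read_genes_bed(path) -> list[GeneModel]:
    """Read BED6 gene models, converting 0-based half-open to 1-based closed."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genes: list[GeneModel] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            fields = raw.split("\t")
            if len(fields) < 6:
                raise FormatError(path, "BED6 requires at least 6 columns", line=ln)
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                bed_start, bed_end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(path, "non-integer BED coordinates", line=ln)
            if bed_start >= bed_end:
                raise FormatError(path, "BED start >= end", line=ln)
            if strand not in ("+", "-"):
                raise FormatError(path, f"bad strand {strand!r}", line=ln)
            genes.append(GeneModel(name, chrom, bed_start + 1, bed_end, strand))
    return genes


def write_genes_bed(genes: Iterable[GeneModel], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.name}\t0\t{g.strand}\n")
    return path


@dataclass
class CategoryTable:
    """gene -> set of functional category labels (e.g. transcription factor)."""

    categories: dict[str, set[str]] = field(default_factory=dict)

    def get(self, gene: str) -> set[str]:
        return self.categories.get(gene, set())

    def __len__(self) -> int:
        return len(self.categories)


def read_categories(path) -> CategoryTable:
    """Read a two-column gene/category TSV; repeated gene lines aggregate to sets."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cats: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            fields = raw.split("\t")
            if len(fields) < 2:
                raise FormatError(path, "expected 2 tab-separated columns", line=ln)
            gene, cat = fields[0].strip(), fields[1].strip()
            if not gene:
                raise FormatError(path, "blank gene field", line=ln)
            cats.setdefault(gene, set()).add(cat)
    return CategoryTable(cats)


def write_categories(table: CategoryTable, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for gene in sorted(table.categories):
            for cat in sorted(table.categories[gene]):
                fh.write(f"{gene}\t{cat}\n")
    return path
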