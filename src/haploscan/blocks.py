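"""Haplotype-block construction over an inbred-strain SNP panel.

Inbred strains are homozygous genome-wide, so each strain carries a single
haplotype per locus and consecutive SNPs show only a handful of distinct
allele strings across the panel. The partition here is a deterministic greedy
left-to-right sweep per chromosome: the current block is extended with the
next SNP as long as (a) the number of distinct complete strain allele-strings
stays at most ``H_max`` and (b) the block stays shorter than ``max_snps``.
The distinct-string count is taken over strains with no missing call inside
the candidate block. This yields a non-overlapping partition of the retained
SNPs — simpler than enumerating overlapping candidate windows, and sufficient
for the downstream per-block ANOVA.

Strains with missing calls inside a block are resolved by unique-match
imputation: a strain gets a group label only if exactly one observed
haplotype is consistent with all of its non-missing positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger("haploscan")


@dataclass(frozen=True)
class BlockParams:
    """Controls for SNP filtering and block construction.

    H_max
        Maximum number of distinct haplotypes a block may contain (>= 2).
    min_snps / max_snps
        Block-size bounds in SNPs. Blocks shorter than ``min_snps`` are still
        emitted but flagged; ``max_snps`` caps block growth so low-diversity
        panels cannot produce chromosome-length blocks.
    max_missing_frac
        Per-SNP missingness threshold applied by :func:`filter_snps`.
    """

    H_max: int = 4
    min_snps: int = 1
    max_snps: int = 30
    max_missing_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.H_max < 2:
            raise ValueError("H_max must be >= 2")
        if not (1 <= self.min_snps <= self.max_snps):
            raise ValueError("need 1 <= min_snps <= max_snps")
        if not (0.0 <= self.max_missing_frac <= 1.0):
            raise ValueError("max_missing_frac must be in [0, 1]")


@dataclass
class HaplotypeBlock:
    """A run of consecutive retained SNPs with a per-strain group labeling.

    ``start``/``stop`` is a half-open variant-index range into the (filtered)
    genotype matrix; ``span_start``/``span_end`` are the 1-based positions of
    the first and last SNP. ``labels[i]`` is strain i's haplotype group in
    0..G-1 (canonical: the first strain carrying a haplotype defines the
    lowest unused label) or -1 if the strain could not be placed.
    """

    block_id: str
    chrom: str
    start: int
    stop: int
    span_start: int
    span_end: int
    labels: np.ndarray
    n_groups: int
    group_sizes: list[int] = field(default_factory=list)
    short: bool = False

    @property
    def n_snps(self) -> int:
        return self.stop - self.start


def filter_snps(matrix: GenotypeMatrix, params: BlockParams) -> GenotypeMatrix:
    """Drop monomorphic SNPs and SNPs with too many missing calls.

    Retains SNPs where both alleles are observed among non-missing calls and
    the missing fraction is <= ``params.max_missing_frac``. Order preserved;
    idempotent.
    """
    calls = matrix.calls
    if calls.shape[0] == 0:
        return matrix.subset_variants([])
    obs = calls != MISSING
    n_obs = obs.sum(axis=1)
    with np.errstate(invalid="ignore"):
        has_ref = ((calls == 0) & obs).any(axis=1)
        has_alt = ((calls == 1) & obs).any(axis=1)
    polymorphic = has_ref & has_alt
    miss_frac = 1.0 - n_obs / matrix.n_strains
    low_missing = miss_frac <= params.max_missing_frac
    keep = polymorphic & low_missing
    n_mono = int((~polymorphic).sum())
    n_miss = int((polymorphic & ~low_missing).sum())
    if n_mono or n_miss:
        logger.info(
            "filter_snps: removed %d monomorphic and %d high-missingness SNPs "
            "(%d retained)",
            n_mono,
            n_miss,
            int(keep.sum()),
        )
    if not keep.any():
        logger.warning("filter_snps: no SNPs retained")
    return matrix.subset_variants(np.flatnonzero(keep))


def _check_filtered(matrix: GenotypeMatrix, params: BlockParams) -> None:
    calls = matrix.calls
    if calls.shape[0] == 0:
        return
    obs = calls != MISSING
    poly = ((calls == 0) & obs).any(axis=1) & ((calls == 1) & obs).any(axis=1)
    if not poly.all():
        i = int(np.flatnonzero(~poly)[0])
        raise ValueError(
            f"matrix not filtered: monomorphic SNP at variant index {i} "
            "(run filter_snps first)"
        )
    miss_frac = 1.0 - obs.sum(axis=1) / matrix.n_strains
    if (miss_frac > params.max_missing_frac).any():
        i = int(np.flatnonzero(miss_frac > params.max_missing_frac)[0])
        raise ValueError(
            f"matrix not filtered: SNP at variant index {i} exceeds "
            f"max_missing_frac={params.max_missing_frac} (run filter_snps first)"
        )


def assign_groups(matrix: GenotypeMatrix, start: int, stop: int) -> np.ndarray:
    """Per-strain haplotype-group labels for variant range [start, stop).

    Strains with complete calls get the label of their exact allele string
    (canonical first-occurrence order). A strain with missing calls gets a
    label only if exactly one observed haplotype matches all of its
    non-missing positions; otherwise -1.
    """
    if not (0 <= start < stop <= matrix.n_variants):
        raise ValueError(f"invalid variant range [{start}, {stop})")
    sub = matrix.calls[start:stop, :]  # (L, n_strains)
    n = matrix.n_strains
    labels = np.full(n, -1, dtype=np.int64)
    haplotypes: dict[tuple, int] = {}
    for j in range(n):
        col = sub[:, j]
        if (col == MISSING).any():
            continue
        key = tuple(int(a) for a in col)
        if key not in haplotypes:
            haplotypes[key] = len(haplotypes)
        labels[j] = haplotypes[key]
    hap_arr = np.array(sorted(haplotypes, key=haplotypes.get), dtype=np.int8)
    for j in range(n):
        col = sub[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        if hap_arr.size == 0:
            continue
        known = ~miss
        if known.any():
            matches = np.flatnonzero(
                (hap_arr[:, known] == col[known]).all(axis=1)
            )
        else:
            matches = np.arange(hap_arr.shape[0])
        if matches.size == 1:
            labels[j] = int(matches[0])
    return labels


def build_blocks(matrix: GenotypeMatrix, params: BlockParams) -> list[HaplotypeBlock]:
    """Partition each chromosome's retained SNPs into haplotype blocks.

    Greedy left-to-right: extend the current block while the distinct
    complete-strain allele-string count stays <= ``H_max`` and length <
    ``max_snps``; otherwise close it and start a new one. Every retained SNP
    ends up in exactly one block. Requires a filtered matrix (re-checked).
    """
    _check_filtered(matrix, params)
    calls = matrix.calls
    n = matrix.n_strains
    blocks: list[HaplotypeBlock] = []
    # running haplotype codes are base-2 integers over the block's alleles;
    # object dtype (exact Python ints) once blocks can outgrow int64
    code_dtype = np.int64 if params.max_snps <= 62 else object
    for chrom, lo, hi in matrix.chromosome_ranges():
        start = lo
        # codes valid only for strains with no missing call so far
        codes = np.zeros(n, dtype=code_dtype)
        complete = np.ones(n, dtype=bool)
        length = 0
        for i in range(lo, hi):
            row = calls[i, :]
            new_complete = complete & (row != MISSING)
            new_codes = codes * 2 + np.where(row == MISSING, 0, row)
            n_distinct = len(set(new_codes[new_complete].tolist()))
            if length > 0 and (n_distinct > params.H_max or length >= params.max_snps):
                blocks.append(_close_block(matrix, chrom, start, i, len(blocks)))
                start = i
                complete = row != MISSING
                codes = np.where(row == MISSING, 0, row).astype(code_dtype)
                length = 1
            else:
                codes, complete = new_codes, new_complete
                length += 1
        if length > 0:
            blocks.append(_close_block(matrix, chrom, start, hi, len(blocks)))
    for b in blocks:
        b.short = b.n_snps < params.min_snps
    n_short = sum(b.short for b in blocks)
    if n_short:
        logger.info("build_blocks: %d blocks shorter than min_snps", n_short)
    return blocks


def _close_block(
    matrix: GenotypeMatrix, chrom: str, start: int, stop: int, index: int
) -> HaplotypeBlock:
    labels = assign_groups(matrix, start, stop)
    placed = labels[labels >= 0]
    n_groups = int(placed.max()) + 1 if placed.size else 0
    sizes = np.bincount(placed, minlength=n_groups).tolist() if placed.size else []
    return HaplotypeBlock(
        block_id=f"b{index:05d}",
        chrom=chrom,
        start=start,
        stop=stop,
        span_start=matrix.variants[start].pos,
        span_end=matrix.variants[stop - 1].pos,
        labels=labels,
        n_groups=n_groups,
        group_sizes=sizes,
    )


def blocks_to_bed(blocks: list[HaplotypeBlock], path) -> None:
    """Export blocks as BED (span, id, group count in the score column)."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                f"{b.chrom}\t{b.span_start - 1}\t{b.span_end}\t{b.block_id}\t"
                f"{b.n_groups}\t+\n"
            )
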