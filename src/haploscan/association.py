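"""Per-block association statistics for the haplotype scan.

The scan correlates the haplotype grouping of strains at each block with the
distribution of trait values across strains by a one-way ANOVA: with G
occupied groups and N strains tested,

    SSB = sum_g n_g (ybar_g - ybar)^2        (between groups)
    SSW = sum_g sum_i (y_gi - ybar_g)^2      (within groups)
    F   = (SSB / (G-1)) / (SSW / (N-G)),     P = upper tail of F(G-1, N-G)

and the genetic effect size is the fraction of trait variance explained by
group membership, eta^2 = SSB / (SSB + SSW). Blocks are ranked by P
(ascending), ties broken by larger effect size then genomic order.

The trait unit for the scan is the per-strain replicate mean, so the ANOVA
factor is the haplotype group across strains. A replicate-level strain-effect
ANOVA (strain as factor) and a Spearman correlation matrix across timepoints
are provided as auxiliary statistics, plus an optional Benjamini-Hochberg
adjustment of the nominal P values.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import HaplotypeBlock
from .candidates import CandidateGene
from .io import InputError, PhenotypeTable

logger = logging.getLogger("haploscan")

#: smallest positive subnormal double; P values that underflow are reported
#: as this floor with ``p_is_floor`` set (the true value is only bounded above)
P_FLOOR = float(np.nextafter(0.0, 1.0))


@dataclass
class AssociationResult:
    """One block's test at one timepoint. ``testable`` False => see ``reason``."""

    block_id: str
    chrom: str
    span_start: int
    span_end: int
    timepoint: str | None
    n_groups: int
    group_sizes: list[int]
    F: float
    df1: int
    df2: int
    p: float
    effect_size: float
    testable: bool = True
    reason: str | None = None
    p_is_floor: bool = False
    rank: int | None = None
    significant: bool = False


@dataclass
class ScanResult:
    """All blocks' results at one timepoint, ranked, with untestable counts."""

    timepoint: str
    results: list[AssociationResult]
    alpha: float
    untestable_reasons: Counter = field(default_factory=Counter)

    @property
    def n_testable(self) -> int:
        return sum(r.testable for r in self.results)

    def significant(self) -> list[AssociationResult]:
        return [r for r in self.results if r.significant]


def _anova_core(values: np.ndarray, labels: np.ndarray):
    """Sums-of-squares decomposition on clean inputs (labels 0..G-1 dense)."""
    n = values.size
    counts = np.bincount(labels)
    sums = np.bincount(labels, weights=values)
    occupied = counts > 0
    counts, sums = counts[occupied], sums[occupied]
    g = counts.size
    grand = values.mean()
    group_means = sums / counts
    ssb = float(np.sum(counts * (group_means - grand) ** 2))
    sst = float(np.sum((values - grand) ** 2))
    ssw = max(sst - ssb, 0.0)
    return g, n, counts, ssb, ssw


def anova_block(
    values: Sequence[float], labels: Sequence[int]
) -> AssociationResult:
    """One-way ANOVA of per-strain trait values grouped by haplotype label.

    Missing labels (< 0) and missing/NaN values are dropped first. If fewer
    than 2 occupied groups remain, or the residual df is < 1, the block is
    untestable and returned with a reason code instead of raising.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    mask = (labels >= 0) & np.isfinite(values)
    values, labels = values[mask], labels[mask]

    def _untestable(reason: str) -> AssociationResult:
        return AssociationResult(
            block_id="",
            chrom="",
            span_start=0,
            span_end=0,
            timepoint=None,
            n_groups=int(np.unique(labels).size),
            group_sizes=[],
            F=math.nan,
            df1=0,
            df2=0,
            p=math.nan,
            effect_size=math.nan,
            testable=False,
            reason=reason,
        )

    if values.size == 0:
        return _untestable("no_data")
    # re-densify labels after dropping strains
    _, dense = np.unique(labels, return_inverse=True)
    g, n, counts, ssb, ssw = _anova_core(values, dense)
    if g < 2:
        return _untestable("fewer_than_2_groups")
    df1, df2 = g - 1, n - g
    if df2 < 1:
        return _untestable("df2=0")
    sst = ssb + ssw
    p_is_floor = False
    if sst == 0.0:
        f_stat, p, effect = 0.0, 1.0, 0.0
    elif ssw == 0.0:
        f_stat, p, effect = math.inf, 0.0, 1.0
        p_is_floor = True  # exact P is 0 only in the noise-free limit
    else:
        f_stat = (ssb / df1) / (ssw / df2)
        p = float(stats.f.sf(f_stat, df1, df2))
        effect = ssb / sst
        if p == 0.0:
            p = P_FLOOR
            p_is_floor = True
    return AssociationResult(
        block_id="",
        chrom="",
        span_start=0,
        span_end=0,
        timepoint=None,
        n_groups=g,
        group_sizes=counts.tolist(),
        F=f_stat,
        df1=df1,
        df2=df2,
        p=p,
        effect_size=effect,
        p_is_floor=p_is_floor,
    )


def rank_results(results: Iterable[AssociationResult]) -> list[AssociationResult]:
    """Order by ascending P; ties broken by larger effect size, then genomic
    position (chromosome, span start). Untestable blocks go last, unranked."""
    results = list(results)
    if not results:
        raise ValueError("rank_results requires at least one result")
    testable = [r for r in results if r.testable]
    untestable = [r for r in results if not r.testable]
    testable.sort(key=lambda r: (r.p, -r.effect_size, r.chrom, r.span_start))
    for i, r in enumerate(testable, start=1):
        r.rank = i
    untestable.sort(key=lambda r: (r.chrom, r.span_start))
    for r in untestable:
        r.rank = None
    return testable + untestable


def scan_timepoint(
    blocks: Sequence[HaplotypeBlock],
    strain_names: Sequence[str],
    phenotypes: PhenotypeTable,
    timepoint,
    alpha: float = 0.001,
) -> ScanResult:
    """Test every block against the per-strain mean trait at one timepoint.

    ``strain_names`` gives the genotype-matrix strain order that the blocks'
    label vectors are indexed by. Strains missing from either side are
    dropped (logged); fewer than 3 shared strains is an error.
    """
    tp = str(timepoint)
    if tp not in phenotypes.timepoints():
        raise InputError(f"timepoint {tp!r} not present in phenotype table")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    means = phenotypes.strain_means(tp)
    shared = [s for s in strain_names if s in means]
    if not shared:
        raise InputError("no overlapping strains between genotypes and phenotypes")
    if len(shared) < 3:
        raise InputError(f"only {len(shared)} shared strains; need >= 3")
    dropped = set(strain_names) - set(shared)
    if dropped:
        logger.info("scan %s: %d strains lack phenotype data", tp, len(dropped))
    values = np.array(
        [means.get(s, math.nan) for s in strain_names], dtype=float
    )
    results: list[AssociationResult] = []
    reasons: Counter = Counter()
    for b in blocks:
        r = anova_block(values, b.labels)
        r.block_id = b.block_id
        r.chrom = b.chrom
        r.span_start = b.span_start
        r.span_end = b.span_end
        r.timepoint = tp
        if not r.testable:
            reasons[r.reason] += 1
        else:
            r.significant = r.p < alpha
        results.append(r)
    ranked = rank_results(results)
    return ScanResult(timepoint=tp, results=ranked, alpha=alpha,
                      untestable_reasons=reasons)


def recurrent_candidates(
    scans: Sequence[ScanResult],
    gene_map: Mapping[str, Sequence[str]],
    alpha: float = 0.001,
    min_timepoints: int = 3,
) -> list[CandidateGene]:
    """Genes whose mapped blocks are significant at >= ``min_timepoints``
    timepoints.

    A gene is significant at a timepoint if any of its mapped blocks has
    P < alpha there; its recurrence count is the number of such timepoints.
    Each returned gene carries the per-timepoint best P over its blocks and
    the blocks supporting each significant timepoint. Defaults mirror a
    P < 0.001 candidate filter recurring at 3 of the timepoints scanned.
    """
    if not scans:
        raise ValueError("need at least one scan")
    if min_timepoints > len(scans):
        raise ValueError(
            f"min_timepoints={min_timepoints} exceeds number of scans ({len(scans)})"
        )
    scanned_ids = {r.block_id for sc in scans for r in sc.results}
    unmapped = scanned_ids - set(gene_map)
    if unmapped:
        raise ValueError(
            f"gene_map does not cover {len(unmapped)} scanned blocks "
            f"(e.g. {sorted(unmapped)[0]})"
        )
    best_p: dict[str, dict[str, float]] = {}
    support: dict[str, dict[str, list[str]]] = {}
    for sc in scans:
        for r in sc.results:
            if not r.testable:
                continue
            for gene in gene_map[r.block_id]:
                tp_best = best_p.setdefault(gene, {})
                if r.p < tp_best.get(sc.timepoint, math.inf):
                    tp_best[sc.timepoint] = r.p
                if r.p < alpha:
                    support.setdefault(gene, {}).setdefault(
                        sc.timepoint, []
                    ).append(r.block_id)
    out: list[CandidateGene] = []
    for gene, tp_best in best_p.items():
        sig_tps = support.get(gene, {})
        if len(sig_tps) >= min_timepoints:
            out.append(
                CandidateGene(
                    gene=gene,
                    categories=set(),
                    best_p=dict(tp_best),
                    recurrence=len(sig_tps),
                    supporting_blocks={
                        tp: sorted(set(ids)) for tp, ids in sig_tps.items()
                    },
                )
            )
    out.sort(key=lambda c: (-c.recurrence, min(c.best_p.values()), c.gene))
    return out


def strain_effect_anova(phenotypes: PhenotypeTable, timepoint) -> AssociationResult:
    """One-way ANOVA of replicate-level trait values with strain as factor.

    Tests whether inter-strain differences exceed intra-strain (replicate)
    variability at one timepoint. Untestable when every strain has a single
    replicate (no within-strain variance, df2 = 0).
    """
    sub = phenotypes.replicate_values(timepoint)
    if sub.empty:
        raise InputError(f"timepoint {timepoint!r} not present in phenotype table")
    strains = sub["strain"].to_numpy()
    _, labels = np.unique(strains, return_inverse=True)
    return anova_block(sub["value"].to_numpy(), labels)


def timepoint_spearman(phenotypes: PhenotypeTable) -> pd.DataFrame:
    """Spearman rank correlation of per-strain means between every timepoint
    pair (average ranks for ties). Pairs with < 3 shared strains are NaN."""
    tps = phenotypes.timepoints()
    wide = (
        phenotypes.data.groupby(["strain", "timepoint"], sort=False)["value"]
        .mean()
        .unstack("timepoint")
        .reindex(columns=tps)
    )
    mat = pd.DataFrame(np.eye(len(tps)), index=tps, columns=tps)
    for i, a in enumerate(tps):
        for b in tps[i + 1 :]:
            pair = wide[[a, b]].dropna()
            if len(pair) < 3:
                rho = math.nan
            else:
                rho = float(stats.spearmanr(pair[a], pair[b]).statistic)
            mat.loc[a, b] = mat.loc[b, a] = rho
    return mat


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (monotone, clipped to [0,1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("P values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

_SCAN_COLUMNS = [
    "block_id", "chrom", "span_start", "span_end", "timepoint", "n_groups",
    "F", "df1", "df2", "p", "effect_size", "rank", "significant", "testable",
    "reason",
]


def scan_to_frame(scan: ScanResult) -> pd.DataFrame:
    rows = [
        {c: getattr(r, c) for c in _SCAN_COLUMNS} for r in scan.results
    ]
    return pd.DataFrame(rows, columns=_SCAN_COLUMNS)


def write_scan_tsv(scan: ScanResult, path) -> None:
    scan_to_frame(scan).to_csv(path, sep="\t", index=False)


def write_scan_bed(scan: ScanResult, path) -> None:
    """Blocks as a BED track with -log10(P) in the score column."""
    with open(path, "w") as fh:
        for r in scan.results:
            if not r.testable:
                continue
            score = -math.log10(r.p) if r.p > 0 else 999.0
            fh.write(
                f"{r.chrom}\t{r.span_start - 1}\t{r.span_end}\t{r.block_id}\t"
                f"{score:.3f}\t+\n"
            )
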