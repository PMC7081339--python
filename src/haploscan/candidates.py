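"""Block-to-gene mapping, functional categorisation and the candidate report.

A block is tied to a gene when its genomic span (1-based closed) intersects
the gene body or the strand-aware promoter window immediately 5' of the
transcription start site (default 15 kb: [TSS - 15000, TSS - 1] on the +
strand, mirrored on the - strand). A nearest-TSS mode is provided as an
alternative. Closed-interval intersection throughout, consistent with the
package's internal coordinate convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .blocks import HaplotypeBlock
from .io import CategoryTable, GeneModel


@dataclass
class CandidateGene:
    """A gene supported by significant blocks at one or more timepoints."""

    gene: str
    categories: set[str] = field(default_factory=set)
    best_p: dict[str, float] = field(default_factory=dict)  # timepoint -> best P
    recurrence: int = 0
    supporting_blocks: dict[str, list[str]] = field(default_factory=dict)

    def all_supporting_blocks(self) -> list[str]:
        return sorted({b for ids in self.supporting_blocks.values() for b in ids})


def promoter_window(gene: GeneModel, promoter_kb: float = 15.0) -> tuple[int, int]:
    """Strand-aware promoter interval (1-based closed), clipped at position 1."""
    if promoter_kb < 0:
        raise ValueError("promoter_kb must be non-negative")
    w = int(round(promoter_kb * 1000))
    if w == 0:
        return (0, -1)  # empty interval
    if gene.strand == "+":
        return (max(1, gene.tss - w), gene.tss - 1)
    return (gene.tss + 1, gene.tss + w)


def _intersects(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def map_block_to_genes(
    block: HaplotypeBlock,
    genes: Sequence[GeneModel],
    promoter_kb: float = 15.0,
) -> list[GeneModel]:
    """Genes whose body or promoter window intersects the block span.

    Returns genes in input order; empty list means the block is intergenic
    for this purpose. Multiple genes may be returned.
    """
    if promoter_kb < 0:
        raise ValueError("promoter_kb must be non-negative")
    hits: list[GeneModel] = []
    for g in genes:
        if g.chrom != block.chrom:
            continue
        if _intersects(block.span_start, block.span_end, g.start, g.end):
            hits.append(g)
            continue
        ps, pe = promoter_window(g, promoter_kb)
        if ps <= pe and _intersects(block.span_start, block.span_end, ps, pe):
            hits.append(g)
    return hits


def nearest_tss_gene(
    block: HaplotypeBlock, genes: Sequence[GeneModel]
) -> GeneModel | None:
    """The same-chromosome gene whose TSS is closest to the block span
    (distance 0 if the TSS falls inside the span); ties by gene name."""
    best: tuple[int, str] | None = None
    best_gene: GeneModel | None = None
    for g in genes:
        if g.chrom != block.chrom:
            continue
        if block.span_start <= g.tss <= block.span_end:
            d = 0
        else:
            d = min(abs(g.tss - block.span_start), abs(g.tss - block.span_end))
        key = (d, g.name)
        if best is None or key < best:
            best, best_gene = key, g
    return best_gene


def build_gene_map(
    blocks: Sequence[HaplotypeBlock],
    genes: Sequence[GeneModel],
    promoter_kb: float = 15.0,
) -> dict[str, list[str]]:
    """block id -> mapped gene names, for every block (possibly empty lists)."""
    return {
        b.block_id: [g.name for g in map_block_to_genes(b, genes, promoter_kb)]
        for b in blocks
    }


@dataclass
class CategorySummary:
    groups: dict[str, list[str]]  # category -> sorted gene names ("other" incl.)
    counts: dict[str, int]
    multi_category: set[str]  # genes carrying more than one category


def categorize_candidates(
    candidates: Sequence[CandidateGene], categories: CategoryTable
) -> CategorySummary:
    """Group candidate genes by functional category.

    A gene appears in every category it carries (and is flagged
    multi-category if that is more than one); genes without a category go to
    the "other" group.
    """
    groups: dict[str, set[str]] = {}
    multi: set[str] = set()
    for c in candidates:
        cats = categories.get(c.gene)
        c.categories = set(cats)
        if not cats:
            groups.setdefault("other", set()).add(c.gene)
            continue
        if len(cats) > 1:
            multi.add(c.gene)
        for cat in cats:
            groups.setdefault(cat, set()).add(c.gene)
    groups.setdefault("other", set())
    sorted_groups = {k: sorted(v) for k, v in sorted(groups.items())}
    return CategorySummary(
        groups=sorted_groups,
        counts={k: len(v) for k, v in sorted_groups.items()},
        multi_category=multi,
    )


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = ["gene", "categories", "recurrence"]


def _ordered(candidates: Sequence[CandidateGene]) -> list[CandidateGene]:
    return sorted(
        candidates,
        key=lambda c: (
            -c.recurrence,
            min(c.best_p.values()) if c.best_p else math.inf,
            c.gene,
        ),
    )


def make_report(
    candidates: Sequence[CandidateGene],
    timepoints: Sequence[str],
    path,
    format: str = "tsv",
) -> Path:
    """Write the candidate report: one row per gene with categories,
    recurrence count, per-timepoint best P and supporting blocks.

    Row order is deterministic: recurrence descending, best P ascending,
    then gene name. ``timepoints`` fixes the column order.
    """
    path = Path(path)
    tps = [str(t) for t in timepoints]
    rows = []
    for c in _ordered(candidates):
        row: dict = {
            "gene": c.gene,
            "categories": ";".join(sorted(c.categories)),
            "recurrence": c.recurrence,
        }
        for tp in tps:
            p = c.best_p.get(tp)
            row[f"best_p_{tp}"] = "" if p is None else repr(p)
        row["supporting_blocks"] = ";".join(c.all_supporting_blocks())
        rows.append(row)
    columns = _REPORT_COLUMNS + [f"best_p_{tp}" for tp in tps] + ["supporting_blocks"]
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(columns) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in columns) + "\n")
    elif format == "json":
        payload = {
            "timepoints": tps,
            "candidates": [
                {
                    "gene": c.gene,
                    "categories": sorted(c.categories),
                    "recurrence": c.recurrence,
                    "best_p": {tp: c.best_p[tp] for tp in tps if tp in c.best_p},
                    "supporting_blocks": {
                        tp: c.supporting_blocks[tp]
                        for tp in tps
                        if tp in c.supporting_blocks
                    },
                }
                for c in _ordered(candidates)
            ],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown report format: {format!r}")
    return path


def read_report(path, format: str = "tsv") -> list[CandidateGene]:
    """Re-parse a report written by :func:`make_report` (best P and
    supporting blocks per significant timepoint are recovered for JSON;
    TSV recovers gene, categories, recurrence, best P and the pooled
    supporting-block list)."""
    path = Path(path)
    if format == "json":
        payload = json.loads(path.read_text())
        return [
            CandidateGene(
                gene=c["gene"],
                categories=set(c["categories"]),
                best_p=dict(c["best_p"]),
                recurrence=c["recurrence"],
                supporting_blocks={k: list(v) for k, v in c["supporting_blocks"].items()},
            )
            for c in payload["candidates"]
        ]
    if format != "tsv":
        raise ValueError(f"unknown report format: {format!r}")
    out: list[CandidateGene] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        tp_cols = [c for c in header if c.startswith("best_p_")]
        for raw in fh:
            fields = dict(zip(header, raw.rstrip("\n").split("\t")))
            best_p = {
                c[len("best_p_"):]: float(fields[c]) for c in tp_cols if fields[c]
            }
            blocks = [b for b in fields["supporting_blocks"].split(";") if b]
            out.append(
                CandidateGene(
                    gene=fields["gene"],
                    categories={c for c in fields["categories"].split(";") if c},
                    best_p=best_p,
                    recurrence=int(fields["recurrence"]),
                    supporting_blocks={"all": blocks} if blocks else {},
                )
            )
    return out
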