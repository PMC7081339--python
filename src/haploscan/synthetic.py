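"""Synthetic inbred-strain panels with known causal structure.

The generator emulates the data the scan consumes: a small panel of inbred
strains (default 16) genotyped at bi-allelic SNPs whose local variation is
blocky — each true block carries a handful of ancestral binary haplotypes
(haplotype-mosaic model with geometric block lengths), of which every strain
carries exactly one — plus a quantitative trait measured with replicates at
six timepoints (default 0, 4, 16, 24, 48, 72 h). A designated causal block
contributes a strain-level genetic effect at chosen timepoints with a
controllable fraction of variance explained; genotyping noise enters as
per-call allele flips and missing calls.

Trait model per timepoint, per strain i:

    y_i = baseline + beta * c_i + e_i,   e_i ~ N(0, strain_noise_sd^2)

where c_i is the mean-centered integer code of strain i's haplotype group at
the causal block (zero at inactive timepoints), and each replicate adds
independent N(0, noise_sd^2) measurement noise. beta is derived from the
requested variance-explained fraction h2 by matching the expected
between-group to total sum of squares of the strain values,

    beta^2 * sum_i c_i^2 = sigma^2 * (h2 * (N - 1) - (G - 1)) / (1 - h2),

so the expected eta^2 at the causal grouping equals h2 (G = occupied groups,
N = strains, sigma = strain_noise_sd). All randomness flows from one master
seed via documented stream splitting, so genotype and phenotype stages are
reproducible in isolation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    GenotypeMatrix,
    PhenotypeTable,
    Variant,
    write_genotypes,
    write_phenotypes,
)

logger = logging.getLogger("haploscan")

_BASES = np.array(list("ACGT"))

# sub-stream indices off the master seed
_STREAM_GENOTYPE = 0
_STREAM_PHENOTYPE = 1
_STREAM_CAUSAL_PICK = 2


class SimulationError(RuntimeError):
    """The requested causal effect cannot be realised on this panel."""


class ParameterError(ValueError):
    """An invalid SimulationConfig field; the message names the field."""


@dataclass(frozen=True)
class ExplicitBlock:
    """Fully specified block for deterministic toy panels."""

    haplotypes: tuple[str, ...]
    assignment: tuple[int, ...]
    chrom: str = "chr1"


@dataclass(frozen=True)
class CausalSpec:
    """Which true block carries the genetic effect, and how strong it is.

    block
        Global true-block index, or None to pick one at random (restricted
        to blocks with >= 2 occupied groups, and to exactly ``n_groups``
        occupied groups when given).
    variance_explained
        Requested fraction of strain-level trait variance explained by the
        causal grouping, either one value for all active timepoints or a
        per-timepoint mapping. Must lie in [0, 1).
    active_timepoints
        Timepoint labels at which the effect is on.
    beta
        Optional direct effect coefficient, overriding the closed-form
        derivation from ``variance_explained``.
    block_snps
        When set, *plant* the causal block: one block of exactly this many
        SNPs with a divergent haplotype pair (complementary strings, so
        every SNP in it is polymorphic) replaces a randomly placed block.
        Planting a block longer than the scan's ``max_snps`` guarantees at
        least one inferred block is tested at the causal grouping itself —
        the design used for end-to-end power validation (see the methods
        note on the resolution limit of the greedy partition).
    """

    active_timepoints: tuple[str, ...]
    variance_explained: float | Mapping[str, float] = 0.8
    block: int | None = None
    n_groups: int | None = None
    beta: float | None = None
    block_snps: int | None = None

    def ve_at(self, timepoint: str) -> float:
        if isinstance(self.variance_explained, Mapping):
            return float(self.variance_explained[timepoint])
        return float(self.variance_explained)


@dataclass(frozen=True)
class SimulationConfig:
    """Panel-generation parameters; defaults are the study-scale conditions
    (16 strains, six timepoints, triplicate measurements)."""

    n_strains: int = 16
    n_chromosomes: int = 2
    snps_per_chromosome: int = 150
    block_length_mean: float = 8.0  # geometric length model, in SNPs
    n_true_haplotypes_max: int = 4
    snp_spacing_bp: float = 1000.0
    missing_rate: float = 0.02
    flip_rate: float = 0.0
    timepoints: tuple[str, ...] = ("0", "4", "16", "24", "48", "72")
    replicates_per_strain: int = 3
    causal_spec: CausalSpec | None = None
    baseline: float = 10.0
    strain_noise_sd: float = 1.0
    noise_sd: float = 0.25  # replicate-level measurement noise
    seed: int = 0
    explicit_blocks: tuple[ExplicitBlock, ...] | None = None

    def __post_init__(self) -> None:
        def bad(fld: str, why: str):
            return ParameterError(f"invalid {fld}: {why}")

        if self.n_strains < 3:
            raise bad("n_strains", "must be >= 3")
        if self.explicit_blocks is None:
            if self.n_chromosomes < 1:
                raise bad("n_chromosomes", "must be >= 1")
            if self.snps_per_chromosome < 1:
                raise bad("snps_per_chromosome", "must be >= 1")
            if self.block_length_mean < 1:
                raise bad("block_length_mean", "must be >= 1")
            if self.n_true_haplotypes_max < 2:
                raise bad("n_true_haplotypes_max", "must be >= 2")
            if self.snp_spacing_bp < 1:
                raise bad("snp_spacing_bp", "must be >= 1")
        for fld in ("missing_rate", "flip_rate"):
            v = getattr(self, fld)
            if not (0.0 <= v <= 1.0):
                raise bad(fld, "must be in [0, 1]")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise bad("timepoints", "labels must be unique")
        if self.replicates_per_strain < 1:
            raise bad("replicates_per_strain", "must be >= 1")
        for fld in ("strain_noise_sd", "noise_sd"):
            if getattr(self, fld) < 0:
                raise bad(fld, "must be >= 0")
        cs = self.causal_spec
        if cs is not None:
            extra = set(map(str, cs.active_timepoints)) - set(self.timepoints)
            if extra:
                raise bad(
                    "causal_spec.active_timepoints",
                    f"not in timepoints: {sorted(extra)}",
                )
            for tp in cs.active_timepoints:
                ve = cs.ve_at(str(tp))
                if not (0.0 <= ve < 1.0):
                    raise bad("causal_spec.variance_explained", "must be in [0, 1)")
            if cs.block_snps is not None:
                if cs.block_snps < 2:
                    raise bad("causal_spec.block_snps", "must be >= 2")
                if cs.block is not None:
                    raise bad(
                        "causal_spec.block_snps",
                        "cannot combine with an explicit block index",
                    )
                if self.explicit_blocks is not None:
                    raise bad(
                        "causal_spec.block_snps", "not available in explicit mode"
                    )
        if self.explicit_blocks is not None:
            for k, eb in enumerate(self.explicit_blocks):
                if len(eb.assignment) != self.n_strains:
                    raise bad(
                        "explicit_blocks",
                        f"block {k}: assignment length != n_strains",
                    )
                lens = {len(h) for h in eb.haplotypes}
                if len(lens) != 1:
                    raise bad("explicit_blocks", f"block {k}: ragged haplotypes")
                if any(set(h) - {"0", "1"} for h in eb.haplotypes):
                    raise bad("explicit_blocks", f"block {k}: alleles must be 0/1")
                if len(set(eb.haplotypes)) != len(eb.haplotypes):
                    raise bad("explicit_blocks", f"block {k}: duplicate haplotypes")
                if len(eb.haplotypes) > self.n_true_haplotypes_max:
                    raise bad(
                        "explicit_blocks",
                        f"block {k}: more than n_true_haplotypes_max haplotypes",
                    )
                if any(not 0 <= a < len(eb.haplotypes) for a in eb.assignment):
                    raise bad("explicit_blocks", f"block {k}: assignment out of range")


@dataclass
class TrueBlock:
    chrom: str
    start: int  # half-open global variant-index range
    stop: int
    haplotypes: list[str]
    assignment: list[int]  # per-strain haplotype index

    def occupied_groups(self) -> int:
        return len(set(self.assignment))

    def dense_codes(self) -> np.ndarray:
        """Occupied-haplotype group codes 0..G-1, in first-occurrence order."""
        _, codes = np.unique(np.asarray(self.assignment), return_inverse=True)
        return codes


@dataclass
class PanelTruth:
    """Latent state of a simulated panel: the ground truth tests check."""

    blocks: list[TrueBlock]
    causal_index: int | None
    seed: int
    betas: dict[str, float] = field(default_factory=dict)
    realized_ve: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        stop = 0
        for b in self.blocks:
            if b.start != stop:
                raise ValueError("true blocks do not partition the variants")
            stop = b.stop
        if self.causal_index is not None and not (
            0 <= self.causal_index < len(self.blocks)
        ):
            raise ValueError("causal block index out of range")

    @property
    def causal_block(self) -> TrueBlock | None:
        return None if self.causal_index is None else self.blocks[self.causal_index]

    def boundaries(self) -> list[int]:
        return [b.start for b in self.blocks] + [self.blocks[-1].stop]

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "causal_index": self.causal_index,
            "betas": self.betas,
            "realized_ve": self.realized_ve,
            "blocks": [
                {
                    "chrom": b.chrom,
                    "start": b.start,
                    "stop": b.stop,
                    "haplotypes": b.haplotypes,
                    "assignment": b.assignment,
                }
                for b in self.blocks
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PanelTruth":
        payload = json.loads(text)
        return cls(
            blocks=[
                TrueBlock(
                    chrom=b["chrom"],
                    start=b["start"],
                    stop=b["stop"],
                    haplotypes=list(b["haplotypes"]),
                    assignment=list(b["assignment"]),
                )
                for b in payload["blocks"]
            ],
            causal_index=payload["causal_index"],
            seed=payload["seed"],
            betas=dict(payload["betas"]),
            realized_ve=dict(payload["realized_ve"]),
        )


# ---------------------------------------------------------------------------
# genotype stage
# ---------------------------------------------------------------------------


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _draw_haplotypes(rng: np.random.Generator, length: int, k_max: int) -> list[str]:
    """k distinct random binary strings, k uniform on 2..min(k_max, 2^length)."""
    cap = min(k_max, 2**length) if length < 32 else k_max
    k = int(rng.integers(2, cap + 1)) if cap > 2 else 2
    haps: list[str] = []
    seen: set[str] = set()
    while len(haps) < k:
        h = "".join(map(str, rng.integers(0, 2, size=length)))
        if h not in seen:
            seen.add(h)
            haps.append(h)
    return haps


def _divergent_haplotypes(
    rng: np.random.Generator, length: int, k: int
) -> list[str]:
    """k haplotypes led by a complementary pair, so every SNP is polymorphic
    whenever both lead haplotypes are carried."""
    h1 = rng.integers(0, 2, size=length)
    haps = ["".join(map(str, h1)), "".join(map(str, 1 - h1))]
    seen = set(haps)
    while len(haps) < k:
        h = "".join(map(str, rng.integers(0, 2, size=length)))
        if h not in seen:
            seen.add(h)
            haps.append(h)
    return haps


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PanelTruth]:
    """Generate a genotype panel with blocky haplotype structure.

    Deterministic given (config, seed); before flip/missing noise every
    strain's allele string within a true block equals one of that block's
    ancestral haplotypes. Returns the matrix and the latent truth.
    """
    rng = _rng(config.seed, _STREAM_GENOTYPE)
    n = config.n_strains
    true_blocks: list[TrueBlock] = []
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    planted_index: int | None = None
    if config.explicit_blocks is not None:
        pos = 0
        spacing = int(config.snp_spacing_bp)
        for eb in config.explicit_blocks:
            length = len(eb.haplotypes[0])
            start_idx = len(variants)
            hap_bits = np.array(
                [[int(c) for c in h] for h in eb.haplotypes], dtype=np.int8
            )
            assign = np.asarray(eb.assignment)
            for j in range(length):
                pos += spacing
                variants.append(Variant(eb.chrom, pos, "A", "G"))
                rows.append(hap_bits[assign, j].copy())
            true_blocks.append(
                TrueBlock(
                    chrom=eb.chrom,
                    start=start_idx,
                    stop=start_idx + length,
                    haplotypes=list(eb.haplotypes),
                    assignment=list(eb.assignment),
                )
            )
    else:
        # phase 1: lay out block lengths per chromosome
        layout: list[tuple[str, int]] = []
        for c in range(1, config.n_chromosomes + 1):
            chrom = f"chr{c}"
            remaining = config.snps_per_chromosome
            while remaining > 0:
                length = min(int(rng.geometric(1.0 / config.block_length_mean)),
                             remaining)
                remaining -= length
                layout.append((chrom, length))
        # phase 2: optionally plant the causal block (own random stream, so
        # an otherwise-identical config without planting yields the same
        # layout draws)
        cs = config.causal_spec
        plant_rng: np.random.Generator | None = None
        if cs is not None and cs.block_snps is not None:
            plant_rng = _rng(config.seed, _STREAM_CAUSAL_PICK)
            planted_index = int(plant_rng.integers(0, len(layout)))
            layout[planted_index] = (layout[planted_index][0], cs.block_snps)
        # phase 3: haplotypes, strain assignments, positions
        pos_by_chrom: dict[str, int] = {}
        for idx, (chrom, length) in enumerate(layout):
            if idx == planted_index:
                k = cs.n_groups if cs.n_groups is not None else 2
                haps = _divergent_haplotypes(plant_rng, length, k)
                assign = plant_rng.integers(0, k, size=n)
                while np.unique(assign).size < k:  # all groups occupied
                    assign = plant_rng.integers(0, k, size=n)
            else:
                haps = _draw_haplotypes(rng, length, config.n_true_haplotypes_max)
                assign = rng.integers(0, len(haps), size=n)
            hap_bits = np.array(
                [[int(ch) for ch in h] for h in haps], dtype=np.int8
            )
            start_idx = len(variants)
            pos = pos_by_chrom.get(chrom, 0)
            for j in range(length):
                pos += max(1, int(rng.geometric(1.0 / config.snp_spacing_bp)))
                ref, alt = rng.choice(_BASES, size=2, replace=False)
                variants.append(Variant(chrom, pos, str(ref), str(alt)))
                rows.append(hap_bits[assign, j].copy())
            pos_by_chrom[chrom] = pos
            true_blocks.append(
                TrueBlock(
                    chrom=chrom,
                    start=start_idx,
                    stop=start_idx + length,
                    haplotypes=haps,
                    assignment=assign.tolist(),
                )
            )
    calls = np.vstack(rows).astype(np.int8)
    if config.flip_rate > 0:
        flips = rng.random(calls.shape) < config.flip_rate
        calls = np.where(flips, 1 - calls, calls).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = MISSING
    if planted_index is not None:
        causal_index = planted_index
    else:
        causal_index = _pick_causal_block(config, true_blocks)
    strains = [f"strain{i:02d}" for i in range(1, n + 1)]
    matrix = GenotypeMatrix(strains, variants, calls)
    truth = PanelTruth(blocks=true_blocks, causal_index=causal_index,
                       seed=config.seed)
    return matrix, truth


def _pick_causal_block(
    config: SimulationConfig, true_blocks: list[TrueBlock]
) -> int | None:
    cs = config.causal_spec
    if cs is None:
        return None
    if cs.block is not None:
        if not 0 <= cs.block < len(true_blocks):
            raise ParameterError(
                f"invalid causal_spec.block: index {cs.block} out of range"
            )
        if true_blocks[cs.block].occupied_groups() < 2:
            raise SimulationError(
                "causal block has fewer than 2 occupied haplotype groups"
            )
        return cs.block
    eligible = [
        i
        for i, b in enumerate(true_blocks)
        if b.occupied_groups() >= 2
        and (cs.n_groups is None or b.occupied_groups() == cs.n_groups)
    ]
    if not eligible:
        raise SimulationError(
            "no true block satisfies the causal-block selector"
        )
    pick_rng = _rng(config.seed, _STREAM_CAUSAL_PICK)
    return int(eligible[pick_rng.integers(0, len(eligible))])


# ---------------------------------------------------------------------------
# phenotype stage
# ---------------------------------------------------------------------------


def derive_beta(
    h2: float, codes: np.ndarray, strain_noise_sd: float
) -> float:
    """Effect coefficient giving expected eta^2 = h2 at the causal grouping.

    Matches expected between-group to total sums of squares of the strain
    values; h2 at or below the null expectation (G-1)/(N-1) yields beta = 0.
    With zero strain noise any beta > 0 explains all variance, so beta is
    set to sqrt(h2) as an arbitrary-unit scale.
    """
    if not (0.0 <= h2 < 1.0):
        raise ParameterError("invalid causal_spec.variance_explained: not in [0, 1)")
    if h2 == 0.0:
        return 0.0
    c = codes - codes.mean()
    s_c = float(np.sum(c * c))
    if s_c == 0.0:
        raise SimulationError("causal block has a single occupied group")
    if strain_noise_sd == 0.0:
        return math.sqrt(h2)
    n = codes.size
    g = int(np.unique(codes).size)
    numer = h2 * (n - 1) - (g - 1)
    if numer <= 0.0:
        logger.warning(
            "requested variance-explained %.3f is at or below the null "
            "expectation (G-1)/(N-1)=%.3f; using beta=0",
            h2,
            (g - 1) / (n - 1),
        )
        return 0.0
    return math.sqrt(strain_noise_sd**2 * numer / (1.0 - h2) / s_c)


def realized_variance_explained(values: np.ndarray, codes: np.ndarray) -> float:
    """eta^2 of strain-level values grouped by the true causal codes."""
    grand = values.mean()
    sst = float(np.sum((values - grand) ** 2))
    if sst == 0.0:
        return math.nan
    ssb = 0.0
    for g in np.unique(codes):
        sel = values[codes == g]
        ssb += sel.size * (sel.mean() - grand) ** 2
    return float(ssb / sst)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    truth: PanelTruth,
    config: SimulationConfig,
) -> tuple[PhenotypeTable, PanelTruth]:
    """Generate the multi-timepoint trait for a simulated panel.

    At each active timepoint the strain value is baseline + beta * centered
    causal group code + strain noise; every replicate adds measurement
    noise. Inactive timepoints carry strain and replicate noise only. The
    realized variance explained (eta^2 at the true causal grouping) is
    recorded in the returned truth.
    """
    n = genotypes.n_strains
    for b in truth.blocks:
        if len(b.assignment) != n:
            raise ValueError("truth inconsistent with genotypes (strain count)")
    if truth.blocks and truth.blocks[-1].stop != genotypes.n_variants:
        raise ValueError("truth inconsistent with genotypes (variant count)")
    cs = config.causal_spec
    active = {str(t) for t in cs.active_timepoints} if cs is not None else set()
    codes = None
    if cs is not None and active:
        cb = truth.causal_block
        if cb is None:
            raise SimulationError("config has a causal_spec but truth has no causal block")
        if cb.occupied_groups() < 2:
            raise SimulationError(
                "causal block has fewer than 2 occupied haplotype groups"
            )
        codes = cb.dense_codes()
    rng = _rng(config.seed, _STREAM_PHENOTYPE)
    records = {"strain": [], "timepoint": [], "replicate": [], "value": []}
    for tp in config.timepoints:
        tp = str(tp)
        strain_noise = (
            rng.normal(0.0, config.strain_noise_sd, size=n)
            if config.strain_noise_sd > 0
            else np.zeros(n)
        )
        if tp in active:
            beta = (
                cs.beta
                if cs.beta is not None
                else derive_beta(cs.ve_at(tp), codes, config.strain_noise_sd)
            )
            centered = codes - codes.mean()
            genetic = beta * centered
        else:
            beta = 0.0
            genetic = np.zeros(n)
        strain_values = config.baseline + genetic + strain_noise
        truth.betas[tp] = float(beta)
        if tp in active:
            truth.realized_ve[tp] = realized_variance_explained(
                strain_values, codes
            )
        else:
            truth.realized_ve[tp] = 0.0
        for rep in range(1, config.replicates_per_strain + 1):
            rep_noise = (
                rng.normal(0.0, config.noise_sd, size=n)
                if config.noise_sd > 0
                else np.zeros(n)
            )
            records["strain"].extend(genotypes.strain_names)
            records["timepoint"].extend([tp] * n)
            records["replicate"].extend([rep] * n)
            records["value"].extend(strain_values + rep_noise)
    table = PhenotypeTable(pd.DataFrame(records))
    return table, truth


def simulate_panel(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PhenotypeTable, PanelTruth]:
    """Convenience wrapper: genotypes then phenotypes off one master seed."""
    genotypes, truth = simulate_genotypes(config)
    phenotypes, truth = simulate_phenotypes(genotypes, truth, config)
    return genotypes, phenotypes, truth


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

FIXTURE_FILES = {
    "vcf": "genotypes.vcf",
    "tsv": "genotypes.tsv",
    "phenotypes": "phenotypes.csv",
    "truth": "truth.json",
}


def write_fixture(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    truth: PanelTruth,
    directory,
) -> dict[str, Path]:
    """Write a panel as VCF + genotype TSV + phenotype CSV + truth JSON.

    Validates everything before touching the filesystem, so a failed call
    leaves no partial files behind. Files round-trip through the io module.
    """
    if not str(directory):
        raise ValueError("empty directory path")
    directory = Path(directory)
    truth.to_json()  # serialise first: any failure aborts before writes
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in FIXTURE_FILES.items()}
    write_genotypes(genotypes, paths["vcf"], format="vcf")
    write_genotypes(genotypes, paths["tsv"], format="tsv")
    write_phenotypes(phenotypes, paths["phenotypes"])
    paths["truth"].write_text(truth.to_json() + "\n")
    return paths


def read_truth(path) -> PanelTruth:
    return PanelTruth.from_json(Path(path).read_text())
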