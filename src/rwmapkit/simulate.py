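"""Synthetic balancer-screen generator with full ground truth.

Emulates the data a regional recessive-lethal screen produces: a B6 × Cast
F2 mapping panel segregating one recessive embryonic-lethal mutation, a
panel of nested deletions with uncertain breakpoints and their
complementation outcomes, weanling counts from balancer intercrosses, and
capture-sequencing variant tables with one planted causative change plus
strain, background and catalogued confounders.  Every emitted record is
consistent with a stored truth object, so downstream mapping, grouping and
filtering can be scored exactly.

Meiosis follows the Haldane model: crossover count Poisson in the genetic
length of the region, breakpoint positions uniform, no interference — the
simplest standard model, with closed-form recombinant fractions
r = (1 − e^(−2d))/2 for checking.  The balancer chromosome is treated as
fully recombination-suppressed and dominantly marked, with balancer
homozygotes lost before genotyping.  All outputs are pure functions of the
configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .allelism import CrossCounts
from .intervals import GenomicInterval, IntervalSet, write_bed
from .mapping import (
    AnimalRecord,
    Deletion,
    DeletionTest,
    GenotypeCall,
    GenotypeTable,
    Marker,
    TestOutcome,
    write_genotype_table,
)
from .variants import (
    KnownVariantSet,
    VariantCall,
    Zygosity,
    write_known_variants,
    write_variant_tsv,
    write_vcf,
)

__all__ = [
    "SimConfig",
    "ScreenTruth",
    "SimulatedScreen",
    "default_markers",
    "default_deletion_panel",
    "simulate_gamete",
    "simulate_f2_cohort",
    "derive_deletion_outcomes",
    "simulate_intercross_weaned",
    "simulate_variant_tables",
    "simulate_screen",
    "write_screen",
]

#: default region footprint: proximal Chr 5 up to ~60.9 Mb
DEFAULT_REGION_LENGTH = 60_900_000
DEFAULT_MARKER_SPACING = 1_500_000


def default_markers(
    region_length: int = DEFAULT_REGION_LENGTH,
    spacing: int = DEFAULT_MARKER_SPACING,
) -> list[Marker]:
    """Evenly spaced microsatellite-style markers across the region."""
    positions = range(spacing, region_length, spacing)
    return [Marker(p, f"D5Sim{i + 1:03d}") for i, p in enumerate(positions)]


def default_deletion_panel(
    region_length: int = DEFAULT_REGION_LENGTH, chrom: str = "5"
) -> list[Deletion]:
    """Three nested deletion complexes with breakpoint-uncertainty zones.

    Extents are fixed fractions of the region so the panel scales with
    region size; uncertainty zones are ~1% of the region on each side.
    """
    L = region_length

    def frac(x: float) -> int:
        return int(round(x * L))

    panel = [
        # (name, complex, min_lo, min_hi, max_lo, max_hi) as fractions
        ("dfA1", "cxA", 0.20, 0.33, 0.19, 0.34),
        ("dfA2", "cxA", 0.23, 0.29, 0.22, 0.30),
        ("dfB1", "cxB", 0.49, 0.62, 0.48, 0.635),
        ("dfB2", "cxB", 0.52, 0.575, 0.51, 0.585),
        ("dfC1", "cxC", 0.78, 0.90, 0.77, 0.91),
        ("dfC2", "cxC", 0.81, 0.86, 0.80, 0.87),
    ]
    return [
        Deletion(
            name=name,
            complex_name=cx,
            min_extent=GenomicInterval(chrom, frac(a), frac(b)),
            max_extent=GenomicInterval(chrom, frac(c), frac(d)),
        )
        for name, cx, a, b, c, d in panel
    ]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated screen.

    ``n_f2`` counts conceptuses; mutant homozygotes among them die before
    genotyping and are absent from the emitted table.  ``variant_noise``
    is (strain SNPs shared with the non-B6 control strain, background
    variants shared by all samples, sites present in the known catalog).
    """

    region_length: int = DEFAULT_REGION_LENGTH
    chrom: str = "5"
    markers: Optional[tuple[Marker, ...]] = None  # None → default grid
    true_mutation_pos: int = 33_250_000  # 1-based, off-marker by default
    cM_per_Mb: float = 0.5
    n_f2: int = 100
    deletions: Optional[tuple[Deletion, ...]] = None  # None → default panel
    seed: int = 0
    mutation_id: str = "simL1"
    variant_noise: tuple[int, int, int] = (20, 30, 15)
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.true_mutation_pos <= self.region_length):
            raise ValueError("true_mutation_pos outside region")
        if self.cM_per_Mb <= 0:
            raise ValueError("cM_per_Mb must be > 0")
        if self.n_f2 <= 0:
            raise ValueError("n_f2 must be > 0")

    @property
    def marker_list(self) -> list[Marker]:
        if self.markers is not None:
            return list(self.markers)
        return default_markers(self.region_length)

    @property
    def deletion_list(self) -> list[Deletion]:
        if self.deletions is not None:
            return list(self.deletions)
        return default_deletion_panel(self.region_length, self.chrom)

    @property
    def genetic_length_morgans(self) -> float:
        return self.region_length / 1e6 * self.cM_per_Mb / 100.0

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "region_length": self.region_length,
            "chrom": self.chrom,
            "true_mutation_pos": self.true_mutation_pos,
            "cM_per_Mb": self.cM_per_Mb,
            "n_f2": self.n_f2,
            "seed": self.seed,
            "mutation_id": self.mutation_id,
            "variant_noise": list(self.variant_noise),
            "genotype_error_rate": self.genotype_error_rate,
            "missing_rate": self.missing_rate,
        }
        if self.markers is not None:
            d["markers"] = [{"name": m.name, "position_bp": m.position}
                            for m in self.markers]
        if self.deletions is not None:
            d["deletions"] = [
                {
                    "name": dl.name,
                    "complex": dl.complex_name,
                    "min_start": dl.min_extent.to_1based()[0],
                    "min_end": dl.min_extent.to_1based()[1],
                    "max_start": dl.max_extent.to_1based()[0],
                    "max_end": dl.max_extent.to_1based()[1],
                }
                for dl in self.deletions
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "markers" in d:
            d["markers"] = tuple(
                Marker(m["position_bp"], m["name"]) for m in d["markers"]
            )
        if "deletions" in d:
            chrom = d.get("chrom", "5")
            d["deletions"] = tuple(
                Deletion(
                    name=x["name"],
                    complex_name=x.get("complex"),
                    min_extent=GenomicInterval.from_1based(
                        chrom, x["min_start"], x["min_end"]
                    ),
                    max_extent=GenomicInterval.from_1based(
                        chrom, x["max_start"], x["max_end"]
                    ),
                )
                for x in d["deletions"]
            )
        if "variant_noise" in d:
            d["variant_noise"] = tuple(d["variant_noise"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class ScreenTruth:
    """Ground truth behind one simulated screen."""

    mutation_pos: int  # 1-based
    deletion_segments: dict[str, GenomicInterval]  # sampled true extents


@dataclass
class SimulatedScreen:
    config: SimConfig
    genotype_table: GenotypeTable  # live animals only
    deletion_tests: list[DeletionTest]
    truth: ScreenTruth
    variant_tables: dict[str, list[VariantCall]]
    known_variants: KnownVariantSet


# -- meiosis -------------------------------------------------------------


def simulate_gamete(
    parent_haplotypes: tuple[np.ndarray, np.ndarray],
    locus_positions: np.ndarray,
    region_length: int,
    genetic_length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one gamete under Haldane meiosis (no interference).

    Crossover count ~ Poisson(genetic_length in Morgans), breakpoints
    uniform on the region; the returned haplotype alternates parental
    phase at each breakpoint, starting from a fair coin flip.
    """
    if genetic_length < 0:
        raise ValueError("genetic_length must be >= 0")
    h0, h1 = parent_haplotypes
    n_co = rng.poisson(genetic_length)
    start_phase = rng.integers(0, 2)
    if n_co == 0:
        return (h1 if start_phase else h0).copy()
    breaks = np.sort(rng.uniform(0, region_length, size=n_co))
    phase = (start_phase + np.searchsorted(breaks, locus_positions)) % 2
    return np.where(phase == 0, h0, h1)


def _cohort_rng_draws(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[AnimalRecord], int]:
    """Draw conceptuses; return live records and dead count."""
    markers = config.marker_list
    positions = np.array([m.position for m in markers], dtype=float)
    mut_pos = float(config.true_mutation_pos)
    loci = np.sort(np.append(positions, mut_pos))
    mut_idx = int(np.searchsorted(loci, mut_pos))
    marker_idx = np.array([i for i in range(len(loci)) if i != mut_idx])
    # F1 parent: one chromosome fully B6 (carries the mutation, allele 0),
    # the homolog fully Cast (allele 1)
    h0 = np.zeros(len(loci), dtype=np.int8)
    h1 = np.ones(len(loci), dtype=np.int8)
    L = config.genetic_length_morgans
    call_codes = np.array(
        [GenotypeCall.B6B6, GenotypeCall.HET, GenotypeCall.CASTCAST], dtype=object
    )
    live: list[AnimalRecord] = []
    dead = 0
    for i in range(config.n_f2):
        g1 = simulate_gamete((h0, h1), loci, config.region_length, L, rng)
        g2 = simulate_gamete((h0, h1), loci, config.region_length, L, rng)
        if g1[mut_idx] == 0 and g2[mut_idx] == 0:
            dead += 1  # mutant homozygote: dies before genotyping
            continue
        dosage = (g1[marker_idx] + g2[marker_idx]).astype(int)  # count of Cast alleles
        calls = call_codes[dosage]
        if config.genotype_error_rate > 0:
            err = rng.random(len(calls)) < config.genotype_error_rate
            for j in np.flatnonzero(err):
                others = [c for c in call_codes if c is not calls[j]]
                calls[j] = others[rng.integers(0, len(others))]
        if config.missing_rate > 0:
            miss = rng.random(len(calls)) < config.missing_rate
            calls[miss] = GenotypeCall.MISSING
        live.append(
            AnimalRecord(f"F2_{i + 1:04d}", tuple(calls), alive=True)
        )
    return live, dead


def simulate_f2_cohort(config: SimConfig) -> GenotypeTable:
    """Simulate the live-animal F2 genotype table for one screen.

    Each of ``n_f2`` conceptuses draws two independent F1 gametes;
    conceptuses homozygous for the mutation-bearing B6 haplotype at the
    mutation position die and are excluded.  Bit-identical for a fixed
    config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    live, _ = _cohort_rng_draws(config, rng)
    return GenotypeTable(config.marker_list, live, chrom=config.chrom)


def derive_deletion_outcomes(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[DeletionTest], dict[str, GenomicInterval]]:
    """Sample true deletion breakpoints and score complementation outcomes.

    Each true breakpoint is uniform within its uncertainty zone; a deletion
    fails to complement iff the mutation lies within the sampled true
    deleted segment.
    """
    tests: list[DeletionTest] = []
    segments: dict[str, GenomicInterval] = {}
    mut0 = config.true_mutation_pos - 1  # 0-based point
    for dl in config.deletion_list:
        left = int(rng.integers(dl.max_extent.start, dl.min_extent.start + 1))
        right = int(rng.integers(dl.min_extent.end, dl.max_extent.end + 1))
        segment = GenomicInterval(dl.min_extent.chrom, left, right)
        segments[dl.name] = segment
        outcome = (
            TestOutcome.FAILS if segment.contains(mut0) else TestOutcome.COMPLEMENTS
        )
        tests.append(DeletionTest(config.mutation_id, dl.name, outcome))
    return tests, segments


def simulate_intercross_weaned(
    n_born: int, complementing: bool, rng: np.random.Generator
) -> CrossCounts:
    """Weanling counts from an m1/Bal × m2/Bal intercross of ``n_born`` pups.

    Balancer homozygotes are lost in utero, so births are 1/3
    trans-heterozygote : 2/3 balancer carrier; non-complementing
    trans-heterozygotes die before weaning.
    """
    if n_born < 0:
        raise ValueError("n_born must be >= 0")
    trans = int(rng.binomial(n_born, 1.0 / 3.0)) if n_born else 0
    balancer = n_born - trans
    if complementing:
        return CrossCounts(
            weaned_non_balancer=trans,
            weaned_balancer=balancer,
            born_total=n_born,
            died_pre_wean=0,
        )
    return CrossCounts(
        weaned_non_balancer=0,
        weaned_balancer=balancer,
        born_total=n_born,
        died_pre_wean=trans,
    )


_BASES = np.array(list("ACGT"))


def _random_snv(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


def simulate_variant_tables(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, list[VariantCall]], KnownVariantSet]:
    """Capture-sequencing variant tables with one planted causative change.

    Samples: ``mutant`` (carrier DNA), ``control_strain`` (the non-B6
    partner strain) and ``control_b6``.  The causative variant is
    heterozygous in the mutant only; strain SNPs are shared between mutant
    and the strain control, background variants are shared by all samples,
    and known-catalog sites appear in the mutant but also in the emitted
    known-variant set.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_strain, n_background, n_known = config.variant_noise
    total = n_strain + n_background + n_known
    taken = {config.true_mutation_pos}
    positions: list[int] = []
    while len(positions) < total:
        p = int(rng.integers(1, config.region_length + 1))
        if p not in taken:
            taken.add(p)
            positions.append(p)
    chrom = config.chrom
    tables: dict[str, list[VariantCall]] = {
        "mutant": [],
        "control_strain": [],
        "control_b6": [],
    }
    ref, alt = _random_snv(rng)
    tables["mutant"].append(
        VariantCall(chrom, config.true_mutation_pos, ref, alt, Zygosity.HET, "mutant")
    )
    cursor = 0
    for _ in range(n_strain):
        pos = positions[cursor]
        cursor += 1
        ref, alt = _random_snv(rng)
        tables["mutant"].append(
            VariantCall(chrom, pos, ref, alt, Zygosity.HET, "mutant")
        )
        tables["control_strain"].append(
            VariantCall(chrom, pos, ref, alt, Zygosity.HOM_ALT, "control_strain")
        )
    for _ in range(n_background):
        pos = positions[cursor]
        cursor += 1
        ref, alt = _random_snv(rng)
        for sample in tables:
            tables[sample].append(
                VariantCall(chrom, pos, ref, alt, Zygosity.HET, sample)
            )
    known_entries = []
    for k in range(n_known):
        pos = positions[cursor]
        cursor += 1
        ref, alt = _random_snv(rng)
        tables["mutant"].append(
            VariantCall(chrom, pos, ref, alt, Zygosity.HET, "mutant")
        )
        known_entries.append((chrom, pos, alt, f"sim_rs{k + 1}"))
    for sample in tables:
        tables[sample].sort()
    return tables, KnownVariantSet(known_entries)


def simulate_screen(config: SimConfig) -> SimulatedScreen:
    """Run the full generator: genotypes, deletion tests, variant tables.

    A single seeded random stream drives all stages in a fixed order, so
    the whole screen is a pure function of the config.
    """
    rng = np.random.default_rng(config.seed)
    live, _ = _cohort_rng_draws(config, rng)
    table = GenotypeTable(config.marker_list, live, chrom=config.chrom)
    tests, segments = derive_deletion_outcomes(config, rng)
    tables, known = simulate_variant_tables(config, rng)
    return SimulatedScreen(
        config=config,
        genotype_table=table,
        deletion_tests=tests,
        truth=ScreenTruth(
            mutation_pos=config.true_mutation_pos, deletion_segments=segments
        ),
        variant_tables=tables,
        known_variants=known,
    )


def write_screen(screen: SimulatedScreen, outdir: Union[str, Path]) -> None:
    """Emit a screen in the TSV/BED/VCF dialects the other modules read."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = screen.config
    write_genotype_table(
        screen.genotype_table, outdir / "genotypes.tsv", outdir / "markers.tsv"
    )
    pd.DataFrame(
        [
            {
                "name": dl.name,
                "complex": dl.complex_name or "",
                "min_start": dl.min_extent.to_1based()[0],
                "min_end": dl.min_extent.to_1based()[1],
                "max_start": dl.max_extent.to_1based()[0],
                "max_end": dl.max_extent.to_1based()[1],
            }
            for dl in cfg.deletion_list
        ]
    ).to_csv(outdir / "deletions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"mutation_id": t.mutation_id, "deletion": t.deletion_name,
             "outcome": t.outcome.value}
            for t in screen.deletion_tests
        ]
    ).to_csv(outdir / "deletion_tests.tsv", sep="\t", index=False)
    write_bed(
        IntervalSet([GenomicInterval(cfg.chrom, 0, cfg.region_length)]),
        outdir / "initial_region.bed",
    )
    for sample, calls in screen.variant_tables.items():
        write_variant_tsv(calls, outdir / f"variants_{sample}.tsv")
        write_vcf(calls, outdir / f"variants_{sample}.vcf",
                  contig_lengths={cfg.chrom: cfg.region_length})
    write_known_variants(screen.known_variants, outdir / "known_variants.tsv")
    cfg.to_yaml(outdir / "sim_config.yaml")
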