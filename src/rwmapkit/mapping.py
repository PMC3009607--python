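"""Critical-region inference by interval exclusion.

A recessive lethal mutation maintained over a balancer chromosome is
localized indirectly: no live F2 intercross animal can be homozygous for
the mutagenized-strain (B6) haplotype at the mutation, so every observed
run of B6/B6 genotypes in a live animal excludes the marker-to-marker span
it covers.  Complementation tests against chromosomal deficiencies add a
second kind of evidence: a deletion that fails to complement must overlap
the mutation (the mutation lies within the deletion's outermost possible
extent), while a deletion that complements cannot remove the mutation
(the mutation lies outside the DNA known to be absent).

Both rules are deliberately conservative.  Deletion breakpoints are only
known to lie within flanking uncertainty zones, so non-complementation
retains the *maximal* extent and complementation subtracts only the
*minimal* extent.  Recombination exclusions use the closed marker-to-marker
span of each B6/B6 run and never extend into flanking heterozygous
intervals, because the crossover position between markers is unobserved;
missing genotypes break runs.  Under these rules, adding evidence can only
shrink the surviving region, and the result is independent of the order in
which evidence is applied.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "Marker",
    "Deletion",
    "TestOutcome",
    "DeletionTest",
    "GenotypeCall",
    "AnimalRecord",
    "GenotypeTable",
    "EvidenceEntry",
    "CriticalRegion",
    "InconsistentEvidenceError",
    "apply_deletion_test",
    "homozygous_b6_spans",
    "recombination_exclusions",
    "map_mutation",
    "read_marker_map",
    "read_deletions",
    "read_deletion_tests",
    "read_genotype_table",
    "write_genotype_table",
]

logger = logging.getLogger(__name__)


class InconsistentEvidenceError(ValueError):
    """Raised when mapping evidence excludes every possible position."""


@dataclass(frozen=True, order=True)
class Marker:
    """A genotyping marker: name and 1-based bp position."""

    position: int  # 1-based, as printed in marker tables
    name: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"marker {self.name}: position must be >= 1")


@dataclass(frozen=True)
class Deletion:
    """A chromosomal deficiency with breakpoint uncertainty.

    ``min_extent`` is the DNA known to be absent; ``max_extent`` bounds the
    region within which the true breakpoints reside (min ⊆ max).
    """

    name: str
    min_extent: GenomicInterval
    max_extent: GenomicInterval
    complex_name: Optional[str] = None  # Dpp6/Hdh/Qdpr-style grouping, metadata only

    def __post_init__(self) -> None:
        if self.min_extent.chrom != self.max_extent.chrom:
            raise ValueError(f"deletion {self.name}: extents on different chromosomes")
        if not (
            self.max_extent.start <= self.min_extent.start
            and self.min_extent.end <= self.max_extent.end
        ):
            raise ValueError(f"deletion {self.name}: min_extent not within max_extent")


class TestOutcome(str, enum.Enum):
    __test__ = False  # not a pytest class, despite the name

    COMPLEMENTS = "C"
    FAILS = "F"

    @classmethod
    def parse(cls, token: str) -> "TestOutcome":
        t = token.strip().upper()
        if t in ("C", "COMPLEMENTS", "COMPLEMENT"):
            return cls.COMPLEMENTS
        if t in ("F", "FAILS", "FAIL"):
            return cls.FAILS
        raise ValueError(f"unknown deletion-test outcome {token!r}")


@dataclass(frozen=True)
class DeletionTest:
    """Outcome of crossing a mutation carrier against a deletion carrier."""

    mutation_id: str
    deletion_name: str
    outcome: TestOutcome


class GenotypeCall(str, enum.Enum):
    """Genotype at one marker in a B6 × Cast F2 animal."""

    B6B6 = "B"
    HET = "H"
    CASTCAST = "C"
    MISSING = "-"

    @classmethod
    def parse(cls, token: str) -> "GenotypeCall":
        try:
            return cls(token.strip().upper() if token.strip() != "-" else "-")
        except ValueError:
            raise ValueError(f"unknown genotype call {token!r}") from None


@dataclass(frozen=True)
class AnimalRecord:
    animal_id: str
    calls: tuple[GenotypeCall, ...]
    alive: bool = True


@dataclass
class GenotypeTable:
    """Live F2 animals × markers genotype matrix."""

    markers: list[Marker]
    animals: list[AnimalRecord]
    chrom: str = "5"

    def __post_init__(self) -> None:
        positions = [m.position for m in self.markers]
        if positions != sorted(positions):
            raise ValueError("markers must be sorted by position")
        if len(set(positions)) != len(positions):
            raise ValueError("marker positions must be unique")
        for a in self.animals:
            if len(a.calls) != len(self.markers):
                raise ValueError(
                    f"animal {a.animal_id}: {len(a.calls)} calls for "
                    f"{len(self.markers)} markers"
                )

    @property
    def live_animals(self) -> list[AnimalRecord]:
        return [a for a in self.animals if a.alive]


@dataclass(frozen=True)
class EvidenceEntry:
    """One replayable mapping step: retain (intersect) or exclude (subtract)."""

    source: str
    action: str  # "retain" | "exclude"
    intervals: IntervalSet

    def apply(self, region: IntervalSet) -> IntervalSet:
        if self.action == "retain":
            return region.intersect(self.intervals)
        if self.action == "exclude":
            return region.subtract(self.intervals)
        raise ValueError(f"unknown evidence action {self.action!r}")


@dataclass
class CriticalRegion:
    """The surviving candidate region for a mutation, with its evidence log."""

    mutation_id: str
    region: IntervalSet
    initial: IntervalSet
    evidence_log: list[EvidenceEntry] = field(default_factory=list)

    def replay(self) -> IntervalSet:
        """Re-apply the evidence log to the initial region (audit check)."""
        region = self.initial
        for entry in self.evidence_log:
            region = entry.apply(region)
        return region

    def width_kb(self) -> int:
        return self.region.width_kb()


# -- core operations -----------------------------------------------------


def apply_deletion_test(
    candidate: IntervalSet, deletion: Deletion, outcome: TestOutcome
) -> IntervalSet:
    """Narrow a candidate region by one deletion-complementation outcome.

    FAILS: the mutation must lie within DNA possibly removed, so the
    candidate is intersected with the deletion's maximal extent.
    COMPLEMENTS: the mutation cannot lie in DNA known absent, so the
    minimal extent is subtracted.
    """
    if candidate.is_empty:
        raise ValueError("candidate region is empty before applying test")
    outcome = TestOutcome(outcome)
    if outcome is TestOutcome.FAILS:
        result = candidate.intersect(IntervalSet([deletion.max_extent]))
        if result.is_empty:
            raise InconsistentEvidenceError(
                f"deletion {deletion.name} fails to complement but its maximal "
                f"extent does not intersect the candidate region"
            )
        return result
    return candidate.subtract(IntervalSet([deletion.min_extent]))


def homozygous_b6_spans(
    calls: Sequence[GenotypeCall],
    markers: Sequence[Marker],
    chrom: str = "5",
) -> IntervalSet:
    """Marker-to-marker spans provably homozygous B6 in one animal.

    Each maximal run of consecutive B6/B6 calls yields the closed span from
    the first to the last marker of the run; a single-marker run yields a
    1-bp span at that marker (the only provably B6/B6 DNA is the marker
    itself).  MISSING calls are uninformative and break runs.
    """
    if len(calls) != len(markers):
        raise ValueError(f"{len(calls)} calls for {len(markers)} markers")
    spans: list[GenomicInterval] = []
    run_start: Optional[int] = None
    for i, call in enumerate(list(calls) + [GenotypeCall.HET]):  # sentinel ends run
        if call is GenotypeCall.B6B6:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                p1 = markers[run_start].position
                p2 = markers[i - 1].position
                spans.append(GenomicInterval.from_1based(chrom, p1, p2))
                run_start = None
    return IntervalSet(spans)


def recombination_exclusions(table: GenotypeTable) -> IntervalSet:
    """Union of B6/B6 exclusion spans over all live animals.

    Dead or unknown-viability animals contribute nothing: only survival
    proves the excluded DNA can be homozygous B6 without lethality.
    """
    live = table.live_animals
    if not live:
        warnings.warn("genotype table has no live animals; nothing excluded")
        logger.warning("recombination_exclusions: empty/no-live table")
        return IntervalSet()
    excluded = IntervalSet()
    for animal in live:
        spans = homozygous_b6_spans(animal.calls, table.markers, table.chrom)
        excluded = excluded.union(spans)
    return excluded


def map_mutation(
    initial: IntervalSet,
    deletion_tests: Iterable[DeletionTest],
    deletions: Mapping[str, Deletion],
    table: Optional[GenotypeTable] = None,
    mutation_id: str = "mutation",
) -> CriticalRegion:
    """Fold all deletion-test and recombination evidence into a critical region.

    Raises :class:`InconsistentEvidenceError`, carrying the full evidence
    replay, if the combined evidence excludes every position.
    """
    region = initial
    log: list[EvidenceEntry] = []
    for test in deletion_tests:
        if test.deletion_name not in deletions:
            raise KeyError(f"deletion {test.deletion_name!r} not in catalog")
        deletion = deletions[test.deletion_name]
        if test.outcome is TestOutcome.FAILS:
            entry = EvidenceEntry(
                source=f"deletion {deletion.name}: fails to complement",
                action="retain",
                intervals=IntervalSet([deletion.max_extent]),
            )
        else:
            entry = EvidenceEntry(
                source=f"deletion {deletion.name}: complements",
                action="exclude",
                intervals=IntervalSet([deletion.min_extent]),
            )
        region = apply_deletion_test(region, deletion, test.outcome)
        log.append(entry)
    if table is not None:
        for animal in table.live_animals:
            spans = homozygous_b6_spans(animal.calls, table.markers, table.chrom)
            if spans.is_empty:
                continue
            region = region.subtract(spans)
            log.append(
                EvidenceEntry(
                    source=f"live F2 {animal.animal_id}: B6/B6 spans",
                    action="exclude",
                    intervals=spans,
                )
            )
    if region.is_empty:
        detail = "; ".join(e.source for e in log)
        raise InconsistentEvidenceError(
            f"{mutation_id}: evidence excludes the entire initial region "
            f"(applied: {detail})"
        )
    return CriticalRegion(
        mutation_id=mutation_id, region=region, initial=initial, evidence_log=log
    )


# -- TSV I/O -------------------------------------------------------------
# Dialects: marker map (name, position_bp); deletions (name, complex,
# min_start, min_end, max_start, max_end; 1-based inclusive); tests
# (mutation_id, deletion, outcome in {C,F}); genotypes (animal_id, alive,
# one column per marker with calls in {B,H,C,-}).


def read_marker_map(path: Union[str, Path]) -> list[Marker]:
    df = pd.read_csv(path, sep="\t")
    markers = [Marker(int(r.position_bp), str(r.name)) for r in df.itertuples(index=False)]
    return sorted(markers)


def read_deletions(path: Union[str, Path], chrom: str = "5") -> dict[str, Deletion]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, Deletion] = {}
    for r in df.itertuples(index=False):
        complex_name = getattr(r, "complex", None)
        out[str(r.name)] = Deletion(
            name=str(r.name),
            min_extent=GenomicInterval.from_1based(chrom, int(r.min_start), int(r.min_end)),
            max_extent=GenomicInterval.from_1based(chrom, int(r.max_start), int(r.max_end)),
            complex_name=None if complex_name is None else str(complex_name),
        )
    return out


def read_deletion_tests(path: Union[str, Path]) -> list[DeletionTest]:
    df = pd.read_csv(path, sep="\t")
    return [
        DeletionTest(str(r.mutation_id), str(r.deletion), TestOutcome.parse(str(r.outcome)))
        for r in df.itertuples(index=False)
    ]


def read_genotype_table(
    genotype_path: Union[str, Path],
    marker_map_path: Union[str, Path],
    chrom: str = "5",
) -> GenotypeTable:
    markers = read_marker_map(marker_map_path)
    df = pd.read_csv(genotype_path, sep="\t", dtype=str)
    marker_cols = list(df.columns[2:])
    by_name = {m.name: m for m in markers}
    missing = [c for c in marker_cols if c not in by_name]
    if missing:
        raise ValueError(f"genotype columns not in marker map: {missing}")
    ordered = sorted(marker_cols, key=lambda c: by_name[c].position)
    animals = []
    for _, row in df.iterrows():
        calls = tuple(GenotypeCall.parse(row[c]) for c in ordered)
        animals.append(
            AnimalRecord(str(row.iloc[0]), calls, alive=str(row.iloc[1]).strip() == "1")
        )
    return GenotypeTable([by_name[c] for c in ordered], animals, chrom=chrom)


def write_genotype_table(
    table: GenotypeTable,
    genotype_path: Union[str, Path],
    marker_map_path: Union[str, Path],
) -> None:
    pd.DataFrame(
        {"name": [m.name for m in table.markers],
         "position_bp": [m.position for m in table.markers]}
    ).to_csv(marker_map_path, sep="\t", index=False)
    rows = []
    for a in table.animals:
        rows.append(
            [a.animal_id, 1 if a.alive else 0] + [c.value for c in a.calls]
        )
    cols = ["animal_id", "alive"] + [m.name for m in table.markers]
    pd.DataFrame(rows, columns=cols).to_csv(genotype_path, sep="\t", index=False)
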