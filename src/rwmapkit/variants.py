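"""Candidate-variant filtering for positional cloning.

After capture sequencing of a mutant carrier and control DNAs, the
causative lesion is expected to be a heterozygous single-nucleotide change
unique to the mutant sample, lying inside the mutation's critical region,
and absent from known-variant catalogs (dbSNP-like).  This module applies
those four predicates to variant call tables, logging the failing
criterion for every rejected record, and triages re-sequenced sites into
mutation / strain SNP / suspected artifact.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pandas as pd

from .intervals import IntervalSet

__all__ = [
    "Zygosity",
    "VariantCall",
    "KnownVariantSet",
    "FilterResult",
    "SiteClass",
    "filter_candidates",
    "classify_putative",
    "read_variant_tsv",
    "write_variant_tsv",
    "read_vcf",
    "write_vcf",
    "read_known_variants",
    "write_known_variants",
]

logger = logging.getLogger(__name__)


class Zygosity(str, enum.Enum):
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    HOM_REF = "HOM_REF"


_BASES = set("ACGT")


@dataclass(frozen=True, order=True)
class VariantCall:
    """A single-sample variant call at a 1-based position."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    zygosity: Zygosity
    sample: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str]:
        """Cross-sample matching key: (chrom, pos, alt)."""
        return (self.chrom, self.pos, self.alt)


class KnownVariantSet:
    """Catalog of known variant sites keyed by (chrom, pos, alt)."""

    def __init__(self, entries: Iterable[tuple] = ()) -> None:
        self._ids: dict[tuple[str, int, str], Optional[str]] = {}
        for entry in entries:
            if len(entry) == 3:
                chrom, pos, alt = entry
                vid = None
            else:
                chrom, pos, alt, vid = entry
            self._ids[(str(chrom), int(pos), str(alt))] = vid

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return key in self._ids

    def __len__(self) -> int:
        return len(self._ids)

    def __iter__(self) -> Iterator[tuple[str, int, str]]:
        return iter(self._ids)

    def id_of(self, key: tuple[str, int, str]) -> Optional[str]:
        return self._ids.get(key)


@dataclass
class FilterResult:
    """Retained candidates plus a per-record rejection log."""

    retained: list[VariantCall]
    rejections: list[tuple[VariantCall, str]] = field(default_factory=list)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.retained)

    def __len__(self) -> int:
        return len(self.retained)


def filter_candidates(
    mutant: Sequence[VariantCall],
    controls: Sequence[Sequence[VariantCall]],
    critical: IntervalSet,
    known: Optional[KnownVariantSet] = None,
    allow_hom_alt: bool = False,
) -> FilterResult:
    """Reduce mutant-sample calls to candidate causative mutations.

    A call survives iff it is (i) heterozygous (``allow_hom_alt`` admits
    homozygous-alternate calls, for DNA from homozygous mutant embryos),
    (ii) positioned inside the critical region, (iii) absent — or called
    homozygous-reference — at the same (chrom, pos, alt) in every control
    sample, and (iv) not present in the known-variant catalog.  Output is
    sorted by position; every rejection is logged with its failing
    criterion.  Idempotent, and invariant to record and control order.
    """
    if critical.is_empty:
        raise ValueError("critical region is empty; nothing can be filtered against")
    known = known or KnownVariantSet()
    control_keys: set[tuple[str, int, str]] = set()
    for control in controls:
        for call in control:
            if call.zygosity is not Zygosity.HOM_REF:
                control_keys.add(call.key)

    allowed_zyg = {Zygosity.HET} | ({Zygosity.HOM_ALT} if allow_hom_alt else set())
    retained: list[VariantCall] = []
    rejections: list[tuple[VariantCall, str]] = []
    for call in mutant:
        if call.zygosity not in allowed_zyg:
            rejections.append((call, f"zygosity {call.zygosity.value} not admissible"))
        elif not (call.chrom == critical.chrom and critical.contains_1based(call.pos)):
            rejections.append((call, "outside critical region"))
        elif call.key in control_keys:
            rejections.append((call, "present in a control sample"))
        elif call.key in known:
            vid = known.id_of(call.key)
            rejections.append((call, f"known variant{f' ({vid})' if vid else ''}"))
        else:
            retained.append(call)
    retained.sort(key=lambda c: (c.chrom, c.pos, c.alt))
    for call, reason in rejections:
        logger.info("rejected %s:%s %s>%s — %s", call.chrom, call.pos, call.ref,
                    call.alt, reason)
    return FilterResult(retained=retained, rejections=rejections)


class SiteClass(str, enum.Enum):
    MUTATION = "MUTATION"
    STRAIN_SNP = "STRAIN_SNP"
    ARTIFACT_SUSPECT = "ARTIFACT_SUSPECT"


def classify_putative(
    site_calls: Sequence[VariantCall],
    mutant_samples: Iterable[str],
    replicates: Iterable[Iterable[str]] = (),
) -> SiteClass:
    """Resolve a re-sequenced site as mutation, strain SNP or artifact.

    ``site_calls`` are the calls observed at one site across samples;
    ``mutant_samples`` names the samples from the mutant lineage;
    ``replicates`` groups sample names that are repeat sequencings of the
    same DNA.  A variant seen in any non-mutagenized strain sample is a
    strain SNP; one that fails to replicate within a repeat-sequencing
    group is a suspected artifact; one confined to mutant-lineage samples
    (and replicating wherever repeated) is a mutation.
    """
    if not site_calls:
        raise ValueError("no calls at site")
    sites = {(c.chrom, c.pos) for c in site_calls}
    if len(sites) > 1:
        raise ValueError(f"calls at differing sites: {sorted(sites)}")
    mutant_samples = set(mutant_samples)
    present = {c.sample for c in site_calls if c.zygosity is not Zygosity.HOM_REF}
    if present - mutant_samples:
        return SiteClass.STRAIN_SNP
    for group in replicates:
        group = set(group)
        hit = present & group
        if hit and hit != group:
            return SiteClass.ARTIFACT_SUSPECT
    return SiteClass.MUTATION


# -- I/O -----------------------------------------------------------------


_TSV_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "zygosity"]


def read_variant_tsv(path: Union[str, Path]) -> list[VariantCall]:
    """Read the TSV variant dialect; malformed records warn and are skipped."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    calls: list[VariantCall] = []
    for i, row in df.iterrows():
        try:
            calls.append(
                VariantCall(
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]),
                    alt=str(row["alt"]),
                    zygosity=Zygosity(str(row["zygosity"]).upper()),
                    sample=str(row["sample"]),
                )
            )
        except (ValueError, KeyError) as exc:
            warnings.warn(f"{path}: skipping malformed record {i + 1}: {exc}")
    return calls


def write_variant_tsv(calls: Sequence[VariantCall], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [[c.sample, c.chrom, c.pos, c.ref, c.alt, c.zygosity.value] for c in calls],
        columns=_TSV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_vcf(path: Union[str, Path], sample: Optional[str] = None) -> list[VariantCall]:
    """Read a single-sample VCF; multi-allelic records are decomposed per alt.

    Genotypes are interpreted per alt allele: any het pattern involving the
    alt is HET, both alleles equal to it is HOM_ALT.
    """
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        name = sample or (samples[0] if samples else None)
        if name is None:
            raise ValueError(f"{path}: VCF has no sample column")
        for rec in vcf:
            gt = rec.samples[name].get("GT")
            if gt is None or all(a is None for a in gt):
                continue
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                n_alt = sum(1 for a in gt if a == alt_index)
                if n_alt == 0:
                    continue
                zyg = Zygosity.HOM_ALT if n_alt == len(gt) else Zygosity.HET
                calls.append(
                    VariantCall(
                        chrom=str(rec.chrom),
                        pos=int(rec.pos),
                        ref=str(rec.ref),
                        alt=str(alt),
                        zygosity=zyg,
                        sample=name,
                    )
                )
    return calls


def write_vcf(
    calls: Sequence[VariantCall],
    path: Union[str, Path],
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write calls for one sample as a minimal VCF 4.2 text file."""
    samples = {c.sample for c in calls}
    if len(samples) > 1:
        raise ValueError(f"one sample per VCF, got {sorted(samples)}")
    sample = samples.pop() if samples else "SAMPLE"
    contigs = contig_lengths or {}
    chroms = sorted({c.chrom for c in calls})
    gt = {Zygosity.HET: "0/1", Zygosity.HOM_ALT: "1/1", Zygosity.HOM_REF: "0/0"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chroms:
            length = contigs.get(chrom)
            if length:
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for c in sorted(calls):
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t.\tGT\t"
                f"{gt[c.zygosity]}\n"
            )


def read_known_variants(path: Union[str, Path]) -> KnownVariantSet:
    """Known variants TSV: chrom, pos, alt, optional id column."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    entries = []
    for _, row in df.iterrows():
        vid = row.get("id")
        entries.append((row["chrom"], int(row["pos"]), row["alt"],
                        None if pd.isna(vid) else str(vid)))
    return KnownVariantSet(entries)


def write_known_variants(known: KnownVariantSet, path: Union[str, Path]) -> None:
    rows = [[chrom, pos, alt, known.id_of((chrom, pos, alt)) or ""]
            for chrom, pos, alt in sorted(known)]
    pd.DataFrame(rows, columns=["chrom", "pos", "alt", "id"]).to_csv(
        path, sep="\t", index=False
    )
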