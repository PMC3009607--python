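"""Packaged study fixtures: the cloned-allele table, the noncomplementing
pairs identified by breeding, and the weanling counts of the Tapt1
deletion-allele complementation cross."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .allelism import ComplementationOutcome, ComplementationResult, CrossCounts

__all__ = [
    "load_allele_table",
    "load_noncomplementing_pairs",
    "load_tapt1_cross_counts",
]


def _data_path(name: str):
    return resources.files("rwmapkit.data").joinpath(name)


def load_allele_table() -> pd.DataFrame:
    """Cloned mutant alleles and their genes (columns: allele, gene).

    16 allele symbols over 13 genes.
    """
    with resources.as_file(_data_path("allele_table.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_noncomplementing_pairs() -> list[ComplementationResult]:
    """The four mutation pairs that failed to complement in breeding tests."""
    with resources.as_file(_data_path("noncomplementing_pairs.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return [
        ComplementationResult(
            str(r.mutation_a), str(r.mutation_b),
            ComplementationOutcome.parse(str(r.outcome)),
        )
        for r in df.itertuples(index=False)
    ]


def load_tapt1_cross_counts() -> CrossCounts:
    """Weanling counts of the Tapt1 knockout × L5Jcs1 balancer intercross:
    31 born, 21 balancer carriers weaned, no trans-heterozygotes, 10 dead
    before weaning."""
    with resources.as_file(_data_path("tapt1_l5jcs1_cross.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    r = df.iloc[0]
    return CrossCounts(
        weaned_non_balancer=int(r.weaned_non_balancer),
        weaned_balancer=int(r.weaned_balancer),
        born_total=int(r.born_total),
        died_pre_wean=int(r.died_pre_wean),
    )
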