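"""Complementation-test planning, allelic grouping and viability statistics.

Two recessive lethals with non-overlapping critical regions cannot be
alleles of the same gene (barring a gene spanning adjacent intervals), so
mapped intervals triage the quadratic space of pairwise complementation
crosses down to the co-localizing pairs that actually need breeding.
Mutations joined by failure-to-complement edges form allelic groups by
transitive closure.

For a cross of two balanced carriers (m1/Bal × m2/Bal) where the balancer
homozygote dies in utero, weaned offspring segregate 1 trans-heterozygote :
2 balancer carrier under the complementation null; departure is tested by
a Pearson chi-square on weaned counts (df = 1, no continuity correction).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence, Union

from scipy import stats

from .intervals import IntervalSet

__all__ = [
    "ComplementationOutcome",
    "ComplementationResult",
    "PairCategory",
    "PairClassification",
    "CrossCounts",
    "ChiSquareResult",
    "ComplementationContradictionError",
    "count_potential_tests",
    "plan_tests",
    "allelic_groups",
    "expected_weaned",
    "complementation_chisq",
    "chisq_sf",
]


class ComplementationContradictionError(ValueError):
    """A recorded failure to complement between mutations mapped to
    disjoint intervals — signals bad mapping or a bad test (or a gene
    spanning adjacent intervals)."""


class ComplementationOutcome(str, enum.Enum):
    COMPLEMENT = "C"
    FAIL = "F"
    UNTESTED = "U"

    @classmethod
    def parse(cls, token: str) -> "ComplementationOutcome":
        t = token.strip().upper()
        aliases = {"C": "C", "COMPLEMENT": "C", "F": "F", "FAIL": "F",
                   "U": "U", "UNTESTED": "U"}
        if t not in aliases:
            raise ValueError(f"unknown complementation outcome {token!r}")
        return cls(aliases[t])


def _pair_key(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self-pair {a!r}")
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ComplementationResult:
    """One pairwise cross outcome; the pair key is unordered."""

    mutation_a: str
    mutation_b: str
    outcome: ComplementationOutcome

    def __post_init__(self) -> None:
        _pair_key(self.mutation_a, self.mutation_b)  # validates a != b

    @property
    def pair(self) -> tuple[str, str]:
        return _pair_key(self.mutation_a, self.mutation_b)


class PairCategory(str, enum.Enum):
    DISJOINT_INFERRED_COMPLEMENT = "disjoint_inferred_complement"
    OVERLAP_UNTESTED = "overlap_untested"
    OVERLAP_COMPLEMENT = "overlap_complement"
    OVERLAP_FAIL = "overlap_fail"


@dataclass(frozen=True)
class PairClassification:
    pair: tuple[str, str]
    category: PairCategory


def count_potential_tests(n: int, ordered: bool = True) -> int:
    """Number of potential pairwise complementation tests among n mutations.

    Ordered counting (n(n−1), the default) counts each reciprocal cross
    separately; unordered counting gives n(n−1)/2 distinct pairs.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    return n * (n - 1) if ordered else n * (n - 1) // 2


def plan_tests(
    regions: Mapping[str, IntervalSet],
    results: Iterable[ComplementationResult] = (),
) -> list[PairClassification]:
    """Classify every unordered mutation pair by interval overlap and outcome.

    Pairs with disjoint regions are inferred to complement without breeding;
    a recorded COMPLEMENT for such a pair is consistent, while a recorded
    FAIL raises :class:`ComplementationContradictionError`.  Overlapping
    pairs carry their recorded outcome, or OVERLAP_UNTESTED.
    """
    recorded: dict[tuple[str, str], ComplementationOutcome] = {}
    for r in results:
        recorded[r.pair] = r.outcome
    unknown = [p for p in recorded if not set(p) <= set(regions)]
    if unknown:
        raise KeyError(f"results reference unmapped mutations: {sorted(unknown)}")
    ids = sorted(regions)
    out: list[PairClassification] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            pair = (a, b)
            outcome = recorded.get(pair, ComplementationOutcome.UNTESTED)
            if regions[a].intersect(regions[b]).is_empty:
                if outcome is ComplementationOutcome.FAIL:
                    raise ComplementationContradictionError(
                        f"{a} and {b} map to disjoint intervals but failed to "
                        f"complement: re-examine mapping or the test "
                        f"(or a gene spanning adjacent intervals)"
                    )
                category = PairCategory.DISJOINT_INFERRED_COMPLEMENT
            elif outcome is ComplementationOutcome.FAIL:
                category = PairCategory.OVERLAP_FAIL
            elif outcome is ComplementationOutcome.COMPLEMENT:
                category = PairCategory.OVERLAP_COMPLEMENT
            else:
                category = PairCategory.OVERLAP_UNTESTED
            out.append(PairClassification(pair, category))
    return out


def allelic_groups(
    results: Iterable[ComplementationResult],
    include_singletons: bool = False,
) -> list[list[str]]:
    """Partition mutations into allelic classes by failure-to-complement.

    Groups are connected components over FAIL edges (allelism is treated as
    transitive).  By default only multi-member groups are returned, sorted
    by their smallest member id; ``include_singletons`` adds mutations seen
    only in complementing/untested records as one-member groups.
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def add(x: str) -> None:
        parent.setdefault(x, x)

    for r in results:
        a, b = r.pair
        add(a)
        add(b)
        if r.outcome is ComplementationOutcome.FAIL:
            parent[find(a)] = find(b)

    components: dict[str, list[str]] = {}
    for x in parent:
        components.setdefault(find(x), []).append(x)
    groups = [sorted(g) for g in components.values()]
    if not include_singletons:
        groups = [g for g in groups if len(g) > 1]
    return sorted(groups, key=lambda g: g[0])


@dataclass(frozen=True)
class CrossCounts:
    """Weanling counts from an m1/Bal × m2/Bal intercross."""

    weaned_non_balancer: int
    weaned_balancer: int
    born_total: Optional[int] = None
    died_pre_wean: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("weaned_non_balancer", "weaned_balancer", "born_total",
                     "died_pre_wean"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.born_total is not None:
            died = self.died_pre_wean or 0
            if self.born_total != self.weaned_balancer + self.weaned_non_balancer + died:
                raise ValueError("born_total != weaned + died_pre_wean")

    @property
    def total_weaned(self) -> int:
        return self.weaned_non_balancer + self.weaned_balancer


def expected_weaned(total_weaned: int) -> tuple[Fraction, Fraction]:
    """Expected (non-balancer, balancer) weanlings under the complementation null.

    With the balancer homozygote lost in utero, survivors to weaning are
    1/3 trans-heterozygote : 2/3 balancer carrier; returned as exact
    rationals before any rounding (21 weaned → 7 and 14).
    """
    if total_weaned < 0:
        raise ValueError("total_weaned must be >= 0")
    return Fraction(total_weaned, 3), Fraction(2 * total_weaned, 3)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    pvalue: float
    df: int = 1


def complementation_chisq(observed: Union[CrossCounts, tuple]) -> ChiSquareResult:
    """Pearson chi-square of weaned counts against the 1:2 null (df = 1).

    No continuity correction is applied.  A complete absence of
    trans-heterozygotes among 21 weanlings gives chi2 = 10.5, p ≈ 0.0012.
    """
    if not isinstance(observed, CrossCounts):
        observed = CrossCounts(*observed)
    total = observed.total_weaned
    if total <= 0:
        raise ValueError("total weaned must be > 0 for a chi-square test")
    e_non, e_bal = (float(x) for x in expected_weaned(total))
    chi2 = (
        (observed.weaned_non_balancer - e_non) ** 2 / e_non
        + (observed.weaned_balancer - e_bal) ** 2 / e_bal
    )
    return ChiSquareResult(statistic=chi2, pvalue=chisq_sf(chi2, 1), df=1)


def chisq_sf(x: float, df: int = 1) -> float:
    """Upper-tail probability P(X >= x) of a chi-squared variable."""
    if df < 1 or int(df) != df:
        raise ValueError("df must be a positive integer")
    if x < 0:
        raise ValueError("x must be >= 0")
    return float(stats.chi2.sf(x, df))
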