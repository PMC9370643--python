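"""Set algebra over DET results: Venn partitioning, same-direction
intersections between colonized and bacteria-free datasets, and the
percentage arithmetic used in summary tables."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .det import Call
from .errors import DomainError, SpecificationError

MAX_VENN_SETS = 6  # combinatorial regions are capped at 2^6 - 1


@dataclass(frozen=True)
class DirectionalSet:
    """A labelled DET set with one direction (UP_A / UP_B) per transcript."""

    label: str
    members: Mapping[str, Call]

    def __post_init__(self) -> None:
        for t, d in self.members.items():
            if d not in (Call.UP_A, Call.UP_B):
                raise SpecificationError(f"{self.label}: {t} has non-directional call {d}")

    @property
    def transcript_ids(self) -> frozenset[str]:
        return frozenset(self.members)

    @classmethod
    def from_det_table(cls, table) -> "DirectionalSet":
        called = table.called
        return cls(
            label=table.comparison.label,
            members={t: Call(c) for t, c in called["call"].items()},
        )


def venn_partition(
    sets: Sequence[DirectionalSet], ignore_direction: bool = True
) -> dict[frozenset[str], set]:
    """Partition the union of 2-6 sets into disjoint Venn regions.

    Keys are the region signatures (frozenset of set labels); every nonempty
    signature is present, empty regions included as empty sets.  With
    ``ignore_direction`` (the default, matching transcript-level Venn
    counts) members are transcript ids; otherwise (transcript, direction)
    pairs, so a transcript called in opposite directions in two comparisons
    lands in two regions.
    """
    if not 2 <= len(sets) <= MAX_VENN_SETS:
        raise SpecificationError(f"venn_partition takes 2-{MAX_VENN_SETS} sets, got {len(sets)}")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise SpecificationError(f"duplicate set labels: {labels}")

    membership: dict = {}
    for s in sets:
        for t, d in s.members.items():
            key = t if ignore_direction else (t, d)
            membership.setdefault(key, set()).add(s.label)

    from itertools import combinations

    regions: dict[frozenset[str], set] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            regions[frozenset(combo)] = set()
    for key, sig in membership.items():
        regions[frozenset(sig)].add(key)
    return regions


def region_counts(partition: Mapping[frozenset[str], set]) -> dict[frozenset[str], int]:
    return {sig: len(members) for sig, members in partition.items()}


def common_pattern(
    colonized: DirectionalSet, bacteria_free: DirectionalSet
) -> set[tuple[str, Call]]:
    """Transcripts with the same direction of differential expression in the
    naturally colonized (stalk) and bacteria-free (hydroponic) datasets.

    A transcript present in both sets but with opposite directions is
    excluded; such genes respond to colonization, not to genotype.
    """
    out = set()
    for t, d in colonized.members.items():
        if bacteria_free.members.get(t) == d:
            out.add((t, d))
    return out


def mapping_percentage(numerator: int, denominator: int, decimals: int = 2) -> float:
    """100 * numerator / denominator, half-up rounded to ``decimals``."""
    if denominator < 1:
        raise DomainError("denominator must be >= 1")
    if numerator < 0:
        raise DomainError("numerator must be >= 0")
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))
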