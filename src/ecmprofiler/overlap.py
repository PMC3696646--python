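"""Multi-set overlap cardinalities and shared-protein statistics between ECMs.

Euler-diagram style reporting: for k protein sets (k <= 5), the count of
proteins lying in exactly each non-empty subset of samples, plus pairwise
shared counts. `shared_with_reference` reproduces the sharing statistics
quoted for the hESC-derived ECM against the feeder ECMs: shared counts,
percentages of the reference detected set, and their mean +/- sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .matrix import AbundanceMatrix

__all__ = ["OverlapReport", "euler_cardinalities", "SharedReport", "shared_with_reference"]

MAX_SETS = 5


@dataclass
class OverlapReport:
    """Exclusive-region cardinalities over a family of protein sets.

    ``region_cardinalities`` maps each non-empty frozenset of sample names to
    the number of proteins lying in exactly those samples' sets (and no
    others); the counts therefore sum to the size of the union.
    """

    sets: dict[str, frozenset[str]]
    region_cardinalities: dict[frozenset[str], int]
    pairwise_shared: dict[tuple[str, str], int] = field(default_factory=dict)

    def region(self, *samples: str) -> int:
        return self.region_cardinalities.get(frozenset(samples), 0)


def euler_cardinalities(sets: Mapping[str, Iterable[str]]) -> OverlapReport:
    """Exact exclusive-region counts for all 2^k - 1 regions of k sets.

    Guarded at k <= 5 (the region count doubles with every extra set).
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    if len(sets) > MAX_SETS:
        raise ValueError(f"at most {MAX_SETS} sets supported, got {len(sets)}")
    frozen = {name: frozenset(s) for name, s in sets.items()}
    union = frozenset().union(*frozen.values())

    regions: dict[frozenset[str], int] = {}
    for element in union:
        signature = frozenset(name for name, s in frozen.items() if element in s)
        regions[signature] = regions.get(signature, 0) + 1

    pairwise = {}
    for a, b in combinations(frozen, 2):
        n = len(frozen[a] & frozen[b])
        pairwise[(a, b)] = n
        pairwise[(b, a)] = n
    return OverlapReport(frozen, regions, pairwise)


@dataclass
class SharedReport:
    """Sharing of a reference sample's detected proteins with other samples."""

    reference: str
    reference_size: int
    counts: dict[str, int]
    percentages: dict[str, float]
    mean_count: float
    sd_count: float
    mean_percentage: float
    sd_percentage: float
    shared_proteins: dict[str, frozenset[str]]


def shared_with_reference(
    matrix: AbundanceMatrix,
    reference: str,
    others: Sequence[str],
    proteins: Iterable[str] | None = None,
) -> SharedReport:
    """Count reference-detected proteins shared with each other sample.

    ``proteins`` optionally restricts the universe first (e.g. to proteins
    classified extracellular/cell surface). Detection means acceptance in at
    least one replicate, i.e. the matrix detection mask — not any abundance
    threshold. Mean and SD over ``others`` use the n-1 sample formula.
    """
    sub = matrix if proteins is None else matrix.subset(proteins=list(proteins))
    ref_set = sub.detected_in(reference)
    if not ref_set:
        raise ValueError(f"reference sample {reference!r} has no detected proteins")

    shared = {s: ref_set & sub.detected_in(s) for s in others}
    counts = {s: len(v) for s, v in shared.items()}
    pct = {s: 100.0 * c / len(ref_set) for s, c in counts.items()}
    cvals = np.array(list(counts.values()), dtype=float)
    pvals = np.array(list(pct.values()), dtype=float)
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0  # noqa: E731
    return SharedReport(
        reference=reference,
        reference_size=len(ref_set),
        counts=counts,
        percentages=pct,
        mean_count=float(cvals.mean()),
        sd_count=sd(cvals),
        mean_percentage=float(pvals.mean()),
        sd_percentage=sd(pvals),
        shared_proteins={s: frozenset(v) for s, v in shared.items()},
    )
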