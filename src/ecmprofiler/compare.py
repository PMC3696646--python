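"""Supportive-vs-unsupportive differential comparison of ECM compositions.

The headline question: which proteins distinguish matrices that maintain
hESC self-renewal from those that do not? The report separates

* proteins unique to one side — detected in every sample of that group (by
  default; configurable to "any") and in no sample of the other, and
* proteins detected on both sides but enriched in the supportive group beyond
  a fold threshold (default: strictly greater than 2-fold on group means),

and ranks candidate substrates deterministically by (uniqueness, fold,
interactome hub degree).

When the abundance values come from a printed table they carry limited
precision. ``input_sig_figs`` gives the threshold test rounding-interval
semantics: a protein passes when the upper bound of its ratio over the
half-ulp rounding intervals of numerator and denominator exceeds the
threshold. With 3 significant figures this admits a ratio printed as
49.7/24.9 (upper bound 49.75/24.85 = 2.002), consistent with the >2-fold
calls made on the unrounded source data behind such tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .matrix import AbundanceMatrix
from .quantify import round_half_ulp

__all__ = ["ComparisonReport", "differential_report"]


@dataclass
class ComparisonReport:
    supportive_samples: list[str]
    unsupportive_samples: list[str]
    unique_to_supportive: frozenset[str]
    unique_to_unsupportive: frozenset[str]
    enriched_in_supportive: list[tuple[str, float]]  # (protein, fold), fold descending
    candidate_ranking: list[str]
    fold_threshold: float = 2.0
    detection_mode: str = "all"
    means_supportive: dict[str, float] = field(default_factory=dict)
    means_unsupportive: dict[str, float] = field(default_factory=dict)

    @property
    def enriched_proteins(self) -> frozenset[str]:
        return frozenset(p for p, _ in self.enriched_in_supportive)


def _group_detected(matrix: AbundanceMatrix, protein: str, samples: Sequence[str], mode: str) -> bool:
    flags = [matrix.is_detected(protein, s) for s in samples]
    return all(flags) if mode == "all" else any(flags)


def differential_report(
    matrix: AbundanceMatrix,
    supportive: Sequence[str],
    unsupportive: Sequence[str],
    proteins: Iterable[str] | None = None,
    fold_threshold: float = 2.0,
    detection_mode: str = "all",
    input_sig_figs: int | None = None,
    hub_degree: Mapping[str, int] | None = None,
) -> ComparisonReport:
    """Differential composition report between two sample groups.

    ``proteins`` restricts the universe first (e.g. to extracellular/cell
    surface classified proteins). ``detection_mode`` ("all" or "any") sets how
    group-level detection is defined. Fold = mean over supportive samples /
    mean over unsupportive samples; the threshold test is strict ``>``, with
    rounding-interval semantics when ``input_sig_figs`` is given (see module
    docstring). ``hub_degree`` feeds the candidate ranking's final tie-break.
    """
    if set(supportive) & set(unsupportive):
        raise ValueError("supportive and unsupportive sample lists overlap")
    if not supportive or not unsupportive:
        raise ValueError("both sample groups must be non-empty")
    if detection_mode not in {"all", "any"}:
        raise ValueError("detection_mode must be 'all' or 'any'")
    sub = matrix.subset(
        proteins=None if proteins is None else list(proteins),
        samples=list(supportive) + list(unsupportive),
    )

    unique_sup: set[str] = set()
    unique_unsup: set[str] = set()
    enriched: list[tuple[str, float]] = []
    means_sup: dict[str, float] = {}
    means_unsup: dict[str, float] = {}
    for protein in sub.proteins:
        in_sup = _group_detected(sub, protein, supportive, detection_mode)
        any_sup = _group_detected(sub, protein, supportive, "any")
        in_unsup = _group_detected(sub, protein, unsupportive, detection_mode)
        any_unsup = _group_detected(sub, protein, unsupportive, "any")
        m_sup = sum(sub.value(protein, s) for s in supportive) / len(supportive)
        m_unsup = sum(sub.value(protein, s) for s in unsupportive) / len(unsupportive)
        means_sup[protein], means_unsup[protein] = m_sup, m_unsup
        if in_sup and not any_unsup:
            unique_sup.add(protein)
        elif in_unsup and not any_sup:
            unique_unsup.add(protein)
        elif in_sup and in_unsup:
            fold = m_sup / m_unsup
            if _exceeds(m_sup, m_unsup, fold_threshold, input_sig_figs):
                enriched.append((protein, fold))
    enriched.sort(key=lambda pf: (-pf[1], pf[0]))

    deg = hub_degree or {}
    pool = sorted(unique_sup) + [p for p, _ in enriched]
    ranking = sorted(
        pool,
        key=lambda p: (
            p not in unique_sup,
            -(float("inf") if p in unique_sup else dict(enriched)[p]),
            -deg.get(p, 0),
            p,
        ),
    )
    return ComparisonReport(
        list(supportive),
        list(unsupportive),
        frozenset(unique_sup),
        frozenset(unique_unsup),
        enriched,
        ranking,
        fold_threshold,
        detection_mode,
        means_sup,
        means_unsup,
    )


def _exceeds(num: float, den: float, threshold: float, sig_figs: int | None) -> bool:
    """Strict fold-threshold test, optionally on the rounding-interval upper bound."""
    if sig_figs is None:
        return num / den > threshold
    hi = (num + round_half_ulp(num, sig_figs)) / (den - round_half_ulp(den, sig_figs))
    return hi > threshold
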