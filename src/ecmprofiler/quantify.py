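"""Spectral-count quantification: normalization, replicate averaging, folds.

Relative abundance is quantified by unweighted spectrum counting. Within one
replicate, each accepted protein's spectrum count is expressed as a percentage
of the total accepted (target, non-decoy) spectra in that replicate, reported
in units of % x 10^3, so a replicate's normalized counts sum to 100,000.
Sample-level values are arithmetic means over replicates, with 0 contributed
by replicates in which the protein was not accepted; a protein counts as
detected in a sample when it was accepted in at least one replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import IdentificationRecord
from .matrix import AbundanceMatrix

__all__ = [
    "SCALE",
    "normalize_counts",
    "mean_over_replicates",
    "build_abundance_matrix",
    "FoldEnrichment",
    "fold_enrichment",
]

#: Unit scale: percentages are multiplied by 10^3 ("% total spectra x 10^3").
SCALE = 100.0 * 1_000.0


def normalize_counts(records: Sequence[IdentificationRecord]) -> dict[str, float]:
    """Normalize one replicate's accepted spectrum counts to % x 10^3.

    The denominator is the total spectrum count of accepted *target* records;
    decoys are validation artifacts, not sample content, and are excluded.
    Records must all come from a single (sample, replicate).
    """
    targets = [r for r in records if not r.is_decoy]
    keys = {(r.sample_id, r.replicate_id) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple replicates: {sorted(keys)}")
    total = sum(r.spectrum_count for r in targets)
    if total == 0:
        raise ValueError("total spectrum count is zero; cannot normalize")
    out: dict[str, float] = {}
    for r in targets:
        out[r.gene_symbol] = out.get(r.gene_symbol, 0.0) + r.spectrum_count / total * SCALE
    return out


def mean_over_replicates(
    replicate_vectors: Sequence[Mapping[str, float]],
) -> tuple[dict[str, float], dict[str, bool]]:
    """Average normalized replicate vectors into one sample column.

    A protein missing from a replicate contributes 0 to the mean (zero-fill);
    it is flagged detected when present in at least one replicate.
    """
    if not replicate_vectors:
        raise ValueError("need at least one replicate")
    n = len(replicate_vectors)
    proteins = sorted({p for vec in replicate_vectors for p in vec})
    values = {p: sum(vec.get(p, 0.0) for vec in replicate_vectors) / n for p in proteins}
    detected = {p: any(p in vec for vec in replicate_vectors) for p in proteins}
    return values, detected


def build_abundance_matrix(accepted: Iterable[IdentificationRecord]) -> AbundanceMatrix:
    """Build the protein x sample matrix from accepted records of all samples.

    Proteins are keyed by gene symbol (the join key used throughout the
    downstream annotation and network stages); samples are ordered by first
    appearance in the record stream.
    """
    by_sample: dict[str, dict[str, list[IdentificationRecord]]] = {}
    for rec in accepted:
        by_sample.setdefault(rec.sample_id, {}).setdefault(rec.replicate_id, []).append(rec)
    if not by_sample:
        raise ValueError("no accepted records")

    columns: dict[str, dict[str, float]] = {}
    det_cols: dict[str, dict[str, bool]] = {}
    for sample, reps in by_sample.items():
        vectors = [normalize_counts(recs) for _, recs in sorted(reps.items())]
        columns[sample], det_cols[sample] = mean_over_replicates(vectors)

    proteins = sorted({p for col in columns.values() for p in col})
    samples = list(by_sample)
    values = pd.DataFrame(
        {s: [columns[s].get(p, 0.0) for p in proteins] for s in samples}, index=proteins
    )
    detected = pd.DataFrame(
        {s: [det_cols[s].get(p, False) for p in proteins] for s in samples}, index=proteins
    )
    return AbundanceMatrix(values, detected)


@dataclass(frozen=True)
class FoldEnrichment:
    """Abundance ratio of one protein between two samples.

    ``ratio`` is defined only when the protein is detected in both samples;
    otherwise the status flags which side (if either) detected it.
    """

    protein: str
    numerator_sample: str
    denominator_sample: str
    ratio: float | None
    status: str  # both_detected | unique_to_numerator | unique_to_denominator | absent

    def __post_init__(self) -> None:
        if (self.status == "both_detected") != (self.ratio is not None):
            raise ValueError("ratio must be present exactly when both samples detect the protein")


def fold_enrichment(matrix: AbundanceMatrix, protein: str, a: str, b: str) -> FoldEnrichment:
    """Fold enrichment of ``protein`` in sample ``a`` over sample ``b``."""
    if protein not in matrix.values.index:
        raise KeyError(f"unknown protein {protein!r}")
    for s in (a, b):
        if s not in matrix.values.columns:
            raise KeyError(f"unknown sample {s!r}")
    in_a, in_b = matrix.is_detected(protein, a), matrix.is_detected(protein, b)
    if in_a and in_b:
        ratio = matrix.value(protein, a) / matrix.value(protein, b)
        status = "both_detected"
    elif in_a:
        ratio, status = None, "unique_to_numerator"
    elif in_b:
        ratio, status = None, "unique_to_denominator"
    else:
        ratio, status = None, "absent"
    return FoldEnrichment(protein, a, b, ratio, status)


def round_half_ulp(value: float, sig_figs: int) -> float:
    """Half of the last-digit spacing of ``value`` printed to ``sig_figs`` digits.

    Used to give rounding-interval semantics to thresholds applied to data
    transcribed from a printed table (see :mod:`ecmprofiler.compare`).
    """
    if value <= 0:
        raise ValueError("value must be positive")
    exponent = math.floor(math.log10(value)) - (sig_figs - 1)
    return 0.5 * 10.0**exponent
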