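"""Identification acceptance criteria and decoy-based protein FDR.

A protein identification in one sample replicate is accepted when it carries
at least ``min_unique_peptides`` unique validated peptides and a protein
probability of at least ``min_protein_probability``. Both comparisons are
closed (>=), exactly as the criteria are worded. Unique-peptide counts are
taken as already filtered at the peptide-probability threshold, which is kept
in the policy for provenance. The protein-level false discovery rate is
estimated from the decoy entries surviving acceptance:

    FDR% = 100 * (accepted decoys) / (accepted targets)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import IdentificationRecord

__all__ = ["ValidationPolicy", "Rejection", "accept", "estimate_protein_fdr", "UndefinedFDRError"]

logger = logging.getLogger(__name__)


class UndefinedFDRError(ValueError):
    """Raised when no accepted target proteins exist to form the FDR ratio."""


@dataclass(frozen=True)
class ValidationPolicy:
    """Acceptance thresholds for protein identifications.

    Defaults: >=2 unique peptides (each established with >=90% probability)
    and >=99% protein probability.
    """

    min_unique_peptides: int = 2
    min_peptide_probability: float = 0.90
    min_protein_probability: float = 0.99

    def __post_init__(self) -> None:
        if self.min_unique_peptides < 1:
            raise ValueError("min_unique_peptides must be >= 1")
        for name in ("min_peptide_probability", "min_protein_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")


@dataclass(frozen=True)
class Rejection:
    record: IdentificationRecord
    reason: str  # "peptides" or "protein_probability"


def accept(
    records: Iterable[IdentificationRecord], policy: ValidationPolicy | None = None
) -> tuple[list[IdentificationRecord], list[Rejection]]:
    """Partition records into accepted identifications and a rejection log.

    Acceptance is evaluated per record, i.e. per (sample, replicate,
    accession): a protein may pass in one replicate and fail in another. The
    rejection reason names the first failed criterion (peptide count checked
    before protein probability).
    """
    policy = policy or ValidationPolicy()
    accepted: list[IdentificationRecord] = []
    rejected: list[Rejection] = []
    records = list(records)
    if not records:
        logger.warning("accept() called with no records")
    for rec in records:
        if rec.n_unique_peptides < policy.min_unique_peptides:
            rejected.append(Rejection(rec, "peptides"))
        elif rec.protein_probability < policy.min_protein_probability:
            rejected.append(Rejection(rec, "protein_probability"))
        else:
            accepted.append(rec)
    return accepted, rejected


def estimate_protein_fdr(accepted: Sequence[IdentificationRecord]) -> float:
    """Protein-level FDR, in percent, from decoy entries in an accepted set."""
    n_decoy = sum(1 for r in accepted if r.is_decoy)
    n_target = sum(1 for r in accepted if not r.is_decoy)
    if n_target == 0:
        raise UndefinedFDRError("no accepted target proteins; FDR undefined")
    return 100.0 * n_decoy / n_target


def write_rejection_log(rejections: Sequence[Rejection], path) -> None:
    """Write the rejection log as TSV (record key + failed criterion)."""
    import pandas as pd

    rows = [
        {
            "sample_id": r.record.sample_id,
            "replicate_id": r.record.replicate_id,
            "accession": r.record.accession,
            "gene_symbol": r.record.gene_symbol,
            "reason": r.reason,
        }
        for r in rejections
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "replicate_id", "accession", "gene_symbol", "reason"]
    ).to_csv(path, sep="\t", index=False)
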