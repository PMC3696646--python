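"""Protein x sample abundance matrix of mean normalized spectrum counts.

Values are mean normalized spectrum counts in units of "% total spectra x 10^3":
a protein contributing 5% of the accepted spectra of a replicate has value 50,000
before averaging. A parallel boolean mask records detection (acceptance in at
least one replicate of the sample); non-detected cells always hold 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AbundanceMatrix"]


@dataclass
class AbundanceMatrix:
    """Mean normalized spectrum counts (proteins x samples) with detection mask.

    Parameters
    ----------
    values
        Float frame indexed by protein symbol with one column per sample.
        Unit: percentage of total accepted spectra x 10^3.
    detected
        Boolean frame of the same shape; ``False`` cells must hold value 0.
    protein_meta
        Optional per-protein metadata (e.g. full protein name, accession,
        ``reference_only`` flags), indexed like ``values``.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    protein_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.detected = self.detected.astype(bool)
        if not self.values.index.equals(self.detected.index) or not self.values.columns.equals(
            self.detected.columns
        ):
            raise ValueError("values and detected must share index and columns")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance values must be non-negative")
        masked = self.values.to_numpy()[~self.detected.to_numpy()]
        if masked.size and not np.allclose(masked, 0.0):
            raise ValueError("non-detected cells must hold value 0")
        if self.protein_meta is not None and not self.protein_meta.index.equals(self.values.index):
            raise ValueError("protein_meta index must match values index")

    # -- accessors ---------------------------------------------------------

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def value(self, protein: str, sample: str) -> float:
        """Mean normalized spectrum count of one cell."""
        return float(self.values.at[protein, sample])

    def is_detected(self, protein: str, sample: str) -> bool:
        return bool(self.detected.at[protein, sample])

    def detected_in(self, sample: str) -> frozenset[str]:
        """Set of proteins detected (accepted in >=1 replicate) in a sample."""
        mask = self.detected[sample]
        return frozenset(mask.index[mask])

    def subset(
        self, proteins: list[str] | None = None, samples: list[str] | None = None
    ) -> "AbundanceMatrix":
        idx = self.values.index if proteins is None else pd.Index(proteins)
        missing = idx.difference(self.values.index)
        if len(missing):
            raise KeyError(f"unknown proteins: {sorted(missing)}")
        cols = self.values.columns if samples is None else pd.Index(samples)
        missing = cols.difference(self.values.columns)
        if len(missing):
            raise KeyError(f"unknown samples: {sorted(missing)}")
        meta = None if self.protein_meta is None else self.protein_meta.loc[idx]
        return AbundanceMatrix(self.values.loc[idx, cols], self.detected.loc[idx, cols], meta)

    # -- round-trip --------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write matrix with non-detected cells left empty (Table-style layout)."""
        out = self.values.astype(object).where(self.detected, "")
        out.to_csv(path, index_label="gene_symbol")

    @classmethod
    def from_csv(cls, path) -> "AbundanceMatrix":
        raw = pd.read_csv(path, index_col="gene_symbol")
        detected = raw.notna()
        values = raw.fillna(0.0).astype(float)
        return cls(values, detected)
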