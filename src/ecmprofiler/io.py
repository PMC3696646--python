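"""Readers and writers for the flat-file dialects the pipeline exchanges.

All formats are strict tab-separated text with fixed headers: protein
identification reports (one row per protein per sample replicate), GO
annotation tables, ontology parent-edge tables (or an OBO subset), interactome
edge lists and mouse-to-human ortholog maps. A packaged fixture encodes the
printed comparison table of extracellular proteins detected in hESC (HUES1)
ECM versus mouse and human feeder-cell ECMs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .matrix import AbundanceMatrix

__all__ = [
    "IdentificationRecord",
    "ReportFormatError",
    "read_identification_report",
    "write_identification_report",
    "read_edge_list",
    "read_ortholog_map",
    "read_annotations",
    "read_ontology_table",
    "load_table1_fixture",
    "load_table1_annotations",
    "TABLE1_SAMPLES",
]

#: Sample order of the packaged comparison table: four MEF-derived ECMs
#: (two strains x two passages), primary and immortalized human placental
#: stromal fibroblasts, and the HUES1 hESC line grown feeder-free.
TABLE1_SAMPLES = ["CD1 P4", "CD1 P9", "MF1xCD1 P4", "MF1xCD1 P9", "hPSF", "ihPSF", "HUES1"]

REPORT_COLUMNS = [
    "sample_id",
    "replicate_id",
    "accession",
    "gene_symbol",
    "species",
    "n_unique_peptides",
    "protein_probability",
    "spectrum_count",
    "is_decoy",
]

_SPECIES = {"human", "mouse"}
_BOOL = {"true": True, "false": False, "1": True, "0": False}


class ReportFormatError(ValueError):
    """Header or structural problem in an input table."""


@dataclass(frozen=True)
class IdentificationRecord:
    """One protein observation in one sample replicate.

    ``n_unique_peptides`` counts unique peptides already filtered at the
    peptide-probability threshold; ``spectrum_count`` is the unweighted number
    of MS/MS spectra assigned to the protein; ``is_decoy`` marks reversed or
    shuffled database entries used for FDR estimation.
    """

    sample_id: str
    replicate_id: str
    accession: str
    gene_symbol: str
    species: str
    n_unique_peptides: int
    protein_probability: float
    spectrum_count: int
    is_decoy: bool

    def __post_init__(self) -> None:
        if self.species not in _SPECIES:
            raise ValueError(f"species must be one of {sorted(_SPECIES)}, got {self.species!r}")
        if not 0.0 <= self.protein_probability <= 1.0:
            raise ValueError(f"protein_probability outside [0,1]: {self.protein_probability}")
        if self.n_unique_peptides < 0 or self.spectrum_count < 0:
            raise ValueError("counts must be non-negative")


def _check_header(actual: list[str], expected: list[str], path) -> None:
    missing = [c for c in expected if c not in actual]
    extra = [c for c in actual if c not in expected]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing column(s) {missing}")
        if extra:
            parts.append(f"unexpected column(s) {extra}")
        raise ReportFormatError(f"{path}: {'; '.join(parts)}")


def read_identification_report(path) -> list[IdentificationRecord]:
    """Read a strict-TSV identification report, preserving row order.

    Raises
    ------
    ReportFormatError
        On a wrong header or duplicated (sample, replicate, accession) keys.
    ValueError
        On unparsable or out-of-range fields; the message carries the
        1-based file line number.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _check_header(list(raw.columns), REPORT_COLUMNS, path)

    records: list[IdentificationRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for i, row in enumerate(raw.itertuples(index=False)):
        line = i + 2  # 1-based, after header
        try:
            rec = IdentificationRecord(
                sample_id=row.sample_id.strip(),
                replicate_id=row.replicate_id.strip(),
                accession=row.accession.strip(),
                gene_symbol=row.gene_symbol.strip(),
                species=row.species.strip().lower(),
                n_unique_peptides=int(row.n_unique_peptides),
                protein_probability=float(row.protein_probability),
                spectrum_count=int(row.spectrum_count),
                is_decoy=_BOOL[row.is_decoy.strip().lower()],
            )
        except KeyError as exc:
            raise ValueError(f"{path}:{line}: bad boolean {exc.args[0]!r} in is_decoy") from exc
        except ValueError as exc:
            raise ValueError(f"{path}:{line}: {exc}") from exc
        key = (rec.sample_id, rec.replicate_id, rec.accession)
        if key in seen:
            raise ReportFormatError(f"{path}:{line}: duplicate record key {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_identification_report(records: Iterable[IdentificationRecord], path) -> None:
    """Write records in the same dialect ``read_identification_report`` reads."""
    rows = [
        {
            **{c: getattr(r, c) for c in REPORT_COLUMNS[:-1]},
            "is_decoy": "true" if r.is_decoy else "false",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def _read_two_col(path, columns: list[str], optional: list[str]) -> pd.DataFrame:
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in raw.columns]
    extra = [c for c in raw.columns if c not in columns + optional]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing column(s) {missing}")
        if extra:
            parts.append(f"unexpected column(s) {extra}")
        raise ReportFormatError(f"{path}: {'; '.join(parts)}")
    for col in raw.columns:
        raw[col] = raw[col].str.strip()
    blank = raw[columns].eq("").any(axis=1)
    if blank.any():
        line = int(blank.idxmax()) + 2
        raise ValueError(f"{path}:{line}: blank identifier")
    return raw


def read_edge_list(path) -> pd.DataFrame:
    """Read an interactome edge list: columns a, b (+ optional source).

    Duplicate and reversed rows are kept verbatim; de-duplication is the
    network-merging step's job. A missing source column is filled with the
    file stem.
    """
    df = _read_two_col(path, ["a", "b"], ["source"])
    if "source" not in df.columns:
        df["source"] = Path(path).stem
    return df[["a", "b", "source"]]


def read_ortholog_map(path) -> dict[str, str]:
    """Read a mouse->human ortholog table (columns mouse_symbol, human_symbol)."""
    df = _read_two_col(path, ["mouse_symbol", "human_symbol"], [])
    selfref = df["mouse_symbol"] == df["human_symbol"]
    if selfref.any():
        line = int(selfref.idxmax()) + 2
        raise ValueError(f"{path}:{line}: self-referential ortholog row")
    return dict(zip(df["mouse_symbol"], df["human_symbol"]))


def read_annotations(path) -> pd.DataFrame:
    """Read a GO annotation table: columns gene_symbol, go_id (+ optional evidence)."""
    df = _read_two_col(path, ["gene_symbol", "go_id"], ["evidence"])
    if "evidence" not in df.columns:
        df["evidence"] = ""
    return df[["gene_symbol", "go_id", "evidence"]]


def read_ontology_table(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read ontology is_a/part_of edges from a 2-col TSV (child, parent [, name]).

    Returns (parents-by-term, name-by-term). Acyclicity is validated by the
    :class:`~ecmprofiler.annotate.Ontology` constructor, not here.
    """
    df = _read_two_col(path, ["child", "parent"], ["name"])
    parents: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        parents.setdefault(row.child, set()).add(row.parent)
        parents.setdefault(row.parent, set())
        if "name" in df.columns and row.name:
            names[row.child] = row.name
    return parents, names


# -- packaged fixture ------------------------------------------------------


def _data_path(name: str):
    return importlib.resources.files("ecmprofiler.data") / name


def load_table1_fixture() -> AbundanceMatrix:
    """Load the packaged printed comparison table of extracellular proteins.

    Seven samples (four MEF ECMs, hPSF, ihPSF, HUES1); 35 rows detected in
    HUES1 ECM plus 7 additional collagen-chain rows listed for reference only
    (absent from HUES1 ECM), flagged ``not_in_HUES1`` in ``protein_meta``.
    ND cells load as value 0 with ``detected=False``.
    """
    with importlib.resources.as_file(_data_path("table1_abundances.tsv")) as p:
        raw = pd.read_csv(p, sep="\t", index_col="gene_symbol")
    meta = pd.DataFrame(
        {
            "protein_name": raw["protein_name"],
            "not_in_HUES1": raw["reference_only"].astype(bool),
        }
    )
    vals = raw[TABLE1_SAMPLES]
    detected = vals.notna()
    values = vals.fillna(0.0).astype(float)
    return AbundanceMatrix(values, detected, meta)


def load_table1_annotations() -> pd.DataFrame:
    """Load the synthetic GO annotation table for the fixture's gene symbols.

    This is a constructed stand-in (not the UniProt-GOA association set) that
    mirrors the classification outcome of the printed table: every row carries
    one of the four extracellular/cell-surface GO terms.
    """
    with importlib.resources.as_file(_data_path("table1_go_annotations_synthetic.tsv")) as p:
        return read_annotations(p)
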