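"""Synthetic identification reports and annotations with known ground truth.

The generator emulates the sampling structure behind spectrum-counting
quantification of cell-derived ECM preparations: each sample has a true
relative protein composition, each replicate draws its spectra multinomially
over that composition, decoy entries contaminate the accepted set at a known
rate, probability scores and unique-peptide counts separate true proteins
from a configurable fraction of noise records, and the proteins carry
class-consistent GO annotations plus a preferential-attachment interactome
with designated hubs. Every stochastic path is driven by one seed.

Default conditions mirror a typical study of this kind: two independent ECM
isolations (replicates) per sample, 10,000 spectra per replicate, a 0.1%
decoy rate among accepted entries, and roughly half of each composition
extracellular or cell surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import IdentificationRecord, write_identification_report

__all__ = [
    "GroundTruth",
    "default_ground_truth",
    "simulate_reports",
    "simulate_annotations_and_network",
    "write_simulation",
]

_EXTRACELLULAR = ("GO:0005576", "GO:0005615")
_CELL_SURFACE = ("GO:0005886", "GO:0009986")
_OTHER = ("GO:0005634", "GO:0005739", "GO:0005829")  # nucleus, mitochondrion, cytosol


@dataclass
class GroundTruth:
    """True per-sample compositions, class labels and nuisance rates.

    ``compositions`` maps sample -> {protein: relative abundance summing to 1}.
    ``decoy_rate`` is the intended expected decoy fraction among accepted
    records. ``noise_fraction`` of true records are degraded (low protein
    probability or a single peptide) so that validation has something to
    reject. ``supportive``/``unsupportive`` designate the sample groups for
    the differential comparison; true fold changes follow from compositions.
    """

    compositions: dict[str, dict[str, float]]
    class_labels: dict[str, str]  # protein -> extracellular | cell_surface | other
    supportive: list[str] = field(default_factory=list)
    unsupportive: list[str] = field(default_factory=list)
    hubs: list[str] = field(default_factory=list)
    decoy_rate: float = 0.001
    noise_fraction: float = 0.05
    n_replicates: int = 2
    total_spectra: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for sample, comp in self.compositions.items():
            arr = np.array(list(comp.values()), dtype=float)
            if (arr < 0).any() or not np.isclose(arr.sum(), 1.0, atol=1e-8):
                raise ValueError(f"composition of {sample!r} must be >=0 and sum to 1")
        if not 0.0 <= self.decoy_rate < 0.5:
            raise ValueError("decoy_rate must lie in [0, 0.5)")
        if self.total_spectra <= 0:
            raise ValueError("total_spectra must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def true_fold_change(self, protein: str) -> float:
        """True supportive/unsupportive abundance ratio (group means)."""
        if not self.supportive or not self.unsupportive:
            raise ValueError("supportive/unsupportive groups not designated")
        num = np.mean([self.compositions[s].get(protein, 0.0) for s in self.supportive])
        den = np.mean([self.compositions[s].get(protein, 0.0) for s in self.unsupportive])
        if den == 0.0:
            return float("inf")
        return float(num / den)


def default_ground_truth(seed: int = 0, n_proteins: int = 80, n_shared: int = 60) -> GroundTruth:
    """A two-condition truth emulating a supportive vs unsupportive contrast.

    Two samples share ``n_shared`` core proteins with log-normal abundances;
    each side additionally carries unique proteins, and a designated subset of
    shared proteins is enriched several-fold in the supportive sample. About
    56% of proteins are labelled extracellular or cell surface, the rest
    "other" (intracellular contaminants). The top shared protein is the
    designated interactome hub (a fibronectin analog).
    """
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:03d}" for i in range(n_proteins)]
    shared = proteins[:n_shared]
    n_unique = (n_proteins - n_shared) // 2
    only_sup = proteins[n_shared : n_shared + n_unique]
    only_unsup = proteins[n_shared + n_unique :]

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_shared)
    enriched = shared[1:7]  # planted >2-fold proteins (hub excluded to keep it shared+abundant)
    sup_w = dict(zip(shared, base))
    unsup_w = dict(zip(shared, base))
    for p in enriched:
        sup_w[p] *= 4.0
    hub = shared[0]
    sup_w[hub] = unsup_w[hub] = float(base.max()) * 3.0  # abundant everywhere, like fibronectin
    for p, w in zip(only_sup, rng.lognormal(0.0, 1.0, len(only_sup))):
        sup_w[p] = w + 0.5
    for p, w in zip(only_unsup, rng.lognormal(0.0, 1.0, len(only_unsup))):
        unsup_w[p] = w + 0.5

    def _norm(w: dict[str, float]) -> dict[str, float]:
        total = sum(w.values())
        return {p: v / total for p, v in w.items()}

    labels: dict[str, str] = {}
    for i, p in enumerate(proteins):
        u = rng.random()
        labels[p] = "extracellular" if u < 0.34 else "cell_surface" if u < 0.56 else "other"
    labels[hub] = "extracellular"
    for p in enriched:
        labels[p] = "extracellular"

    return GroundTruth(
        compositions={"supportive_ecm": _norm(sup_w), "unsupportive_ecm": _norm(unsup_w)},
        class_labels=labels,
        supportive=["supportive_ecm"],
        unsupportive=["unsupportive_ecm"],
        hubs=[hub],
        seed=seed,
    )


def simulate_reports(truth: GroundTruth) -> list[IdentificationRecord]:
    """Draw per-replicate identification reports from the ground truth.

    Spectrum counts are multinomial over the sample composition. True
    proteins receive protein probability >= 0.99 and >= 2 unique peptides; a
    ``noise_fraction`` of records are degraded to fail one criterion. Decoy
    records (passing all criteria, as accepted decoys do) are appended so the
    expected decoy fraction among accepted records equals ``decoy_rate``.
    Deterministic for a fixed ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    records: list[IdentificationRecord] = []
    for sample in truth.compositions:
        comp = truth.compositions[sample]
        proteins = list(comp)
        probs = np.array([comp[p] for p in proteins], dtype=float)
        for rep in range(1, truth.n_replicates + 1):
            counts = rng.multinomial(truth.total_spectra, probs)
            rep_id = f"rep{rep}"
            n_true = 0
            for protein, count in zip(proteins, counts):
                if count == 0:
                    continue
                noisy = rng.random() < truth.noise_fraction
                if noisy:
                    # split noise between the two failure modes
                    if rng.random() < 0.5:
                        peptides, probability = 1, float(rng.uniform(0.99, 1.0))
                    else:
                        peptides = 2 + int(rng.poisson(2.0))
                        probability = float(rng.uniform(0.5, 0.95))
                else:
                    peptides = 2 + int(rng.poisson(min(count / 5.0, 20.0)))
                    probability = float(rng.uniform(0.99, 1.0))
                    n_true += 1
                records.append(
                    IdentificationRecord(
                        sample_id=sample,
                        replicate_id=rep_id,
                        accession=f"ACC_{protein}",
                        gene_symbol=protein,
                        species="human",
                        n_unique_peptides=peptides,
                        protein_probability=probability,
                        spectrum_count=int(count),
                        is_decoy=False,
                    )
                )
            # E[decoys] = T * r / (1 - r)  =>  E[decoys / (T + decoys)] ~= r
            r = truth.decoy_rate
            n_decoys = rng.binomial(n_true, r / (1.0 - r)) if r > 0 else 0
            for d in range(n_decoys):
                records.append(
                    IdentificationRecord(
                        sample_id=sample,
                        replicate_id=rep_id,
                        accession=f"DECOY_{sample}_{rep_id}_{d:03d}",
                        gene_symbol=f"DECOY{d:03d}",
                        species="human",
                        n_unique_peptides=2,
                        protein_probability=float(rng.uniform(0.99, 1.0)),
                        spectrum_count=int(rng.integers(1, 4)),
                        is_decoy=True,
                    )
                )
    return records


def simulate_annotations_and_network(
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame, list[pd.DataFrame], pd.DataFrame]:
    """Generate class-consistent annotations, ontology, interactome, orthologs.

    Returns (annotation table, ontology parent table, edge lists, ortholog
    map table). Extracellular proteins carry at least one of the two
    extracellular terms, cell-surface proteins one of the two surface terms,
    "other" proteins unrelated cellular-component terms. The interactome is a
    preferential-attachment graph over all proteins in which each designated
    hub is wired to strictly dominate every other node's degree. The ortholog
    table emits a distinct lower-cased mouse-style alias for every protein.
    """
    rng = np.random.default_rng(truth.seed + 1)
    proteins = sorted({p for comp in truth.compositions.values() for p in comp})

    ann_rows = []
    for p in proteins:
        cls = truth.class_labels.get(p, "other")
        pool = {"extracellular": _EXTRACELLULAR, "cell_surface": _CELL_SURFACE}.get(cls, _OTHER)
        for term in rng.choice(pool, size=rng.integers(1, len(pool) + 1), replace=False):
            ann_rows.append({"gene_symbol": p, "go_id": str(term), "evidence": "IEA"})
    annotations = pd.DataFrame(ann_rows, columns=["gene_symbol", "go_id", "evidence"])

    # tiny acyclic cellular-component fragment (child, parent)
    ontology = pd.DataFrame(
        [
            ("GO:0005615", "GO:0005576"),  # extracellular space is_a extracellular region
            ("GO:0009986", "GO:0110165"),
            ("GO:0005886", "GO:0110165"),
            ("GO:0005576", "GO:0110165"),
            ("GO:0005634", "GO:0110165"),
            ("GO:0005739", "GO:0110165"),
            ("GO:0005829", "GO:0110165"),
        ],
        columns=["child", "parent"],
    )

    n = len(proteins)
    order = list(rng.permutation(n))
    G = nx.barabasi_albert_graph(n, m=2, seed=int(rng.integers(0, 2**31 - 1)))
    G = nx.relabel_nodes(G, {order[i]: proteins[i] for i in range(n)})
    for hub in truth.hubs:
        others = [p for p in proteins if p != hub]
        max_other = max(d for v, d in G.degree() if v != hub)
        need = max_other + 1 - G.degree(hub)
        candidates = [p for p in others if not G.has_edge(hub, p)]
        for p in rng.choice(candidates, size=min(max(need, 0) + 2, len(candidates)), replace=False):
            G.add_edge(hub, str(p))

    edges = [(a, b) for a, b in G.edges()]
    rng.shuffle(edges)
    thirds = np.array_split(np.arange(len(edges)), 3)
    names = ["pina_synthetic", "matrixdb_synthetic", "adhesome_synthetic"]
    edge_lists = [
        pd.DataFrame(
            [{"a": edges[i][0], "b": edges[i][1], "source": name} for i in idx],
            columns=["a", "b", "source"],
        )
        for idx, name in zip(thirds, names)
    ]

    ortho = pd.DataFrame(
        [{"mouse_symbol": p.lower(), "human_symbol": p} for p in proteins],
        columns=["mouse_symbol", "human_symbol"],
    )
    return annotations, ontology, edge_lists, ortho


def write_simulation(truth: GroundTruth, outdir) -> dict[str, str]:
    """Write one full synthetic data set in the pipeline's file dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = simulate_reports(truth)
    annotations, ontology, edge_lists, ortho = simulate_annotations_and_network(truth)

    paths = {"report": str(outdir / "identifications.tsv")}
    write_identification_report(records, paths["report"])
    annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    paths["annotations"] = str(outdir / "annotations.tsv")
    ontology.to_csv(outdir / "ontology.tsv", sep="\t", index=False)
    paths["ontology"] = str(outdir / "ontology.tsv")
    for i, df in enumerate(edge_lists):
        p = outdir / f"edges_{i}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"edges_{i}"] = str(p)
    ortho.to_csv(outdir / "orthologs.tsv", sep="\t", index=False)
    paths["orthologs"] = str(outdir / "orthologs.tsv")
    return paths
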