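"""End-to-end pipeline orchestration with config, manifest and provenance.

Stage order: validate -> quantify -> classify -> overlap -> cluster/enrich ->
network -> compare. A "matrix-entry" run accepts a pre-normalized abundance
matrix (e.g. the packaged printed comparison table) and skips validation and
quantification, so the downstream stages can be exercised on printed data.
Every run writes a manifest listing the seed, a hash of the configuration and
every output file with per-stage record counts; identical config and seed
yield identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import annotate, compare, io, network, overlap, profiles, quantify, validation
from .matrix import AbundanceMatrix

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to/from YAML."""

    out_dir: str
    report_path: str | None = None  # identification report TSV (record-entry mode)
    matrix_path: str | None = None  # pre-normalized matrix CSV (matrix-entry mode)
    use_table1_fixture: bool = False
    annotations_path: str | None = None
    ontology_path: str | None = None
    edge_list_paths: list[str] = field(default_factory=list)
    ortholog_map_path: str | None = None

    min_unique_peptides: int = 2
    min_peptide_probability: float = 0.90
    min_protein_probability: float = 0.99
    propagate: bool = False
    linkage: str = "average"
    cluster_threshold: float = 0.5
    enrichment_alpha: float = 0.05
    background: str = "classified"  # classified | all
    density_mode: str = "connected"  # connected | all
    fold_threshold: float = 2.0
    input_sig_figs: int | None = None
    detection_mode: str = "all"
    supportive: list[str] = field(default_factory=list)
    unsupportive: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()[:16]

    def validate_paths(self) -> None:
        for name in ("report_path", "matrix_path", "annotations_path", "ontology_path",
                     "ortholog_map_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p}")
        for p in self.edge_list_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"edge list: no such file {p}")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # context: which stage died
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all applicable stages; return the output directory."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "files": [],
    }

    def emit(name: str) -> Path:
        p = out / name
        manifest["files"].append(name)
        return p

    # -- validate + quantify (record-entry mode) ---------------------------
    matrix: AbundanceMatrix
    fdr: float | None = None
    if config.use_table1_fixture:
        matrix = io.load_table1_fixture()
        manifest["stages"]["input"] = {"mode": "table1_fixture", "n_proteins": len(matrix.proteins)}
    elif config.matrix_path:
        matrix = AbundanceMatrix.from_csv(config.matrix_path)
        manifest["stages"]["input"] = {"mode": "matrix", "n_proteins": len(matrix.proteins)}
    elif config.report_path:
        matrix, fdr = _validate_and_quantify(config, out, manifest, emit)
    else:
        raise PipelineStageError(
            "input", ValueError("one of report_path, matrix_path, use_table1_fixture required")
        )

    emit("matrix.csv")
    matrix.to_csv(out / "matrix.csv")

    # -- classify ----------------------------------------------------------
    classified = _classify(config, matrix, out, manifest, emit)
    ecm_set = annotate.class_filter(classified, {"extracellular", "cell_surface"})

    # -- overlap -----------------------------------------------------------
    _overlap(config, matrix, ecm_set, out, manifest, emit, fdr)

    # -- cluster + enrich --------------------------------------------------
    _cluster_and_enrich(config, matrix, out, manifest, emit)

    # -- network -----------------------------------------------------------
    degree: dict[str, int] = {}
    if config.edge_list_paths:
        degree = _network(config, ecm_set, out, manifest, emit)

    # -- compare -----------------------------------------------------------
    if config.supportive and config.unsupportive:
        _compare(config, matrix, ecm_set, degree, out, manifest, emit)

    manifest["files"].append("manifest.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


@_stage("validate_quantify")
def _validate_and_quantify(config, out, manifest, emit):
    records = io.read_identification_report(config.report_path)
    policy = validation.ValidationPolicy(
        config.min_unique_peptides,
        config.min_peptide_probability,
        config.min_protein_probability,
    )
    accepted, rejected = validation.accept(records, policy)
    validation.write_rejection_log(rejected, emit("rejections.tsv"))
    fdr = validation.estimate_protein_fdr(accepted)
    targets = [r for r in accepted if not r.is_decoy]
    matrix = quantify.build_abundance_matrix(targets)
    manifest["stages"]["validate"] = {
        "n_records": len(records),
        "n_accepted": len(accepted),
        "n_rejected": len(rejected),
        "protein_fdr_percent": fdr,
    }
    manifest["stages"]["quantify"] = {
        "n_proteins": len(matrix.proteins),
        "n_samples": len(matrix.samples),
    }
    return matrix, fdr


@_stage("classify")
def _classify(config, matrix, out, manifest, emit):
    if config.use_table1_fixture and config.annotations_path is None:
        ann = io.load_table1_annotations()
    elif config.annotations_path:
        ann = io.read_annotations(config.annotations_path)
    else:
        ann = None
    ontology = None
    if config.ontology_path:
        parents, names = io.read_ontology_table(config.ontology_path)
        ontology = annotate.Ontology(parents, names)
    if ann is None:
        classified = [annotate.ClassifiedProtein(p, frozenset(), "other") for p in matrix.proteins]
    else:
        classified = annotate.classify(matrix.proteins, ann, ontology, config.propagate)
    import pandas as pd

    pd.DataFrame(
        [{"gene_symbol": c.symbol, "class": c.cls, "go_terms": ";".join(sorted(c.go_terms))}
         for c in classified]
    ).to_csv(emit("classifications.tsv"), sep="\t", index=False)
    counts = {}
    for c in classified:
        counts[c.cls] = counts.get(c.cls, 0) + 1
    manifest["stages"]["classify"] = counts
    return classified


@_stage("overlap")
def _overlap(config, matrix, ecm_set, out, manifest, emit, fdr):
    universe = sorted(ecm_set) if ecm_set else None
    sets = {
        s: set((matrix.subset(proteins=universe) if universe else matrix).detected_in(s))
        for s in matrix.samples
    }
    payload = {"detected_counts": {s: len(v) for s, v in sets.items()}}
    if fdr is not None:
        payload["protein_fdr_percent"] = fdr
    nonempty = {s: v for s, v in sets.items() if v}
    if 2 <= len(nonempty) <= overlap.MAX_SETS:
        rep = overlap.euler_cardinalities(nonempty)
        payload["regions"] = {
            "|".join(sorted(region)): count for region, count in rep.region_cardinalities.items()
        }
    with open(emit("overlap.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    manifest["stages"]["overlap"] = {"n_samples": len(sets)}


@_stage("cluster_enrich")
def _cluster_and_enrich(config, matrix, out, manifest, emit):
    import pandas as pd

    try:
        cs = profiles.cluster_proteins(matrix, config.linkage, config.cluster_threshold)
    except ValueError as exc:
        manifest["stages"]["cluster"] = {"skipped": str(exc)}
        return
    rows = [{"gene_symbol": p, "cluster": i} for i, ms in enumerate(cs.clusters) for p in ms]
    rows += [{"gene_symbol": p, "cluster": -1} for p in cs.singletons]
    pd.DataFrame(rows, columns=["gene_symbol", "cluster"]).to_csv(
        emit("clusters.tsv"), sep="\t", index=False
    )
    manifest["stages"]["cluster"] = {
        "n_clusters": len(cs.clusters),
        "n_singletons": len(cs.singletons),
        "n_dropped": len(cs.dropped),
    }

    if config.annotations_path or config.use_table1_fixture:
        ann = (
            io.read_annotations(config.annotations_path)
            if config.annotations_path
            else io.load_table1_annotations()
        )
        amap = annotate.annotation_map(ann)
        background = cs.proteins
        results = []
        for i, members in enumerate(cs.clusters):
            results.extend(
                profiles.enrich_cluster(
                    members, amap, background, config.enrichment_alpha, cluster_id=i
                )
            )
        pd.DataFrame([asdict(r) for r in results]).to_csv(
            emit("enrichment.tsv"), sep="\t", index=False
        )
        manifest["stages"]["enrich"] = {
            "n_tests": len(results),
            "n_significant": sum(r.significant for r in results),
        }


@_stage("network")
def _network(config, ecm_set, out, manifest, emit) -> dict[str, int]:
    edge_lists = [io.read_edge_list(p) for p in config.edge_list_paths]
    G = network.merge_interactomes(edge_lists)
    hits = set(ecm_set)
    if config.ortholog_map_path:
        omap = io.read_ortholog_map(config.ortholog_map_path)
        mapped, unmapped = network.map_orthologs(hits, omap)
        hits = set(mapped) | {h for h in hits if h in G}
    if not hits:
        manifest["stages"]["network"] = {"skipped": "no hits"}
        return {}
    rep = network.induce_and_measure(G, sorted(hits), config.density_mode == "all")
    network.export_node_table(rep, emit("network_nodes.tsv"))
    network.export_edge_list(rep.graph, emit("network_edges.tsv"))
    manifest["stages"]["network"] = {
        "n_nodes": rep.n_nodes,
        "n_edges": rep.n_edges,
        "density": rep.density,
    }
    return rep.degree


@_stage("compare")
def _compare(config, matrix, ecm_set, degree, out, manifest, emit):
    proteins = sorted(ecm_set & set(matrix.proteins)) if ecm_set else None
    rep = compare.differential_report(
        matrix,
        config.supportive,
        config.unsupportive,
        proteins=proteins,
        fold_threshold=config.fold_threshold,
        detection_mode=config.detection_mode,
        input_sig_figs=config.input_sig_figs,
        hub_degree=degree,
    )
    payload = {
        "supportive": rep.supportive_samples,
        "unsupportive": rep.unsupportive_samples,
        "unique_to_supportive": sorted(rep.unique_to_supportive),
        "unique_to_unsupportive": sorted(rep.unique_to_unsupportive),
        "enriched_in_supportive": [[p, f] for p, f in rep.enriched_in_supportive],
        "candidate_ranking": rep.candidate_ranking,
        "fold_threshold": rep.fold_threshold,
    }
    with open(emit("comparison.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    manifest["stages"]["compare"] = {
        "n_unique_supportive": len(rep.unique_to_supportive),
        "n_unique_unsupportive": len(rep.unique_to_unsupportive),
        "n_enriched": len(rep.enriched_in_supportive),
    }
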