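"""Synthetic ground-truth generator: sampling moments and construction rules."""

import networkx as nx
import numpy as np
import pytest

from ecmprofiler.annotate import CELL_SURFACE_TERMS, EXTRACELLULAR_TERMS, Ontology
from ecmprofiler.network import merge_interactomes
from ecmprofiler.simulate import (
    GroundTruth,
    default_ground_truth,
    simulate_annotations_and_network,
    simulate_reports,
)


def small_truth(seed=0, **kw):
    defaults = dict(
        compositions={"s1": {"A": 0.5, "B": 0.5}},
        class_labels={"A": "extracellular", "B": "other"},
        seed=seed,
    )
    defaults.update(kw)
    return GroundTruth(**defaults)


class TestGroundTruth:
    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_truth(compositions={"s1": {"A": 0.5, "B": 0.6}})

    def test_decoy_rate_bounds(self):
        with pytest.raises(ValueError, match="decoy_rate"):
            small_truth(decoy_rate=0.5)

    def test_zero_spectra_rejected(self):
        with pytest.raises(ValueError, match="total_spectra"):
            small_truth(total_spectra=0)

    def test_true_fold_change(self):
        t = GroundTruth(
            compositions={"sup": {"A": 0.8, "B": 0.2}, "unsup": {"A": 0.2, "B": 0.8}},
            class_labels={},
            supportive=["sup"],
            unsupportive=["unsup"],
        )
        assert t.true_fold_change("A") == pytest.approx(4.0)
        t2 = GroundTruth(
            compositions={"sup": {"A": 1.0}, "unsup": {"B": 1.0}},
            class_labels={},
            supportive=["sup"],
            unsupportive=["unsup"],
        )
        assert t2.true_fold_change("A") == float("inf")


class TestSimulateReports:
    def test_degenerate_composition_takes_all_spectra(self):
        t = small_truth(
            compositions={"s1": {"A": 1.0}},
            total_spectra=100,
            noise_fraction=0.0,
            decoy_rate=0.0,
        )
        recs = simulate_reports(t)
        by_rep = {}
        for r in recs:
            by_rep.setdefault(r.replicate_id, []).append(r)
        assert set(by_rep) == {"rep1", "rep2"}
        for rep_recs in by_rep.values():
            assert len(rep_recs) == 1 and rep_recs[0].spectrum_count == 100

    def test_same_seed_reproduces_reports(self):
        t1, t2 = default_ground_truth(seed=42), default_ground_truth(seed=42)
        assert simulate_reports(t1) == simulate_reports(t2)

    def test_different_seed_differs(self):
        r1 = simulate_reports(default_ground_truth(seed=1))
        r2 = simulate_reports(default_ground_truth(seed=2))
        assert r1 != r2

    def test_multinomial_mean_within_3_se(self):
        # 200 replicate draws of a 50/50 composition over 10,000 spectra:
        # mean count of A must fall within 3 SE of n*p (binomial moments)
        n, p, n_sims = 10_000, 0.5, 200
        t = small_truth(
            compositions={"s1": {"A": p, "B": 1 - p}},
            n_replicates=n_sims,
            total_spectra=n,
            noise_fraction=0.0,
            decoy_rate=0.0,
        )
        counts = [r.spectrum_count for r in simulate_reports(t) if r.gene_symbol == "A"]
        assert len(counts) == n_sims
        se = np.sqrt(n * p * (1 - p))
        assert abs(np.mean(counts) - n * p) <= 3 * se / np.sqrt(n_sims)

    def test_true_records_pass_thresholds_noise_fails_one(self):
        t = default_ground_truth(seed=5)
        recs = [r for r in simulate_reports(t) if not r.is_decoy]
        passing = [r for r in recs if r.n_unique_peptides >= 2 and r.protein_probability >= 0.99]
        assert len(passing) / len(recs) > 0.85  # noise fraction is small
        failing = [r for r in recs if r not in passing]
        for r in failing:
            assert r.n_unique_peptides < 2 or r.protein_probability < 0.99

    def test_decoys_pass_acceptance(self):
        t = small_truth(
            compositions={"s1": {"A": 1.0}},
            decoy_rate=0.2,
            total_spectra=1000,
            n_replicates=50,
            noise_fraction=0.0,
        )
        decoys = [r for r in simulate_reports(t) if r.is_decoy]
        assert decoys, "decoy rate 0.2 over 50 replicates must emit decoys"
        for d in decoys:
            assert d.n_unique_peptides >= 2 and d.protein_probability >= 0.99


@pytest.fixture(scope="module")
def generated():
    truth = default_ground_truth(seed=11)
    return truth, simulate_annotations_and_network(truth)


class TestAnnotationsAndNetwork:

    def test_class_consistent_annotations(self, generated):
        truth, (annotations, _, _, _) = generated
        terms = {}
        for row in annotations.itertuples(index=False):
            terms.setdefault(row.gene_symbol, set()).add(row.go_id)
        for protein, cls in truth.class_labels.items():
            if cls == "extracellular":
                assert terms[protein] & EXTRACELLULAR_TERMS
            elif cls == "cell_surface":
                assert terms[protein] & CELL_SURFACE_TERMS
            else:
                assert not terms[protein] & (EXTRACELLULAR_TERMS | CELL_SURFACE_TERMS)

    def test_ontology_acyclic_by_topological_sort(self, generated):
        _, (_, ontology, _, _) = generated
        G = nx.DiGraph(list(ontology.itertuples(index=False, name=None)))
        list(nx.topological_sort(G))  # raises on a cycle
        Ontology({c: {p} for c, p in ontology.itertuples(index=False, name=None)})

    def test_designated_hub_has_top_degree(self, generated):
        truth, (_, _, edge_lists, _) = generated
        G = merge_interactomes(edge_lists)
        degrees = dict(G.degree())
        hub = truth.hubs[0]
        assert degrees[hub] == max(degrees.values())
        assert sum(1 for d in degrees.values() if d == degrees[hub]) == 1  # strict top-1

    def test_ortholog_aliases_round_trip(self, generated):
        truth, (_, _, _, ortho) = generated
        omap = dict(zip(ortho["mouse_symbol"], ortho["human_symbol"]))
        for protein in truth.class_labels:
            assert omap[protein.lower()] == protein
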