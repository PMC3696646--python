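"""Measure the topology of a hit subnetwork on a merged interactome.

Builds a synthetic ground truth, generates its preferential-attachment
interactome from three source edge lists (merged with provenance), maps the
extracellular/cell-surface proteins onto it and reports degree, clustering
coefficient and network density of the induced subnetwork.
"""

from ecmprofiler import default_ground_truth, induce_and_measure, merge_interactomes
from ecmprofiler.simulate import simulate_annotations_and_network

truth = default_ground_truth(seed=7)
annotations, ontology, edge_lists, orthologs = simulate_annotations_and_network(truth)

interactome = merge_interactomes(edge_lists)
print(f"merged interactome: {interactome.number_of_nodes()} nodes, "
      f"{interactome.number_of_edges()} edges from {len(edge_lists)} sources")

hits = sorted(p for p, cls in truth.class_labels.items()
              if cls in {"extracellular", "cell_surface"})
report = induce_and_measure(interactome, hits)
print(f"hit subnetwork: {report.n_nodes} connected nodes, {report.n_edges} edges, "
      f"density {report.density:.3f}")
print("top hubs (degree, clustering coefficient):")
for v in report.hubs[:5]:
    print(f"  {v}: k={report.degree[v]}, C={report.clustering[v]:.3f}")
print(f"-> the designated hub {truth.hubs[0]} (the fibronectin analog) dominates "
      "the network, as a scaffolding ECM protein should.")
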