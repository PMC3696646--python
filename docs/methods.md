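# Methods

## Problem and model

The package compares the protein composition of cell-derived extracellular
matrices (ECMs) quantified by label-free spectral counting. The measurement
model is deliberately minimal: an LC-MS/MS run assigns each accepted protein
an unweighted spectrum count, and a protein's relative abundance in a
replicate is its share of all accepted target spectra. No peptide-level
modelling, length correction (NSAF/emPAI) or intensity weighting is applied —
the unweighted count is the quantity of record, and everything downstream
(averaging, folds, clustering) operates on it.

## Validation and FDR

Identifications are accepted per (sample, replicate, accession) when they
carry at least `min_unique_peptides` (default 2) unique peptides — counts are
taken as already filtered at the peptide-probability threshold (default 0.90,
kept in the policy for provenance) — and a protein probability of at least
`min_protein_probability` (default 0.99). All comparisons are closed (≥):
"at least" is taken literally, so a probability of exactly 0.99 passes and
0.989 fails. Tightening any threshold can only shrink the accepted set.

The protein-level FDR is the decoy ratio, FDR% = 100 · D/T over accepted
records. This replaces search-engine-internal probability-based estimates,
which are not re-derivable from report-level inputs; the decoy ratio is the
standard target–decoy estimator and is directly testable against a known
planted decoy rate. It is undefined (an error, not 0) when no targets are
accepted.

## Quantification

Within one replicate, normalized(p) = count(p) / Σ count · 100 · 10³, in
units of "% total spectra × 10³"; a replicate's values sum to 100,000 by
construction. The denominator covers accepted *target* records only: decoys
are artifacts of validation, not sample content. Sample-level values are
arithmetic means over replicates with zero-fill — a replicate in which the
protein was not accepted contributes 0 — while detection (acceptance in ≥ 1
replicate) is tracked separately in a boolean mask. Zero-fill keeps the
detected-set semantics independent of abundance and reproduces half-means for
one-of-two-replicate detections. Fold enrichment between two samples is the
ratio of mean values and is only defined when both samples detect the
protein; otherwise the result is a status flag (`unique_to_numerator`, etc.),
never a numeric ratio, mirroring the ND (not detected) cells of published
tables.

### Thresholds on printed data

Abundance values transcribed from a printed table carry 3 significant
figures. A strict fold threshold applied to such values can flip a call that
was made on the unrounded source data: a true ratio marginally above 2 can
print as 49.7/24.9 = 1.996. The differential comparison therefore accepts an
optional `input_sig_figs`: when set, the strict `>` test is applied to the
upper bound of the ratio over the half-ulp rounding intervals of numerator
and denominator ((v − u/2, v + u/2) with u one unit in the last printed
digit). With exact data (`input_sig_figs=None`, the default) the test is a
plain strict inequality.

## Classification

Extracellular: annotated with GO:0005576 or GO:0005615. Cell surface:
annotated with GO:0005886 or GO:0009986 and neither extracellular term —
extracellular takes precedence for dually annotated proteins (a decision;
either order is defensible, and precedence matches treating secreted matrix
identity as the stronger signal). By default only direct annotations are
matched, reflecting retrieval from a curated association set; with
`propagate=True` annotation sets are closed over is_a/part_of ancestors
first, which can only add classifications (monotone by construction). The
ontology is a lightweight acyclic parent graph; cyclicity is rejected at
construction.

## Overlap

Euler-region cardinalities are computed exactly by signature counting (each
protein's membership pattern across ≤ 5 sets; the guard exists because the
region count is 2^k − 1). Shared-protein statistics against a reference
sample use the detection mask, not abundance thresholds; the summary over a
group of samples reports mean and sample SD (n−1 denominator), which is what
reproduces the printed 13 ± 1.6 from shared counts {11, 13, 15, 13}.

## Clustering and enrichment

Similarity between protein profiles is the uncentered Pearson correlation
r_u(x, y) = Σxy / √(Σx² Σy²) — cosine similarity of the raw vectors. Not
subtracting means is the right choice for abundance profiles in which zero is
meaningful absence, and it makes r_u scale-invariant, so normalization
constants cancel. Distance is 1 − r_u (scipy's cosine metric); linkage
defaults to average (UPGMA), the usual companion of uncentered correlation in
expression-style clustering, configurable to complete or single (the source
analyses did not state a linkage). All-zero profiles have undefined
similarity and are dropped with a warning. Flat clusters are extracted by
cutting where the cophenetic merge distance is ≤ 1 − threshold (threshold
0.5 by default), which is exactly the family of maximal subtrees whose root
merge similarity meets the threshold; ND cells enter profile vectors as 0.

Per-cluster GO enrichment uses the hypergeometric upper tail
p = Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n), with Benjamini–Hochberg adjustment
across the terms tested within the cluster and significance at q ≤ alpha
(default 0.05). The default background is the set of clustered proteins
(cluster-versus-dataset contrast); a whole-identification background is a
caller choice, since genome-scale universes would require external gene
lists. An EASE-style conservative variant (one observed success subtracted
before taking the tail) is available and off by default.

## Network topology

Interactome sources merge into one undirected simple graph: reversed
duplicates collapse, per-edge source tags accumulate, self-loops are dropped
and counted. Mouse symbols are converted to human orthologs before hit
mapping; unmapped symbols are excluded and logged, many-to-one mappings
deduplicate. On the induced hit subnetwork: degree k(v); local clustering
coefficient C(v) = 2e(v)/(k(k−1)) with C = 0 for k < 2; density
ρ = 2E/(N(N−1)) where N by default counts connected nodes only — published
ECM network figures omit disconnected nodes, and isolates would deflate ρ —
with an include-isolates mode matching tools that compute over all nodes.
Hub ranking is by descending degree with ties broken by symbol.

## Synthetic data

The generator emulates the sampling structure of the experiment, not the
instrument: per sample a true relative composition; per replicate a
multinomial draw of `total_spectra` spectra over that composition (no
peptide-level simulation — quantification is defined at the spectrum level);
probability scores ≥ 0.99 and ≥ 2 peptides for true records, with a
`noise_fraction` degraded to fail exactly one criterion; decoy records that
pass validation, drawn Binomial(T, r/(1−r)) so the expected decoy fraction
among accepted records is the planted rate r. Defaults are the study
conditions: 2 replicates (two independent ECM isolations), 10,000 spectra per
replicate (the order of magnitude that yields ~10²-protein accepted sets on
the instrument class involved), decoy rate 0.001 (matching the 0.1% FDR
regime), noise fraction 0.05, and ~56% extracellular/cell-surface labels.
Annotations are class-consistent by construction; the ontology fragment is
acyclic; the interactome is preferential-attachment with designated hubs
wired to strictly dominate all other degrees; ortholog tables emit distinct
lower-cased mouse-style aliases. All randomness flows from one seed.

What the generator does not emulate: protein-length and detectability biases,
shared/razor peptide ambiguity, replicate-level batch effects, and
correlated compositions across more than two samples. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
sampling model, not robustness to those real-data phenomena.

## Pipeline

Stages run in a fixed order (validate → quantify → classify → overlap →
cluster/enrich → network → compare); any stage error aborts with the stage
name. A matrix-entry mode accepts a pre-normalized abundance matrix — such as
the packaged printed table — and skips validation/quantification, so the
downstream stages are exercisable on published data without raw spectra. The
manifest records the seed, a hash of the canonical config and every output
file with per-stage counts; identical config and seed give byte-identical
numeric outputs.

## Packaged fixture

`data/table1_abundances.tsv` transcribes the printed comparison of
extracellular proteins detected in HUES1 hESC ECM against six feeder ECMs:
35 rows detected in HUES1 plus 7 collagen-chain rows listed for reference
only (flagged `not_in_HUES1`), ND cells encoded as empty and loaded as
value 0 / detected = false. `data/table1_go_annotations_synthetic.tsv` is a
constructed stand-in for the GO association set (which is not redistributed
here), assigning each fixture gene one of the four classification terms so
that the fixture classifies as published.

## Numerical and problem-size choices

Probability thresholds compare with ≥ at float precision (inputs are exact
decimals at report precision). Normalization asserts conservation to 1e-6
relative. Cosine distances are clipped to [0, 2] before linkage to absorb
float round-off. Test problem sizes — e.g. recovery runs with 20 seeds, 2 ×
10⁴-spectrum replicates, interactome oracles up to 50 nodes, Monte-Carlo
checks at 10⁵ draws — are chosen so the statistical bounds (2–3 SE) are
sharp enough to catch implementation errors while the whole suite stays
interactive. Statistical recovery tests fix their seeds; the bounds used
(binomial/delta-method standard errors) are derived in the tests themselves.

## Known limitations

Real identification reports aggregate protein groups and shared peptides
upstream of this package; the gene-symbol join assumes one symbol per
accession. The enrichment background excludes unannotated callers' choices
and does not reproduce DAVID's fuzzy term clustering or its gene universes.
Euler cardinalities are exact but capped at five sets. Fig-style layout is
out of scope: networks are measured, not drawn.
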