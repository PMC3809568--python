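# pluriscreen

Boolean-network screening for candidate self-renewal regulators in human
pluripotent stem cells.

## The problem

Self-renewal of human embryonic stem cells (hESCs) is governed by the
transcription-factor triad OCT3/4, SOX2 and NANOG, supported by bFGF and
ACTIVIN/NODAL signaling and opposed by the BMP4-driven differentiation
program (GADD45G, trophoblast markers hCG and GCM1).  Many secreted or cell
surface factors respond to perturbations of these regulators, but which of
them feed *back* into the core circuit — and could therefore be added to
culture media to sustain the undifferentiated state — is unknown.

`pluriscreen` implements a qualitative-modeling pipeline that proposes such
factors from perturbation expression data alone:

1. **Network expansion.** Starting from a small literature core network,
   each gain perturbation (protein stimulation, over-expression) or loss
   perturbation (RNAi knockdown) of a core regulator contributes signed
   edges: a gene with |log2 FC| ≥ 1.5, differential *p* < 1e-05 and
   detection *p* < 1e-05 gains an incoming edge whose sign follows the
   perturbation logic (up after a gain ⇒ activation; signs invert for
   losses).
2. **Filtering and clustering.** Candidate targets must be regulated by at
   least 5 distinct core regulators and carry receptor-related Gene Ontology
   annotation (GO:0007166 cell surface receptor linked signaling pathway, or
   GO:0005102 receptor binding).  Genes with identical signed incoming-edge
   signatures collapse into one cluster node, yielding the reduced
   perturbation network.
3. **Model enumeration.** Every candidate model adds exactly one feedback
   edge from a cluster node to a core regulator, activating or inhibiting:
   |clusters| × |core| × 2 models (59 clusters × 10 core genes × 2 = 1180 at
   the published scale).
4. **Synchronous Boolean dynamics.** Each model is simulated with the
   inhibitor-dominant rule (a node is active iff some activator is active
   and no inhibitor is) under systematic in-silico knockout and
   over-expression of every regulatory node; all attractor states — fixed
   points and cycles — are stacked into a binary steady-state matrix.
5. **PCA-angle scoring.** Column-centered PCA reduces the matrix to two
   components; each marker gene gets a loading vector, and each model three
   angle statistics: the summed pairwise angle among OCT3/4–SOX2–NANOG
   (pluripotency coherence), the BMP4–GADD45G angle, and the angle between
   the pluripotency and differentiation group directions.  Models with small
   within-pluripotency angles and large cross angles — networks whose steady
   states keep the triad jointly active and the differentiation markers
   jointly opposed — are Pareto-ranked and the top clusters selected.

A synthetic-data module generates perturbation tables with planted
regulator→target structure (effect sizes and p-values straddling the calling
thresholds by construction) so the entire pipeline is testable without any
external download, and ships the in-text fixtures: the default 10-gene core
network and the table of 15 candidate genes in 8 signature clusters.

## Worked example

Run the fixture study — the 8 published candidate clusters on the default
10-gene core — end to end:

```bash
pluriscreen run-all --seed 1 --outdir fixture_run
```

which prints (abridged):

```json
{
  "n_clusters": 8,
  "n_filtered_genes": 15,
  "n_models": 160,
  "n_nodes": 18,
  "n_scorable_models": 160,
  "selected_clusters": ["C14", "C15", "C16", "C28", "C36", "C39", "C41", "C5"],
  ...
}
```

by default `run-all` uses synthetic mode; pass a config file to choose the
fixture study:

```yaml
# config.yaml
mode: table1
k_clusters: 8
```

The counts read: the 15 candidate genes collapse into 8 clusters
(`n_clusters`), giving a reduced network of 10 core + 8 cluster nodes
(`n_nodes: 18`) and 8 × 10 × 2 = 160 candidate models, all of which produce
scorable steady-state matrices.  `fixture_run/scores.tsv` holds the three
angles per model, `score_plane.png` the pluripotency-angle vs cross-angle
plane with selected models highlighted, and `steady_states.tsv` every
attractor state with its provenance (model, clamped node, clamp value).

The same stages are available as library calls (`pluriscreen.run_pipeline`,
`pluriscreen.compute_attractors`, `pluriscreen.score_matrix`, ...) and as
individual CLI subcommands (`simulate-data`, `expand`, `cluster`,
`enumerate`, `dynamics`, `score`).

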