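# metcoherence

Quantify how well a set of differential gene-expression changes "makes
sense" on a cell's metabolic network — and whether that agreement is
mediated by transcription-factor regulation instead.

The package is aimed at systems biologists studying global modes of
bacterial gene regulation (DNA supercoiling, nucleoid-associated
proteins) who have per-gene differential-expression calls for several
genetic backgrounds and want a network-level statistic comparing them,
without re-deriving graph constructions and null models each time.

## The statistic

Metabolism is represented as a directed **gene-centric network**: gene
*G1* points to *G2* whenever a product of *G1*'s reaction is a
substrate of *G2*'s reaction (with ubiquitous *currency metabolites*
like ATP excluded, either from a list or by a degree threshold).
Mapping the significantly changed genes onto this network yields an
**effective subnetwork** — the node-induced subgraph on the
significant genes. Its fraction of connected nodes is the **metabolic
coherence ratio**

&nbsp;&nbsp;&nbsp;&nbsp;MCR = |{v : deg(v) ≥ 1 in the effective subnetwork}| / |effective nodes|

and the size-corrected **metabolic coherence** is the z-score

&nbsp;&nbsp;&nbsp;&nbsp;MC = (MCR − ⟨MCR′⟩) / σ(MCR′)

where MCR′ is recomputed on random gene sets of the same size drawn
uniformly without replacement from the network's nodes (5000
realizations by default). MC ≈ 0 means the expression pattern sits on
the network no better than chance; MC ≫ 0 means it traces connected
pathway structure.

The same machinery run on the transcription-factor → metabolic-gene
network gives the **digital CTC** (digital control strength). A signed
complement, **TRN consistency**, scores each effective regulatory link
as consistent when activation joins equal expression signs (or
repression opposite signs), and converts the consistent-link fraction
into a z-score against a null that permutes the observed signs across
the effective nodes.

Flux balance analysis (linear programming, biomass maximization,
parsimonious flux selection) refines the analysis to the reactions
actually carrying flux under a growth medium, including randomized
rich-to-minimal medium-reduction scans.

A synthetic-data module generates toy metabolisms (pathway chains plus
currency hubs), expression calls with a tunable *planting fraction*
interpolating from random to fully pathway-contiguous, signed toy
TRNs, and small flux models with closed-form optima — so the entire
pipeline is testable end to end without any external database.

## Worked example

```bash
metcoherence simulate --outdir demo --seed 42
metcoherence coherence --reactions demo/reactions.tsv \
    --currency list --currency-list demo/currency.txt \
    --calls demo/calls_wildtype.tsv --background wildtype --seed 1
```

prints

```json
{
  "background": "wildtype",
  "degenerate": false,
  "genes_not_in_network": 8,
  "mc": 2.987769133305705,
  "mcr": 0.76,
  "n_connected": 19,
  "n_effective": 25,
  "n_realizations": 5000,
  "network_label": "reactions",
  "seed": 1
}
```

19 of the 25 significant genes found in the network touch another
significant gene (MCR = 0.76), which is 3.0 standard deviations above
the random-gene-set expectation: this "wild-type-like" call set (80 %
of its genes planted along pathways) is strongly coherent with the
metabolism. The same command on `calls_fis_hns.tsv` — the double-mutant
preset with only 10 % planted genes — prints `"mcr": 0.36, "mc":
-0.35`: indistinguishable from random. `metcoherence run --config
demo/config.yaml` computes all backgrounds plus the TRN and
FBA-filtered statistics in one pass, with full seed/config provenance
in the output JSON.

The library surface mirrors the CLI
(`build_reaction_adjacency`, `project_to_genes`, `mc_zscore`,
`digital_ctc`, `trn_consistency_zscore`, `solve_fba`,
`medium_reduction_trajectory`, …); see `docs/methods.md` for the
modelling details and design choices.

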