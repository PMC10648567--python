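# scaforge

Ligand-based target fishing and scaffold-constrained genetic optimization of
drug analogs, built around cannabidiol (CBD) as the default query ligand.

## The problem

Given one ligand of interest, two questions recur in early drug discovery:

1. **Which disease-associated protein targets might it bind?** scaforge
   answers this by *target fishing*: drugs structurally similar to the query
   (average of Morgan and MACCS fingerprint Tanimoto similarities,
   `(T_Morgan + T_MACCS)/2 > 0.4`) are extracted from a drug–target
   interaction dataset; the targets they are annotated to bind are scored
   with a binding-affinity oracle, and a target is kept when both the query
   and at least one linked similar drug score pIC50 > 4.0; finally, targets
   are joined against a gene–phenotype table (via an accession → gene-symbol
   cross-reference) and only those with a matching disease phenotype
   (default substring: "Alzheimer") are reported.
2. **Can the ligand be improved against each target?** scaforge evolves
   analogs with a seeded genetic algorithm that freezes the query's Murcko
   scaffold (ring systems + linkers), minimizes a docking-oracle score
   (kcal/mol, lower = stronger), and enforces the drug-likeness surface
   QED ≥ 0.5, SAScore ≤ 6.0, logP ≤ 5.0 plus the PAINS / BRENK / NIH / ZINC
   structural-alert filters. Analog quality is summarized by the penalized
   partition coefficient

   ```
   plogP = logP − SAScore − RingPenalty,   RingPenalty = max(0, largest ring − 6)
   ```

External predictors (affinity model, docking engine) are abstracted behind
oracle contracts with deterministic surrogate implementations, and a
synthetic-data generator plants a fully known ground truth (query-similar
neighbors, above-cutoff targets, disease-tagged genes), so the complete
pipeline runs and is tested offline, end to end, from a single seed.

## Worked example

```
$ scaforge simulate --seed 5 --out bundle
wrote 7 files to bundle

$ scaforge identify --data-dir bundle --seed 5 --out report.tsv
3 target(s) identified -> report.tsv

$ head -4 report.tsv
accession  gene_symbol  pic50_query  best_supporting_drug  similarity  pic50_support  phenotype
T018       GENE18       6.5          SIM001                0.6974      5.3333         Alzheimer disease, type 1
T022       GENE22       6.5          SIM001                0.6974      5.3333         Alzheimer disease, type 2
T027       GENE27       6.5          SIM006                0.7546      5.54           Alzheimer disease, type 3
```

The three reported accessions are exactly the planted disease-tagged,
affinity-positive targets of the simulated scenario (`bundle/truth.tsv`);
`pic50_query` = 6.5 is the surrogate's score for the query against a planted
target, and each row carries the supporting similar drug with its similarity
(> 0.4) and pIC50 (> 4.0) as machine-checkable evidence.

```
$ scaforge optimize --target T018 --data-dir bundle --seed 5 --out analogs.tsv
8 analog(s) -> analogs.tsv (+ analogs.smi)

$ head -3 analogs.tsv
No.    QED   SAScore  plogP  logP  Filters  DockingScore
No.1   0.76  3.62     1.23   4.85  Pass     -9.00
No.2   0.73  3.91     1.00   4.91  Pass     -9.00
```

Every analog keeps CBD's Murcko scaffold, satisfies QED ≥ 0.5 / SAScore ≤ 6 /
logP ≤ 5 and the alert filters, and reaches the surrogate docking optimum of
−9.00 kcal/mol (both planted pharmacophore features — a hydroxyl and a
fluorine — acquired). Note the improvement over the seed: CBD itself has
logP 5.85 and docking −6.50 here (`scaforge props` prints its full profile).

A Python API mirrors each subcommand (`scaforge.chem`, `scaforge.fishing`,
`scaforge.ga`, `scaforge.oracles`, `scaforge.datagen`); see
`docs/methods.md` for the model details and design choices.

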