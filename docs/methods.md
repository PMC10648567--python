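# Methods

## Pipeline model

scaforge implements a two-stage in-silico discovery workflow around a query
ligand (cannabidiol by default, fixture `scaforge.chem.CBD_SMILES`).

**Stage 1 — target fishing.** The working assumption is the classical
similar-property principle: structurally similar ligands tend to share
targets. Similarity is the unweighted mean of two Tanimoto coefficients,
one on Morgan circular fingerprints (radius 2, 2048 bits — the ECFP4-style
de-facto standard; no radius/width was prescribed, so the standard is used)
and one on the 166 MACCS structural keys (RDKit's vector has 167 positions,
bit 0 unused). Averaging a dense hashed fingerprint with a sparse key-based
one damps the known tendency of single-fingerprint Tanimoto values to
saturate low or high. Both gating thresholds are **strict** inequalities:
similarity must exceed 0.4 and the affinity oracle's pIC50 must exceed 4.0
("higher than", not "at least"); the tests pin this with values placed
exactly at the thresholds.

The affinity filter keeps a target when the query scores above the cutoff
**and at least one** similar drug linked to that target does. The stricter
reading — every linked similar drug above the cutoff — is available as
`PipelineConfig(require_all_supporters=True)`; the permissive reading is the
default because requiring all annotated binders of a promiscuous target to
clear the cutoff collapses recall as datasets grow. Disease matching is a
case-insensitive substring over phenotype text, since phenotype nomenclature
is not controlled ("Alzheimer disease 2", "Alzheimer disease, type 3", …);
accessions absent from the cross-reference are treated as unmatched rather
than errors. Report rows are ordered by descending query pIC50 then
accession, making reports byte-reproducible.

**Stage 2 — scaffold-constrained GA.** Analogs are evolved under a hard
structural constraint: the child's Murcko scaffold (ring systems plus
linkers, side chains removed; equality = canonical-SMILES string equality)
must equal the seed's. Selection is constraint-domination: feasible beats
infeasible, infeasibles rank by summed normalized violation, feasibles rank
by docking score with plogP, then QED, then canonical SMILES as
deterministic tie-breaks (a total order, so runs are reproducible).

## GA operators and parameters

The variation operators act on the decorations only and re-validate the
scaffold after every edit (up to 20 retries, then identity):

* **append** a single atom from {C, N, O, S, F, Cl} at any position with a
  free valence;
* **delete** a terminal non-scaffold atom;
* **swap** the element of a non-scaffold, non-aromatic heavy atom;
* **bond-order toggle** (single ↔ double) on a non-ring bond.

Crossover decomposes both parents into scaffold plus side chains per
attachment atom (`ReplaceCore`) and grafts the side chains of one randomly
chosen parent at one randomly chosen differing attachment point onto the
other parent; single-point grafting keeps the failure rate of the rebuild
low, and any failure falls back to mutation. Stereo tags orphaned by an edit
are cleaned; a retry guards scaffold identity, so ring stereocenters
survive by validation rather than by construction.

Defaults: population 100, 50 generations, crossover probability 0.6,
mutation probability 0.4, tournament size 3, elitism 2, hall of fame 8.
These are conventional mid-size GA settings; with the elitist archive the
best-so-far feasible docking score is non-increasing by construction, which
the tests assert. The hall of fame keeps unique (by canonical SMILES)
feasible individuals; its size cap of 8 reflects that a handful of analogs
per target is what a chemist will actually inspect.

Feasibility = QED ≥ 0.5 ∧ SAScore ≤ 6.0 ∧ logP ≤ 5.0 ∧ scaffold preserved ∧
no *actionable* structural alert (next section). The violation measure is
`max(0, 0.5−QED)/0.5 + max(0, SAS−6)/4 + max(0, logP−5)/5 + #actionable
alerts + [scaffold broken]`, zero exactly on feasibility.

## Structural alerts and the scaffold-inherent waiver

`run_filters` matches molecules against RDKit's built-in PAINS (families
A/B/C), BRENK, NIH and ZINC catalogs (catalog provenance = the RDKit
version, recorded in every `FilterReport`) and is strict: any match in any
catalog fails the molecule.

The optimizer, however, cannot act on an alert whose matched atoms lie
entirely inside the frozen scaffold. This is not hypothetical: CBD's own
Murcko scaffold contains a cyclohexene, and the BRENK `isolated_alkene`
pattern matches that ring double bond, so under a literal all-catalogs-pass
rule *no* scaffold-preserving CBD analog could ever be feasible.
`actionable_alert_matches` therefore excludes alert occurrences confined to
scaffold atoms (occurrence-level, not alert-name-level: CBD's isopropenyl
alkene and pentyl chain remain actionable because those occurrences touch
decoration atoms, and the GA does in practice have to remove them). For
seeds whose scaffold is alert-free the waiver is a no-op and feasibility
reduces to the strict verdict. Reports print the strict per-catalog
verdicts alongside, so nothing is hidden.

## Surrogate oracles

Both external predictors are behind minimal contracts (`AffinityOracle`,
`DockingOracle`) and shipped as deterministic surrogates, pure functions of
(canonical structure, target, spec) — notation variants of a molecule score
identically, which is tested.

* **Affinity:** `pIC50 = baseline + effect · T_Morgan(drug, ref(target))`
  with baseline 3.5 and effect 3.0; targets without a planted reference
  return the baseline. A planted (query, target) pair thus scores 6.5 and
  anything with Morgan Tanimoto ≤ 1/6 to the reference stays ≤ 4.0.
* **Docking:** `score = −(base + Σ wᵢ·[molecule contains feature i])`
  clipped to [−12, 0] kcal/mol, features being target-specific SMARTS
  patterns. The bounded range mimics realistic docking magnitudes, and the
  closed-form optimum (all features present) makes GA convergence an exact,
  testable claim. The default convergence scenario plants a hydroxyl
  (`[OX2H]`, weight 2.5 — already present in CBD) and a fluorine (`[F]`,
  weight 2.5 — one atom-append away) on a base of 4.0, optimum −9.0.

These surrogates model *interfaces and orderings*, not chemistry: surrogate
pIC50 and docking numbers are meaningful only relative to their planted
structure, and nothing here approximates a trained affinity model or a
physical docking function.

## Synthetic scenarios

`datagen.generate_scenario` builds the default study bundle: 100 drugs (the
query, 10 planted near-neighbors, 89 decoys), 50 random-sequence 50-mer
protein targets of which 8 are affinity-planted and 3 of those
disease-tagged with an "Alzheimer …" phenotype, interaction edges linking
every planted target to at least one neighbor plus noise edges, and two
disease-tagged *non*-planted distractor targets that must be rejected by
the affinity filter rather than by table absence.

Neighbors are made by 1–3 scaffold-preserving edits of the query and
**verified** to exceed average-Tanimoto 0.45 and Morgan-Tanimoto 0.20
(margins above the 0.4 gate and the pIC50 > 4.0 requirement); decoys come
from a heteroaromatic/heterocyclic fragment grammar disjoint from the
query's chemotype and are verified below 0.35 / 0.15. Candidates failing a
margin are regenerated, and a scenario that cannot meet its margins raises
rather than silently shipping a broken ground truth. Protein sequences are
uniform-random because the surrogate affinity oracle addresses targets by
sequence identity, not content; sequence realism would add nothing to what
the tests can show. One seeded `random.Random` drives the whole scenario;
identical seeds give byte-identical bundles.

What the generator does **not** emulate: database scale (tens of thousands
of drugs), correlated target families, realistic pIC50 noise, assay
heterogeneity, or any property–sequence relationship. Passing the recovery
tests therefore demonstrates the pipeline's logic (gating, joining,
thresholding, evidence bookkeeping) — not predictive performance on real
pharmacological data.

## Numerical choices and degenerate inputs

* Internal computation is full precision; reports round to two decimals.
* Property profiles, fingerprints and alert matches are cached per
  canonical SMILES (the GA revisits duplicates constantly).
* Acyclic molecules have an empty-scaffold sentinel; they are valid
  everywhere except as GA seeds, where the scaffold constraint would be
  undefined and a configuration error is raised.
* Similarity/affinity ties at a threshold are excluded (strict `>`).
* An empty candidate or similar-drug set propagates as an empty result,
  never an error; a missing sequence for a candidate target or an oracle
  failure is an error naming the pair.
* Test and acceptance runs use the library defaults (population 100 × 50
  generations, ~5 s with caching; five scenario seeds for recovery), sizes
  at which every asserted property is stable.

## Known limitations

* The GA explores single-atom decorations and side-chain recombination
  only; it cannot fuse rings onto the scaffold or perform scaffold hops —
  by design, but it bounds the reachable chemical space.
* The ring penalty `max(0, largest ring − 6)` is the standard penalized-logP
  convention; other conventions (e.g. counting all macrocycles) exist.
* The BRENK/“ZINC” alert sets vary between public collections; results are
  tied to the RDKit catalog versions recorded in report provenance.
* External oracle adapters (`external:<command>`) are specified but not
  shipped; only the surrogate path is a tested integration.
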