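"""Synthetic study-scenario generator.

Builds a complete, self-contained input bundle for the two-stage pipeline:
a drug library containing the query ligand, a planted cluster of
query-similar molecules (average Morgan/MACCS Tanimoto to the query
strictly above 0.4) and structurally unrelated decoys; random-sequence
protein targets, a planted subset of which the surrogate affinity oracle
scores above the 4.0 pIC50 cutoff for the query and its neighbors; an
interaction edge table linking neighbors to the planted targets (plus
noise edges); a disease table tagging a known subset of the planted
targets with an "Alzheimer"-containing phenotype; and a ground-truth
manifest recording what the identification stage should recover.

Every separation the pipeline relies on is *verified at generation time*,
not hoped for: neighbors are regenerated until they clear the similarity
and affinity margins, decoys until they fall safely below both.
All outputs are deterministic functions of the scenario seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem, DataStructs
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .chem import CBD_SMILES, Molecule, avg_tanimoto, canonicalize, mol_from_rdkit, morgan_fp, murcko_scaffold
from .ga import mutate
from .oracles import SurrogateSpec

__all__ = [
    "QUERY_DRUG_ID",
    "ScenarioConfig",
    "GroundTruth",
    "Bundle",
    "GenerationError",
    "generate_scenario",
    "write_bundle",
    "read_truth",
]

#: Drug id under which the query ligand itself appears in the library.
QUERY_DRUG_ID = "QUERY"

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Decoy cores: heteroaromatic and saturated-heterocycle chemotypes disjoint
# from the query's resorcinol/terpene substructures, so decoys land far
# below the similarity threshold without many regeneration rounds.
_DECOY_CORES = (
    "c1ccncc1",
    "c1cncnc1",
    "c1ccoc1",
    "c1ccsc1",
    "c1cc[nH]c1",
    "c1c[nH]cn1",
    "C1CCNCC1",
    "C1COCCN1",
    "C1CNCCN1",
    "C1CCOC1",
    "NS(=O)(=O)c1ccncc1",
    "CC(=O)Nc1cncnc1",
    "N#Cc1ccoc1",
    "OC(=O)C1CCNCC1",
)
_DECOY_ELEMENTS = ("C", "N", "O", "F", "Cl")

# Margins enforced at generation time. Neighbors must exceed the 0.4
# average-similarity gate and score > 4.0 pIC50 under the planted affinity
# surrogate (baseline 3.5 + 3.0 x Morgan Tanimoto, i.e. Morgan > 1/6);
# decoys must stay strictly below both with room to spare.
_NEIGHBOR_MIN_AVG_SIM = 0.45
_NEIGHBOR_MIN_MORGAN = 0.20
_DECOY_MAX_AVG_SIM = 0.35
_DECOY_MAX_MORGAN = 0.15

#: Docking features planted for every affinity target (hydroxyl + fluorine,
#: each single-edit reachable from typical seeds; optimum -9.0 kcal/mol).
_DOCKING_FEATURES = (("[OX2H]", 2.5), ("[F]", 2.5))


class GenerationError(RuntimeError):
    """Raised when a scenario cannot satisfy its separation margins."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Shape of one synthetic study scenario.

    ``n_drugs`` counts the whole library including the query itself and the
    ``n_planted_similar`` near-neighbors; the remainder are decoys.
    ``edit_depth`` is the maximum number of scaffold-preserving substituent
    edits applied to the query to produce each neighbor.
    """

    n_drugs: int = 100
    n_planted_similar: int = 10
    n_targets: int = 50
    n_planted_affinity_targets: int = 8
    n_disease_tagged: int = 3
    edit_depth: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_similar + 1 > self.n_drugs:
            raise ValueError("n_planted_similar + query exceeds n_drugs")
        if self.n_planted_affinity_targets > self.n_targets:
            raise ValueError("n_planted_affinity_targets exceeds n_targets")
        if self.n_disease_tagged > self.n_planted_affinity_targets:
            raise ValueError("n_disease_tagged exceeds n_planted_affinity_targets")
        if self.edit_depth < 1:
            raise ValueError("edit_depth must be >= 1")


@dataclass
class GroundTruth:
    """What the identification stage should recover from the bundle."""

    planted_similar_ids: list[str]
    expected_candidate_targets: list[str]
    expected_final_targets: list[str]


@dataclass
class Bundle:
    """In-memory synthetic dataset, exactly what :func:`write_bundle` emits."""

    query_id: str
    query_smiles: str
    drugs: list[tuple[str, str]]
    targets: list[tuple[str, str]]
    edges: list[tuple[str, str]]
    disease: list[tuple[str, str]]
    xref: list[tuple[str, str]]
    oracle_spec: SurrogateSpec
    truth: GroundTruth = field(default_factory=lambda: GroundTruth([], [], []))


def _random_sequence(rng: random.Random, length: int = 50) -> str:
    return "".join(rng.choice(_AMINO_ACIDS) for _ in range(length))


def _decorate(core_smiles: str, n_edits: int, rng: random.Random) -> Molecule | None:
    """Append random substituent atoms to a decoy core (no scaffold rule)."""
    mol = Chem.MolFromSmiles(core_smiles)
    rw = Chem.RWMol(mol)
    for _ in range(n_edits):
        rw.UpdatePropertyCache(strict=False)  # new atoms need valence info
        sites = [a.GetIdx() for a in rw.GetAtoms() if a.GetTotalNumHs() >= 1]
        if not sites:
            break
        site = rng.choice(sites)
        new_idx = rw.AddAtom(Chem.Atom(rng.choice(_DECOY_ELEMENTS)))
        rw.AddBond(site, new_idx, Chem.BondType.SINGLE)
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return mol_from_rdkit(out)


def _make_neighbors(
    query: Molecule, cfg: ScenarioConfig, rng: random.Random, max_attempts: int = 400
) -> list[Molecule]:
    scaffold = murcko_scaffold(query)
    fp_query = morgan_fp(query)
    neighbors: list[Molecule] = []
    seen = {query.smiles_canonical}
    attempts = 0
    while len(neighbors) < cfg.n_planted_similar:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not plant {cfg.n_planted_similar} near-neighbors within "
                f"{max_attempts} attempts (similarity/affinity margins unreachable)"
            )
        cand = query
        for _ in range(rng.randint(1, cfg.edit_depth)):
            cand = mutate(cand, scaffold, rng)
        if cand.smiles_canonical in seen:
            continue
        if avg_tanimoto(query, cand) < _NEIGHBOR_MIN_AVG_SIM:
            continue
        if DataStructs.TanimotoSimilarity(fp_query, morgan_fp(cand)) < _NEIGHBOR_MIN_MORGAN:
            continue
        neighbors.append(cand)
        seen.add(cand.smiles_canonical)
    return neighbors


def _make_decoys(
    query: Molecule, n: int, rng: random.Random, max_attempts_each: int = 50
) -> list[Molecule]:
    fp_query = morgan_fp(query)
    decoys: list[Molecule] = []
    seen = {query.smiles_canonical}
    for _ in range(n):
        for attempt in range(max_attempts_each):
            cand = _decorate(rng.choice(_DECOY_CORES), rng.randint(0, 4), rng)
            if cand is None or cand.smiles_canonical in seen:
                continue
            if avg_tanimoto(query, cand) >= _DECOY_MAX_AVG_SIM:
                continue
            if DataStructs.TanimotoSimilarity(fp_query, morgan_fp(cand)) >= _DECOY_MAX_MORGAN:
                continue
            decoys.append(cand)
            seen.add(cand.smiles_canonical)
            break
        else:
            raise GenerationError("could not generate a decoy below the similarity margins")
    return decoys


def generate_scenario(
    cfg: ScenarioConfig, query_smiles: str = CBD_SMILES
) -> tuple[Bundle, GroundTruth]:
    """Generate the full synthetic bundle and its ground-truth manifest."""
    rng = random.Random(cfg.seed)
    query = canonicalize(query_smiles)

    neighbors = _make_neighbors(query, cfg, rng)
    n_decoys = cfg.n_drugs - 1 - cfg.n_planted_similar
    decoys = _make_decoys(query, n_decoys, rng)

    neighbor_ids = [f"SIM{i:03d}" for i in range(len(neighbors))]
    decoy_ids = [f"DEC{i:03d}" for i in range(len(decoys))]
    drugs: list[tuple[str, str]] = [(QUERY_DRUG_ID, query.smiles_canonical)]
    drugs += list(zip(neighbor_ids, (m.smiles_canonical for m in neighbors)))
    drugs += list(zip(decoy_ids, (m.smiles_canonical for m in decoys)))

    target_ids = [f"T{i:03d}" for i in range(cfg.n_targets)]
    targets = [(tid, _random_sequence(rng)) for tid in target_ids]
    planted_targets = sorted(rng.sample(target_ids, cfg.n_planted_affinity_targets))
    disease_tagged = planted_targets[: cfg.n_disease_tagged]

    edges: set[tuple[str, str]] = set()
    if neighbor_ids:
        # guarantee every planted target is reachable from some neighbor
        for j, tid in enumerate(planted_targets):
            edges.add((neighbor_ids[j % len(neighbor_ids)], tid))
        for nid in neighbor_ids:
            for tid in rng.sample(planted_targets, min(2, len(planted_targets))):
                edges.add((nid, tid))
            if rng.random() < 0.5 and target_ids:
                edges.add((nid, rng.choice(target_ids)))  # noise edge
    for did in decoy_ids:
        for _ in range(rng.randint(0, 3)):
            edges.add((did, rng.choice(target_ids)))
    for _ in range(2):
        if target_ids:
            edges.add((QUERY_DRUG_ID, rng.choice(target_ids)))

    gene_by_target = {tid: f"GENE{i}" for i, tid in enumerate(target_ids)}
    xref = [(tid, gene_by_target[tid]) for tid in target_ids]
    disease: list[tuple[str, str]] = []
    for k, tid in enumerate(disease_tagged):
        disease.append((gene_by_target[tid], f"Alzheimer disease, type {k + 1}"))
    # distractors: disease-tag up to two non-planted targets too; they must
    # be rejected by the affinity filter, not by absence from the table
    non_planted = [t for t in target_ids if t not in planted_targets]
    for tid in rng.sample(non_planted, min(2, len(non_planted))):
        disease.append((gene_by_target[tid], "Alzheimer disease, susceptibility"))
    other_phenotypes = ("Parkinson disease", "Diabetes mellitus", "Hypertension", "Asthma")
    for tid in target_ids:
        if rng.random() < 0.3:
            disease.append((gene_by_target[tid], rng.choice(other_phenotypes)))
    disease.sort()

    spec = SurrogateSpec(
        seed=cfg.seed,
        affinity_refs={tid: query.smiles_canonical for tid in planted_targets},
        target_sequences=dict(targets),
        docking_features={tid: _DOCKING_FEATURES for tid in planted_targets},
    )

    expected_candidates = sorted({t for d, t in edges if d in set(neighbor_ids)})
    truth = GroundTruth(
        planted_similar_ids=list(neighbor_ids),
        expected_candidate_targets=expected_candidates,
        expected_final_targets=list(disease_tagged) if neighbor_ids else [],
    )
    bundle = Bundle(
        query_id=QUERY_DRUG_ID,
        query_smiles=query.smiles_canonical,
        drugs=drugs,
        targets=targets,
        edges=sorted(edges),
        disease=disease,
        xref=xref,
        oracle_spec=spec,
        truth=truth,
    )
    return bundle, truth


def write_bundle(bundle: Bundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the seven bundle files in the formats stage 1 consumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {name: out_dir / name for name in (
        "drugs.smi", "targets.fasta", "interactions.tsv",
        "disease.tsv", "xref.tsv", "oracle_spec.yaml", "truth.tsv",
    )}
    paths["drugs.smi"].write_text(
        "".join(f"{smiles} {drug_id}\n" for drug_id, smiles in bundle.drugs)
    )
    records = [SeqRecord(Seq(seq), id=acc, description="") for acc, seq in bundle.targets]
    with paths["targets.fasta"].open("w") as fh:
        seqio_write(records, fh, "fasta")
    paths["interactions.tsv"].write_text(
        "drug_id\taccession\n" + "".join(f"{d}\t{t}\n" for d, t in bundle.edges)
    )
    paths["disease.tsv"].write_text(
        "gene_symbol\tphenotype\n" + "".join(f"{g}\t{p}\n" for g, p in bundle.disease)
    )
    paths["xref.tsv"].write_text(
        "accession\tgene_symbol\n" + "".join(f"{a}\t{g}\n" for a, g in bundle.xref)
    )
    paths["oracle_spec.yaml"].write_text(bundle.oracle_spec.to_yaml())
    truth_lines = ["role\tid\n"]
    for role, ids in (
        ("planted_similar", bundle.truth.planted_similar_ids),
        ("expected_candidate", bundle.truth.expected_candidate_targets),
        ("expected_final", bundle.truth.expected_final_targets),
    ):
        truth_lines += [f"{role}\t{i}\n" for i in ids]
    paths["truth.tsv"].write_text("".join(truth_lines))
    return paths


def read_truth(path: str | Path) -> GroundTruth:
    """Read back a ground-truth manifest written by :func:`write_bundle`."""
    truth = GroundTruth([], [], [])
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        role, ident = line.split("\t")
        if role == "planted_similar":
            truth.planted_similar_ids.append(ident)
        elif role == "expected_candidate":
            truth.expected_candidate_targets.append(ident)
        elif role == "expected_final":
            truth.expected_final_targets.append(ident)
        else:
            raise ValueError(f"unknown role {role!r} in truth manifest")
    return truth
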