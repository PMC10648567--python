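"""Stage 2 — scaffold-constrained genetic optimization of analogs.

Evolves analogs of a seed molecule that preserve the seed's Murcko
scaffold, minimize a docking-oracle score, and satisfy the drug-likeness
constraint surface (QED >= 0.5, SAScore <= 6.0, logP <= 5.0) and the
structural-alert filters.

Constraint handling is by constraint-domination: a feasible individual
always outranks an infeasible one; infeasible individuals rank by total
normalized violation; feasible ones rank by docking score with plogP, QED
and the canonical SMILES as deterministic tie-breaks.

Because the scaffold is frozen by construction, alert matches confined
entirely to scaffold atoms are not actionable by the optimizer and are
excluded from the feasibility test (see
:func:`scaforge.chem.actionable_alert_matches`); every alert touching a
decoration atom must be absent. For seeds with an alert-free scaffold this
is exactly the strict all-catalogs-pass requirement.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import rdmolops

from .chem import (
    FilterReport,
    Molecule,
    PropertyProfile,
    drug_likeness,
    actionable_alert_matches,
    mol_from_rdkit,
    murcko_scaffold,
    run_filters,
)
from .oracles import DockingOracle

__all__ = [
    "Individual",
    "GAConfig",
    "HallOfFame",
    "QED_MIN",
    "SASCORE_MAX",
    "LOGP_MAX",
    "initialize_population",
    "mutate",
    "crossover",
    "evaluate",
    "compare",
    "rank_key",
    "evolve",
]

logger = logging.getLogger(__name__)

# Drug-likeness constraint surface.
QED_MIN = 0.5
SASCORE_MAX = 6.0
LOGP_MAX = 5.0

_ELEMENTS = ("C", "N", "O", "S", "F", "Cl")
_MUTATION_RETRIES = 20


@dataclass
class Individual:
    """One GA solution: a molecule plus its evaluation."""

    mol: Molecule
    profile: PropertyProfile | None = None
    filter_report: FilterReport | None = None
    actionable_alerts: dict[str, tuple[str, ...]] | None = None
    docking_score: float = float("nan")
    feasible: bool = False
    violation: float = float("inf")
    generation_born: int = 0

    @property
    def evaluated(self) -> bool:
        return self.profile is not None


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters (all seeded, fully reproducible)."""

    population_size: int = 100
    generations: int = 50
    crossover_prob: float = 0.6
    mutation_prob: float = 0.4
    elite_count: int = 2
    hall_of_fame_size: int = 8
    tournament_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.crossover_prob <= 1.0 and 0.0 <= self.mutation_prob <= 1.0):
            raise ValueError("crossover_prob and mutation_prob must lie in [0, 1]")
        if self.elite_count >= self.population_size:
            raise ValueError("elite_count must be smaller than population_size")


@dataclass
class HallOfFame:
    """Best unique feasible individuals found so far, best docking first."""

    maxsize: int = 8
    members: list[Individual] = field(default_factory=list)
    #: Best-so-far feasible docking score after each generation (nan while
    #: no feasible individual has been seen).
    best_feasible_history: list[float] = field(default_factory=list)

    def update(self, population: list[Individual]) -> None:
        seen = {ind.mol.smiles_canonical for ind in self.members}
        for ind in population:
            if ind.feasible and ind.mol.smiles_canonical not in seen:
                self.members.append(ind)
                seen.add(ind.mol.smiles_canonical)
        self.members.sort(key=rank_key)
        del self.members[self.maxsize:]

    @property
    def best_score(self) -> float:
        return self.members[0].docking_score if self.members else float("nan")


def rank_key(ind: Individual):
    """Total-order sort key implementing constraint-domination (lower wins)."""
    if not ind.evaluated:
        raise ValueError("individual has not been evaluated")
    return (
        0 if ind.feasible else 1,
        0.0 if ind.feasible else ind.violation,
        ind.docking_score,
        -ind.profile.plogp,
        -ind.profile.qed,
        ind.mol.smiles_canonical,
    )


def compare(x: Individual, y: Individual) -> int:
    """-1 if ``x`` outranks ``y``, 1 if ``y`` outranks ``x``, else 0."""
    kx, ky = rank_key(x), rank_key(y)
    return -1 if kx < ky else (1 if kx > ky else 0)


# ---------------------------------------------------------------------------
# variation operators


def _scaffold_atom_set(mol: Chem.Mol, scaffold: Molecule) -> set[int]:
    return set(mol.GetSubstructMatch(scaffold.rdmol))


def _finalize(rw: Chem.RWMol) -> Chem.Mol | None:
    try:
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        # edits next to stereocenters can orphan stereo tags; drop invalid ones
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        return mol
    except Exception:
        return None


def _op_append(rw: Chem.RWMol, rng: random.Random, scaffold_atoms: set[int]) -> bool:
    sites = [a.GetIdx() for a in rw.GetAtoms() if a.GetTotalNumHs() >= 1]
    if not sites:
        return False
    site = rng.choice(sites)
    new_idx = rw.AddAtom(Chem.Atom(rng.choice(_ELEMENTS)))
    rw.AddBond(site, new_idx, Chem.BondType.SINGLE)
    return True


def _op_delete(rw: Chem.RWMol, rng: random.Random, scaffold_atoms: set[int]) -> bool:
    sites = [
        a.GetIdx()
        for a in rw.GetAtoms()
        if a.GetDegree() == 1 and a.GetIdx() not in scaffold_atoms
    ]
    if not sites:
        return False
    rw.RemoveAtom(rng.choice(sites))
    return True


def _op_swap(rw: Chem.RWMol, rng: random.Random, scaffold_atoms: set[int]) -> bool:
    sites = [
        a.GetIdx()
        for a in rw.GetAtoms()
        if a.GetIdx() not in scaffold_atoms and not a.GetIsAromatic()
    ]
    if not sites:
        return False
    atom = rw.GetAtomWithIdx(rng.choice(sites))
    choices = [e for e in _ELEMENTS if e != atom.GetSymbol()]
    atom.SetAtomicNum(Chem.GetPeriodicTable().GetAtomicNumber(rng.choice(choices)))
    atom.SetFormalCharge(0)
    atom.SetNoImplicit(False)
    atom.SetNumExplicitHs(0)
    return True


def _op_bond_order(rw: Chem.RWMol, rng: random.Random, scaffold_atoms: set[int]) -> bool:
    bonds = [
        b
        for b in rw.GetBonds()
        if not b.IsInRing()
        and not b.GetBeginAtom().GetIsAromatic()
        and not b.GetEndAtom().GetIsAromatic()
        and b.GetBondType() in (Chem.BondType.SINGLE, Chem.BondType.DOUBLE)
    ]
    if not bonds:
        return False
    bond = rng.choice(bonds)
    if bond.GetBondType() == Chem.BondType.SINGLE:
        bond.SetBondType(Chem.BondType.DOUBLE)
    else:
        bond.SetBondType(Chem.BondType.SINGLE)
    return True


_OPERATORS = (_op_append, _op_delete, _op_swap, _op_bond_order)


def mutate(
    m: Molecule,
    seed_scaffold: Molecule,
    rng: random.Random,
    max_retries: int = _MUTATION_RETRIES,
) -> Molecule:
    """Apply one random scaffold-preserving structural edit.

    Operators: append a substituent atom, delete a terminal non-scaffold
    atom, swap a non-scaffold heavy atom among C/N/O/S/F/Cl, or toggle a
    non-ring bond between single and double. A child that fails valence
    sanitization or whose Murcko scaffold differs from the seed's is
    discarded; after ``max_retries`` failures the input is returned
    unchanged.
    """
    for _ in range(max_retries + 1):
        rw = Chem.RWMol(m.rdmol)
        scaffold_atoms = _scaffold_atom_set(rw, seed_scaffold)
        op = rng.choice(_OPERATORS)
        if not op(rw, rng, scaffold_atoms):
            continue
        mol = _finalize(rw)
        if mol is None or mol.GetNumAtoms() == 0 or len(rdmolops.GetMolFrags(mol)) != 1:
            continue
        child = mol_from_rdkit(mol)
        if murcko_scaffold(child) == seed_scaffold:
            return child
    return m


def _decompose(m: Molecule, scaffold: Molecule) -> dict[int, list[str]] | None:
    """Side chains per scaffold attachment atom index, as dummy-labelled SMILES."""
    try:
        chains = Chem.ReplaceCore(m.rdmol, scaffold.rdmol, labelByIndex=True)
    except Exception:
        return None
    if chains is None:
        return None
    out: dict[int, list[str]] = {}
    for frag in Chem.GetMolFrags(chains, asMols=True, sanitizeFrags=False):
        dummies = [a for a in frag.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            return None  # multi-attachment side chain: no clean decomposition
        idx = dummies[0].GetIsotope()
        out.setdefault(idx, []).append(Chem.MolToSmiles(frag))
    return {k: sorted(v) for k, v in out.items()}


def _graft(
    m: Molecule, scaffold: Molecule, attach_idx: int, new_frags: list[str]
) -> Molecule | None:
    """Replace the side chains of ``m`` at one scaffold position."""
    rw = Chem.RWMol(m.rdmol)
    match = rw.GetMol().GetSubstructMatch(scaffold.rdmol)
    if not match or attach_idx >= len(match):
        return None
    scaffold_atoms = set(match)
    root = match[attach_idx]
    # collect the existing side-chain atoms rooted at this position
    doomed: set[int] = set()
    stack = [
        n.GetIdx()
        for n in rw.GetAtomWithIdx(root).GetNeighbors()
        if n.GetIdx() not in scaffold_atoms
    ]
    while stack:
        idx = stack.pop()
        if idx in doomed:
            continue
        doomed.add(idx)
        stack.extend(
            n.GetIdx()
            for n in rw.GetAtomWithIdx(idx).GetNeighbors()
            if n.GetIdx() not in scaffold_atoms and n.GetIdx() not in doomed
        )
    for idx in sorted(doomed, reverse=True):
        rw.RemoveAtom(idx)
    # removal renumbers atoms: re-locate the attachment root
    match = rw.GetMol().GetSubstructMatch(scaffold.rdmol)
    if not match:
        return None
    root = match[attach_idx]
    for frag_smiles in new_frags:
        frag = Chem.MolFromSmiles(frag_smiles, sanitize=False)
        if frag is None:
            return None
        offset = rw.GetNumAtoms()
        rw.InsertMol(frag)
        dummy = next(
            (a.GetIdx() for a in rw.GetAtoms() if a.GetIdx() >= offset and a.GetAtomicNum() == 0),
            None,
        )
        if dummy is None:
            return None
        dummy_atom = rw.GetAtomWithIdx(dummy)
        neighbors = dummy_atom.GetNeighbors()
        if len(neighbors) != 1:
            return None
        order = rw.GetBondBetweenAtoms(dummy, neighbors[0].GetIdx()).GetBondType()
        rw.AddBond(root, neighbors[0].GetIdx(), order)
        rw.RemoveAtom(dummy)
    mol = _finalize(rw)
    if mol is None or mol.GetNumAtoms() == 0 or len(rdmolops.GetMolFrags(mol)) != 1:
        return None
    return mol_from_rdkit(mol)


def crossover(
    a: Molecule,
    b: Molecule,
    seed_scaffold: Molecule,
    rng: random.Random,
    max_retries: int = 8,
) -> Molecule:
    """Recombine two parents sharing the seed scaffold.

    Both parents are decomposed into scaffold plus per-attachment-point side
    chains; the child is parent ``a`` with the side chains at one randomly
    chosen differing attachment point taken from a randomly chosen parent.
    Falls back to ``mutate(a)`` when no clean decomposition or valid graft
    exists.
    """
    if a == b:
        return a
    da = _decompose(a, seed_scaffold)
    db = _decompose(b, seed_scaffold)
    if da is None or db is None:
        return mutate(a, seed_scaffold, rng)
    differing = sorted(
        idx for idx in set(da) | set(db) if da.get(idx, []) != db.get(idx, [])
    )
    if not differing:
        return a
    for _ in range(max_retries):
        idx = rng.choice(differing)
        if rng.random() < 0.5:
            return a  # keep a's substituent at the chosen point
        child = _graft(a, seed_scaffold, idx, db.get(idx, []))
        if child is not None and murcko_scaffold(child) == seed_scaffold:
            return child
    return mutate(a, seed_scaffold, rng)


# ---------------------------------------------------------------------------
# evaluation and the generational loop


def evaluate(
    mol: Molecule,
    seed_scaffold: Molecule,
    oracle: DockingOracle,
    target_id: str,
    generation_born: int = 0,
) -> Individual:
    """Score a molecule: properties, filters, docking, feasibility.

    Feasible iff QED >= 0.5, SAScore <= 6.0, logP <= 5.0, the Murcko
    scaffold equals the seed scaffold, and no actionable structural alert
    matches (alerts confined to the frozen scaffold excluded). ``violation``
    sums the normalized constraint shortfalls and is 0 exactly when
    feasible.
    """
    profile = drug_likeness(mol)
    report = run_filters(mol)
    actionable = actionable_alert_matches(mol, seed_scaffold)
    try:
        docking = oracle.score(mol, target_id)
    except Exception as exc:
        raise RuntimeError(f"docking oracle failed on {mol.smiles_canonical}: {exc}") from exc
    scaffold_ok = murcko_scaffold(mol) == seed_scaffold
    n_alerts = sum(len(v) for v in actionable.values())
    violation = (
        max(0.0, QED_MIN - profile.qed) / QED_MIN
        + max(0.0, profile.sascore - SASCORE_MAX) / (10.0 - SASCORE_MAX)
        + max(0.0, profile.logp - LOGP_MAX) / LOGP_MAX
        + float(n_alerts)
        + (0.0 if scaffold_ok else 1.0)
    )
    return Individual(
        mol=mol,
        profile=profile,
        filter_report=report,
        actionable_alerts=actionable,
        docking_score=docking,
        feasible=violation == 0.0,
        violation=violation,
        generation_born=generation_born,
    )


def initialize_population(
    seed_mol: Molecule,
    cfg: GAConfig,
    rng: random.Random,
    seed_scaffold: Molecule | None = None,
) -> list[Molecule]:
    """Seed molecule plus single-mutation variants, all scaffold-preserving."""
    scaffold = seed_scaffold if seed_scaffold is not None else murcko_scaffold(seed_mol)
    if scaffold.is_empty:
        raise ValueError(
            "seed molecule is acyclic: the scaffold constraint is undefined for an empty scaffold"
        )
    population = [seed_mol]
    while len(population) < cfg.population_size:
        population.append(mutate(seed_mol, scaffold, rng))
    return population


def _tournament(population: list[Individual], rng: random.Random, k: int) -> Individual:
    return min(rng.sample(population, min(k, len(population))), key=rank_key)


def evolve(
    seed_mol: Molecule,
    target_id: str,
    cfg: GAConfig,
    oracle: DockingOracle,
) -> HallOfFame:
    """Run the generational GA and return the hall of fame.

    Tournament selection (size 3), single-point scaffold-aware crossover and
    one-edit mutation at the configured probabilities, elitism of
    ``elite_count``, and a running hall of fame of unique feasible
    individuals. Fully reproducible under ``cfg.seed``. If no feasible
    individual is ever found the hall of fame is returned empty with a
    logged warning.
    """
    rng = random.Random(cfg.seed)
    scaffold = murcko_scaffold(seed_mol)
    cache: dict[str, Individual] = {}

    def score(mol: Molecule, gen: int) -> Individual:
        key = mol.smiles_canonical
        cached = cache.get(key)
        if cached is None:
            cache[key] = cached = evaluate(mol, scaffold, oracle, target_id, gen)
        return cached

    molecules = initialize_population(seed_mol, cfg, rng, scaffold)
    population = [score(m, 0) for m in molecules]
    hof = HallOfFame(maxsize=cfg.hall_of_fame_size)
    hof.update(population)
    hof.best_feasible_history.append(hof.best_score)
    for gen in range(1, cfg.generations + 1):
        elites = sorted(population, key=rank_key)[: cfg.elite_count]
        offspring: list[Individual] = list(elites)
        while len(offspring) < cfg.population_size:
            parent = _tournament(population, rng, cfg.tournament_size)
            child_mol = parent.mol
            if rng.random() < cfg.crossover_prob:
                other = _tournament(population, rng, cfg.tournament_size)
                child_mol = crossover(child_mol, other.mol, scaffold, rng)
            if rng.random() < cfg.mutation_prob:
                child_mol = mutate(child_mol, scaffold, rng)
            offspring.append(score(child_mol, gen))
        population = offspring
        hof.update(population)
        hof.best_feasible_history.append(hof.best_score)
        n_feasible = sum(ind.feasible for ind in population)
        logger.info(
            "generation %d: best=%s feasible=%d/%d hof=%d",
            gen,
            f"{hof.best_score:.3f}" if hof.members else "none",
            n_feasible,
            len(population),
            len(hof.members),
        )
    if not hof.members:
        logger.warning(
            "no feasible individual found in %d generations for target %s",
            cfg.generations,
            target_id,
        )
    return hof
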