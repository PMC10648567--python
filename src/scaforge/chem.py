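"""Molecular parsing, fingerprints, similarity, drug-likeness and alert filters.

This module is the shared computational substrate for both pipeline stages:
ligand-based target fishing (which needs canonical structures and fingerprint
similarity) and scaffold-constrained analog optimization (which needs the
penalized-logP objective, the QED / SAScore / logP drug-likeness surface,
Murcko scaffolds, and the PAINS / BRENK / NIH / ZINC structural-alert
catalogs).

All computations are deterministic functions of the canonical SMILES; heavy
RDKit objects (parsed molecules, fingerprints, catalog matches) are cached
per canonical structure.
"""

from __future__ import annotations

import functools
import os
import sys
from dataclasses import dataclass

import rdkit
from rdkit import Chem, RDConfig
from rdkit.Chem import AllChem, Crippen, DataStructs, MACCSkeys, QED
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams
from rdkit.Chem.Scaffolds import MurckoScaffold

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib, importable only after the path append)

__all__ = [
    "CBD_SMILES",
    "ALERT_CATALOGS",
    "MORGAN_RADIUS",
    "MORGAN_NBITS",
    "Molecule",
    "EMPTY_SCAFFOLD",
    "PropertyProfile",
    "FilterReport",
    "ParseError",
    "canonicalize",
    "morgan_fp",
    "maccs_fp",
    "avg_tanimoto",
    "ring_penalty",
    "plogp",
    "drug_likeness",
    "run_filters",
    "actionable_alert_matches",
    "murcko_scaffold",
]

#: Cannabidiol, the query ligand and optimization seed.
CBD_SMILES = "CCCCCc1cc(O)c([C@@H]2C=C(C)CC[C@H]2C(=C)C)c(O)c1"

#: Structural-alert catalog names, in reporting order.
ALERT_CATALOGS = ("PAINS", "BRENK", "NIH", "ZINC")

# Morgan fingerprint parameters (ECFP4-equivalent, the de-facto standard).
MORGAN_RADIUS = 2
MORGAN_NBITS = 2048


class ParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class Molecule:
    """A parsed molecule identified by its canonical SMILES.

    Two inputs describing the same structure compare equal because equality
    (and hashing) is driven by ``smiles_canonical`` alone.
    """

    smiles_input: str
    smiles_canonical: str
    n_atoms: int
    n_rings: int
    largest_ring_size: int

    @property
    def is_empty(self) -> bool:
        return self.smiles_canonical == ""

    @property
    def rdmol(self) -> Chem.Mol:
        if self.is_empty:
            return Chem.Mol()
        return _rdmol(self.smiles_canonical)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Molecule):
            return NotImplemented
        return self.smiles_canonical == other.smiles_canonical

    def __hash__(self) -> int:
        return hash(self.smiles_canonical)


#: Sentinel returned by :func:`murcko_scaffold` for acyclic molecules.
EMPTY_SCAFFOLD = Molecule(
    smiles_input="", smiles_canonical="", n_atoms=0, n_rings=0, largest_ring_size=0
)


@dataclass(frozen=True)
class PropertyProfile:
    """Drug-likeness surface of one molecule.

    ``plogp`` is the penalized octanol-water partition estimate,
    logP - SAScore - RingPenalty, the quantity maximized (all else equal)
    during analog generation. The four ``*_pass`` booleans report the strict
    structural-alert verdicts (no waivers).
    """

    qed: float
    sascore: float
    logp: float
    ring_penalty: int
    plogp: float
    pains_pass: bool
    brenk_pass: bool
    nih_pass: bool
    zinc_pass: bool


@dataclass(frozen=True)
class FilterReport:
    """Structural-alert verdicts for one molecule.

    ``matches`` maps each catalog name to the (possibly empty) tuple of
    matched alert names; ``overall_pass`` is true iff every catalog matched
    nothing. ``catalog_version`` records the provenance of the alert sets.
    """

    matches: dict[str, tuple[str, ...]]
    overall_pass: bool
    catalog_version: str

    def passed(self, catalog: str) -> bool:
        return len(self.matches[catalog]) == 0


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    return mol


@functools.lru_cache(maxsize=100_000)
def _rdmol(canonical_smiles: str) -> Chem.Mol:
    return _mol_from_smiles(canonical_smiles)


def _describe(mol: Chem.Mol, smiles_input: str, canonical: str) -> Molecule:
    ring_info = mol.GetRingInfo()
    sizes = [len(r) for r in ring_info.AtomRings()]
    return Molecule(
        smiles_input=smiles_input,
        smiles_canonical=canonical,
        n_atoms=mol.GetNumAtoms(),
        n_rings=len(sizes),
        largest_ring_size=max(sizes, default=0),
    )


def canonicalize(smiles: str) -> Molecule:
    """Parse a SMILES string and return the canonical :class:`Molecule`.

    Raises :class:`ParseError` (naming the offending input) on invalid
    SMILES. Canonicalization is idempotent: re-canonicalizing the canonical
    form returns an equal molecule.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    mol = _mol_from_smiles(smiles.strip())
    canonical = Chem.MolToSmiles(mol)
    return _describe(_rdmol(canonical), smiles, canonical)


def mol_from_rdkit(mol: Chem.Mol, smiles_input: str | None = None) -> Molecule:
    """Wrap an in-memory RDKit molecule (already sanitized) as a Molecule."""
    canonical = Chem.MolToSmiles(mol)
    if canonical == "":
        return EMPTY_SCAFFOLD
    return _describe(_rdmol(canonical), smiles_input or canonical, canonical)


@functools.lru_cache(maxsize=100_000)
def _morgan_fp(canonical_smiles: str):
    return AllChem.GetMorganFingerprintAsBitVect(
        _rdmol(canonical_smiles), MORGAN_RADIUS, nBits=MORGAN_NBITS
    )


@functools.lru_cache(maxsize=100_000)
def _maccs_fp(canonical_smiles: str):
    return MACCSkeys.GenMACCSKeys(_rdmol(canonical_smiles))


def morgan_fp(m: Molecule):
    """Morgan (circular) bit fingerprint, radius 2, 2048 bits."""
    return _morgan_fp(m.smiles_canonical)


def maccs_fp(m: Molecule):
    """MACCS structural-key fingerprint (166 keys; RDKit bit 0 is unused)."""
    return _maccs_fp(m.smiles_canonical)


def avg_tanimoto(a: Molecule, b: Molecule) -> float:
    """Average of the Morgan and MACCS Tanimoto similarities of two molecules.

    Symmetric, in [0, 1], and equal to 1.0 exactly when both fingerprints
    are identical. This is the similarity used by the target-fishing gate.
    """
    t_morgan = DataStructs.TanimotoSimilarity(morgan_fp(a), morgan_fp(b))
    t_maccs = DataStructs.TanimotoSimilarity(maccs_fp(a), maccs_fp(b))
    return (t_morgan + t_maccs) / 2.0


def ring_penalty(m: Molecule) -> int:
    """Number of atoms by which the largest ring exceeds six (0 otherwise).

    Large-ring penalty of the penalized-logP objective. Acyclic molecules
    and molecules whose rings all have six or fewer atoms incur no penalty.
    """
    return max(0, m.largest_ring_size - 6)


def plogp(logp: float, sascore: float, ring_penalty: float) -> float:
    """Penalized logP: logP - SAScore - RingPenalty."""
    return logp - sascore - ring_penalty


_catalog_cache: dict[tuple[str, ...], FilterCatalog] = {}


def _catalog(names: tuple[str, ...] = ALERT_CATALOGS) -> FilterCatalog:
    if names not in _catalog_cache:
        params = FilterCatalogParams()
        for name in names:
            if not params.AddCatalog(getattr(FilterCatalogParams.FilterCatalogs, name)):
                raise RuntimeError(f"alert catalog {name} unavailable in this RDKit build")
        _catalog_cache[names] = FilterCatalog(params)
    return _catalog_cache[names]


def catalog_version() -> str:
    """Provenance string for the structural-alert catalogs in use."""
    return f"rdkit-{rdkit.__version__}"


@functools.lru_cache(maxsize=100_000)
def _filter_matches(
    canonical_smiles: str,
) -> dict[str, tuple[tuple[str, tuple[frozenset[int], ...]], ...]]:
    """Per-catalog alert matches, each with its per-occurrence atom index sets.

    One alert pattern can match a molecule in several places; the atom sets
    are kept per occurrence so downstream logic can reason about where each
    match sits (e.g. inside an immutable scaffold).
    """
    mol = _rdmol(canonical_smiles)
    out: dict[str, tuple[tuple[str, tuple[frozenset[int], ...]], ...]] = {}
    for name in ALERT_CATALOGS:
        cat = _catalog((name,))
        hits: list[tuple[str, tuple[frozenset[int], ...]]] = []
        for entry in cat.GetMatches(mol):
            occurrences = tuple(
                frozenset(mol_idx for _, mol_idx in fm.atomPairs)
                for fm in entry.GetFilterMatches(mol)
            )
            hits.append((entry.GetDescription(), occurrences))
        out[name] = tuple(hits)
    return out


def run_filters(m: Molecule) -> FilterReport:
    """Match a molecule against the PAINS, BRENK, NIH and ZINC alert catalogs.

    ``overall_pass`` is true iff all four catalogs matched zero alerts; the
    per-catalog matched alert names are reported so a failure is auditable.
    """
    raw = _filter_matches(m.smiles_canonical)
    matches = {name: tuple(alert for alert, _ in raw[name]) for name in ALERT_CATALOGS}
    overall = all(len(v) == 0 for v in matches.values())
    return FilterReport(matches=matches, overall_pass=overall, catalog_version=catalog_version())


def actionable_alert_matches(m: Molecule, frozen_scaffold: Molecule) -> dict[str, tuple[str, ...]]:
    """Alert matches excluding those confined to an immutable scaffold.

    During scaffold-constrained optimization the scaffold atoms cannot be
    edited, so an alert whose matched atoms all belong to the scaffold is
    not actionable by the optimizer and is excluded here; every match that
    touches at least one decoration atom is retained. For seeds whose bare
    scaffold is alert-free this reduces to the strict :func:`run_filters`
    verdict.
    """
    raw = _filter_matches(m.smiles_canonical)
    if frozen_scaffold.is_empty:
        return {name: tuple(alert for alert, _ in raw[name]) for name in ALERT_CATALOGS}
    match = m.rdmol.GetSubstructMatch(frozen_scaffold.rdmol)
    scaffold_atoms = frozenset(match)
    out: dict[str, tuple[str, ...]] = {}
    for name in ALERT_CATALOGS:
        kept = tuple(
            alert
            for alert, occurrences in raw[name]
            # actionable iff some occurrence touches a non-scaffold atom
            # (no atom info at all is treated as actionable, conservatively)
            if not occurrences
            or any(not (atoms and atoms <= scaffold_atoms) for atoms in occurrences)
        )
        out[name] = kept
    return out


@functools.lru_cache(maxsize=100_000)
def _profile(canonical_smiles: str) -> PropertyProfile:
    mol = _rdmol(canonical_smiles)
    m = _describe(mol, canonical_smiles, canonical_smiles)
    qed = QED.qed(mol)
    sas = sascorer.calculateScore(mol)
    logp = Crippen.MolLogP(mol)
    rp = ring_penalty(m)
    report = run_filters(m)
    return PropertyProfile(
        qed=qed,
        sascore=sas,
        logp=logp,
        ring_penalty=rp,
        plogp=plogp(logp, sas, rp),
        pains_pass=report.passed("PAINS"),
        brenk_pass=report.passed("BRENK"),
        nih_pass=report.passed("NIH"),
        zinc_pass=report.passed("ZINC"),
    )


def drug_likeness(m: Molecule) -> PropertyProfile:
    """Compute the full drug-likeness profile of a molecule.

    QED is Bickerton's desirability-weighted estimate (mean weights);
    SAScore is the Ertl-Schuffenhauer fragment-contribution synthetic
    accessibility score in [1, 10]; logP is the Wildman-Crippen atom
    contribution estimate. plogp = logp - sascore - ring_penalty.
    """
    return _profile(m.smiles_canonical)


def murcko_scaffold(m: Molecule) -> Molecule:
    """Murcko scaffold: ring systems plus linkers, side chains removed.

    Acyclic molecules yield :data:`EMPTY_SCAFFOLD`. Idempotent — the
    scaffold of a scaffold is itself.
    """
    if m.is_empty or m.n_rings == 0:
        return EMPTY_SCAFFOLD
    scaffold = MurckoScaffold.GetScaffoldForMol(m.rdmol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return EMPTY_SCAFFOLD
    return mol_from_rdkit(scaffold)
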