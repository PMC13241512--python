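"""Graph genetic-algorithm refinement of candidate structures.

Candidates evolve directly on the molecular graph (atom/bond/substructure
edits and fragment crossover) under the reward

    R = (1/N) * sum_x d_cos(eps_x, eps_molecule)  -  W / T

where the sum runs over the N available spectral modalities, W is the
number of wrong atoms of the candidate's formula relative to the target
formula (hydrogens included) and T is the target's total atom count. The
formula term penalises rather than forbids off-formula candidates, keeping
the search exploratory. Multiple seeded runs are aggregated by max-score
deduplication; matches are checked with Morgan fingerprints
(radius 6, 2048 bits).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator

from .chem import molecular_formula
from .retrieval import fused_score

logger = logging.getLogger(__name__)

__all__ = [
    "RewardBreakdown",
    "GAConfig",
    "Candidate",
    "CandidateRanking",
    "MatchResult",
    "wrong_atom_count",
    "reward",
    "evolve",
    "aggregate",
    "is_match",
    "GraphGARefiner",
]

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=6, fpSize=2048)


@dataclass(frozen=True)
class RewardBreakdown:
    """Eq. terms of the GA reward: cosines, formula penalty, scalar R."""

    per_modality: dict[str, float]
    n: int
    w: int
    t: int
    r: float


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    offspring_size: int = 200
    mutation_rate: float = 0.05
    generations: int = 15
    n_seeds: int = 3
    elitism: int = 5

    def __post_init__(self):
        if self.generations < 1 or self.n_seeds < 1:
            raise ValueError("generations and n_seeds must be >= 1")
        if self.elitism < 1:
            raise ValueError("elitism must be >= 1")


@dataclass
class Candidate:
    smiles: str
    reward: RewardBreakdown
    provenance: str = "generated"  # "retrieved" | "generated"


@dataclass
class CandidateRanking:
    """Deduplicated candidates sorted by R descending."""

    candidates: list[Candidate] = field(default_factory=list)

    def top(self, k: int = 20) -> list[Candidate]:
        return self.candidates[:k]

    def __len__(self) -> int:
        return len(self.candidates)


@dataclass(frozen=True)
class MatchResult:
    fingerprint_match: bool  # Morgan radius 6 / 2048 bits equality (primary)
    canonical_match: bool  # exact canonical-SMILES equality (collision guard)

    def __bool__(self) -> bool:
        return self.fingerprint_match


def wrong_atom_count(candidate_formula: dict[str, int],
                     target_formula: dict[str, int]) -> tuple[int, int]:
    """W = summed per-element absolute count difference; T = target atom total."""
    if not candidate_formula or not target_formula:
        raise ValueError("formulas must be non-empty")
    elements = set(candidate_formula) | set(target_formula)
    w = sum(abs(candidate_formula.get(el, 0) - target_formula.get(el, 0))
            for el in elements)
    t = sum(target_formula.values())
    return w, t


def reward(candidate_smiles: str, spectra_embeddings: dict[str, np.ndarray],
           target_formula: dict[str, int], aligner) -> RewardBreakdown:
    """Score one candidate; invalid structures get an -inf sentinel."""
    mol = Chem.MolFromSmiles(candidate_smiles)
    if mol is None:
        logger.warning("invalid candidate %r; assigning -inf reward", candidate_smiles)
        return RewardBreakdown({}, len(spectra_embeddings), 0,
                               sum(target_formula.values()), -math.inf)
    mol_emb = aligner.encode_molecule(candidate_smiles)
    per_mod = {}
    for m, e in spectra_embeddings.items():
        per_mod[m] = fused_score({m: e}, mol_emb)
    sim = fused_score(spectra_embeddings, mol_emb)
    w, t = wrong_atom_count(molecular_formula(mol), target_formula)
    return RewardBreakdown(per_mod, len(spectra_embeddings), w, t, sim - w / t)


# ---------------------------------------------------------------------------
# Graph operators
# ---------------------------------------------------------------------------

_PALETTE = ("C", "N", "O", "Cl")
_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "Cl": 1}


def _editable(mol: Chem.Mol) -> Chem.RWMol | None:
    m = Chem.Mol(mol)
    try:
        Chem.Kekulize(m, clearAromaticFlags=True)
    except Exception:
        return None
    return Chem.RWMol(m)


def _finalize(mol: Chem.RWMol) -> str | None:
    try:
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        smi = Chem.MolToSmiles(m)
        if not smi or "." in smi:
            return None
        return smi
    except Exception:
        return None


def _free_valence(atom: Chem.Atom) -> int:
    cap = _MAX_VALENCE.get(atom.GetSymbol())
    if cap is None:
        return 0
    used = int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))
    return cap - used


def _cut_fragment(mol: Chem.Mol, rng: np.random.Generator) -> tuple[Chem.RWMol, int] | None:
    """Cut a random acyclic single bond; return one fragment + attachment index."""
    em = _editable(mol)
    if em is None:
        return None
    bonds = [
        b for b in em.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE and not b.IsInRing()
    ]
    if not bonds:
        return None
    b = bonds[int(rng.integers(len(bonds)))]
    i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
    em.RemoveBond(i, j)
    frags = Chem.GetMolFrags(em.GetMol())
    attach = i if rng.random() < 0.5 else j
    frag_atoms = next(f for f in frags if attach in f)
    keep = set(frag_atoms)
    out = Chem.RWMol()
    remap: dict[int, int] = {}
    for idx in sorted(keep):
        remap[idx] = out.AddAtom(Chem.Atom(em.GetAtomWithIdx(idx)))
    for bond in em.GetBonds():
        a, c = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a in keep and c in keep:
            out.AddBond(remap[a], remap[c], bond.GetBondType())
    return out, remap[attach]


def crossover(smiles_a: str, smiles_b: str, rng: np.random.Generator) -> str | None:
    """Join a random fragment of each parent at their cut points."""
    ma, mb = Chem.MolFromSmiles(smiles_a), Chem.MolFromSmiles(smiles_b)
    if ma is None or mb is None:
        return None
    cut_a = _cut_fragment(ma, rng)
    cut_b = _cut_fragment(mb, rng)
    if cut_a is None or cut_b is None:
        return None
    frag_a, at_a = cut_a
    frag_b, at_b = cut_b
    combined = Chem.RWMol(frag_a)
    offset = combined.GetNumAtoms()
    for idx in range(frag_b.GetNumAtoms()):
        combined.AddAtom(Chem.Atom(frag_b.GetAtomWithIdx(idx)))
    for bond in frag_b.GetBonds():
        combined.AddBond(bond.GetBeginAtomIdx() + offset,
                         bond.GetEndAtomIdx() + offset, bond.GetBondType())
    combined.AddBond(at_a, at_b + offset, Chem.BondType.SINGLE)
    return _finalize(combined)


def mutate(smiles: str, rng: np.random.Generator, n_tries: int = 8) -> str | None:
    """One random graph edit: element swap, atom add/delete, bond-order change
    or substituent append. Returns None if no valid edit is found."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    for _ in range(n_tries):
        em = _editable(mol)
        if em is None:
            return None
        op = int(rng.integers(5))
        n = em.GetNumAtoms()
        if n == 0:
            return None
        if op == 0:  # element swap
            idx = int(rng.integers(n))
            atom = em.GetAtomWithIdx(idx)
            used = int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))
            choices = [s for s in _PALETTE
                       if s != atom.GetSymbol() and _MAX_VALENCE[s] >= used]
            if not choices:
                continue
            atom.SetAtomicNum(
                Chem.GetPeriodicTable().GetAtomicNumber(
                    str(choices[int(rng.integers(len(choices)))])
                )
            )
        elif op == 1:  # add one atom
            sites = [i for i in range(n) if _free_valence(em.GetAtomWithIdx(i)) >= 1]
            if not sites:
                continue
            anchor = int(sites[int(rng.integers(len(sites)))])
            sym = str(_PALETTE[int(rng.integers(len(_PALETTE)))])
            new = em.AddAtom(Chem.Atom(sym))
            em.AddBond(anchor, new, Chem.BondType.SINGLE)
        elif op == 2:  # delete a terminal atom
            terms = [a.GetIdx() for a in em.GetAtoms() if a.GetDegree() == 1]
            if not terms or n <= 2:
                continue
            em.RemoveAtom(int(terms[int(rng.integers(len(terms)))]))
        elif op == 3:  # bond order toggle
            bonds = [b for b in em.GetBonds() if not b.IsInRing()]
            if not bonds:
                continue
            b = bonds[int(rng.integers(len(bonds)))]
            if b.GetBondType() == Chem.BondType.DOUBLE:
                b.SetBondType(Chem.BondType.SINGLE)
            else:
                a1, a2 = b.GetBeginAtom(), b.GetEndAtom()
                if _free_valence(a1) >= 1 and _free_valence(a2) >= 1:
                    b.SetBondType(Chem.BondType.DOUBLE)
                else:
                    continue
        else:  # append a small substituent
            frag = str(["C", "O", "N", "Cl", "CO", "C=O"][int(rng.integers(6))])
            sites = [i for i in range(n) if _free_valence(em.GetAtomWithIdx(i)) >= 1]
            if not sites:
                continue
            anchor = int(sites[int(rng.integers(len(sites)))])
            fmol = Chem.MolFromSmiles(frag)
            offset = em.GetNumAtoms()
            for k in range(fmol.GetNumAtoms()):
                em.AddAtom(Chem.Atom(fmol.GetAtomWithIdx(k)))
            for bond in fmol.GetBonds():
                em.AddBond(bond.GetBeginAtomIdx() + offset,
                           bond.GetEndAtomIdx() + offset, bond.GetBondType())
            em.AddBond(anchor, offset, Chem.BondType.SINGLE)
        out = _finalize(em)
        if out is not None and out != Chem.MolToSmiles(mol):
            return out
    return None


# ---------------------------------------------------------------------------
# Evolution loop
# ---------------------------------------------------------------------------


def _rank_probabilities(n: int) -> np.ndarray:
    # selection proportional to rank of R (best gets weight n)
    w = np.arange(n, 0, -1, dtype=float)
    return w / w.sum()


def evolve(initial_population: list[str], reward_fn, config: GAConfig,
           seed: int = 0, history: list | None = None) -> list[Candidate]:
    """Run one seeded GA; returns the final population sorted by R descending.

    `reward_fn(smiles) -> RewardBreakdown`. Elitism guarantees the best R is
    non-decreasing across generations. Deterministic given `seed`. If a list
    is passed as `history`, the per-generation best and mean R are appended
    to it.
    """
    if not initial_population:
        raise ValueError("initial population must be non-empty")
    rng = np.random.default_rng(seed)
    cache: dict[str, RewardBreakdown] = {}

    def score(smi: str) -> RewardBreakdown:
        if smi not in cache:
            cache[smi] = reward_fn(smi)
        return cache[smi]

    pop: dict[str, Candidate] = {}
    for smi in initial_population:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            logger.warning("dropping invalid initial candidate %r", smi)
            continue
        can = Chem.MolToSmiles(mol)
        br = score(can)
        if math.isfinite(br.r):
            pop.setdefault(can, Candidate(can, br, "retrieved"))
    if not pop:
        raise ValueError("no valid initial candidates")

    # pad undersized populations with mutated copies
    base = list(pop)
    guard = 0
    while len(pop) < config.population_size and guard < 20 * config.population_size:
        guard += 1
        child = mutate(base[int(rng.integers(len(base)))], rng)
        if child is not None and child not in pop:
            br = score(child)
            if math.isfinite(br.r):
                pop[child] = Candidate(child, br, "generated")

    def sorted_pop() -> list[Candidate]:
        return sorted(pop.values(), key=lambda c: (-c.reward.r, c.smiles))

    for _gen in range(config.generations):
        ranked = sorted_pop()
        if history is not None:
            rs = [c.reward.r for c in ranked]
            history.append({"generation": _gen, "best_r": max(rs),
                            "mean_r": float(np.mean(rs))})
        probs = _rank_probabilities(len(ranked))
        offspring: dict[str, str] = {}
        for _ in range(config.offspring_size):
            pa, pb = rng.choice(len(ranked), size=2, p=probs)
            child = crossover(ranked[int(pa)].smiles, ranked[int(pb)].smiles, rng)
            if child is not None and rng.random() < config.mutation_rate:
                mutated = mutate(child, rng)
                child = mutated if mutated is not None else child
            if child is not None:
                offspring.setdefault(child, "generated")
        if not offspring:
            logger.warning("generation %d produced no valid offspring", _gen)
            continue
        merged = dict(pop)
        for smi in offspring:
            if smi not in merged:
                br = score(smi)
                if math.isfinite(br.r):
                    merged[smi] = Candidate(smi, br, "generated")
        elite = sorted_pop()[: config.elitism]
        survivors = sorted(merged.values(), key=lambda c: (-c.reward.r, c.smiles))
        keep = {c.smiles: c for c in elite}
        for c in survivors:
            if len(keep) >= config.population_size:
                break
            keep.setdefault(c.smiles, c)
        pop = keep

    return sorted_pop()


def aggregate(runs: list[list[Candidate]]) -> CandidateRanking:
    """Union populations across seeds; keep each structure's best R; sort."""
    if not runs:
        raise ValueError("at least one run required")
    best: dict[str, Candidate] = {}
    for run in runs:
        for cand in run:
            prev = best.get(cand.smiles)
            if prev is None or cand.reward.r > prev.reward.r:
                best[cand.smiles] = cand
    ordered = sorted(best.values(), key=lambda c: (-c.reward.r, c.smiles))
    return CandidateRanking(ordered)


def is_match(candidate: str, reference: str) -> MatchResult:
    """Structure identity check: Morgan (r=6, 2048 bits) fingerprint equality,
    with exact canonical-SMILES equality reported alongside."""
    mc, mr = Chem.MolFromSmiles(candidate), Chem.MolFromSmiles(reference)
    if mc is None or mr is None:
        raise ValueError("both structures must be valid")
    fp_match = _MORGAN.GetFingerprint(mc) == _MORGAN.GetFingerprint(mr)
    can_match = Chem.MolToSmiles(mc) == Chem.MolToSmiles(mr)
    return MatchResult(fp_match, can_match)


class GraphGARefiner(BaseEstimator):
    """Configured GA refiner (sklearn get_params/set_params compatible).

    refine() runs `n_seeds` independent seeded evolutions under the Eq.-style
    reward and aggregates them into a single deduplicated ranking.
    """

    def __init__(self, population_size=100, offspring_size=200, mutation_rate=0.05,
                 generations=15, n_seeds=3, elitism=5):
        self.population_size = population_size
        self.offspring_size = offspring_size
        self.mutation_rate = mutation_rate
        self.generations = generations
        self.n_seeds = n_seeds
        self.elitism = elitism

    def _config(self) -> GAConfig:
        return GAConfig(self.population_size, self.offspring_size,
                        self.mutation_rate, self.generations,
                        self.n_seeds, self.elitism)

    def refine(self, initial_population: list[str], reward_fn,
               seed: int = 0) -> CandidateRanking:
        cfg = self._config()
        runs = [
            evolve(initial_population, reward_fn, cfg, seed=seed + k)
            for k in range(cfg.n_seeds)
        ]
        self.runs_ = runs
        return aggregate(runs)
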