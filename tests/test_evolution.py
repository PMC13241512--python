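"""Reward identities, graph operators, evolution loop and aggregation."""

import math

import numpy as np
import pytest
from rdkit import Chem

from spectromatch.chem import molecular_formula
from spectromatch.evolution import (
    Candidate,
    GAConfig,
    GraphGARefiner,
    RewardBreakdown,
    aggregate,
    crossover,
    evolve,
    is_match,
    mutate,
    reward,
    wrong_atom_count,
)


class _StubAligner:
    """Maps SMILES to fixed embeddings for reward arithmetic tests."""

    def __init__(self, table):
        self.table = {Chem.MolToSmiles(Chem.MolFromSmiles(k)): np.asarray(v, float)
                      for k, v in table.items()}

    def encode_molecule(self, smiles):
        return self.table[Chem.MolToSmiles(Chem.MolFromSmiles(smiles))]


class TestWrongAtomCount:
    @pytest.mark.parametrize(
        "candidate,target,expected_w,expected_t",
        [
            ("c1ccccc1", "c1ccccc1", 0, 12),  # benzene vs itself
            ("Cc1ccccc1", "c1ccccc1", 3, 12),  # toluene: |7-6| + |8-6|
            ("Clc1ccccc1", "c1ccccc1", 2, 12),  # chlorobenzene: |1-0| + |5-6|
        ],
    )
    def test_hand_counted_examples(self, candidate, target, expected_w, expected_t):
        w, t = wrong_atom_count(
            molecular_formula(candidate), molecular_formula(target)
        )
        assert (w, t) == (expected_w, expected_t)

    def test_empty_formula_rejected(self):
        with pytest.raises(ValueError):
            wrong_atom_count({}, {"C": 1})


class TestReward:
    def test_perfect_candidate_scores_one(self):
        e = np.array([1.0, 0.0])
        aligner = _StubAligner({"c1ccccc1": e})
        br = reward("c1ccccc1", {"c13": e, "h1": e},
                    molecular_formula("c1ccccc1"), aligner)
        assert br.r == pytest.approx(1.0)
        assert br.w == 0 and br.t == 12

    def test_mixed_cosines_with_formula_penalty(self):
        mol = np.array([1.0, 0.0])
        aligner = _StubAligner({"Cc1ccccc1": mol})
        spec = {"c13": np.array([0.8, 0.6]), "h1": np.array([0.6, 0.8])}
        br = reward("Cc1ccccc1", spec, molecular_formula("c1ccccc1"), aligner)
        # mean cosine 0.7 minus W/T = 3/12
        assert br.r == pytest.approx(0.7 - 0.25)
        assert br.n == 2

    def test_single_modality_with_correct_formula(self):
        mol = np.array([1.0, 0.0])
        aligner = _StubAligner({"CCO": mol})
        br = reward("CCO", {"ir": np.array([0.9, np.sqrt(1 - 0.81)])},
                    molecular_formula("CCO"), aligner)
        assert br.r == pytest.approx(0.9)

    def test_reward_equals_fused_score_when_formula_correct(self, rng):
        mol = rng.normal(size=4)
        mol /= np.linalg.norm(mol)
        aligner = _StubAligner({"CCO": mol})
        spec = {m: rng.normal(size=4) for m in ("c13", "h1", "ir")}
        br = reward("CCO", spec, molecular_formula("CCO"), aligner)
        from spectromatch.retrieval import fused_score

        assert br.r == pytest.approx(fused_score(spec, mol))
        assert br.r <= 1.0

    def test_invalid_candidate_gets_minus_inf_sentinel(self):
        aligner = _StubAligner({"CCO": np.ones(2)})
        br = reward("C(C(", {"c13": np.ones(2)}, molecular_formula("CCO"), aligner)
        assert br.r == -math.inf


class TestGraphOperators:
    def test_mutate_produces_valid_different_structures(self, small_corpus, rng):
        changed = 0
        for rec in small_corpus[:15]:
            child = mutate(rec.smiles, rng)
            if child is not None:
                mol = Chem.MolFromSmiles(child)
                assert mol is not None
                assert child == Chem.MolToSmiles(mol)
                changed += child != rec.smiles
        assert changed >= 10

    def test_crossover_produces_valid_structures(self, small_corpus, rng):
        ok = 0
        for a, b in zip(small_corpus[:10], small_corpus[10:20]):
            child = crossover(a.smiles, b.smiles, rng)
            if child is not None:
                assert Chem.MolFromSmiles(child) is not None
                ok += 1
        assert ok >= 5


def _formula_reward(target_smiles):
    """Reward independent of embeddings: 1 - W/T (maximised by the target)."""
    target = molecular_formula(target_smiles)

    def fn(smiles):
        w, t = wrong_atom_count(molecular_formula(smiles), target)
        return RewardBreakdown({}, 1, w, t, 1.0 - w / t)

    return fn


class TestEvolve:
    def test_elitism_keeps_best_reward_nondecreasing(self):
        history = []
        cfg = GAConfig(population_size=20, offspring_size=30, generations=6,
                       n_seeds=1, elitism=2)
        evolve(["CCO", "CCC", "CCN"], _formula_reward("CCOC(C)=O"), cfg,
               seed=0, history=history)
        bests = [h["best_r"] for h in history]
        assert all(b2 >= b1 for b1, b2 in zip(bests, bests[1:]))

    def test_deterministic_given_seed(self):
        cfg = GAConfig(population_size=10, offspring_size=15, generations=3,
                       n_seeds=1)
        rf = _formula_reward("CCOCC")
        a = evolve(["CCO", "CCC"], rf, cfg, seed=5)
        b = evolve(["CCO", "CCC"], rf, cfg, seed=5)
        assert [c.smiles for c in a] == [c.smiles for c in b]

    def test_uncuttable_single_molecule_carries_population_over(self, caplog):
        # benzene has no acyclic single bond: crossover always fails
        cfg = GAConfig(population_size=1, offspring_size=5, generations=2,
                       n_seeds=1, mutation_rate=0.0)
        final = evolve(["c1ccccc1"], _formula_reward("c1ccccc1"), cfg, seed=0)
        assert [c.smiles for c in final] == ["c1ccccc1"]

    def test_empty_initial_population_rejected(self):
        with pytest.raises(ValueError):
            evolve([], _formula_reward("CCO"), GAConfig())

    def test_initial_population_provenance_is_retrieved(self):
        cfg = GAConfig(population_size=5, offspring_size=5, generations=1,
                       n_seeds=1)
        final = evolve(["CCO"], _formula_reward("CCO"), cfg, seed=1)
        by_smiles = {c.smiles: c for c in final}
        assert by_smiles["CCO"].provenance == "retrieved"


class TestAggregate:
    def _cand(self, smiles, r, prov="generated"):
        return Candidate(smiles, RewardBreakdown({}, 1, 0, 10, r), prov)

    def test_single_run_is_sorted(self):
        run = [self._cand("CCO", 0.3), self._cand("CCC", 0.9)]
        ranking = aggregate([run])
        assert [c.smiles for c in ranking.candidates] == ["CCC", "CCO"]

    def test_duplicates_keep_best_score(self):
        runs = [[self._cand("CCO", 0.6)], [self._cand("CCO", 0.7)]]
        ranking = aggregate(runs)
        assert len(ranking) == 1
        assert ranking.candidates[0].reward.r == 0.7

    def test_matches_bruteforce_union_sort(self, rng):
        smiles_pool = [f"{'C' * (i + 1)}O" for i in range(10)]
        runs = []
        for _ in range(3):
            runs.append([
                self._cand(s, float(rng.uniform(-1, 1)))
                for s in rng.choice(smiles_pool, size=10, replace=True)
            ])
        ranking = aggregate(runs)
        best = {}
        for run in runs:
            for c in run:
                if c.smiles not in best or c.reward.r > best[c.smiles]:
                    best[c.smiles] = c.reward.r
        expected = sorted(best.items(), key=lambda t: (-t[1], t[0]))
        assert [(c.smiles, c.reward.r) for c in ranking.candidates] == expected

    def test_no_duplicate_canonical_structures(self, rng):
        runs = [[self._cand("CCO", 0.1), self._cand("OCC", 0.2)]]
        # same molecule written two ways enters evolve pre-canonicalized;
        # aggregate itself trusts canonical keys
        ranking = aggregate(runs)
        assert len({c.smiles for c in ranking.candidates}) == len(ranking)

    def test_empty_runs_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])


class TestIsMatch:
    def test_identical_structures_match(self):
        m = is_match("CCO", "OCC")
        assert m.fingerprint_match and m.canonical_match and bool(m)

    def test_benzene_toluene_do_not_match(self):
        m = is_match("c1ccccc1", "Cc1ccccc1")
        assert not m.fingerprint_match and not bool(m)

    def test_canonical_match_implies_fingerprint_match(self, small_corpus):
        for rec in small_corpus[:10]:
            m = is_match(rec.smiles, rec.smiles)
            assert m.canonical_match and m.fingerprint_match

    def test_invalid_structure_rejected(self):
        with pytest.raises(ValueError):
            is_match("xyz", "CCO")


def test_refiner_exposes_sklearn_params():
    ref = GraphGARefiner(generations=5)
    assert ref.get_params()["generations"] == 5
    ref.set_params(n_seeds=2)
    assert ref._config().n_seeds == 2
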