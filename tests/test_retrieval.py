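"""Formula pools, multimodal cosine fusion, ranking and rank metrics."""

import numpy as np
import pytest

from spectromatch.chem import MoleculeRecord, molecular_formula
from spectromatch.retrieval import (
    MoleculeIndex,
    RetrievalResult,
    formula_pool,
    fused_score,
    rank,
    rank_metrics,
)

SMILES_20 = [
    "CCO", "CCC", "CCN", "CCCl", "CC(=O)O", "CC(=O)OC", "c1ccccc1",
    "Cc1ccccc1", "CCOC", "CCCO", "CC(C)O", "CCCC", "CC(C)N", "OCCO",
    "CC(=O)N", "CCCCl", "c1ccncc1", "CC#N", "C=CC", "CC(C)=O",
]


@pytest.fixture()
def toy_index(rng):
    records = [MoleculeRecord.from_smiles(s, f"m{i}") for i, s in enumerate(SMILES_20)]
    emb = rng.normal(size=(len(records), 8))
    emb /= np.linalg.norm(emb, axis=1, keepdims=True)
    return MoleculeIndex(records, emb)


class TestFormulaPool:
    def test_exact_match_selects_only_isomers(self, toy_index):
        pool = formula_pool(toy_index, molecular_formula("CCO"), tolerance=0)
        assert {r.smiles for r in pool.records} == {"CCO"}

    def test_large_tolerance_returns_whole_index(self, toy_index):
        pool = formula_pool(toy_index, molecular_formula("CCO"), tolerance=1000)
        assert len(pool) == len(toy_index)

    def test_tolerance_two_matches_bruteforce_tally(self, toy_index):
        target = molecular_formula("CCO")
        pool = formula_pool(toy_index, target, tolerance=2)
        expected = set()
        for rec in toy_index.records:
            els = set(rec.formula) | set(target)
            dist = sum(abs(rec.formula.get(e, 0) - target.get(e, 0)) for e in els)
            if dist <= 2:
                expected.add(rec.smiles)
        assert {r.smiles for r in pool.records} == expected

    def test_empty_formula_rejected(self, toy_index):
        with pytest.raises(ValueError):
            formula_pool(toy_index, {})

    def test_empty_pool_returned_explicitly(self, toy_index):
        pool = formula_pool(toy_index, {"Br": 1}, tolerance=0)
        assert len(pool) == 0


class TestFusedScore:
    def test_perfect_agreement_scores_one(self, rng):
        e = rng.normal(size=6)
        e /= np.linalg.norm(e)
        assert fused_score({"c13": e, "h1": e}, e) == pytest.approx(1.0)

    def test_mean_of_two_cosines(self):
        mol = np.array([1.0, 0.0])
        s1 = np.array([0.8, 0.6])
        s2 = np.array([0.6, 0.8])
        assert fused_score({"a": s1, "b": s2}, mol) == pytest.approx(0.7)

    def test_single_modality_equals_its_cosine(self, rng):
        e = rng.normal(size=5)
        m = rng.normal(size=5)
        cos = e @ m / (np.linalg.norm(e) * np.linalg.norm(m))
        assert fused_score({"ir": e}, m) == pytest.approx(cos)

    def test_permutation_invariant_and_bounded_by_extremes(self, rng):
        m = rng.normal(size=4)
        embs = {k: rng.normal(size=4) for k in ("c13", "h1", "ir")}
        cosines = [fused_score({k: v}, m) for k, v in embs.items()]
        fused = fused_score(embs, m)
        assert min(cosines) <= fused <= max(cosines)
        reordered = dict(reversed(list(embs.items())))
        assert fused_score(reordered, m) == pytest.approx(fused)

    def test_modality_count_bounds(self, rng):
        with pytest.raises(ValueError):
            fused_score({}, rng.normal(size=3))


class TestRanking:
    def test_self_retrieval_with_orthogonal_competitors(self):
        records = [MoleculeRecord.from_smiles(s, f"m{i}")
                   for i, s in enumerate(["CCO", "CCC", "CCN"])]
        emb = np.eye(3)
        index = MoleculeIndex(records, emb)
        result = rank(index, {"c13": emb[1]}, true_smiles=records[1].smiles)
        assert result.true_rank == 1

    def test_matches_bruteforce_cosine_sort(self, toy_index, rng):
        q = {"c13": rng.normal(size=8), "h1": rng.normal(size=8)}
        result = rank(toy_index, q)
        fused = [
            fused_score(q, toy_index.embeddings[i]) for i in range(len(toy_index))
        ]
        expected = sorted(
            zip([r.smiles for r in toy_index.records], fused),
            key=lambda t: (-t[1], t[0]),
        )
        assert result.smiles == [s for s, _ in expected]
        np.testing.assert_allclose(result.scores, [f for _, f in expected], atol=1e-12)

    def test_scores_nonincreasing(self, toy_index, rng):
        result = rank(toy_index, {"c13": rng.normal(size=8)})
        assert np.all(np.diff(result.scores) <= 1e-12)

    def test_perfect_extra_modality_never_hurts_truth(self, toy_index):
        truth_i = 4
        truth_emb = toy_index.embeddings[truth_i]
        truth_smiles = toy_index.records[truth_i].smiles
        base = rank(toy_index, {"c13": truth_emb}, true_smiles=truth_smiles)
        both = rank(toy_index, {"c13": truth_emb, "h1": truth_emb},
                    true_smiles=truth_smiles)
        assert both.true_rank <= base.true_rank

    def test_dimension_mismatch_rejected(self, toy_index):
        with pytest.raises(ValueError):
            rank(toy_index, {"c13": np.zeros(5)})

    def test_empty_pool_rejected(self, toy_index):
        with pytest.raises(ValueError):
            rank(toy_index.subset([]), {"c13": np.zeros(8)})


class TestRankMetrics:
    def _result(self, true_rank):
        return RetrievalResult(["a"], ["a"], np.array([1.0]), true_rank=true_rank)

    def test_all_rank_one_gives_perfect_top1(self):
        metrics = rank_metrics([self._result(1)] * 4)
        assert metrics["topk"]["top1"] == 1.0

    def test_counting_example(self):
        metrics = rank_metrics([self._result(r) for r in (1, 2, 6)])
        assert metrics["topk"]["top1"] == pytest.approx(1 / 3)
        assert metrics["topk"]["top5"] == pytest.approx(2 / 3)

    def test_topk_nondecreasing_in_k(self, rng):
        results = [self._result(int(r)) for r in rng.integers(1, 30, size=25)]
        table = rank_metrics(results, ks=(1, 3, 5, 20))["topk"]
        vals = [table[f"top{k}"] for k in (1, 3, 5, 20)]
        assert vals == sorted(vals)

    def test_unannotated_result_rejected(self):
        with pytest.raises(ValueError):
            rank_metrics([RetrievalResult(["a"], ["a"], np.array([1.0]))])
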