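"""Formula-filtered cosine retrieval of molecules from an embedded index.

A query is a bag of 1-4 spectrum embeddings. Each candidate molecule is
scored by the arithmetic mean of the per-modality cosine similarities
(multimodal fusion); candidates are ranked descending with deterministic
canonical-SMILES tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .chem import MoleculeRecord, SpectrumSet, molecular_formula

__all__ = [
    "MoleculeIndex",
    "RetrievalResult",
    "build_index",
    "formula_pool",
    "fused_score",
    "rank",
    "rank_metrics",
    "MoleculeRetriever",
]


@dataclass
class MoleculeIndex:
    """Molecule records plus their precomputed unit-norm embeddings."""

    records: list[MoleculeRecord]
    embeddings: np.ndarray  # (n, d)
    provenance: str = "synthetic-corpus"

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        if len(self.records) != self.embeddings.shape[0]:
            raise ValueError("one embedding per molecule required")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, idx) -> "MoleculeIndex":
        idx = np.asarray(idx, dtype=int)
        return MoleculeIndex([self.records[i] for i in idx],
                             self.embeddings[idx], self.provenance)


@dataclass
class RetrievalResult:
    """Ranked candidates with fused and per-modality scores."""

    ids: list[str]
    smiles: list[str]
    scores: np.ndarray
    per_modality: dict[str, np.ndarray] = field(default_factory=dict)
    true_rank: int | None = None  # 1-based rank of the true molecule

    def top(self, k: int) -> list[tuple[str, float]]:
        return [(self.smiles[i], float(self.scores[i])) for i in range(min(k, len(self.smiles)))]


def build_index(records: list[MoleculeRecord], aligner,
                provenance: str = "synthetic-corpus") -> MoleculeIndex:
    emb = aligner.transform([r.smiles for r in records])
    return MoleculeIndex(list(records), emb, provenance)


def formula_pool(index: MoleculeIndex, query_formula: dict[str, int],
                 tolerance: int = 0) -> MoleculeIndex:
    """Sub-index of candidates whose formula is within `tolerance` of the query.

    Distance = sum over the union of element symbols of the absolute count
    difference (hydrogens included). tolerance 0 means exact match. An empty
    pool is returned as-is; the caller decides whether to fall back to the
    full index.
    """
    if not query_formula or sum(query_formula.values()) < 1:
        raise ValueError("query formula must contain at least one atom")
    keep = []
    for i, rec in enumerate(index.records):
        elements = set(rec.formula) | set(query_formula)
        dist = sum(
            abs(rec.formula.get(el, 0) - query_formula.get(el, 0)) for el in elements
        )
        if dist <= tolerance:
            keep.append(i)
    return index.subset(keep)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def fused_score(spectra_embeddings: dict[str, np.ndarray],
                molecule_embedding: np.ndarray) -> float:
    """Mean cosine similarity over exactly the modalities present (1-4)."""
    if not 1 <= len(spectra_embeddings) <= 4:
        raise ValueError("between 1 and 4 modality embeddings required")
    return float(
        np.mean([_cosine(e, molecule_embedding) for e in spectra_embeddings.values()])
    )


def rank(index: MoleculeIndex, spectra_embeddings: dict[str, np.ndarray],
         true_smiles: str | None = None) -> RetrievalResult:
    """Sort the index by fused score, descending; ties broken by SMILES."""
    if len(index) == 0:
        raise ValueError("cannot rank an empty pool")
    d = index.embeddings.shape[1]
    for mod, e in spectra_embeddings.items():
        if np.asarray(e).shape != (d,):
            raise ValueError(f"dimension mismatch for modality {mod!r}")
    emb = index.embeddings
    norms = np.linalg.norm(emb, axis=1)
    norms[norms == 0] = 1.0
    per_mod = {}
    for mod, e in spectra_embeddings.items():
        ne = np.linalg.norm(e)
        qe = e / ne if ne > 0 else e
        per_mod[mod] = (emb @ qe) / norms
    scores = np.mean(np.stack(list(per_mod.values())), axis=0)
    smiles = [r.smiles for r in index.records]
    order = np.lexsort((smiles, -scores))
    result = RetrievalResult(
        ids=[index.records[i].mol_id for i in order],
        smiles=[smiles[i] for i in order],
        scores=scores[order],
        per_modality={m: v[order] for m, v in per_mod.items()},
    )
    if true_smiles is not None:
        truth = true_smiles
        result.true_rank = (
            result.smiles.index(truth) + 1 if truth in result.smiles else None
        )
    return result


def rank_metrics(results: list[RetrievalResult],
                 ks: tuple[int, ...] = (1, 3, 5, 20)) -> dict:
    """Top-k accuracy table and rank histogram over annotated results."""
    ranks = []
    for r in results:
        if r.true_rank is None:
            raise ValueError("every result must be annotated with the true rank")
        ranks.append(r.true_rank)
    ranks = np.asarray(ranks)
    table = {f"top{k}": float(np.mean(ranks <= k)) for k in ks}
    hist = np.bincount(ranks)
    return {"topk": table, "ranks": ranks.tolist(), "rank_histogram": hist.tolist()}


class MoleculeRetriever(BaseEstimator):
    """Retrieval front end over a trained aligner (sklearn-style).

    fit(records) embeds the grounding database; query(spectrum_set, formula)
    returns a ranked RetrievalResult restricted to the formula pool
    (falling back to the full index when the pool is empty).
    """

    def __init__(self, aligner=None, formula_tolerance: int = 0):
        self.aligner = aligner
        self.formula_tolerance = formula_tolerance

    def fit(self, X: list[MoleculeRecord], y=None):
        if self.aligner is None:
            raise ValueError("a trained aligner is required")
        self.index_ = build_index(list(X), self.aligner)
        return self

    def query(self, spectrum_set: SpectrumSet, formula: dict[str, int] | str | None = None,
              true_smiles: str | None = None) -> RetrievalResult:
        spec_emb = self.aligner.encode_spectra(spectrum_set)
        pool = self.index_
        if formula is not None:
            if isinstance(formula, str):
                formula = molecular_formula(formula)
            pool = formula_pool(self.index_, formula, self.formula_tolerance)
            if len(pool) == 0:
                pool = self.index_
        return rank(pool, spec_emb, true_smiles=true_smiles)
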