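"""Symmetric InfoNCE alignment of spectrum and molecule encoders.

Each spectral modality is aligned against the molecule embedding (hub
design): the per-batch loss is the sum over available modalities of the
symmetric InfoNCE loss L(S,M) + L(M,S) at temperature tau = 0.07. Training
uses Adam at learning rate 1e-4 with early stopping (patience 3 epochs on
the validation loss) and returns the best-validation parameters.
"""

from __future__ import annotations

import copy
import logging

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .autodiff import Adam, Tensor, constant
from .chem import MoleculeRecord, SpectrumSet
from .encoders import (
    EncoderConfig,
    SmilesVocab,
    build_encoders,
    load_checkpoint,
    save_checkpoint,
)

logger = logging.getLogger(__name__)

__all__ = ["info_nce", "symmetric_loss", "SpectrumMoleculeAligner", "ContrastiveConfig"]


def info_nce(queries: np.ndarray, keys: np.ndarray, tau: float = 0.07) -> float:
    """Mean InfoNCE loss: position i of `queries` pairs with position i of `keys`.

    loss = mean_i [ -log( exp(q_i.k_i / tau) / sum_j exp(q_i.k_j / tau) ) ]
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    keys = np.atleast_2d(np.asarray(keys, dtype=float))
    if queries.shape != keys.shape or queries.shape[0] < 1:
        raise ValueError("queries and keys must be equal-shape batches of size >= 1")
    if tau <= 0:
        raise ValueError("temperature must be positive")
    logits = queries @ keys.T / tau
    lse = logsumexp(logits, axis=1)
    return float(np.mean(lse - np.diag(logits)))


def symmetric_loss(spectrum_batch: np.ndarray, molecule_batch: np.ndarray,
                   tau: float = 0.07) -> float:
    """L_symm = L(S->M) + L(M->S) on a paired batch."""
    return info_nce(spectrum_batch, molecule_batch, tau) + info_nce(
        molecule_batch, spectrum_batch, tau
    )


def _info_nce_graph(Q: Tensor, K: Tensor, tau: float) -> Tensor:
    B = Q.shape[0]
    logits = (Q @ K.swapaxes(0, 1)) * (1.0 / tau)
    lse = logits.logsumexp_lastaxis().reshape(B)
    diag = (logits * constant(np.eye(B))).sum(axis=1)
    return (lse - diag).mean()


def _symmetric_graph(S: Tensor, M: Tensor, tau: float) -> Tensor:
    return _info_nce_graph(S, M, tau) + _info_nce_graph(M, S, tau)


class ContrastiveConfig:
    """Bag of training hyperparameters (see SpectrumMoleculeAligner params)."""

    def __init__(self, temperature=0.07, learning_rate=1e-4, batch_size=64,
                 max_epochs=200, patience=3, validation_fraction=0.1, seed=0):
        if temperature <= 0:
            raise ValueError("temperature must be > 0")
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.temperature = temperature
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed


class SpectrumMoleculeAligner(BaseEstimator):
    """Contrastively aligned spectrum/molecule encoders (sklearn-style).

    fit(X, y) takes X = list of SpectrumSet and y = the paired SMILES
    strings; transform(smiles) returns unit-norm molecule embeddings and
    encode_spectra embeds a SpectrumSet. Dot products in the shared space
    are cosine similarities.

    Parameters mirror the published training recipe: temperature 0.07,
    learning rate 1e-4, early stopping with patience 3 epochs on a 10%
    validation split.
    """

    def __init__(self, embedding_dim=64, hidden_dim=256, token_dim=32,
                 modalities=("c13", "h1"), temperature=0.07, learning_rate=1e-4,
                 batch_size=64, max_epochs=200, patience=3,
                 validation_fraction=0.1, random_state=0):
        self.embedding_dim = embedding_dim
        self.hidden_dim = hidden_dim
        self.token_dim = token_dim
        self.modalities = modalities
        self.temperature = temperature
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _init_model(self, smiles: list[str]) -> None:
        self.vocab_ = SmilesVocab.from_smiles(smiles)
        self.config_ = EncoderConfig(
            embedding_dim=self.embedding_dim,
            hidden_dim=self.hidden_dim,
            token_dim=self.token_dim,
            seed=self.random_state,
        )
        self.encoders_ = build_encoders(self.vocab_, self.config_)

    def _prepare_inputs(self, spectra: list[SpectrumSet], smiles: list[str]):
        mats = {}
        for mod in self.modalities:
            enc = self.encoders_[mod]
            mats[mod] = np.stack([enc.prepare(s[mod]) for s in spectra])
        mol_enc = self.encoders_["molecule"]
        tokens = np.stack([mol_enc.prepare(s) for s in smiles])
        return mats, tokens

    def _batch_loss(self, mats, tokens, idx) -> Tensor:
        mol_emb = self.encoders_["molecule"].forward_tokens(tokens[idx])
        total = None
        for mod in self.modalities:
            spec_emb = self.encoders_[mod].forward(constant(mats[mod][idx]))
            term = _symmetric_graph(spec_emb, mol_emb, self.temperature)
            total = term if total is None else total + term
        return total

    def _eval_loss(self, mats, tokens, idx) -> float:
        if len(idx) == 0:
            return float("nan")
        return self._batch_loss(mats, tokens, idx).item()

    def fit(self, X: list[SpectrumSet], y: list[str], validation_data=None):
        """Train all encoders jointly on paired (spectra, molecule) data.

        By default 10% of the molecules are held out and their loss drives
        early stopping. For dereplication-style training (the grounding
        database is known and queries are fresh measurements of its
        molecules), pass ``validation_data=(X_val, y_val)`` containing
        independently augmented spectra; all of X then trains and early
        stopping monitors robustness to measurement noise instead of
        generalisation to unseen molecules.
        """
        if len(X) != len(y) or len(y) < 2:
            raise ValueError("need >= 2 paired molecules/spectra of equal length")
        smiles = [m.smiles if isinstance(m, MoleculeRecord) else m for m in y]
        for s, mods in zip(X, [x.modalities for x in X]):
            missing = set(self.modalities) - set(mods)
            if missing:
                raise ValueError(f"spectrum set missing modalities {missing}")
        self._init_model(smiles)
        mats, tokens = self._prepare_inputs(X, smiles)
        n = len(smiles)

        rng = np.random.default_rng(self.random_state)
        if validation_data is not None:
            X_val, y_val = validation_data
            val_smiles = [
                m.smiles if isinstance(m, MoleculeRecord) else m for m in y_val
            ]
            val_mats, val_tokens = self._prepare_inputs(X_val, val_smiles)
            train_idx = np.arange(n)
            val_idx = np.arange(len(val_smiles))
        else:
            perm = rng.permutation(n)
            n_val = int(round(self.validation_fraction * n))
            n_val = min(max(n_val, 1 if n >= 10 else 0), n - 2)
            val_idx, train_idx = perm[:n_val], perm[n_val:]
            val_mats, val_tokens = mats, tokens

        params = []
        for mod in (*self.modalities, "molecule"):
            params.extend(self.encoders_[mod].parameters())
        opt = Adam(params, lr=self.learning_rate)

        best_val = np.inf
        best_state = None
        since_improve = 0
        self.history_ = []
        for epoch in range(self.max_epochs):
            order = rng.permutation(train_idx)
            train_losses = []
            for start in range(0, len(order), self.batch_size):
                batch = order[start : start + self.batch_size]
                if len(batch) < 2:
                    logger.warning("skipping degenerate batch of size %d", len(batch))
                    continue
                opt.zero_grad()
                loss = self._batch_loss(mats, tokens, batch)
                loss.backward()
                opt.step()
                train_losses.append(loss.item())
            if len(val_idx):
                val_loss = self._eval_loss(val_mats, val_tokens, val_idx)
            else:
                val_loss = self._eval_loss(mats, tokens, train_idx)
            self.history_.append(
                {"epoch": epoch, "train_loss": float(np.mean(train_losses)),
                 "val_loss": val_loss}
            )
            if val_loss < best_val:
                best_val = val_loss
                best_state = {
                    m: self.encoders_[m].state_dict()
                    for m in (*self.modalities, "molecule")
                }
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= self.patience:
                    break
        if best_state is not None:
            for m, state in best_state.items():
                self.encoders_[m].load_state_dict(state)
        self.best_val_loss_ = float(best_val)
        self.n_epochs_ = len(self.history_)
        return self

    # ------------------------------------------------------------------

    def transform(self, smiles_list) -> np.ndarray:
        """Unit-norm molecule embeddings, shape (n, d)."""
        mol_enc = self.encoders_["molecule"]
        smiles = [m.smiles if isinstance(m, MoleculeRecord) else m for m in smiles_list]
        tokens = np.stack([mol_enc.prepare(s) for s in smiles])
        return mol_enc.forward_tokens(tokens).data

    def encode_molecule(self, smiles: str) -> np.ndarray:
        return self.transform([smiles])[0]

    def encode_spectra(self, spectrum_set: SpectrumSet,
                       modalities=None) -> dict[str, np.ndarray]:
        """Per-modality unit-norm spectrum embeddings for one query."""
        mods = modalities or [m for m in spectrum_set.modalities
                              if m in self.encoders_]
        out = {}
        for mod in mods:
            enc = self.encoders_[mod]
            x = enc.prepare(spectrum_set[mod])
            out[mod] = enc.forward(constant(x[None, :])).data[0]
        return out

    def save(self, path) -> None:
        save_checkpoint(path, self.encoders_, self.config_, self.vocab_,
                        extra={"modalities": list(self.modalities),
                               "history": self.history_})

    @classmethod
    def load(cls, path) -> "SpectrumMoleculeAligner":
        encoders, config, vocab, extra = load_checkpoint(path)
        est = cls(embedding_dim=config.embedding_dim, hidden_dim=config.hidden_dim,
                  token_dim=config.token_dim,
                  modalities=tuple(extra.get("modalities", ("c13", "h1"))),
                  random_state=config.seed)
        est.encoders_ = encoders
        est.config_ = config
        est.vocab_ = vocab
        est.history_ = extra.get("history", [])
        return est
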