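"""Modality encoders mapping spectra and SMILES into a shared embedding space.

Every encoder ends in a linear projection head to the shared dimension `d`
followed by L2 normalisation, so dot products between embeddings are exactly
cosine similarities. Architectures at desk scale:

* ¹³C  — multi-layer perceptron on the 512-bin binary vector.
* ¹H   — average-pool (10,000 → 250) then MLP.
* IR   — average-pool (1600 → 200) then MLP.
* HSQC — 2-D average-pool (512² → 32²), flatten, MLP.
* molecule — token embeddings + learned positions, one single-head
  self-attention block, masked mean pooling, linear head.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, constant, parameter
from .codec import C13_BINS, H1_LEN, HSQC_SHAPE, IR_LEN, SpectrumVector

__all__ = [
    "EncoderConfig",
    "MLPEncoder",
    "PooledMLPEncoder",
    "HSQCEncoder",
    "MoleculeEncoder",
    "build_encoders",
    "encode",
    "tokenize_smiles",
    "detokenize",
    "SmilesVocab",
]

_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|se|@@|[BCNOPSFIbcnops]|[0-9]|%[0-9]{2}"
    r"|[=#$:/\\\.\-\+\(\)@~\*])"
)


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into atom/bond/ring tokens.

    Two-letter elements (Cl, Br, Si) and bracket atoms are kept whole, so
    detokenize(tokenize(s)) == s.
    """
    tokens = _SMILES_TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"cannot tokenize SMILES {smiles!r}")
    return tokens


def detokenize(tokens: list[str]) -> str:
    return "".join(tokens)


class SmilesVocab:
    """Token vocabulary with padding and unknown-token fallback."""

    PAD = "<pad>"
    UNK = "<unk>"

    def __init__(self, tokens: list[str]):
        self.itos = [self.PAD, self.UNK] + sorted(set(tokens))
        self.stoi = {t: i for i, t in enumerate(self.itos)}

    @classmethod
    def from_smiles(cls, smiles_list) -> "SmilesVocab":
        toks: list[str] = []
        for s in smiles_list:
            toks.extend(tokenize_smiles(s))
        return cls(toks)

    def __len__(self) -> int:
        return len(self.itos)

    def encode(self, smiles: str, max_len: int) -> np.ndarray:
        ids = [self.stoi.get(t, 1) for t in tokenize_smiles(smiles)][:max_len]
        out = np.zeros(max_len, dtype=np.int64)
        out[: len(ids)] = ids
        return out


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters shared by all modality encoders."""

    embedding_dim: int = 64  # shared space dimension d
    hidden_dim: int = 256
    token_dim: int = 32
    max_tokens: int = 96
    h1_pool: int = 40  # 10,000 -> 250
    ir_pool: int = 8  # 1,600 -> 200
    hsqc_pool: int = 16  # 512x512 -> 32x32
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-scale, scale, (n_in, n_out))


class _Module:
    """Base class: parameter registry + deterministic forward."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}

    def add_param(self, name: str, data: np.ndarray) -> Tensor:
        p = parameter(data)
        self._params[name] = p
        return p

    def parameters(self) -> list[Tensor]:
        return list(self._params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self._params[k].data = np.asarray(v, dtype=np.float64).copy()


class MLPEncoder(_Module):
    """input -> hidden (ReLU) -> hidden (ReLU) -> linear projection -> d."""

    def __init__(self, n_in: int, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        h, d = config.hidden_dim, config.embedding_dim
        self.W1 = self.add_param("W1", _glorot(rng, n_in, h))
        self.b1 = self.add_param("b1", np.zeros(h))
        self.W2 = self.add_param("W2", _glorot(rng, h, h))
        self.b2 = self.add_param("b2", np.zeros(h))
        self.Wp = self.add_param("Wp", _glorot(rng, h, d))
        self.bp = self.add_param("bp", np.zeros(d))
        self.n_in = n_in

    def forward(self, x: Tensor) -> Tensor:
        h1 = (x @ self.W1 + self.b1).relu()
        h2 = (h1 @ self.W2 + self.b2).relu()
        return (h2 @ self.Wp + self.bp).l2_normalize()

    def prepare(self, vec: SpectrumVector) -> np.ndarray:
        return np.asarray(vec.values, dtype=np.float64).ravel()


class PooledMLPEncoder(MLPEncoder):
    """Fixed average-pooling front end followed by an MLP (¹H, IR)."""

    def __init__(self, n_raw: int, pool: int, config: EncoderConfig,
                 rng: np.random.Generator):
        if n_raw % pool:
            raise ValueError("pool must divide the raw vector length")
        super().__init__(n_raw // pool, config, rng)
        self.n_raw, self.pool = n_raw, pool

    def prepare(self, vec: SpectrumVector) -> np.ndarray:
        v = np.asarray(vec.values, dtype=np.float64)
        return v.reshape(self.n_raw // self.pool, self.pool).mean(axis=1)


class HSQCEncoder(MLPEncoder):
    """2-D average-pooling of the 512x512 grid, flatten, MLP."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        p = config.hsqc_pool
        n_c, n_h = HSQC_SHAPE
        super().__init__((n_c // p) * (n_h // p), config, rng)
        self.pool = p

    def prepare(self, vec: SpectrumVector) -> np.ndarray:
        g = np.asarray(vec.values, dtype=np.float64)
        p = self.pool
        n_c, n_h = g.shape
        pooled = g.reshape(n_c // p, p, n_h // p, p).mean(axis=(1, 3))
        return pooled.ravel()


class MoleculeEncoder(_Module):
    """Small from-scratch token transformer over SMILES.

    Token + position embeddings, one single-head self-attention block with a
    residual connection, a per-token feed-forward layer, masked mean pooling
    over real tokens, then the linear projection head. The per-token
    nonlinearity precedes pooling so that the embedding is sensitive to token
    order, not just token composition (isomers that are SMILES anagrams must
    separate).
    """

    def __init__(self, vocab: SmilesVocab, config: EncoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        t, d = config.token_dim, config.embedding_dim
        L = config.max_tokens
        self.vocab = vocab
        self.max_tokens = L
        self.token_dim = t
        self.E = self.add_param("E", rng.normal(0.0, 0.1, (len(vocab), t)))
        self.P = self.add_param("P", rng.normal(0.0, 0.1, (L, t)))
        self.Wq = self.add_param("Wq", _glorot(rng, t, t))
        self.Wk = self.add_param("Wk", _glorot(rng, t, t))
        self.Wv = self.add_param("Wv", _glorot(rng, t, t))
        self.Wo = self.add_param("Wo", _glorot(rng, t, t))
        self.W1 = self.add_param("W1", _glorot(rng, t, config.hidden_dim))
        self.b1 = self.add_param("b1", np.zeros(config.hidden_dim))
        self.Wp = self.add_param("Wp", _glorot(rng, config.hidden_dim, d))
        self.bp = self.add_param("bp", np.zeros(d))

    def prepare(self, smiles: str) -> np.ndarray:
        return self.vocab.encode(smiles, self.max_tokens)

    def forward_tokens(self, token_ids: np.ndarray) -> Tensor:
        token_ids = np.atleast_2d(token_ids)
        B, L = token_ids.shape
        mask = (token_ids != 0).astype(np.float64)  # (B, L)
        x = self.E.take_rows(token_ids) + self.P.take_rows(
            np.broadcast_to(np.arange(L), (B, L))
        )
        q = x @ self.Wq
        k = x @ self.Wk
        v = x @ self.Wv
        scores = (q @ k.swapaxes(1, 2)) * (1.0 / np.sqrt(self.token_dim))
        attn_mask = np.where(mask[:, None, :] > 0, 0.0, -1e9)  # mask padded keys
        attn = (scores + constant(attn_mask)).softmax_lastaxis()
        x = x + (attn @ v) @ self.Wo  # residual
        h = (x @ self.W1 + self.b1).relu()  # per-token, before pooling
        m = constant(mask[:, :, None])
        counts = np.maximum(mask.sum(axis=1, keepdims=True), 1.0)
        pooled = (h * m).sum(axis=1) * constant(1.0 / counts)
        return (pooled @ self.Wp + self.bp).l2_normalize()

    def forward(self, token_ids) -> Tensor:
        if isinstance(token_ids, Tensor):  # uniform call surface with MLPEncoder
            token_ids = token_ids.data.astype(np.int64)
        return self.forward_tokens(np.asarray(token_ids))


def build_encoders(vocab: SmilesVocab, config: EncoderConfig) -> dict[str, _Module]:
    """One encoder per modality plus the molecule encoder, seeded deterministically."""
    rng = np.random.default_rng(config.seed)
    return {
        "c13": MLPEncoder(C13_BINS, config, rng),
        "h1": PooledMLPEncoder(H1_LEN, config.h1_pool, config, rng),
        "ir": PooledMLPEncoder(IR_LEN, config.ir_pool, config, rng),
        "hsqc": HSQCEncoder(config, rng),
        "molecule": MoleculeEncoder(vocab, config, rng),
    }


def encode(encoders: dict[str, _Module], item, modality: str | None = None) -> np.ndarray:
    """Embed one spectrum vector or SMILES string; unit-norm output.

    Spectrum inputs are dispatched on their modality tag; strings go through
    the molecule encoder.
    """
    if isinstance(item, str):
        enc = encoders["molecule"]
        return enc.forward_tokens(enc.prepare(item)[None, :]).data[0]
    if isinstance(item, SpectrumVector):
        modality = item.modality
    if modality is None or modality not in encoders:
        raise ValueError(f"no encoder configured for modality {modality!r}")
    enc = encoders[modality]
    x = enc.prepare(item)
    if x.shape[-1] != enc.n_in:
        raise ValueError(f"shape mismatch for {modality}: got {x.shape}")
    return enc.forward(constant(x[None, :])).data[0]


def save_checkpoint(path, encoders: dict[str, _Module], config: EncoderConfig,
                    vocab: SmilesVocab, extra: dict | None = None) -> None:
    """Persist parameters (.npz) plus config and vocabulary (.json)."""
    import os

    arrays = {}
    for name, enc in encoders.items():
        for k, v in enc.state_dict().items():
            arrays[f"{name}/{k}"] = v
    np.savez(str(path) + ".npz", **arrays)
    meta = {
        "format_version": 1,
        "config": config.to_dict(),
        "vocab": vocab.itos,
        "extra": extra or {},
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh)
    assert os.path.exists(str(path) + ".npz")


def load_checkpoint(path) -> tuple[dict[str, _Module], EncoderConfig, SmilesVocab, dict]:
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    config = EncoderConfig(**meta["config"])
    vocab = SmilesVocab([])
    vocab.itos = meta["vocab"]
    vocab.stoi = {t: i for i, t in enumerate(vocab.itos)}
    encoders = build_encoders(vocab, config)
    data = np.load(str(path) + ".npz")
    for key in data.files:
        name, pname = key.split("/", 1)
        encoders[name]._params[pname].data = data[key].astype(np.float64)
    return encoders, config, vocab, meta.get("extra", {})
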