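"""Token embeddings and the modified target-sequence co-attention.

The attention variant adds a scaled query passthrough to standard scaled
dot-product attention::

    modified_attention(Q, K, V) = softmax(Q K^T / sqrt(d_K)) V + Q / sqrt(d_Q)

so target-side (query) information is reiterated alongside whatever the
sequence keys contribute. Targets act as queries, aptamer sequences as keys
and values: the attention asks "which sequence positions would interact with
this target".

Pretrained DNA / chemistry language-model providers are pluggable; the
built-in provider hashes tokens to fixed unit vectors so the whole pipeline
is deterministic and runs without downloaded weights.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

DEFAULT_EMBED_DIM = 64


class TokenizationError(ValueError):
    pass


@dataclass
class EmbeddingSequence:
    """T x d token-embedding matrix with a validity mask."""

    vectors: np.ndarray
    mask: np.ndarray


@dataclass
class CoAttentionOutput:
    context: np.ndarray  # T_q x d
    weights: np.ndarray  # T_q x T_k, row-stochastic over unmasked keys


def kmer_tokenize(seq: str, k: int = 6) -> list[str]:
    """Overlapping k-mers, stride 1 (the DNA language-model convention)."""
    s = str(seq)
    if len(s) < k:
        raise TokenizationError(f"sequence length {len(s)} < k={k}")
    return [s[i : i + k] for i in range(len(s) - k + 1)]


def smiles_tokenize(smiles: str) -> list[str]:
    """Character tokens — the simplest deterministic chemistry tokenizer."""
    if not smiles:
        raise TokenizationError("empty SMILES")
    return list(smiles)


def _token_vector(token: str, d: int, seed: int) -> np.ndarray:
    digest = hashlib.blake2b(f"{seed}:{token}".encode(), digest_size=8).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "big"))
    v = rng.standard_normal(d)
    return v / np.linalg.norm(v)


def hash_embed(tokens: list[str], d: int = DEFAULT_EMBED_DIM, seed: int = 0) -> EmbeddingSequence:
    """Deterministic fallback embedding: token -> seeded unit hash vector."""
    if d < 8:
        raise ValueError("embedding dimension must be >= 8")
    cache: dict[str, np.ndarray] = {}
    rows = []
    for t in tokens:
        if t not in cache:
            cache[t] = _token_vector(t, d, seed)
        rows.append(cache[t])
    return EmbeddingSequence(vectors=np.stack(rows), mask=np.ones(len(rows)))


class HashEmbeddingProvider:
    """Default provider satisfying the ``embed(items) -> [EmbeddingSequence]``
    interface for both DNA (6-mer) and SMILES (character) inputs."""

    def __init__(self, d: int = DEFAULT_EMBED_DIM, seed: int = 0, kind: str = "dna", k: int = 6):
        self.d, self.seed, self.kind, self.k = d, seed, kind, k

    def embed(self, items: list[str]) -> list[EmbeddingSequence]:
        tok = (lambda s: kmer_tokenize(s, self.k)) if self.kind == "dna" else smiles_tokenize
        return [hash_embed(tok(s), self.d, self.seed) for s in items]


def modified_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, key_mask: np.ndarray | None = None
) -> CoAttentionOutput:
    """Scaled dot-product attention with the additive query passthrough."""
    Q, K, V = (np.asarray(x, dtype=float) for x in (Q, K, V))
    d_K = K.shape[1]
    d_Q = Q.shape[1]
    if d_Q != d_K:
        raise ValueError(f"query dim {d_Q} != key dim {d_K}")
    if V.shape[1] != d_Q:
        raise ValueError("value dim must equal query dim for the passthrough sum")
    logits = Q @ K.T / np.sqrt(d_K)
    if key_mask is not None:
        key_mask = np.asarray(key_mask, dtype=bool)
        if not key_mask.any():
            raise ValueError("all keys masked")
        logits = np.where(key_mask[None, :], logits, -np.inf)
    logits = logits - logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    w = w / w.sum(axis=1, keepdims=True)
    context = w @ V + Q / np.sqrt(d_Q)
    return CoAttentionOutput(context=context, weights=w)


def _project(emb: EmbeddingSequence, P: np.ndarray) -> np.ndarray:
    return emb.vectors @ P


def co_attend(
    target_emb: EmbeddingSequence,
    seq_emb: EmbeddingSequence,
    d: int = DEFAULT_EMBED_DIM,
    seed: int = 0,
) -> CoAttentionOutput:
    """Co-attention with the target as query and the sequence as key/value.

    Provider dimensions are aligned to a common ``d`` by fixed seeded linear
    projections (orthonormal columns), so heterogeneous providers compose.
    Masked positions are excluded from softmax and carry zero weight.
    """
    if seq_emb.vectors.size == 0 or not np.asarray(seq_emb.mask, dtype=bool).any():
        raise ValueError("empty sequence embedding")
    rng = np.random.default_rng(seed)

    def proj(dim_in: int) -> np.ndarray:
        M = rng.standard_normal((dim_in, d))
        q, _ = np.linalg.qr(M) if dim_in >= d else (M / np.sqrt(dim_in), None)
        return q[:, :d] if dim_in >= d else M / np.sqrt(dim_in)

    Pq = proj(target_emb.vectors.shape[1])
    Pk = proj(seq_emb.vectors.shape[1])
    tmask = np.asarray(target_emb.mask, dtype=bool)
    Q = _project(target_emb, Pq)
    K = V = _project(seq_emb, Pk)
    out = modified_attention(Q, K, V, key_mask=seq_emb.mask)
    out.context[~tmask] = 0.0
    out.weights[~tmask] = 0.0
    return out


def pooled_context(out: CoAttentionOutput, mask: np.ndarray | None = None) -> np.ndarray:
    """Mean context vector over unmasked query positions (model input feature)."""
    if mask is None:
        return out.context.mean(axis=0)
    keep = np.asarray(mask, dtype=bool)
    return out.context[keep].mean(axis=0)
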