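"""AptaClux: summarizing enriched SELEX pools into consensus candidates.

A VAE is trained over the unique sequences of one or more NGS pool rounds,
encoding each read as concatenated sequence + secondary-structure one-hots.
The training loss is ``sequence + structure + KL`` with the same elementwise
forms as AptaVAE. Two summarization routes then operate on the identical
matrix of posterior means:

* high-density (HD): Gaussian KDE (bandwidth 0.5, evaluated after PCA
  reduction by default) ranks sequences by latent density; the top fraction
  (default 1%) is aligned and collapsed to a consensus candidate;
* cluster-consensus (CC): fixed-seed k-means (default k=10) partitions the
  latent space; cluster centers are decoded to sequences and aligned into a
  consensus candidate, with per-cluster sequence logos as a side product.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import KernelDensity

from . import _autograd as ag
from .bga_library import GAP, progressive_msa
from .seqstruct import ALPHABET, decode_onehot, encode_pair, fold_structure

_CLIP = 1e-7


@dataclass
class PoolRound:
    """Unique sequences with read counts for one SELEX round."""

    round_id: int
    members: dict[str, int]

    def __post_init__(self):
        for s, c in self.members.items():
            if c < 1:
                raise ValueError(f"count {c} < 1 for {s}")

    @property
    def depth(self) -> int:
        return sum(self.members.values())

    def sequences(self) -> list[str]:
        return list(self.members.keys())


@dataclass
class CluxConfig:
    latent_dim: int = 32
    hidden: int = 128
    bandwidth: float = 0.5
    density_fraction: float = 0.01
    k_clusters: int = 10
    pca_dims: int = 8          # 0 = evaluate KDE in the raw latent space
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 400
    patience: int = 60
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if not (0 < self.density_fraction <= 1):
            raise ValueError("density_fraction must lie in (0, 1]")
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")


@dataclass
class ClusterSummary:
    label: int
    members: list[str]
    center_sequence: str
    logo_counts: np.ndarray


@dataclass
class PoolSummary:
    hd_candidate: str
    cc_candidate: str
    hd_members: list[str]
    center_sequences: list[str]
    clusters: list[ClusterSummary]
    latent_hash: str
    round_ids: list[int]
    seed: int


class AptaClux:
    """Sequence+structure VAE over a pooled read set."""

    def __init__(self, cfg: CluxConfig, L: int, use_structure: bool = True):
        self.cfg = cfg
        self.L = L
        self.use_structure = use_structure
        rng = np.random.default_rng(cfg.seed)
        d_in = L * (7 if use_structure else 4)
        self.enc = ag.Linear(d_in, cfg.hidden, rng)
        self.mu_head = ag.Linear(cfg.hidden, cfg.latent_dim, rng)
        self.logvar_head = ag.Linear(cfg.hidden, cfg.latent_dim, rng)
        self.dec = ag.Linear(cfg.latent_dim, cfg.hidden, rng)
        self.head_seq = ag.Linear(cfg.hidden, L * 4, rng)
        self.head_struct = ag.Linear(cfg.hidden, L * 3, rng)
        self.history: list[dict] = []

    @property
    def params(self):
        layers = [self.enc, self.mu_head, self.logvar_head, self.dec, self.head_seq, self.head_struct]
        return [p for l in layers for p in l.params]

    def _encode_graph(self, X):
        h = self.enc(ag.Tensor(X, requires_grad=False)).relu()
        return self.mu_head(h), self.logvar_head(h).clip(-10.0, 10.0)

    def _decode_graph(self, z):
        h = self.dec(z).relu()
        return self.head_seq(h).sigmoid(), self.head_struct(h).sigmoid()

    def encode_mu(self, X: np.ndarray) -> np.ndarray:
        mu, _ = self._encode_graph(np.atleast_2d(X))
        return mu.data

    def decode_sequences(self, z: np.ndarray) -> list[str]:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        seq_p, _ = self._decode_graph(ag.Tensor(z, requires_grad=False))
        out = []
        for row in seq_p.data:
            out.append(str(decode_onehot(row.reshape(self.L, 4), np.ones(self.L))))
        return out

    def snapshot(self):
        return [p.data.copy() for p in self.params]

    def load(self, snap):
        for p, d in zip(self.params, snap):
            p.data[...] = d


def encode_pool(seqs: list[str], L: int, use_structure: bool = True,
                structures: Optional[dict[str, str]] = None) -> np.ndarray:
    """One-hot feature matrix for a read set; structures are folded with the
    built-in folder unless supplied externally."""
    rows = []
    for s in seqs:
        db = structures[s] if structures and s in structures else str(fold_structure(s))
        enc = encode_pair(s, db, max_len=L)
        feat = [enc.seq_onehot.reshape(-1)]
        if use_structure:
            feat.append(enc.struct_onehot.reshape(-1))
        rows.append(np.concatenate(feat))
    return np.asarray(rows)


def _bce_sum(pred: ag.Tensor, target: np.ndarray) -> ag.Tensor:
    y = ag.Tensor(target, requires_grad=False)
    x = pred.clip(_CLIP, 1 - _CLIP)
    return (-(y * x.log() + (1.0 - y) * (1.0 - x).log())).sum() / target.shape[0]


def train_aptaclux(
    pools: PoolRound | list[PoolRound],
    cfg: CluxConfig | None = None,
    use_structure: bool = True,
    structures: Optional[dict[str, str]] = None,
) -> AptaClux:
    """Train the pool VAE on the union of unique sequences across rounds.

    Loss per step: total = sequence + structure + KL, each term logged so the
    identity is auditable. The checkpoint with the lowest validation loss is
    restored before returning.
    """
    cfg = cfg or CluxConfig()
    if isinstance(pools, PoolRound):
        pools = [pools]
    seqs = sorted({s for p in pools for s in p.members})
    if len(seqs) < 50:
        raise ValueError("need at least 50 unique sequences")
    L = max(len(s) for s in seqs)
    X = encode_pool(seqs, L, use_structure, structures)
    model = AptaClux(cfg, L=L, use_structure=use_structure)
    model.train_sequences = seqs
    model.train_X = X
    n = len(seqs)
    rng = np.random.default_rng(cfg.seed + 1)
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    va, tr = perm[:n_val], perm[n_val:]
    opt = ag.Adam(model.params, lr=cfg.learning_rate)
    Lseq = model.L * 4

    def loss_on(idx, train):
        mu, logvar = model._encode_graph(X[idx])
        if train:
            eps = rng.standard_normal(mu.data.shape)
            z = mu + (logvar * 0.5).exp() * ag.Tensor(eps, requires_grad=False)
        else:
            z = mu
        seq_p, struct_p = model._decode_graph(z)
        seq_l = _bce_sum(seq_p, X[idx][:, :Lseq])
        if use_structure:
            struct_l = _bce_sum(struct_p, X[idx][:, Lseq:])
        else:
            struct_l = ag.Tensor(0.0)
        kl = (-0.5) * (1.0 + logvar - mu.square() - logvar.exp()).sum() / len(idx)
        return seq_l + struct_l + kl, seq_l, struct_l, kl

    best_val, best_snap, best_epoch = np.inf, model.snapshot(), -1
    for epoch in range(cfg.epochs):
        order = tr[rng.permutation(len(tr))]
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            opt.zero_grad()
            total, *_ = loss_on(batch, train=True)
            if not np.isfinite(total.data):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            total.backward()
            opt.step()
        vt, vs, vst, vkl = loss_on(va, train=False)
        model.history.append(
            {"epoch": epoch, "val_total": float(vt.data), "val_sequence": float(vs.data),
             "val_structure": float(vst.data), "val_kl": float(vkl.data)}
        )
        if float(vt.data) < best_val:
            best_val, best_snap, best_epoch = float(vt.data), model.snapshot(), epoch
        if epoch - best_epoch >= cfg.patience:
            break
    model.load(best_snap)
    model.best_val = best_val
    return model


def latent_means(model: AptaClux, pool: PoolRound,
                 structures: Optional[dict[str, str]] = None) -> tuple[np.ndarray, list[str]]:
    """Posterior means for each unique pool sequence (deterministic)."""
    seqs = pool.sequences()
    X = encode_pool(seqs, model.L, model.use_structure, structures)
    return model.encode_mu(X), seqs


def kde_density(latents: np.ndarray, bandwidth: float = 0.5, pca_dims: int = 8,
                seed: int = 0, sample_weight: np.ndarray | None = None) -> np.ndarray:
    """Gaussian KDE density at each point, self-term included.

    With ``pca_dims > 0`` the latents are first reduced by PCA so that a
    bandwidth of 0.5 remains numerically meaningful in high-dimensional
    latent spaces; ``pca_dims=0`` evaluates in the raw space. Passing read
    counts as ``sample_weight`` evaluates the density of the pool's reads
    (each unique sequence contributing its multiplicity), which is what an
    encoding of the raw read stream would yield.
    """
    Z = np.asarray(latents, dtype=float)
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 points for density estimation")
    if np.allclose(Z.var(axis=0), 0.0):
        warnings.warn("zero variance in all latent dimensions; densities are uniform")
        return np.full(Z.shape[0], 1.0)
    if 0 < pca_dims < Z.shape[1]:
        k = min(pca_dims, Z.shape[0])
        Z = PCA(n_components=k, random_state=seed).fit_transform(Z)
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth).fit(Z, sample_weight=sample_weight)
    return np.exp(kde.score_samples(Z))


def top_density_fraction(densities: np.ndarray, fraction: float = 0.01) -> np.ndarray:
    """Indices of the ceil(fraction*n) densest points; ties -> lower index."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    d = np.asarray(densities, dtype=float)
    k = int(np.ceil(fraction * len(d)))
    order = np.argsort(-d, kind="stable")
    return order[:k]


def kmeans_latent(latents: np.ndarray, cfg: CluxConfig, model: Optional[AptaClux] = None,
                  sample_weight: Optional[np.ndarray] = None):
    """Fixed-seed k-means over posterior means; centers decoded if a model
    is supplied. Returns (labels, centers, center_sequences).

    ``sample_weight`` (typically read counts) makes the centers summarize
    the pool's read mass rather than its unique-sequence diversity, so
    singleton background reads do not claim clusters of their own.
    """
    Z = np.asarray(latents, dtype=float)
    if Z.shape[0] < cfg.k_clusters:
        raise ValueError(f"{Z.shape[0]} points < k={cfg.k_clusters}")
    km = KMeans(n_clusters=cfg.k_clusters, init="k-means++", n_init=1,
                max_iter=300, tol=1e-6, random_state=cfg.seed)
    labels = km.fit_predict(Z, sample_weight=sample_weight)
    centers = km.cluster_centers_
    center_seqs = model.decode_sequences(centers) if model is not None else []
    return labels, centers, center_seqs


def candidate_consensus(seqs: list[str]) -> str:
    """Align and collapse to a per-column plurality consensus (A/C/G/T only).

    Gap-majority columns are dropped; base ties resolve lexicographically.
    """
    seqs = [str(s) for s in seqs]
    if not seqs:
        raise ValueError("no sequences for consensus")
    if len(seqs) == 1:
        return seqs[0]
    aln = progressive_msa(seqs)
    n = len(aln.rows)

    def collapse(drop_gappy: bool) -> str:
        out = []
        for j in range(aln.n_cols):
            col = aln.column(j)
            if drop_gappy and col.count(GAP) / n >= 0.5:
                continue
            if col.count(GAP) == n:
                continue
            best = max(ALPHABET, key=lambda b: (col.count(b), -ALPHABET.index(b)))
            out.append(best)
        return "".join(out)

    cons = collapse(drop_gappy=True)
    # highly divergent inputs can gap-dominate every column; fall back to a
    # plurality call over all columns rather than return an empty candidate
    return cons if cons else collapse(drop_gappy=False)


def sequence_logo_counts(seqs: list[str]) -> np.ndarray:
    """Position x 4 base counts (columns A,C,G,T); ragged input is aligned
    first, so gap entries reduce the column sums below the member count."""
    seqs = [str(s) for s in seqs]
    if not seqs:
        raise ValueError("no sequences for logo")
    if len(set(len(s) for s in seqs)) > 1:
        seqs = progressive_msa(seqs).rows
    L = len(seqs[0])
    counts = np.zeros((L, 4))
    for s in seqs:
        for i, c in enumerate(s):
            if c in ALPHABET:
                counts[i, ALPHABET.index(c)] += 1
    return counts


def summarize_pool(model: AptaClux, pool: PoolRound, cfg: CluxConfig | None = None,
                   structures: Optional[dict[str, str]] = None) -> PoolSummary:
    """Run both summarization routes on one pool round.

    Both routes consume the identical latent matrix; its hash is recorded in
    the output for provenance.
    """
    cfg = cfg or model.cfg
    Z, seqs = latent_means(model, pool, structures)
    latent_hash = hashlib.blake2b(Z.tobytes(), digest_size=8).hexdigest()
    counts = np.array([pool.members[s] for s in seqs], dtype=float)
    dens = kde_density(Z, bandwidth=cfg.bandwidth, pca_dims=cfg.pca_dims,
                       seed=cfg.seed, sample_weight=counts)
    hd_idx = top_density_fraction(dens, cfg.density_fraction)
    hd_members = [seqs[i] for i in hd_idx]
    hd_candidate = candidate_consensus(hd_members)
    k = min(cfg.k_clusters, Z.shape[0])
    eff = CluxConfig(**{**cfg.__dict__, "k_clusters": k})
    labels, centers, center_seqs = kmeans_latent(Z, eff, model, sample_weight=counts)
    # align centers replicated by cluster read mass: a consensus column is
    # then carried by the pool's mass, not by however many sparse background
    # clusters happen to exist
    mass = np.array([counts[labels == lab].sum() for lab in range(k)])
    reps = np.maximum(1, np.round(20 * mass / max(mass.sum(), 1)).astype(int))
    cc_candidate = candidate_consensus(
        [s for s, r in zip(center_seqs, reps) for _ in range(int(r))]
    )
    clusters = []
    for lab in range(k):
        members = [seqs[i] for i in np.flatnonzero(labels == lab)]
        if not members:
            continue
        clusters.append(
            ClusterSummary(
                label=lab,
                members=members,
                center_sequence=center_seqs[lab],
                logo_counts=sequence_logo_counts(members),
            )
        )
    return PoolSummary(
        hd_candidate=hd_candidate,
        cc_candidate=cc_candidate,
        hd_members=hd_members,
        center_sequences=center_seqs,
        clusters=clusters,
        latent_hash=latent_hash,
        round_ids=[pool.round_id],
        seed=cfg.seed,
    )


def read_pool_tsv(path, round_id: int) -> PoolRound:
    """Read 'seq<TAB>count' rows into a PoolRound."""
    members: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            s, c = line.split("\t")
            members[s] = members.get(s, 0) + int(c)
    return PoolRound(round_id=round_id, members=members)


def write_pool_tsv(path, pool: PoolRound) -> None:
    with open(path, "w") as fh:
        for s, c in sorted(pool.members.items()):
            fh.write(f"{s}\t{c}\n")


def read_pool_fastq(path, round_id: int) -> PoolRound:
    """Read FASTQ; counts are read multiplicities."""
    from Bio import SeqIO

    members: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fastq"):
        s = str(rec.seq).upper()
        members[s] = members.get(s, 0) + 1
    return PoolRound(round_id=round_id, members=members)


def save_model(model: AptaClux, path) -> None:
    """Persist trained pool-VAE weights and geometry as .npz."""
    import json

    cfg = model.cfg
    meta = {**cfg.__dict__, "L": model.L, "use_structure": model.use_structure}
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> AptaClux:
    import json

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        arrays = [z[f"p{i}"] for i in range(len(z.files) - 1)]
    L = meta.pop("L")
    use_structure = meta.pop("use_structure")
    model = AptaClux(CluxConfig(**meta), L=L, use_structure=use_structure)
    model.load(arrays)
    return model
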