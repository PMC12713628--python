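"""Synthetic study data: aptamer-target training pairs and SELEX pools.

The family generator emulates a small-molecule target family in the spirit
of the steroids: eight toy targets share a fused four-ring carbon scaffold
and differ only in peripheral substituents, and each target class has a
distinct sequence motif implanted at a class-fixed position — the "shared
backbone, class-specific binding determinant" assumption that makes guided
library design learnable. A pair's relative score follows Beta(2, 2) with
Gaussian noise, and its motif is present with probability equal to the
score, so high-scoring training examples are motif-bearing.

The SELEX simulator evolves a read pool by multinomial resampling under an
exponential fitness law (fitness = negative scaled edit distance to a
planted binder), followed by per-base mutation (a PCR-error analogue). This
reproduces the qualitative phenomena the pipeline must handle: round-wise
enrichment of the binder family and accumulation of selection bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .aptaclux import PoolRound
from .aptavae import AptamerTargetPair, make_pair
from .seqstruct import ALPHABET, NucleotideSequence, fold_structure

#: 17-carbon fused four-ring scaffold shared by every toy target.
SCAFFOLD = "C1CCC2C1CCC3C2CCC4C3CCCC4"

#: Per-class substituent edits on the scaffold (hydroxyl / ketone / methyl
#: style decorations), yielding eight distinct parseable molecules.
_CLASS_SMILES = [
    SCAFFOLD + "O",
    SCAFFOLD + "=O",
    SCAFFOLD + "C",
    SCAFFOLD + "CO",
    SCAFFOLD + "(C)O",
    "O" + SCAFFOLD,
    SCAFFOLD + "CC",
    SCAFFOLD + "C(=O)C",
]


@dataclass
class SyntheticFamilySpec:
    n_classes: int = 8
    seq_len: int = 40
    n_pairs: int = 195
    motif_len_min: int = 8
    motif_len_max: int = 12
    score_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < self.n_classes:
            raise ValueError("need at least one pair per class")


@dataclass
class SyntheticFamily:
    pairs: list[AptamerTargetPair]
    motifs: list[str]          # per class (index 0 = class 1)
    positions: list[int]       # 0-based implant start per class
    targets: list[tuple[int, str, str]]
    spec: SyntheticFamilySpec


def gen_targets(spec: SyntheticFamilySpec | None = None) -> list[tuple[int, str, str]]:
    """Eight (class_id, name, SMILES) records sharing the fused-ring scaffold."""
    spec = spec or SyntheticFamilySpec()
    if spec.n_classes > len(_CLASS_SMILES):
        raise ValueError(f"at most {len(_CLASS_SMILES)} built-in target classes")
    return [(i + 1, f"S{i + 1}", smi) for i, smi in enumerate(_CLASS_SMILES[: spec.n_classes])]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=n))


def gen_pairs(spec: SyntheticFamilySpec | None = None) -> SyntheticFamily:
    """Generate the synthetic training set.

    Per pair: class drawn uniformly; score ~ clip(Beta(2,2) + N(0, sd), 0, 1);
    a random background sequence carries the class motif at the class-fixed
    position with probability equal to the score; the structure is the
    built-in fold of the final sequence.
    """
    spec = spec or SyntheticFamilySpec()
    rng = np.random.default_rng(spec.seed)
    motifs: list[str] = []
    positions: list[int] = []
    lens = rng.integers(spec.motif_len_min, spec.motif_len_max + 1, size=spec.n_classes)
    while len(motifs) < spec.n_classes:
        m = _random_seq(rng, int(lens[len(motifs)]))
        if m not in motifs:
            motifs.append(m)
    for c in range(spec.n_classes):
        positions.append(int(rng.integers(0, spec.seq_len - len(motifs[c]) + 1)))
    targets = gen_targets(spec)
    # target chemistry is identical within a class; derive it once
    proto = {cid: make_pair("A" * 8, "." * 8, smi, cid, 0.5) for cid, _, smi in targets}
    classes = [int(rng.integers(1, spec.n_classes + 1)) for _ in range(spec.n_pairs)]
    raw = np.clip(
        rng.beta(2, 2, size=spec.n_pairs) + rng.normal(0, spec.score_noise_sd, size=spec.n_pairs),
        0, 1,
    )
    # relative scores are min-max normalized per source table; one synthetic
    # "source" per target class, so every class anchors at 0 and 1
    scores = raw.copy()
    for c in range(1, spec.n_classes + 1):
        idx = np.flatnonzero(np.array(classes) == c)
        lo, hi = raw[idx].min(), raw[idx].max()
        scores[idx] = (raw[idx] - lo) / (hi - lo) if hi > lo else 0.5
    pairs: list[AptamerTargetPair] = []
    for k in range(spec.n_pairs):
        c = classes[k]
        score = float(scores[k])
        seq = list(_random_seq(rng, spec.seq_len))
        if rng.random() < score:
            m, pos = motifs[c - 1], positions[c - 1]
            seq[pos : pos + len(m)] = m
        seq = "".join(seq)
        p = proto[c]
        pairs.append(
            AptamerTargetPair(
                seq=NucleotideSequence(seq),
                db=fold_structure(seq),
                smiles=p.smiles,
                matrices=p.matrices,
                fingerprint=p.fingerprint,
                class_label=c,
                score=score,
            )
        )
    return SyntheticFamily(pairs=pairs, motifs=motifs, positions=positions, targets=targets, spec=spec)


# ---------------------------------------------------------------------------
# SELEX simulation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSelexSpec:
    pool_size: int = 2000
    rounds: tuple[int, ...] = (3, 5, 7)
    binder: str | None = None
    binder_len: int = 40
    sharpness: float = 2.5
    mutation_rate: float = 0.002
    planted_fraction: float = 0.02
    planted_divergence: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.pool_size < 1000:
            raise ValueError("pool size must be at least 10^3")
        if not (0.0 <= self.mutation_rate <= 0.1):
            raise ValueError("mutation rate must lie in [0, 0.1]")


@dataclass
class SelexResult:
    pools: dict[int, PoolRound]
    binder: str
    spec: SyntheticSelexSpec
    trajectory: list[float] = field(default_factory=list)  # binder-family mass per round


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(out)) < rate)
    for i in hits:
        out[i] = ALPHABET[(ALPHABET.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def simulate_selex(spec: SyntheticSelexSpec | None = None) -> SelexResult:
    """Simulate SELEX rounds and report the requested pools.

    Round t+1 read counts are multinomial with probabilities proportional to
    count_i * exp(sharpness * fitness_i), fitness_i being the negative edit
    distance to the planted binder scaled by the binder length; per-base
    mutation is applied after resampling. The initial pool is random
    background plus a small planted binder family (slightly diverged copies
    of the binder), so an enrichable lineage exists from round zero.
    """
    spec = spec or SyntheticSelexSpec()
    rng = np.random.default_rng(spec.seed)
    binder = spec.binder or _random_seq(rng, spec.binder_len)
    counts: dict[str, int] = {}
    n_plant = int(round(spec.planted_fraction * spec.pool_size))
    for _ in range(n_plant):
        s = _mutate(binder, rng, spec.planted_divergence)
        counts[s] = counts.get(s, 0) + 1
    for _ in range(spec.pool_size - n_plant):
        s = _random_seq(rng, len(binder))
        counts[s] = counts.get(s, 0) + 1

    fit_cache: dict[str, float] = {}

    def fitness(s: str) -> float:
        if s not in fit_cache:
            fit_cache[s] = -edlib.align(s, binder)["editDistance"] / len(binder)
        return fit_cache[s]

    pools: dict[int, PoolRound] = {}
    trajectory: list[float] = []
    max_round = max(spec.rounds)
    for t in range(1, max_round + 1):
        seqs = sorted(counts)
        w = np.array([counts[s] * np.exp(spec.sharpness * fitness(s)) for s in seqs])
        p = w / w.sum()
        drawn = rng.multinomial(spec.pool_size, p)
        nxt: dict[str, int] = {}
        for s, c in zip(seqs, drawn):
            if c == 0:
                continue
            if spec.mutation_rate > 0:
                p_any = 1.0 - (1.0 - spec.mutation_rate) ** len(s)
                k = rng.binomial(c, p_any)
            else:
                k = 0
            if c - k > 0:
                nxt[s] = nxt.get(s, 0) + int(c - k)
            for _ in range(int(k)):
                m = _mutate(s, rng, spec.mutation_rate)
                nxt[m] = nxt.get(m, 0) + 1
        counts = nxt
        family_mass = sum(c for s, c in counts.items() if fitness(s) > -0.25) / spec.pool_size
        trajectory.append(family_mass)
        if t in spec.rounds:
            pools[t] = PoolRound(round_id=t, members=dict(counts))
    return SelexResult(pools=pools, binder=binder, spec=spec, trajectory=trajectory)
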