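"""Batch-generated analysis (BGA) and guided-library construction.

BGA repeatedly draws latent codes from the trained latent space of an
AptaVAE (by default the aggregate posterior over the training pairs; a
standard-normal prior mode is available), decodes them, and tracks running
statistics — mean score, score
standard deviation, and the proportion of decoded sequences whose predicted
score exceeds a threshold (default 0.9) — until those statistics reach a
steady state. The high-scoring survivors are grouped by predicted class,
aligned, and collapsed into a per-class library template in which conserved
columns become confined bases and variable columns remain N, flanked by
lowercase primers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import edlib
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seqstruct import ALPHABET, PrimerSpec

GAP = "-"


# ---------------------------------------------------------------------------
# BGA
# ---------------------------------------------------------------------------


@dataclass
class BGAConfig:
    batch_size: int = 64
    n_batches: int = 150
    threshold: float = 0.9
    convergence_tolerance: float = 0.01
    convergence_window: int = 5
    sample_prior: bool = False  # True: N(0,I); False: aggregate posterior
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class BGAStats:
    """Per-batch and cumulative score statistics of the generated stream."""

    batch_mean: list[float] = field(default_factory=list)
    batch_std: list[float] = field(default_factory=list)
    batch_proportion: list[float] = field(default_factory=list)
    cum_mean: list[float] = field(default_factory=list)
    cum_std: list[float] = field(default_factory=list)
    cum_proportion: list[float] = field(default_factory=list)

    @property
    def n_batches(self) -> int:
        return len(self.batch_mean)


@dataclass
class BGAResult:
    sequences: list[str]
    classes: list[int]
    scores: list[float]
    all_scores: np.ndarray
    stats: BGAStats
    converged: bool
    empty: bool


def bga_sample(model, cfg: BGAConfig) -> BGAResult:
    """Sample the trained latent space in batches; retain high scorers.

    By default latent vectors are drawn from the aggregate posterior of the
    training pairs (pick a training code uniformly, then sample its diagonal
    Gaussian): the trained region of a high-dimensional latent space carries
    negligible standard-normal mass, so prior draws land far from every
    posterior and decode to uninformative blends. ``sample_prior=True``
    restores plain N(0, I) sampling. Decoding is deterministic given z, so
    the stream is reproducible from the seed. Sequences whose predicted
    score strictly exceeds ``cfg.threshold`` are retained with their
    predicted class.
    """
    rng = np.random.default_rng(cfg.seed)
    anchors = None if cfg.sample_prior else getattr(model, "train_mu", None)
    stats = BGAStats()
    seqs: list[str] = []
    classes: list[int] = []
    scores: list[float] = []
    pooled: list[float] = []
    for _ in range(cfg.n_batches):
        eps = rng.standard_normal((cfg.batch_size, model.cfg.latent_dim))
        if anchors is None:
            z = eps
        else:
            pick = rng.integers(0, anchors.shape[0], size=cfg.batch_size)
            z = anchors[pick] + np.exp(0.5 * model.train_logvar[pick]) * eps
        bundles = model.decode_latent(z)
        batch_scores = np.array([b.score for b in bundles])
        pooled.extend(batch_scores.tolist())
        stats.batch_mean.append(float(batch_scores.mean()))
        stats.batch_std.append(float(batch_scores.std()))
        stats.batch_proportion.append(float((batch_scores > cfg.threshold).mean()))
        arr = np.array(pooled)
        stats.cum_mean.append(float(arr.mean()))
        stats.cum_std.append(float(arr.std()))
        stats.cum_proportion.append(float((arr > cfg.threshold).mean()))
        for b in bundles:
            if b.score > cfg.threshold:
                seqs.append(str(b.sequence))
                classes.append(b.class_label)
                scores.append(b.score)
    return BGAResult(
        sequences=seqs,
        classes=classes,
        scores=scores,
        all_scores=np.array(pooled),
        stats=stats,
        converged=bga_converged(stats, cfg),
        empty=len(seqs) == 0,
    )


def bga_converged(stats: BGAStats, cfg: BGAConfig) -> bool:
    """Steady-state test: the relative change of every cumulative statistic
    over the last ``convergence_window`` batches stays below the tolerance."""
    w = cfg.convergence_window
    if stats.n_batches < w:
        return False

    def settled(series: list[float]) -> bool:
        tail = series[-w:]
        for prev, cur in zip(tail[:-1], tail[1:]):
            denom = max(abs(prev), 1e-12)
            if abs(cur - prev) / denom >= cfg.convergence_tolerance:
                return False
        return True

    return settled(stats.cum_mean) and settled(stats.cum_std) and settled(stats.cum_proportion)


def group_and_sort(
    seqs: list[str], classes: list[int], scores: list[float], n_classes: int = 8
) -> dict[int, list[tuple[str, float]]]:
    """Per-class lists sorted by descending score; ties break lexicographically."""
    groups: dict[int, list[tuple[str, float]]] = {c: [] for c in range(1, n_classes + 1)}
    for s, c, sc in zip(seqs, classes, scores):
        if c not in groups:
            raise KeyError(f"unknown class id {c}")
        groups[c].append((s, sc))
    for c in groups:
        groups[c].sort(key=lambda t: (-t[1], t[0]))
    return groups


# ---------------------------------------------------------------------------
# progressive multiple sequence alignment
# ---------------------------------------------------------------------------

MATCH, MISMATCH, GAP_PEN = 1.0, -1.0, -2.0
_SYMS = ALPHABET + GAP


@dataclass
class Alignment:
    """Gapped rows of equal length; de-gapping row i returns input i."""

    rows: list[str]

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


def _col_score(f1: np.ndarray, f2: np.ndarray) -> float:
    # expected sum-of-pairs score between two profile columns
    # (frequency vectors over A,C,G,T,-); base-gap pairs cost the gap penalty
    b1, b2 = f1[:4], f2[:4]
    same = float(b1 @ b2)
    tot = float(b1.sum() * b2.sum())
    s = MATCH * same + MISMATCH * (tot - same)
    s += GAP_PEN * float(b1.sum() * f2[4] + b2.sum() * f1[4])
    return s


def _profile(rows: list[str]) -> np.ndarray:
    n_cols = len(rows[0])
    P = np.zeros((n_cols, 5))
    for r in rows:
        for j, c in enumerate(r):
            P[j, _SYMS.index(c)] += 1.0
    return P / len(rows)


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> list[str]:
    """Semi-global profile-profile DP: linear gaps, free terminal gaps."""
    A, B = _profile(rows_a), _profile(rows_b)
    m, n = len(A), len(B)
    occ_a = A[:, :4].sum(axis=1)
    occ_b = B[:, :4].sum(axis=1)
    F = np.zeros((m + 1, n + 1))
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            diag = F[i - 1, j - 1] + _col_score(A[i - 1], B[j - 1])
            up = F[i - 1, j] + (GAP_PEN * occ_a[i - 1] if j < n else 0.0)
            left = F[i, j - 1] + (GAP_PEN * occ_b[j - 1] if i < m else 0.0)
            F[i, j] = max(diag, up, left)
    # F[:,0] and F[0,:] stay zero: leading gaps are free
    i, j = m, n
    ops: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = F[i - 1, j - 1] + _col_score(A[i - 1], B[j - 1])
            if math.isclose(F[i, j], diag, abs_tol=1e-9):
                ops.append("D")
                i, j = i - 1, j - 1
                continue
        if i > 0:
            up = F[i - 1, j] + (GAP_PEN * occ_a[i - 1] if 0 < j < n else 0.0)
            if math.isclose(F[i, j], up, abs_tol=1e-9):
                ops.append("U")
                i -= 1
                continue
        ops.append("L")
        j -= 1
    ops.reverse()
    out_a, out_b = [], []
    ia = ib = 0
    for op in ops:
        if op == "D":
            out_a.append(ia)
            out_b.append(ib)
            ia += 1
            ib += 1
        elif op == "U":
            out_a.append(ia)
            out_b.append(None)
            ia += 1
        else:
            out_a.append(None)
            out_b.append(ib)
            ib += 1
    merged = []
    for r in rows_a:
        merged.append("".join(r[k] if k is not None else GAP for k in out_a))
    for r in rows_b:
        merged.append("".join(r[k] if k is not None else GAP for k in out_b))
    return merged


def pairwise_align_score(a: str, b: str) -> float:
    """Optimal pairwise alignment score under the aligner's scoring scheme
    (match +1, mismatch -1, gap -2, terminal gaps free)."""
    m, n = len(a), len(b)
    F = np.zeros((m + 1, n + 1))
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            diag = F[i - 1, j - 1] + (MATCH if a[i - 1] == b[j - 1] else MISMATCH)
            up = F[i - 1, j] + (GAP_PEN if j < n else 0.0)
            left = F[i, j - 1] + (GAP_PEN if i < m else 0.0)
            F[i, j] = max(diag, up, left)
    return float(F[m, n])


def progressive_msa(seqs: list[str]) -> Alignment:
    """Guide-tree progressive alignment (UPGMA on edit distances).

    Deterministic given input order; a single sequence is returned as-is.
    """
    seqs = [str(s) for s in seqs]
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return Alignment(rows=list(seqs))
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = edlib.align(seqs[i], seqs[j])["editDistance"]
    Z = linkage(squareform(D, checks=False), method="average")
    clusters: dict[int, tuple[list[str], list[int]]] = {
        i: ([s], [i]) for i, s in enumerate(seqs)
    }
    nxt = n
    for a, b, _, _ in Z:
        ra, ia = clusters.pop(int(a))
        rb, ib = clusters.pop(int(b))
        clusters[nxt] = (_align_profiles(ra, rb), ia + ib)
        nxt += 1
    rows, order = clusters.popitem()[1]
    restored = [None] * n
    for row, src in zip(rows, order):
        restored[src] = row
    return Alignment(rows=restored)


# ---------------------------------------------------------------------------
# library templates
# ---------------------------------------------------------------------------


@dataclass
class LibraryTemplate:
    """Per-position confined base or N, with the source alignment columns."""

    symbols: str                      # over A,C,G,T,N; 1-based positions
    confined: list[int]               # 1-based indices of confined positions
    source_columns: list[int]         # alignment column (0-based) per position
    primers: Optional[PrimerSpec] = None


def consensus_template(a: Alignment, conservation_threshold: float = 0.8) -> LibraryTemplate:
    """Collapse an alignment into a library template.

    Columns that are mostly gaps (gap fraction >= 0.5) are dropped; a kept
    column is confined to its modal base when that base reaches the
    conservation threshold among non-gap entries, else it stays N.
    """
    if not a.rows:
        raise ValueError("empty alignment")
    n_rows = len(a.rows)
    symbols: list[str] = []
    confined: list[int] = []
    source: list[int] = []
    for j in range(a.n_cols):
        col = a.column(j)
        gaps = col.count(GAP)
        if gaps / n_rows >= 0.5:
            continue
        counts = [(col.count(b), b) for b in ALPHABET]
        best_count, best_base = max(counts, key=lambda t: (t[0], -ALPHABET.index(t[1])))
        non_gap = n_rows - gaps
        if best_count / non_gap >= conservation_threshold:
            symbols.append(best_base)
            confined.append(len(symbols))
        else:
            symbols.append("N")
        source.append(j)
    if not symbols:
        raise ValueError("all alignment columns dropped (gap-dominated)")
    return LibraryTemplate(symbols="".join(symbols), confined=confined, source_columns=source)


def emit_library(t: LibraryTemplate, primers: PrimerSpec) -> tuple[str, str]:
    """Render the library string (lowercase primers flanking the template)
    and a FASTA header listing the confined positions."""
    lib = str(primers.forward).lower() + t.symbols + str(primers.reverse).lower()
    header = "confined=" + ",".join(str(i) for i in t.confined)
    return lib, header


def class_library(
    group: list[tuple[str, float]],
    primers: PrimerSpec,
    conservation_threshold: float = 0.8,
) -> tuple[LibraryTemplate, str, str]:
    """Template + rendered library for one class's high-scoring sequences."""
    seqs = [s for s, _ in group]
    aln = progressive_msa(seqs)
    tmpl = consensus_template(aln, conservation_threshold)
    tmpl.primers = primers
    lib, header = emit_library(tmpl, primers)
    return tmpl, lib, header
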