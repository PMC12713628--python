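"""Evaluation machinery and conventional NGS post-processing baselines.

Candidate quality is measured two ways: base-level (mean Levenshtein
distance to a ground-truth binder) and feature-space (Euclidean distance
between candidate and truth centroids after a shared 2-component PCA of
flattened sequence+structure one-hots). A model-agnostic ranking harness
(AUROC, AUPRC, Top-1) covers head-to-head comparisons on labeled panels.

The baselines mirror what frequency/enrichment/cluster-based NGS tools
report: top-count sequences, round-over-round enrichment ratios, and greedy
edit-distance clustering with largest-cluster / whole-library consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import edlib
import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import average_precision_score, roc_auc_score

from .aptaclux import PoolRound, candidate_consensus
from .seqstruct import encode_pair, fold_structure


@dataclass
class RankedCandidates:
    sequences: list[str]
    scores: list[float]

    def __post_init__(self):
        if any(b > a for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing")

    def top(self, n: int) -> "RankedCandidates":
        return RankedCandidates(self.sequences[:n], self.scores[:n])


@dataclass
class MetricReport:
    auroc: float
    auprc: float
    top1: float


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitution/insertion/deletion)."""
    return int(edlib.align(str(a), str(b))["editDistance"])


def avg_edit_distance(cands: RankedCandidates | list[str], truth: str, top_n: int | None = None) -> float:
    """Mean edit distance of the (top-N) candidates to a single truth sequence."""
    seqs = cands.sequences if isinstance(cands, RankedCandidates) else list(cands)
    if top_n is not None:
        seqs = seqs[:top_n]
    if not seqs:
        raise ValueError("empty candidate set")
    return float(np.mean([levenshtein(s, truth) for s in seqs]))


def pca_2d(features: np.ndarray) -> np.ndarray:
    """Project rows onto the top-2 principal components.

    Columns are centered; the sign of each component is fixed so that its
    largest-magnitude loading is positive. Rank-deficient inputs get a zero
    second component (with a warning) rather than an error.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points for a 2-component PCA")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    k = min(2, rank)
    if k == 0:
        warnings.warn("degenerate feature matrix; all projections zero")
        return np.zeros((X.shape[0], 2))
    p = PCA(n_components=k)
    Y = p.fit_transform(X)
    for c in range(k):
        load = p.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            Y[:, c] = -Y[:, c]
    if k < 2:
        warnings.warn("rank < 2; second component set to zero")
        Y = np.column_stack([Y, np.zeros(X.shape[0])])
    return Y


def centroid_distance(coords_a: np.ndarray, truth_coords: np.ndarray) -> float:
    """Euclidean distance between set centroids in a shared projection basis."""
    A = np.atleast_2d(np.asarray(coords_a, dtype=float))
    T = np.atleast_2d(np.asarray(truth_coords, dtype=float))
    if A.size == 0 or T.size == 0:
        raise ValueError("empty coordinate set")
    return float(np.linalg.norm(A.mean(axis=0) - T.mean(axis=0)))


def sequence_feature_matrix(seqs: list[str], max_len: int | None = None) -> np.ndarray:
    """Flattened sequence+structure one-hot features (the PCA feature space)."""
    L = max_len or max(len(s) for s in seqs)
    rows = []
    for s in seqs:
        enc = encode_pair(s, str(fold_structure(s)), max_len=L)
        rows.append(np.concatenate([enc.seq_onehot.reshape(-1), enc.struct_onehot.reshape(-1)]))
    return np.asarray(rows)


def feature_space_comparison(candidate_sets: dict[str, list[str]], truth_seqs: list[str]) -> dict[str, float]:
    """Centroid distance of each candidate set to the truth projection.

    The 2-component PCA basis is fit on the union of all sets so every
    centroid lives in the same coordinate system.
    """
    all_seqs = [s for seqs in candidate_sets.values() for s in seqs] + list(truth_seqs)
    L = max(len(s) for s in all_seqs)
    X = sequence_feature_matrix(all_seqs, max_len=L)
    Y = pca_2d(X)
    bounds = np.cumsum([0] + [len(s) for s in candidate_sets.values()])
    truth_coords = Y[bounds[-1] :]
    out = {}
    for (name, _), lo, hi in zip(candidate_sets.items(), bounds[:-1], bounds[1:]):
        out[name] = centroid_distance(Y[lo:hi], truth_coords)
    return out


def ranking_metrics(scores, labels) -> MetricReport:
    """AUROC (Mann-Whitney, tie-corrected), AUPRC (step interpolation), and
    Top-1 (is the best-scored item a positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("need at least one positive and one negative label")
    auroc = float(roc_auc_score(labels, scores))
    auprc = float(average_precision_score(labels, scores))
    top1 = float(labels[int(np.argmax(scores))] == 1)
    return MetricReport(auroc=auroc, auprc=auprc, top1=top1)


# ---------------------------------------------------------------------------
# conventional baselines
# ---------------------------------------------------------------------------


def baseline_frequency(pool: PoolRound, n: int | None = None) -> RankedCandidates:
    """Rank by read count, descending; count ties break lexicographically."""
    items = sorted(pool.members.items(), key=lambda kv: (-kv[1], kv[0]))
    if n is not None:
        items = items[:n]
    return RankedCandidates([s for s, _ in items], [float(c) for _, c in items])


def baseline_enrichment(early: PoolRound, late: PoolRound, n: int | None = None,
                        pseudocount: float = 1.0) -> RankedCandidates:
    """Rank by depth-normalized round-over-round frequency ratio.

    score = ((c_late + pc) / depth_late) / ((c_early + pc) / depth_early);
    the pseudocount keeps sequences appearing only late finite and ranked.
    """
    de, dl = early.depth, late.depth
    scored = []
    for s in set(early.members) | set(late.members):
        ce = early.members.get(s, 0)
        cl = late.members.get(s, 0)
        scored.append((s, ((cl + pseudocount) / dl) / ((ce + pseudocount) / de)))
    scored.sort(key=lambda kv: (-kv[1], kv[0]))
    if n is not None:
        scored = scored[:n]
    return RankedCandidates([s for s, _ in scored], [x for _, x in scored])


def baseline_cluster_consensus(pool: PoolRound, radius: int = 3) -> tuple[str, str]:
    """Greedy single-linkage clustering at edit distance <= radius.

    Sequences are visited in count order (ties lexicographic); each joins
    the first existing cluster whose seed is within the radius, else seeds a
    new one. Returns (largest-cluster consensus, whole-library consensus).
    """
    if not pool.members:
        raise ValueError("empty pool")
    ordered = [s for s, _ in sorted(pool.members.items(), key=lambda kv: (-kv[1], kv[0]))]
    seeds: list[str] = []
    clusters: list[list[str]] = []
    cluster_counts: list[int] = []
    for s in ordered:
        placed = False
        for i, seed in enumerate(seeds):
            if levenshtein(s, seed) <= radius:
                clusters[i].append(s)
                cluster_counts[i] += pool.members[s]
                placed = True
                break
        if not placed:
            seeds.append(s)
            clusters.append([s])
            cluster_counts.append(pool.members[s])
    largest = clusters[int(np.argmax(cluster_counts))]
    return candidate_consensus(largest), candidate_consensus(ordered)


def motif_recovery(template: str, motif: str) -> float:
    """Fraction of a planted motif recovered as confined bases in a template.

    The template is a library string over A/C/G/T/N in alignment-consensus
    coordinates (N = unconfined); the motif is scanned over every offset and
    the best ungapped match fraction is returned, so insertions elsewhere in
    the alignment do not shift the score.
    """
    t, m = str(template), str(motif)
    if len(m) == 0 or len(t) < len(m):
        return 0.0
    best = 0
    for off in range(len(t) - len(m) + 1):
        best = max(best, sum(1 for k, b in enumerate(m) if t[off + k] == b))
    return best / len(m)
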