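"""BGA statistics, convergence, the progressive aligner, library templates."""

import numpy as np
import pytest
from Bio import Align

from dlselex.bga_library import (
    Alignment,
    BGAConfig,
    BGAStats,
    GAP,
    bga_converged,
    bga_sample,
    class_library,
    consensus_template,
    emit_library,
    group_and_sort,
    pairwise_align_score,
    progressive_msa,
)
from dlselex.seqstruct import NucleotideSequence, PrimerSpec


class _StubModel:
    """Decoder stub emitting a fixed motif at fixed positions plus noise.

    Mimics the AptaVAE decode surface (`decode_latent`, `cfg.latent_dim`)
    so BGA and templating can be exercised without training.
    """

    class _Cfg:
        latent_dim = 8

    cfg = _Cfg()

    def __init__(self, motif="GGTACCGG", start=4, L=20, score=1.0, sub_rate=0.15):
        self.motif, self.start, self.L = motif, start, L
        self.score_value = score
        self.sub_rate = sub_rate
        proto_rng = np.random.default_rng(99)
        self.background = ["ACGT"[i] for i in proto_rng.integers(0, 4, L)]

    def decode_latent(self, z):
        out = []
        for row in np.atleast_2d(z):
            local = np.random.default_rng(abs(int(row.sum() * 1e6)) % 2**31)
            seq = list(self.background)
            for pos in np.flatnonzero(local.random(self.L) < self.sub_rate):
                seq[pos] = "ACGT"[int(local.integers(0, 4))]
            seq[self.start : self.start + len(self.motif)] = self.motif
            bundle = type("B", (), {})()
            bundle.sequence = NucleotideSequence("".join(seq))
            bundle.score = self.score_value
            bundle.class_label = 1
            out.append(bundle)
        return out


class TestBGASample:
    def test_constant_score_stub(self):
        res = bga_sample(_StubModel(score=1.0), BGAConfig(batch_size=8, n_batches=6, seed=0))
        assert res.stats.cum_proportion[-1] == 1.0
        assert res.stats.cum_std[-1] == 0.0
        assert not res.empty

    def test_stats_match_direct_recomputation(self):
        cfg = BGAConfig(batch_size=8, n_batches=5, seed=3)
        res = bga_sample(_StubModel(score=0.95), cfg)
        pooled = res.all_scores
        assert np.isclose(res.stats.cum_mean[-1], pooled.mean())
        assert np.isclose(res.stats.cum_std[-1], pooled.std())
        assert np.isclose(res.stats.cum_proportion[-1], (pooled > cfg.threshold).mean())
        for i in range(cfg.n_batches):
            batch = pooled[i * 8 : (i + 1) * 8]
            assert np.isclose(res.stats.batch_mean[i], batch.mean())

    def test_same_seed_identical_multiset(self):
        cfg = BGAConfig(batch_size=8, n_batches=4, seed=9)
        a = bga_sample(_StubModel(), cfg)
        b = bga_sample(_StubModel(), cfg)
        assert a.sequences == b.sequences

    def test_below_threshold_gives_empty_status(self):
        res = bga_sample(_StubModel(score=0.5), BGAConfig(batch_size=4, n_batches=3, seed=0))
        assert res.empty and res.sequences == []

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BGAConfig(batch_size=0)
        with pytest.raises(ValueError):
            BGAConfig(threshold=1.5)


class TestConvergence:
    def _stats(self, means, stds=None, props=None):
        n = len(means)
        return BGAStats(
            batch_mean=list(means), batch_std=[0.0] * n, batch_proportion=[0.0] * n,
            cum_mean=list(means), cum_std=list(stds or [1.0] * n),
            cum_proportion=list(props or [0.5] * n),
        )

    def test_identical_batches_converge_after_window(self):
        cfg = BGAConfig(convergence_window=5)
        assert bga_converged(self._stats([0.7] * 5), cfg)
        assert not bga_converged(self._stats([0.7] * 4), cfg)

    def test_monotone_drift_not_converged(self):
        cfg = BGAConfig(convergence_window=5, convergence_tolerance=0.01)
        drifting = [1.0 * 1.1**i for i in range(10)]  # 10%/batch
        assert not bga_converged(self._stats(drifting), cfg)

    def test_shrinking_noise_converges_at_predictable_index(self):
        """Relative deltas 0.5^k fall below tol=0.01 from k=7 on, so the
        5-wide window is first satisfied when batches 8..11 are all settled."""
        cfg = BGAConfig(convergence_window=5, convergence_tolerance=0.01)
        vals = [1.0]
        for k in range(12):
            vals.append(vals[-1] * (1 + 0.5**k))
        first = next(
            n for n in range(cfg.convergence_window, len(vals))
            if bga_converged(self._stats(vals[:n]), cfg)
        )
        deltas = [0.5**k for k in range(12)]
        settled_from = next(i for i, d in enumerate(deltas) if d < 0.01)
        assert first == settled_from + cfg.convergence_window


class TestGroupAndSort:
    def test_groups_scores_descending(self):
        groups = group_and_sort(["AA", "CC", "GG"], [1, 2, 1], [0.5, 0.9, 0.8], n_classes=2)
        assert [s for s, _ in groups[1]] == ["GG", "AA"]
        assert groups[2] == [("CC", 0.9)]

    def test_empty_class_and_unknown_class(self):
        groups = group_and_sort([], [], [], n_classes=3)
        assert groups[3] == []
        with pytest.raises(KeyError):
            group_and_sort(["AA"], [9], [0.5], n_classes=3)

    def test_tie_break_lexicographic(self):
        groups = group_and_sort(["TT", "AA"], [1, 1], [0.5, 0.5], n_classes=1)
        assert [s for s, _ in groups[1]] == ["AA", "TT"]


class TestProgressiveMSA:
    def test_identical_sequences_gap_free(self):
        aln = progressive_msa(["ACGTACGT"] * 4)
        assert all(r == "ACGTACGT" for r in aln.rows)

    def test_single_sequence_returned_as_is(self):
        assert progressive_msa(["ACGT"]).rows == ["ACGT"]

    def test_two_sequence_score_equals_needleman_wunsch(self, rng):
        """Biopython's global aligner with the same scoring scheme (match +1,
        mismatch -1, gap -2, free terminal gaps) is the independent oracle."""
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
        for _ in range(25):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(5, 20))))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(5, 20))))
            assert pairwise_align_score(a, b) == aligner.score(a, b)

    def test_degap_roundtrip(self, rng):
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(8, 16))))
                for _ in range(6)]
        aln = progressive_msa(seqs)
        assert len(set(len(r) for r in aln.rows)) == 1
        for src, row in zip(seqs, aln.rows):
            assert row.replace(GAP, "") == src


class TestConsensusTemplate:
    def test_identical_rows_all_confined(self):
        tmpl = consensus_template(Alignment(rows=["ACGT"] * 5))
        assert tmpl.symbols == "ACGT"
        assert tmpl.confined == [1, 2, 3, 4]

    def test_split_column_is_n(self):
        tmpl = consensus_template(Alignment(rows=["AA", "AC", "AA", "AC"]))
        assert tmpl.symbols == "AN"

    def test_threshold_boundary(self):
        # 4xA 1xC -> 0.8 >= threshold: confined; 3xA 2xC -> 0.6: N
        conf = consensus_template(Alignment(rows=["A"] * 4 + ["C"]))
        assert conf.symbols == "A"
        free = consensus_template(Alignment(rows=["A"] * 3 + ["C"] * 2))
        assert free.symbols == "N"

    def test_gap_majority_column_dropped(self):
        tmpl = consensus_template(Alignment(rows=["A-G", "A-G", "ACG"]))
        assert tmpl.symbols == "AG"
        assert tmpl.source_columns == [0, 2]

    def test_all_columns_dropped_is_error(self):
        with pytest.raises(ValueError):
            consensus_template(Alignment(rows=["-", "-", "A"]))

    def test_row_permutation_invariance(self, rng):
        rows = ["ACGTAC", "ACGTAA", "ACCTAC", "TCGTAC", "ACGTAC"]
        ref = consensus_template(Alignment(rows=rows)).symbols
        for _ in range(5):
            perm = list(rng.permutation(len(rows)))
            assert consensus_template(Alignment(rows=[rows[i] for i in perm])).symbols == ref


class TestEmitLibrary:
    def test_lowercase_primer_rendering(self):
        tmpl = consensus_template(Alignment(rows=["ANNG".replace("N", "A"), "ACCG", "AGGG"]))
        primers = PrimerSpec(NucleotideSequence("AT"), NucleotideSequence("GC"))
        lib, header = emit_library(tmpl, primers)
        assert lib == "at" + tmpl.symbols + "gc"
        assert header == "confined=" + ",".join(map(str, tmpl.confined))

    def test_header_lists_confined_indices(self):
        tmpl = consensus_template(Alignment(rows=["AAAG", "ACCG", "AGTG"]))
        assert tmpl.symbols == "ANNG"
        _, header = emit_library(tmpl, PrimerSpec(NucleotideSequence("A"), NucleotideSequence("C")))
        assert header == "confined=1,4"


class TestMotifRecoveryWithStub:
    def test_planted_motif_recovered_as_confined(self):
        """End-to-end BGA -> group -> MSA -> template on a stub decoder that
        plants a fixed motif: at least 70% of motif positions come back
        confined to the planted base."""
        from dlselex.evalbench import motif_recovery

        model = _StubModel(motif="GGTACCGG", start=4, L=20, score=1.0)
        res = bga_sample(model, BGAConfig(batch_size=16, n_batches=4, seed=2))
        groups = group_and_sort(res.sequences, res.classes, res.scores, n_classes=1)
        tmpl, lib, header = class_library(groups[1], PrimerSpec(
            NucleotideSequence("ACGT"), NucleotideSequence("TGCA")))
        assert motif_recovery(tmpl.symbols, "GGTACCGG") >= 0.7
        assert lib.startswith("acgt") and lib.endswith("tgca")
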