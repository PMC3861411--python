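import itertools
import math

import numpy as np
import pytest

from tfannot.motif import (DEFAULT_CONFIG, Pfm, PfmError, SmaxCache,
                           TfEntry, TransferConfig, _PfmProfile,
                           dbd_pair_features, gamma_overlap,
                           global_identity, hit_probability,
                           local_alignment_kernel, local_score_normalized,
                           merge_pfms, mismatch_kernel, outlier_filter,
                           predict_pfm_similarity, read_pfm,
                           select_best_matches, smax_distance,
                           smax_similarity, train_pfm_svr, write_pfm)


def pfm(name, consensus, strength=9.0):
    """Near-deterministic PFM around a DNA consensus."""
    counts = np.ones((len(consensus), 4))
    for i, c in enumerate(consensus):
        counts[i, "ACGT".index(c)] += strength
    return Pfm(name, counts)


class TestPfmContainer:
    def test_probabilities_normalized(self):
        p = pfm("x", "ACGT")
        np.testing.assert_allclose(p.probabilities.sum(axis=1), 1.0)

    def test_reverse_complement_is_involution(self):
        p = pfm("x", "ACGGTA")
        np.testing.assert_array_equal(
            p.reverse_complement().reverse_complement().counts, p.counts)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(PfmError):
            Pfm("bad", np.array([[1.0, 2.0, 3.0]]))
        with pytest.raises(PfmError):
            Pfm("neg", np.array([[1.0, -1.0, 1.0, 1.0]]))
        with pytest.raises(PfmError):
            Pfm("zero", np.array([[0.0, 0.0, 0.0, 0.0]]))


class TestPfmIo:
    def test_jaspar_round_trip(self, tmp_path):
        pfms = [pfm("M1", "ACGTCA"), pfm("M2", "TTGACA")]
        path = tmp_path / "lib.jaspar"
        write_pfm(pfms, path, "jaspar")
        back = read_pfm(path, "jaspar")
        assert [p.id for p in back] == ["M1", "M2"]
        assert len(back[0]) == 6
        for a, b in zip(pfms, back):
            np.testing.assert_allclose(a.counts, b.counts)

    def test_transfac_round_trip_and_cross_dialect(self, tmp_path):
        pfms = [pfm("M1", "ACGTCA")]
        tpath = tmp_path / "lib.transfac"
        jpath = tmp_path / "lib.jaspar"
        write_pfm(pfms, tpath, "transfac")
        write_pfm(pfms, jpath, "jaspar")
        t = read_pfm(tpath, "transfac")[0]
        j = read_pfm(jpath, "jaspar")[0]
        # the position-major block parses to the same matrix as its
        # letter-major twin
        np.testing.assert_allclose(t.counts, j.counts)
        assert t.id == j.id == "M1"


class TestHitProbability:
    def test_single_position_concentrated_on_A(self):
        p = Pfm("a", np.array([[10.0, 0, 0, 0]]))
        threshold, alpha = hit_probability(p, TransferConfig(alpha_hit=0.3))
        assert alpha == pytest.approx(0.25)
        assert threshold > 0

    def test_uninformative_pfm_degenerates(self):
        p = Pfm("u", np.ones((3, 4)))
        threshold, alpha = hit_probability(p)
        assert alpha == 0.0 and math.isinf(threshold)

    @pytest.mark.parametrize("consensus", ["ACG", "ACGT", "AACCG"])
    def test_distribution_matches_exhaustive_enumeration(self, consensus):
        cfg = TransferConfig(alpha_hit=0.05)
        p = pfm("x", consensus)
        prof = _PfmProfile.build(p, cfg)
        L = len(consensus)
        exceed = sum(0.25 ** L for seq in
                     itertools.product(range(4), repeat=L)
                     if sum(prof.scores[i, seq[i]] for i in range(L))
                     >= prof.threshold)
        assert prof.alpha == pytest.approx(exceed, abs=1e-12)
        assert exceed <= 0.05


# a loose hit significance so even very short PFMs have attainable hits
LOOSE = TransferConfig(alpha_hit=0.3)


class TestGamma:
    def test_matches_brute_force_on_two_position_pfms(self):
        X = pfm("X", "AC")
        Y = pfm("Y", "GT")
        px = _PfmProfile.build(X, LOOSE)
        py = _PfmProfile.build(Y, LOOSE)
        for k in (-1, 0, 1):
            w_lo, w_hi = min(0, k), max(2, k + 2)
            width = w_hi - w_lo
            expected = sum(
                0.25 ** width for seq in
                itertools.product(range(4), repeat=width)
                if (sum(px.scores[i, seq[i - w_lo]] for i in range(2))
                    >= px.threshold
                    and sum(py.scores[j, seq[j + k - w_lo]]
                            for j in range(2)) >= py.threshold))
            assert gamma_overlap(X, Y, k, LOOSE) == pytest.approx(
                expected, abs=1e-14)

    def test_matches_brute_force_on_mixed_lengths(self):
        X = pfm("X", "ACGT")
        Y = pfm("Y", "CGTA")
        cfg = TransferConfig(alpha_hit=0.05)
        px = _PfmProfile.build(X, cfg)
        py = _PfmProfile.build(Y, cfg)
        for k in range(-3, 4):
            w_lo, w_hi = min(0, k), max(4, k + 4)
            width = w_hi - w_lo
            expected = sum(
                0.25 ** width for seq in
                itertools.product(range(4), repeat=width)
                if (sum(px.scores[i, seq[i - w_lo]] for i in range(4))
                    >= px.threshold
                    and sum(py.scores[j, seq[j + k - w_lo]]
                            for j in range(4)) >= py.threshold))
            assert gamma_overlap(X, Y, k, cfg) == pytest.approx(
                expected, abs=1e-14)

    def test_full_overlap_of_identical_pfms_is_alpha(self):
        X = pfm("X", "ACGTA")
        cfg = TransferConfig(alpha_hit=0.05)
        prof = _PfmProfile.build(X, cfg)
        assert gamma_overlap(X, X, 0, cfg) == pytest.approx(prof.alpha)


class TestSmax:
    def test_self_distance_zero_and_norm_one(self):
        cache = SmaxCache()
        for consensus in ("ACGTACGT", "TTGACAAT"):
            sim = smax_similarity(pfm("x", consensus), pfm("y", consensus),
                                  cache=cache)
            assert sim.s_norm == pytest.approx(1.0)
            assert sim.distance == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self):
        cache = SmaxCache()
        x, y = pfm("x", "ACGTACGT"), pfm("y", "ACGGACTT")
        assert smax_similarity(x, y, cache=cache).smax == pytest.approx(
            smax_similarity(y, x, cache=cache).smax)

    def test_reverse_complement_invariance(self):
        cache = SmaxCache()
        x, y = pfm("x", "ACGTAACG"), pfm("y", "ACGCAACG")
        d = smax_distance(x, y, cache=cache)
        assert smax_distance(x.reverse_complement(), y,
                             cache=cache) == pytest.approx(d)
        assert smax_distance(x, y.reverse_complement(),
                             cache=cache) == pytest.approx(d)

    def test_distance_is_premetric_on_random_pfms(self):
        rng = np.random.default_rng(3)
        cache = SmaxCache()
        pfms = [Pfm(f"r{i}", rng.dirichlet([0.5] * 4, size=6) * 50 + 1e-6)
                for i in range(4)]
        for p in pfms:
            assert smax_distance(p, p, cache=cache) == pytest.approx(
                0.0, abs=1e-12)
        for a, b in itertools.combinations(pfms, 2):
            d = smax_distance(a, b, cache=cache)
            assert 0.0 <= d <= 1.0
            assert smax_distance(b, a, cache=cache) == pytest.approx(d)

    def test_unrelated_motifs_are_distant(self):
        # near-deterministic, non-overlapping consensus: no sequence can be
        # a hit for both
        d = smax_distance(pfm("x", "AAAAAA", 50), pfm("y", "CCCCCC", 50))
        assert d == 1.0


class TestDbdFeatures:
    def test_identical_sequences_are_self_similar(self):
        f = dbd_pair_features("MKVLAWCRQH", "MKVLAWCRQH")
        assert f.global_identity == 1.0
        assert f.local_score == pytest.approx(1.0)
        assert f.mismatch_kernel == pytest.approx(1.0)
        assert f.local_alignment_kernel == pytest.approx(1.0)

    def test_mismatch_kernel_m0_is_kmer_dot_product(self):
        a, b = "MKVLAWMKV", "KVLAWKVQ"
        def counts(seq):
            out = {}
            for i in range(len(seq) - 2):
                out[seq[i:i + 3]] = out.get(seq[i:i + 3], 0) + 1
            return out
        ca, cb = counts(a), counts(b)
        expected = sum(v * cb.get(u, 0) for u, v in ca.items())
        assert mismatch_kernel(a, b, k=3, m=0,
                               normalized=False) == expected

    def test_mismatch_kernel_in_unit_interval(self):
        v = mismatch_kernel("MKVLAWCRQH", "MKVLAWCRQG")
        assert 0 < v <= 1

    def test_lak_large_beta_limit_is_local_alignment_score(self):
        from tfannot.homology import local_align
        a, b = "MKVLAW", "MKVICW"
        beta = 12.0
        k = local_alignment_kernel(a, b, beta=beta, normalized=False)
        assert math.log(k) / beta == pytest.approx(
            local_align(a, b), abs=0.05)

    def test_unrelated_sequences_score_low(self):
        f = dbd_pair_features("MKVLAWCRQH", "GGGGGGGGGG")
        assert f.local_score < 0.2
        assert f.mismatch_kernel < 0.2


class TestSvr:
    def test_constant_targets_predict_the_constant(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 4))
        y = np.full(30, 0.7)
        model = train_pfm_svr(X, y, seed=0)
        preds = predict_pfm_similarity(model, rng.random((10, 4)))
        np.testing.assert_allclose(preds, 0.7, atol=0.02)

    def test_too_few_pairs_suggests_pooling(self):
        with pytest.raises(ValueError, match="pool"):
            train_pfm_svr(np.zeros((5, 4)), np.zeros(5))

    def test_predictions_clipped_to_unit_interval(self):
        rng = np.random.default_rng(1)
        X = rng.random((40, 2))
        y = 2.0 * X[:, 0]  # targets beyond [0, 1]
        model = train_pfm_svr(X, y, seed=0)
        preds = predict_pfm_similarity(model, rng.random((20, 2)))
        assert (preds >= 0).all() and (preds <= 1).all()


class TestBestMatchSelection:
    def _cands(self, sims):
        return [(TfEntry(f"t{i}", "Other", "MKV"), s)
                for i, s in enumerate(sims)]

    def test_dynamic_threshold_tracks_best_candidate(self):
        selected, t, conf = select_best_matches(self._cands([0.93, 0.6]))
        assert t == pytest.approx(0.93)
        assert [e.id for e, _ in selected] == ["t0"]
        assert conf == pytest.approx(0.93)

    def test_dynamic_threshold_capped_at_bmt_max(self):
        selected, t, _ = select_best_matches(self._cands([0.99, 0.97, 0.6]))
        assert t == 0.95
        assert len(selected) == 2

    def test_no_candidate_above_floor_means_no_prediction(self):
        selected, t, conf = select_best_matches(self._cands([0.4, 0.49]))
        assert selected == [] and t is None and conf is None

    def test_static_threshold_is_strict(self):
        selected, t, _ = select_best_matches(self._cands([0.93]),
                                             threshold=0.95)
        assert selected == []
        selected, t, _ = select_best_matches(self._cands([0.96]),
                                             threshold=0.95)
        assert len(selected) == 1 and t == 0.95


class TestOutlierFilter:
    def test_identical_pfms_all_survive(self):
        ps = [pfm(f"p{i}", "ACGTAC") for i in range(3)]
        assert outlier_filter(ps) == ps

    def test_distant_third_matrix_removed(self):
        cache = SmaxCache()
        ps = [pfm("a", "ACGTAC", 50), pfm("b", "ACGTAC", 50),
              pfm("far", "TGCATG", 50)]
        kept = outlier_filter(ps, factor=1.5, cache=cache)
        assert [p.id for p in kept] == ["a", "b"]

    def test_single_pfm_never_removed(self):
        ps = [pfm("only", "ACGTAC")]
        assert outlier_filter(ps) == ps


class TestMerge:
    def test_merging_identical_pfms_is_idempotent(self):
        x = pfm("x", "ACGTACGT")
        merged = merge_pfms([x, Pfm("x2", x.counts.copy())])
        np.testing.assert_allclose(merged.probabilities, x.probabilities,
                                   atol=1e-12)

    def test_merging_with_reverse_complement_resolves_orientation(self):
        x = pfm("x", "AACGTC", 30)
        merged = merge_pfms([x, x.reverse_complement()])
        probs = merged.probabilities
        direct = np.abs(probs - x.probabilities).max()
        flipped = np.abs(probs - x.reverse_complement().probabilities).max()
        assert min(direct, flipped) < 1e-9

    def test_submotif_aligns_at_bruteforce_offset(self):
        # long motif and its exact interior slice
        x = pfm("x", "AACGTCGA", 30)
        sub = Pfm("sub", x.counts[2:6].copy())
        merged = merge_pfms([x, sub])
        assert len(merged) == len(x)  # no overhang: interior alignment
        np.testing.assert_allclose(merged.probabilities, x.probabilities,
                                   atol=1e-12)

    def test_merge_requires_input(self):
        with pytest.raises(ValueError):
            merge_pfms([])
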