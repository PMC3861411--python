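import random

import numpy as np
import pytest

from tfannot.features import (DomainEncoder, KmerEncoder, PseudoAAEncoder,
                              bitscore_percentiles, domain_features,
                              kmer_features, pseudo_aa_features,
                              pssm_features, residue_correlation)
from tfannot.homology import AlignmentHit, HitList
from tfannot.seqio import AMINO_ACIDS, SUPERCLASSES, ProteinRecord


def _hits(bits_by_class, key="label"):
    hits = []
    for cls, values in bits_by_class.items():
        for i, b in enumerate(values):
            kwargs = {key: cls}
            hits.append(AlignmentHit(subject_id=f"{cls}{i}", raw_score=0,
                                     bits=float(b), **kwargs))
    return HitList(query_id="q", hits=hits)


class TestPercentiles:
    def test_single_hit_and_missing_class(self):
        feats = bitscore_percentiles(_hits({"TF": [10.0]}), ["TF", "non-TF"])
        np.testing.assert_allclose(feats.values,
                                   [10, 10, 10, 10, 10, 0, 0, 0, 0, 0])
        assert feats.missing == ("non-TF",)

    def test_block_is_five_number_summary(self):
        feats = bitscore_percentiles(_hits({"TF": [5, 3, 1, 4, 2],
                                            "non-TF": [7]}),
                                     ["TF", "non-TF"])
        np.testing.assert_allclose(feats.values[:5], [1, 2, 3, 4, 5])
        # linear-interpolation quantiles on an even-sized list
        feats2 = bitscore_percentiles(_hits({"TF": [1, 2, 3, 4]}), ["TF"])
        np.testing.assert_allclose(feats2.values, [1, 1.75, 2.5, 3.25, 4])

    def test_superclass_task_gives_25_dims(self):
        hits = _hits({sc: [1.0, 2.0] for sc in SUPERCLASSES},
                     key="superclass")
        feats = bitscore_percentiles(hits, SUPERCLASSES)
        assert len(feats.values) == 25
        blocks = feats.values.reshape(5, 5)
        assert (np.diff(blocks, axis=1) >= 0).all()

    def test_hit_order_is_irrelevant(self):
        hits = _hits({"TF": [9, 1, 5], "non-TF": [2, 8]})
        shuffled = HitList(query_id="q", hits=list(reversed(hits.hits)))
        np.testing.assert_array_equal(
            bitscore_percentiles(hits, ["TF", "non-TF"]).values,
            bitscore_percentiles(shuffled, ["TF", "non-TF"]).values)


class TestPssm:
    def test_vector_length_and_sigmoid_range(self):
        rec = ProteinRecord(id="q", sequence="MKVLAW" * 5)
        hits = HitList(query_id="q", hits=[
            AlignmentHit(subject_id="s", raw_score=0, bits=30.0,
                         aligned_pairs=[(0, "M"), (1, "K"), (2, "V")])])
        prof = pssm_features(rec, hits)
        assert prof.vector.shape == (400,)
        assert ((prof.vector > 0) & (prof.vector < 1)).all()
        assert not prof.from_query_only

    def test_no_hits_flags_query_only_profile(self):
        rec = ProteinRecord(id="q", sequence="MKVLAW")
        prof = pssm_features(rec, None)
        assert prof.from_query_only

    def test_homopolymer_concentrates_one_compressed_row(self):
        rec = ProteinRecord(id="q", sequence="AAAAAAAA")
        prof = pssm_features(rec, None)
        row_a = AMINO_ACIDS.index("A")
        nonzero_rows = np.flatnonzero(np.abs(prof.compressed).sum(axis=1))
        assert list(nonzero_rows) == [row_a]


class TestKmer:
    def test_counting_examples(self):
        f = kmer_features("AAA", k=1)
        assert f.counts[AMINO_ACIDS.index("A")] == 3
        assert f.counts.sum() == 3
        f2 = kmer_features("ACA", k=2)
        from tfannot.features import kmer_index
        assert f2.counts[kmer_index("AC")] == 1
        assert f2.counts[kmer_index("CA")] == 1
        assert f2.counts.sum() == 2

    def test_total_counts_equal_window_count(self):
        rnd = random.Random(3)
        for _ in range(10):
            n = rnd.randint(5, 60)
            k = rnd.randint(1, 3)
            seq = "".join(rnd.choices(AMINO_ACIDS, k=n))
            assert kmer_features(seq, k).counts.sum() == n - k + 1

    def test_k_longer_than_sequence_is_zero_vector(self):
        assert kmer_features("MK", k=5).counts.sum() == 0

    def test_encoder_dim(self):
        X = KmerEncoder(k=2).fit(None).transform(["MKVLAW", "ACDE"])
        assert X.shape == (2, 400)


class TestPseudoAA:
    def test_zero_tiers_is_composition(self):
        feats = pseudo_aa_features("MKVLAWMKV", n_tiers=0)
        k1 = kmer_features("MKVLAWMKV", k=1).counts
        np.testing.assert_allclose(feats.vector, k1 / k1.sum())
        assert len(feats.vector) == 20

    def test_homopolymer_has_zero_tier_factors(self):
        feats = pseudo_aa_features("AAAAAAAAAA", n_tiers=3)
        np.testing.assert_allclose(feats.tiers, 0.0)

    def test_first_tier_matches_hand_evaluation(self):
        # theta_1 of "ARN" = mean of Theta(A,R) and Theta(R,N)
        expected = (residue_correlation("A", "R")
                    + residue_correlation("R", "N")) / 2
        feats = pseudo_aa_features("ARN", n_tiers=1)
        assert feats.tiers[0] == pytest.approx(expected)

    def test_vector_length_and_nonnegativity(self):
        feats = pseudo_aa_features("MKVLAWMKVL", n_tiers=4)
        assert len(feats.vector) == 24
        assert (feats.vector >= 0).all()
        with pytest.raises(ValueError):
            pseudo_aa_features("MKV", n_tiers=5)


class TestDomainFeatures:
    def test_binary_encoding(self):
        vocab = ("IPR1", "IPR2", "IPR3")
        np.testing.assert_array_equal(domain_features([], vocab).bits,
                                      [0, 0, 0])
        np.testing.assert_array_equal(
            domain_features(["IPR2"], vocab).bits, [0, 1, 0])
        # out-of-vocabulary ids are ignored
        np.testing.assert_array_equal(
            domain_features(["IPR2", "NEW"], vocab).bits, [0, 1, 0])

    def test_vocabulary_is_union_of_training_domains(self):
        rnd = random.Random(8)
        train = [[f"IPR{rnd.randint(1, 30)}" for _ in range(rnd.randint(0, 5))]
                 for _ in range(50)]
        enc = DomainEncoder().fit(train)
        assert set(enc.vocabulary_) == {d for row in train for d in row}
        X = enc.transform(train)
        assert X.shape == (50, len(enc.vocabulary_))
        for row, domains in zip(X, train):
            assert row.sum() == len(set(domains))


def test_feature_tsv_export_and_vocabulary_round_trip(tmp_path):
    from tfannot.features import save_features_tsv
    X = np.array([[1.5, 0.25], [2.0, 0.5]])
    path = tmp_path / "feats.tsv"
    save_features_tsv(X, ["a", "b"], path, row_ids=["r1", "r2"])
    lines = path.read_text().splitlines()
    assert lines[0] == "id\ta\tb"
    assert lines[1] == "r1\t1.5\t0.25"
    enc = DomainEncoder().fit([["IPR2", "IPR1"]])
    vpath = tmp_path / "vocab.txt"
    enc.save_vocabulary(vpath)
    enc2 = DomainEncoder().load_vocabulary(vpath)
    assert enc2.vocabulary_ == enc.vocabulary_
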