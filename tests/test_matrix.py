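from collections import Counter

import numpy as np
import pytest

from memovec import (
    FeatureTable,
    MemoMatrix,
    MemoVector,
    SpectralDocument,
    filter_blanks,
    filter_words,
    matrix_from_aligned,
    matrix_from_unaligned,
    merge,
    normalize_samplewise,
    vector_from_documents,
)

WORDS = [f"peak@{100 + k}.00" for k in range(12)] + [f"loss@{10 + k}.00" for k in range(8)]


def doc(words, feature="f", sample=""):
    return SpectralDocument(feature_id=feature, words=tuple(words), source_sample=sample)


def random_counts(rng, n_samples, n_words, density=0.4):
    data = rng.integers(0, 6, size=(n_samples, n_words)) * (
        rng.random((n_samples, n_words)) < density
    )
    # guarantee no all-zero rows
    for i in range(n_samples):
        if data[i].sum() == 0:
            data[i, rng.integers(n_words)] = 1
    return {
        f"S{i}": {WORDS[j % len(WORDS)] + f"_{j}": int(v) for j, v in enumerate(row) if v}
        for i, row in enumerate(data)
    }


class TestVectorFromDocuments:
    def test_counts_are_summed_occurrences(self):
        docs = [doc(["peak@150.12", "loss@50.00"]), doc(["peak@150.12"])]
        v = vector_from_documents(docs, "S")
        assert v.counts == {"peak@150.12": 2, "loss@50.00": 1}

    def test_empty_document_list_gives_empty_vector(self):
        assert vector_from_documents([], "S").counts == {}

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        docs = [
            doc(rng.choice(WORDS, size=rng.integers(1, 15)).tolist(), feature=f"f{i}")
            for i in range(100)
        ]
        v = vector_from_documents(docs, "S")
        brute = Counter(w for d in docs for w in d.words)
        assert v.counts == dict(brute)

    def test_mixed_source_sample_rejected(self):
        with pytest.raises(ValueError, match="belongs to sample"):
            vector_from_documents([doc(["a"], sample="other")], "S")


class TestMatrixFromUnaligned:
    def test_disjoint_vocabularies_zero_filled(self):
        m = matrix_from_unaligned({"S1": [doc(["a"])], "S2": [doc(["b", "b"])]})
        assert m.sample_ids == ("S1", "S2")
        assert m.vocabulary == ("a", "b")
        np.testing.assert_array_equal(m.dense(), [[1, 0], [0, 2]])

    def test_sample_order_equivariance(self):
        docs = {"S1": [doc(["a", "b"])], "S2": [doc(["b"])], "S3": [doc(["c"])]}
        m1 = matrix_from_unaligned(docs)
        m2 = matrix_from_unaligned(dict(reversed(docs.items())))
        for s in docs:
            assert m1.vector(s).counts == m2.vector(s).counts
        assert m2.sample_ids == ("S3", "S2", "S1")

    def test_single_sample_matches_its_vector(self):
        docs = [doc(["a", "a", "b"])]
        m = matrix_from_unaligned({"S1": docs})
        assert m.vector("S1").counts == vector_from_documents(docs, "S1").counts

    def test_conservation_of_total_word_occurrences(self, small_study):
        from memovec.documents import documents_from_spectra

        samples = {
            sid: documents_from_spectra(sp)[0] for sid, sp in small_study.spectra.items()
        }
        m = matrix_from_unaligned(samples)
        total_words = sum(len(d.words) for docs in samples.values() for d in docs)
        assert m.counts.sum() == total_words


class TestMatrixFromAligned:
    def test_presence_absence_rule(self):
        table = FeatureTable(("f1",), ("S1", "S2"), np.array([[5.0, 0.0]]))
        m = matrix_from_aligned({"f1": doc(["peak@100.00"], feature="f1")}, table)
        assert m.vector("S1").counts == {"peak@100.00": 1}
        assert m.vector("S2").counts == {}

    def test_all_zero_table_gives_empty_vectors(self):
        table = FeatureTable(("f1",), ("S1",), np.array([[0.0]]))
        m = matrix_from_aligned({"f1": doc(["a"], feature="f1")}, table)
        assert m.shape == (1, 0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        features = [f"f{i}" for i in range(5)]
        samples = [f"S{j}" for j in range(3)]
        values = rng.integers(0, 2, size=(5, 3)) * rng.uniform(1, 100, size=(5, 3))
        table = FeatureTable(tuple(features), tuple(samples), values)
        docs = {
            f: doc(rng.choice(WORDS, size=rng.integers(1, 8)).tolist(), feature=f)
            for f in features
        }
        m = matrix_from_aligned(docs, table)
        for j, s in enumerate(samples):
            brute = Counter()
            for i, f in enumerate(features):
                if values[i, j] > 0:
                    brute.update(docs[f].words)
            assert m.vector(s).counts == dict(brute)

    def test_unknown_document_feature_is_error(self):
        table = FeatureTable(("f1",), ("S1",), np.array([[1.0]]))
        with pytest.raises(ValueError, match="f2"):
            matrix_from_aligned({"f1": doc(["a"]), "f2": doc(["b"])}, table)

    def test_feature_without_document_skipped_with_warning(self, caplog):
        table = FeatureTable(("f1", "f2"), ("S1",), np.array([[1.0], [1.0]]))
        with caplog.at_level("WARNING"):
            m = matrix_from_aligned({"f1": doc(["a"], feature="f1")}, table)
        assert m.vector("S1").counts == {"a": 1}
        assert "no document" in caplog.text

    def test_diagonal_table_equals_unaligned_route(self):
        """A table where each feature is present only in its source sample
        makes the aligned route coincide with the unaligned one."""
        rng = np.random.default_rng(2)
        per_sample = {
            f"S{j}": [
                doc(rng.choice(WORDS, size=5).tolist(), feature=f"S{j}_f{i}", sample=f"S{j}")
                for i in range(4)
            ]
            for j in range(3)
        }
        features = [d.feature_id for docs in per_sample.values() for d in docs]
        samples = list(per_sample)
        values = np.zeros((len(features), len(samples)))
        for i, f in enumerate(features):
            values[i, samples.index(f.split("_")[0])] = 1.0
        table = FeatureTable(tuple(features), tuple(samples), values)
        flat = {d.feature_id: d for docs in per_sample.values() for d in docs}
        assert matrix_from_aligned(flat, table) == matrix_from_unaligned(per_sample)


class TestMerge:
    def test_empty_matrix_is_identity_element(self):
        a = MemoMatrix.from_counts({"S1": {"a": 1.0}})
        empty = MemoMatrix([], [], np.zeros((0, 0)))
        assert merge([a, empty]) == a

    def test_commutative_up_to_row_order(self):
        a = MemoMatrix.from_counts({"S1": {"a": 1, "b": 2}})
        b = MemoMatrix.from_counts({"S2": {"b": 3, "c": 1}})
        ab, ba = merge([a, b]), merge([b, a])
        for s in ("S1", "S2"):
            assert ab.vector(s).counts == ba.vector(s).counts

    def test_merge_equals_pooled_construction(self):
        rng = np.random.default_rng(3)
        pools = [random_counts(rng, 3, 10) for _ in range(3)]
        # disjoint sample ids
        pools = [
            {f"G{g}_{s}": c for s, c in pool.items()} for g, pool in enumerate(pools)
        ]
        merged = merge([MemoMatrix.from_counts(p) for p in pools])
        pooled = MemoMatrix.from_counts({s: c for p in pools for s, c in p.items()})
        for s in pooled.sample_ids:
            assert merged.vector(s).counts == pooled.vector(s).counts
        assert merged.vocabulary == pooled.vocabulary

    def test_merge_of_row_split_recovers_matrix(self):
        rng = np.random.default_rng(4)
        m = MemoMatrix.from_counts(random_counts(rng, 6, 12))
        halves = [
            MemoMatrix.from_counts({s: m.vector(s).counts for s in m.sample_ids[:3]}),
            MemoMatrix.from_counts({s: m.vector(s).counts for s in m.sample_ids[3:]}),
        ]
        assert merge(halves) == m

    def test_duplicate_sample_ids_rejected(self):
        a = MemoMatrix.from_counts({"S1": {"a": 1.0}})
        with pytest.raises(ValueError, match="duplicate sample"):
            merge([a, a])

    def test_mixed_normalization_rejected(self):
        a = MemoMatrix.from_counts({"S1": {"a": 1.0}})
        b = normalize_samplewise(MemoMatrix.from_counts({"S2": {"a": 2.0}}))
        with pytest.raises(ValueError, match="normalized"):
            merge([a, b])


class TestFilterBlanks:
    def test_blank_word_removed_everywhere(self):
        m = MemoMatrix.from_counts(
            {"S1": {"w": 5, "x": 1}, "B": {"w": 1}}
        )
        out = filter_blanks(m, {"B"})
        assert out.sample_ids == ("S1",)
        assert out.vocabulary == ("x",)

    def test_no_blanks_is_identity(self):
        m = MemoMatrix.from_counts({"S1": {"a": 1.0}})
        assert filter_blanks(m, set()) == m

    def test_matches_brute_force_column_scan(self):
        rng = np.random.default_rng(5)
        m = MemoMatrix.from_counts(random_counts(rng, 8, 15))
        blanks = {"S0", "S3"}
        out = filter_blanks(m, blanks)
        contaminated = {
            w for b in blanks for w, c in m.vector(b).counts.items() if c > 0
        }
        expected_vocab = tuple(sorted(set(m.vocabulary) - contaminated))
        # brute-force: drop contaminated words, keep remaining nonzero columns
        survivors = {
            w for w in expected_vocab
            if any(m.vector(s).counts.get(w, 0) for s in m.sample_ids if s not in blanks)
        }
        assert set(out.vocabulary) == survivors
        for s in out.sample_ids:
            expect = {
                w: c for w, c in m.vector(s).counts.items() if w not in contaminated
            }
            assert out.vector(s).counts == expect

    def test_unknown_blank_id_rejected(self):
        m = MemoMatrix.from_counts({"S1": {"a": 1.0}})
        with pytest.raises(ValueError, match="unknown blank"):
            filter_blanks(m, {"nope"})


class TestNormalize:
    def test_rows_become_relative_frequencies(self):
        m = MemoMatrix.from_counts({"S1": {"a": 2.0, "b": 2.0}})
        out = normalize_samplewise(m)
        assert out.vector("S1").counts == {"a": 0.5, "b": 0.5}
        assert out.normalized

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        m = MemoMatrix.from_counts(random_counts(rng, 5, 9))
        once = normalize_samplewise(m)
        twice = normalize_samplewise(once)
        np.testing.assert_allclose(twice.dense(), once.dense(), atol=1e-12)

    def test_random_matrix_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        m = MemoMatrix.from_counts(random_counts(rng, 10, 50))
        out = normalize_samplewise(m)
        np.testing.assert_allclose(out.dense().sum(axis=1), 1.0, atol=1e-9)

    def test_all_zero_row_names_sample(self):
        m = MemoMatrix(["S1", "S2"], ["a"], np.array([[1.0], [0.0]]))
        with pytest.raises(ValueError, match="S2"):
            normalize_samplewise(m)


class TestFilterWords:
    def test_defaults_are_identity(self):
        rng = np.random.default_rng(8)
        m = MemoMatrix.from_counts(random_counts(rng, 4, 10))
        assert filter_words(m) == m

    def test_min_two_removes_singleton_words(self):
        m = MemoMatrix.from_counts({"S1": {"only": 3, "shared": 1}, "S2": {"shared": 2}})
        out = filter_words(m, min_samples=2)
        assert out.vocabulary == ("shared",)

    def test_matches_brute_force_occurrence_count(self):
        rng = np.random.default_rng(9)
        m = MemoMatrix.from_counts(random_counts(rng, 7, 20))
        out = filter_words(m, min_samples=2, max_samples=5)
        for w in m.vocabulary:
            occ = sum(1 for s in m.sample_ids if m.vector(s).counts.get(w, 0) > 0)
            assert (w in out.vocabulary) == (2 <= occ <= 5)


class TestMemoMatrixInvariants:
    def test_all_zero_columns_dropped_and_vocabulary_sorted(self):
        m = MemoMatrix(["S1"], ["z", "a", "dead"], np.array([[1.0, 2.0, 0.0]]))
        assert m.vocabulary == ("a", "z")
        np.testing.assert_array_equal(m.dense(), [[2.0, 1.0]])

    def test_row_restricted_to_nonzeros_equals_vector(self):
        rng = np.random.default_rng(10)
        counts = random_counts(rng, 4, 12)
        m = MemoMatrix.from_counts(counts)
        for s, c in counts.items():
            assert m.vector(s).counts == {w: float(v) for w, v in c.items()}

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            MemoMatrix(["S1"], ["a"], np.array([[-1.0]]))

    def test_zero_valued_entries_never_stored(self):
        v = MemoVector("S", {"a": 0.0, "b": 1.0})
        assert v.counts == {"b": 1.0}
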