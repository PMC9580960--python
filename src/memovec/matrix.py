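"""Per-sample word-count vectors and the sample x word count matrix.

A sample's fingerprint vector is the sum of word occurrences over all of
its documents. Vectors from different samples are aligned on their word
vocabularies into a sparse count matrix; matrices can be merged (e.g. to
append newly profiled samples, or to combine acquisitions from different
instruments), stripped of blank-associated words, and normalized
sample-wise before cross-platform comparison.

The vocabulary is kept in lexicographic order and all-zero columns are
dropped, so a matrix has exactly one canonical representation and
equality/round-trip checks are meaningful.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .documents import SpectralDocument
from .spectra_io import FeatureTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MemoVector:
    """One sample's word -> count fingerprint (zero entries never stored)."""

    sample_id: str
    counts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError(f"negative count in vector for {self.sample_id!r}")
        object.__setattr__(
            self, "counts", {w: v for w, v in self.counts.items() if v != 0}
        )


def vector_from_documents(
    documents: Iterable[SpectralDocument], sample_id: str
) -> MemoVector:
    """Aggregate documents of one sample by summing word occurrences."""
    tally: Counter[str] = Counter()
    for doc in documents:
        if doc.source_sample and doc.source_sample != sample_id:
            raise ValueError(
                f"document {doc.feature_id!r} belongs to sample "
                f"{doc.source_sample!r}, not {sample_id!r}"
            )
        tally.update(doc.words)
    return MemoVector(sample_id=sample_id, counts=dict(tally))


class MemoMatrix:
    """Sparse sample x word count matrix with canonical ordering.

    Attributes
    ----------
    sample_ids : tuple of str
        Row labels, in construction order.
    vocabulary : tuple of str
        Column labels (words), lexicographically sorted; no all-zero columns.
    counts : scipy.sparse.csr_matrix
        Non-negative counts (or relative frequencies once ``normalized``).
    normalized : bool
        Whether rows have been scaled to sum to one.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        vocabulary: Sequence[str],
        counts: sparse.spmatrix | np.ndarray,
        normalized: bool = False,
    ):
        sample_ids = tuple(str(s) for s in sample_ids)
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(vocabulary)) != len(vocabulary):
            raise ValueError("duplicate words in vocabulary")
        counts = sparse.csr_matrix(counts, dtype=float)
        counts.eliminate_zeros()
        if counts.shape != (len(sample_ids), len(vocabulary)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(sample_ids)} samples x {len(vocabulary)} words"
            )
        if counts.nnz and counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        # canonicalize: drop all-zero columns, sort vocabulary
        occupancy = np.asarray((counts != 0).sum(axis=0)).ravel()
        vocabulary = tuple(str(w) for w in vocabulary)
        keep = [j for j in range(len(vocabulary)) if occupancy[j] > 0]
        order = sorted(keep, key=lambda j: vocabulary[j])
        self.sample_ids = sample_ids
        self.vocabulary = tuple(vocabulary[j] for j in order)
        self.counts = sparse.csr_matrix(counts[:, order]) if order else sparse.csr_matrix(
            (len(sample_ids), 0)
        )
        self.normalized = bool(normalized)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_vectors(
        cls, vectors: Sequence[MemoVector], normalized: bool = False
    ) -> "MemoMatrix":
        """Align vectors on the union of their vocabularies (zero-filled)."""
        vocab = sorted({w for v in vectors for w in v.counts})
        col = {w: j for j, w in enumerate(vocab)}
        mat = sparse.lil_matrix((len(vectors), len(vocab)))
        for i, v in enumerate(vectors):
            for w, c in v.counts.items():
                mat[i, col[w]] = c
        return cls([v.sample_id for v in vectors], vocab, mat.tocsr(), normalized)

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, Mapping[str, float]], normalized: bool = False
    ) -> "MemoMatrix":
        return cls.from_vectors(
            [MemoVector(s, dict(c)) for s, c in counts.items()], normalized
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, normalized: bool = False) -> "MemoMatrix":
        return cls(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
            normalized,
        )

    # -- views --------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def vector(self, sample_id: str) -> MemoVector:
        i = self.sample_ids.index(sample_id)
        row = self.counts.getrow(i).tocoo()
        return MemoVector(sample_id, {self.vocabulary[j]: v for j, v in zip(row.col, row.data)})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(),
            index=list(self.sample_ids),
            columns=list(self.vocabulary),
        )

    def dense(self) -> np.ndarray:
        return self.counts.toarray()

    def __eq__(self, other) -> bool:
        if not isinstance(other, MemoMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.vocabulary == other.vocabulary
            and self.normalized == other.normalized
            and (self.counts != other.counts).nnz == 0
        )

    def __repr__(self) -> str:
        n, v = self.shape
        return f"<MemoMatrix {n} samples x {v} words, normalized={self.normalized}>"


# ---------------------------------------------------------------------------
# construction routes


def matrix_from_unaligned(
    samples: Mapping[str, Sequence[SpectralDocument]]
) -> MemoMatrix:
    """Build a matrix straight from per-sample documents (no feature alignment).

    This is the route that bypasses retention-time-based feature alignment
    entirely: each sample's vector is built independently and vectors are
    aligned on words only.
    """
    vectors = [vector_from_documents(docs, sid) for sid, docs in samples.items()]
    return MemoMatrix.from_vectors(vectors)


def matrix_from_aligned(
    feature_documents: Mapping[str, SpectralDocument], table: FeatureTable
) -> MemoMatrix:
    """Build a matrix from an aligned feature table plus per-feature documents.

    The table is used strictly for presence/absence (value > 0 means the
    feature was detected in the sample — a gap-filled small value therefore
    counts as present); each present feature contributes its document's
    word occurrences to the sample's vector.

    Features present in the table but lacking a document (e.g. rejected at
    filtering) are skipped with a logged warning; documents whose feature id
    is absent from the table are an error.
    """
    unknown = sorted(set(feature_documents) - set(table.feature_ids))
    if unknown:
        raise ValueError(
            "documents reference feature ids absent from the table: "
            + ", ".join(unknown)
        )
    missing = [f for f in table.feature_ids if f not in feature_documents]
    if missing:
        logger.warning(
            "%d of %d features have no document and are skipped",
            len(missing),
            len(table.feature_ids),
        )
    vectors = []
    for j, sample in enumerate(table.sample_ids):
        tally: Counter[str] = Counter()
        for i, fid in enumerate(table.feature_ids):
            if table.values[i, j] > 0 and fid in feature_documents:
                tally.update(feature_documents[fid].words)
        vectors.append(MemoVector(sample, dict(tally)))
    return MemoMatrix.from_vectors(vectors)


# ---------------------------------------------------------------------------
# matrix algebra


def merge(matrices: Sequence[MemoMatrix]) -> MemoMatrix:
    """Stack matrices over the union vocabulary (sample sets must be disjoint).

    Supports the incremental workflow: fingerprint new samples on their own,
    then merge into a pre-existing matrix without touching the old data.
    """
    if not matrices:
        return MemoMatrix([], [], sparse.csr_matrix((0, 0)))
    flags = {m.normalized for m in matrices}
    if len(flags) > 1:
        raise ValueError("cannot merge normalized with raw matrices")
    seen: set[str] = set()
    for m in matrices:
        clash = seen & set(m.sample_ids)
        if clash:
            raise ValueError(f"duplicate sample id(s) across matrices: {sorted(clash)}")
        seen |= set(m.sample_ids)
    vectors = [m.vector(s) for m in matrices for s in m.sample_ids]
    return MemoMatrix.from_vectors(vectors, normalized=flags.pop())


def filter_blanks(matrix: MemoMatrix, blank_ids: Iterable[str]) -> MemoMatrix:
    """Remove background words and the blank samples that defined them.

    Every word with a nonzero count in *any* blank is dropped from the
    vocabulary (absolute rule, no fold-change), then the blank rows are
    removed.
    """
    blanks = set(blank_ids)
    unknown = blanks - set(matrix.sample_ids)
    if unknown:
        raise ValueError(f"unknown blank sample id(s): {sorted(unknown)}")
    if not blanks:
        return matrix
    blank_rows = [i for i, s in enumerate(matrix.sample_ids) if s in blanks]
    keep_rows = [i for i, s in enumerate(matrix.sample_ids) if s not in blanks]
    contaminated = np.asarray(
        (matrix.counts[blank_rows] != 0).sum(axis=0)
    ).ravel() > 0
    keep_cols = np.flatnonzero(~contaminated)
    return MemoMatrix(
        [matrix.sample_ids[i] for i in keep_rows],
        [matrix.vocabulary[j] for j in keep_cols],
        matrix.counts[keep_rows][:, keep_cols],
        matrix.normalized,
    )


def normalize_samplewise(matrix: MemoMatrix) -> MemoMatrix:
    """Scale each row to relative frequencies (row sum one).

    Used before comparing acquisitions whose overall word yield differs
    (e.g. two mass spectrometers with different sensitivity).
    """
    sums = np.asarray(matrix.counts.sum(axis=1)).ravel()
    zero = [matrix.sample_ids[i] for i in np.flatnonzero(sums == 0)]
    if zero:
        raise ValueError(f"cannot normalize all-zero sample row(s): {zero}")
    scaled = sparse.diags(1.0 / sums) @ matrix.counts
    return MemoMatrix(matrix.sample_ids, matrix.vocabulary, scaled, normalized=True)


def filter_words(
    matrix: MemoMatrix, min_samples: int = 0, max_samples: int | None = None
) -> MemoMatrix:
    """Keep words whose nonzero-sample count lies in ``[min_samples, max_samples]``.

    Off by default (``(0, n)`` is the identity): the fingerprint matrix is
    normally used unfiltered.
    """
    n = len(matrix.sample_ids)
    max_samples = n if max_samples is None else max_samples
    if not 0 <= min_samples <= max_samples <= n:
        raise ValueError("need 0 <= min_samples <= max_samples <= n_samples")
    occupancy = np.asarray((matrix.counts != 0).sum(axis=0)).ravel()
    keep = np.flatnonzero((occupancy >= min_samples) & (occupancy <= max_samples))
    return MemoMatrix(
        matrix.sample_ids,
        [matrix.vocabulary[j] for j in keep],
        matrix.counts[:, keep],
        matrix.normalized,
    )
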