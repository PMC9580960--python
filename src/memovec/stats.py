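"""Sample-level statistics on fingerprint matrices.

Bray-Curtis dissimilarities between the per-sample word-count vectors,
principal coordinates analysis (classical Gower scaling) of the resulting
distance matrix, and a PERMANOVA pseudo-F test of a grouping factor
(Anderson's permutational ANOVA on distances). Distances and ordinations
use the canonical scikit-bio containers so results plug into the wider
ecosystem; PERMANOVA outcomes are wrapped in a small result record.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.ordination import OrdinationResults, pcoa as _skbio_pcoa

from .matrix import MemoMatrix, normalize_samplewise


@dataclass(frozen=True)
class PermanovaResult:
    """Outcome of one PERMANOVA test.

    ``pseudo_F`` is the ratio of among-group to within-group mean squared
    distance; larger values mean more pronounced group separation. The
    p-value is ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)``, so its
    floor at 999 permutations is 0.001.
    """

    grouping_factor: str
    pseudo_F: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int


def bray_curtis(matrix: MemoMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between sample rows.

    ``d(u, v) = sum|u_i - v_i| / sum(u_i + v_i)`` over the shared
    vocabulary; 0 for identical vectors, 1 for disjoint word sets.
    """
    dense = matrix.dense()
    if dense.shape[0] and (dense.sum(axis=1) == 0).any():
        zero = [s for s, t in zip(matrix.sample_ids, dense.sum(axis=1)) if t == 0]
        raise ValueError(f"Bray-Curtis undefined for all-zero sample row(s): {zero}")
    condensed = pdist(dense, metric="braycurtis") if dense.shape[0] > 1 else np.zeros(0)
    return DistanceMatrix(squareform(condensed), ids=list(matrix.sample_ids))


def pcoa(dm: DistanceMatrix, k: int | None = None) -> OrdinationResults:
    """Principal coordinates of a distance matrix (Gower's classical scaling).

    Axes with non-positive eigenvalues are dropped (no Lingoes/Cailliez
    correction; negative eigenvalues from non-Euclidean dissimilarities are
    discarded and the explained proportions are relative to the positive
    part). Requesting more axes than there are positive eigenvalues
    truncates to what exists.
    """
    import warnings

    with warnings.catch_warnings():
        # full eigendecomposition is intentional at fingerprint-study scale
        warnings.filterwarnings("ignore", message="EIGH", category=RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh", warn_neg_eigval=False)
    positive = res.eigvals[res.eigvals > 0]
    axes = list(positive.index)
    if k is not None:
        axes = axes[:k]
    kept = OrdinationResults(
        short_method_name="PCoA",
        long_method_name="Principal Coordinate Analysis",
        eigvals=res.eigvals[axes],
        samples=res.samples[axes],
        proportion_explained=(res.eigvals[axes] / positive.sum()),
    )
    return kept


def permanova(
    dm: DistanceMatrix,
    grouping: Mapping[str, str] | Sequence[str],
    factor: str = "group",
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Anderson's PERMANOVA of one grouping factor on a distance matrix.

    ``grouping`` is either a sample-id -> level mapping covering every
    sample in ``dm`` or a level sequence aligned with ``dm.ids``. Ties
    (``F_perm == F_obs``) count toward the p-value numerator.
    """
    if isinstance(grouping, Mapping):
        missing = [s for s in dm.ids if s not in grouping]
        if missing:
            raise ValueError(f"grouping does not cover sample(s): {missing}")
        labels = [str(grouping[s]) for s in dm.ids]
    else:
        if len(grouping) != len(dm.ids):
            raise ValueError("grouping length does not match distance matrix")
        labels = [str(g) for g in grouping]
    levels = set(labels)
    if len(levels) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    res = _skbio_permanova(dm, labels, permutations=n_permutations, seed=seed)
    return PermanovaResult(
        grouping_factor=factor,
        pseudo_F=float(res["test statistic"]),
        p_value=float(res["p-value"]),
        n_permutations=int(res["number of permutations"]),
        n_samples=int(res["sample size"]),
        n_groups=int(res["number of groups"]),
    )


def export_for_embedding(matrix: MemoMatrix, path: str | os.PathLike) -> None:
    """Write the sample-wise-normalized matrix as wide CSV for UMAP/TMAP tools."""
    from .spectra_io import write_matrix

    out = matrix if matrix.normalized or matrix.shape[0] == 0 else normalize_samplewise(matrix)
    write_matrix(out, path, dialect="wide")
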