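"""Group structural covariance networks and jackknife individualization.

The group SCN is the region x region matrix of Pearson correlations of
regional GMV across subjects. Each subject's individualized SCN is the
edge-wise jackknife pseudovalue

    Theta_i = n * r_full - (n - 1) * r_loo(i),

where ``r_full`` is the correlation over all n subjects and ``r_loo(i)``
the correlation with subject i left out: the subject's contribution to the
group correlation. Pseudovalues are not bounded by [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from scn_cpm.atlas_io import CohortGMV

#: symmetry tolerance for vectorize()
SYMMETRY_ATOL = 1e-10


@dataclass(frozen=True)
class EdgeIndex:
    """Enumeration of the strict upper triangle of an N x N matrix.

    Pairs (i, j) with i < j are ordered row-major, the order produced by
    ``np.triu_indices(N, 1)``; the pair <-> linear-index map is bijective.
    """

    n_regions: int

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")

    @property
    def n_edges(self) -> int:
        N = self.n_regions
        return N * (N - 1) // 2

    @property
    def pairs(self) -> np.ndarray:
        """Array of shape (E, 2) with the (i, j) pair of every edge."""
        iu = np.triu_indices(self.n_regions, k=1)
        return np.column_stack(iu)

    def index_of(self, i: int, j: int) -> int:
        """Linear edge index of the pair (i, j), i < j."""
        N = self.n_regions
        if not (0 <= i < j < N):
            raise ValueError(f"invalid pair ({i}, {j}) for N={N}")
        # edges before row i, plus offset within row i
        return i * N - i * (i + 1) // 2 + (j - i - 1)


@dataclass(frozen=True)
class GroupSCN:
    """Group-level structural covariance network (Pearson correlations)."""

    r_matrix: np.ndarray
    n: int


@dataclass(frozen=True)
class IndividualSCN:
    """Jackknife-individualized SCN: subjects x edges pseudovalues.

    ``r_full`` holds the group edge correlations, ``r_loo[i]`` the edge
    correlations with subject i removed, and
    ``pseudovalues[i] = n * r_full - (n - 1) * r_loo[i]``.
    """

    pseudovalues: np.ndarray
    edge_index: EdgeIndex
    r_full: np.ndarray
    r_loo: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.pseudovalues.shape[0]


def _check_variance(X: np.ndarray, names, context: str) -> None:
    sd = X.std(axis=0)
    bad = np.nonzero(sd == 0.0)[0]
    if bad.size:
        label = names[bad[0]] if names is not None else f"column {bad[0]}"
        raise ValueError(f"region {label} has zero variance {context}")


def build_group_scn(cohort: "CohortGMV", region_names=None) -> GroupSCN:
    """Pairwise Pearson correlation of regional GMV across subjects."""
    X = np.asarray(cohort.gmv, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("at least 3 subjects are required for a group SCN")
    _check_variance(X, region_names, "across subjects")
    r = np.corrcoef(X, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return GroupSCN(r_matrix=r, n=n)


def jackknife_individual_scn(
    cohort: "CohortGMV",
    fisher_z: bool = False,
    region_names=None,
) -> IndividualSCN:
    """Individualized SCN via jackknife pseudovalues of edge correlations.

    For each subject i and edge e, ``r_loo[i, e]`` is recomputed over the
    remaining n-1 subjects and the pseudovalue is
    ``n * r_full[e] - (n - 1) * r_loo[i, e]``.

    With ``fisher_z=True`` the pseudovalues are computed on Fisher
    z-transformed correlations instead of raw r (correlations are clipped
    at +/-(1 - 1e-15) to keep the transform finite).
    """
    X = np.asarray(cohort.gmv, dtype=float)
    n, N = X.shape
    if n < 4:
        raise ValueError("at least 4 subjects are required for jackknife pseudovalues")
    _check_variance(X, region_names, "across subjects")

    edge_index = EdgeIndex(N)
    iu = np.triu_indices(N, k=1)
    r_full = np.corrcoef(X, rowvar=False)[iu]

    E = edge_index.n_edges
    r_loo = np.empty((n, E), dtype=float)
    subject_ids = getattr(cohort, "subject_ids", None)
    for i in range(n):
        sub = np.delete(X, i, axis=0)
        sd = sub.std(axis=0)
        bad = np.nonzero(sd == 0.0)[0]
        if bad.size:
            sid = subject_ids[i] if subject_ids is not None else f"index {i}"
            label = region_names[bad[0]] if region_names is not None else f"column {bad[0]}"
            raise ValueError(
                f"region {label} has zero variance with subject {sid} left out"
            )
        r_loo[i] = np.corrcoef(sub, rowvar=False)[iu]

    if fisher_z:
        clip = 1.0 - 1e-15
        theta_full = np.arctanh(np.clip(r_full, -clip, clip))
        theta_loo = np.arctanh(np.clip(r_loo, -clip, clip))
    else:
        theta_full, theta_loo = r_full, r_loo

    pseudo = n * theta_full[None, :] - (n - 1) * theta_loo
    return IndividualSCN(
        pseudovalues=pseudo, edge_index=edge_index, r_full=r_full, r_loo=r_loo
    )


def vectorize(matrix: np.ndarray) -> tuple[np.ndarray, EdgeIndex]:
    """Flatten the strict upper triangle of a symmetric matrix row-major."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=SYMMETRY_ATOL, rtol=0.0):
        raise ValueError(f"matrix is not symmetric within {SYMMETRY_ATOL}")
    N = matrix.shape[0]
    edge_index = EdgeIndex(N)
    return matrix[np.triu_indices(N, k=1)], edge_index
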