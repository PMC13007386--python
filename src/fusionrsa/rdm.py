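"""Representational dissimilarity matrices and their vectorisations.

Neural RDMs hold cellwise ``1 - decoding accuracy`` for the 6 unordered
pairs of 4 conditions; model RDMs are binary hypothesis matrices (1 where
the coded feature differs between conditions, 0.5 where it does not).
RDVs are the lower triangle, column-major, diagonal excluded (length 6);
any fixed order works for rank correlations as long as it is consistent,
and this one is fixed package-wide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schemes import condition_contrast, scheme_conditions

#: column-major lower-triangle index order for a 4x4 matrix
_TRIL_ROWS, _TRIL_COLS = np.tril_indices(4, k=-1)
_ORDER = np.lexsort((_TRIL_ROWS, _TRIL_COLS))  # column-major
TRIL_ROWS = _TRIL_ROWS[_ORDER]
TRIL_COLS = _TRIL_COLS[_ORDER]


@dataclass
class RDM:
    info_type: str
    condition_labels: tuple[str, ...]
    matrix: np.ndarray  # 4x4, symmetric, NaN diagonal
    source: str = "neural"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("RDM must be 4x4")
        off = ~np.eye(4, dtype=bool)
        if not np.allclose(
            self.matrix[off], self.matrix.T[off], rtol=0.0, atol=1e-9, equal_nan=True
        ):
            raise ValueError("RDM must be symmetric")

    @property
    def rdv(self) -> np.ndarray:
        return self.matrix[TRIL_ROWS, TRIL_COLS]


def build_neural_rdm(
    pairwise_acc: np.ndarray,
    info_type: str,
    source: str = "neural",
    convention: str = "one_minus_accuracy",
) -> RDM:
    """Neural RDM from a 4x4 pairwise decoding-accuracy matrix.

    ``convention='one_minus_accuracy'`` (default) stores cellwise
    ``1 - accuracy``; ``'accuracy'`` stores the accuracy itself, under
    which well-decoded (more dissimilar) pairs get the larger value, like
    the binary model RDMs.  The commonality index is mathematically
    invariant to this choice as long as it is applied to both neural RDVs:
    flipping both negates the two neural-model correlations, whose product
    is what enters the partialling.
    """
    acc = np.asarray(pairwise_acc, dtype=float)
    if acc.shape != (4, 4):
        raise ValueError("pairwise accuracy matrix must be 4x4")
    off = ~np.eye(4, dtype=bool)
    if np.nanmin(acc[off]) < 0 or np.nanmax(acc[off]) > 1:
        raise ValueError("accuracies must lie in [0, 1]")
    if convention == "one_minus_accuracy":
        mat = 1.0 - acc
    elif convention == "accuracy":
        mat = acc.copy()
    else:
        raise ValueError(f"unknown dissimilarity convention {convention!r}")
    np.fill_diagonal(mat, np.nan)
    return RDM(
        info_type=info_type,
        condition_labels=scheme_conditions(info_type),
        matrix=mat,
        source=source,
    )


def build_model_rdm(
    info_type: str,
    high: float = 1.0,
    low: float = 0.5,
) -> RDM:
    """Binary hypothesis RDM for one information type.

    Cells are ``high`` (default 1) where the two conditions differ on the
    coded feature and ``low`` (default 0.5) otherwise.  In the response
    scheme, cells involving a cue-colour condition take ``low`` (an
    assumption the defaults make explicit and configurable).
    """
    conds = scheme_conditions(info_type)
    contrast = condition_contrast(info_type, info_type)
    mat = np.full((4, 4), low)
    for i in range(4):
        for j in range(4):
            if contrast[i] * contrast[j] < 0:  # opposite feature levels
                mat[i, j] = high
    np.fill_diagonal(mat, np.nan)
    return RDM(info_type=info_type, condition_labels=conds, matrix=mat, source="model")


def rdm_to_rdv(rdm: RDM | np.ndarray) -> np.ndarray:
    """Lower triangle (column-major, no diagonal) of a symmetric 4x4 RDM."""
    mat = rdm.matrix if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    if mat.shape != (4, 4):
        raise ValueError("expected a 4x4 matrix")
    off = ~np.eye(4, dtype=bool)
    if not np.allclose(mat[off], mat.T[off], rtol=0.0, atol=1e-9, equal_nan=True):
        raise ValueError("matrix is asymmetric beyond tolerance")
    return mat[TRIL_ROWS, TRIL_COLS]


def rdv_to_matrix(rdv: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rdm_to_rdv` (NaN diagonal)."""
    rdv = np.asarray(rdv, dtype=float)
    if rdv.shape != (6,):
        raise ValueError("RDV must have length 6")
    mat = np.full((4, 4), np.nan)
    mat[TRIL_ROWS, TRIL_COLS] = rdv
    mat[TRIL_COLS, TRIL_ROWS] = rdv
    return mat


def aggregate_rdms(rdms: list[RDM], over: str | None = None) -> RDM:
    """Cellwise arithmetic mean of RDMs with identical labels/info type.

    ``over`` ("hemisphere" or "participant") is bookkeeping only — the
    mean is the same either way, and grouping order cannot matter for
    equal counts by linearity.
    """
    if not rdms:
        raise ValueError("nothing to aggregate")
    first = rdms[0]
    for r in rdms[1:]:
        if r.condition_labels != first.condition_labels or r.info_type != first.info_type:
            raise ValueError("cannot aggregate RDMs with mismatched labels or info type")
    return RDM(
        info_type=first.info_type,
        condition_labels=first.condition_labels,
        matrix=np.mean([r.matrix for r in rdms], axis=0),
        source=first.source,
    )
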