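"""Cross-validated linear-SVM decoding for fMRI betas and MEG epochs.

fMRI uses leave-one-block-out cross-validation on (condition, block)
pattern samples; MEG uses time-resolved stratified k-fold (default 10) on
trials, with one fold partition reused at every time sample so the
accuracy trace is comparable across time.  Features are z-scored with
training-fold statistics only.  The classifier is a linear SVM (C = 1, no
class weighting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sklearn
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .containers import BetaPatterns, SensorEpochs

sklearn.set_config(assume_finite=True)

CHANCE = 0.5

try:  # fast path: liblinear without estimator overhead (same solver as LinearSVC)
    from sklearn.svm._base import _fit_liblinear as _liblinear
except ImportError:  # pragma: no cover - exercised only on other sklearn versions
    _liblinear = None


def _zscore_train_apply(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _fit_predict_accuracy(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, y_test: np.ndarray
) -> float:
    """Linear SVM (C=1, z-scored by training stats) test accuracy.

    Binary labels must be 0/1.  Decision values <= 0 go to class 0, so an
    exact zero lands on the lower label deterministically.
    """
    Xtr, Xte = _zscore_train_apply(X_train, X_test)
    y_train = np.asarray(y_train, dtype=float)
    if _liblinear is not None:
        coef, intercept, _ = _liblinear(
            Xtr, y_train, C=1.0, fit_intercept=True, intercept_scaling=1.0,
            class_weight=None, penalty="l2", dual=True, verbose=0,
            max_iter=1000, tol=1e-4, random_state=0, loss="squared_hinge",
        )
        pred = (Xte @ coef[:, : Xte.shape[1]].T + intercept).ravel() > 0
        return float(np.mean(pred.astype(float) == np.asarray(y_test, dtype=float)))
    clf = LinearSVC(C=1.0, random_state=0).fit(Xtr, y_train)
    return float(np.mean(clf.predict(Xte) == np.asarray(y_test, dtype=float)))


@dataclass
class DecodingResult:
    """Cross-validated accuracy; scalar for fMRI, a time vector for MEG."""

    accuracy: np.ndarray  # () for fMRI, (time,) for MEG
    per_fold: np.ndarray  # (fold,) or (fold, time)
    n_folds: int
    labels: tuple
    alignment: str | None = None
    times_ms: np.ndarray | None = None


def decode_fmri_lobo(betas: BetaPatterns, labels: dict[str, int]) -> DecodingResult:
    """Leave-one-block-out decoding of a binary condition labelling.

    ``labels`` maps condition label -> class in {0, 1}; conditions absent
    from the mapping are dropped.  One fold per block: train on the
    remaining blocks' (condition, block) patterns, test on the held-out
    block.
    """
    keep = [i for i, c in enumerate(betas.condition_labels) if c in labels]
    if not keep:
        raise ValueError("labels match no condition")
    y_raw = np.array([labels[betas.condition_labels[i]] for i in keep])
    classes = np.unique(y_raw)
    if classes.size != 2:
        raise ValueError("labels must define two classes")
    y_cond = (y_raw == classes[1]).astype(float)
    n_blocks = len(betas.block_ids)
    if n_blocks < 3:
        raise ValueError("leave-one-block-out needs at least 3 blocks")
    vals = betas.values[keep]  # (cond, block, voxel)
    per_fold = np.empty(n_blocks)
    for bi, blk in enumerate(betas.block_ids):
        train_idx = [b for b in range(n_blocks) if b != bi]
        X_train = vals[:, train_idx].reshape(-1, vals.shape[2])
        y_train = np.repeat(y_cond, len(train_idx))
        if len(set(y_train)) < 2:
            raise ValueError(f"training partition for held-out block {blk} is single-class")
        X_test = vals[:, bi]
        per_fold[bi] = _fit_predict_accuracy(X_train, y_train, X_test, y_cond)
    return DecodingResult(
        accuracy=np.asarray(per_fold.mean()),
        per_fold=per_fold,
        n_folds=n_blocks,
        labels=tuple(sorted(labels)),
    )


def _stratified_partition(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    if counts.min() < k:
        raise ValueError(
            f"cannot stratify {counts.min()} samples of the minority class "
            f"into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    return [test for _, test in skf.split(np.zeros_like(y), y)]


def decode_meg_timecourse(
    epochs: SensorEpochs,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    balance: bool = False,
) -> DecodingResult:
    """Time-resolved k-fold decoding of per-trial binary labels.

    The stratified fold partition is drawn once (seeded) and reused at
    every time sample.  With ``balance=True`` the majority class is
    subsampled to the minority size within each training fold (seeded);
    test folds are left untouched.
    """
    y = np.asarray(labels)
    if y.size != epochs.n_trials:
        raise ValueError("labels must match the trial axis")
    if k < 2:
        raise ValueError("k must be >= 2")
    uniq = np.unique(y)
    if uniq.size != 2:
        raise ValueError("labels must define two classes")
    y = (y == uniq[1]).astype(float)
    folds = _stratified_partition(y, k, seed)
    bal_rng = np.random.default_rng([seed, 11])
    n_times = epochs.times_ms.size
    per_fold = np.empty((k, n_times))
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(y.size), test_idx)
        if balance:
            cls, counts = np.unique(y[train_idx], return_counts=True)
            m = counts.min()
            keep = np.concatenate(
                [
                    bal_rng.choice(train_idx[y[train_idx] == c], size=m, replace=False)
                    for c in cls
                ]
            )
            train_idx = np.sort(keep)
        y_tr, y_te = y[train_idx], y[test_idx]
        for ti in range(n_times):
            per_fold[fi, ti] = _fit_predict_accuracy(
                epochs.values[train_idx, :, ti], y_tr, epochs.values[test_idx, :, ti], y_te
            )
    return DecodingResult(
        accuracy=per_fold.mean(axis=0),
        per_fold=per_fold,
        n_folds=k,
        labels=tuple(np.unique(y)),
        alignment=epochs.alignment,
        times_ms=epochs.times_ms,
    )


def shuffle_beta_conditions(betas: BetaPatterns, rng: np.random.Generator) -> BetaPatterns:
    """Permute condition labels independently within each block.

    The block is the unit of exchangeability for fMRI: a permutation
    reassigns which condition each within-block pattern is labelled as,
    leaving the block structure intact.
    """
    vals = betas.values.copy()
    for bi in range(vals.shape[1]):
        vals[:, bi] = vals[rng.permutation(vals.shape[0]), bi]
    return BetaPatterns(
        roi=betas.roi,
        condition_labels=betas.condition_labels,
        block_ids=betas.block_ids,
        values=vals,
        hemisphere=betas.hemisphere,
    )


def permutation_null_decoding(
    data: BetaPatterns | SensorEpochs,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
    k: int = 10,
) -> np.ndarray:
    """Null accuracy distribution from full CV runs on shuffled labels.

    fMRI (BetaPatterns): condition labels are shuffled within each block.
    MEG (SensorEpochs): trial labels are permuted; returns (n_perm, time).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    if isinstance(data, BetaPatterns):
        out = np.empty(n_perm)
        for p in range(n_perm):
            out[p] = decode_fmri_lobo(shuffle_beta_conditions(data, rng), labels).accuracy
        return out
    y = np.asarray(labels)
    out = np.empty((n_perm, data.times_ms.size))
    for p in range(n_perm):
        out[p] = decode_meg_timecourse(
            data, y[rng.permutation(y.size)], k=k, seed=seed
        ).accuracy
    return out


def empirical_p(observed: float, null: np.ndarray) -> float:
    """One-tailed add-one permutation p-value: (1 + #{null >= obs})/(1 + n)."""
    null = np.asarray(null)
    return float((1 + np.sum(null >= observed)) / (1 + null.size))


def _pairwise_lobo_accuracy(values: np.ndarray) -> np.ndarray:
    """4x4 pairwise leave-one-block-out accuracy from a (4, block, voxel) array.

    Internal fast path shared by :func:`pairwise_condition_decoding` and the
    fusion permutation loop (which calls it thousands of times).
    """
    n_cond, n_blocks, _ = values.shape
    acc = np.full((n_cond, n_cond), np.nan)
    block_range = np.arange(n_blocks)
    for i in range(n_cond):
        for j in range(i + 1, n_cond):
            pair = values[[i, j]]  # (2, block, voxel)
            fold_acc = 0.0
            for b in range(n_blocks):
                train_blocks = block_range[block_range != b]
                X_train = pair[:, train_blocks].reshape(-1, pair.shape[2])
                y_train = np.repeat([0.0, 1.0], train_blocks.size)
                fold_acc += _fit_predict_accuracy(
                    X_train, y_train, pair[:, b], np.array([0.0, 1.0])
                )
            acc[i, j] = acc[j, i] = fold_acc / n_blocks
    return acc


def pairwise_condition_decoding(
    data: BetaPatterns | SensorEpochs,
    condition_labels=None,
    conditions: tuple | None = None,
    k: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Decode all 6 unordered pairs of 4 conditions.

    Returns a symmetric 4x4 accuracy matrix (NaN diagonal) for fMRI, or a
    (time, 4, 4) stack for MEG.  For MEG, ``condition_labels`` is the
    per-trial condition of each epoch and ``conditions`` fixes the row
    order (default: sorted unique labels); class sizes are balanced within
    training folds.
    """
    if isinstance(data, BetaPatterns):
        if len(data.condition_labels) != 4:
            raise ValueError("pairwise decoding expects 4 conditions")
        if len(data.block_ids) < 3:
            raise ValueError("leave-one-block-out needs at least 3 blocks")
        return _pairwise_lobo_accuracy(data.values)
    labels = np.asarray(condition_labels)
    cats = np.asarray(sorted(set(labels.tolist())) if conditions is None else list(conditions))
    if cats.size != 4:
        raise ValueError(f"pairwise decoding expects 4 condition levels, got {cats.size}")
    missing = [c for c in cats if not np.any(labels == c)]
    if missing:
        raise ValueError(f"condition level(s) with no trials: {missing}")
    n_times = data.times_ms.size
    acc = np.full((n_times, 4, 4), np.nan)
    for i in range(4):
        for j in range(i + 1, 4):
            sel = np.isin(labels, [cats[i], cats[j]])
            sub = SensorEpochs(
                alignment=data.alignment,
                times_ms=data.times_ms,
                sampling_rate_hz=data.sampling_rate_hz,
                values=data.values[sel],
                trial_ids=data.trial_ids[sel],
            )
            res = decode_meg_timecourse(
                sub, (labels[sel] == cats[j]).astype(int), k=k, seed=seed, balance=True
            )
            acc[:, i, j] = acc[:, j, i] = res.accuracy
    return acc
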