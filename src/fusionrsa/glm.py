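"""Minimal first-level GLM: epoch regressors convolved with a canonical HRF.

Trials are modelled as boxcar epochs lasting from stimulus onset until the
response (duration = RT), convolved with the canonical double-gamma
haemodynamic response (peak 6 s, undershoot 16 s, undershoot ratio 1/6).
One regressor per (condition, block) plus a constant per block, so a
12-block session yields 12 beta patterns per condition.  Error and omitted
trials are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .containers import BetaPatterns
from .paradigm import usable_trials
from .schemes import assign_conditions, scheme_conditions

HRF_PEAK_S = 6.0
HRF_UNDERSHOOT_S = 16.0
HRF_RATIO = 6.0


def double_gamma_hrf(t_s: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF sampled at times ``t_s`` (seconds)."""
    t_s = np.asarray(t_s, dtype=float)
    h = gamma_dist.pdf(t_s, HRF_PEAK_S) - gamma_dist.pdf(t_s, HRF_UNDERSHOOT_S) / HRF_RATIO
    h[t_s < 0] = 0.0
    return h


@dataclass
class DesignMatrix:
    matrix: np.ndarray                     # (n_scans, n_columns)
    columns: list[tuple[str, str, int]]    # (kind, condition, block)
    frame_times_s: np.ndarray
    condition_labels: tuple[str, ...]
    block_ids: tuple[int, ...]
    empty_cells: list[tuple[str, int]]     # (condition, block) with no trials

    @property
    def task_column_index(self) -> dict[tuple[str, int], int]:
        return {
            (cond, blk): i
            for i, (kind, cond, blk) in enumerate(self.columns)
            if kind == "task"
        }


def build_design_matrix(
    trials: pd.DataFrame,
    regressor_scheme: str,
    tr_s: float = 2.0,
    trial_spacing_s: float = 6.0,
    hrf_oversample: int = 20,
) -> DesignMatrix:
    """Condition x block epoch regressors for one scheme.

    Trials are laid out at ``trial_spacing_s`` intervals within each block
    (timing is a generator convention; only relative overlap matters).
    Each usable trial contributes a boxcar of duration RT to its
    (condition, block) regressor; the boxcars are convolved with the
    canonical double-gamma HRF and sampled at the scan times.  Condition
    cells with no usable trial in a block produce an all-zero column and
    are flagged in ``empty_cells``.
    """
    if (trials["rt_ms"] <= 0).any():
        raise ValueError("zero- or negative-duration trial epochs")
    conds = scheme_conditions(regressor_scheme)
    blocks = tuple(int(b) for b in sorted(trials["block"].unique()))
    usable = usable_trials(trials).copy()
    usable["condition"] = assign_conditions(usable, regressor_scheme)

    n_per_block = trials.groupby("block").size().max()
    block_dur_s = n_per_block * trial_spacing_s + 24.0
    n_scans_per_block = int(np.ceil(block_dur_s / tr_s))
    n_scans = n_scans_per_block * len(blocks)
    frame_times = np.arange(n_scans) * tr_s

    dt = tr_s / hrf_oversample
    hi_len = int(np.ceil(block_dur_s / dt)) + 1
    hrf = double_gamma_hrf(np.arange(0, 32.0, dt))

    columns: list[tuple[str, str, int]] = []
    mats = []
    empty_cells: list[tuple[str, int]] = []
    for cond in conds:
        for bi, blk in enumerate(blocks):
            sel = usable[(usable["block"] == blk) & (usable["condition"] == cond)]
            hi = np.zeros(hi_len)
            # trial order within block defines onset slots
            block_trials = trials[trials["block"] == blk]
            slot = {tid: k for k, tid in enumerate(block_trials["trial_id"])}
            for _, tr in sel.iterrows():
                onset = slot[tr["trial_id"]] * trial_spacing_s
                i0 = int(round(onset / dt))
                i1 = int(round((onset + tr["rt_ms"] / 1000.0) / dt))
                hi[i0 : max(i1, i0 + 1)] = 1.0
            if not len(sel):
                empty_cells.append((cond, blk))
            conv = np.convolve(hi, hrf)[:hi_len] * dt
            col = np.zeros(n_scans)
            scan_idx = (np.arange(n_scans_per_block) * tr_s / dt).round().astype(int)
            col[bi * n_scans_per_block : (bi + 1) * n_scans_per_block] = conv[scan_idx]
            columns.append(("task", cond, blk))
            mats.append(col)
    for bi, blk in enumerate(blocks):
        col = np.zeros(n_scans)
        col[bi * n_scans_per_block : (bi + 1) * n_scans_per_block] = 1.0
        columns.append(("constant", "", blk))
        mats.append(col)

    return DesignMatrix(
        matrix=np.column_stack(mats),
        columns=columns,
        frame_times_s=frame_times,
        condition_labels=conds,
        block_ids=blocks,
        empty_cells=empty_cells,
    )


def fit_glm(bold: np.ndarray, design: DesignMatrix, roi: str = "roi") -> BetaPatterns:
    """Ordinary least squares fit; betas reshaped to (condition, block, voxel).

    A rank-deficient design triggers a warning and falls back to the
    minimum-norm (pseudo-inverse) solution.
    """
    bold = np.asarray(bold, dtype=float)
    X = design.matrix
    if bold.shape[0] != X.shape[0]:
        raise ValueError(
            f"bold has {bold.shape[0]} scans but design has {X.shape[0]}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"design matrix is rank-deficient (rank {rank} < {X.shape[1]} "
            "columns); using the minimum-norm solution",
            RuntimeWarning,
            stacklevel=2,
        )
    beta = np.linalg.pinv(X) @ bold  # (n_columns, n_voxels)

    idx = design.task_column_index
    n_vox = bold.shape[1]
    values = np.zeros((len(design.condition_labels), len(design.block_ids), n_vox))
    for ci, cond in enumerate(design.condition_labels):
        for bi, blk in enumerate(design.block_ids):
            values[ci, bi] = beta[idx[(cond, blk)]]
    return BetaPatterns(
        roi=roi,
        condition_labels=design.condition_labels,
        block_ids=design.block_ids,
        values=values,
    )


def simulate_bold(
    design: DesignMatrix,
    true_betas: np.ndarray,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """BOLD series X @ beta + Gaussian noise, for exercising the GLM path."""
    true_betas = np.asarray(true_betas, dtype=float)
    if true_betas.shape[0] != design.matrix.shape[1]:
        raise ValueError("true_betas rows must match design columns")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=(design.matrix.shape[0], true_betas.shape[1]))
    return design.matrix @ true_betas + noise
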