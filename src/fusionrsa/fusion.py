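"""Model-based MEG-fMRI fusion via the three-way commonality index.

For each ROI (fMRI RDV), time point (MEG RDV) and hypothesis model (model
RDV), the commonality index is

    C(RoI, t, m) = rho(fMRI, MEG) - rho(fMRI, MEG | Model)

where rho is Spearman's correlation and the second term is the standard
partial correlation computed on the pairwise Spearman coefficients.  The
index is positive when the model explains rank variance shared by the two
neural RDVs — the three-way intersection.  Significance is assessed by a
one-tailed permutation test that shuffles the fMRI condition labels within
blocks, rebuilds the fMRI RDM and recomputes the full time course, with
Storey FDR across time points within each trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .containers import BetaPatterns
from .decoding import pairwise_condition_decoding
from .rdm import TRIL_COLS, TRIL_ROWS, build_neural_rdm, rdm_to_rdv

_EPS = 1e-10


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson on average ranks.

    Returns NaN when either vector is constant (undefined rather than 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("spearman needs two equal-length vectors of length >= 3")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((rx - rx.mean()) @ (ry - ry.mean())) / (x.size * sx * sy))


def partial_spearman(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Spearman correlation of x and y with z partialled out.

    (rho_xy - rho_xz rho_yz) / sqrt((1 - rho_xz^2)(1 - rho_yz^2)), on the
    pairwise Spearman coefficients.  NaN (never +-inf) when |rho_xz| or
    |rho_yz| reaches 1 within 1e-10, or any pairwise rho is undefined.
    """
    rho_xy = spearman(x, y)
    rho_xz = spearman(x, z)
    rho_yz = spearman(y, z)
    if np.isnan(rho_xy) or np.isnan(rho_xz) or np.isnan(rho_yz):
        return float("nan")
    if abs(rho_xz) >= 1 - _EPS or abs(rho_yz) >= 1 - _EPS:
        return float("nan")
    return float(
        (rho_xy - rho_xz * rho_yz)
        / (np.sqrt(1 - rho_xz**2) * np.sqrt(1 - rho_yz**2))
    )


def commonality_index(
    fmri_rdv: np.ndarray, meg_rdv: np.ndarray, model_rdv: np.ndarray
) -> float:
    """rho(fMRI, MEG) minus the model-partialled correlation; NaN if degenerate."""
    raw = spearman(fmri_rdv, meg_rdv)
    part = partial_spearman(fmri_rdv, meg_rdv, model_rdv)
    if np.isnan(raw) or np.isnan(part):
        return float("nan")
    return raw - part


@dataclass
class CommonalityTrace:
    """Per-(ROI, model) commonality time series with inference annotations."""

    roi: str
    info_type: str
    alignment: str
    times_ms: np.ndarray
    commonality: np.ndarray
    rho_fmri_meg: np.ndarray
    rho_meg_model: np.ndarray
    rho_fmri_model: float
    p_values: np.ndarray | None = None
    q_values: np.ndarray | None = None
    sig_mask: np.ndarray | None = None
    null_traces: np.ndarray | None = field(default=None, repr=False)


def _rank_normalise(v: np.ndarray) -> tuple[np.ndarray, bool]:
    """Centred, unit-norm average ranks; flag False when constant."""
    r = rankdata(v)
    r = r - r.mean()
    n = np.linalg.norm(r)
    if n == 0:
        return r, False
    return r / n, True


def _commonality_against_stack(
    fmri_rdv: np.ndarray,
    meg_ranks: np.ndarray,
    meg_ok: np.ndarray,
    model_ranks: np.ndarray,
    model_ok: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised commonality of one fMRI RDV against a pre-ranked MEG stack.

    ``meg_ranks`` rows are centred unit-norm ranks; dot products are then
    Spearman correlations.  Returns (commonality, rho_fmri_meg,
    rho_meg_model) with NaN where any component is undefined or a
    partialling denominator degenerates.
    """
    rf, f_ok = _rank_normalise(np.asarray(fmri_rdv, dtype=float))
    rho_xy = meg_ranks @ rf
    rho_yz = meg_ranks @ model_ranks
    rho_xz = float(rf @ model_ranks)
    n = meg_ranks.shape[0]
    com = np.full(n, np.nan)
    if f_ok and model_ok and abs(rho_xz) < 1 - _EPS:
        ok = meg_ok & (np.abs(rho_yz) < 1 - _EPS)
        part = np.full(n, np.nan)
        part[ok] = (rho_xy[ok] - rho_xz * rho_yz[ok]) / (
            np.sqrt(max(1 - rho_xz**2, 0.0)) * np.sqrt(np.maximum(1 - rho_yz[ok] ** 2, 0.0))
        )
        com[ok] = rho_xy[ok] - part[ok]
    rho_xy = np.where(meg_ok & f_ok, rho_xy, np.nan)
    rho_yz = np.where(meg_ok & model_ok, rho_yz, np.nan)
    return com, rho_xy, rho_yz


def _rank_stack(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ranks = np.empty_like(stack, dtype=float)
    ok = np.empty(stack.shape[0], dtype=bool)
    for t in range(stack.shape[0]):
        ranks[t], ok[t] = _rank_normalise(stack[t])
    return ranks, ok


def commonality_timecourse(
    fmri_rdv: np.ndarray,
    meg_rdv_stack: np.ndarray,
    model_rdv: np.ndarray,
    times_ms: np.ndarray,
    roi: str = "roi",
    info_type: str = "",
    alignment: str = "stimulus",
) -> CommonalityTrace:
    """Commonality at every time point, with component correlations kept."""
    meg_rdv_stack = np.asarray(meg_rdv_stack, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    if meg_rdv_stack.shape[0] != times_ms.size:
        raise ValueError("meg_rdv_stack time dimension must match times_ms")
    meg_ranks, meg_ok = _rank_stack(meg_rdv_stack)
    model_ranks, model_ok = _rank_normalise(np.asarray(model_rdv, dtype=float))
    com, raw, rho_mm = _commonality_against_stack(
        fmri_rdv, meg_ranks, meg_ok, model_ranks, model_ok
    )
    return CommonalityTrace(
        roi=roi,
        info_type=info_type,
        alignment=alignment,
        times_ms=times_ms,
        commonality=com,
        rho_fmri_meg=raw,
        rho_meg_model=rho_mm,
        rho_fmri_model=spearman(fmri_rdv, model_rdv),
    )


def storey_fdr(p_values: np.ndarray, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values with the fixed-lambda pi0 estimator.

    pi0 = min(1, #{p > lambda} / ((1 - lambda) m));
    q(i) = min_{j >= i} pi0 * m * p_(j) / j on sorted p-values.  Fewer than
    10 p-values fall back to Benjamini-Hochberg (pi0 = 1) with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be a vector")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return np.full_like(p, np.nan)
    if m < 10:
        warnings.warn(
            f"only {m} p-values: pi0 estimation is unstable, falling back to "
            "Benjamini-Hochberg",
            RuntimeWarning,
            stacklevel=2,
        )
        pi0 = 1.0
    else:
        pi0 = min(1.0, np.sum(pv > lambda_) / ((1.0 - lambda_) * m))
        pi0 = max(pi0, 1.0 / m)  # guard against pi0 = 0 wiping out all q-values
    order = np.argsort(pv, kind="stable")
    q_sorted = pi0 * m * pv[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.full_like(p, np.nan)
    q[mask] = np.clip(q_sorted[np.argsort(order)], 0.0, 1.0)
    return q


def permutation_test_commonality(
    betas: BetaPatterns,
    meg_rdv_stack: np.ndarray,
    model_rdv: np.ndarray,
    times_ms: np.ndarray,
    info_type: str = "",
    alignment: str = "stimulus",
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    lambda_: float = 0.5,
    keep_null: bool = False,
) -> CommonalityTrace:
    """Observed commonality trace plus permutation / Storey-FDR inference.

    Each permutation shuffles the fMRI condition labels within blocks,
    re-runs the pairwise leave-one-block-out decoding, rebuilds the fMRI
    RDV, and recomputes the whole commonality time course against the fixed
    MEG RDV stack and model.  One-tailed add-one p-values per time point;
    q-values by Storey FDR across the trace; significant = q < alpha and
    commonality > 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    acc = pairwise_condition_decoding(betas)
    fmri_rdv = rdm_to_rdv(build_neural_rdm(acc, info_type or "across").matrix)
    trace = commonality_timecourse(
        fmri_rdv, meg_rdv_stack, model_rdv, times_ms,
        roi=betas.roi, info_type=info_type, alignment=alignment,
    )
    n_times = trace.times_ms.size
    meg_ranks, meg_ok = _rank_stack(np.asarray(meg_rdv_stack, dtype=float))
    model_ranks, model_ok = _rank_normalise(np.asarray(model_rdv, dtype=float))
    null = np.empty((n_perm, n_times))
    from .decoding import _pairwise_lobo_accuracy

    vals = betas.values
    for p in range(n_perm):
        perm_vals = np.empty_like(vals)
        for bi in range(vals.shape[1]):
            perm_vals[:, bi] = vals[rng.permutation(vals.shape[0]), bi]
        perm_acc = _pairwise_lobo_accuracy(perm_vals)
        perm_rdv = (1.0 - perm_acc)[TRIL_ROWS, TRIL_COLS]
        null[p], _, _ = _commonality_against_stack(
            perm_rdv, meg_ranks, meg_ok, model_ranks, model_ok
        )
    obs = trace.commonality
    p_values = np.full(n_times, np.nan)
    for t in range(n_times):
        if np.isnan(obs[t]):
            continue
        nt = null[:, t]
        nt = nt[~np.isnan(nt)]
        p_values[t] = (1 + np.sum(nt >= obs[t])) / (1 + nt.size)
    if np.all(np.isnan(p_values)):
        warnings.warn("commonality trace is entirely undefined; empty significance mask",
                      RuntimeWarning, stacklevel=2)
        q_values = np.full(n_times, np.nan)
    else:
        q_values = storey_fdr(p_values, lambda_=lambda_)
    sig = (q_values < alpha) & (obs > 0)
    sig = np.where(np.isnan(q_values), False, sig).astype(bool)
    trace.p_values = p_values
    trace.q_values = q_values
    trace.sig_mask = sig
    if keep_null:
        trace.null_traces = null
    return trace


@dataclass
class TemporalMetrics:
    """The three trace summaries; NaN marks 'no data point'."""

    time_to_first_sig_ms: float
    time_to_max_ms: float
    time_from_max_to_response_ms: float
    reliable: bool  # False when the trace never reaches significance


def temporal_metrics(trace: CommonalityTrace, response_ref_ms: float | None = None) -> TemporalMetrics:
    """Time to first significant commonality, to the maximum, and from the
    maximum to the response.

    First-sig is the earliest time >= 0 (stimulus-aligned) or anywhere in
    the span (response-aligned) with a significant positive commonality;
    NaN when the trace never reaches significance.  Time-from-max is
    ``response_ref - t_max`` (response-aligned reference defaults to 0),
    positive when the maximum precedes the response.
    """
    if trace.sig_mask is None:
        raise ValueError("run the permutation test before extracting temporal metrics")
    t = trace.times_ms
    com = trace.commonality
    if response_ref_ms is None:
        response_ref_ms = 0.0 if trace.alignment == "response" else float(t[-1])
    eligible = trace.sig_mask & (t >= 0 if trace.alignment == "stimulus" else True)
    first_sig = float(t[eligible][0]) if np.any(eligible) else float("nan")
    if np.all(np.isnan(com)):
        t_max = float("nan")
        from_max = float("nan")
    else:
        t_max = float(t[np.nanargmax(com)])
        from_max = response_ref_ms - t_max
    return TemporalMetrics(
        time_to_first_sig_ms=first_sig,
        time_to_max_ms=t_max,
        time_from_max_to_response_ms=from_max,
        reliable=bool(np.any(trace.sig_mask)),
    )
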