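"""Planted-effect generators for fMRI beta patterns and MEG sensor epochs.

Both generators share one effect model: every information type carries a
fixed random latent pattern (over voxels or sensors), and the two levels of
the information type sit at +-effect_size/2 times that pattern, in units of
the noise SD.  Latent patterns are orthogonalised across information types
so planted contrasts are unambiguous.  Everything is reproducible from the
seed; omitting an effect spec leaves zero signal for that contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import BetaPatterns, EffectSpec, SensorEpochs
from .schemes import condition_contrast, trial_feature_sign

STIMULUS_SPAN_MS = (-200.0, 2500.0)
RESPONSE_SPAN_MS = (-2500.0, 500.0)
DEFAULT_SAMPLING_RATE_HZ = 200.0
DEFAULT_N_SENSORS = 160
ENVELOPE_RAMP_MS = 20.0


def _orthogonalise(patterns: np.ndarray) -> np.ndarray:
    """Gram-Schmidt across rows, preserving each row's original norm.

    Latent patterns stay i.i.d.-standard-normal scaled (unit variance per
    feature), so ``effect_size`` is a per-feature amplitude in noise-SD
    units and multivariate separability grows with the square root of the
    feature count — the usual MVPA simulation convention.
    """
    out = patterns.astype(float).copy()
    for i in range(out.shape[0]):
        norm0 = np.linalg.norm(out[i])
        for j in range(i):
            denom = out[j] @ out[j]
            if denom > 0:
                out[i] -= (out[i] @ out[j]) / denom * out[j]
        norm1 = np.linalg.norm(out[i])
        if norm1 > 0:
            out[i] *= norm0 / norm1
    return out


def simulate_fmri_betas(
    trials: pd.DataFrame,
    roi_specs: list[dict],
    effect_specs: list[EffectSpec],
    scheme: str,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> dict[str, BetaPatterns]:
    """Block-wise condition beta patterns per ROI under one regressor scheme.

    For each ROI, conditions carrying an effect (per ``effect_specs`` whose
    ``target`` is the ROI id or ``None`` for all ROIs) get mean
    ``contrast * effect_size/2 * noise_sd * latent_pattern``; betas are that
    mean plus i.i.d. Gaussian noise per (condition, block, voxel).  The
    generator operates at condition level, so error trials contribute
    nothing beyond the block list.
    """
    blocks = tuple(int(b) for b in sorted(trials["block"].unique()))
    from .schemes import scheme_conditions

    conds = scheme_conditions(scheme)
    out: dict[str, BetaPatterns] = {}
    for ri, rs in enumerate(roi_specs):
        roi, n_vox = rs["roi"], int(rs["n_voxels"])
        rng = np.random.default_rng([seed, ri])
        specs = [
            s for s in effect_specs if s.target is None or s.target == roi
        ]
        raw = np.stack(
            [
                (
                    np.random.default_rng([s.seed, ri]) if s.seed is not None else rng
                ).normal(size=n_vox)
                for s in specs
            ]
        ) if specs else np.zeros((0, n_vox))
        patterns = _orthogonalise(raw)
        mean = np.zeros((len(conds), n_vox))
        for s, pat in zip(specs, patterns):
            contrast = condition_contrast(s.info_type, scheme)
            mean += np.outer(contrast, pat) * (s.effect_size / 2.0) * s.noise_sd
        noise = rng.normal(0.0, noise_sd, size=(len(conds), len(blocks), n_vox))
        out[roi] = BetaPatterns(
            roi=roi,
            condition_labels=conds,
            block_ids=blocks,
            values=mean[:, None, :] + noise,
        )
    return out


def _effect_envelope(t_ms: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """1 inside the window, 0 outside, raised-cosine ramps at the edges."""
    t0, t1 = window
    ramp = min(ENVELOPE_RAMP_MS, (t1 - t0) / 2.0)
    env = np.zeros_like(t_ms)
    inside = (t_ms >= t0) & (t_ms <= t1)
    env[inside] = 1.0
    if ramp > 0:
        up = inside & (t_ms < t0 + ramp)
        env[up] = 0.5 * (1.0 - np.cos(np.pi * (t_ms[up] - t0) / ramp))
        down = inside & (t_ms > t1 - ramp)
        env[down] = 0.5 * (1.0 - np.cos(np.pi * (t1 - t_ms[down]) / ramp))
    return env


def _grid(span_ms: tuple[float, float], fs_hz: float) -> np.ndarray:
    step = 1000.0 / fs_hz
    n = int(round((span_ms[1] - span_ms[0]) / step))
    return span_ms[0] + np.arange(n + 1) * step


def simulate_meg_epochs(
    trials: pd.DataFrame,
    n_sensors: int = DEFAULT_N_SENSORS,
    effect_specs: list[EffectSpec] | None = None,
    alignment: str = "stimulus",
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    span_ms: tuple[float, float] | None = None,
    seed: int = 0,
) -> SensorEpochs:
    """Sensor epochs with window-limited planted condition signals.

    Each effect spec's ``target`` is a (start, end) window in
    stimulus-aligned milliseconds (``None`` = the whole stimulus span);
    inside it, the effect's fixed sensor topography is added with sign
    +-1 per trial (by the trial's feature level), scaled by
    ``effect_size/2 * noise_sd`` and a raised-cosine on/off envelope.
    Response-aligned epochs shift each trial by its RT quantised to the
    sampling grid, so a response-aligned sample at -RT equals the
    stimulus-aligned sample at 0 exactly.  Noise is drawn per trial on a
    master stimulus-time grid, so the two alignments of the same dataset
    (same seed) are mutually consistent.  Omitted trials are dropped from
    response-aligned epochs.
    """
    effect_specs = effect_specs or []
    if span_ms is None:
        span_ms = STIMULUS_SPAN_MS if alignment == "stimulus" else RESPONSE_SPAN_MS
    stim_span = STIMULUS_SPAN_MS if alignment != "stimulus" else span_ms
    for s in effect_specs:
        if s.target is not None:
            t0, t1 = s.target
            if t0 >= t1:
                raise ValueError(f"effect window {s.target} is empty")
            if t0 < stim_span[0] or t1 > stim_span[1]:
                raise ValueError(
                    f"effect window {s.target} lies outside the epoch span "
                    f"{stim_span}"
                )

    step = 1000.0 / sampling_rate_hz
    use = trials if alignment == "stimulus" else trials[~trials["omitted"]]
    rt_q = (np.round(use["rt_ms"].to_numpy() / step) * step) if alignment == "response" else None

    # master grid in stimulus time covering both alignment frames; its extent
    # must not depend on which alignment is requested, so that the two
    # alignments of one dataset (same trials + seed) share their noise
    all_rt_q = np.round(trials["rt_ms"].to_numpy() / step) * step
    req_lo = span_ms[0] if alignment == "stimulus" else float(all_rt_q.min()) + span_ms[0]
    req_hi = span_ms[1] if alignment == "stimulus" else float(all_rt_q.max()) + span_ms[1]
    lo = min(STIMULUS_SPAN_MS[0], float(all_rt_q.min()) + RESPONSE_SPAN_MS[0], req_lo)
    hi = max(STIMULUS_SPAN_MS[1], float(all_rt_q.max()) + RESPONSE_SPAN_MS[1], req_hi)
    master = _grid((np.floor(lo / step) * step, np.ceil(hi / step) * step), sampling_rate_hz)

    topo_rng = np.random.default_rng([seed, 7])
    raw = np.stack(
        [
            (
                np.random.default_rng([s.seed, 7]) if s.seed is not None else topo_rng
            ).normal(size=n_sensors)
            for s in effect_specs
        ]
    ) if effect_specs else np.zeros((0, n_sensors))
    topos = _orthogonalise(raw)

    signs = []
    for s in effect_specs:
        sign = np.asarray(trial_feature_sign(use, s.info_type), dtype=float)
        if s.info_type == "response":
            sign = np.where(use["omitted"].to_numpy(), 0.0, sign)
        signs.append(sign)

    # per-effect signal envelope on the master grid (stimulus time)
    envs = []
    for s in effect_specs:
        window = s.target if s.target is not None else stim_span
        envs.append(_effect_envelope(master, window) * (s.effect_size / 2.0) * s.noise_sd)

    times = _grid(span_ms, sampling_rate_hz)
    values = np.empty((len(use), n_sensors, times.size))
    trial_ids = use["trial_id"].to_numpy()
    noise_sd_trial = effect_specs[0].noise_sd if effect_specs else 1.0
    for k, tid in enumerate(trial_ids):
        rng = np.random.default_rng([seed, int(tid)])
        row = rng.normal(0.0, noise_sd_trial, size=(n_sensors, master.size))
        for topo, sign, env in zip(topos, signs, envs):
            row += np.outer(topo, env) * sign[k]
        shift = 0.0 if alignment == "stimulus" else rt_q[k]
        idx = np.round((times + shift - master[0]) / step).astype(int)
        values[k] = row[:, idx]
    return SensorEpochs(
        alignment=alignment,
        times_ms=times,
        sampling_rate_hz=sampling_rate_hz,
        values=values,
        trial_ids=trial_ids,
    )
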