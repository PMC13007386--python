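"""Array containers shared across the pipeline, with portable NPZ+JSON IO."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class BetaPatterns:
    """Condition-wise GLM pattern estimates for one ROI.

    ``values`` is (condition, block, voxel): one multivoxel pattern per
    condition per block, i.e. 12 patterns per condition for the standard
    12-block session.
    """

    roi: str
    condition_labels: tuple[str, ...]
    block_ids: tuple[int, ...]
    values: np.ndarray
    hemisphere: str = "bilateral"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (condition, block, voxel)")
        if self.values.shape[0] != len(self.condition_labels):
            raise ValueError("condition axis does not match condition_labels")
        if self.values.shape[1] != len(self.block_ids):
            raise ValueError("block axis does not match block_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("beta values must be finite")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[2]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), values=self.values)
        meta = {
            "kind": "BetaPatterns",
            "roi": self.roi,
            "hemisphere": self.hemisphere,
            "condition_labels": list(self.condition_labels),
            "block_ids": [int(b) for b in self.block_ids],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "BetaPatterns":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        values = np.load(path.with_suffix(".npz"))["values"]
        return cls(
            roi=meta["roi"],
            condition_labels=tuple(meta["condition_labels"]),
            block_ids=tuple(meta["block_ids"]),
            values=values,
            hemisphere=meta.get("hemisphere", "bilateral"),
        )


@dataclass
class SensorEpochs:
    """Epoched multichannel time series, (trial, sensor, time).

    ``alignment`` is ``"stimulus"`` (t=0 at stimulus onset) or ``"response"``
    (t=0 at the button press).  ``times_ms`` is a strictly increasing grid
    with constant step 1000/sampling_rate_hz.
    """

    alignment: str
    times_ms: np.ndarray
    sampling_rate_hz: float
    values: np.ndarray
    trial_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.alignment not in ("stimulus", "response"):
            raise ValueError("alignment must be 'stimulus' or 'response'")
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (trial, sensor, time)")
        if self.values.shape[2] != self.times_ms.size:
            raise ValueError("time axis does not match times_ms")
        step = np.diff(self.times_ms)
        if self.times_ms.size > 1:
            if np.any(step <= 0):
                raise ValueError("times_ms must be strictly increasing")
            if not np.allclose(step, 1000.0 / self.sampling_rate_hz, atol=1e-6):
                raise ValueError("times_ms step must equal 1000/sampling_rate_hz")
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.values.shape[0])
        else:
            self.trial_ids = np.asarray(self.trial_ids)
            if self.trial_ids.size != self.values.shape[0]:
                raise ValueError("trial_ids does not match trial axis")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.values.shape[1]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            values=self.values,
            times_ms=self.times_ms,
            trial_ids=self.trial_ids,
        )
        meta = {
            "kind": "SensorEpochs",
            "alignment": self.alignment,
            "sampling_rate_hz": self.sampling_rate_hz,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SensorEpochs":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        arrs = np.load(path.with_suffix(".npz"))
        return cls(
            alignment=meta["alignment"],
            times_ms=arrs["times_ms"],
            sampling_rate_hz=meta["sampling_rate_hz"],
            values=arrs["values"],
            trial_ids=arrs["trial_ids"],
        )


@dataclass(frozen=True)
class EffectSpec:
    """A planted multivariate condition effect.

    ``effect_size`` is the per-feature pattern amplitude in units of the
    noise SD (the two feature levels sit at +-effect_size/2 along a fixed
    random latent pattern).  ``target`` names the ROI carrying the effect
    (fMRI) or the (start, end) ms window inside which the effect is on
    (MEG); ``None`` means everywhere / the whole epoch.
    """

    info_type: str
    effect_size: float
    target: object = None
    noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
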