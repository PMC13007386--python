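"""Trial-level structure of the cued stimulus-response mapping task.

The paradigm: on each trial a visual stimulus appears in one of four
positions (two per hemifield, at an inner and an outer eccentricity), and
the fixation square's colour cues one of two stimulus-response mapping
rules.  Four cue colours map two-to-one onto the two rules.  The
participant presses one of four buttons according to the cued rule.
Blocks are balanced: every (cue colour x stimulus position) configuration
occurs equally often within a block.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STIMULI = ("left-outer", "left-inner", "right-inner", "right-outer")
CUE_COLOURS = ("c1", "c2", "c3", "c4")
RULES = (1, 2)

#: cue colour -> rule; two colours per rule
DEFAULT_COLOUR_RULE_MAP = {"c1": 1, "c2": 1, "c3": 2, "c4": 2}

#: rule -> {stimulus_position -> button}; rule 1 is the identity layout
#: (left-outer..right-outer = 1..4), rule 2 the reverse permutation.  The
#: true assignments are a per-participant counterbalancing detail, so they
#: are configurable everywhere.
DEFAULT_RULE_DEFINITIONS = {
    1: {"left-outer": 1, "left-inner": 2, "right-inner": 3, "right-outer": 4},
    2: {"left-outer": 4, "left-inner": 3, "right-inner": 2, "right-outer": 1},
}

#: buttons pressed by the two inner fingers
INNER_BUTTONS = frozenset({2, 3})

TRIAL_TABLE_COLUMNS = [
    "trial_id",
    "block",
    "stimulus_position",
    "hemifield",
    "eccentricity",
    "cue_colour",
    "rule",
    "response_button",
    "response_group",
    "rt_ms",
    "correct",
    "omitted",
]


def hemifield_of(stimulus_position: str) -> str:
    return stimulus_position.split("-")[0]


def eccentricity_of(stimulus_position: str) -> str:
    return stimulus_position.split("-")[1]


def response_group_of(button: int) -> str:
    return "inner" if button in INNER_BUTTONS else "outer"


def map_stimulus_to_response(
    stimulus_position: str,
    rule: int,
    rule_definitions: dict | None = None,
) -> int:
    """Button prescribed for ``stimulus_position`` under ``rule``.

    ``rule_definitions`` maps each rule id to a bijection
    stimulus position -> button (1..4).
    """
    defs = DEFAULT_RULE_DEFINITIONS if rule_definitions is None else rule_definitions
    if rule not in defs:
        raise ValueError(f"unknown rule id: {rule!r}")
    mapping = defs[rule]
    if sorted(mapping.values()) != [1, 2, 3, 4]:
        raise ValueError(f"rule {rule!r} is not a bijection onto buttons 1..4")
    if stimulus_position not in mapping:
        raise ValueError(f"unknown stimulus position: {stimulus_position!r}")
    return mapping[stimulus_position]


def _validate_colour_rule_map(colour_rule_map: dict) -> None:
    for colour in CUE_COLOURS:
        if colour_rule_map.get(colour) not in RULES:
            raise ValueError(
                f"cue colour {colour!r} is not mapped to a valid rule in "
                f"colour_rule_map {colour_rule_map!r}"
            )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # moment-match a log-normal to the requested arithmetic mean/sd
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_trial_sequence(
    n_blocks: int = 12,
    n_trials_per_block: int = 80,
    colour_rule_map: dict | None = None,
    behaviour_params: dict | None = None,
    rule_definitions: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a balanced, pseudorandom trial table.

    Each block contains every (cue colour x stimulus position) configuration
    exactly ``n_trials_per_block / 16`` times, in shuffled order.  Behaviour
    is drawn per trial: correctness (Bernoulli at ``accuracy_rate``),
    omission (``omission_rate``), and RT from a log-normal moment-matched to
    ``rt_mean_ms`` / ``rt_sd_ms``.  Errors press a uniformly random
    non-target button.  Fully reproducible from ``seed``.
    """
    if n_trials_per_block % 16 != 0:
        raise ValueError(
            f"n_trials_per_block must be divisible by 16 (4 cue colours x 4 "
            f"stimuli); got {n_trials_per_block}"
        )
    crm = DEFAULT_COLOUR_RULE_MAP if colour_rule_map is None else colour_rule_map
    _validate_colour_rule_map(crm)
    params = {
        "accuracy_rate": 0.8078,
        "rt_mean_ms": 1692.0,
        "rt_sd_ms": 284.0,
        "omission_rate": 0.026,
    }
    if behaviour_params:
        params.update(behaviour_params)
    for key in ("accuracy_rate", "omission_rate"):
        if not 0.0 <= params[key] <= 1.0:
            raise ValueError(f"{key} must lie in [0, 1]; got {params[key]}")
    if params["rt_mean_ms"] <= 0 or params["rt_sd_ms"] <= 0:
        raise ValueError("rt parameters must be positive")

    rng = np.random.default_rng(seed)
    reps = n_trials_per_block // 16
    configs = [(c, s) for c in CUE_COLOURS for s in STIMULI] * reps
    mu, sigma = _lognormal_params(params["rt_mean_ms"], params["rt_sd_ms"])

    rows = []
    trial_id = 0
    for block in range(1, n_blocks + 1):
        order = rng.permutation(len(configs))
        for idx in order:
            colour, stim = configs[idx]
            rule = crm[colour]
            target = map_stimulus_to_response(stim, rule, rule_definitions)
            omitted = bool(rng.random() < params["omission_rate"])
            correct = (not omitted) and bool(rng.random() < params["accuracy_rate"])
            if omitted:
                button = -1
            elif correct:
                button = target
            else:
                button = int(rng.choice([b for b in (1, 2, 3, 4) if b != target]))
            rt = float(rng.lognormal(mu, sigma))
            rows.append(
                {
                    "trial_id": trial_id,
                    "block": block,
                    "stimulus_position": stim,
                    "hemifield": hemifield_of(stim),
                    "eccentricity": eccentricity_of(stim),
                    "cue_colour": colour,
                    "rule": rule,
                    "response_button": button,
                    "response_group": response_group_of(button) if button > 0 else "none",
                    "rt_ms": rt,
                    "correct": correct,
                    "omitted": omitted,
                }
            )
            trial_id += 1
    return pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS)


def usable_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Correct, non-omitted trials — the set every analysis stage sees."""
    return trials[trials["correct"] & ~trials["omitted"]]
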