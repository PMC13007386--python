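"""The four 4-condition regressor schemes used to build RDMs.

Each information type gets its own condition scheme so that its 4x4 RDM
isolates that feature:

- ``across``  : hemifield x rule — {left-r1, left-r2, right-r1, right-r2}
- ``within``  : eccentricity x rule — {inner-r1, inner-r2, outer-r1, outer-r2}
- ``rule``    : the four cue colours — {c1, c2, c3, c4}
- ``response``: two response-group conditions plus two cue-colour conditions
  (one colour from each rule) — {inner-resp, outer-resp, colour-a, colour-b}

For trial-level analyses the response scheme must partition trials; trials
carrying one of the two selected colours go to that colour condition and the
remaining trials split by response group (a package design choice — the
original regressor formulation lets a trial load on two regressors).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INFO_TYPES = ("across", "within", "rule", "response")

#: the two cue colours singled out in the response scheme (one per rule
#: under the default colour->rule map)
RESPONSE_SCHEME_COLOURS = ("c1", "c3")

SCHEME_CONDITIONS: dict[str, tuple[str, str, str, str]] = {
    "across": ("left-r1", "left-r2", "right-r1", "right-r2"),
    "within": ("inner-r1", "inner-r2", "outer-r1", "outer-r2"),
    "rule": ("c1", "c2", "c3", "c4"),
    "response": ("inner-resp", "outer-resp", "colour-a", "colour-b"),
}


def scheme_conditions(info_type: str) -> tuple[str, str, str, str]:
    if info_type not in SCHEME_CONDITIONS:
        raise ValueError(
            f"unknown info_type {info_type!r}; expected one of {INFO_TYPES}"
        )
    return SCHEME_CONDITIONS[info_type]


def assign_conditions(
    trials: pd.DataFrame,
    info_type: str,
    response_scheme_colours: tuple[str, str] = RESPONSE_SCHEME_COLOURS,
) -> pd.Series:
    """Condition label of each trial under a scheme (categorical Series).

    Every usable trial receives exactly one of the scheme's four labels.
    """
    conds = scheme_conditions(info_type)
    if info_type == "across":
        labels = trials["hemifield"] + "-r" + trials["rule"].astype(str)
    elif info_type == "within":
        labels = trials["eccentricity"] + "-r" + trials["rule"].astype(str)
    elif info_type == "rule":
        labels = trials["cue_colour"].astype(str)
    else:  # response
        col_a, col_b = response_scheme_colours
        labels = pd.Series(
            np.where(
                trials["cue_colour"] == col_a,
                "colour-a",
                np.where(
                    trials["cue_colour"] == col_b,
                    "colour-b",
                    trials["response_group"].astype(str) + "-resp",
                ),
            ),
            index=trials.index,
        )
    return pd.Series(pd.Categorical(labels, categories=conds), index=trials.index)


def condition_contrast(info_type: str, scheme: str) -> np.ndarray:
    """Signed +-1/0 loading of each scheme condition on an information type.

    Used by the generators to plant a multivariate effect for ``info_type``
    into data whose conditions follow ``scheme``.  Conditions that do not
    vary on the feature load 0.
    """
    conds = scheme_conditions(scheme)
    out = np.zeros(4)
    for i, c in enumerate(conds):
        if info_type == "across" and scheme == "across":
            out[i] = 1.0 if c.startswith("left") else -1.0
        elif info_type == "within" and scheme == "within":
            out[i] = 1.0 if c.startswith("inner") else -1.0
        elif info_type == "rule":
            if scheme in ("across", "within"):
                out[i] = 1.0 if c.endswith("r1") else -1.0
            elif scheme == "rule":
                out[i] = 1.0 if c in ("c1", "c2") else -1.0
        elif info_type == "response" and scheme == "response":
            if c == "inner-resp":
                out[i] = 1.0
            elif c == "outer-resp":
                out[i] = -1.0
    return out


def trial_feature_sign(trials: pd.DataFrame, info_type: str) -> pd.Series:
    """Per-trial +-1 sign of the binary feature behind ``info_type``."""
    if info_type == "across":
        return np.where(trials["hemifield"] == "left", 1.0, -1.0)
    if info_type == "within":
        return np.where(trials["eccentricity"] == "inner", 1.0, -1.0)
    if info_type == "rule":
        return np.where(trials["rule"] == 1, 1.0, -1.0)
    if info_type == "response":
        return np.where(trials["response_group"] == "inner", 1.0, -1.0)
    raise ValueError(f"unknown info_type {info_type!r}")
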