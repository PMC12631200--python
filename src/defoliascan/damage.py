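"""Damage-stage coding from defoliation percentage (DP).

Stages are ordinal: mild (1) for DP <= 30, moderate (2) for
30 < DP < 50, severe (3) for DP >= 50. Mild is the "early detection"
class: at DP <= 30 growth is not yet measurably depressed, so trees
caught at this stage can still be treated before the peak feeding phase.
"""

from __future__ import annotations

import numpy as np

from defoliascan.errors import InvalidInputError

MILD = 1
MODERATE = 2
SEVERE = 3

STAGE_NAMES = {MILD: "mild", MODERATE: "moderate", SEVERE: "severe"}
STAGE_ORDER = (MILD, MODERATE, SEVERE)

# DP interval sampled per stage by the synthetic generator; open interval
# endpoints for moderate are respected by sampling strictly inside.
STAGE_DP_RANGE = {MILD: (5.0, 30.0), MODERATE: (30.0, 50.0), SEVERE: (50.0, 90.0)}


def stage_from_dp(dp):
    """Map defoliation percentage(s) to ordinal stage code(s).

    Parameters
    ----------
    dp : float or array-like
        Defoliation percentage in [0, 100].

    Returns
    -------
    int or ndarray of int
        1 (mild) iff dp <= 30, 2 (moderate) iff 30 < dp < 50,
        3 (severe) iff dp >= 50.
    """
    arr = np.asarray(dp, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100) or not np.all(np.isfinite(arr)):
        raise InvalidInputError("dp must be finite and within [0, 100]")
    stages = np.full(arr.shape, MODERATE, dtype=int)
    stages[arr <= 30.0] = MILD
    stages[arr >= 50.0] = SEVERE
    if np.isscalar(dp) or arr.ndim == 0:
        return int(stages)
    return stages
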