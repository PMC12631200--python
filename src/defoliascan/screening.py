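"""Kruskal-Wallis screening of candidate features across damage stages.

A feature is retained only if it differs across all three stages AND
between the mild and moderate stages specifically (both raw p < alpha,
default 0.01, no multiple-testing correction). The pairwise criterion is
what makes the screen an early-detection filter: a feature that only
reacts at the severe stage passes the overall test but is useless for
separating mild from moderate trees, so it is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from defoliascan.damage import MILD, MODERATE, SEVERE
from defoliascan.errors import InvalidInputError

DEFAULT_ALPHA = 0.01


def kruskal_wallis(*groups) -> tuple:
    """Tie-corrected Kruskal-Wallis H and chi-square p-value.

    Identical values across all groups give (H=0, p=1) rather than an
    error. Requires >= 2 groups, each with >= 2 values, total n >= 5.
    """
    if len(groups) < 2:
        raise InvalidInputError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise InvalidInputError("each group needs >= 2 values")
    if sum(a.size for a in arrays) < 5:
        raise InvalidInputError("total sample size must be >= 5")
    concat = np.concatenate(arrays)
    if np.all(concat == concat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


@dataclass
class ScreeningReport:
    """Per-feature overall and mild-vs-moderate p-values plus retention."""

    table: pd.DataFrame  # feature, h_overall, p_overall, p_mild_moderate, retained
    alpha: float

    @property
    def retained_features(self) -> list:
        return self.table.loc[self.table["retained"], "feature"].tolist()

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "features": self.table.to_dict(orient="records"),
            "retained": self.retained_features,
        }


def screen_features(features: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                    stage_col: str = "stage", exclude=("tree_id",)) -> ScreeningReport:
    """Dual-criterion K-W screen over every feature column.

    Retained iff the overall three-stage test AND the mild-vs-moderate
    pairwise test are both significant at ``alpha``.
    """
    stages = features[stage_col].to_numpy()
    present = set(np.unique(stages).tolist())
    if not {MILD, MODERATE, SEVERE} <= present:
        raise InvalidInputError(f"all three stages required, found {sorted(present)}")
    rows = []
    candidates = [
        c for c in features.columns if c != stage_col and c not in exclude
    ]
    if not candidates:
        raise InvalidInputError("no feature columns to screen")
    for col in candidates:
        v = features[col].to_numpy(dtype=float)
        by_stage = [v[stages == s] for s in (MILD, MODERATE, SEVERE)]
        h_all, p_all = kruskal_wallis(*by_stage)
        _, p_mm = kruskal_wallis(by_stage[0], by_stage[1])
        rows.append(
            {
                "feature": col,
                "h_overall": h_all,
                "p_overall": p_all,
                "p_mild_moderate": p_mm,
                "retained": bool(p_all < alpha and p_mm < alpha),
            }
        )
    return ScreeningReport(table=pd.DataFrame(rows), alpha=alpha)
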