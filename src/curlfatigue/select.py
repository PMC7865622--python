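"""Dual Spearman screening for fatigue-specific features.

Each of the 33 window features is rank-correlated with the fused Borg RPE
twice: once within the fatigue-only subset (reps labeled Borg 17-20) and
once on the complete dataset.  A feature is flagged significant in a screen
when its two-sided p-value falls below the significance allowance (default
0.1, no multiple-testing correction).  The selected set is the overlap —
features significant in both screens: correlated with exertion overall, yet
still informative inside the fatigue band where RPE ties are heavy
(average-rank handling matters there).

``REFERENCE_FLAGS`` packages the per-feature significance flags published
for the original 20-volunteer concentration-curl dataset; intersecting them
reproduces the 16-feature selection independently of any synthetic cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_COLUMNS, STATS

__all__ = [
    "SelectionResult",
    "spearman",
    "screen",
    "overlap",
    "select_features",
    "REFERENCE_FLAGS",
    "reference_selection",
]

DEFAULT_ALPHA = 0.1

# Published significance flags (fatigue subset, complete dataset) for the
# original study's real recordings, one (mean, sd, aad) triple per signal.
_REFERENCE_TRIPLES = {
    # signal:            fatigue subset        complete dataset
    "gyr_x":             ((0, 0, 0),           (0, 0, 0)),
    "gyr_y":             ((1, 0, 1),           (1, 1, 0)),
    "gyr_z":             ((1, 1, 1),           (1, 1, 0)),
    "mag_x":             ((0, 0, 0),           (0, 0, 0)),
    "mag_y":             ((0, 1, 0),           (0, 0, 0)),
    "mag_z":             ((0, 0, 1),           (0, 1, 1)),
    "acc_x":             ((1, 1, 1),           (0, 0, 0)),
    "acc_y":             ((1, 1, 1),           (1, 1, 1)),
    "acc_z":             ((1, 1, 1),           (1, 1, 1)),
    "total_acceleration": ((1, 1, 1),          (1, 1, 1)),
    "exerted_force":     ((1, 1, 1),           (1, 1, 1)),
}

REFERENCE_FLAGS: dict[str, dict[str, bool]] = {
    subset: {
        f"{sig}_{stat}": bool(triples[k][i])
        for sig, triples in _REFERENCE_TRIPLES.items()
        for i, stat in enumerate(STATS)
    }
    for k, subset in enumerate(("fatigue", "complete"))
}


@dataclass
class SelectionResult:
    """Per-feature screening statistics and the overlap selection.

    ``table`` is indexed by feature name with columns ``rho_fatigue``,
    ``p_fatigue``, ``sig_fatigue``, ``rho_complete``, ``p_complete``,
    ``sig_complete`` and ``selected``.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def selected_features(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def counts_by_statistic(self) -> dict[str, int]:
        """Number of selected features per window statistic."""
        out = {}
        for stat in STATS:
            out[stat] = int(sum(
                self.table.loc[f, "selected"]
                for f in self.table.index if f.endswith(f"_{stat}")
            ))
        return out


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and two-sided p.

    Constant input yields ``(nan, nan)`` rather than an error; callers treat
    that as insignificant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired (equal length)")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(x, y)
    return (float(rho), float(p))


def screen(
    matrix: pd.DataFrame,
    subset: str = "complete",
    alpha: float = DEFAULT_ALPHA,
    target: str = "fused_rpe",
    feature_columns: Sequence[str] = FEATURE_COLUMNS,
) -> pd.DataFrame:
    """Rank-correlate every feature with the RPE label within one subset.

    ``subset`` is ``"complete"`` (all reps) or ``"fatigue_only"`` (reps with
    ``is_fatigued`` true).  Returns a table indexed by feature with columns
    ``rho``, ``p`` and ``significant`` (p < alpha).
    """
    if subset == "fatigue_only":
        data = matrix[matrix["is_fatigued"].astype(bool)]
    elif subset == "complete":
        data = matrix
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if len(data) == 0:
        raise ValueError(f"subset {subset!r} is empty; cannot screen features")
    y = data[target].to_numpy(dtype=float)
    rows = []
    for feat in feature_columns:
        rho, p = spearman(data[feat].to_numpy(dtype=float), y)
        rows.append({
            "feature": feat,
            "rho": rho,
            "p": p,
            "significant": bool(np.isfinite(p) and p < alpha),
        })
    return pd.DataFrame(rows).set_index("feature")


def overlap(
    flags_fatigue: Mapping[str, bool], flags_complete: Mapping[str, bool]
) -> list[str]:
    """Features significant in both screens, in stable (input) order."""
    if set(flags_fatigue) != set(flags_complete):
        raise ValueError("screens cover different feature universes")
    return [f for f in flags_fatigue if flags_fatigue[f] and flags_complete[f]]


def select_features(
    matrix: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    target: str = "fused_rpe",
    feature_columns: Sequence[str] = FEATURE_COLUMNS,
) -> SelectionResult:
    """Run both screens on a feature matrix and intersect the flags."""
    fat = screen(matrix, "fatigue_only", alpha, target, feature_columns)
    comp = screen(matrix, "complete", alpha, target, feature_columns)
    table = pd.DataFrame({
        "rho_fatigue": fat["rho"],
        "p_fatigue": fat["p"],
        "sig_fatigue": fat["significant"],
        "rho_complete": comp["rho"],
        "p_complete": comp["p"],
        "sig_complete": comp["significant"],
    })
    table["selected"] = table["sig_fatigue"] & table["sig_complete"]
    return SelectionResult(table=table, alpha=alpha)


def reference_selection() -> SelectionResult:
    """Selection built from the published significance flags (no data).

    Correlation columns are absent (NaN); only the flags and the overlap are
    meaningful.  Intersecting the published flags yields 16 features with
    per-statistic counts mean 6, sd 5, aad 5.
    """
    feats = list(REFERENCE_FLAGS["fatigue"])
    table = pd.DataFrame({
        "rho_fatigue": np.nan,
        "p_fatigue": np.nan,
        "sig_fatigue": [REFERENCE_FLAGS["fatigue"][f] for f in feats],
        "rho_complete": np.nan,
        "p_complete": np.nan,
        "sig_complete": [REFERENCE_FLAGS["complete"][f] for f in feats],
    }, index=pd.Index(feats, name="feature"))
    table["selected"] = table["sig_fatigue"] & table["sig_complete"]
    return SelectionResult(table=table, alpha=DEFAULT_ALPHA)
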