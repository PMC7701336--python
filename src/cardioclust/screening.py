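"""Feature redundancy screening by Pearson's r and MIC.

Every feature pair is scored with the Pearson product-moment correlation and
the maximal information coefficient.  A pair is flagged as redundant when
|r| exceeds ``r_threshold`` (default 0.8) or MIC exceeds ``mic_threshold``
(default 0.5); one member of each flagged pair is dropped and the remaining
features are selected for clustering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mic import mic

__all__ = [
    "pearson_r",
    "screen_features",
    "ScreeningReport",
    "ConstantFeatureError",
    "DEFAULT_DROP_PREFERENCE",
]

#: Features preferred for dropping when they appear in a flagged pair.
#: EF_LV is definitionally derivable from two other table quantities
#: (EF_LV = 1 - V_LV_ES / V_LV_ED), so it carries no information beyond them;
#: when its redundancy is flagged, it is the member excluded.
DEFAULT_DROP_PREFERENCE = ("EF_LV",)


class ConstantFeatureError(ValueError):
    """Correlation with a constant vector is undefined; treated as an upstream bug."""


class ScreeningConfigError(ValueError):
    pass


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Raises ``ConstantFeatureError`` if either vector is constant (rather than
    silently returning 0 or NaN).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have equal length")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc))
    sy = np.sqrt(np.sum(yc * yc))
    if sx == 0.0 or sy == 0.0:
        raise ConstantFeatureError("correlation undefined for constant input")
    r = float(np.sum(xc * yc) / (sx * sy))
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class ScreeningReport:
    """Result of pairwise redundancy screening.

    ``flagged_pairs`` lists tuples (feature_a, feature_b, r, mic, trigger)
    with trigger in {"pearson", "mic", "both"}; ``selected`` preserves the
    original column order.
    """

    feature_names: List[str]
    pearson_matrix: np.ndarray
    mic_matrix: np.ndarray
    flagged_pairs: List[Tuple[str, str, float, float, str]]
    dropped: List[str]
    selected: List[str]
    r_threshold: float
    mic_threshold: float
    drop_log: List[Dict] = field(default_factory=list)

    def pair_table(self) -> pd.DataFrame:
        """One row per feature pair: |r| vs MIC (scatter-plot data)."""
        rows = []
        d = len(self.feature_names)
        for i in range(d):
            for j in range(i + 1, d):
                rows.append(
                    {
                        "feature_a": self.feature_names[i],
                        "feature_b": self.feature_names[j],
                        "pearson_r": self.pearson_matrix[i, j],
                        "abs_r": abs(self.pearson_matrix[i, j]),
                        "mic": self.mic_matrix[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "pearson_matrix": self.pearson_matrix.tolist(),
            "mic_matrix": self.mic_matrix.tolist(),
            "flagged_pairs": [list(p) for p in self.flagged_pairs],
            "dropped": self.dropped,
            "selected": self.selected,
            "r_threshold": self.r_threshold,
            "mic_threshold": self.mic_threshold,
            "drop_log": self.drop_log,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ScreeningReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_names=d["feature_names"],
            pearson_matrix=np.asarray(d["pearson_matrix"]),
            mic_matrix=np.asarray(d["mic_matrix"]),
            flagged_pairs=[tuple(p) for p in d["flagged_pairs"]],
            dropped=d["dropped"],
            selected=d["selected"],
            r_threshold=d["r_threshold"],
            mic_threshold=d["mic_threshold"],
            drop_log=d.get("drop_log", []),
        )


def _trigger(abs_r: float, mic_val: float, r_thr: float, mic_thr: float) -> Optional[str]:
    p = abs_r > r_thr
    m = mic_val > mic_thr
    if p and m:
        return "both"
    if p:
        return "pearson"
    if m:
        return "mic"
    return None


def screen_features(
    table: pd.DataFrame,
    r_threshold: float = 0.8,
    mic_threshold: float = 0.5,
    features: Optional[Sequence[str]] = None,
    drop_preference: Optional[Sequence[str]] = DEFAULT_DROP_PREFERENCE,
    mic_method: str = "auto",
) -> ScreeningReport:
    """Screen a cohort table for redundant feature pairs.

    Flagged pairs (|r| > ``r_threshold`` or MIC > ``mic_threshold``) are
    resolved greedily in descending trigger strength; within a pair, a
    member named in ``drop_preference`` (by default the definitionally
    derived EF_LV) is dropped; otherwise the member with the larger mean |r|
    against all other remaining features is dropped (ties broken by later
    column order).
    """
    if not (0.0 <= r_threshold <= 1.0):
        raise ScreeningConfigError(f"r_threshold {r_threshold} outside [0, 1]")
    if not (0.0 <= mic_threshold <= 1.0):
        raise ScreeningConfigError(f"mic_threshold {mic_threshold} outside [0, 1]")
    if features is None:
        features = [c for c in table.columns if c != "case_id"]
    features = list(features)
    if len(features) < 2:
        raise ScreeningConfigError("need at least 2 features")
    n = len(table)
    if n < 8:
        raise ScreeningConfigError("need at least 8 cases")

    d = len(features)
    X = table[features].to_numpy(float)
    r_mat = np.eye(d)
    mic_mat = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            r_mat[i, j] = r_mat[j, i] = pearson_r(X[:, i], X[:, j])
            mic_mat[i, j] = mic_mat[j, i] = mic(X[:, i], X[:, j], method=mic_method)

    flagged = []
    for i in range(d):
        for j in range(i + 1, d):
            trig = _trigger(abs(r_mat[i, j]), mic_mat[i, j], r_threshold, mic_threshold)
            if trig is not None:
                flagged.append((features[i], features[j], float(r_mat[i, j]), float(mic_mat[i, j]), trig))

    # greedy resolution: strongest trigger first, re-checked after each drop
    remaining = list(features)
    dropped: List[str] = []
    drop_log: List[Dict] = []
    pref = set(drop_preference or [])
    idx = {f: i for i, f in enumerate(features)}

    def strength(fa: str, fb: str) -> float:
        i, j = idx[fa], idx[fb]
        return max(
            abs(r_mat[i, j]) / r_threshold if r_threshold > 0 else np.inf,
            mic_mat[i, j] / mic_threshold if mic_threshold > 0 else np.inf,
        )

    while True:
        live = [
            (fa, fb)
            for fa, fb, _, _, _ in flagged
            if fa in remaining and fb in remaining
        ]
        if not live:
            break
        fa, fb = max(live, key=lambda p: (strength(*p), -idx[p[0]], -idx[p[1]]))
        others = [f for f in remaining if f not in (fa, fb)]
        if fa in pref and fb not in pref:
            victim = fa
        elif fb in pref and fa not in pref:
            victim = fb
        else:
            def mean_abs_r(f: str) -> float:
                if not others:
                    return 0.0
                i = idx[f]
                return float(np.mean([abs(r_mat[i, idx[o]]) for o in others]))

            ra, rb = mean_abs_r(fa), mean_abs_r(fb)
            if ra > rb:
                victim = fa
            elif rb > ra:
                victim = fb
            else:  # tie: drop the later column
                victim = fa if idx[fa] > idx[fb] else fb
        remaining.remove(victim)
        dropped.append(victim)
        drop_log.append(
            {
                "pair": [fa, fb],
                "dropped": victim,
                "r": r_mat[idx[fa], idx[fb]],
                "mic": mic_mat[idx[fa], idx[fb]],
            }
        )

    selected = [f for f in features if f in remaining]
    return ScreeningReport(
        feature_names=features,
        pearson_matrix=r_mat,
        mic_matrix=mic_mat,
        flagged_pairs=flagged,
        dropped=dropped,
        selected=selected,
        r_threshold=r_threshold,
        mic_threshold=mic_threshold,
        drop_log=drop_log,
    )
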