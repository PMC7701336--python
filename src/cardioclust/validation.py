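"""Confirmation battery: PCA projection, inter-cluster tests, robust regression.

Three independent checks support (or refute) the pathological-cluster
interpretation of a fitted mixture:

* a 2-component PCA projection of the standardized selected features, with
  cluster centers projected through the case-derived transform — pathological
  clusters should sit far from the bulk of the cohort;
* systematic unpaired unequal-variance (Welch) t-tests and two-sided
  Mann-Whitney rank tests over every (large-cluster pair, feature) cell —
  most cells should reject, confirming that the large clusters genuinely
  differ in feature distribution;
* comparison of the pipeline LV measures against a noisy reference channel:
  means/SDs, percent mean differences, and robust linear regression under
  Huber's criterion (gross reference outliers must not tilt the line).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import comb

__all__ = [
    "PCAProjection",
    "pca_project",
    "welch_t_test",
    "mann_whitney_u",
    "pairwise_cluster_tests",
    "TestMatrixReport",
    "huber_fit",
    "HuberFit",
    "percent_mean_difference",
    "compare_to_ground_truth",
    "GroundTruthComparison",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAProjection:
    """Scores of cases and cluster centers in the top principal components."""

    mean_: np.ndarray
    scale_: np.ndarray
    components_: np.ndarray            # (n_components, d) orthonormal loadings
    case_scores: np.ndarray            # (n, n_components)
    center_scores: np.ndarray          # (k, n_components)
    explained_variance_ratio: np.ndarray

    def scores_frame(self, case_ids=None, assignments=None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.case_scores, columns=[f"pc{i + 1}" for i in range(self.case_scores.shape[1])]
        )
        if case_ids is not None:
            df.insert(0, "case_id", np.asarray(case_ids))
        if assignments is not None:
            df["cluster"] = np.asarray(assignments)
        return df


def pca_project(X, centers, n_components: int = 2, standardize: bool = True) -> PCAProjection:
    """Project cases and cluster centers onto the top principal components.

    Loadings come from the singular value decomposition of the standardized,
    centered case matrix; centers are transformed with the case-derived
    standardizer and loadings (never refitted on the centers).  Component
    signs are fixed so the largest-magnitude loading of each component is
    positive.
    """
    X = np.asarray(X, dtype=float)
    centers = np.asarray(centers, dtype=float)
    n, d = X.shape
    if n_components > d:
        raise ValueError(f"n_components={n_components} exceeds dimensionality {d}")
    if n <= d:
        raise ValueError(f"need n > d, got n={n}, d={d}")
    if centers.ndim != 2 or centers.shape[1] != d:
        raise ValueError("centers must share the feature space of X")

    mean = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0)
        if np.any(scale == 0):
            raise ValueError("constant feature; cannot standardize")
    else:
        scale = np.ones(d)
    Z = (X - mean) / scale
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    comps = vt[:n_components]
    # deterministic sign: largest-|loading| entry positive
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    evr = (s**2) / np.sum(s**2)
    case_scores = Z @ comps.T
    center_scores = ((centers - mean) / scale) @ comps.T
    return PCAProjection(
        mean_=mean,
        scale_=scale,
        components_=comps,
        case_scores=case_scores,
        center_scores=center_scores,
        explained_variance_ratio=evr[:n_components],
    )


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------


def welch_t_test(a, b) -> Tuple[float, float]:
    """Unpaired unequal-variance t-test (Welch); two-sided p.

    Uses the Welch statistic with Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0  # identical constant samples
        return math.copysign(math.inf, diff), 0.0  # constant, different means
    t = diff / math.sqrt(se2)
    denom = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    # denom can underflow to 0 for subnormal variances; fall back to pooled df
    df = se2**2 / denom if denom > 0.0 else float(na + nb - 2)
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


class DegenerateTestError(ValueError):
    pass


_EXACT_ENUM_LIMIT = 200_000  # max C(n1+n2, n1) for exact enumeration


def mann_whitney_u(a, b, method: str = "auto") -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is reported for the first sample.

    ``method="exact"`` enumerates all assignments of the pooled midranks to
    the first sample (tie-aware); feasible while C(n1+n2, n1) stays below
    2e5, which covers both groups up to ~9v9.  ``method="asymptotic"`` uses
    the tie-corrected normal approximation with continuity correction.
    ``"auto"`` picks exact whenever feasible.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise DegenerateTestError("all values tied across both samples")
    ranks = sps.rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n_comb = comb(n1 + n2, n1, exact=True)
    if method == "auto":
        method = "exact" if n_comb <= _EXACT_ENUM_LIMIT else "asymptotic"

    if method == "exact":
        if n_comb > _EXACT_ENUM_LIMIT:
            raise ValueError(f"exact enumeration infeasible: C({n1 + n2},{n1})={n_comb}")
        idx = np.fromiter(
            (i for c in combinations(range(n1 + n2), n1) for i in c), dtype=np.int64
        ).reshape(n_comb, n1)
        u_all = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
        eps = 1e-9
        p_ge = np.mean(u_all >= u1 - eps)
        p_le = np.mean(u_all <= u1 + eps)
        p = min(1.0, 2.0 * min(p_ge, p_le))
        return float(u1), float(p)

    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        raise DegenerateTestError("zero variance after tie correction")
    # continuity-corrected two-sided p
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / math.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(u1), float(min(p, 1.0))


@dataclass
class TestMatrixReport:
    """Welch and Mann-Whitney p-values over (large-cluster pair, feature) cells."""

    cells: pd.DataFrame  # cluster_a, cluster_b, feature, welch_p, mw_p, error
    alpha: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def counts(self) -> Dict[str, Dict[str, int]]:
        out = {}
        for fam in ("welch_p", "mw_p"):
            p = self.cells[fam]
            out[fam] = {
                "below_alpha": int((p < self.alpha).sum()),
                "at_or_above_alpha": int((p >= self.alpha).sum()),
                "failed": int(p.isna().sum()),
            }
        return out

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def pairwise_cluster_tests(
    table: pd.DataFrame,
    assignments: Sequence[int],
    large_clusters: Sequence[int],
    features: Sequence[str],
    alpha: float = 0.05,
) -> TestMatrixReport:
    """Run both test families over every (pair of large clusters, feature) cell.

    Per-cell failures (degenerate samples) are recorded as flagged cells with
    NaN p-values rather than aborting the battery.
    """
    assignments = np.asarray(assignments)
    for cl in large_clusters:
        if int((assignments == cl).sum()) < 2:
            raise ValueError(f"cluster {cl} has fewer than 2 members")
    rows = []
    for ca, cb in combinations(sorted(large_clusters), 2):
        ma = assignments == ca
        mb = assignments == cb
        for feat in features:
            a = table.loc[ma, feat].to_numpy(float)
            b = table.loc[mb, feat].to_numpy(float)
            rec = {"cluster_a": ca, "cluster_b": cb, "feature": feat, "error": ""}
            try:
                _, rec["welch_p"] = welch_t_test(a, b)
            except Exception as exc:  # flagged, not fatal
                rec["welch_p"] = np.nan
                rec["error"] += f"welch: {exc}; "
            try:
                _, rec["mw_p"] = mann_whitney_u(a, b, method="asymptotic" if len(a) + len(b) > 20 else "auto")
            except Exception as exc:
                rec["mw_p"] = np.nan
                rec["error"] += f"mann-whitney: {exc}"
            rows.append(rec)
    cells = pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "feature", "welch_p", "mw_p", "error"])
    return TestMatrixReport(cells=cells, alpha=alpha)


# ---------------------------------------------------------------------------
# robust regression and ground-truth comparison
# ---------------------------------------------------------------------------


@dataclass
class HuberFit:
    slope: float
    intercept: float
    scale: float
    n_iter: int
    converged: bool


def huber_fit(
    x,
    y,
    delta: float = 1.345,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> HuberFit:
    """Robust simple linear regression under Huber's criterion.

    Iteratively-reweighted least squares: residuals are standardized by the
    median-absolute-deviation scale (re-estimated each iteration); points
    with |residual| beyond ``delta`` scales get down-weighted proportionally.
    ``delta = 1.345`` gives 95% efficiency at the Gaussian model.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant x; slope unidentifiable")

    # ordinary least-squares start
    A = np.column_stack([x, np.ones_like(x)])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = y - A @ beta
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = mad / 0.6744897501960817  # consistent with sd at the normal
        if scale <= 0:
            converged = True  # exact fit (e.g. noiseless line)
            break
        r = resid / scale
        w = np.minimum(1.0, delta / np.maximum(np.abs(r), 1e-300))
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol * (1.0 + np.max(np.abs(beta))):
            beta = beta_new
            converged = True
            break
        beta = beta_new
    resid = y - A @ beta
    mad = np.median(np.abs(resid - np.median(resid)))
    return HuberFit(
        slope=float(beta[0]),
        intercept=float(beta[1]),
        scale=float(mad / 0.6744897501960817),
        n_iter=it,
        converged=converged,
    )


def percent_mean_difference(reference_mean: float, pipeline_mean: float) -> float:
    """Relative excess of the reference mean over the pipeline mean (fraction)."""
    return reference_mean / pipeline_mean - 1.0


@dataclass
class GroundTruthComparison:
    """Pipeline-vs-reference LV measures: moments, percent differences, Huber fits."""

    measures: pd.DataFrame  # per measure: pipeline/gt mean & sd, pct_mean_diff
    huber_fits: Dict[str, HuberFit]
    n_matched: int

    def to_dict(self) -> dict:
        return {
            "n_matched": self.n_matched,
            "measures": self.measures.to_dict(orient="records"),
            "huber_fits": {
                k: {
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "scale": f.scale,
                    "n_iter": f.n_iter,
                    "converged": f.converged,
                }
                for k, f in self.huber_fits.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [
            "Pipeline vs reference LV measures",
            "=" * 72,
            f"matched cases: {self.n_matched}",
            f"{'measure':<10}{'pipe mean':>11}{'pipe sd':>9}{'ref mean':>11}"
            f"{'ref sd':>9}{'diff %':>8}",
        ]
        for _, r in self.measures.iterrows():
            lines.append(
                f"{r['measure']:<10}{r['pipeline_mean']:>11.2f}{r['pipeline_sd']:>9.2f}"
                f"{r['gt_mean']:>11.2f}{r['gt_sd']:>9.2f}{100 * r['pct_mean_diff']:>8.1f}"
            )
        for name, f in self.huber_fits.items():
            lines.append(
                f"Huber fit {name}: reference = {f.slope:.3f} x pipeline + {f.intercept:.3f}"
                f" (converged: {f.converged})"
            )
        return "\n".join(lines)


def compare_to_ground_truth(features: pd.DataFrame, gt: pd.DataFrame) -> GroundTruthComparison:
    """Compare pipeline-derived LV measures to the reference channel.

    Pipeline EDV is reconstructed from the identity EDV = ESV / (1 - EF).
    Tables are joined on ``case_id``; unmatched ids raise with the offending
    ids listed.  Huber regressions fit reference on pipeline for EDV and ESV.
    """
    merged = features.merge(gt, on="case_id", how="inner")
    missing_gt = set(features["case_id"]) - set(gt["case_id"])
    missing_feat = set(gt["case_id"]) - set(features["case_id"])
    if missing_gt or missing_feat:
        raise ValueError(
            "unmatched case ids: "
            f"{sorted(missing_gt)[:5]} without reference, {sorted(missing_feat)[:5]} without features"
        )
    esv = merged["V_LV_ES"].to_numpy(float)
    ef = merged["EF_LV"].to_numpy(float)
    edv = esv / (1.0 - ef)
    rows = []
    pairs = {
        "LV_EDV": (edv, merged["gt_V_LV_ED"].to_numpy(float)),
        "LV_ESV": (esv, merged["gt_V_LV_ES"].to_numpy(float)),
        "LV_EF": (ef, merged["gt_EF_LV"].to_numpy(float)),
    }
    for name, (pipe, ref) in pairs.items():
        rows.append(
            {
                "measure": name,
                "pipeline_mean": float(pipe.mean()),
                "pipeline_sd": float(pipe.std(ddof=1)),
                "gt_mean": float(ref.mean()),
                "gt_sd": float(ref.std(ddof=1)),
                "pct_mean_diff": percent_mean_difference(float(ref.mean()), float(pipe.mean())),
            }
        )
    fits = {
        "LV_EDV": huber_fit(edv, pairs["LV_EDV"][1]),
        "LV_ESV": huber_fit(esv, pairs["LV_ESV"][1]),
    }
    return GroundTruthComparison(
        measures=pd.DataFrame(rows), huber_fits=fits, n_matched=len(merged)
    )
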