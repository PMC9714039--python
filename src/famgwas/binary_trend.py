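"""Child-trend association test for a binary family-risk outcome.

The outcome is a per-family binary label (high-risk status, HRS) copied to
the children.  The genotype relative risk is multiplicative and constrained:
carrying one copy of the effect allele multiplies the risk by ``R1`` and two
copies by ``R2 = R1**2`` (the two-allele risk is never a free parameter).

The likelihood is retrospective on the child genotype under a rare-outcome
approximation: with HWE genotype frequencies f(g; q),

    P(g | case)    = f(g; q) * R1**g / sum_g' f(g'; q) * R1**g'
    P(g | control) = f(g; q)

Maximum likelihood is taken over (q, R1); the null fixes R1 = 1.  The test
statistic is twice the log-likelihood difference, referred to chi-square
with 1 degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2 as chi2_dist

from .family_io import FamilySet

__all__ = ["TrendResult", "trend_test", "screen_top_markers", "hrs_trend_scan"]


@dataclass
class TrendResult:
    marker_id: str
    r1_hat: float
    q_hat: float
    chi2: float
    p: float
    n_cases: int
    n_controls: int
    testable: bool = True


def _counts(dosages: np.ndarray) -> np.ndarray:
    return np.array([(dosages == g).sum() for g in (0, 1, 2)], dtype=float)


def _loglik(case_counts, ctrl_counts, q, log_r1):
    f = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    logf = np.log(np.maximum(f, 1e-300))
    g = np.arange(3)
    logw = logf + g * log_r1
    lognorm = np.log(np.exp(logw - logw.max()).sum()) + logw.max()
    return float(case_counts @ (logw - lognorm) + ctrl_counts @ logf)


def trend_test(dosages, status, marker_id: str = "") -> TrendResult:
    """Likelihood-ratio child-trend test at one marker.

    ``dosages``: effect-allele counts (0/1/2, negatives/NaN = missing);
    ``status``: binary outcome per child (1 = case family, 0 = control).
    A marker monomorphic in the tested children is flagged non-testable.
    """
    g = np.asarray(dosages, dtype=float)
    s = np.asarray(status, dtype=float)
    ok = ~np.isnan(g) & (g >= 0) & ~np.isnan(s)
    g, s = g[ok].astype(int), s[ok].astype(int)
    case_counts = _counts(g[s == 1])
    ctrl_counts = _counts(g[s == 0])
    n_cases, n_controls = int(case_counts.sum()), int(ctrl_counts.sum())
    base = dict(marker_id=marker_id, n_cases=n_cases, n_controls=n_controls)
    if n_cases == 0 or len(np.unique(g)) < 2:
        return TrendResult(r1_hat=np.nan, q_hat=np.nan, chi2=np.nan, p=np.nan,
                           testable=False, **base)

    total = case_counts + ctrl_counts
    q0 = float((total @ np.arange(3)) / (2 * total.sum()))
    q0 = min(max(q0, 1e-6), 1 - 1e-6)
    ll0 = _loglik(case_counts, ctrl_counts, q0, 0.0)

    def negll(x):
        q = 1 / (1 + np.exp(-x[0]))
        return -_loglik(case_counts, ctrl_counts, q, x[1])

    x0 = np.array([np.log(q0 / (1 - q0)), 0.0])
    res = optimize.minimize(negll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    ll1 = -res.fun
    chi2 = max(0.0, 2 * (ll1 - ll0))
    p = float(chi2_dist.sf(chi2, 1)) if chi2 > 0 else 1.0
    q_hat = float(1 / (1 + np.exp(-res.x[0])))
    return TrendResult(r1_hat=float(np.exp(res.x[1])), q_hat=q_hat,
                       chi2=chi2, p=p, **base)


def screen_top_markers(results: list[TrendResult] | pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Flag nominal (p < alpha) and Bonferroni (p < alpha / n markers)
    significance across a set of trend-test results."""
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(
            [
                {
                    "marker_id": r.marker_id,
                    "r1_hat": r.r1_hat,
                    "chi2": r.chi2,
                    "p": r.p,
                    "n_cases": r.n_cases,
                    "n_controls": r.n_controls,
                    "testable": r.testable,
                }
                for r in results
            ]
        )
    out = results.copy()
    n = max(int(out["testable"].sum()) if "testable" in out else len(out), 1)
    out["nominal"] = out["p"] < alpha
    out["bonferroni"] = out["p"] < alpha / n
    for col in ("nominal", "bonferroni"):
        out[col] = out[col].fillna(False)
    return out


def hrs_trend_scan(
    fs: FamilySet,
    markers=None,
    require_parent_for_controls: bool = True,
) -> pd.DataFrame:
    """Run the trend test on the ``hrs`` phenotype column for a marker subset.

    Children are individuals listing a parent; controls (hrs == 0) may be
    required to have at least one parent with any genotype data, mirroring
    the design choice of not using controls without parents.  The effect
    allele is the founder minor allele.
    """
    if fs.phenotypes is None or "hrs" not in fs.phenotypes.columns:
        raise ValueError("FamilySet phenotypes must carry an 'hrs' column")
    from .family_io import founder_allele_stats

    child_rows = np.where(fs.child_mask)[0]
    hrs = fs.phenotypes["hrs"].to_numpy(dtype=float)[child_rows]
    keep = ~np.isnan(hrs)
    if require_parent_for_controls:
        has_parent = np.zeros(len(child_rows), dtype=bool)
        for pos_arr in (fs.father_pos, fs.mother_pos):
            pp = pos_arr[child_rows]
            ok = pp >= 0
            has_parent[ok] |= (fs.genotypes[pp[ok]] >= 0).any(axis=1)
        keep &= (hrs == 1) | has_parent
    child_rows = child_rows[keep]
    hrs = hrs[keep]

    if "minor_is_a2" in fs.markers.columns:
        minor_is_a2 = fs.markers["minor_is_a2"].to_numpy(dtype=bool)
    else:
        minor_is_a2 = founder_allele_stats(fs)["minor_is_a2"].to_numpy(dtype=bool)

    if markers is None:
        marker_idx = range(fs.n_markers)
    else:
        ids = fs.markers["marker_id"].to_numpy()
        marker_idx = [
            int(np.where(ids == m)[0][0]) if isinstance(m, str) else int(m) for m in markers
        ]
    results = []
    for j in marker_idx:
        d = fs.genotypes[child_rows, j].astype(float)
        d[d < 0] = np.nan
        if not minor_is_a2[j]:
            d = 2 - d
        results.append(trend_test(d, hrs, marker_id=fs.markers["marker_id"].iloc[j]))
    return screen_top_markers(results)
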