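"""Variance-components association tests for family-based quantitative traits.

The trait of the children in each nuclear family is modeled as multivariate
normal around a fixed-effect mean with covariance

    Sigma = Ve * I + Vg * K + Va * Pi

where ``K`` is the kinship-scaled polygenic matrix (1 on the diagonal, 0.5
between full siblings), ``Pi`` the expected single-marker IBD-sharing matrix,
and Ve/Vg/Va the environmental, polygenic and additive major-locus variance
components.  Only children contribute phenotypes; parents contribute genetic
information through the transmission table.

Four test modes, each a 1-df likelihood-ratio test with one-sided upper-tail
chi-square(1) p-values:

``general``
    effect-allele dosage (0/1/2) as a combined between/within-family fixed
    effect (the *total* association model);
``paternal`` / ``maternal``
    count (0/1) of the effect allele inherited from the tested parent, over
    the informative probands of that mode; the reported effect comes from a
    model containing only the parental-origin term (no child-dosage term);
``difference``
    null model with the dosage term, full model adding the maternal-origin
    count -- a nested test of whether paternal and maternal transmissions
    differ, used to filter POE signals that are mere child effects.

When no family contributes two or more phenotyped probands the three
variance components are not separately identified and the model collapses to
a single residual variance, making the fit an exact (closed-form) Gaussian
maximum likelihood; otherwise variances are maximized numerically on the log
scale with GLS-profiled mean parameters.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2 as chi2_dist

from .family_io import FamilySet, founder_allele_stats
from .transmission import TransmissionTable

__all__ = [
    "VarianceComponents",
    "TestResult",
    "family_loglik",
    "sib_marker_ibd",
    "fit_model",
    "scan",
    "difference_filter",
]

_XTOL = 1e-10
_MAXITER = 500


@dataclass
class VarianceComponents:
    ve: float
    vg: float
    va: float

    def __post_init__(self):
        if min(self.ve, self.vg, self.va) < 0:
            raise ValueError("variance components must be non-negative")


@dataclass
class TestResult:
    marker_id: str
    trait: str
    mode: str
    effect: float
    chi2: float
    p: float
    n_probands: int
    converged: bool
    testable: bool = True

    @property
    def se(self) -> float:
        """Wald-style standard error sqrt(effect^2 / chi2)."""
        if not self.testable or not self.chi2 > 0:
            return np.nan
        return float(np.sqrt(self.effect**2 / self.chi2))


# ---------------------------------------------------------------------------
# likelihood primitives


def family_loglik(y, design, beta, vc: VarianceComponents, K=None, Pi=None) -> float:
    """Exact multivariate-normal log density of one family's children.

    ``y``: trait values; ``design``: (k, p) predictor matrix; ``beta``: mean
    coefficients; ``K``/``Pi`` default to identity (singleton or unrelated).
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    k = len(y)
    X = np.atleast_2d(np.asarray(design, dtype=float))
    r = y - X @ np.asarray(beta, dtype=float)
    K = np.eye(k) if K is None else np.asarray(K, dtype=float)
    Pi = np.eye(k) if Pi is None else np.asarray(Pi, dtype=float)
    sigma = vc.ve * np.eye(k) + vc.vg * K + vc.va * Pi
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular family covariance: {sigma}") from exc
    z = np.linalg.solve(L, r)
    logdet = 2 * np.log(np.diag(L)).sum()
    return float(-0.5 * (k * np.log(2 * np.pi) + logdet + z @ z))


def sib_marker_ibd(sib1, sib2, father, mother) -> float:
    """Expected proportion of alleles a sib pair shares IBD at one marker.

    Exact conditional expectation given the four genotypes, under a uniform
    prior over which parental copy each child inherited; 0.5 (the prior mean)
    when any of the four genotypes is missing or the configuration is
    Mendelian-inconsistent.
    """
    calls = [sib1, sib2, father, mother]
    calls = [-1 if c is None else int(c) for c in calls]
    if any(c < 0 for c in calls):
        return 0.5
    s1, s2, f, m = calls
    f_alleles = [(0, 0), (0, 1), (1, 1)][f]
    m_alleles = [(0, 0), (0, 1), (1, 1)][m]
    configs = []
    for i1, j1, i2, j2 in itertools.product(range(2), repeat=4):
        if f_alleles[i1] + m_alleles[j1] != s1:
            continue
        if f_alleles[i2] + m_alleles[j2] != s2:
            continue
        configs.append(((i1 == i2) + (j1 == j2)) / 2)
    if not configs:
        return 0.5
    return float(np.mean(configs))


# ---------------------------------------------------------------------------
# fitting machinery


class _Blocks:
    """Family grouping of a proband set: singleton indices and >=2-child
    blocks with their K and Pi matrices."""

    def __init__(self, fam_codes: np.ndarray, Pi_entries=None):
        self.n = len(fam_codes)
        order = np.argsort(fam_codes, kind="stable")
        codes_sorted = fam_codes[order]
        boundaries = np.flatnonzero(np.r_[True, codes_sorted[1:] != codes_sorted[:-1], True])
        self.singles = []
        self.multi = []
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            idx = order[a:b]
            if len(idx) == 1:
                self.singles.append(idx[0])
            else:
                k = len(idx)
                K = np.full((k, k), 0.5)
                np.fill_diagonal(K, 1.0)
                if Pi_entries is None:
                    Pi = np.eye(k)
                else:
                    Pi = np.eye(k)
                    for (i, j), v in Pi_entries.get(codes_sorted[a], {}).items():
                        Pi[i, j] = Pi[j, i] = v
                self.multi.append((idx, K, Pi))
        self.singles = np.asarray(self.singles, dtype=np.int64)

    @property
    def has_multi(self) -> bool:
        return len(self.multi) > 0


def _ols_ml(y: np.ndarray, X: np.ndarray):
    """Closed-form Gaussian ML for the collapsed single-variance model."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    rss = float(r @ r)
    rss = max(rss, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
    return ll, beta, rss


def _profile_negll(logv, y, X, blocks: _Blocks):
    ve, vg, va = np.exp(np.clip(logv, -40, 40))
    p = X.shape[1]
    n = blocks.n
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    yWy = 0.0
    logdet = 0.0
    s = ve + vg + va
    if len(blocks.singles):
        Xs = X[blocks.singles]
        ys = y[blocks.singles]
        w = 1.0 / s
        XtWX += w * (Xs.T @ Xs)
        XtWy += w * (Xs.T @ ys)
        yWy += w * float(ys @ ys)
        logdet += len(ys) * np.log(s)
    for idx, K, Pi in blocks.multi:
        k = len(idx)
        sigma = ve * np.eye(k) + vg * K + va * Pi
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e12
        Zx = np.linalg.solve(L, X[idx])
        Zy = np.linalg.solve(L, y[idx])
        XtWX += Zx.T @ Zx
        XtWy += Zx.T @ Zy
        yWy += float(Zy @ Zy)
        logdet += 2 * np.log(np.diag(L)).sum()
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtWX, XtWy, rcond=None)[0]
    quad = yWy - float(beta @ XtWy)
    return 0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def _betas_at(logv, y, X, blocks):
    """GLS mean coefficients at a given variance point."""
    ve, vg, va = np.exp(logv)
    p = X.shape[1]
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    s = ve + vg + va
    if len(blocks.singles):
        Xs = X[blocks.singles]
        ys = y[blocks.singles]
        XtWX += (Xs.T @ Xs) / s
        XtWy += (Xs.T @ ys) / s
    for idx, K, Pi in blocks.multi:
        k = len(idx)
        sigma = ve * np.eye(k) + vg * K + va * Pi
        L = np.linalg.cholesky(sigma)
        Zx = np.linalg.solve(L, X[idx])
        Zy = np.linalg.solve(L, y[idx])
        XtWX += Zx.T @ Zx
        XtWy += Zx.T @ Zy
    return np.linalg.lstsq(XtWX, XtWy, rcond=None)[0]


def _fit_vc(y, X, blocks: _Blocks, x0=None):
    """Maximize the profiled likelihood over log-variances.

    Returns (loglik, beta, logv_hat, converged).  Deterministic: fixed start
    (empirical variance split equally) plus one perturbed restart on failure.
    """
    var_y = max(float(np.var(y)), 1e-12)
    start = np.log(np.full(3, var_y / 3)) if x0 is None else np.asarray(x0, dtype=float)
    best = None
    for attempt, s0 in enumerate((start, start + np.array([0.5, -0.5, -1.0]))):
        res = optimize.minimize(
            _profile_negll,
            s0,
            args=(y, X, blocks),
            method="L-BFGS-B",
            bounds=[(np.log(var_y) - 20, np.log(var_y) + 5)] * 3,
            options={"maxiter": _MAXITER, "ftol": _XTOL},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
    beta = _betas_at(best.x, y, X, blocks)
    return -best.fun, beta, best.x, bool(best.success)


def _lrt(y, Xn, Xf, blocks: _Blocks):
    """Likelihood-ratio machinery shared by all modes.

    Returns (chi2, effect, converged) where the effect is the coefficient of
    the last column of ``Xf``.
    """
    if not blocks.has_multi:
        ll0, _, _ = _ols_ml(y, Xn)
        llf, beta, _ = _ols_ml(y, Xf)
        conv = True
    else:
        ll0, _, v0, c0 = _fit_vc(y, Xn, blocks)
        llf, beta, _, c1 = _fit_vc(y, Xf, blocks, x0=v0)
        conv = c0 and c1
    chi2 = max(0.0, 2 * (llf - ll0))
    return chi2, float(beta[-1]), conv


class _ScanContext:
    """Per-(trait, mode) preparation shared across markers of a scan."""

    def __init__(self, fs: FamilySet, tt: TransmissionTable, trait, mode, covariates):
        if fs.phenotypes is None:
            raise ValueError("FamilySet carries no phenotypes")
        if trait not in fs.phenotypes.columns:
            raise KeyError(f"unknown trait {trait!r}")
        self.fs, self.tt, self.trait, self.mode = fs, tt, trait, mode
        rows = tt.child_rows
        self.y_all = fs.phenotypes[trait].to_numpy(dtype=float)[rows]
        cov_cols = []
        for c in covariates:
            cov_cols.append(fs.phenotypes[c].to_numpy(dtype=float)[rows])
        self.cov = np.column_stack(cov_cols) if cov_cols else np.empty((len(rows), 0))
        self.base_ok = ~np.isnan(self.y_all)
        if self.cov.size:
            self.base_ok &= ~np.isnan(self.cov).any(axis=1)
        self.fam_codes = pd.factorize(fs.individuals["fid"].to_numpy()[rows])[0]
        # effect-allele orientation: minor allele in founders by default
        if "minor_is_a2" in fs.markers.columns:
            self.minor_is_a2 = fs.markers["minor_is_a2"].to_numpy(dtype=bool)
        else:
            self.minor_is_a2 = founder_allele_stats(fs)["minor_is_a2"].to_numpy(dtype=bool)
        self.C = fs.genotypes[rows]

    def marker_arrays(self, j: int):
        """(probands mask, predictor columns dict) for marker ``j``."""
        tt, mode = self.tt, self.mode
        flip = not self.minor_is_a2[j]
        dosage = self.C[:, j].astype(float)
        dosage[self.C[:, j] < 0] = np.nan
        if flip:
            dosage = 2 - dosage
        def orient(cnt):
            out = cnt.astype(float)
            out[cnt < 0] = np.nan
            return 1 - out if flip else out
        pat = orient(tt.pat[:, j])
        mat = orient(tt.mat[:, j])
        if mode == "general":
            mask = tt.informative["general"][:, j]
            pred = {"x": dosage}
        elif mode == "paternal":
            mask = tt.informative["paternal"][:, j]
            pred = {"x": pat}
        elif mode == "maternal":
            mask = tt.informative["maternal"][:, j]
            pred = {"x": mat}
        elif mode == "difference":
            # the full model needs maternal counts: maternal-informative set
            mask = tt.informative["maternal"][:, j] & ~np.isnan(dosage)
            pred = {"x0": dosage, "x": mat}
        else:
            raise ValueError(f"unknown mode {mode!r}")
        mask = mask & self.base_ok
        for v in pred.values():
            mask = mask & ~np.isnan(v)
        return mask, pred

    def fit(self, j: int) -> TestResult:
        mask, pred = self.marker_arrays(j)
        idx = np.where(mask)[0]
        marker_id = self.fs.markers["marker_id"].iloc[j]
        base = dict(marker_id=marker_id, trait=self.trait, mode=self.mode,
                    n_probands=len(idx))
        if len(idx) < 2:
            return TestResult(effect=np.nan, chi2=np.nan, p=np.nan,
                              converged=False, testable=False, **base)
        y = self.y_all[idx]
        ones = np.ones(len(idx))
        covs = [ones] + ([self.cov[idx][:, k] for k in range(self.cov.shape[1])])
        tested = pred["x"][idx]
        if np.ptp(tested) == 0:
            return TestResult(effect=np.nan, chi2=np.nan, p=np.nan,
                              converged=False, testable=False, **base)
        null_extra = [pred["x0"][idx]] if "x0" in pred else []
        Xn = np.column_stack(covs + null_extra)
        Xf = np.column_stack(covs + null_extra + [tested])
        blocks = self._blocks(idx, j)
        chi2, effect, conv = _lrt(y, Xn, Xf, blocks)
        p = float(chi2_dist.sf(chi2, 1)) if chi2 > 0 else 1.0
        return TestResult(effect=effect, chi2=chi2, p=p, converged=conv, **base)

    def _blocks(self, idx: np.ndarray, j: int) -> _Blocks:
        codes = self.fam_codes[idx]
        uniq, counts = np.unique(codes, return_counts=True)
        if (counts > 1).any():
            pi_entries = {}
            rows = self.tt.child_rows
            for code in uniq[counts > 1]:
                members = idx[codes == code]
                entries = {}
                for a in range(len(members)):
                    for b in range(a + 1, len(members)):
                        ra, rb = rows[members[a]], rows[members[b]]
                        fa = self.fs.father_pos[ra]
                        mo = self.fs.mother_pos[ra]
                        g = self.fs.genotypes
                        entries[(a, b)] = sib_marker_ibd(
                            g[ra, j],
                            g[rb, j],
                            g[fa, j] if fa >= 0 else None,
                            g[mo, j] if mo >= 0 else None,
                        )
                pi_entries[code] = entries
            return _Blocks(codes, pi_entries)
        return _Blocks(codes)


# ---------------------------------------------------------------------------
# public API


def fit_model(
    fs: FamilySet,
    tt: TransmissionTable,
    trait: str,
    mode: str,
    marker: int | str,
    covariates=("sex",),
) -> TestResult:
    """Fit null and full models at one marker and return the LRT result.

    ``marker`` may be a positional index or a marker ID.
    """
    ctx = _ScanContext(fs, tt, trait, mode, covariates)
    if isinstance(marker, str):
        hits = np.where(fs.markers["marker_id"].to_numpy() == marker)[0]
        if not len(hits):
            raise KeyError(f"unknown marker {marker!r}")
        marker = int(hits[0])
    return ctx.fit(int(marker))


def scan(
    fs: FamilySet,
    tt: TransmissionTable,
    trait: str,
    mode: str,
    covariates=("sex",),
    markers=None,
) -> pd.DataFrame:
    """Run one test mode for one trait across markers.

    Deterministic given the data (fixed optimizer starts, no randomness).
    Returns the fixed-column result table: trait, mode, marker, chr, pos,
    effect/other allele, proband count, effect, SE, chi2, p.
    """
    ctx = _ScanContext(fs, tt, trait, mode, covariates)
    mk = fs.markers
    idx = range(fs.n_markers) if markers is None else markers
    rows = []
    for j in idx:
        res = ctx.fit(j)
        eff_allele, other = (
            (mk["a2"].iloc[j], mk["a1"].iloc[j])
            if ctx.minor_is_a2[j]
            else (mk["a1"].iloc[j], mk["a2"].iloc[j])
        )
        rows.append(
            {
                "trait": trait,
                "mode": mode,
                "marker_id": res.marker_id,
                "chrom": mk["chrom"].iloc[j],
                "pos": mk["pos"].iloc[j],
                "effect_allele": eff_allele,
                "other_allele": other,
                "n_probands": res.n_probands,
                "effect": res.effect,
                "se": res.se,
                "chi2": res.chi2,
                "p": res.p,
                "converged": res.converged,
                "testable": res.testable,
            }
        )
    return pd.DataFrame(rows)


def difference_filter(
    poe_results: pd.DataFrame, diff_results: pd.DataFrame, alpha_diff: float
) -> pd.DataFrame:
    """Keep POE associations whose paternal-vs-maternal difference test is
    significant at ``alpha_diff``; drop (with a warning) POE rows that have
    no matching difference-test record."""
    merged = poe_results.merge(
        diff_results[["trait", "marker_id", "p"]].rename(columns={"p": "diff_p"}),
        on=["trait", "marker_id"],
        how="left",
    )
    missing = merged["diff_p"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} POE associations lack a difference-test "
            "record and were excluded"
        )
    return merged[~missing & (merged["diff_p"] <= alpha_diff)].reset_index(drop=True)
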