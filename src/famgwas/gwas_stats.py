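"""Post-scan statistics and the multiple-testing / quality-filter strategy.

Covers Wald standard-error reconstruction from likelihood-ratio output,
proportion of variance explained (PVE), the genomic inflation factor,
chi-square to one-sided p conversion, the four-criterion significance
filter, and Manhattan/QQ plot data tables.

Filter criteria per association:

(i)   genome-wide significance, p <= alpha_gw (default 5e-8);
(ii)  for POE associations only, a significant paternal-vs-maternal
      difference test, diff_p <= alpha_diff (0.05 Bonferroni-corrected for
      the number of post hoc difference tests);
(iii) study-wide significance, p <= 0.05 / (n markers x n scans);
(iv)  at least ``min_carriers`` children in the sample carry the minor
      allele (computed over all genotyped children, not informative
      probands).

Tier A = (i) and, for POE modes, (ii); tier B = tier A plus (iii) and (iv).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .family_io import FamilySet

__all__ = [
    "FilterPolicy",
    "FilterReport",
    "se_from_wald",
    "pve",
    "lambda_gc",
    "chi2_to_p",
    "apply_filter",
    "qq_manhattan_tables",
    "minor_allele_carriers",
    "annotate_results",
    "round_sig",
]

POE_MODES = ("paternal", "maternal")


def se_from_wald(effect: float, chi2: float) -> float:
    """Reconstruct the standard error of an effect from its LRT chi-square,
    treating the statistic as a Wald statistic: SE = sqrt(effect^2 / chi2)."""
    if not chi2 > 0:
        return np.nan
    return float(np.sqrt(effect**2 / chi2))


def pve(beta: float, se: float, maf: float, n: int) -> float:
    """Proportion of trait variance explained by a marker.

    PVE = 2 b^2 MAF (1-MAF) / [2 b^2 MAF (1-MAF) + SE^2 * 2 N * MAF (1-MAF)],
    with the founder MAF and the proband count as N.  (The MAF factors cancel
    algebraically but are kept for fidelity to the reporting formula.)
    """
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if n < 1:
        raise ValueError("n must be >= 1")
    num = 2 * beta**2 * maf * (1 - maf)
    den = num + se**2 * 2 * n * maf * (1 - maf)
    return float(num / den)


def lambda_gc(chi2_values) -> float:
    """Genomic inflation factor: median observed chi-square divided by the
    chi-square(1) median."""
    vals = np.asarray(chi2_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite chi-square values")
    return float(np.median(vals) / chi2_dist.ppf(0.5, 1))


def chi2_to_p(chi2: float, df: int = 1) -> float:
    """One-sided upper-tail p-value of a chi-square statistic."""
    if chi2 < 0:
        raise ValueError("chi2 must be >= 0")
    return float(chi2_dist.sf(chi2, df))


def round_sig(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures (report formatting)."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.format_float_positional(
        x, precision=sig, unique=False, fractional=False, trim="k"))


@dataclass
class FilterPolicy:
    """Thresholds of the four-criterion filter.

    ``alpha_diff`` and ``alpha_studywide`` are recomputed from the realized
    scan dimensions via :meth:`from_dimensions`, never hard-coded.
    """

    alpha_gw: float = 5e-8
    alpha_diff: float = 0.05
    alpha_studywide: float = 0.05
    min_carriers: int = 30

    @classmethod
    def from_dimensions(
        cls,
        n_markers: int,
        n_scans: int,
        n_diff_tests: int,
        base_alpha: float = 0.05,
        alpha_gw: float = 5e-8,
        min_carriers: int = 30,
    ) -> "FilterPolicy":
        return cls(
            alpha_gw=alpha_gw,
            alpha_diff=base_alpha / max(n_diff_tests, 1),
            alpha_studywide=base_alpha / max(n_markers * n_scans, 1),
            min_carriers=min_carriers,
        )


@dataclass
class FilterReport:
    criteria: pd.DataFrame  # per association: pass/fail per criterion
    tier_a: pd.DataFrame
    tier_b: pd.DataFrame
    policy: FilterPolicy


def apply_filter(results: pd.DataFrame, policy: FilterPolicy) -> FilterReport:
    """Apply the four-criterion filter to an annotated result table.

    ``results`` needs columns ``trait, mode, marker_id, p, diff_p,
    minor_carriers`` (``diff_p`` may be NaN for general-mode rows).  POE rows
    lacking a difference-test record are excluded from tier A with a warning.
    """
    res = results.reset_index(drop=True)
    is_poe = res["mode"].isin(POE_MODES)
    crit_i = res["p"] <= policy.alpha_gw
    missing_diff = is_poe & res["diff_p"].isna()
    if (missing_diff & crit_i).any():
        warnings.warn(
            f"{int((missing_diff & crit_i).sum())} POE associations lack a "
            "difference-test record and were excluded from tier A"
        )
    crit_ii = np.where(is_poe, res["diff_p"] <= policy.alpha_diff, True)
    crit_iii = res["p"] <= policy.alpha_studywide
    crit_iv = res["minor_carriers"] >= policy.min_carriers
    crit = res.assign(
        crit_i=crit_i,
        crit_ii=crit_ii & ~missing_diff,
        crit_iii=crit_iii,
        crit_iv=crit_iv,
    )
    tier_a_mask = crit["crit_i"] & crit["crit_ii"]
    tier_b_mask = tier_a_mask & crit["crit_iii"] & crit["crit_iv"]
    return FilterReport(
        criteria=crit,
        tier_a=res[tier_a_mask].reset_index(drop=True),
        tier_b=res[tier_b_mask].reset_index(drop=True),
        policy=policy,
    )


def minor_allele_carriers(fs: FamilySet) -> np.ndarray:
    """Per-marker count of children carrying at least one minor allele
    (minor in founders), over all genotyped children in the dataset."""
    from .family_io import founder_allele_stats

    child_rows = np.where(fs.child_mask)[0]
    G = fs.genotypes[child_rows]
    if "minor_is_a2" in fs.markers.columns:
        minor_is_a2 = fs.markers["minor_is_a2"].to_numpy(dtype=bool)
    else:
        minor_is_a2 = founder_allele_stats(fs)["minor_is_a2"].to_numpy(dtype=bool)
    carriers_a2 = ((G == 1) | (G == 2)).sum(axis=0)
    carriers_a1 = ((G == 1) | (G == 0)).sum(axis=0)
    return np.where(minor_is_a2, carriers_a2, carriers_a1)


def annotate_results(
    results: pd.DataFrame,
    fs: FamilySet,
    diff_results: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach SE, founder MAF, PVE, minor-carrier counts and (for POE rows)
    difference-test p-values to a scan result table."""
    from .family_io import founder_allele_stats

    res = results.copy()
    mk = fs.markers.set_index("marker_id")
    if "maf_founders" not in mk.columns:
        mk = mk.assign(maf_founders=founder_allele_stats(fs)["maf_founders"].to_numpy())
    res["maf_founders"] = mk["maf_founders"].reindex(res["marker_id"]).to_numpy()
    carriers = pd.Series(minor_allele_carriers(fs), index=fs.markers["marker_id"])
    res["minor_carriers"] = carriers.reindex(res["marker_id"]).to_numpy()
    if "se" not in res.columns:
        res["se"] = [se_from_wald(b, c) for b, c in zip(res["effect"], res["chi2"])]
    res["pve"] = [
        pve(b, s, m, int(n)) if np.isfinite(b) and np.isfinite(s) and 0 < m <= 0.5 and n >= 1
        else np.nan
        for b, s, m, n in zip(res["effect"], res["se"], res["maf_founders"], res["n_probands"])
    ]
    if diff_results is not None:
        res = res.merge(
            diff_results[["trait", "marker_id", "p"]].rename(columns={"p": "diff_p"}),
            on=["trait", "marker_id"],
            how="left",
        )
    elif "diff_p" not in res.columns:
        res["diff_p"] = np.nan
    return res


def qq_manhattan_tables(results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready tables from a result frame with chrom/pos/p columns.

    Manhattan: chrom, pos, -log10 p and a cumulative genome coordinate with
    strictly increasing chromosome offsets.  QQ: expected vs observed
    -log10 p with expected quantiles at rank/(n+1).
    """
    res = results.dropna(subset=["p"]).copy()
    chrom_order = {c: i for i, c in enumerate(pd.unique(res["chrom"]))}
    res = res.sort_values(["chrom", "pos"], key=lambda s: s.map(chrom_order) if s.name == "chrom" else s)
    offset = 0
    cum = np.empty(len(res))
    for _, grp_idx in res.groupby("chrom", sort=False).indices.items():
        pos = res["pos"].to_numpy()[grp_idx]
        cum[grp_idx] = pos + offset
        offset += pos.max() + 1
    manhattan = pd.DataFrame(
        {
            "chrom": res["chrom"].to_numpy(),
            "pos": res["pos"].to_numpy(),
            "neglog10_p": -np.log10(np.maximum(res["p"].to_numpy(), 1e-300)),
            "cum_pos": cum,
        }
    )
    p_sorted = np.sort(res["p"].to_numpy())
    n = len(p_sorted)
    expected = np.arange(1, n + 1) / (n + 1)
    qq = pd.DataFrame(
        {
            "expected_neglog10_p": -np.log10(expected),
            "observed_neglog10_p": -np.log10(np.maximum(p_sorted, 1e-300)),
        }
    )
    return manhattan, qq
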