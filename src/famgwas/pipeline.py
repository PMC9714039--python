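"""End-to-end orchestration: QC -> transmission phasing -> per-trait scans
-> difference filter -> statistics/tiering -> binary-trend HRS screen.

Traits are consumed already scored/standardized (age adjustment and any
norming happen upstream); no within-pipeline transformation to normality is
applied.  All outputs are fixed-header TSV files plus a plain-text summary
log echoing every threshold actually applied.  A run is deterministic given
its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binary_trend, family_io, gwas_stats, transmission, vc_assoc

log = logging.getLogger("famgwas")

__all__ = ["RunConfig", "run_gwas", "run_hrs_screen"]

SCAN_MODES = ("general", "paternal", "maternal")


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run (echoed into the output
    directory verbatim)."""

    ped: str
    map: str
    phenotypes: str
    out_dir: str
    traits: list[str] | None = None  # None -> every non-covariate column
    modes: tuple[str, ...] = SCAN_MODES
    covariates: tuple[str, ...] = ("sex",)
    include_hrs_covariate: bool = False
    mendel_max_rate: float = 0.01
    max_missing: float = 0.05
    hwe_alpha: float = 1e-6
    min_maf: float = 0.01
    het_sd_window: float = 3.0
    alpha_gw: float = 5e-8
    base_alpha: float = 0.05
    min_carriers: int = 30

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in asdict(self).items()}, fh, sort_keys=False)


def _setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        log.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)


def load_and_qc(cfg: RunConfig):
    """Read inputs and run the QC cascade; returns (FamilySet, reports)."""
    fs = family_io.read_pedfile(cfg.ped, cfg.map)
    family_io.read_phenotypes(cfg.phenotypes, fs)
    fs, reports = family_io.qc_cascade(
        fs,
        mendel_max_rate=cfg.mendel_max_rate,
        max_missing=cfg.max_missing,
        hwe_alpha=cfg.hwe_alpha,
        min_maf=cfg.min_maf,
        het_sd_window=cfg.het_sd_window,
    )
    return fs, reports


def run_gwas(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a summary dict and writes all tables."""
    out = Path(cfg.out_dir)
    _setup_logging(out)
    cfg.to_yaml(out / "config.yaml")

    try:
        fs, reports = load_and_qc(cfg)
    except Exception as exc:
        raise RuntimeError(f"stage 'qc' failed: {exc}") from exc
    qc_frames = [f for f in (r.to_frame().assign(stage=r.stage) for r in reports) if len(f)]
    (pd.concat(qc_frames) if qc_frames else pd.DataFrame(
        columns=["kind", "entity", "reason", "value", "threshold", "stage"]
    )).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    for r in reports:
        log.info(
            "QC %s: removed %d individuals, %d markers (thresholds %s)",
            r.stage, len(r.removed_individuals), len(r.removed_markers), r.thresholds,
        )

    tt = transmission.build_transmission_table(fs)
    counts = tt.proband_counts(fs.markers["marker_id"])
    for m in transmission.MODES:
        log.info("probands (%s): min %d, max %d per marker",
                 m, counts[f"n_{m}"].min(), counts[f"n_{m}"].max())

    covs = list(cfg.covariates)
    if cfg.include_hrs_covariate and "hrs" not in covs:
        covs.append("hrs")
    traits = cfg.traits or [
        c for c in fs.phenotypes.columns if c not in ("sex", "hrs")
    ]

    scan_dir = out / "scans"
    scan_dir.mkdir(exist_ok=True)
    all_results = []
    lambdas = []
    try:
        for trait in traits:
            for mode in cfg.modes:
                res = vc_assoc.scan(fs, tt, trait, mode, covariates=covs)
                res.to_csv(scan_dir / f"{trait}_{mode}.tsv", sep="\t", index=False)
                lam = gwas_stats.lambda_gc(res.loc[res["testable"], "chi2"])
                lambdas.append({"trait": trait, "mode": mode, "lambda_gc": lam})
                log.info("scan %s/%s: %d markers, lambda=%.3f", trait, mode, len(res), lam)
                manhattan, qq = gwas_stats.qq_manhattan_tables(res[res["testable"]])
                manhattan.to_csv(scan_dir / f"{trait}_{mode}_manhattan.tsv", sep="\t", index=False)
                qq.to_csv(scan_dir / f"{trait}_{mode}_qq.tsv", sep="\t", index=False)
                all_results.append(res)
    except Exception as exc:
        (out / "INCOMPLETE").write_text(f"scan stage failed: {exc}\n")
        raise RuntimeError(f"stage 'scan' failed: {exc}") from exc
    pd.DataFrame(lambdas).to_csv(out / "lambda_gc.tsv", sep="\t", index=False)
    results = pd.concat(all_results, ignore_index=True)

    # post hoc difference tests for genome-wide-significant POE associations
    poe_hits = results[
        results["mode"].isin(gwas_stats.POE_MODES)
        & results["testable"]
        & (results["p"] <= cfg.alpha_gw)
    ]
    diff_rows = []
    for (trait, marker_id), _ in poe_hits.groupby(["trait", "marker_id"]):
        r = vc_assoc.fit_model(fs, tt, trait, "difference", marker=marker_id, covariates=covs)
        diff_rows.append(
            {"trait": trait, "marker_id": marker_id, "effect": r.effect,
             "chi2": r.chi2, "p": r.p, "n_probands": r.n_probands}
        )
    diff_results = pd.DataFrame(
        diff_rows, columns=["trait", "marker_id", "effect", "chi2", "p", "n_probands"]
    )
    diff_results.to_csv(out / "difference_tests.tsv", sep="\t", index=False)

    n_diff = len(diff_results)
    policy = gwas_stats.FilterPolicy.from_dimensions(
        n_markers=fs.n_markers,
        n_scans=len(traits) * len(cfg.modes),
        n_diff_tests=n_diff,
        base_alpha=cfg.base_alpha,
        alpha_gw=cfg.alpha_gw,
        min_carriers=cfg.min_carriers,
    )
    annotated = gwas_stats.annotate_results(
        results[results["testable"]], fs, diff_results if n_diff else None
    )
    report = gwas_stats.apply_filter(annotated, policy)
    report.criteria.to_csv(out / "criteria.tsv", sep="\t", index=False)
    report.tier_a.to_csv(out / "tier_a.tsv", sep="\t", index=False)
    report.tier_b.to_csv(out / "tier_b.tsv", sep="\t", index=False)

    summary = {
        "n_individuals": fs.n_individuals,
        "n_markers": fs.n_markers,
        "n_scans": len(traits) * len(cfg.modes),
        "n_diff_tests": n_diff,
        "alpha_gw": cfg.alpha_gw,
        "alpha_diff": policy.alpha_diff,
        "alpha_studywide": policy.alpha_studywide,
        "min_carriers": policy.min_carriers,
        "n_tier_a": len(report.tier_a),
        "n_tier_b": len(report.tier_b),
        "lambda_range": [
            float(min(l["lambda_gc"] for l in lambdas)),
            float(max(l["lambda_gc"] for l in lambdas)),
        ] if lambdas else None,
    }
    with open(out / "summary.txt", "w") as fh:
        fh.write("famgwas run summary\n")
        for k, v in summary.items():
            fh.write(f"{k}\t{v}\n")
    log.info("thresholds: genome-wide %g, difference %g, study-wide %g, carriers >= %d",
             policy.alpha_gw, policy.alpha_diff, policy.alpha_studywide, policy.min_carriers)
    return summary


def run_hrs_screen(cfg: RunConfig, markers=None) -> pd.DataFrame:
    """Binary-trend screen of tier-A markers against the high-risk status.

    ``markers`` defaults to the markers in the existing tier-A report of the
    run directory; an empty tier yields an empty report (success).
    """
    out = Path(cfg.out_dir)
    _setup_logging(out)
    fs, _ = load_and_qc(cfg)
    if markers is None:
        tier_path = out / "tier_a.tsv"
        if tier_path.exists():
            tier = pd.read_csv(tier_path, sep="\t")
            markers = sorted(set(tier["marker_id"])) if len(tier) else []
        else:
            raise FileNotFoundError(f"{tier_path} not found; run the GWAS first")
    markers = [m for m in markers if m in set(fs.markers["marker_id"])]
    if not markers:
        report = pd.DataFrame(
            columns=["marker_id", "r1_hat", "chi2", "p", "n_cases", "n_controls",
                     "testable", "nominal", "bonferroni"]
        )
    else:
        report = binary_trend.hrs_trend_scan(fs, markers)
    report.to_csv(out / "hrs_trend.tsv", sep="\t", index=False)
    log.info("HRS trend screen: %d markers, %d nominal, %d Bonferroni",
             len(report),
             int(report["nominal"].sum()) if len(report) else 0,
             int(report["bonferroni"].sum()) if len(report) else 0)
    return report
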