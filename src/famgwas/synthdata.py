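"""Synthetic nuclear-family datasets with known genetic architecture.

The generator emulates the statistical structure the analysis assumes:
mostly one-child families (a small minority with two children), biallelic
autosomal markers with founder allele frequencies drawn under HWE, children
produced by Mendelian transmission with the true parental origin of every
allele recorded, quantitative traits built from additive / paternal-origin /
maternal-origin allele effects plus a family-shared polygenic component, an
independent environmental residual and a sex covariate, and a binary
per-family high-risk-status (HRS) label.  Missingness (whole ungenotyped
parents, sporadic genotype calls, phenotype values) is applied last.

A causal marker may be an imperfect tag of an unobserved QTL: the QTL is
coupled to the typed marker at haplotype level with a configurable D' (and
its own allele frequency), and the trait effects apply to the QTL alleles,
so association at the typed marker is diluted by r^2 exactly as in a real
tagging design.

Every dataset is bit-reproducible from its :class:`SimConfig` (seed
included) and is accompanied by a truth table that the analysis modules
never consume.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import beta as beta_dist

from .family_io import MISSING, SEX_FEMALE, SEX_MALE, FamilySet, write_pedfile, write_phenotypes

__all__ = [
    "CausalMarker",
    "SimConfig",
    "SimResult",
    "simulate",
    "corrupt",
    "power_experiment",
    "PowerResult",
]


@dataclass(frozen=True)
class CausalMarker:
    """Trait effects attached to one typed marker (in trait-SD units).

    ``beta_additive`` multiplies the child's QTL dosage; ``beta_pat`` /
    ``beta_mat`` multiply the paternally / maternally inherited QTL allele
    count.  ``qtl_freq``/``dprime`` place an unobserved QTL in LD with the
    typed marker; by default the typed marker is the QTL (D' = 1, same
    frequency).
    """

    marker: int
    trait: str = "trait1"
    beta_additive: float = 0.0
    beta_pat: float = 0.0
    beta_mat: float = 0.0
    qtl_freq: float | None = None
    dprime: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic family dataset.

    Defaults mirror the cohort structure the analysis targets: ~400 nuclear
    families, 97% with a single child (a sibling in ~3%), per-parent
    probability 0.15 of being entirely ungenotyped, standardized traits with
    a polygenic share Vg = 0.4 and environmental share Ve = 0.6, a small sex
    effect, and ~60% of families labeled high-risk.
    """

    n_families: int = 400
    sibship_probs: tuple[float, ...] = (0.97, 0.03)  # P(1 child), P(2 children)
    n_markers: int = 100
    maf_range: tuple[float, float] = (0.01, 0.5)
    traits: tuple[str, ...] = ("trait1",)
    causal: tuple[CausalMarker, ...] = ()
    ve: float = 0.6
    vg: float = 0.4
    sex_effect: float = 0.1
    missing_genotype_rate: float = 0.01
    missing_parent_rate: float = 0.15
    missing_phenotype_rate: float = 0.01
    hrs_fraction: float = 0.6
    hrs_marker: int | None = None
    hrs_r1: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.sibship_probs) - 1) > 1e-9:
            raise ValueError("sibship probabilities must sum to 1")
        for r in (self.missing_genotype_rate, self.missing_parent_rate,
                  self.missing_phenotype_rate, self.hrs_fraction):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        for c in self.causal:
            if not 0 <= c.marker < self.n_markers:
                raise ValueError(f"causal marker index {c.marker} out of range")
            if c.trait not in self.traits:
                raise ValueError(f"causal trait {c.trait!r} not in traits")


@dataclass
class TruthTable:
    """Ground truth written alongside a simulated dataset (never consumed by
    the analysis modules): causal effects, family HRS labels, and the true
    parental origin of every child allele before missingness."""

    causal: pd.DataFrame
    families: pd.DataFrame  # fid, hrs
    child_keys: np.ndarray
    true_pat: np.ndarray  # (children, markers) a2-allele counts from father
    true_mat: np.ndarray
    mafs: np.ndarray

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        self.causal.to_csv(outdir / "truth_causal.tsv", sep="\t", index=False)
        self.families.to_csv(outdir / "truth_families.tsv", sep="\t", index=False)


@dataclass
class SimResult:
    fs: FamilySet
    truth: TruthTable
    config: SimConfig

    def write(self, outdir) -> None:
        """Write .ped/.map, phenotype TSV, truth TSVs and a config echo."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_pedfile(self.fs, outdir / "families.ped", outdir / "families.map")
        write_phenotypes(self.fs, outdir / "phenotypes.tsv")
        self.truth.write(outdir)
        cfg = asdict(self.config)
        cfg["causal"] = [asdict(c) for c in self.config.causal]
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)


def _haplotype_freqs(p_marker: float, q_qtl: float, dprime: float) -> np.ndarray:
    """Joint frequencies of (marker a2, QTL risk) haplotypes 11/10/01/00 at
    positive coupling D = D' * Dmax."""
    d_max = min(p_marker * (1 - q_qtl), (1 - p_marker) * q_qtl)
    d = dprime * d_max
    f = np.array(
        [
            p_marker * q_qtl + d,
            p_marker * (1 - q_qtl) - d,
            (1 - p_marker) * q_qtl - d,
            (1 - p_marker) * (1 - q_qtl) + d,
        ]
    )
    if (f < -1e-12).any():
        raise ValueError("inconsistent haplotype frequencies")
    return np.clip(f, 0, 1)


def simulate(config: SimConfig) -> SimResult:
    """Generate one dataset under ``config``.  Deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n_fam, n_mark = config.n_families, config.n_markers

    sizes = rng.choice(
        np.arange(1, len(config.sibship_probs) + 1), size=n_fam, p=config.sibship_probs
    )
    mafs = rng.uniform(*config.maf_range, size=n_mark)
    causal_by_marker = {c.marker: c for c in config.causal}

    # founder haplotypes: (family, parent 0/1, marker, copy) a2 indicators
    H = (rng.random((n_fam, 2, n_mark, 2)) < mafs[None, None, :, None]).astype(np.int8)
    # QTL haplotypes coupled to the typed marker
    Q = H.copy()
    for j, c in causal_by_marker.items():
        if c.qtl_freq is None and c.dprime == 1.0:
            continue
        q_qtl = mafs[j] if c.qtl_freq is None else c.qtl_freq
        f = _haplotype_freqs(mafs[j], q_qtl, c.dprime)
        # draw QTL allele conditional on the marker allele of each haplotype
        p_q_given_m1 = f[0] / max(f[0] + f[1], 1e-300)
        p_q_given_m0 = f[2] / max(f[2] + f[3], 1e-300)
        m_allele = H[:, :, j, :]
        u = rng.random(m_allele.shape)
        Q[:, :, j, :] = np.where(
            m_allele == 1, u < p_q_given_m1, u < p_q_given_m0
        ).astype(np.int8)

    # children: pick one haplotype copy from each parent per marker
    n_children = int(sizes.sum())
    fam_of_child = np.repeat(np.arange(n_fam), sizes)
    pick_pat = rng.integers(2, size=(n_children, n_mark))
    pick_mat = rng.integers(2, size=(n_children, n_mark))
    fam_col = fam_of_child[:, None]
    ar = np.arange(n_mark)[None, :]
    true_pat = H[fam_col, 0, ar, pick_pat]
    true_mat = H[fam_col, 1, ar, pick_mat]
    qtl_pat = Q[fam_col, 0, ar, pick_pat]
    qtl_mat = Q[fam_col, 1, ar, pick_mat]

    # assemble individuals: father, mother, children per family
    rows, geno_rows = [], []
    child_ptr = 0
    child_row_idx = []
    for i in range(n_fam):
        fid = f"F{i:04d}"
        fa, mo = f"{fid}_P", f"{fid}_M"
        rows.append((fid, fa, "0", "0", SEX_MALE))
        geno_rows.append(H[i, 0].sum(axis=1))
        rows.append((fid, mo, "0", "0", SEX_FEMALE))
        geno_rows.append(H[i, 1].sum(axis=1))
        for k in range(sizes[i]):
            sex = SEX_MALE if rng.random() < 0.5 else SEX_FEMALE
            rows.append((fid, f"{fid}_C{k + 1}", fa, mo, sex))
            geno_rows.append(true_pat[child_ptr] + true_mat[child_ptr])
            child_row_idx.append(len(rows) - 1)
            child_ptr += 1
    individuals = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"])
    geno = np.asarray(geno_rows, dtype=np.int8)
    child_row_idx = np.asarray(child_row_idx)

    markers = pd.DataFrame(
        {
            "marker_id": [f"rs{j + 1:06d}" for j in range(n_mark)],
            "chrom": ["1"] * n_mark,
            "cm": np.zeros(n_mark),
            "pos": np.arange(1, n_mark + 1) * 1000,
            "a1": ["A"] * n_mark,
            "a2": ["B"] * n_mark,
        }
    )

    # HRS labels per family, optionally driven by a child genotype
    if config.hrs_marker is not None and config.hrs_r1 != 1.0:
        j = config.hrs_marker
        first_child = np.cumsum(sizes) - sizes  # index of each family's first child
        g_fam = (true_pat + true_mat)[first_child, j]
        p_g = np.array([(1 - mafs[j]) ** 2, 2 * mafs[j] * (1 - mafs[j]), mafs[j] ** 2])
        norm = float(p_g @ config.hrs_r1 ** np.arange(3))
        p_hrs = np.clip(config.hrs_fraction * config.hrs_r1 ** g_fam / norm, 0, 1)
        hrs_fam = (rng.random(n_fam) < p_hrs).astype(float)
    else:
        hrs_fam = (rng.random(n_fam) < config.hrs_fraction).astype(float)

    # traits on children only
    sex_child = individuals["sex"].to_numpy()[child_row_idx]
    sex01 = (sex_child == SEX_MALE).astype(float)
    shared = rng.normal(0, np.sqrt(config.vg / 2), size=n_fam)[fam_of_child]
    phen = pd.DataFrame(index=range(len(individuals)), dtype=float)
    causal_rows = []
    for trait in config.traits:
        own = rng.normal(0, np.sqrt(config.vg / 2), size=n_children)
        env = rng.normal(0, np.sqrt(config.ve), size=n_children)
        y = config.sex_effect * sex01 + shared + own + env
        for c in config.causal:
            if c.trait != trait:
                continue
            y = (
                y
                + c.beta_additive * (qtl_pat[:, c.marker] + qtl_mat[:, c.marker])
                + c.beta_pat * qtl_pat[:, c.marker]
                + c.beta_mat * qtl_mat[:, c.marker]
            )
        col = np.full(len(individuals), np.nan)
        col[child_row_idx] = y
        phen[trait] = col
    for c in config.causal:
        q = mafs[c.marker] if c.qtl_freq is None else c.qtl_freq
        var_qtl = ((c.beta_additive + c.beta_pat) ** 2 + (c.beta_additive + c.beta_mat) ** 2) * q * (1 - q)
        causal_rows.append(
            {
                "marker_id": markers["marker_id"].iloc[c.marker],
                "trait": c.trait,
                "beta_additive": c.beta_additive,
                "beta_pat": c.beta_pat,
                "beta_mat": c.beta_mat,
                "qtl_freq": q,
                "dprime": c.dprime,
                "h2": var_qtl / (var_qtl + config.vg + config.ve),
            }
        )

    sex_cov = np.where(individuals["sex"].to_numpy() == SEX_MALE, 1.0, 0.0)
    phen["sex"] = sex_cov
    hrs_col = np.full(len(individuals), np.nan)
    hrs_col[child_row_idx] = hrs_fam[fam_of_child]
    phen["hrs"] = hrs_col

    # missingness: ungenotyped parents, sporadic calls, phenotype values
    parent_rows = np.where((individuals["father"] == "0").to_numpy())[0]
    drop_parent = parent_rows[rng.random(len(parent_rows)) < config.missing_parent_rate]
    geno[drop_parent] = MISSING
    if config.missing_genotype_rate > 0:
        mask = rng.random(geno.shape) < config.missing_genotype_rate
        geno[mask] = MISSING
    if config.missing_phenotype_rate > 0:
        for trait in config.traits:
            col = phen[trait].to_numpy()
            drop = (rng.random(len(col)) < config.missing_phenotype_rate) & ~np.isnan(col)
            col[drop] = np.nan
            phen[trait] = col

    fs = FamilySet(individuals, markers, geno, phen)
    truth = TruthTable(
        causal=pd.DataFrame(
            causal_rows,
            columns=["marker_id", "trait", "beta_additive", "beta_pat", "beta_mat",
                     "qtl_freq", "dprime", "h2"],
        ),
        families=pd.DataFrame({"fid": [f"F{i:04d}" for i in range(n_fam)], "hrs": hrs_fam}),
        child_keys=fs.keys()[child_row_idx],
        true_pat=true_pat,
        true_mat=true_mat,
        mafs=mafs,
    )
    return SimResult(fs=fs, truth=truth, config=config)


# ---------------------------------------------------------------------------
# QC fixtures


def corrupt(
    fs: FamilySet,
    mendelian_error_rate: float = 0.0,
    mendelian_targets=None,
    outlier_individuals=(),
    seed: int = 0,
) -> tuple[FamilySet, dict]:
    """Plant QC defects into a copy of ``fs`` and return a manifest.

    ``mendelian_error_rate``: fraction of each target child's markers to
    corrupt into Mendelian-impossible calls (only markers where a parental
    genotype makes an impossible call constructible are used).
    ``mendelian_targets``: child keys (``fid:iid``); default all children.
    ``outlier_individuals``: keys whose genotypes are set fully heterozygous
    (heterozygosity rate 1.0).
    """
    rng = np.random.default_rng(seed)
    geno = fs.genotypes.copy()
    keys = fs.keys()
    key_to_row = {k: i for i, k in enumerate(keys)}
    manifest = {"mendelian": [], "outliers": list(outlier_individuals)}

    if mendelian_error_rate > 0:
        if mendelian_targets is None:
            mendelian_targets = keys[fs.child_mask]
        for key in mendelian_targets:
            row = key_to_row[key]
            fa, mo = fs.father_pos[row], fs.mother_pos[row]
            F = geno[fa] if fa >= 0 else np.full(fs.n_markers, MISSING, dtype=np.int8)
            M = geno[mo] if mo >= 0 else np.full(fs.n_markers, MISSING, dtype=np.int8)
            # markers where an impossible child call exists given the parents
            can_low = (F == 2) | (M == 2)   # child 0 impossible
            can_high = (F == 0) | (M == 0)  # child 2 impossible
            usable = np.where(can_low | can_high)[0]
            n_plant = int(round(mendelian_error_rate * fs.n_markers))
            chosen = rng.choice(usable, size=min(n_plant, len(usable)), replace=False)
            for j in chosen:
                geno[row, j] = 0 if can_low[j] else 2
                manifest["mendelian"].append((key, fs.markers["marker_id"].iloc[j]))

    for key in outlier_individuals:
        geno[key_to_row[key]] = 1

    out = FamilySet(fs.individuals, fs.markers, geno, fs.phenotypes)
    return out, manifest


# ---------------------------------------------------------------------------
# power


@dataclass
class PowerResult:
    power: float
    ci_low: float
    ci_high: float
    n_replicates: int
    n_significant: int
    alpha: float


def power_experiment(
    n_families: int = 480,
    h2: float = 0.1,
    q: float = 0.5,
    dprime: float = 1.0,
    alpha: float = 0.001,
    mode: str = "general",
    n_replicates: int = 1000,
    seed: int = 0,
) -> PowerResult:
    """Monte-Carlo power of one association test mode.

    Each replicate simulates ``n_families`` one-child families with both
    parents genotyped and a single typed marker tagging (at the given D')
    a QTL of frequency ``q`` explaining ``h2`` of the variance of a
    standard-normal trait, then runs the test and records p <= alpha.
    Reports the rejection fraction with a Clopper-Pearson 95% CI.
    """
    from .transmission import build_transmission_table
    from .vc_assoc import fit_model

    beta = np.sqrt(h2 / (2 * q * (1 - q)))
    base = SimConfig(
        n_families=n_families,
        sibship_probs=(1.0,),
        n_markers=1,
        maf_range=(q, q),
        causal=(CausalMarker(marker=0, beta_additive=beta, qtl_freq=q, dprime=dprime),),
        ve=1 - h2,
        vg=0.0,
        sex_effect=0.0,
        missing_genotype_rate=0.0,
        missing_parent_rate=0.0,
        missing_phenotype_rate=0.0,
        seed=0,
    )
    sub_seeds = np.random.default_rng(seed).integers(2**31, size=n_replicates)
    hits = 0
    for s in sub_seeds:
        sim = simulate(replace(base, seed=int(s)))
        tt = build_transmission_table(sim.fs)
        res = fit_model(sim.fs, tt, "trait1", mode, marker=0)
        if res.testable and res.p <= alpha:
            hits += 1
    lo = beta_dist.ppf(0.025, hits, n_replicates - hits + 1) if hits > 0 else 0.0
    hi = beta_dist.ppf(0.975, hits + 1, n_replicates - hits) if hits < n_replicates else 1.0
    return PowerResult(
        power=hits / n_replicates,
        ci_low=float(lo),
        ci_high=float(hi),
        n_replicates=n_replicates,
        n_significant=hits,
        alpha=alpha,
    )
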