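"""Pedigree/genotype I/O and the sample/marker quality-control cascade.

The canonical input dialect is PLINK-style text: a ``.ped`` file with six
leading columns (family ID, individual ID, father ID, mother ID, sex,
phenotype placeholder) followed by two allele columns per marker, and a
``.map`` file with one row per marker (chromosome, marker ID, genetic
position in cM, physical position in bp).  Missing alleles are coded ``0``.

QC follows a fixed cascade on nuclear-family data:

1. :func:`mendelian_screen`  -- remove individuals/markers with an excess of
   Mendelian-impossible transmissions, then blank residual inconsistencies;
2. :func:`marker_qc`         -- per-marker missingness, founder Hardy-Weinberg
   exact test and founder minor-allele frequency;
3. :func:`heterozygosity_outliers` -- per-individual heterozygosity-rate
   outliers (mean +/- k SD);
4. :func:`dedupe_positions`  -- one survivor per duplicated physical position.

Genotypes are stored as the per-individual count of the marker's ``a2``
allele (alleles ordered alphabetically), with ``-1`` for a missing call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING = -1
SEX_UNKNOWN, SEX_MALE, SEX_FEMALE = 0, 1, 2

__all__ = [
    "FamilySet",
    "QcReport",
    "PedFormatError",
    "PedValidationError",
    "read_pedfile",
    "write_pedfile",
    "read_phenotypes",
    "write_phenotypes",
    "mendelian_screen",
    "marker_qc",
    "heterozygosity_outliers",
    "dedupe_positions",
    "qc_cascade",
    "hwe_exact_pvalue",
    "founder_allele_stats",
    "mendelian_error_mask",
]


class PedFormatError(ValueError):
    """Malformed .ped/.map content (column counts, allele codes, ...)."""


class PedValidationError(ValueError):
    """Structurally invalid pedigree (duplicate IDs, bad references, ...)."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class FamilySet:
    """A set of nuclear families with attached genotypes and phenotypes.

    Attributes
    ----------
    individuals
        One row per individual: ``fid``, ``iid``, ``father``, ``mother``
        (``"0"`` when absent), ``sex`` (0 unknown / 1 male / 2 female).
    markers
        One row per marker: ``marker_id``, ``chrom``, ``cm``, ``pos``,
        ``a1``, ``a2`` (allele labels, alphabetical), and after
        :func:`marker_qc` also ``maf_founders`` and ``minor_is_a2``.
    genotypes
        ``int8`` array of shape (n individuals, n markers) holding the
        count of the ``a2`` allele, ``-1`` = missing call.
    phenotypes
        Optional frame aligned positionally with ``individuals``; numeric
        trait columns plus the ``sex`` covariate (female=0, male=1) and any
        extra covariates such as ``hrs``.
    """

    individuals: pd.DataFrame
    markers: pd.DataFrame
    genotypes: np.ndarray
    phenotypes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.individuals = self.individuals.reset_index(drop=True)
        self.markers = self.markers.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.individuals), len(self.markers)):
            raise PedValidationError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        if self.phenotypes is not None:
            self.phenotypes = self.phenotypes.reset_index(drop=True)
            if len(self.phenotypes) != len(self.individuals):
                raise PedValidationError("phenotype rows do not align with individuals")
        self._resolve_parents()

    # -- pedigree structure -------------------------------------------------

    def _resolve_parents(self) -> None:
        ind = self.individuals
        keys = list(zip(ind["fid"], ind["iid"]))
        if len(set(keys)) != len(keys):
            dup = pd.Series(keys).value_counts()
            bad = dup[dup > 1].index[0]
            raise PedValidationError(f"duplicate individual ID within family: {bad}")
        lookup = {k: i for i, k in enumerate(keys)}
        n = len(ind)
        father = np.full(n, -1, dtype=np.int64)
        mother = np.full(n, -1, dtype=np.int64)
        for i, (fid, fa, mo) in enumerate(zip(ind["fid"], ind["father"], ind["mother"])):
            if fa != "0":
                father[i] = lookup.get((fid, fa), -1)
            if mo != "0":
                mother[i] = lookup.get((fid, mo), -1)
        if (father == np.arange(n)).any() or (mother == np.arange(n)).any():
            raise PedValidationError("an individual lists itself as its own parent")
        self.father_pos = father
        self.mother_pos = mother

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def keys(self) -> np.ndarray:
        """``fid:iid`` labels, positionally aligned with rows."""
        return (self.individuals["fid"] + ":" + self.individuals["iid"]).to_numpy()

    @property
    def founder_mask(self) -> np.ndarray:
        """Individuals with no resolvable parent row (PLINK founder semantics)."""
        return (self.father_pos < 0) & (self.mother_pos < 0)

    @property
    def child_mask(self) -> np.ndarray:
        """Individuals that list at least one parent in the pedigree."""
        listed = (self.individuals["father"] != "0") | (self.individuals["mother"] != "0")
        return listed.to_numpy()

    def parent_dosages(self, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(father, mother) dosage rows for ``rows``; missing row -> all ``-1``."""
        out = []
        for pos in (self.father_pos[rows], self.mother_pos[rows]):
            g = np.full((len(rows), self.n_markers), MISSING, dtype=np.int8)
            ok = pos >= 0
            g[ok] = self.genotypes[pos[ok]]
            out.append(g)
        return out[0], out[1]

    # -- subsetting ---------------------------------------------------------

    def subset_individuals(self, keep: np.ndarray) -> "FamilySet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.where(keep)[0]
        phen = self.phenotypes.iloc[keep] if self.phenotypes is not None else None
        return FamilySet(
            self.individuals.iloc[keep],
            self.markers,
            self.genotypes[keep],
            phen,
        )

    def subset_markers(self, keep: np.ndarray) -> "FamilySet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.where(keep)[0]
        return FamilySet(
            self.individuals,
            self.markers.iloc[keep],
            self.genotypes[:, keep],
            self.phenotypes,
        )


@dataclass
class QcReport:
    """Record of one QC stage: what was removed and why."""

    stage: str
    removed_individuals: list = field(default_factory=list)  # (key, reason, value, threshold)
    removed_markers: list = field(default_factory=list)
    genotypes_set_missing: int = 0
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("individual", k, r, v, t) for (k, r, v, t) in self.removed_individuals
        ] + [("marker", k, r, v, t) for (k, r, v, t) in self.removed_markers]
        return pd.DataFrame(rows, columns=["kind", "entity", "reason", "value", "threshold"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# file I/O


def read_pedfile(ped_path, map_path) -> FamilySet:
    """Read a PLINK-text .ped/.map pair into a :class:`FamilySet`.

    Allele code ``0`` on either side of a call marks the whole call missing;
    sex codes 1/2 map to male/female and anything else to unknown.  Each
    marker must be biallelic; allele labels are ordered alphabetically so a
    write/read round trip is stable.
    """
    mk = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str, comment="#")
    if mk.shape[1] < 4:
        raise PedFormatError(f"{map_path}: expected 4 columns (chrom id cM pos)")
    markers = pd.DataFrame(
        {
            "marker_id": mk[1],
            "chrom": mk[0],
            "cm": mk[2].astype(float),
            "pos": mk[3].astype(np.int64),
        }
    )
    if (markers["pos"] <= 0).any():
        raise PedFormatError(f"{map_path}: positions must be positive")
    m = len(markers)

    rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise PedFormatError(
                    f"{ped_path}: row {lineno} has {len(parts)} columns, "
                    f"expected {6 + 2 * m} for {m} markers"
                )
            rows.append(parts)
    if not rows:
        raise PedFormatError(f"{ped_path}: empty file")
    arr = np.array(rows, dtype=object)
    sex_raw = arr[:, 4]
    sex = np.where(sex_raw == "1", SEX_MALE, np.where(sex_raw == "2", SEX_FEMALE, SEX_UNKNOWN))
    individuals = pd.DataFrame(
        {
            "fid": arr[:, 0],
            "iid": arr[:, 1],
            "father": arr[:, 2],
            "mother": arr[:, 3],
            "sex": sex.astype(np.int8),
        }
    )
    alleles = arr[:, 6:].reshape(len(arr), m, 2)
    geno = np.full((len(arr), m), MISSING, dtype=np.int8)
    a1_list, a2_list = [], []
    for j in range(m):
        pair = alleles[:, j, :]
        called = (pair[:, 0] != "0") & (pair[:, 1] != "0")
        labels = sorted(set(pair[called].ravel()))
        if len(labels) > 2:
            raise PedFormatError(
                f"marker {markers['marker_id'][j]} has >2 alleles: {labels}"
            )
        a1 = labels[0] if labels else "0"
        a2 = labels[1] if len(labels) > 1 else "0"
        a1_list.append(a1)
        a2_list.append(a2)
        if labels:
            geno[called, j] = (pair[called] == a2).sum(axis=1)
    markers["a1"] = a1_list
    markers["a2"] = a2_list
    return FamilySet(individuals, markers, geno)


def write_pedfile(fs: FamilySet, ped_path, map_path) -> None:
    """Write a :class:`FamilySet` back to PLINK-text .ped/.map."""
    mk = fs.markers
    with open(map_path, "w") as fh:
        for _, r in mk.iterrows():
            fh.write(f"{r['chrom']}\t{r['marker_id']}\t{r['cm']:g}\t{r['pos']}\n")
    sex_out = {SEX_MALE: "1", SEX_FEMALE: "2", SEX_UNKNOWN: "0"}
    a1 = mk["a1"].to_numpy()
    a2 = mk["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, row in fs.individuals.iterrows():
            g = fs.genotypes[i]
            calls = np.empty((fs.n_markers, 2), dtype=object)
            calls[g == 0] = np.stack([a1, a1], axis=1)[g == 0]
            calls[g == 1] = np.stack([a1, a2], axis=1)[g == 1]
            calls[g == 2] = np.stack([a2, a2], axis=1)[g == 2]
            calls[g == MISSING] = ["0", "0"]
            fields = [row["fid"], row["iid"], row["father"], row["mother"],
                      sex_out[int(row["sex"])], "-9"]
            fields.extend(calls.ravel())
            fh.write(" ".join(fields) + "\n")


def read_phenotypes(path, fs: FamilySet | None = None) -> pd.DataFrame:
    """Read a tab-delimited phenotype table (``FID IID trait... [SEX]``).

    Missing values are coded ``NA``.  When ``fs`` is given the result is
    aligned positionally with ``fs.individuals`` (and also attached to it);
    table rows for individuals absent from the pedigree are dropped with a
    warning.  The returned frame always carries a numeric ``sex`` covariate
    column (female=0, male=1), taken from the ``SEX`` column when present and
    otherwise derived from the pedigree sex codes.
    """
    tab = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, na_values=["NA"])
    cols = list(tab.columns)
    if cols[:2] != ["FID", "IID"]:
        raise PedFormatError(f"{path}: header must start with 'FID\\tIID'")
    value_cols = [c for c in cols[2:] if c != "SEX"]
    if fs is None:
        return tab
    key = pd.MultiIndex.from_frame(tab[["FID", "IID"]])
    ped_key = pd.MultiIndex.from_frame(fs.individuals[["fid", "iid"]])
    extra = ~key.isin(ped_key)
    if extra.any():
        warnings.warn(
            f"{int(extra.sum())} phenotype rows refer to individuals not in the "
            "pedigree and were dropped"
        )
        tab = tab[~extra]
        key = key[~extra]
    aligned = tab.set_index(key).reindex(ped_key)
    phen = aligned[value_cols].astype(float).reset_index(drop=True)
    if "SEX" in cols:
        phen["sex"] = aligned["SEX"].to_numpy(dtype=float)
    else:
        sx = fs.individuals["sex"].to_numpy()
        phen["sex"] = np.where(sx == SEX_MALE, 1.0, np.where(sx == SEX_FEMALE, 0.0, np.nan))
    fs.phenotypes = phen.reset_index(drop=True)
    return fs.phenotypes


def write_phenotypes(fs: FamilySet, path) -> None:
    if fs.phenotypes is None:
        raise ValueError("FamilySet carries no phenotypes")
    out = fs.phenotypes.copy()
    sex = out.pop("sex")
    out.insert(0, "IID", fs.individuals["iid"].to_numpy())
    out.insert(0, "FID", fs.individuals["fid"].to_numpy())
    out["SEX"] = sex
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Mendelian screen


def mendelian_error_mask(C: np.ndarray, F: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Boolean mask of Mendelian-impossible (child, marker) configurations.

    ``C``/``F``/``M`` are dosage arrays (count of the a2 allele, -1 missing)
    for children and their father/mother rows.  A configuration is impossible
    when a called child cannot have received one allele from each called
    parent (missing parents constrain nothing).
    """
    err = np.zeros(C.shape, dtype=bool)
    cf = (C >= 0) & (F >= 0)
    cm = (C >= 0) & (M >= 0)
    err |= cf & (((C == 0) & (F == 2)) | ((C == 2) & (F == 0)))
    err |= cm & (((C == 0) & (M == 2)) | ((C == 2) & (M == 0)))
    both = cf & cm
    err |= both & (C == 1) & (((F == 0) & (M == 0)) | ((F == 2) & (M == 2)))
    return err


def _mendelian_tables(fs: FamilySet):
    child_rows = np.where(fs.child_mask)[0]
    C = fs.genotypes[child_rows]
    F, M = fs.parent_dosages(child_rows)
    err = mendelian_error_mask(C, F, M)
    return child_rows, C, F, M, err


def mendelian_screen(fs: FamilySet, max_rate: float = 0.01) -> tuple[FamilySet, QcReport]:
    """Remove individuals/markers with Mendelian-error rates above ``max_rate``
    and set the remaining inconsistent genotypes (child and both parents at
    the offending marker) to missing.

    Rates are computed over informative parent-child comparisons only: a
    (child, marker) comparison is informative when the child and at least one
    parent are called.  Each inconsistency is attributed to the child of the
    comparison (parents are screened through their own marker-level QC).
    """
    report = QcReport("mendelian_screen", thresholds={"max_rate": max_rate})
    child_rows, C, F, M, err = _mendelian_tables(fs)

    for fid, grp in fs.individuals.groupby("fid", sort=False):
        if (fs.genotypes[grp.index.to_numpy()] < 0).all():
            warnings.warn(f"family {fid} has no genotyped members; skipped")

    n = fs.n_individuals
    ind_err = np.zeros(n)
    ind_cmp = np.zeros(n)
    comp_child = (C >= 0) & ((F >= 0) | (M >= 0))
    ind_err[child_rows] += err.sum(axis=1)
    ind_cmp[child_rows] += comp_child.sum(axis=1)

    with np.errstate(invalid="ignore"):
        ind_rate = np.where(ind_cmp > 0, ind_err / np.maximum(ind_cmp, 1), 0.0)
        mk_cmp = comp_child.sum(axis=0)
        mk_rate = np.where(mk_cmp > 0, err.sum(axis=0) / np.maximum(mk_cmp, 1), 0.0)

    drop_ind = ind_rate > max_rate
    keys = fs.keys()
    for i in np.where(drop_ind)[0]:
        report.removed_individuals.append((keys[i], "mendelian_errors", float(ind_rate[i]), max_rate))
    drop_mk = mk_rate > max_rate
    for j in np.where(drop_mk)[0]:
        report.removed_markers.append(
            (fs.markers["marker_id"].iloc[j], "mendelian_errors", float(mk_rate[j]), max_rate)
        )

    out = fs.subset_individuals(~drop_ind).subset_markers(~drop_mk)

    # blank residual inconsistencies on the surviving data
    child_rows, C, F, M, err = _mendelian_tables(out)
    if err.any():
        geno = out.genotypes.copy()
        ci, mj = np.nonzero(err)
        n_blanked = 0
        for i, j in zip(ci, mj):
            for row in (child_rows[i], out.father_pos[child_rows[i]], out.mother_pos[child_rows[i]]):
                if row >= 0 and geno[row, j] != MISSING:
                    geno[row, j] = MISSING
                    n_blanked += 1
        out.genotypes = geno
        report.genotypes_set_missing = n_blanked
    return out, report


# ---------------------------------------------------------------------------
# marker QC


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value for biallelic genotype counts.

    Sums, over all heterozygote counts compatible with the observed allele
    count, the conditional probabilities no larger than that of the observed
    configuration (standard exact HWE test, no mid-p correction).
    """
    n_het, n_hom1, n_hom2 = int(n_het), int(n_hom1), int(n_hom2)
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    ks = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    # log P(het = k | n, rare) up to a shared constant
    logp = (
        ks * np.log(2)
        - gammaln((rare - ks) / 2 + 1)
        - gammaln((2 * n - rare - ks) / 2 + 1)
        - gammaln(ks + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[np.searchsorted(ks, n_het)]
    return float(p[p <= p_obs * (1 + 1e-12)].sum())


def founder_allele_stats(fs: FamilySet) -> pd.DataFrame:
    """Per-marker founder genotype counts, founder MAF and minor-allele side."""
    G = fs.genotypes[fs.founder_mask]
    n0 = (G == 0).sum(axis=0)
    n1 = (G == 1).sum(axis=0)
    n2 = (G == 2).sum(axis=0)
    tot = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a2 = np.where(tot > 0, (2 * n2 + n1) / (2 * np.maximum(tot, 1)), np.nan)
    maf = np.minimum(p_a2, 1 - p_a2)
    return pd.DataFrame(
        {
            "n_hom_a1": n0,
            "n_het": n1,
            "n_hom_a2": n2,
            "n_called": tot,
            "freq_a2": p_a2,
            "maf_founders": maf,
            "minor_is_a2": p_a2 <= 0.5,
        }
    )


def marker_qc(
    fs: FamilySet,
    max_missing: float = 0.05,
    hwe_alpha: float = 1e-6,
    min_maf: float = 0.01,
) -> tuple[FamilySet, QcReport]:
    """Remove markers failing missingness, founder-HWE or founder-MAF
    thresholds; annotate survivors with ``maf_founders``/``minor_is_a2``.

    Each removal carries exactly one primary reason, checked in the order
    missingness -> no founder data -> HWE -> MAF.
    """
    report = QcReport(
        "marker_qc",
        thresholds={"max_missing": max_missing, "hwe_alpha": hwe_alpha, "min_maf": min_maf},
    )
    # missingness over genotyped individuals only: entirely ungenotyped
    # samples (e.g. parents without DNA) do not count against markers
    genotyped = (fs.genotypes >= 0).any(axis=1)
    if genotyped.any():
        miss = (fs.genotypes[genotyped] < 0).mean(axis=0)
    else:
        miss = np.ones(fs.n_markers)
    stats = founder_allele_stats(fs)
    ids = fs.markers["marker_id"].to_numpy()
    keep = np.ones(fs.n_markers, dtype=bool)
    hwe_p = np.full(fs.n_markers, np.nan)
    for j in range(fs.n_markers):
        if miss[j] > max_missing:
            keep[j] = False
            report.removed_markers.append((ids[j], "missingness", float(miss[j]), max_missing))
            continue
        if stats["n_called"].iloc[j] == 0:
            keep[j] = False
            report.removed_markers.append((ids[j], "no founder data", 0.0, np.nan))
            continue
        p = hwe_exact_pvalue(
            stats["n_het"].iloc[j], stats["n_hom_a1"].iloc[j], stats["n_hom_a2"].iloc[j]
        )
        hwe_p[j] = p
        if p < hwe_alpha:
            keep[j] = False
            report.removed_markers.append((ids[j], "hwe", p, hwe_alpha))
            continue
        if stats["maf_founders"].iloc[j] < min_maf:
            keep[j] = False
            report.removed_markers.append(
                (ids[j], "maf", float(stats["maf_founders"].iloc[j]), min_maf)
            )
    out = fs.subset_markers(keep)
    out.markers = out.markers.assign(
        maf_founders=stats["maf_founders"].to_numpy()[keep],
        minor_is_a2=stats["minor_is_a2"].to_numpy()[keep],
        hwe_p=hwe_p[keep],
    )
    return out, report


def heterozygosity_outliers(
    fs: FamilySet, sd_window: float = 3.0
) -> tuple[FamilySet, QcReport]:
    """Remove individuals whose heterozygosity rate lies outside
    mean +/- ``sd_window``*SD of the sample (population SD).

    With fewer than 3 individuals, or a degenerate zero SD, nobody is removed.
    """
    report = QcReport("heterozygosity_outliers", thresholds={"sd_window": sd_window})
    if fs.n_individuals < 3:
        warnings.warn("fewer than 3 individuals; heterozygosity screen skipped")
        return fs, report
    called = (fs.genotypes >= 0).sum(axis=1)
    het = (fs.genotypes == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        rate = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    valid = ~np.isnan(rate)
    if valid.sum() < 3:
        warnings.warn("fewer than 3 genotyped individuals; heterozygosity screen skipped")
        return fs, report
    mu = rate[valid].mean()
    sd = rate[valid].std()
    if sd == 0:
        return fs, report
    out_mask = valid & (np.abs(rate - mu) > sd_window * sd)
    keys = fs.keys()
    for i in np.where(out_mask)[0]:
        report.removed_individuals.append((keys[i], "heterozygosity", float(rate[i]), sd_window))
    return fs.subset_individuals(~out_mask), report


def dedupe_positions(fs: FamilySet) -> tuple[FamilySet, QcReport]:
    """Keep one marker per duplicated (chromosome, position).

    When the allele codes of a duplicate pair match, the first-listed marker
    survives; otherwise a marker with an rs-prefixed ID is prioritized, ties
    broken by listing order.
    """
    report = QcReport("dedupe_positions")
    mk = fs.markers
    keep = np.ones(len(mk), dtype=bool)
    ids = mk["marker_id"].to_numpy()
    for (_, _), idx in mk.groupby(["chrom", "pos"], sort=False).indices.items():
        if len(idx) < 2:
            continue
        idx = np.sort(idx)
        allele_sets = {frozenset((mk["a1"].iloc[i], mk["a2"].iloc[i])) for i in idx}
        if len(allele_sets) == 1:
            survivor = idx[0]
        else:
            rs = [i for i in idx if ids[i].startswith("rs")]
            survivor = rs[0] if rs else idx[0]
        for i in idx:
            if i != survivor:
                keep[i] = False
                report.removed_markers.append((ids[i], "duplicate position", float(mk["pos"].iloc[i]), np.nan))
    return fs.subset_markers(keep), report


def qc_cascade(
    fs: FamilySet,
    mendel_max_rate: float = 0.01,
    max_missing: float = 0.05,
    hwe_alpha: float = 1e-6,
    min_maf: float = 0.01,
    het_sd_window: float = 3.0,
) -> tuple[FamilySet, list[QcReport]]:
    """Run the full fixed-order QC cascade and collect the stage reports."""
    reports = []
    fs, rep = mendelian_screen(fs, mendel_max_rate)
    reports.append(rep)
    fs, rep = marker_qc(fs, max_missing, hwe_alpha, min_maf)
    reports.append(rep)
    fs, rep = heterozygosity_outliers(fs, het_sd_window)
    reports.append(rep)
    fs, rep = dedupe_positions(fs)
    reports.append(rep)
    return fs, reports
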