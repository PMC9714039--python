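"""Pedigree I/O and QC cascade behavior."""

import warnings
from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest

from famgwas import family_io
from famgwas.family_io import (
    MISSING,
    FamilySet,
    PedFormatError,
    PedValidationError,
    dedupe_positions,
    heterozygosity_outliers,
    hwe_exact_pvalue,
    marker_qc,
    mendelian_screen,
    qc_cascade,
    read_pedfile,
    read_phenotypes,
    write_pedfile,
)
from famgwas.synthdata import SimConfig, corrupt, simulate

from conftest import make_family_set, make_trio


# ---------------------------------------------------------------------------
# file I/O


def test_ped_roundtrip_trio(tmp_path):
    """A fully called trio survives a write/read cycle unchanged, and '0 0'
    allele pairs come back as missing calls."""
    fs = make_family_set(
        [
            ("F1", "dad", "0", "0", 1),
            ("F1", "mum", "0", "0", 2),
            ("F1", "kid", "dad", "mum", 2),
        ],
        [[0, 1], [2, 1], [1, MISSING]],
    )
    write_pedfile(fs, tmp_path / "x.ped", tmp_path / "x.map")
    back = read_pedfile(tmp_path / "x.ped", tmp_path / "x.map")
    assert back.n_individuals == 3
    assert back.n_markers == 2
    assert np.array_equal(back.genotypes, fs.genotypes)
    assert back.genotypes[2, 1] == MISSING
    assert list(back.individuals["sex"]) == [1, 2, 2]
    assert back.father_pos[2] == 0 and back.mother_pos[2] == 1


def test_ped_roundtrip_synthetic_cohort(tmp_path):
    """A full synthetic cohort (hundreds of families, missing parents and
    sporadic missing calls) round-trips to a bit-identical genotype matrix."""
    sim = simulate(SimConfig(n_families=400, n_markers=60, seed=11))
    sim.write(tmp_path)
    back = read_pedfile(tmp_path / "families.ped", tmp_path / "families.map")
    assert np.array_equal(back.genotypes, sim.fs.genotypes)
    assert list(back.markers["marker_id"]) == list(sim.fs.markers["marker_id"])
    phen = read_phenotypes(tmp_path / "phenotypes.tsv", back)
    orig = sim.fs.phenotypes["trait1"].to_numpy()
    assert np.allclose(phen["trait1"].to_numpy(), orig, equal_nan=True)


def test_ped_format_errors(tmp_path):
    (tmp_path / "x.map").write_text("1 m1 0 1000\n1 m2 0 2000\n")
    (tmp_path / "bad.ped").write_text("F1 kid 0 0 1 -9 A B\n")  # one marker short
    with pytest.raises(PedFormatError, match="row 1"):
        read_pedfile(tmp_path / "bad.ped", tmp_path / "x.map")
    (tmp_path / "dup.ped").write_text(
        "F1 kid 0 0 1 -9 A B A A\nF1 kid 0 0 2 -9 A A B B\n"
    )
    with pytest.raises(PedValidationError, match="duplicate"):
        read_pedfile(tmp_path / "dup.ped", tmp_path / "x.map")


# ---------------------------------------------------------------------------
# Mendelian screen


def test_mendelian_impossible_transmission_blanked():
    """One child AA with both parents BB is one detected error; below the
    removal threshold it leads to the trio's genotypes at that marker being
    set missing, leaving everything else untouched."""
    ind, geno = [], []
    for i in range(30):
        fid = f"F{i}"
        ind += [(fid, "d", "0", "0", 1), (fid, "m", "0", "0", 2), (fid, "k", "d", "m", 1)]
        geno += [[1] * 40, [1] * 40, [1] * 40]
    geno = np.array(geno, dtype=np.int8)
    geno[0, 0], geno[1, 0], geno[2, 0] = 2, 2, 0  # child AA, parents BB
    fs = make_family_set(ind, geno)
    out, report = mendelian_screen(fs, max_rate=0.05)
    assert report.removed_individuals == []
    assert report.removed_markers == []
    assert report.genotypes_set_missing == 3
    assert (out.genotypes[:3, 0] == MISSING).all()
    assert (out.genotypes[3:, :] != MISSING).all()
    assert (out.genotypes[:3, 1:] != MISSING).all()


def test_mendelian_forced_transmission_clean():
    fs = make_trio(child=1, father=0, mother=2)
    out, report = mendelian_screen(fs)
    assert report.genotypes_set_missing == 0
    assert np.array_equal(out.genotypes, fs.genotypes)


def test_mendelian_corrupted_individual_removed():
    """An individual with ~2% planted impossible calls exceeds the 1%
    threshold and is removed; the manifest recount matches the report."""
    sim = simulate(SimConfig(n_families=150, n_markers=200, seed=5,
                             missing_parent_rate=0.0, missing_genotype_rate=0.0))
    target = sim.fs.keys()[sim.fs.child_mask][0]
    bad, manifest = corrupt(sim.fs, mendelian_error_rate=0.02,
                            mendelian_targets=[target], seed=9)
    assert len(manifest["mendelian"]) == 4  # 2% of 200
    out, report = mendelian_screen(bad, max_rate=0.01)
    removed = [k for k, *_ in report.removed_individuals]
    assert removed == [target]
    assert not report.removed_markers  # 1 error per marker over ~150 comparisons


# ---------------------------------------------------------------------------
# HWE exact test


def hwe_oracle(n_het, n_hom1, n_hom2):
    """Exact-rational enumeration over all heterozygote counts at fixed
    allele count (independent of the implementation)."""
    n = n_het + n_hom1 + n_hom2
    n_a = 2 * n_hom1 + n_het
    rare = min(n_a, 2 * n - n_a)

    def weight(k):
        na, nb = (rare - k) // 2, (2 * n - rare - k) // 2
        return Fraction(
            factorial(n) * 2**k * factorial(rare) * factorial(2 * n - rare),
            factorial(na) * factorial(nb) * factorial(k) * factorial(2 * n),
        )

    ks = list(range(rare % 2, min(rare, 2 * n - rare) + 1, 2))
    probs = {k: weight(k) for k in ks}
    total = sum(probs.values())
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs) / total)


@pytest.mark.parametrize(
    "counts",
    [
        (50, 25, 25),  # the canonical balanced configuration
        (0, 50, 50),
        (10, 1, 89),
        (57, 14, 50),
        (1, 0, 199),
        (100, 0, 0),
        (3, 2, 1),
    ],
)
def test_hwe_exact_matches_enumeration_oracle(counts):
    het, h1, h2 = counts
    assert hwe_exact_pvalue(het, h1, h2) == pytest.approx(hwe_oracle(het, h1, h2), abs=1e-12)


def test_hwe_random_counts_match_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(2, 200))
        g = rng.multinomial(n, [0.25, 0.5, 0.25])
        assert hwe_exact_pvalue(g[1], g[0], g[2]) == pytest.approx(
            hwe_oracle(g[1], g[0], g[2]), abs=1e-12
        )


# ---------------------------------------------------------------------------
# marker QC


def _founders_fs(geno_counts, extra_markers=()):
    """Founder-only set from per-marker (n_hom_a1, n_het, n_hom_a2)."""
    cols = []
    for n0, n1, n2 in (geno_counts, *extra_markers):
        cols.append([0] * n0 + [1] * n1 + [2] * n2)
    geno = np.array(cols, dtype=np.int8).T
    ind = [("F%d" % i, "p%d" % i, "0", "0", 1) for i in range(geno.shape[0])]
    return make_family_set(ind, geno)


def test_marker_qc_hwe_retention_and_removal():
    fs = _founders_fs((25, 50, 25), extra_markers=[(50, 0, 50)])
    out, report = marker_qc(fs)
    assert list(out.markers["marker_id"]) == ["m1"]
    ((mid, reason, value, thr),) = report.removed_markers
    assert (mid, reason) == ("m2", "hwe")
    assert value < 1e-6
    assert out.markers["hwe_p"].iloc[0] == pytest.approx(hwe_oracle(50, 25, 25), abs=1e-12)


def test_marker_qc_missingness_and_maf():
    geno = np.array(
        [
            [0] * 12 + [1] * 26 + [2] * 12,
            [MISSING] * 3 + [1] * 22 + [0] * 13 + [2] * 12,
            [0] * 49 + [1],
        ],
        dtype=np.int8,
    ).T
    ind = [("F%d" % i, "p%d" % i, "0", "0", 1) for i in range(50)]
    fs = make_family_set(ind, geno)
    out, report = marker_qc(fs, max_missing=0.05, hwe_alpha=1e-30, min_maf=0.05)
    reasons = {mid: reason for mid, reason, *_ in report.removed_markers}
    assert reasons == {"m2": "missingness", "m3": "maf"}
    assert list(out.markers["marker_id"]) == ["m1"]


def test_marker_qc_no_founder_data():
    fs = make_family_set(
        [
            ("F1", "dad", "0", "0", 1),
            ("F1", "mum", "0", "0", 2),
            ("F1", "kid", "dad", "mum", 1),
        ],
        [[MISSING], [MISSING], [1]],
    )
    out, report = marker_qc(fs, max_missing=0.9)
    assert report.removed_markers[0][1] == "no founder data"
    assert out.n_markers == 0


# ---------------------------------------------------------------------------
# heterozygosity


def test_heterozygosity_identical_rates_no_removal():
    fs = _founders_fs((0, 10, 0))
    out, report = heterozygosity_outliers(fs)
    assert out.n_individuals == 10
    assert report.removed_individuals == []


def test_heterozygosity_gross_outlier_removed():
    geno = np.zeros((30, 50), dtype=np.int8)
    rng = np.random.default_rng(0)
    geno[:, :] = rng.choice([0, 1, 2], p=[0.45, 0.35, 0.2], size=(30, 50))
    geno[7, :] = 1  # heterozygosity forced to 1.0
    ind = [("F%d" % i, "p%d" % i, "0", "0", 1) for i in range(30)]
    fs = make_family_set(ind, geno)
    out, report = heterozygosity_outliers(fs)
    assert [k for k, *_ in report.removed_individuals] == ["F7:p7"]


def test_heterozygosity_planted_outliers_match_independent_recount(rng):
    sim = simulate(SimConfig(n_families=200, n_markers=150, seed=21,
                             missing_parent_rate=0.0))
    keys = sim.fs.keys()
    planted = [keys[3], keys[100]]
    bad, manifest = corrupt(sim.fs, outlier_individuals=planted)
    out, report = heterozygosity_outliers(bad)
    # independent recount of mean/SD over heterozygosity rates
    g = bad.genotypes
    rate = (g == 1).sum(1) / (g >= 0).sum(1)
    mu, sd = rate.mean(), rate.std()
    expected = set(np.asarray(bad.keys())[np.abs(rate - mu) > 3 * sd])
    assert {k for k, *_ in report.removed_individuals} == expected
    assert set(planted) <= expected


# ---------------------------------------------------------------------------
# duplicate positions


def test_dedupe_same_alleles_keeps_first():
    fs = make_family_set(
        [("F1", "p1", "0", "0", 1)], [[1, 1]], marker_ids=["rsA", "rsB"],
        pos=[5000, 5000],
    )
    out, report = dedupe_positions(fs)
    assert list(out.markers["marker_id"]) == ["rsA"]


def test_dedupe_prioritizes_rs_ids():
    fs = make_family_set(
        [("F1", "p1", "0", "0", 1)],
        [[1, 1]],
        marker_ids=["psy_x", "rs9"],
        pos=[5000, 5000],
        alleles=[("A", "B"), ("C", "T")],
    )
    out, _ = dedupe_positions(fs)
    assert list(out.markers["marker_id"]) == ["rs9"]


def test_dedupe_unique_positions_noop():
    fs = make_family_set([("F1", "p1", "0", "0", 1)], [[1, 0, 2]])
    out, report = dedupe_positions(fs)
    assert list(out.markers["marker_id"]) == ["m1", "m2", "m3"]
    assert report.removed_markers == []


# ---------------------------------------------------------------------------
# cascade properties


def test_qc_cascade_idempotent_and_counts_consistent():
    sim = simulate(SimConfig(n_families=150, n_markers=80, seed=13))
    fs1, reports = qc_cascade(sim.fs)
    # retained + removed markers equals input markers across the stages
    n = sim.fs.n_markers
    for rep in reports:
        n_removed = len(rep.removed_markers)
        n -= n_removed
    assert n == fs1.n_markers
    fs2, reports2 = qc_cascade(fs1)
    assert fs2.n_individuals == fs1.n_individuals
    assert fs2.n_markers == fs1.n_markers
    assert np.array_equal(fs2.genotypes, fs1.genotypes)
    assert all(not r.removed_markers and not r.removed_individuals for r in reports2)


def test_family_without_genotypes_warns_not_raises():
    fs = make_family_set(
        [
            ("F1", "dad", "0", "0", 1),
            ("F1", "mum", "0", "0", 2),
            ("F1", "kid", "dad", "mum", 1),
        ],
        np.full((3, 4), MISSING),
    )
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        out, _ = mendelian_screen(fs)
    assert any("no genotyped members" in str(w.message) for w in rec)
    assert out.n_individuals == 3
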