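"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from famgwas.family_io import FamilySet


def make_family_set(individuals, genotypes, marker_ids=None, chrom=None, pos=None,
                    alleles=None, phenotypes=None):
    """Build a FamilySet from explicit rows.

    ``individuals``: list of (fid, iid, father, mother, sex) tuples;
    ``genotypes``: (n, m) array of a2-allele counts (-1 missing).
    """
    geno = np.asarray(genotypes, dtype=np.int8)
    m = geno.shape[1]
    ind = pd.DataFrame(individuals, columns=["fid", "iid", "father", "mother", "sex"])
    markers = pd.DataFrame(
        {
            "marker_id": marker_ids or [f"m{j + 1}" for j in range(m)],
            "chrom": chrom or ["1"] * m,
            "cm": np.zeros(m),
            "pos": pos or list(range(1000, 1000 + 1000 * m, 1000)),
            "a1": [a[0] for a in alleles] if alleles else ["A"] * m,
            "a2": [a[1] for a in alleles] if alleles else ["B"] * m,
        }
    )
    return FamilySet(ind, markers, geno, phenotypes)


def make_trio(child, father, mother, n_extra_markers=0):
    """One trio, first marker carrying the given dosages."""
    geno = np.full((3, 1 + n_extra_markers), 1, dtype=np.int8)
    geno[0, 0], geno[1, 0], geno[2, 0] = father, mother, child
    return make_family_set(
        [
            ("F1", "dad", "0", "0", 1),
            ("F1", "mum", "0", "0", 2),
            ("F1", "kid", "dad", "mum", 1),
        ],
        geno,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
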