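"""Parental-origin assignment and informativeness for parent-of-origin tests.

For each child and biallelic marker, Mendelian logic either forces the
origin of the child's alleles (any configuration except the triple
heterozygote, or a missing parent compensated by the other parent's
homozygosity) or leaves it ambiguous.  Origin counts are expressed as the
number of ``a2`` alleles transmitted by each parent (0 or 1), with sentinel
codes for ambiguity.

A child is an *informative proband* for a parent-of-origin (POE) test when

(i)  both parents are genotyped, one parent is homozygous or the parental
     genotypes differ, and the tested parent is heterozygous; or
(ii) one parent's genotype is missing but the other parent is homozygous,
     in which case the child is informative for the *missing* parent's test
     (the homozygous parent pins down that transmission);

and in all cases the tested parent's transmitted allele is determinate.
For the general (non-POE) test a child is informative whenever its own call
is non-missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .family_io import MISSING, FamilySet, mendelian_error_mask

# origin-count sentinel codes
INDETERMINATE = -1
UNAVAILABLE = -2
ERROR = -3

MODES = ("general", "paternal", "maternal")

__all__ = [
    "INDETERMINATE",
    "UNAVAILABLE",
    "ERROR",
    "MODES",
    "TransmissionTable",
    "assign_parental_origin",
    "informative_flags",
    "parental_origin_matrix",
    "informative_matrix",
    "build_transmission_table",
]


def parental_origin_matrix(
    C: np.ndarray, F: np.ndarray, M: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized origin assignment over (child, marker) dosage arrays.

    Returns ``(pat, mat)`` int8 arrays: count of the a2 allele transmitted by
    the father / mother, or a sentinel (INDETERMINATE, UNAVAILABLE for a
    missing child call, ERROR for a Mendelian impossibility).
    """
    pat = np.full(C.shape, UNAVAILABLE, dtype=np.int8)
    mat = np.full(C.shape, UNAVAILABLE, dtype=np.int8)

    called = C >= 0
    for val, p, m in ((0, 0, 0), (2, 1, 1)):
        sel = called & (C == val)
        pat[sel] = p
        mat[sel] = m

    het = called & (C == 1)
    # a homozygous parent forces both origins
    for cond, p, m in (
        (het & (F == 0), 0, 1),
        (het & (F == 2), 1, 0),
        (het & (F == 1) & (M == 0), 1, 0),
        (het & (F == 1) & (M == 2), 0, 1),
        (het & (F < 0) & (M == 0), 1, 0),
        (het & (F < 0) & (M == 2), 0, 1),
    ):
        pat[cond] = p
        mat[cond] = m
    undecided = het & (pat == UNAVAILABLE)  # het parents and/or missing parents
    pat[undecided] = INDETERMINATE
    mat[undecided] = INDETERMINATE

    err = mendelian_error_mask(C, F, M)
    pat[err] = ERROR
    mat[err] = ERROR
    return pat, mat


def informative_matrix(
    C: np.ndarray, F: np.ndarray, M: np.ndarray, mode: str
) -> np.ndarray:
    """Vectorized informativeness flags for one test mode."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    called = C >= 0
    if mode == "general":
        return called
    pat, mat = parental_origin_matrix(C, F, M)
    err = pat == ERROR
    if mode == "paternal":
        rule_i = (F == 1) & ((M == 0) | (M == 2))
        rule_ii = (F < 0) & ((M == 0) | (M == 2)) & (pat >= 0)
    else:
        rule_i = (M == 1) & ((F == 0) | (F == 2))
        rule_ii = (M < 0) & ((F == 0) | (F == 2)) & (mat >= 0)
    return called & ~err & (rule_i | rule_ii)


def _as_matrix(child, father, mother):
    to_code = lambda x: MISSING if x is None else int(x)
    C = np.array([[to_code(child)]], dtype=np.int8)
    F = np.array([[to_code(father)]], dtype=np.int8)
    M = np.array([[to_code(mother)]], dtype=np.int8)
    return C, F, M


def assign_parental_origin(child, father, mother) -> tuple[int, int, str]:
    """Scalar origin assignment for one trio configuration.

    Dosages are counts of the a2 allele (0/1/2) or ``None``/-1 for missing.
    Returns ``(paternal_count, maternal_count, status)`` where status is one
    of ``"ok"``, ``"indeterminate"``, ``"unavailable"``, ``"error"``; counts
    are only meaningful when the status is ``"ok"``.
    """
    C, F, M = _as_matrix(child, father, mother)
    pat, mat = parental_origin_matrix(C, F, M)
    p, m = int(pat[0, 0]), int(mat[0, 0])
    status = {ERROR: "error", UNAVAILABLE: "unavailable", INDETERMINATE: "indeterminate"}.get(p, "ok")
    return p, m, status


def informative_flags(child, father, mother, mode: str) -> bool:
    """Scalar informativeness flag for one trio configuration and mode."""
    C, F, M = _as_matrix(child, father, mother)
    return bool(informative_matrix(C, F, M, mode)[0, 0])


@dataclass
class TransmissionTable:
    """Per (child, marker) parental-origin counts and informativeness flags.

    ``child_rows`` indexes the children back into ``FamilySet`` rows; all
    arrays have shape (n children, n markers).  Origin counts refer to the
    a2 allele of each marker.
    """

    child_rows: np.ndarray
    child_keys: np.ndarray
    pat: np.ndarray
    mat: np.ndarray
    informative: dict  # mode -> bool array

    @property
    def n_children(self) -> int:
        return len(self.child_rows)

    def proband_counts(self, marker_ids=None) -> pd.DataFrame:
        """Informative-proband counts per marker and mode (genotype-based;
        phenotype availability further restricts these at scan time)."""
        out = pd.DataFrame({m: self.informative[m].sum(axis=0) for m in MODES})
        out.columns = [f"n_{m}" for m in MODES]
        if marker_ids is not None:
            out.insert(0, "marker_id", np.asarray(marker_ids))
        return out

    def to_frame(self, fs: FamilySet) -> pd.DataFrame:
        """Long-format export: child, marker, origin counts, status flags."""
        n_c, n_m = self.pat.shape
        ids = fs.markers["marker_id"].to_numpy()
        return pd.DataFrame(
            {
                "child": np.repeat(self.child_keys, n_m),
                "marker_id": np.tile(ids, n_c),
                "pat_count": self.pat.ravel(),
                "mat_count": self.mat.ravel(),
                "informative_general": self.informative["general"].ravel(),
                "informative_paternal": self.informative["paternal"].ravel(),
                "informative_maternal": self.informative["maternal"].ravel(),
            }
        )


def build_transmission_table(fs: FamilySet) -> TransmissionTable:
    """Phase every child in the pedigree at every marker.

    Children are individuals listing at least one parent.  Mendelian
    inconsistencies left in the data surface as ERROR codes (the QC screen
    is expected to have run first).
    """
    child_rows = np.where(fs.child_mask)[0]
    C = fs.genotypes[child_rows]
    F, M = fs.parent_dosages(child_rows)
    pat, mat = parental_origin_matrix(C, F, M)
    informative = {mode: informative_matrix(C, F, M, mode) for mode in MODES}
    return TransmissionTable(
        child_rows=child_rows,
        child_keys=fs.keys()[child_rows],
        pat=pat,
        mat=mat,
        informative=informative,
    )
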