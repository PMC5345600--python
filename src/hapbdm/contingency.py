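"""Contingency-table primitives for the hybrid-group comparisons.

Count tables are plain :class:`pandas.DataFrame` objects with group labels as
the index and allele or two-locus haplotype labels as columns.  The haplotype
columns are always the four ordered lineage combinations ``I.I``, ``I.II``,
``II.I``, ``II.II``, where the first symbol is the allele at the
alphabetically first marker of the pair; ``I.I`` and ``II.II`` are parental
haplotypes, ``I.II`` and ``II.I`` recombinant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

HAPLOTYPES = ("I.I", "I.II", "II.I", "II.II")
PARENTAL = ("I.I", "II.II")
RECOMBINANT = ("I.II", "II.I")
ALLELES = ("I", "II")


def haplotype_class(haplotype: str) -> str:
    """``parental`` for I.I / II.II, ``recombinant`` for I.II / II.I."""
    if haplotype not in HAPLOTYPES:
        raise ValueError(f"unknown haplotype {haplotype!r}")
    return "parental" if haplotype in PARENTAL else "recombinant"


@dataclass(frozen=True)
class HaplotypeCountTable:
    """2 groups × 4 haplotypes count table for one marker pair.

    ``n_complete`` holds, per group row, the number of individuals with
    non-missing calls at both loci (pairwise-complete deletion); the four
    column counts of each row sum to it.
    """

    pair: tuple[str, str]
    table: pd.DataFrame

    @property
    def n_complete(self) -> pd.Series:
        return self.table.sum(axis=1)


def _lineage_codes(group: pd.DataFrame, markers: list[str]) -> np.ndarray:
    """Marker calls as int8 codes: 0 = lineage I, 1 = lineage II, -1 = missing."""
    sub = group[markers].to_numpy(dtype=object)
    codes = np.full(sub.shape, -1, dtype=np.int8)
    codes[sub == "I"] = 0
    codes[sub == "II"] = 1
    return codes


def haplotype_count_table(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    pair: tuple[str, str],
    labels: tuple[str, str] = ("a", "b"),
) -> HaplotypeCountTable:
    """Tally two-locus haplotypes for a pair of hybrid groups.

    Only individuals with calls at *both* loci of the pair enter the tally
    (missingness at other loci is irrelevant here).  The pair is ordered
    alphabetically; identical markers are rejected.
    """
    m1, m2 = sorted(pair)
    if m1 == m2:
        raise ValueError("marker pair must consist of two distinct markers")
    rows = []
    for group in (group_a, group_b):
        codes = _lineage_codes(group, [m1, m2])
        complete = (codes >= 0).all(axis=1)
        idx = codes[complete, 0] * 2 + codes[complete, 1]  # 0=I.I 1=I.II 2=II.I 3=II.II
        counts = np.bincount(idx, minlength=4)
        rows.append([counts[0], counts[1], counts[2], counts[3]])
    table = pd.DataFrame(rows, index=list(labels), columns=list(HAPLOTYPES))
    return HaplotypeCountTable(pair=(m1, m2), table=table)


def allele_count_table(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    marker: str,
    labels: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """2 groups × 2 alleles count table at one locus (non-missing calls)."""
    rows = []
    for group in (group_a, group_b):
        codes = _lineage_codes(group, [marker])[:, 0]
        rows.append([int((codes == 0).sum()), int((codes == 1).sum())])
    return pd.DataFrame(rows, index=list(labels), columns=list(ALLELES))


def adjusted_residuals(table: pd.DataFrame) -> pd.DataFrame:
    """Adjusted (standardized Pearson) residuals of a count table.

    d_ij = (n_ij - E_ij) / sqrt(E_ij (1 - n_i+/N) (1 - n_+j/N)) with
    E_ij = n_i+ n_+j / N.  Under independence these behave as z-scores with
    zero mean and unit standard deviation.  Cells whose expected count is
    zero are undefined and returned as NaN; in a two-row table the defined
    residuals satisfy d_1j = -d_2j exactly.
    """
    counts = table.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("table must contain at least one observation")
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(expected * (1.0 - row / n) * (1.0 - col / n))
        resid = (counts - expected) / denom
    resid[expected == 0] = np.nan
    return pd.DataFrame(resid, index=table.index, columns=table.columns)


def fisher_exact_two_sided(table: pd.DataFrame | np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2×2 table.

    Uses the probability-mass convention: the p-value sums the hypergeometric
    probabilities of all tables with the observed margins that are at most as
    probable as the observed one.
    """
    counts = np.asarray(table, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.sum() <= 0:
        raise ValueError("table must contain at least one observation")
    return float(stats.fisher_exact(counts, alternative="two-sided").pvalue)


def sequential_bonferroni(
    pvals, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down (sequential Bonferroni) multiple-testing correction.

    Sorted p-values p_(i) are compared with alpha/(m-i+1); rejections stop at
    the first failure.  Returns ``(reject, p_adjusted)`` aligned with the
    input order; adjusted p-values are monotone in rank and capped at 1.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([], dtype=bool), np.array([], dtype=float)
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return reject, p_adj


@dataclass(frozen=True)
class CmhResult:
    """Generalized Cochran–Mantel–Haenszel general-association test result."""

    statistic: float
    df: int
    p_value: float


def generalized_cmh(strata) -> CmhResult:
    """Generalized CMH test of group × category association across strata.

    Each stratum is a 2×C count table sharing column labels (here: one
    marker pair's viable/inviable × 4-haplotype table; strata are the 28
    pairs).  The general-association statistic compares, summed over strata,
    the first row's observed category counts with their conditional
    expectations under the multivariate hypergeometric distribution given the
    margins:

        U = sum_k (O_k - E_k),   V = sum_k Cov_k,   M2 = U' V^-1 U

    over the first C-1 categories, with df = C-1 on 2 rows.  Categories empty
    in every stratum are dropped before computing df; if V is singular after
    dropping, a generalized inverse is used and df reduces to rank(V).
    """
    tables = [np.asarray(getattr(s, "table", s), dtype=float) for s in strata]
    if not tables:
        raise ValueError("at least one stratum required")
    ncols = tables[0].shape[1]
    for t in tables:
        if t.shape != (2, ncols):
            raise ValueError("all strata must be 2-row tables with shared columns")
        if (t < 0).any():
            raise ValueError("counts must be non-negative")

    col_totals = np.sum([t.sum(axis=0) for t in tables], axis=0)
    keep = col_totals > 0
    if keep.sum() < 2:
        logger.warning("fewer than two non-empty categories; CMH degenerate")
        return CmhResult(statistic=0.0, df=0, p_value=1.0)

    c = int(keep.sum())
    u = np.zeros(c - 1)
    v = np.zeros((c - 1, c - 1))
    for t in tables:
        t = t[:, keep]
        n = t.sum()
        if n <= 1:  # stratum carries no information about association
            continue
        r1 = t[0].sum()
        p = t.sum(axis=0) / n
        u += t[0, : c - 1] - r1 * p[: c - 1]
        cov = (np.diag(p) - np.outer(p, p))[: c - 1, : c - 1]
        v += r1 * (n - r1) / (n - 1) * cov

    df = c - 1
    try:
        sol = np.linalg.solve(v, u)
    except np.linalg.LinAlgError:
        rank = int(np.linalg.matrix_rank(v))
        logger.warning("singular CMH covariance; using pseudo-inverse, df=%d", rank)
        sol = np.linalg.pinv(v) @ u
        df = rank
    m2 = float(u @ sol)
    p_value = float(stats.chi2.sf(m2, df)) if df > 0 else 1.0
    return CmhResult(statistic=m2, df=df, p_value=p_value)
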