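"""Association statistics for collapsed contingency tables.

Scores are the Pearson 1-d.f. chi-square (no continuity correction),
the odds ratio, standalone single-SNP p-values, and the improvement
metric

    improvement = min(p_single_1, p_single_2) / p_pair,

which is large when a SNP pair is far more significant jointly than
either SNP alone.  Pairwise p-values in an exhaustive scan routinely
underflow double precision, so log10 p-values are carried alongside and
the improvement metric has a log-space form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .contingency import ContingencyTable
from ._kernels import chi2_stat

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class AssociationResult:
    """One scored SNP pair under one pattern."""

    snp_i: str
    snp_j: str
    pattern_id: int
    chi2: float
    p_pair: float
    log10_p_pair: float
    odds_ratio: float
    p_single_i: float
    p_single_j: float
    improvement: float
    log10_improvement: float
    degenerate: bool = False


def is_degenerate(t: ContingencyTable) -> bool:
    """True when any margin of the 2x2 table is zero."""
    return (
        t.n_db + t.n_dw == 0
        or t.n_hb + t.n_hw == 0
        or t.n_db + t.n_hb == 0
        or t.n_dw + t.n_hw == 0
    )


def chi_square_1df(t: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square statistic and upper-tail p for a 2x2 table.

    ``n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` with a = N_D,B,
    b = N_D,W, c = N_H,B, d = N_H,W, referred to chi-square with 1 d.f.
    Degenerate margins give (0, 1).
    """
    chi2 = chi2_stat(t.n_db, t.n_dw, t.n_hb, t.n_hw)
    if chi2 == 0.0:
        return 0.0, 1.0
    return float(chi2), float(sps.chi2.sf(chi2, 1))


def chi2_log10_sf(chi2) -> np.ndarray | float:
    """log10 upper-tail probability of chi-square(1), underflow-safe."""
    return sps.chi2.logsf(chi2, 1) / _LN10


def odds_ratio(t: ContingencyTable) -> float:
    """(N_D,B * N_H,W) / (N_D,W * N_H,B).

    ``inf`` when only the denominator is zero; ``nan`` (undefined) when
    numerator and denominator are both zero.
    """
    num = t.n_db * t.n_hw
    den = t.n_dw * t.n_hb
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


def _collapse_pvalue(black: np.ndarray, phenotype: np.ndarray) -> tuple[float, float]:
    """(chi2, p) of the 2x2 table formed by a boolean sample grouping."""
    a = int((black & phenotype).sum())
    b = int((~black & phenotype).sum())
    c = int((black & ~phenotype).sum())
    d = int((~black & ~phenotype).sum())
    chi2 = chi2_stat(a, b, c, d)
    if chi2 == 0.0:
        return 0.0, 1.0
    return float(chi2), float(sps.chi2.sf(chi2, 1))


def dichotomy_pvalues(column: np.ndarray, phenotype: np.ndarray) -> tuple[float, float]:
    """p-values of the dominant ({1} vs {2,3}) and recessive ({1,2} vs {3}) collapses."""
    column = np.asarray(column, dtype=np.uint8)
    phenotype = np.asarray(phenotype, dtype=bool)
    valid = column > 0
    col = column[valid]
    ph = phenotype[valid]
    _, p_dom = _collapse_pvalue(col >= 2, ph)
    _, p_rec = _collapse_pvalue(col == 3, ph)
    return p_dom, p_rec


def single_snp_pvalue(
    column: np.ndarray, phenotype: np.ndarray, method: str = "best-dichotomy"
) -> float:
    """Standalone 1-d.f. chi-square p-value of one SNP.

    ``best-dichotomy`` (default) is the minimum over the dominant
    ({hom-major} vs {het, hom-minor}) and recessive ({hom-major, het} vs
    {hom-minor}) genotype collapses -- these are exactly the marginal
    projections of the eight interaction patterns.  ``allelic`` tests
    the 2x2 allele-count table.  Missing genotypes are excluded; a
    monomorphic column is degenerate and returns 1.
    """
    column = np.asarray(column, dtype=np.uint8)
    phenotype = np.asarray(phenotype, dtype=bool)
    if method == "best-dichotomy":
        p_dom, p_rec = dichotomy_pvalues(column, phenotype)
        return min(p_dom, p_rec)
    if method == "allelic":
        valid = column > 0
        col = column[valid]
        ph = phenotype[valid]
        n1 = np.array([int(((col == g) & ph).sum()) for g in (1, 2, 3)])
        n0 = np.array([int(((col == g) & ~ph).sum()) for g in (1, 2, 3)])
        a = 2 * n1[0] + n1[1]  # major alleles in cases
        b = 2 * n1[2] + n1[1]  # minor alleles in cases
        c = 2 * n0[0] + n0[1]
        d = 2 * n0[2] + n0[1]
        chi2 = chi2_stat(int(a), int(b), int(c), int(d))
        return 1.0 if chi2 == 0.0 else float(sps.chi2.sf(chi2, 1))
    raise ValueError(f"unknown method {method!r}")


def improvement_metric(p1: float, p2: float, p_pair: float) -> float:
    """min(p1 / p_pair, p2 / p_pair) for p-values in (0, 1].

    Scale-free in the three p-values.  For pairwise p-values that
    underflow double precision use :func:`improvement_metric_log10`.
    """
    if p_pair <= 0.0:
        raise ValueError("p_pair must be > 0; use improvement_metric_log10 for underflowed p")
    return min(p1, p2) / p_pair


def improvement_metric_log10(log10_p1: float, log10_p2: float, log10_p_pair: float) -> float:
    """log10 of the improvement metric from log10 p-values."""
    return min(log10_p1, log10_p2) - log10_p_pair
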