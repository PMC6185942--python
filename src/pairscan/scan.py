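"""Exhaustive scan of all unordered SNP pairs under the eight patterns.

Every pair of SNPs is scored with eight 1-d.f. chi-square tests, one per
genotype interaction pattern; results at or below the p-value threshold
are retained and ranked both by pairwise p-value and by improvement
metric.  Because the pattern set is transpose-closed, scanning unordered
pairs (i < j) with all eight patterns covers ordered pairs exactly.

Two engines produce bit-identical statistics: ``lookup`` (default) sums
pre-computed per-word black/white counts over 2-bit-packed case/control
vectors; ``naive`` counts samples directly and serves as the oracle.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import _kernels
from .contingency import build_lookup_table, pack_codes, count_pair_naive
from .genotype_io import GenotypeMatrix
from .patterns import enumerate_patterns
from .stats import (
    AssociationResult,
    chi2_log10_sf,
    improvement_metric_log10,
    odds_ratio,
    single_snp_pvalue,
)

logger = logging.getLogger(__name__)

N_PATTERNS = 8


def count_pairs(m: int) -> int:
    """Number of unordered SNP pairs among m SNPs: m(m-1)/2, exact."""
    if m < 0:
        raise ValueError("m must be >= 0")
    return m * (m - 1) // 2


def count_tests(m: int) -> int:
    """Number of chi-square tests in a full scan: 8 per pair."""
    return N_PATTERNS * count_pairs(m)


@dataclass(frozen=True)
class ScanConfig:
    """Scan settings.

    ``p_threshold=None`` applies a Bonferroni cutoff 0.05 / (8 C(m,2))
    over all tests actually performed; fixed cutoffs (e.g. the 1e-13 /
    1e-14 used on large real scans) can be given explicitly.  ``dedupe``
    controls whether one row per pair (its minimum-p pattern) or all
    significant (pair, pattern) rows are retained.  ``min_maf`` /
    ``min_callrate`` are optional pre-filters, off by default.
    """

    p_threshold: float | None = None
    top_k_p: int = 20
    top_k_improvement: int = 10000
    dedupe: str = "best-pattern-per-pair"  # or "all-patterns"
    engine: str = "lookup"  # or "naive"
    single_snp_method: str = "best-dichotomy"
    min_maf: float = 0.0
    min_callrate: float = 0.0

    def __post_init__(self) -> None:
        if self.p_threshold is not None and not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.top_k_p < 1 or self.top_k_improvement < 1:
            raise ValueError("top-k sizes must be >= 1")
        if self.dedupe not in ("best-pattern-per-pair", "all-patterns"):
            raise ValueError(f"unknown dedupe mode {self.dedupe!r}")
        if self.engine not in ("lookup", "naive"):
            raise ValueError(f"unknown engine {self.engine!r}")


@dataclass
class ScanReport:
    """Outcome of one exhaustive scan.

    ``n_significant`` counts significant *tests* (pair x pattern, as the
    per-dataset bookkeeping of large scans is usually reported);
    ``results`` holds the retained rows after the dedupe policy.
    """

    n_snps: int
    n_pairs: int
    n_tests: int
    p_threshold: float
    n_significant: int
    results: list[AssociationResult]
    top_by_p: list[AssociationResult]
    top_by_improvement: list[AssociationResult]
    engine: str
    runtime_s: float
    config: ScanConfig
    snp_ids: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_snps": self.n_snps,
            "n_pairs": self.n_pairs,
            "n_tests": self.n_tests,
            "p_threshold": self.p_threshold,
            "n_significant_tests": self.n_significant,
            "n_results": len(self.results),
            "engine": self.engine,
            "runtime_s": round(self.runtime_s, 3),
            "config": asdict(self.config),
        }


def _column_maf(column: np.ndarray) -> float:
    valid = column > 0
    n = int(valid.sum())
    if n == 0:
        return 0.0
    minor = 2 * int((column == 3).sum()) + int((column == 2).sum())
    f = minor / (2 * n)
    return min(f, 1.0 - f)


def _prefilter(matrix: GenotypeMatrix, config: ScanConfig) -> np.ndarray:
    keep = np.ones(matrix.n_snps, dtype=bool)
    if config.min_callrate > 0.0:
        call = (matrix.genotypes > 0).mean(axis=0)
        keep &= call >= config.min_callrate
    if config.min_maf > 0.0:
        mafs = np.array([_column_maf(matrix.genotypes[:, j]) for j in range(matrix.n_snps)])
        keep &= mafs >= config.min_maf
    return np.flatnonzero(keep)


def scan(matrix: GenotypeMatrix, config: ScanConfig | None = None) -> ScanReport:
    """Run the exhaustive pairwise scan.

    Deterministic given (matrix, config); the two engines return
    identical reports.  Raises if the matrix lacks cases or controls or
    has fewer than two SNPs after pre-filtering.
    """
    config = config or ScanConfig()
    if matrix.n_cases == 0 or matrix.n_controls == 0:
        raise ValueError("scan requires at least one case and one control")
    t0 = time.perf_counter()

    cols = _prefilter(matrix, config)
    if cols.size < matrix.n_snps:
        logger.info("pre-filter kept %d of %d SNPs", cols.size, matrix.n_snps)
    m = int(cols.size)
    if m < 2:
        raise ValueError("scan requires at least two SNPs after pre-filtering")
    snp_ids = [matrix.snp_ids[j] for j in cols]
    geno = np.ascontiguousarray(matrix.genotypes[:, cols].T)  # (m, n_samples)
    pheno = matrix.phenotype

    n_pairs = count_pairs(m)
    n_tests = count_tests(m)
    p_threshold = config.p_threshold
    if p_threshold is None:
        p_threshold = 0.05 / n_tests

    chi2 = np.empty((n_pairs, N_PATTERNS), dtype=np.float64)
    if config.engine == "lookup":
        table = build_lookup_table()
        case_words = np.ascontiguousarray(
            np.stack([pack_codes(row[pheno]) for row in geno])
        )
        ctrl_words = np.ascontiguousarray(
            np.stack([pack_codes(row[~pheno]) for row in geno])
        )
        _kernels.scan_pairs_lookup(case_words, ctrl_words, table.black, table.white, chi2)
    else:
        masks = np.stack([p.mask4() for p in enumerate_patterns()])
        _kernels.scan_pairs_naive(geno, pheno, masks, chi2)

    log10p = np.asarray(chi2_log10_sf(chi2))
    log10p[chi2 == 0.0] = 0.0  # degenerate tables: p = 1 exactly
    p = np.power(10.0, log10p)
    sig = p <= p_threshold
    n_significant = int(sig.sum())

    # single-SNP p-values, computed once per SNP before assembling rows
    p_single = np.array(
        [single_snp_pvalue(geno[j], pheno, config.single_snp_method) for j in range(m)]
    )
    log10_p_single = np.log10(np.maximum(p_single, np.finfo(float).tiny))

    if config.dedupe == "best-pattern-per-pair":
        best_t = np.argmin(log10p, axis=1)  # ties -> lowest pattern id
        rows_k = np.flatnonzero(sig[np.arange(n_pairs), best_t])
        rows = [(int(k), int(best_t[k])) for k in rows_k]
    else:
        kk, tt = np.nonzero(sig)
        rows = [(int(k), int(t)) for k, t in zip(kk, tt)]

    pair_i, pair_j = np.triu_indices(m, k=1)
    patterns = enumerate_patterns()
    results: list[AssociationResult] = []
    for k, t in rows:
        i, j = int(pair_i[k]), int(pair_j[k])
        tab = count_pair_naive(geno[i], geno[j], pheno, patterns[t])
        lp = float(log10p[k, t])
        results.append(
            AssociationResult(
                snp_i=snp_ids[i],
                snp_j=snp_ids[j],
                pattern_id=patterns[t].id,
                chi2=float(chi2[k, t]),
                p_pair=float(p[k, t]),
                log10_p_pair=lp,
                odds_ratio=odds_ratio(tab),
                p_single_i=float(p_single[i]),
                p_single_j=float(p_single[j]),
                improvement=_safe_pow10(
                    improvement_metric_log10(
                        float(log10_p_single[i]), float(log10_p_single[j]), lp
                    )
                ),
                log10_improvement=improvement_metric_log10(
                    float(log10_p_single[i]), float(log10_p_single[j]), lp
                ),
                degenerate=bool(chi2[k, t] == 0.0),
            )
        )

    report = ScanReport(
        n_snps=m,
        n_pairs=n_pairs,
        n_tests=n_tests,
        p_threshold=float(p_threshold),
        n_significant=n_significant,
        results=results,
        top_by_p=rank_results(results, "p_pair", config.top_k_p),
        top_by_improvement=rank_results(results, "improvement", config.top_k_improvement),
        engine=config.engine,
        runtime_s=time.perf_counter() - t0,
        config=config,
        snp_ids=snp_ids,
    )
    return report


def _safe_pow10(x: float) -> float:
    try:
        return 10.0 ** x
    except OverflowError:  # pragma: no cover
        return math.inf


def rank_results(
    results: list[AssociationResult], key: str, k: int
) -> list[AssociationResult]:
    """Top-k rows by pairwise p-value (ascending) or improvement (descending).

    Ties break by the other key, then (snp_i, snp_j, pattern_id); the
    sort is stable and log-space values are used so underflowed
    p-values still order correctly.
    """
    if key == "p_pair":
        sort_key = lambda r: (  # noqa: E731
            r.log10_p_pair, -r.log10_improvement, r.snp_i, r.snp_j, r.pattern_id
        )
    elif key == "improvement":
        sort_key = lambda r: (  # noqa: E731
            -r.log10_improvement, r.log10_p_pair, r.snp_i, r.snp_j, r.pattern_id
        )
    else:
        raise ValueError(f"unknown ranking key {key!r}")
    return sorted(results, key=sort_key)[:k]


def results_to_dataframe(
    results: list[AssociationResult], matrix: GenotypeMatrix | None = None
) -> pd.DataFrame:
    """Render results as the standard TSV row layout.

    When ``matrix`` carries loci, per-SNP chromosome/position columns
    are included (needed downstream by gene-network inference).
    """
    cols = {
        "snp_i": [r.snp_i for r in results],
        "snp_j": [r.snp_j for r in results],
        "pattern_id": [r.pattern_id for r in results],
        "chi2": [r.chi2 for r in results],
        "p_pair": [r.p_pair for r in results],
        "log10_p_pair": [r.log10_p_pair for r in results],
        "odds_ratio": [r.odds_ratio for r in results],
        "p_single_i": [r.p_single_i for r in results],
        "p_single_j": [r.p_single_j for r in results],
        "improvement": [r.improvement for r in results],
        "log10_improvement": [r.log10_improvement for r in results],
        "degenerate": [int(r.degenerate) for r in results],
    }
    df = pd.DataFrame(cols)
    if matrix is not None and matrix.snp_loci is not None:
        loci = matrix.loci_by_id()
        df.insert(2, "chrom_i", [loci[r.snp_i][0] for r in results])
        df.insert(3, "pos_i", [loci[r.snp_i][1] for r in results])
        df.insert(4, "chrom_j", [loci[r.snp_j][0] for r in results])
        df.insert(5, "pos_j", [loci[r.snp_j][1] for r in results])
    return df
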