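"""Compiled inner loops of the exhaustive pair scan.

Both engines fill the same ``(n_pairs, 8)`` chi-square statistic array,
pairs enumerated as (i, j) with i < j in row-major order, so engine
outputs are bit-identical whenever their integer counts agree.
"""

import numpy as np
from numba import njit

N_PATTERNS = 8


@njit(cache=True)
def chi2_stat(a, b, c, d):
    """Pearson 1-d.f. chi-square of the 2x2 table [[a, b], [c, d]].

    No continuity correction; any zero margin makes the statistic 0
    (degenerate table).
    """
    r1 = a + b
    r2 = c + d
    c1 = a + c
    c2 = b + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 0.0
    n = r1 + r2
    diff = float(a * d - b * c)
    return n * diff * diff / (float(r1) * r2 * c1 * c2)


@njit(cache=True)
def scan_pairs_lookup(case_words, ctrl_words, lut_black, lut_white, out):
    """Lookup engine: sum pre-computed per-word black/white counts.

    case_words/ctrl_words: (m, n_words) uint8, one packed row per SNP.
    lut_black/lut_white: (256, 256, 8) uint8.
    out: (m*(m-1)//2, 8) float64 chi-square statistics.
    """
    m = case_words.shape[0]
    wc = case_words.shape[1]
    wt = ctrl_words.shape[1]
    a = np.empty(N_PATTERNS, np.int64)
    b = np.empty(N_PATTERNS, np.int64)
    c = np.empty(N_PATTERNS, np.int64)
    d = np.empty(N_PATTERNS, np.int64)
    k = 0
    for i in range(m - 1):
        xi_case = case_words[i]
        xi_ctrl = ctrl_words[i]
        for j in range(i + 1, m):
            for t in range(N_PATTERNS):
                a[t] = 0
                b[t] = 0
                c[t] = 0
                d[t] = 0
            xj_case = case_words[j]
            for w in range(wc):
                x = xi_case[w]
                y = xj_case[w]
                for t in range(N_PATTERNS):
                    a[t] += lut_black[x, y, t]
                    b[t] += lut_white[x, y, t]
            xj_ctrl = ctrl_words[j]
            for w in range(wt):
                x = xi_ctrl[w]
                y = xj_ctrl[w]
                for t in range(N_PATTERNS):
                    c[t] += lut_black[x, y, t]
                    d[t] += lut_white[x, y, t]
            for t in range(N_PATTERNS):
                out[k, t] = chi2_stat(a[t], b[t], c[t], d[t])
            k += 1


@njit(cache=True)
def scan_pairs_naive(genotypes, phenotype, masks, out):
    """Naive engine: count every sample of every pair under every pattern.

    genotypes: (m, n_samples) uint8 codes; phenotype: (n_samples,) bool
    (True = case); masks: (8, 4, 4) bool with missing row/col False.
    """
    m = genotypes.shape[0]
    n = genotypes.shape[1]
    a = np.empty(N_PATTERNS, np.int64)
    b = np.empty(N_PATTERNS, np.int64)
    c = np.empty(N_PATTERNS, np.int64)
    d = np.empty(N_PATTERNS, np.int64)
    k = 0
    for i in range(m - 1):
        gi_row = genotypes[i]
        for j in range(i + 1, m):
            gj_row = genotypes[j]
            for t in range(N_PATTERNS):
                a[t] = 0
                b[t] = 0
                c[t] = 0
                d[t] = 0
            for s in range(n):
                gi = gi_row[s]
                gj = gj_row[s]
                if gi == 0 or gj == 0:
                    continue
                if phenotype[s]:
                    for t in range(N_PATTERNS):
                        if masks[t, gi, gj]:
                            a[t] += 1
                        else:
                            b[t] += 1
                else:
                    for t in range(N_PATTERNS):
                        if masks[t, gi, gj]:
                            c[t] += 1
                        else:
                            d[t] += 1
            for t in range(N_PATTERNS):
                out[k, t] = chi2_stat(a[t], b[t], c[t], d[t])
            k += 1
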