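"""2x2 case/control contingency tables for SNP pairs under a pattern.

Two interchangeable counting routes are provided:

* :func:`count_pair_naive` walks the samples of a pair directly;
* :func:`count_pair_lookup` uses 2-bit-packed genotype words and a
  pre-computed lookup table holding, for every pattern and every pair of
  word values, how many of the four packed positions fall in the black
  and white genotype groups.

The two routes are bit-identical by construction; the naive route is the
oracle in the test suite.  With ``p = 4`` genotypes per 8-bit word the
table is 8 patterns x 256 x 256 word pairs x 2 counts (~1 MiB), small
enough to stay cache-resident.

A sample contributes to a pair's table only if both genotypes are
non-missing; packed padding positions carry the missing code 0 and
therefore never count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .patterns import InteractionPattern, enumerate_patterns

#: genotypes packed per word (2 bits each -> 8-bit words, 256 values)
GENOTYPES_PER_WORD = 4
_WEIGHTS = np.array([1, 4, 16, 64], dtype=np.uint16)

_LOOKUP_CACHE_VERSION = 1


class ContingencyTable(NamedTuple):
    """Counts N_D,B / N_H,B / N_D,W / N_H,W of a collapsed 3x3 table.

    D = diseased (case), H = healthy (control); B/W = black/white
    genotype group under a pattern.  Samples missing either genotype are
    in neither group, so row sums may fall short of the group sizes.
    """

    n_db: int
    n_hb: int
    n_dw: int
    n_hw: int


@dataclass(frozen=True)
class PackedVector:
    """Genotype codes of one SNP restricted to one phenotype group, 2-bit packed.

    ``words[w]`` packs genotypes ``4w .. 4w+3`` little-endian (position
    ``j`` occupies bits ``2j..2j+1``).  Trailing pad positions carry
    code 0 (missing).
    """

    words: np.ndarray  # uint8, shape (ceil(n_genotypes/4),)
    n_genotypes: int
    group: str  # "case" or "control"


@dataclass(frozen=True)
class LookupTable:
    """Pre-computed per-pattern black/white counts for every word pair.

    ``black[x, y, t]`` (and ``white``) give the number of packed
    positions where the genotype pair from word values ``(x, y)`` is
    mutually non-missing and falls in the black (white) group of pattern
    ``t+1``.  Pattern axis is innermost so the eight counts of one word
    pair share a cache line in the scan hot loop.
    """

    black: np.ndarray  # uint8, shape (256, 256, 8)
    white: np.ndarray  # uint8, shape (256, 256, 8)
    pattern_ids: tuple[int, ...]

    def save(self, path) -> None:
        """Persist to an .npz cache (versioned); see :meth:`load`."""
        np.savez_compressed(
            path,
            version=np.array([_LOOKUP_CACHE_VERSION]),
            black=self.black,
            white=self.white,
            pattern_ids=np.array(self.pattern_ids),
        )

    @classmethod
    def load(cls, path) -> "LookupTable":
        with np.load(path) as z:
            if int(z["version"][0]) != _LOOKUP_CACHE_VERSION:
                raise ValueError("lookup-table cache version mismatch")
            return cls(
                black=z["black"],
                white=z["white"],
                pattern_ids=tuple(int(i) for i in z["pattern_ids"]),
            )


def pack_codes(codes: np.ndarray) -> np.ndarray:
    """Pack a vector of genotype codes {0,1,2,3} into uint8 words."""
    codes = np.asarray(codes, dtype=np.uint8)
    n = codes.size
    n_words = -(-n // GENOTYPES_PER_WORD)
    padded = np.zeros(n_words * GENOTYPES_PER_WORD, dtype=np.uint16)
    padded[:n] = codes
    return (padded.reshape(-1, GENOTYPES_PER_WORD) * _WEIGHTS).sum(axis=1).astype(np.uint8)


def unpack_words(words: np.ndarray, n_genotypes: int) -> np.ndarray:
    """Inverse of :func:`pack_codes`, truncated to the valid length."""
    words = np.asarray(words, dtype=np.uint8)
    shifts = np.arange(GENOTYPES_PER_WORD, dtype=np.uint8) * 2
    codes = (words[:, None] >> shifts) & 3
    return codes.reshape(-1)[:n_genotypes].astype(np.uint8)


def pack_column(
    column: np.ndarray, phenotype: np.ndarray
) -> tuple[PackedVector, PackedVector]:
    """Split one SNP column into packed case and control vectors.

    Genotypes keep sample order within each group; the last word of each
    vector is zero-padded.
    """
    column = np.asarray(column, dtype=np.uint8)
    phenotype = np.asarray(phenotype, dtype=bool)
    if column.shape != phenotype.shape:
        raise ValueError("column and phenotype lengths differ")
    case_codes = column[phenotype]
    ctrl_codes = column[~phenotype]
    return (
        PackedVector(pack_codes(case_codes), int(case_codes.size), "case"),
        PackedVector(pack_codes(ctrl_codes), int(ctrl_codes.size), "control"),
    )


def _word_code_matrix() -> np.ndarray:
    """(256, 4) matrix of the genotype codes packed in each word value."""
    words = np.arange(256, dtype=np.uint16)
    shifts = np.arange(GENOTYPES_PER_WORD) * 2
    return ((words[:, None] >> shifts) & 3).astype(np.int64)


def build_lookup_table(
    patterns: Sequence[InteractionPattern] | None = None,
) -> LookupTable:
    """Pre-compute black/white counts for all patterns and word pairs.

    Deterministic: depends only on the pattern set.
    """
    if patterns is None:
        patterns = enumerate_patterns()
    wc = _word_code_matrix()
    black = np.zeros((256, 256, len(patterns)), dtype=np.uint8)
    white = np.zeros_like(black)
    valid4 = np.zeros((4, 4), dtype=np.uint8)
    valid4[1:, 1:] = 1
    for t, p in enumerate(patterns):
        m4 = p.mask4().astype(np.uint8)
        w4 = valid4 & (1 - m4)
        for j in range(GENOTYPES_PER_WORD):
            cx = wc[:, j][:, None]
            cy = wc[:, j][None, :]
            black[:, :, t] += m4[cx, cy]
            white[:, :, t] += w4[cx, cy]
    return LookupTable(black=black, white=white, pattern_ids=tuple(p.id for p in patterns))


def count_pair_naive(
    col_i: np.ndarray,
    col_j: np.ndarray,
    phenotype: np.ndarray,
    pattern: InteractionPattern,
) -> ContingencyTable:
    """Count the 2x2 table by walking samples directly (the oracle path)."""
    col_i = np.asarray(col_i, dtype=np.uint8)
    col_j = np.asarray(col_j, dtype=np.uint8)
    phenotype = np.asarray(phenotype, dtype=bool)
    if not (col_i.shape == col_j.shape == phenotype.shape):
        raise ValueError("column/phenotype lengths differ")
    m4 = pattern.mask4()
    valid = (col_i > 0) & (col_j > 0)
    blk = m4[col_i, col_j]  # implies valid: mask4 row/col 0 are False
    wht = valid & ~blk
    return ContingencyTable(
        n_db=int((blk & phenotype).sum()),
        n_hb=int((blk & ~phenotype).sum()),
        n_dw=int((wht & phenotype).sum()),
        n_hw=int((wht & ~phenotype).sum()),
    )


def count_pair_lookup(
    packed_i: tuple[PackedVector, PackedVector],
    packed_j: tuple[PackedVector, PackedVector],
    pattern_id: int,
    table: LookupTable,
) -> ContingencyTable:
    """Count the 2x2 table by summing lookup-table entries word-wise.

    ``packed_i``/``packed_j`` are the (case, control) pairs produced by
    :func:`pack_column` from the same phenotype split.
    """
    (ci, ti), (cj, tj) = packed_i, packed_j
    if ci.words.size != cj.words.size or ti.words.size != tj.words.size:
        raise ValueError("packed vectors have mismatching word counts")
    t = table.pattern_ids.index(pattern_id)
    return ContingencyTable(
        n_db=int(table.black[ci.words, cj.words, t].sum()),
        n_hb=int(table.black[ti.words, tj.words, t].sum()),
        n_dw=int(table.white[ci.words, cj.words, t].sum()),
        n_hw=int(table.white[ti.words, tj.words, t].sum()),
    )
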