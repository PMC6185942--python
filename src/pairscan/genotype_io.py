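"""Case-control genotype matrices: encoding and PLINK-text / TSV I/O.

Genotype encoding: 0 = missing, 1 = homozygous major, 2 = heterozygous,
3 = homozygous minor, with major/minor determined per SNP from allele
counts over non-missing calls (exact 50/50 ties break to the
lexicographically smaller allele label so encoding never depends on
input order).

Two interchange formats are supported: PLINK text (.ped/.map, alleles as
characters, missing = 0, phenotype 1 = control / 2 = case) and a plain
TSV matrix with one header row of SNP ids plus a final ``Status`` column
and one already-encoded row per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_ALLELE = "0"
_STATUS_TRUE = {"t", "1", "case"}
_STATUS_FALSE = {"f", "0", "control"}


class GenotypeIOError(ValueError):
    """Malformed genotype input (parse errors, bad codes, bad layout)."""


class MultiAllelicError(GenotypeIOError):
    """A SNP with more than two distinct alleles; not supported."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs genotype codes with case/control labels.

    Attributes
    ----------
    genotypes:
        uint8 array (n_samples, m_snps) with codes in {0, 1, 2, 3}.
    phenotype:
        bool array (n_samples,), True = case.
    snp_ids, sample_ids:
        Identifier lists matching the matrix axes.
    snp_loci:
        Optional per-SNP (chromosome, 1-based position).
    alleles:
        Optional per-SNP (major, minor) labels; ``None`` entries mean
        the labels are unknown (e.g. TSV input or an all-missing SNP).
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    snp_loci: list[tuple[str, int]] | None = None
    alleles: list[tuple[str, str] | None] | None = field(default=None)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.uint8)
        self.phenotype = np.asarray(self.phenotype, dtype=bool)
        n, m = self.genotypes.shape
        if self.phenotype.shape != (n,) or len(self.sample_ids) != n:
            raise GenotypeIOError("sample axis lengths disagree")
        if len(self.snp_ids) != m:
            raise GenotypeIOError("snp_ids length does not match matrix")
        if self.snp_loci is not None and len(self.snp_loci) != m:
            raise GenotypeIOError("snp_loci length does not match matrix")
        if self.alleles is not None and len(self.alleles) != m:
            raise GenotypeIOError("alleles length does not match matrix")
        if self.genotypes.size and self.genotypes.max() > 3:
            raise GenotypeIOError("genotype codes must be in {0,1,2,3}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.phenotype).sum())

    def column(self, j: int) -> np.ndarray:
        return self.genotypes[:, j]

    def loci_by_id(self) -> dict[str, tuple[str, int]]:
        """Mapping snp_id -> (chromosome, position); empty if loci unknown."""
        if self.snp_loci is None:
            return {}
        return dict(zip(self.snp_ids, self.snp_loci))


def encode_genotypes(
    raw_calls: list[tuple[str, str]],
) -> tuple[np.ndarray, tuple[str, str] | None]:
    """Encode one SNP's per-sample allele-label pairs to codes 0-3.

    Missing calls are pairs containing the sentinel ``"0"``.  Returns
    the encoded column and the (major, minor) labels, or ``None`` labels
    when every call is missing.  For a monomorphic SNP the observed
    allele is major and the minor label is the placeholder ``"."``.
    """
    counts: dict[str, int] = {}
    for a1, a2 in raw_calls:
        if a1 == MISSING_ALLELE or a2 == MISSING_ALLELE:
            continue  # a half-called genotype is missing entirely
        for a in (a1, a2):
            counts[a] = counts.get(a, 0) + 1
    if len(counts) > 2:
        raise MultiAllelicError(
            f"multi-allelic SNP not supported (alleles {sorted(counts)})"
        )
    if not counts:
        return np.zeros(len(raw_calls), dtype=np.uint8), None
    # major = most frequent; ties break to the lexicographically smaller label
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    major = ordered[0][0]
    minor = ordered[1][0] if len(ordered) == 2 else "."
    codes = np.empty(len(raw_calls), dtype=np.uint8)
    for s, (a1, a2) in enumerate(raw_calls):
        if a1 == MISSING_ALLELE or a2 == MISSING_ALLELE:
            codes[s] = 0
        else:
            codes[s] = 1 + (a1 != major) + (a2 != major)
    return codes, (major, minor)


def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK text .ped/.map into an encoded matrix.

    Phenotype column: 1 = control, 2 = case; samples with unknown
    phenotype (0 or -9) are dropped with a logged count.  Multi-allelic
    SNPs are rejected (dropped) with a logged diagnostic.
    """
    map_rows: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) not in (3, 4):
                raise GenotypeIOError(f"{map_path}: line {ln}: expected 3 or 4 fields")
            try:
                pos = int(tok[-1])
            except ValueError as exc:
                raise GenotypeIOError(f"{map_path}: line {ln}: bad position") from exc
            map_rows.append((tok[0], tok[1], pos))
    if not map_rows:
        raise GenotypeIOError(f"{map_path}: no SNPs defined")
    m = len(map_rows)

    sample_ids: list[str] = []
    phenotype: list[bool] = []
    calls: list[list[str]] = []  # 2m allele tokens per retained sample
    n_dropped = 0
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise GenotypeIOError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * m} fields, got {len(tok)}"
                )
            pheno = tok[5]
            if pheno not in ("1", "2"):
                n_dropped += 1
                continue
            sample_ids.append(tok[1])
            phenotype.append(pheno == "2")
            calls.append(tok[6:])
    if n_dropped:
        logger.info("dropped %d sample(s) with unknown phenotype", n_dropped)
    if not sample_ids:
        raise GenotypeIOError(f"{ped_path}: no samples with known phenotype")

    n = len(sample_ids)
    columns: list[np.ndarray] = []
    alleles: list[tuple[str, str] | None] = []
    keep: list[int] = []
    for j in range(m):
        raw = [(calls[s][2 * j], calls[s][2 * j + 1]) for s in range(n)]
        try:
            codes, lab = encode_genotypes(raw)
        except MultiAllelicError as exc:
            logger.warning("rejecting SNP %s: %s", map_rows[j][1], exc)
            continue
        columns.append(codes)
        alleles.append(lab)
        keep.append(j)
    if not columns:
        raise GenotypeIOError("all SNPs rejected")
    return GenotypeMatrix(
        genotypes=np.stack(columns, axis=1),
        phenotype=np.array(phenotype, dtype=bool),
        snp_ids=[map_rows[j][1] for j in keep],
        sample_ids=sample_ids,
        snp_loci=[(map_rows[j][0], map_rows[j][2]) for j in keep],
        alleles=alleles,
    )


def _parse_status(value: str, row: int) -> bool:
    v = str(value).strip().lower()
    if v in _STATUS_TRUE:
        return True
    if v in _STATUS_FALSE:
        return False
    raise GenotypeIOError(f"row {row}: unrecognised Status value {value!r}")


def read_matrix_tsv(path) -> GenotypeMatrix:
    """Read an encoded TSV matrix (SNP-id header + final Status column)."""
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if df.shape[1] < 1 or df.columns[-1] != "Status":
        raise GenotypeIOError(f"{path}: last column must be 'Status'")
    snp_ids = [str(c) for c in df.columns[:-1]]
    if not snp_ids:
        raise GenotypeIOError(f"{path}: no SNP columns")
    sample_ids = [str(i) for i in df.index]
    phenotype = np.array(
        [_parse_status(v, r + 1) for r, v in enumerate(df["Status"])], dtype=bool
    )
    cells = df.iloc[:, :-1].to_numpy()
    geno = np.zeros(cells.shape, dtype=np.uint8)
    for r in range(cells.shape[0]):
        for c in range(cells.shape[1]):
            v = str(cells[r, c]).strip()
            if v not in ("0", "1", "2", "3"):
                raise GenotypeIOError(
                    f"{path}: invalid genotype code {v!r} at row {r + 1}"
                    f" (sample {sample_ids[r]}), column {c + 1} (SNP {snp_ids[c]})"
                )
            geno[r, c] = int(v)
    return GenotypeMatrix(
        genotypes=geno,
        phenotype=phenotype,
        snp_ids=snp_ids,
        sample_ids=sample_ids,
    )


def write_matrix_tsv(matrix: GenotypeMatrix, path) -> None:
    """Write the TSV rendition; ``read_matrix_tsv`` round-trips it bit-exactly."""
    with open(path, "w") as fh:
        fh.write("\t".join(["Sample", *matrix.snp_ids, "Status"]) + "\n")
        for s in range(matrix.n_samples):
            row = [matrix.sample_ids[s]]
            row.extend(str(int(g)) for g in matrix.genotypes[s])
            row.append("T" if matrix.phenotype[s] else "F")
            fh.write("\t".join(row) + "\n")


_DEFAULT_ALLELES = ("A", "B")


def write_plink_text(matrix: GenotypeMatrix, ped_path, map_path) -> None:
    """Write .ped/.map renditions.

    SNPs without stored allele labels are written with placeholder
    labels ``A`` (major) / ``B`` (minor); loci default to chromosome 1
    with consecutive positions when unknown.
    """
    loci = matrix.snp_loci or [("1", j + 1) for j in range(matrix.n_snps)]
    alleles = matrix.alleles or [None] * matrix.n_snps
    with open(map_path, "w") as fh:
        for (chrom, pos), sid in zip(loci, matrix.snp_ids):
            fh.write(f"{chrom}\t{sid}\t0\t{pos}\n")
    code_to_pair = []
    for lab in alleles:
        major, minor = lab if lab is not None else _DEFAULT_ALLELES
        if minor == ".":
            minor = _DEFAULT_ALLELES[1] if major != _DEFAULT_ALLELES[1] else "C"
        code_to_pair.append(
            {0: ("0", "0"), 1: (major, major), 2: (major, minor), 3: (minor, minor)}
        )
    with open(ped_path, "w") as fh:
        for s in range(matrix.n_samples):
            tok = [
                f"FAM{s + 1}",
                matrix.sample_ids[s],
                "0",
                "0",
                "0",
                "2" if matrix.phenotype[s] else "1",
            ]
            for j in range(matrix.n_snps):
                tok.extend(code_to_pair[j][int(matrix.genotypes[s, j])])
            fh.write(" ".join(tok) + "\n")
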