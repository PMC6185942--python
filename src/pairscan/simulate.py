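"""Synthetic case-control GWAS data with a planted pattern interaction.

Null SNPs are drawn per sample from Hardy-Weinberg proportions at
per-SNP minor-allele frequencies sampled uniformly from ``maf_range``,
independent of phenotype and of each other (linkage equilibrium).  One
optional SNP pair is planted with a two-level penetrance model realising
a genotype interaction pattern: individuals whose joint genotype falls
in the pattern's black group are affected with probability ``f_black``,
all others with ``f_white``.  The two penetrances are calibrated from a
broad-sense heritability on the observed disease scale,

    h2 = p_black (1 - p_black) (f_black - f_white)^2 / (K (1 - K)),

where ``p_black`` is the population frequency of black joint genotypes
under HWE and linkage equilibrium and ``K`` the disease prevalence.
Case/control ascertainment is retrospective: individuals are simulated
from population genotype frequencies and accepted until the requested
numbers of cases and controls are reached, so sample counts are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genotype_io import GenotypeMatrix, write_matrix_tsv, write_plink_text
from .patterns import InteractionPattern, enumerate_patterns


class CalibrationError(ValueError):
    """Requested heritability is infeasible for the pattern/MAF/prevalence."""


@dataclass(frozen=True)
class PlantedInteraction:
    """Ground-truth interaction to plant: pattern, MAFs, h2, prevalence."""

    pattern_id: int = 1
    maf1: float = 0.4
    maf2: float = 0.4
    heritability: float = 0.1
    prevalence: float = 0.25
    snp_indices: tuple[int, int] = (0, 1)


@dataclass(frozen=True)
class SimulationConfig:
    """Study design of one synthetic dataset; the seed fixes it entirely."""

    n_snps: int = 1000
    n_cases: int = 1000
    n_controls: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    planted: PlantedInteraction | None = field(default_factory=PlantedInteraction)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_snps < 1 or self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_snps, n_cases, n_controls must be >= 1")


@dataclass(frozen=True)
class PenetranceModel:
    """Two-level penetrance realising a pattern's black/white dichotomy."""

    f_black: float
    f_white: float
    p_black: float

    def heritability(self, prevalence: float) -> float:
        """Broad-sense h2 on the observed scale implied by the model."""
        p = self.p_black
        return (
            p * (1.0 - p) * (self.f_black - self.f_white) ** 2
            / (prevalence * (1.0 - prevalence))
        )


def hwe_frequencies(maf: float) -> np.ndarray:
    """HWE genotype frequencies (hom-major, het, hom-minor) at a given MAF."""
    q = maf
    return np.array([(1.0 - q) ** 2, 2.0 * q * (1.0 - q), q * q])


def _pattern_by_id(pattern_id: int) -> InteractionPattern:
    for p in enumerate_patterns():
        if p.id == pattern_id:
            return p
    raise ValueError(f"no pattern with id {pattern_id}")


def calibrate_penetrance(
    pattern: InteractionPattern | int,
    maf1: float,
    maf2: float,
    heritability: float,
    prevalence: float,
) -> PenetranceModel:
    """Solve the two penetrances from (pattern, MAFs, h2, prevalence).

    ``f_black - f_white = sqrt(h2 K (1-K) / (p_black (1 - p_black)))``
    with the population mean pinned at K.  Raises
    :class:`CalibrationError` when either penetrance leaves [0, 1] --
    presence patterns have common black groups, so large h2 at low
    prevalence is genuinely unrealisable.
    """
    if isinstance(pattern, int):
        pattern = _pattern_by_id(pattern)
    if not (0.0 <= heritability < 1.0):
        raise CalibrationError("heritability must lie in [0, 1)")
    if not (0.0 < prevalence < 1.0):
        raise CalibrationError("prevalence must lie in (0, 1)")
    joint = np.outer(hwe_frequencies(maf1), hwe_frequencies(maf2))
    p_black = float(joint[pattern.mask_array()].sum())
    if heritability == 0.0:
        return PenetranceModel(prevalence, prevalence, p_black)
    if p_black <= 0.0 or p_black >= 1.0:
        raise CalibrationError("pattern's black group has degenerate frequency")
    k = prevalence
    delta = np.sqrt(heritability * k * (1.0 - k) / (p_black * (1.0 - p_black)))
    f_black = k + (1.0 - p_black) * delta
    f_white = k - p_black * delta
    if not (0.0 <= f_white <= 1.0 and 0.0 <= f_black <= 1.0):
        raise CalibrationError(
            f"h2={heritability} infeasible for p_black={p_black:.4f}, K={k}:"
            f" penetrances ({f_black:.4f}, {f_white:.4f}) leave [0, 1]"
        )
    return PenetranceModel(float(f_black), float(f_white), p_black)


def _sample_planted_pair(
    rng: np.random.Generator,
    pattern: InteractionPattern,
    maf1: float,
    maf2: float,
    model: PenetranceModel,
    n_cases: int,
    n_controls: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample joint genotypes; returns (case_pairs, control_pairs)."""
    joint = np.outer(hwe_frequencies(maf1), hwe_frequencies(maf2)).ravel()
    black_flat = pattern.mask_array().ravel()
    case_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    n_case = n_ctrl = 0
    batch = max(4096, 4 * (n_cases + n_controls))
    # expected acceptance is ~K for cases, ~1-K for controls; far more
    # than enough batches are allowed before declaring the model degenerate
    max_draws = 1000 * (n_cases + n_controls) + 10 * batch
    drawn = 0
    while n_case < n_cases or n_ctrl < n_controls:
        if drawn > max_draws:
            raise CalibrationError("degenerate penetrance: case/control accrual stalled")
        cells = rng.choice(9, size=batch, p=joint)
        f = np.where(black_flat[cells], model.f_black, model.f_white)
        diseased = rng.random(batch) < f
        pairs = np.stack([cells // 3 + 1, cells % 3 + 1], axis=1).astype(np.uint8)
        if n_case < n_cases:
            take = pairs[diseased][: n_cases - n_case]
            case_rows.append(take)
            n_case += len(take)
        if n_ctrl < n_controls:
            take = pairs[~diseased][: n_controls - n_ctrl]
            ctrl_rows.append(take)
            n_ctrl += len(take)
        drawn += batch
    return np.concatenate(case_rows), np.concatenate(ctrl_rows)


def generate_dataset(config: SimulationConfig) -> tuple[GenotypeMatrix, dict]:
    """Generate one dataset; returns (matrix, ground-truth record).

    Cases occupy the first ``n_cases`` rows.  The ground truth records
    the planted indices/ids, pattern, penetrance model and seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    m = config.n_snps
    lo, hi = config.maf_range

    mafs = rng.uniform(lo, hi, size=m)
    p_hom_major = (1.0 - mafs) ** 2
    p_not_hom_minor = p_hom_major + 2.0 * mafs * (1.0 - mafs)
    u = rng.random((n, m))
    geno = (1 + (u >= p_hom_major) + (u >= p_not_hom_minor)).astype(np.uint8)

    truth: dict = {"seed": config.seed, "planted": None}
    if config.planted is not None:
        pl = config.planted
        pattern = _pattern_by_id(pl.pattern_id)
        model = calibrate_penetrance(
            pattern, pl.maf1, pl.maf2, pl.heritability, pl.prevalence
        )
        i0, i1 = pl.snp_indices
        if not (0 <= i0 < m and 0 <= i1 < m and i0 != i1):
            raise ValueError("planted snp_indices out of range or equal")
        case_pairs, ctrl_pairs = _sample_planted_pair(
            rng, pattern, pl.maf1, pl.maf2, model, config.n_cases, config.n_controls
        )
        geno[: config.n_cases, i0] = case_pairs[:, 0]
        geno[: config.n_cases, i1] = case_pairs[:, 1]
        geno[config.n_cases :, i0] = ctrl_pairs[:, 0]
        geno[config.n_cases :, i1] = ctrl_pairs[:, 1]
        mafs[i0] = pl.maf1
        mafs[i1] = pl.maf2
        truth["planted"] = {
            "snp_indices": [i0, i1],
            "snp_ids": [f"snp_{i0 + 1:05d}", f"snp_{i1 + 1:05d}"],
            "pattern_id": pl.pattern_id,
            "maf1": pl.maf1,
            "maf2": pl.maf2,
            "heritability": pl.heritability,
            "prevalence": pl.prevalence,
            "f_black": model.f_black,
            "f_white": model.f_white,
            "p_black": model.p_black,
        }

    if config.missing_rate > 0.0:
        geno[rng.random(geno.shape) < config.missing_rate] = 0

    phenotype = np.zeros(n, dtype=bool)
    phenotype[: config.n_cases] = True
    matrix = GenotypeMatrix(
        genotypes=geno,
        phenotype=phenotype,
        snp_ids=[f"snp_{j + 1:05d}" for j in range(m)],
        sample_ids=[
            f"case_{s + 1:05d}" if s < config.n_cases else f"control_{s - config.n_cases + 1:05d}"
            for s in range(n)
        ],
        snp_loci=[("1", 1 + 1000 * j) for j in range(m)],
        alleles=[("A", "G")] * m,
    )
    truth["config"] = asdict(config)
    return matrix, truth


def write_fixture(matrix: GenotypeMatrix, truth: dict, out_dir) -> dict[str, Path]:
    """Write TSV, .ped/.map and ground-truth JSON renditions of a dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tsv": out / "matrix.tsv",
        "ped": out / "genotypes.ped",
        "map": out / "genotypes.map",
        "truth": out / "truth.json",
    }
    write_matrix_tsv(matrix, paths["tsv"])
    write_plink_text(matrix, paths["ped"], paths["map"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def benchmark_configs(
    heritabilities: tuple[float, ...] = (0.05, 0.1, 0.15),
    snp_counts: tuple[int, ...] = (1000, 5000, 10000),
    seed: int = 0,
) -> list[SimulationConfig]:
    """Configs spanning the benchmark grid of SNP counts x heritabilities."""
    configs = []
    for k, n_snps in enumerate(snp_counts):
        for l, h2 in enumerate(heritabilities):
            configs.append(
                SimulationConfig(
                    n_snps=n_snps,
                    planted=PlantedInteraction(heritability=h2),
                    seed=seed + 100 * k + l,
                )
            )
    return configs
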