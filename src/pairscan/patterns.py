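"""Biologically plausible two-locus genotype interaction patterns.

Two biallelic SNPs jointly define a 3x3 genotype table (hom-major, het,
hom-minor at each locus), so there are 2**9 = 512 possible black/white
labellings of that table.  Under a bio-molecule complex model -- each
locus produces one protein subtype per allele, the subtypes of the two
loci dock into at most four complexes, and exactly one complex is
disease-associated -- only eight labellings are biologically
interpretable:

* *presence* condition: the complex alters risk whenever it can form,
  i.e. whenever each locus carries at least one copy of the complex's
  allele (4 black cells, a Cartesian product of carrier genotypes);
* *solo* condition: the complex alters risk only when it is the sole
  complex formed, i.e. both loci are homozygous for the complex's
  alleles (1 black cell).

Four complexes (major/major, major/minor, minor/major, minor/minor)
times two conditions give the eight patterns enumerated here.  The set
is closed under transposition, which is what makes scanning unordered
SNP pairs with all eight patterns equivalent to scanning ordered pairs.

Genotype codes follow the package-wide encoding: 0 missing, 1 hom-major,
2 het, 3 hom-minor.  Masks are indexed over codes (1, 2, 3) x (1, 2, 3);
missing genotypes fall outside the mask domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

Allele = Literal["major", "minor"]
Condition = Literal["presence", "solo"]

#: genotype codes (1..3) carrying at least one copy of the given allele
_CARRIERS: dict[str, tuple[int, ...]] = {"major": (1, 2), "minor": (2, 3)}
#: genotype code homozygous for the given allele
_HOMOZYGOTE: dict[str, int] = {"major": 1, "minor": 3}

_COMPLEX_ORDER: tuple[tuple[Allele, Allele], ...] = (
    ("major", "major"),
    ("major", "minor"),
    ("minor", "major"),
    ("minor", "minor"),
)


@dataclass(frozen=True)
class InteractionPattern:
    """One black/white labelling of the 3x3 joint-genotype table.

    Attributes
    ----------
    id:
        Stable integer 1-8.  Presence patterns are 1-4 and solo patterns
        5-8, complexes ordered (major,major), (major,minor),
        (minor,major), (minor,minor).  This ordering is a package
        convention chosen so result files are comparable across runs.
    complex:
        The disease-associated complex as the allele contributed by each
        locus, e.g. ``("major", "minor")``.
    condition:
        ``"presence"`` or ``"solo"`` (see module docstring).
    mask:
        3x3 nested tuple of bools over genotype codes (1,2,3) x (1,2,3);
        ``True`` marks a black (risk-grouped) genotype.
    """

    id: int
    complex: tuple[Allele, Allele]
    condition: Condition
    mask: tuple[tuple[bool, bool, bool], ...]

    def mask_array(self) -> np.ndarray:
        """Mask as a 3x3 boolean ndarray indexed by ``[code1-1, code2-1]``."""
        return np.array(self.mask, dtype=bool)

    def mask4(self) -> np.ndarray:
        """Mask padded to 4x4 so genotype codes index it directly.

        Row and column 0 (missing genotype) are all ``False``: a missing
        call belongs to neither the black nor the white group.
        """
        m = np.zeros((4, 4), dtype=bool)
        m[1:, 1:] = self.mask_array()
        return m

    def black_cells(self) -> frozenset[tuple[int, int]]:
        """Set of black genotype-code pairs ``(g1, g2)`` with codes in 1..3."""
        return frozenset(
            (i + 1, j + 1) for i in range(3) for j in range(3) if self.mask[i][j]
        )


def _freeze(mask: np.ndarray) -> tuple[tuple[bool, bool, bool], ...]:
    return tuple(tuple(bool(v) for v in row) for row in mask)


def derive_pattern(
    complex: tuple[Allele, Allele], condition: Condition, id: int = 0
) -> InteractionPattern:
    """Derive the mask implied by a disease-associated complex.

    Parameters
    ----------
    complex:
        ``(allele_site1, allele_site2)`` with alleles ``"major"`` or
        ``"minor"`` -- which allele of each locus contributes to the
        complex.
    condition:
        ``"presence"``: black cells are every genotype pair where each
        locus carries >=1 copy of its complex allele.  ``"solo"``: the
        single cell homozygous for both complex alleles.
    id:
        Pattern id to stamp on the result; :func:`enumerate_patterns`
        assigns the canonical ids.
    """
    a, b = complex
    if a not in _CARRIERS or b not in _CARRIERS:
        raise ValueError(f"complex alleles must be 'major'/'minor', got {complex!r}")
    mask = np.zeros((3, 3), dtype=bool)
    if condition == "presence":
        for g1 in _CARRIERS[a]:
            for g2 in _CARRIERS[b]:
                mask[g1 - 1, g2 - 1] = True
    elif condition == "solo":
        mask[_HOMOZYGOTE[a] - 1, _HOMOZYGOTE[b] - 1] = True
    else:
        raise ValueError(f"condition must be 'presence' or 'solo', got {condition!r}")
    return InteractionPattern(id=id, complex=(a, b), condition=condition, mask=_freeze(mask))


def enumerate_patterns() -> list[InteractionPattern]:
    """The eight patterns, deduplicated by mask, in canonical order.

    Presence patterns first (ids 1-4), then solo (ids 5-8); within each
    condition the complexes run (maj,maj), (maj,min), (min,maj),
    (min,min).  Deterministic: calling twice yields identical lists.
    """
    patterns: list[InteractionPattern] = []
    seen: set[tuple] = set()
    next_id = 1
    for condition in ("presence", "solo"):
        for cx in _COMPLEX_ORDER:
            p = derive_pattern(cx, condition, id=next_id)
            if p.mask in seen:  # pragma: no cover - the 8 masks are distinct
                continue
            seen.add(p.mask)
            patterns.append(p)
            next_id += 1
    return patterns


def transpose_pattern(p: InteractionPattern) -> InteractionPattern:
    """The pattern whose mask is the transpose of ``p``'s mask.

    The eight-pattern set is closed under transposition (swapping the
    two loci swaps the complex's allele roles), so the result is again a
    canonical pattern with its own id.
    """
    target = _freeze(p.mask_array().T)
    for q in enumerate_patterns():
        if q.mask == target:
            return q
    raise ValueError("mask transpose left the eight-pattern set")  # pragma: no cover


def pattern_table(patterns: Iterable[InteractionPattern] | None = None) -> list[dict]:
    """Flat description of the patterns (id, complex, condition, 9 mask bits).

    Suitable for JSON/TSV export and documentation fixtures.
    """
    rows = []
    for p in patterns if patterns is not None else enumerate_patterns():
        row = {
            "id": p.id,
            "allele_site1": p.complex[0],
            "allele_site2": p.complex[1],
            "condition": p.condition,
        }
        for i in range(3):
            for j in range(3):
                row[f"mask_{i + 1}{j + 1}"] = int(p.mask[i][j])
        rows.append(row)
    return rows
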