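"""Alleles, genotypes and individuals at a single diploid locus.

The model tracks four alleles. Residents carry ``W1``/``W2``; migrants carry
``L1``/``L2``. ``L2`` is the unique deleterious allele: L2/L2 homozygotes
suffer reduced survival, reduced breeding-pool entry, and depress the
fecundity of any pairing they enter.

This module holds the scalar (single-individual) layer: the vectorized
population engine in :mod:`floodsim.engine` applies the same rules to whole
arrays and is cross-checked against these functions in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

__all__ = [
    "ALLELES",
    "W1",
    "W2",
    "L1",
    "L2",
    "Genotype",
    "Individual",
    "survival_multiplier",
    "pair_fecundity_multiplier",
    "mendelian_offspring",
]

#: Allele labels in canonical order; integer codes used by the engine are
#: the positions in this tuple.
ALLELES = ("W1", "W2", "L1", "L2")
W1, W2, L1, L2 = range(4)

RESIDENT_ALLELES = frozenset({"W1", "W2"})
MIGRANT_ALLELES = frozenset({"L1", "L2"})


def _check_allele(label: str) -> str:
    if label not in ALLELES:
        raise ValueError(f"unknown allele label {label!r}; expected one of {ALLELES}")
    return label


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of alleles: ``Genotype('W1', 'L2') == Genotype('L2', 'W1')``."""

    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        _check_allele(self.allele_a)
        _check_allele(self.allele_b)
        # canonicalize so equality/hash are order-insensitive
        a, b = sorted((self.allele_a, self.allele_b), key=ALLELES.index)
        object.__setattr__(self, "allele_a", a)
        object.__setattr__(self, "allele_b", b)

    @property
    def is_L2_homozygote(self) -> bool:
        return self.allele_a == "L2" and self.allele_b == "L2"

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)

    def __str__(self) -> str:  # e.g. "W1/L2"
        return f"{self.allele_a}/{self.allele_b}"


@dataclass
class Individual:
    """One diploid organism.

    ``introduced`` is True only for individuals that entered via a migration
    pulse; all in-simulation births have it False, so migrant mating
    penalties never propagate to descendants. ``age`` counts survived
    generations.
    """

    sex: str  # "female" | "male"
    genotype: Genotype
    introduced: bool = False
    age: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.introduced and not set(self.genotype.alleles) <= MIGRANT_ALLELES:
            raise ValueError(
                "introduced individuals carry only migrant alleles (L1/L2), "
                f"got {self.genotype}"
            )


def survival_multiplier(genotype: Genotype, params: ModelParams) -> float:
    """Viability penalty: ``survival_mult_L2L2`` for L2/L2 homozygotes, else 1."""
    return params.survival_mult_L2L2 if genotype.is_L2_homozygote else 1.0


def pair_fecundity_multiplier(
    parent_a: Genotype, parent_b: Genotype, params: ModelParams
) -> float:
    """Fecundity penalty of a pairing, by the number of L2/L2 parents.

    1.0 if neither parent is L2/L2, ``fecundity_mult_one_homo`` if exactly
    one is (default 0.7, a 30% reduction), ``fecundity_mult_both_homo`` if
    both are (default 0.2, an 80% reduction).
    """
    n_homo = int(parent_a.is_L2_homozygote) + int(parent_b.is_L2_homozygote)
    if n_homo == 0:
        return 1.0
    if n_homo == 1:
        return params.fecundity_mult_one_homo
    return params.fecundity_mult_both_homo


def mendelian_offspring(
    mother: Individual, father: Individual, rng: np.random.Generator
) -> Individual:
    """Draw one offspring: one allele uniformly from each parent, sex 50/50."""
    if mother.sex != "female" or father.sex != "male":
        raise ValueError(
            f"mendelian_offspring requires a female mother and male father, "
            f"got mother.sex={mother.sex!r}, father.sex={father.sex!r}"
        )
    maternal = mother.genotype.alleles[rng.integers(2)]
    paternal = father.genotype.alleles[rng.integers(2)]
    sex = "female" if rng.random() < 0.5 else "male"
    return Individual(sex=sex, genotype=Genotype(maternal, paternal), introduced=False, age=0)
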