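"""Model parameterization and validation.

A single :class:`ModelParams` object fully specifies one stochastic
replicate of the gene-flooding model: the demography (carrying capacity,
adult survival, litter sizes), the migration schedule (fraction ``m``
introduced every generation), the genotype-dependent fitness penalties
attached to the migrant-associated deleterious allele L2, and the RNG seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["ModelParams", "ParameterError", "PULSE_BASES"]

#: Conventions for converting the migration fraction ``m`` into a head-count.
#: ``"capacity"`` introduces round(m * K) migrants per generation (a constant
#: pulse); ``"current"`` introduces round(m * N) where N is the standing
#: population size at the start of the generation.
PULSE_BASES = ("capacity", "current")


class ParameterError(ValueError):
    """Raised when a model parameter violates its documented constraint."""


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of one simulation run.

    Parameters
    ----------
    K
        Carrying capacity, individuals. The population is stochastically
        culled back to ``K`` whenever it exceeds it.
    m
        Migration fraction in [0, 1): the per-generation migrant pulse is
        ``round(m * K)`` individuals (or ``round(m * N)`` under the
        ``"current"`` pulse basis).
    generations
        Number of generations to simulate (the horizon).
    base_survival
        Per-generation adult survival probability, genotype-independent
        baseline. Adults persisting across generations is what makes
        generations overlap.
    survival_mult_L2L2
        Survival multiplier applied to L2/L2 homozygotes (default 0.5,
        a 50% survival reduction).
    repro_mult_L2L2
        Breeding-pool entry multiplier for L2/L2 homozygotes — the
        "reduced reproductive success" penalty, distinct from the survival
        and pair-fecundity penalties.
    fecundity_mult_one_homo
        Pair fecundity multiplier when exactly one parent is L2/L2
        (default 0.7, a 30% fecundity reduction).
    fecundity_mult_both_homo
        Pair fecundity multiplier when both parents are L2/L2
        (default 0.2, an 80% reduction).
    mean_litter
        Mean Poisson litter size per pairing, before fecundity penalties,
        summed over mating rounds.
    mating_penalty
        Probability reduction in [0, 1] applied to *introduced* individuals'
        breeding-pool entry; never inherited by their descendants.
    multiple_paternity_factor
        Number of mating rounds per generation. Each pooled female redraws
        a mate every round; per-round litter means are divided by the round
        count so expected fecundity is invariant to mating structure.
    migrant_L2_freq
        Frequency of L2 among migrant gametes (migrants carry only L1/L2).
    resident_W2_freq
        Frequency of W2 among founder gametes (residents carry only W1/W2).
    seed
        Integer seed; a replicate is fully reproducible from its params.
    pulse_basis
        ``"capacity"`` (default) or ``"current"``; see :data:`PULSE_BASES`.
    """

    K: int = 1000
    m: float = 0.1
    generations: int = 100
    base_survival: float = 0.5
    survival_mult_L2L2: float = 0.5
    repro_mult_L2L2: float = 0.5
    fecundity_mult_one_homo: float = 0.7
    fecundity_mult_both_homo: float = 0.2
    mean_litter: float = 2.0
    mating_penalty: float = 0.0
    multiple_paternity_factor: int = 1
    migrant_L2_freq: float = 0.5
    resident_W2_freq: float = 0.5
    seed: int = 0
    pulse_basis: str = "capacity"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check every field against its constraint; raise :class:`ParameterError`."""
        if not (isinstance(self.K, (int,)) and self.K >= 2):
            raise ParameterError(f"K must be an integer >= 2, got {self.K!r}")
        if not (isinstance(self.generations, int) and self.generations >= 1):
            raise ParameterError(
                f"generations must be a positive integer, got {self.generations!r}"
            )
        if not (0.0 <= self.m < 1.0):
            raise ParameterError(f"m must lie in [0, 1), got {self.m!r}")
        if not (0.0 <= self.base_survival <= 1.0):
            raise ParameterError(
                f"base_survival must lie in [0, 1], got {self.base_survival!r}"
            )
        for name in (
            "survival_mult_L2L2",
            "repro_mult_L2L2",
            "fecundity_mult_one_homo",
            "fecundity_mult_both_homo",
            "mating_penalty",
            "migrant_L2_freq",
            "resident_W2_freq",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")
        if not (self.mean_litter >= 0):
            raise ParameterError(
                f"mean_litter must be non-negative, got {self.mean_litter!r}"
            )
        if not (
            isinstance(self.multiple_paternity_factor, int)
            and self.multiple_paternity_factor >= 1
        ):
            raise ParameterError(
                "multiple_paternity_factor must be a positive integer, got "
                f"{self.multiple_paternity_factor!r}"
            )
        if self.pulse_basis not in PULSE_BASES:
            raise ParameterError(
                f"pulse_basis must be one of {PULSE_BASES}, got {self.pulse_basis!r}"
            )
        if not isinstance(self.seed, int):
            raise ParameterError(f"seed must be an integer, got {self.seed!r}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))
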