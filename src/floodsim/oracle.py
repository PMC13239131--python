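"""Infinite-population (mean-field) companion to the stochastic engine.

Tracks expected genotype masses through the same per-generation event order
as the individual-based model — migrant pulse, viability survival,
breeding-pool entry, fecundity-weighted random mating, frequency-neutral
culling — but in expectation, with no sampling noise. It exists to validate
the stochastic engine: at large carrying capacity the replicate-mean allele
frequencies of the individual-based model must track this recursion.

State is a pair of 4x4 symmetric genotype-mass matrices (ordered allele
pairs over W1, W2, L1, L2), one for natives and one for introduced
individuals, in units of the carrying capacity K. Keeping the introduced
compartment separate lets the migrant mating penalty act on exactly the
individuals that arrived in a pulse. Masses above 1 (= K) are scaled back
uniformly, mirroring the frequency-neutral cull.

The mating step collapses the stochastic pairing machinery to expected
pair weights: with every pooled female mating each round and per-round
litter means divided by the round count, expected offspring production is
independent of the multiple-paternity factor, so the recursion needs no
notion of mating rounds. The reduction is exact for expectations only —
this is a validation device, not a results generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .individuals import ALLELES, L2
from .params import ModelParams

__all__ = [
    "GenotypeFrequencies",
    "OracleState",
    "founder_state",
    "migrant_fraction",
    "oracle_step",
    "oracle_trajectory",
]

_N_ALLELES = 4


@dataclass(frozen=True)
class GenotypeFrequencies:
    """Frequencies of the 10 unordered genotypes over the four alleles.

    Backed by a symmetric 4x4 matrix over ordered allele pairs; the
    unordered view sums the two off-diagonal entries of each pair.
    """

    matrix: np.ndarray  # (4, 4) symmetric, non-negative, sums to 1

    def __post_init__(self) -> None:
        total = float(self.matrix.sum())
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError(f"genotype frequencies must sum to 1, got {total!r}")
        if (self.matrix < -1e-15).any():
            raise ValueError("genotype frequencies must be non-negative")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("genotype matrix must be symmetric")

    def as_dict(self) -> dict[tuple[str, str], float]:
        out: dict[tuple[str, str], float] = {}
        for i in range(_N_ALLELES):
            for j in range(i, _N_ALLELES):
                value = self.matrix[i, j] if i == j else self.matrix[i, j] * 2
                out[(ALLELES[i], ALLELES[j])] = float(value)
        return out

    def allele_frequencies(self) -> dict[str, float]:
        gam = self.matrix.sum(axis=0)  # symmetric: row and column marginals agree
        return {label: float(gam[i]) for i, label in enumerate(ALLELES)}

    @property
    def resident_frequency(self) -> float:
        """Combined frequency of the resident alleles W1 + W2."""
        freqs = self.allele_frequencies()
        return freqs["W1"] + freqs["W2"]


@dataclass(frozen=True)
class OracleState:
    """Genotype masses (units of K) split into native and introduced pools."""

    native: np.ndarray  # (4, 4) symmetric mass matrix
    introduced: np.ndarray

    @property
    def total_mass(self) -> float:
        return float(self.native.sum() + self.introduced.sum())

    def frequencies(self) -> GenotypeFrequencies:
        combined = self.native + self.introduced
        return GenotypeFrequencies(matrix=combined / combined.sum())

    @property
    def resident_frequency(self) -> float:
        return self.frequencies().resident_frequency


def _hwe_matrix(gametes: np.ndarray) -> np.ndarray:
    return np.outer(gametes, gametes)


def founder_state(params: ModelParams) -> OracleState:
    """Resident founders at Hardy-Weinberg over {W1, W2}, mass 1 (= K)."""
    gam = np.array(
        [1 - params.resident_W2_freq, params.resident_W2_freq, 0.0, 0.0]
    )
    return OracleState(
        native=_hwe_matrix(gam), introduced=np.zeros((_N_ALLELES, _N_ALLELES))
    )


def migrant_fraction(m: float) -> float:
    """Expected post-pulse migrant fraction when a pulse of m*K joins a
    population standing at K: m / (1 + m)."""
    return m / (1.0 + m)


def _survival_weights(params: ModelParams) -> np.ndarray:
    w = np.full((_N_ALLELES, _N_ALLELES), params.base_survival)
    w[L2, L2] *= params.survival_mult_L2L2
    return w


def oracle_step(state: OracleState, params: ModelParams) -> OracleState:
    """Advance expected genotype masses by one generation.

    Mirrors the engine's event order: (1) a migrant pulse of mass m (or
    m x current mass under the 'current' basis) at Hardy-Weinberg over
    {L1, L2}; (2) viability reweighting; (3) breeding-pool entry weights
    (mating penalty on the introduced pool, reproductive-success multiplier
    on L2/L2) and random union of gametes with pair-fecundity weights; the
    offspring join the surviving adults; (4) uniform cull back to mass 1,
    which is frequency-neutral.
    """
    native = state.native.copy()
    introduced = state.introduced.copy()

    # (1) migrant pulse
    if params.m > 0:
        pulse_mass = (
            params.m
            if params.pulse_basis == "capacity"
            else params.m * state.total_mass
        )
        mig_gam = np.array(
            [0.0, 0.0, 1 - params.migrant_L2_freq, params.migrant_L2_freq]
        )
        introduced = introduced + pulse_mass * _hwe_matrix(mig_gam)

    # (2) viability survival
    w = _survival_weights(params)
    native_surv = native * w
    introduced_surv = introduced * w

    # (3) breeding pool and mating
    entry = np.ones((_N_ALLELES, _N_ALLELES))
    entry[L2, L2] = params.repro_mult_L2L2
    pool = native_surv * entry + introduced_surv * entry * (1 - params.mating_penalty)
    pool_mass = pool.sum()
    offspring = np.zeros((_N_ALLELES, _N_ALLELES))
    if pool_mass > 0:
        homo_mass = pool[L2, L2]
        non_homo = pool.copy()
        non_homo[L2, L2] = 0.0
        non_homo_mass = non_homo.sum()
        p_homo = homo_mass / pool_mass
        classes = []  # (probability, gamete distribution) per parental class
        if non_homo_mass > 0:
            gam_non = (non_homo.sum(axis=0) + non_homo.sum(axis=1)) / (
                2 * non_homo_mass
            )
            classes.append((1 - p_homo, gam_non, False))
        if homo_mass > 0:
            gam_homo = np.zeros(_N_ALLELES)
            gam_homo[L2] = 1.0
            classes.append((p_homo, gam_homo, True))
        fec = {
            0: 1.0,
            1: params.fecundity_mult_one_homo,
            2: params.fecundity_mult_both_homo,
        }
        pooled_females = pool_mass / 2.0
        for p_f, gam_f, homo_f in classes:
            for p_m, gam_m, homo_m in classes:
                weight = p_f * p_m * fec[int(homo_f) + int(homo_m)]
                if weight > 0:
                    pair = np.outer(gam_f, gam_m)
                    offspring += weight * (pair + pair.T) / 2.0
        offspring *= pooled_females * params.mean_litter

    native_next = native_surv + offspring
    introduced_next = introduced_surv

    # (4) cull back to capacity (frequency-neutral)
    total = native_next.sum() + introduced_next.sum()
    if total > 1.0:
        native_next /= total
        introduced_next /= total
    return OracleState(native=native_next, introduced=introduced_next)


def oracle_trajectory(
    params: ModelParams, generations: int | None = None
) -> list[OracleState]:
    """Iterate the recursion from the founder state; deterministic.

    Returns ``generations + 1`` states including the founder state.
    """
    if generations is None:
        generations = params.generations
    states = [founder_state(params)]
    for _ in range(generations):
        states.append(oracle_step(states[-1], params))
    return states
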