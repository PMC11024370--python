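"""Closed-form expectations for spontaneous-mutation accumulation under selfing.

A pure line maintained by single-seed descent receives, each generation, an
expected N = mu * G new heterozygous mutations (mu: per-site per-generation
mutation probability; G: genome length in bp). Under Mendelian segregation in a
selfed offspring each heterozygous site independently becomes homozygous for
the derived allele with probability 1/4 (fixed), is lost with probability 1/4,
and stays heterozygous with probability 1/2.

The standing heterozygous load is therefore a geometric series with initial
value N and ratio 1/2; after g generations it is N*(2 - 2**(1-g)), and at
saturation exactly 2N. The expected number of mutations newly fixed per
generation at saturation is (1/4) * 2N = N/2, so after g generations a lineage
carries about g*N/2 fixed mutations, of which a fraction ``coding_fraction``
fall in coding sequence. All quantities here are expectations; real-valued
(non-integer) counts are intentional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Sentinel for a heterozygous load at its stationary value (2N). The limit is
#: used directly rather than approximated with a large generation count.
SATURATED = "saturated"

#: Rice reference genome length in bp (default genome size for the model).
DEFAULT_GENOME_LENGTH = 373_000_000

#: Fraction of the genome in coding sequence, back-computed from the ratio of
#: the coding to whole-genome fixed-mutation expectations (10.4 / 69.0).
DEFAULT_CODING_FRACTION = 10.4 / 69.0


@dataclass(frozen=True)
class LineageParams:
    """Parameters of the selfing mutation-accumulation model.

    ``retention_ratio`` (probability a heterozygous site stays heterozygous)
    and ``fixation_fraction`` (probability it fixes homozygous) are fixed at
    1/2 and 1/4 by Mendelian segregation under selfing and are exposed only so
    the arithmetic is explicit; other values are rejected.
    """

    mu: float
    genome_length: int = DEFAULT_GENOME_LENGTH
    coding_fraction: float = DEFAULT_CODING_FRACTION
    retention_ratio: float = 0.5
    fixation_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if self.genome_length <= 0:
            raise ValueError(f"genome_length must be positive, got {self.genome_length}")
        if not 0.0 <= self.coding_fraction <= 1.0:
            raise ValueError(f"coding_fraction must lie in [0, 1], got {self.coding_fraction}")
        if self.retention_ratio != 0.5 or self.fixation_fraction != 0.25:
            raise ValueError(
                "Mendelian selfing fixes retention_ratio = 1/2 and "
                "fixation_fraction = 1/4; other values are not modelled"
            )


@dataclass(frozen=True)
class LoadEstimate:
    """Expected mutational load of a selfed lineage after some generations."""

    new_het_per_gen: float
    het_load: float
    fixed_per_gen: float
    accumulated_fixed: float
    accumulated_fixed_coding: float

    def __post_init__(self) -> None:
        fields = (
            self.new_het_per_gen,
            self.het_load,
            self.fixed_per_gen,
            self.accumulated_fixed,
            self.accumulated_fixed_coding,
        )
        if any(v < 0 for v in fields):
            raise ValueError("load estimates must be nonnegative")
        if self.het_load > 2 * self.new_het_per_gen * (1 + 1e-12):
            raise ValueError("het_load cannot exceed its saturation value 2N")
        if self.accumulated_fixed_coding > self.accumulated_fixed * (1 + 1e-12):
            raise ValueError("coding fixed count cannot exceed the genome-wide count")


def new_het_per_generation(params: LineageParams) -> float:
    """Expected new heterozygous mutations per generation, N = mu * G."""
    return params.mu * params.genome_length


def _check_generations(generations) -> int:
    g = int(generations)
    if g != generations:
        raise ValueError(f"generations must be an integer, got {generations!r}")
    if g < 0:
        raise ValueError(f"generations must be >= 0, got {g}")
    return g


def het_load(n_new: float, generations) -> float:
    """Expected standing heterozygous load after ``generations`` generations.

    Sum of the geometric series N * (1/2)**k for k = 0..g-1, i.e.
    N * (2 - 2**(1-g)); with ``generations=SATURATED`` the stationary value 2N.
    """
    if n_new < 0:
        raise ValueError(f"N must be >= 0, got {n_new}")
    if generations == SATURATED:
        return 2.0 * n_new
    g = _check_generations(generations)
    return n_new * (2.0 - 2.0 ** (1 - g))


def fixed_per_generation(n_new: float) -> float:
    """Expected mutations fixed homozygous per generation at saturation, N/2.

    One quarter of the saturated heterozygous load 2N fixes each generation.
    """
    if n_new < 0:
        raise ValueError(f"N must be >= 0, got {n_new}")
    return n_new / 2.0


def accumulated_fixed(
    n_new: float,
    generations,
    coding_fraction: float = DEFAULT_CODING_FRACTION,
) -> LoadEstimate:
    """Expected fixed-mutation load accumulated over ``generations`` generations.

    Returns the full :class:`LoadEstimate`: the per-generation influx N, the
    saturated heterozygous load 2N, the per-generation fixation N/2, the
    genome-wide accumulated count g*N/2 and its coding-sequence share.
    """
    if n_new < 0:
        raise ValueError(f"N must be >= 0, got {n_new}")
    if not 0.0 <= coding_fraction <= 1.0:
        raise ValueError(f"coding_fraction must lie in [0, 1], got {coding_fraction}")
    g = _check_generations(generations)
    total = g * n_new / 2.0
    return LoadEstimate(
        new_het_per_gen=n_new,
        het_load=het_load(n_new, SATURATED),
        fixed_per_gen=fixed_per_generation(n_new),
        accumulated_fixed=total,
        accumulated_fixed_coding=total * coding_fraction,
    )


def mu_for_target_n(n_new: float, genome_length: int = DEFAULT_GENOME_LENGTH) -> float:
    """Per-site rate mu that yields an expected N new het mutations/generation."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if n_new < 0:
        raise ValueError("N must be >= 0")
    return n_new / genome_length
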