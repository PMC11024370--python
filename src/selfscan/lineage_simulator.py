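"""Forward stochastic simulation of a selfed lineage under single-seed descent.

Each generation, every heterozygous site independently resolves by Mendelian
segregation — fixed homozygous with probability 1/4, lost with probability 1/4,
retained heterozygous with probability 1/2 — and a Poisson(N) number of new
heterozygous mutations arises at fresh loci (infinite-sites: at genome scale,
recurrent mutation at the same site is negligible). This is the stochastic
counterpart of the closed forms in :mod:`selfscan.mutation_model` and the
engine behind :mod:`selfscan.synthetic_data`.

The segregation probabilities are exposed so that perturbed models can be
simulated; defaults are the Mendelian (1/4, 1/4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FIXATION_PROB = 0.25
LOSS_PROB = 0.25


@dataclass
class LineageState:
    """Het/fixed status of every mutant locus in one lineage.

    Loci are opaque integer identifiers handed out sequentially; the
    ``next_locus`` counter guarantees new mutations never collide with old ones.
    """

    generation: int = 0
    het_sites: frozenset = frozenset()
    fixed_sites: frozenset = frozenset()
    next_locus: int = 0

    def __post_init__(self) -> None:
        if self.het_sites & self.fixed_sites:
            raise ValueError("a locus cannot be both heterozygous and fixed")


@dataclass(frozen=True)
class Trajectory:
    """Per-generation records of one simulated lineage.

    Arrays are aligned by generation (index 0 = first simulated generation).
    ``newly_lost`` is kept alongside the four core columns because the
    fixed/lost symmetry of segregation is a useful diagnostic.
    """

    new_het: np.ndarray
    het_count: np.ndarray
    newly_fixed: np.ndarray
    newly_lost: np.ndarray
    fixed_total: np.ndarray
    rng_seed: int
    burn_in: int = 0

    def __post_init__(self) -> None:
        n = len(self.new_het)
        for arr in (self.het_count, self.newly_fixed, self.newly_lost, self.fixed_total):
            if len(arr) != n:
                raise ValueError("trajectory columns must have equal length")
        if not np.array_equal(np.cumsum(self.newly_fixed), self.fixed_total):
            raise ValueError("fixed_total must be the running sum of newly_fixed")

    def __len__(self) -> int:
        return len(self.new_het)

    @property
    def stationary_mean_het(self) -> float:
        """Mean standing heterozygous count over post-burn-in generations."""
        return float(np.mean(self.het_count[self.burn_in:]))

    @property
    def stationary_mean_fixed(self) -> float:
        """Mean newly fixed mutations per generation, post burn-in."""
        return float(np.mean(self.newly_fixed[self.burn_in:]))

    @property
    def stationary_mean_lost(self) -> float:
        return float(np.mean(self.newly_lost[self.burn_in:]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(1, len(self) + 1),
                "new_het": self.new_het,
                "het_count": self.het_count,
                "newly_fixed": self.newly_fixed,
                "newly_lost": self.newly_lost,
                "fixed_total": self.fixed_total,
            }
        )


def step(
    state: LineageState,
    n_new: float,
    rng: np.random.Generator,
    fixation_prob: float = FIXATION_PROB,
    loss_prob: float = LOSS_PROB,
) -> LineageState:
    """Advance one generation of selfing.

    Existing heterozygous sites resolve independently (fix / lose / retain);
    Poisson(``n_new``) fresh heterozygous loci are then added. Draw order over
    existing sites is by sorted locus id, so a given generator state yields a
    reproducible outcome.
    """
    if n_new < 0:
        raise ValueError(f"N must be >= 0, got {n_new}")
    if fixation_prob < 0 or loss_prob < 0 or fixation_prob + loss_prob > 1:
        raise ValueError("fixation/loss probabilities must be nonnegative and sum to <= 1")

    het = np.array(sorted(state.het_sites), dtype=np.int64)
    if het.size:
        u = rng.random(het.size)
        fixed_mask = u < fixation_prob
        lost_mask = (u >= fixation_prob) & (u < fixation_prob + loss_prob)
        retained = het[~fixed_mask & ~lost_mask]
        newly_fixed = het[fixed_mask]
    else:
        retained = het
        newly_fixed = het

    n_fresh = int(rng.poisson(n_new)) if n_new > 0 else 0
    fresh = range(state.next_locus, state.next_locus + n_fresh)

    return LineageState(
        generation=state.generation + 1,
        het_sites=frozenset(retained.tolist()) | frozenset(fresh),
        fixed_sites=state.fixed_sites | frozenset(newly_fixed.tolist()),
        next_locus=state.next_locus + n_fresh,
    )


def run(
    n_new: float,
    generations: int,
    burn_in: int = 0,
    seed: int = 0,
    fixation_prob: float = FIXATION_PROB,
    loss_prob: float = LOSS_PROB,
) -> Trajectory:
    """Simulate ``generations`` generations from a mutation-free founder.

    ``burn_in`` marks how many leading generations the stationary summaries
    exclude; it must leave at least one generation to average over.
    """
    if generations <= burn_in or burn_in < 0:
        raise ValueError("need generations > burn_in >= 0")
    rng = np.random.default_rng(seed)
    state = LineageState()

    new_het = np.zeros(generations, dtype=np.int64)
    het_count = np.zeros(generations, dtype=np.int64)
    newly_fixed = np.zeros(generations, dtype=np.int64)
    newly_lost = np.zeros(generations, dtype=np.int64)

    for t in range(generations):
        prev = state
        state = step(prev, n_new, rng, fixation_prob, loss_prob)
        new_het[t] = state.next_locus - prev.next_locus
        het_count[t] = len(state.het_sites)
        newly_fixed[t] = len(state.fixed_sites) - len(prev.fixed_sites)
        resolved = len(prev.het_sites) - (len(state.het_sites) - new_het[t])
        newly_lost[t] = resolved - newly_fixed[t]

    return Trajectory(
        new_het=new_het,
        het_count=het_count,
        newly_fixed=newly_fixed,
        newly_lost=newly_lost,
        fixed_total=np.cumsum(newly_fixed),
        rng_seed=seed,
        burn_in=burn_in,
    )
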