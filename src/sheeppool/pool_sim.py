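"""Simulator of the two-stage pooled screen.

First stage: the cohort is randomly permuted and chunked into consecutive
pools of size ``a`` (the remainder forms one smaller final pool); each pool
costs one PCR reaction.  A pool whose members all share one genotype is
called wholesale; a pool showing mixed genotypes sends every member to an
individual second-stage retest (one reaction each).  The assay is error-free
by default, so called genotypes always equal true genotypes and the only
quantity at stake is the realized reaction count, which the analytic design
formula predicts in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pool_design import expected_reactions

__all__ = [
    "PoolPlan",
    "ScreenOutcome",
    "make_pools",
    "screen",
    "simulate_reaction_counts",
    "empirical_curve",
]


@dataclass(frozen=True)
class PoolPlan:
    """Partition of individual IDs into ordered pools of size ``a``."""

    assignments: tuple[tuple[str, ...], ...]
    a: int

    def __post_init__(self) -> None:
        flat = [i for grp in self.assignments for i in grp]
        if len(flat) != len(set(flat)):
            raise ValueError("an individual appears in more than one pool")
        for grp in self.assignments[:-1]:
            if len(grp) != self.a:
                raise ValueError("only the last pool may be smaller than a")


@dataclass(frozen=True)
class ScreenOutcome:
    """Reaction accounting and genotype calls of one simulated screen."""

    pool_tests: int
    retests: int
    genotype_calls: dict

    @property
    def total_reactions(self) -> int:
        return self.pool_tests + self.retests


def make_pools(ids: Sequence[str], a: int, seed: int) -> PoolPlan:
    """Seeded random permutation of ``ids`` chunked into pools of ``a``."""
    if a < 1:
        raise ValueError(f"pool size must be >= 1, got {a}")
    ids = list(ids)
    if not ids:
        raise ValueError("no individuals to pool")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    groups = tuple(
        tuple(shuffled[i : i + a]) for i in range(0, len(shuffled), a)
    )
    return PoolPlan(assignments=groups, a=int(a))


def _as_genotype_map(population) -> Mapping[str, int]:
    if isinstance(population, pd.DataFrame):
        return dict(zip(population["id"], population["genotype"]))
    return population


def screen(population, plan: PoolPlan, false_negative_rate: float = 0.0,
           seed: int | None = None) -> ScreenOutcome:
    """Run the two-stage screen on true genotypes.

    ``population`` is a genotype table (columns ``id, genotype``) or a mapping
    id -> genotype code.  A pool triggers retests iff its members' genotypes
    differ.  ``false_negative_rate`` optionally lets a mixed pool escape
    detection (its members then receive the pool's majority call); it
    defaults to 0, the error-free assay model.
    """
    geno = _as_genotype_map(population)
    missing = [i for grp in plan.assignments for i in grp if i not in geno]
    if missing:
        raise ValueError(f"no genotype for individual(s): {missing[:5]}")
    rng = np.random.default_rng(seed) if false_negative_rate > 0 else None

    pool_tests = len(plan.assignments)
    retests = 0
    calls: dict = {}
    for grp in plan.assignments:
        g = [geno[i] for i in grp]
        uniform = len(set(g)) == 1
        if not uniform and rng is not None and rng.random() < false_negative_rate:
            maj = max(set(g), key=g.count)
            calls.update({i: maj for i in grp})
            continue
        if uniform:
            calls.update({i: g[0] for i in grp})
        else:
            retests += len(grp)
            calls.update(zip(grp, g))
    return ScreenOutcome(pool_tests=pool_tests, retests=retests, genotype_calls=calls)


def _batch_totals(geno: np.ndarray, a: int) -> np.ndarray:
    """Total reactions for each replicate row of a (replicates, N) genotype array."""
    reps, n = geno.shape
    n_full = n // a
    rem = n % a
    totals = np.full(reps, n_full + (1 if rem else 0), dtype=np.int64)
    if n_full:
        full = geno[:, : n_full * a].reshape(reps, n_full, a)
        mixed = (full != full[:, :, :1]).any(axis=2)
        totals += a * mixed.sum(axis=1)
    if rem:
        tail = geno[:, n_full * a :]
        mixed_tail = (tail != tail[:, :1]).any(axis=1)
        totals += rem * mixed_tail
    return totals


def simulate_reaction_counts(
    N: int,
    carrier_prob: float,
    a: int,
    replicates: int,
    seed: int,
) -> np.ndarray:
    """Realized total reaction counts over seeded replicates.

    Each replicate independently assigns every individual carrier status
    (heterozygous, dosage 1) with probability ``carrier_prob``, pools into
    consecutive groups of ``a`` (remainder pool kept), and applies the
    mixed-pool retest rule.  Returns the vector of per-replicate totals.
    """
    if not 0.0 <= carrier_prob <= 1.0:
        raise ValueError(f"carrier_prob must lie in [0, 1], got {carrier_prob}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    geno = (rng.random((replicates, N)) < carrier_prob).astype(np.int8)
    return _batch_totals(geno, a)


def empirical_curve(
    population,
    a_min: int,
    a_max: int,
    replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Simulated mean/SD of total reactions per pool size on a fixed cohort.

    Pooling is re-randomized each replicate; the Eq.-style analytic
    prediction (evaluated at the cohort's carrier frequency) is reported
    alongside for comparison.
    """
    if a_min < 1 or a_max < a_min or replicates < 1:
        raise ValueError("need 1 <= a_min <= a_max and replicates >= 1")
    geno_map = _as_genotype_map(population)
    geno = np.asarray(list(geno_map.values()))
    n = geno.size
    carrier_freq = float((geno >= 1).mean())
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(a_min, a_max + 1):
        perms = np.array([rng.permutation(n) for _ in range(replicates)])
        totals = _batch_totals(geno[perms], a)
        rows.append(
            {
                "a": a,
                "mean_reactions": totals.mean(),
                "sd_reactions": totals.std(ddof=1) if replicates > 1 else 0.0,
                "predicted": round(
                    expected_reactions(n, carrier_freq, a).n_expected, 1
                ),
            }
        )
    return pd.DataFrame(rows)
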