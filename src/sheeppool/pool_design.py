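"""Mathematical-expectation (ME) pooled-genotyping design.

Two-stage group testing for a low-frequency biallelic variant: samples are
genotyped in pools of size ``a``; any pool showing more than one genotype is
resolved by retesting each of its members individually.  For a cohort of
``N`` individuals and an assumed detection-positive frequency ``p``, the
expected total number of PCR reactions is

    n(a) = N * ( 1/a * (1-p)^a + (1 + 1/a) * (1 - (1-p)^a) )

which is algebraically identical to the classical Dorfman expectation
``N * (1/a + 1 - (1-p)^a)``.  The design task is to pick the integer pool
size minimizing ``n(a)`` over a candidate range, and to estimate ``p`` from
a small pilot of individually genotyped animals beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignPoint",
    "DesignCurve",
    "PilotResult",
    "expected_reactions",
    "design_curve",
    "estimate_pilot_maf",
    "savings_report",
    "plot_curve",
]


@dataclass(frozen=True)
class DesignPoint:
    """Expected reaction count at one pool size.

    Attributes
    ----------
    a : pool size (individuals per group).
    n_expected : expected total reaction count (pool tests plus retests).
    N : total cohort size.
    p : assumed detection-positive frequency.
    """

    a: int
    n_expected: float
    N: int
    p: float


@dataclass(frozen=True)
class DesignCurve:
    """Design curve ``n_expected`` versus pool size, with its optimum."""

    points: tuple[DesignPoint, ...]
    optimum: DesignPoint = field(init=False)

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("design curve needs at least one point")
        # ties broken toward smaller a: first minimum in ascending-a order
        best = min(self.points, key=lambda pt: (pt.n_expected, pt.a))
        object.__setattr__(self, "optimum", best)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "a": [pt.a for pt in self.points],
                "n_expected": [round(pt.n_expected, 1) for pt in self.points],
                "is_optimum": [pt.a == self.optimum.a for pt in self.points],
            }
        )


@dataclass(frozen=True)
class PilotResult:
    """MAF estimate from a pilot of individually genotyped animals."""

    n_pilot: int
    counts: tuple[int, int, int]
    maf_hat: float


def _validate_Npa(N: int, p: float, a: int) -> None:
    if N < 1 or int(N) != N:
        raise ValueError(f"total sample size N must be a positive integer, got {N}")
    if a < 1 or int(a) != a:
        raise ValueError(f"pool size a must be a positive integer, got {a}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"frequency p must lie in [0, 1], got {p}")


def expected_reactions(N: int, p: float, a: int) -> DesignPoint:
    """Expected total reaction count for pool size ``a``.

    Evaluates ``N * (1/a * (1-p)^a + (1 + 1/a) * (1 - (1-p)^a))``.
    Summaries report the value rounded to one decimal.
    """
    _validate_Npa(N, p, a)
    q = (1.0 - p) ** a
    n = N * (1.0 / a * q + (1.0 + 1.0 / a) * (1.0 - q))
    return DesignPoint(a=int(a), n_expected=float(n), N=int(N), p=float(p))


def design_curve(N: int, p: float, a_min: int, a_max: int) -> DesignCurve:
    """Evaluate the design over every integer pool size in ``[a_min, a_max]``."""
    if a_min < 1 or a_max < a_min:
        raise ValueError(f"need 1 <= a_min <= a_max, got [{a_min}, {a_max}]")
    pts = tuple(expected_reactions(N, p, a) for a in range(int(a_min), int(a_max) + 1))
    return DesignCurve(points=pts)


def estimate_pilot_maf(counts: Sequence[int]) -> PilotResult:
    """Minor-allele frequency from pilot genotype counts ``(n_II, n_ID, n_DD)``.

    The allele frequency of the deletion allele is ``(n_ID + 2 n_DD) / (2 n)``,
    folded onto the minor side (``<= 0.5``) so a pilot fixed for the alternate
    allele still reports a MAF of zero.
    """
    counts = tuple(int(c) for c in counts)
    if len(counts) != 3 or any(c < 0 for c in counts):
        raise ValueError(f"counts must be three nonnegative integers, got {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("pilot counts are all zero")
    freq = (counts[1] + 2 * counts[2]) / (2 * n)
    return PilotResult(n_pilot=n, counts=counts, maf_hat=min(freq, 1.0 - freq))


def savings_report(curve: DesignCurve) -> dict:
    """Reaction budget of the optimal pooled design versus one-by-one PCR."""
    opt = curve.optimum
    return {
        "a_optimum": opt.a,
        "n_expected": round(opt.n_expected, 1),
        "n_one_by_one": opt.N,
        "ratio": opt.n_expected / opt.N,
    }


def plot_curve(curve: DesignCurve, path: str) -> None:
    """Save the design curve as a PNG, marking the optimum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.array([pt.a for pt in curve.points])
    n = np.array([pt.n_expected for pt in curve.points])
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(a, n, "o-", ms=4)
    ax.plot([curve.optimum.a], [curve.optimum.n_expected], "^", ms=10, color="C3")
    ax.annotate(
        f"a={curve.optimum.a}, n={curve.optimum.n_expected:.1f}",
        (curve.optimum.a, curve.optimum.n_expected),
        textcoords="offset points",
        xytext=(6, 8),
        fontsize=8,
    )
    ax.set_xlabel("pool size a")
    ax.set_ylabel("expected reactions")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
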