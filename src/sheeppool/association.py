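"""Genotype–trait association for non-normal growth traits.

The screening workflow first checks each trait arm against a fitted normal
distribution (one-sample Kolmogorov–Smirnov with sample-estimated mean and
SD; an optional seeded Monte-Carlo Lilliefors p-value accounts for the
estimation).  Because livestock body measurements typically fail that
screen, the genotype comparison is the Mann–Whitney U test between
wild-type homozygotes and deletion carriers, stratified by sex, with an
exact permutation null when the smaller arm is small and tie-free and a
tie-corrected, continuity-corrected normal approximation otherwise.
Summaries report per-arm mean ± standard error alongside U and the
two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormalityResult",
    "AssociationResult",
    "ks_normality",
    "mann_whitney",
    "association_table",
]

EXACT_MAX_ARM = 10  # exact permutation null when the smaller arm is this size or less


@dataclass(frozen=True)
class NormalityResult:
    ks_stat: float
    p_value: float
    n: int
    method: str


@dataclass(frozen=True)
class AssociationResult:
    U: float
    z: float
    p_value: float
    mean_wild: float
    se_wild: float
    mean_del: float
    se_del: float
    n_wild: int
    n_del: int
    method: str
    significant: bool


def ks_normality(
    values,
    lilliefors: bool = False,
    n_mc: int = 10_000,
    seed: int = 0,
) -> NormalityResult:
    """Kolmogorov–Smirnov test against a normal with estimated parameters.

    Default p-value is the asymptotic Kolmogorov distribution (anti-
    conservative when parameters are estimated, matching common statistical-
    package usage).  With ``lilliefors=True`` the p-value is instead the
    seeded Monte-Carlo proportion of ``n_mc`` normal samples of the same size
    whose estimated-parameter KS statistic is at least as large.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError(f"need at least 4 observations, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test undefined (SD = 0)")
    stat, p_asym = stats.kstest(x, "norm", args=(x.mean(), sd))
    if not lilliefors:
        return NormalityResult(float(stat), float(p_asym), x.size, "asymptotic")
    rng = np.random.default_rng(seed)
    null = np.empty(n_mc)
    for i in range(n_mc):
        z = rng.standard_normal(x.size)
        null[i] = stats.kstest(z, "norm", args=(z.mean(), z.std(ddof=1))).statistic
    p_mc = (1 + (null >= stat - 1e-15).sum()) / (n_mc + 1)
    return NormalityResult(float(stat), float(p_mc), x.size, "lilliefors-mc")


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def mann_whitney(
    values_wild,
    values_del,
    mode: str = "auto",
    alpha: float = 0.05,
) -> AssociationResult:
    """Two-sided Mann–Whitney U comparison of wild-type vs carrier arms.

    ``mode``: "exact" enumerates the null permutation distribution of U
    (valid without ties), "approx" uses the tie-corrected normal
    approximation with continuity correction, "auto" picks exact when the
    smaller arm has at most ten observations and the pooled data are
    tie-free.  U is reported for the wild-type arm with midrank ties.
    """
    x = np.asarray(values_wild, dtype=float)
    y = np.asarray(values_del, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both genotype arms must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    ties = _has_ties(x, y)
    if mode == "exact" and ties:
        raise ValueError("exact mode requires tie-free data")
    use_exact = mode == "exact" or (
        mode == "auto" and not ties and min(x.size, y.size) <= EXACT_MAX_ARM
    )
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)

    # tie-corrected z with continuity correction, reported in both modes
    n1, n2 = x.size, y.size
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 > 0:
        z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(sigma2) if u != mu else 0.0
    else:
        z = 0.0

    return AssociationResult(
        U=u,
        z=float(z),
        p_value=float(res.pvalue),
        mean_wild=float(x.mean()),
        se_wild=float(x.std(ddof=1) / np.sqrt(n1)) if n1 > 1 else float("nan"),
        mean_del=float(y.mean()),
        se_del=float(y.std(ddof=1) / np.sqrt(n2)) if n2 > 1 else float("nan"),
        n_wild=n1,
        n_del=n2,
        method=method,
        significant=bool(res.pvalue < alpha),
    )


def association_table(
    traits: pd.DataFrame,
    genotypes: pd.DataFrame | None = None,
    trait_names: list[str] | None = None,
    stratify_by_sex: bool = True,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-(sex, trait) Mann–Whitney comparison of wild-type vs carriers.

    ``traits`` holds one row per individual with columns ``id, sex`` and the
    trait columns; genotypes come either from a ``genotype`` column already
    present or from ``genotypes`` (columns ``id, genotype``) joined on id —
    unmatched ids are dropped with a warning count column in the attrs.
    Carriers are dosage >= 1.  ``correction`` in {None, "bonferroni", "bh"}
    adjusts p-values across the table (off by default).
    """
    df = traits.copy()
    if genotypes is not None:
        geno = genotypes.loc[:, ["id", "genotype"]]
        before = len(df)
        df = df.drop(columns=["genotype"], errors="ignore").merge(
            geno, on="id", how="inner"
        )
        unmatched = before - len(df)
    else:
        unmatched = 0
        if "genotype" not in df.columns:
            raise ValueError("no genotype column and no genotype table given")
    if trait_names is None:
        reserved = {"id", "breed", "sex", "genotype"}
        trait_names = [c for c in df.columns if c not in reserved]
    missing = [t for t in trait_names if t not in df.columns]
    if missing:
        raise ValueError(f"trait column(s) missing from table: {missing}")

    strata = df.groupby("sex", sort=False) if stratify_by_sex else [("all", df)]
    rows = []
    for sex, sub in strata:
        wild = sub[sub["genotype"] == 0]
        dele = sub[sub["genotype"] >= 1]
        for trait in trait_names:
            base = {"sex": sex, "trait": trait}
            if wild.empty or dele.empty:
                rows.append({**base, "error": "empty genotype arm"})
                continue
            r = mann_whitney(wild[trait], dele[trait], alpha=alpha)
            rows.append(
                {
                    **base,
                    "n_wild": r.n_wild,
                    "mean_wild": r.mean_wild,
                    "se_wild": r.se_wild,
                    "n_del": r.n_del,
                    "mean_del": r.mean_del,
                    "se_del": r.se_del,
                    "U": r.U,
                    "p_value": r.p_value,
                    "method": r.method,
                    "significant": r.significant,
                }
            )
    out = pd.DataFrame(rows)
    if correction and "p_value" in out.columns:
        p = out["p_value"].to_numpy()
        if correction == "bonferroni":
            adj = np.minimum(p * p.size, 1.0)
        elif correction == "bh":
            order = np.argsort(p)
            ranked = p[order] * p.size / (np.arange(p.size) + 1)
            adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
            adj = np.empty_like(p)
            adj[order] = np.minimum(adj_sorted, 1.0)
        else:
            raise ValueError(f"unknown correction {correction!r}")
        out["p_adjusted"] = adj
        out["significant"] = adj < alpha
    out.attrs["unmatched_ids"] = unmatched
    if unmatched:
        import warnings

        warnings.warn(f"{unmatched} trait row(s) had no matching genotype id")
    return out
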