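"""Per-breed population-genetic parameters of a biallelic locus.

From genotype counts (n_II, n_ID, n_DD) the module reports genotype and
allele frequencies, the minor-allele frequency, and the Nei diversity panel:
homozygosity Ho = sum(p_i^2), heterozygosity He = 1 - Ho, and the effective
number of alleles Ne = 1/Ho, all computed from allele frequencies.  Table
output rounds half-up to three decimals, the precision at which the
allele-frequency-based and observed-genotype-share definitions coincide for
rare variants; full precision is retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeCounts",
    "LocusStats",
    "locus_stats",
    "breed_table",
    "hwe_exact_test",
    "round3",
]


def round3(x: float) -> float:
    """Half-up rounding to three decimals (table convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), ROUND_HALF_UP))


@dataclass(frozen=True)
class GenotypeCounts:
    breed: str
    n_II: int
    n_ID: int
    n_DD: int

    def __post_init__(self) -> None:
        if min(self.n_II, self.n_ID, self.n_DD) < 0:
            raise ValueError(f"breed {self.breed!r}: negative genotype count")
        if self.n_total < 1:
            raise ValueError(f"breed {self.breed!r}: no individuals")

    @property
    def n_total(self) -> int:
        return self.n_II + self.n_ID + self.n_DD


@dataclass(frozen=True)
class LocusStats:
    """One breed's row of the locus-parameter table (full precision)."""

    breed: str
    n_total: int
    gf_wild: float
    gf_del: float
    freq_wild: float
    freq_del: float
    ho: float
    he: float
    ne: float
    maf: float

    def rounded(self) -> dict:
        return {
            "breed": self.breed,
            "size": self.n_total,
            "gf_wild": round3(self.gf_wild),
            "gf_del": round3(self.gf_del),
            "af_wild": round3(self.freq_wild),
            "af_del": round3(self.freq_del),
            "Ho": round3(self.ho),
            "He": round3(self.he),
            "Ne": round3(self.ne),
            "MAF": round3(self.maf),
        }


def locus_stats(counts: GenotypeCounts) -> LocusStats:
    """Allele frequencies and the Nei diversity panel from genotype counts."""
    n = counts.n_total
    q = (counts.n_ID + 2 * counts.n_DD) / (2 * n)  # deletion allele
    p = 1.0 - q
    ho = p * p + q * q
    return LocusStats(
        breed=counts.breed,
        n_total=n,
        gf_wild=counts.n_II / n,
        gf_del=(counts.n_ID + counts.n_DD) / n,
        freq_wild=p,
        freq_del=q,
        ho=ho,
        he=1.0 - ho,
        ne=1.0 / ho,
        maf=min(p, q),
    )


_CODE_TO_COUNTS = {0: "n_II", 1: "n_ID", 2: "n_DD"}


def breed_table(records: pd.DataFrame, genotype_col: str = "genotype") -> pd.DataFrame:
    """Per-breed locus-parameter table from a genotype record table.

    ``records`` needs columns ``breed`` and ``genotype_col`` (0/1/2 dosage).
    Breeds appear in first-occurrence order; columns and 3-decimal rounding
    follow the standard published layout.
    """
    bad = ~records[genotype_col].isin([0, 1, 2])
    if bad.any():
        row = records.index[bad][0]
        raise ValueError(
            f"unknown genotype code {records.loc[row, genotype_col]!r} at row {row}"
        )
    rows = []
    for breed in records["breed"].drop_duplicates():
        sub = records.loc[records["breed"] == breed, genotype_col]
        kw = {"n_II": 0, "n_ID": 0, "n_DD": 0}
        for code, cnt in sub.value_counts().items():
            kw[_CODE_TO_COUNTS[int(code)]] = int(cnt)
        rows.append(locus_stats(GenotypeCounts(breed=str(breed), **kw)).rounded())
    return pd.DataFrame(rows)


def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Exact Hardy–Weinberg test p-value (optional diagnostic).

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts no more likely than the observed one (the standard
    exact test for biallelic markers).
    """
    n = counts.n_total
    n_minor = min(counts.n_ID + 2 * counts.n_DD, counts.n_ID + 2 * counts.n_II)
    obs_het = counts.n_ID
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # log-probabilities of each compatible heterozygote count
    from scipy.special import gammaln

    def logp(h):
        rare_hom = (n_minor - h) // 2
        common_hom = n - h - rare_hom
        return (
            h * np.log(2)
            + gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(rare_hom + 1)
            - gammaln(common_hom + 1)
            - (gammaln(2 * n + 1) - gammaln(n_minor + 1) - gammaln(2 * n - n_minor + 1))
        )

    lp = np.array([logp(h) for h in hets])
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    p_obs = probs[hets == obs_het][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())
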