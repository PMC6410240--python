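"""Population-genetic statistics on indel genotype count tables.

Works on diploid genotype counts (Del/Del, Del/Non, Non/Non) from
wild-caught samples, or directly on chromosome-scale allele counts from
haploid-line surveys. Provides allele-frequency estimates with exact
(Clopper–Pearson) or score (Wilson) confidence intervals, chi-squared and
Levene–Haldane exact tests of Hardy–Weinberg equilibrium, Fisher 2x2
comparisons between samples, and a stratified seasonal report.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one stratum (collection, sex, or pooled)."""

    n_deldel: int
    n_delnon: int
    n_nonnon: int
    stratum: str = "All"
    sex: str | None = None

    def __post_init__(self):
        for c in (self.n_deldel, self.n_delnon, self.n_nonnon):
            if c < 0 or int(c) != c:
                raise ValueError("genotype counts must be non-negative integers")

    @property
    def n(self) -> int:
        return self.n_deldel + self.n_delnon + self.n_nonnon

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n

    @property
    def n_del_alleles(self) -> int:
        return 2 * self.n_deldel + self.n_delnon

    def __add__(self, other: "GenotypeCounts") -> "GenotypeCounts":
        return GenotypeCounts(
            self.n_deldel + other.n_deldel,
            self.n_delnon + other.n_delnon,
            self.n_nonnon + other.n_nonnon,
            stratum="All",
        )


@dataclass(frozen=True)
class FrequencyEstimate:
    p_hat: float
    n_chromosomes: int
    ci_low: float
    ci_high: float
    ci_method: str
    level: float = 0.95

    def __post_init__(self):
        if not (0 <= self.ci_low <= self.p_hat <= self.ci_high <= 1):
            raise ValueError("confidence interval must bracket the estimate")


@dataclass(frozen=True)
class HWEResult:
    e_deldel: float
    e_delnon: float
    e_nonnon: float
    chi2: float
    df: int
    p_chi2: float
    p_exact: float | None = None


CI_METHODS = {"clopper_pearson": "beta", "wilson": "wilson"}


def allele_frequency_from_chromosomes(
    x_del: int,
    n_chromosomes: int,
    ci_method: str = "clopper_pearson",
    level: float = 0.95,
) -> FrequencyEstimate:
    """Deletion-allele frequency with a binomial CI on the chromosome count.

    ``x_del`` successes out of ``n_chromosomes`` trials; suitable both for
    diploid samples (x = 2*DelDel + DelNon of 2n) and haploid-line surveys
    (one chromosome per line).
    """
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    if not 0 <= x_del <= n_chromosomes:
        raise ValueError("allele count outside [0, n_chromosomes]")
    if ci_method not in CI_METHODS:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo, hi = proportion_confint(
        x_del, n_chromosomes, alpha=1 - level, method=CI_METHODS[ci_method]
    )
    p_hat = x_del / n_chromosomes
    # proportion_confint returns NaN bounds at the boundary for some methods
    lo = 0.0 if math.isnan(lo) else float(lo)
    hi = 1.0 if math.isnan(hi) else float(hi)
    return FrequencyEstimate(p_hat, n_chromosomes, lo, hi, ci_method, level)


def allele_frequency(
    counts: GenotypeCounts,
    ci_method: str = "clopper_pearson",
    level: float = 0.95,
) -> FrequencyEstimate:
    """Deletion-allele frequency from diploid genotype counts."""
    if counts.n < 1:
        raise ValueError("empty sample")
    return allele_frequency_from_chromosomes(
        counts.n_del_alleles, counts.n_chromosomes, ci_method, level
    )


def _check_polymorphic(counts: GenotypeCounts) -> None:
    x = counts.n_del_alleles
    if counts.n < 1 or x == 0 or x == counts.n_chromosomes:
        raise ValueError("HWE test undefined for a monomorphic sample")


def hwe_chisq(counts: GenotypeCounts, yates: bool = False) -> HWEResult:
    """Chi-squared goodness-of-fit test of Hardy–Weinberg proportions.

    Expected counts use the estimated allele frequency; df = 1 (three
    genotype classes, one estimated parameter). Yates continuity correction
    optional, off by default.
    """
    _check_polymorphic(counts)
    n = counts.n
    p = counts.n_del_alleles / counts.n_chromosomes
    q = 1 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([counts.n_deldel, counts.n_delnon, counts.n_nonnon], float)
    dev = np.abs(observed - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float(np.sum(dev**2 / expected))
    p_chi2 = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(*expected, chi2=chi2, df=1, p_chi2=p_chi2)


def _levene_haldane_pmf(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given n and the
    minor-allele count (Levene–Haldane). Returns (het counts, probabilities)."""
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    logs = []
    for h in hets:
        n_minor_hom = (n_minor - h) // 2
        n_major_hom = n - h - n_minor_hom
        if n_major_hom < 0:
            logs.append(-np.inf)
            continue
        ln = (
            math.lgamma(n + 1)
            - math.lgamma(n_minor_hom + 1)
            - math.lgamma(h + 1)
            - math.lgamma(n_major_hom + 1)
            + h * math.log(2)
            + math.lgamma(n_minor + 1)
            + math.lgamma(2 * n - n_minor + 1)
            - math.lgamma(2 * n + 1)
        )
        logs.append(ln)
    logp = np.array(logs)
    keep = np.isfinite(logp)
    probs = np.exp(logp[keep] - logp[keep].max())
    probs /= probs.sum()
    return hets[keep], probs


def hwe_exact(counts: GenotypeCounts) -> float:
    """Exact Hardy–Weinberg test (Levene–Haldane conditional distribution).

    The p-value is the total conditional probability of all heterozygote
    counts whose probability does not exceed that of the observed count.
    """
    _check_polymorphic(counts)
    n = counts.n
    n_del = counts.n_del_alleles
    n_minor = min(n_del, counts.n_chromosomes - n_del)
    hets, probs = _levene_haldane_pmf(n, n_minor)
    p_obs = probs[hets == counts.n_delnon]
    if p_obs.size == 0:
        raise ValueError("observed heterozygote count infeasible for allele counts")
    # small relative tolerance so ties in the tail definition are kept
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-9)].sum()))


def hwe_test(counts: GenotypeCounts, yates: bool = False) -> HWEResult:
    """Chi-squared and exact HWE tests in one result."""
    res = hwe_chisq(counts, yates=yates)
    return HWEResult(
        res.e_deldel,
        res.e_delnon,
        res.e_nonnon,
        res.chi2,
        res.df,
        res.p_chi2,
        p_exact=hwe_exact(counts),
    )


def fisher_2x2(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-sided Fisher exact test comparing two binomial samples.

    ``x_i`` successes of ``n_i`` trials. Returns (sample odds ratio,
    two-sided p) from the hypergeometric distribution with fixed margins.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts outside margins")
    if n1 == 0 or n2 == 0:
        raise ValueError("empty sample")
    table = [[x1, n1 - x1], [x2, n2 - x2]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


@dataclass
class SeasonalReport:
    """Stratified frequency/HWE report plus pairwise comparisons."""

    frequencies: pd.DataFrame
    hwe: pd.DataFrame
    pairwise: pd.DataFrame
    notes: list[str] = field(default_factory=list)


def seasonal_report(
    genotype_counts: list[GenotypeCounts],
    sex_allele_counts: pd.DataFrame | None = None,
    ci_method: str = "clopper_pearson",
    level: float = 0.95,
) -> SeasonalReport:
    """Per-collection frequency/CI and HWE tests with pairwise Fisher tests.

    ``genotype_counts`` is one entry per collection; a pooled "All" row is the
    element-wise sum. ``sex_allele_counts`` (optional) has columns
    ``collection, sex, n_chromosomes, n_del`` and adds per-sex frequency rows
    and male-vs-female Fisher tests within each collection.
    """
    if not genotype_counts:
        raise ValueError("need at least one stratum")
    strata = list(genotype_counts)
    pooled = strata[0]
    for s in strata[1:]:
        pooled = pooled + s
    all_rows = strata + [pooled]

    freq_rows, hwe_rows = [], []
    for c in all_rows:
        est = allele_frequency(c, ci_method, level)
        freq_rows.append(
            dict(
                stratum=c.stratum,
                sex=c.sex or "both",
                n_chromosomes=est.n_chromosomes,
                p_del=est.p_hat,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
            )
        )
        try:
            h = hwe_test(c)
            hwe_rows.append(
                dict(
                    stratum=c.stratum,
                    chi2=h.chi2,
                    p_chi2=h.p_chi2,
                    p_exact=h.p_exact,
                )
            )
        except ValueError:
            hwe_rows.append(
                dict(stratum=c.stratum, chi2=np.nan, p_chi2=np.nan, p_exact=np.nan)
            )

    pair_rows = []
    for a, b in itertools.combinations(strata, 2):
        odds, p = fisher_2x2(
            a.n_del_alleles, a.n_chromosomes, b.n_del_alleles, b.n_chromosomes
        )
        pair_rows.append(
            dict(comparison="collection", a=a.stratum, b=b.stratum, odds_ratio=odds, p=p)
        )

    notes = []
    if sex_allele_counts is not None:
        for coll, grp in sex_allele_counts.groupby("collection", sort=False):
            for _, row in grp.iterrows():
                est = allele_frequency_from_chromosomes(
                    int(row.n_del), int(row.n_chromosomes), ci_method, level
                )
                freq_rows.append(
                    dict(
                        stratum=coll,
                        sex=row.sex,
                        n_chromosomes=est.n_chromosomes,
                        p_del=est.p_hat,
                        ci_low=est.ci_low,
                        ci_high=est.ci_high,
                    )
                )
            if len(grp) == 2:
                (x1, n1), (x2, n2) = (
                    (int(r.n_del), int(r.n_chromosomes)) for _, r in grp.iterrows()
                )
                odds, p = fisher_2x2(x1, n1, x2, n2)
                pair_rows.append(
                    dict(comparison="sex", a=coll, b=coll, odds_ratio=odds, p=p)
                )
    return SeasonalReport(
        frequencies=pd.DataFrame(freq_rows),
        hwe=pd.DataFrame(hwe_rows),
        pairwise=pd.DataFrame(pair_rows),
        notes=notes,
    )


__all__ = [
    "GenotypeCounts",
    "FrequencyEstimate",
    "HWEResult",
    "SeasonalReport",
    "allele_frequency",
    "allele_frequency_from_chromosomes",
    "hwe_chisq",
    "hwe_exact",
    "hwe_test",
    "fisher_2x2",
    "seasonal_report",
]
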