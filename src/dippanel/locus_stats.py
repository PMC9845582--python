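"""Per-locus forensic parameters, HWE exact testing and pairwise LD testing.

Conventions adopted (all verified against the printed parameter ranges of the
43-locus autosomal DIP panel they reproduce):

* He uses the unbiased small-sample correction He = 2pq * 2n/(2n-1);
* PM is computed from *observed* genotype proportions (an HWE-expected variant
  is exposed as well); PD = 1 - PM exactly;
* PE = Ho^2 (1 - 2 Ho (1-Ho)^2) and TPI = 1/(2(1-Ho)) are functions of the
  observed heterozygosity;
* the HWE test is the exact conditional test: condition on the allele counts,
  enumerate every feasible heterozygote count of matching parity, and sum the
  conditional probabilities no larger than the observed configuration's;
* the LD test estimates two-locus haplotype frequencies by EM from unphased
  genotypes and calibrates the likelihood-ratio statistic by permutation.

Display rounding is half-up to 4 decimal places; internal maths is full
precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import DD, DI, II, MISSING, GenotypeDataset, ParameterError


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Report-style rounding: half-up at ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given counts."""


# ---------------------------------------------------------------------------
# per-locus parameters
# ---------------------------------------------------------------------------


def observed_heterozygosity(n_dd: int, n_di: int, n_ii: int) -> float:
    total = n_dd + n_di + n_ii
    if total < 1:
        raise UndefinedStatisticError("observed heterozygosity needs >= 1 individual")
    return n_di / total


def expected_heterozygosity_unbiased(p: float, n: int) -> float:
    """Unbiased expected heterozygosity He = 2pq * 2n/(2n-1)."""
    if not (0.0 <= p <= 1.0):
        raise ParameterError("p must lie in [0, 1]")
    if n < 1:
        raise ParameterError("n must be >= 1")
    return 2.0 * p * (1.0 - p) * (2 * n) / (2 * n - 1)


def pic(p: float) -> float:
    """Polymorphism information content of a biallelic locus (max 0.375)."""
    if not (0.0 <= p <= 1.0):
        raise ParameterError("p must lie in [0, 1]")
    q = 1.0 - p
    # clamp: cancellation near fixation can drift a hair below zero
    return max(0.0, 1.0 - (p * p + q * q) - 2.0 * p * p * q * q)


def match_probability(n_dd: int, n_di: int, n_ii: int) -> tuple[float, float]:
    """(PM, PD) from observed genotype proportions; PD = 1 - PM."""
    total = n_dd + n_di + n_ii
    if total < 1:
        raise UndefinedStatisticError("match probability needs >= 1 individual")
    pm = sum((c / total) ** 2 for c in (n_dd, n_di, n_ii))
    return pm, 1.0 - pm


def match_probability_expected(p: float) -> tuple[float, float]:
    """HWE-expected variant: PM from expected genotype proportions."""
    probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
    pm = float((probs**2).sum())
    return pm, 1.0 - pm


def power_of_exclusion(ho: float) -> float:
    """Trio exclusion power PE = Ho^2 (1 - 2 Ho (1-Ho)^2)."""
    if not (0.0 <= ho <= 1.0):
        raise ParameterError("Ho must lie in [0, 1]")
    return ho * ho * (1.0 - 2.0 * ho * (1.0 - ho) ** 2)


def typical_paternity_index(ho: float) -> float:
    """TPI = 1 / (2 (1 - Ho)); undefined at Ho = 1."""
    if not (0.0 <= ho <= 1.0):
        raise ParameterError("Ho must lie in [0, 1]")
    if ho == 1.0:
        raise UndefinedStatisticError("TPI is infinite at Ho = 1")
    return 1.0 / (2.0 * (1.0 - ho))


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_dd: int, n_di: int, n_ii: int) -> float:
    """Exact conditional HWE test for a biallelic locus.

    Conditions on the observed allele counts and enumerates every feasible
    heterozygote count with the parity of the rare-allele count; the p-value
    sums the conditional probabilities of configurations no more probable
    than the observed one.  A monomorphic locus returns p = 1 by convention.
    """
    if min(n_dd, n_di, n_ii) < 0 or n_dd + n_di + n_ii < 1:
        raise ParameterError("genotype counts must be nonnegative, total >= 1")
    n = n_dd + n_di + n_ii
    n_d = 2 * n_dd + n_di
    n_rare = min(n_d, 2 * n - n_d)
    if n_rare == 0:
        return 1.0

    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(n_het | allele counts) up to a shared constant:
    #   n! / (n_hom_rare! n_het! n_hom_common!) * 2^n_het, hypergeometric on alleles
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = probs[np.searchsorted(hets, n_di)]
    # 1e-12 relative slack keeps ties included despite floating-point noise
    return float(probs[probs <= observed * (1.0 + 1e-12)].sum())


# ---------------------------------------------------------------------------
# pairwise linkage disequilibrium
# ---------------------------------------------------------------------------


def _em_haplotypes(counts: np.ndarray, tol: float = 1e-10, max_iter: int = 1000):
    """EM haplotype-frequency estimation from a 3x3 two-locus genotype table.

    ``counts[i, j]`` holds individuals with deletion dosage i at locus A and j
    at locus B.  Returns (haplotype freqs [AB, Ab, aB, ab] with A/B = deletion,
    log-likelihood, converged flag).
    """
    n = counts.sum()
    pa = (counts * np.arange(3)[:, None]).sum() / (2 * n)
    pb = (counts * np.arange(3)[None, :]).sum() / (2 * n)
    # start at linkage equilibrium
    h = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    h = np.clip(h, 1e-12, None)
    h /= h.sum()
    converged = False
    for _ in range(max_iter):
        # only the double heterozygote is phase-ambiguous
        denom = h[0] * h[3] + h[1] * h[2]
        frac_cis = h[0] * h[3] / denom if denom > 0 else 0.5
        n_dh = counts[1, 1]
        hap_counts = np.array(
            [
                2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + n_dh * frac_cis,
                2 * counts[2, 0] + counts[2, 1] + counts[1, 0] + n_dh * (1 - frac_cis),
                2 * counts[0, 2] + counts[0, 1] + counts[1, 2] + n_dh * (1 - frac_cis),
                2 * counts[0, 0] + counts[0, 1] + counts[1, 0] + n_dh * frac_cis,
            ],
            dtype=float,
        )
        new = hap_counts / (2 * n)
        if np.abs(new - h).max() < tol:
            h = new
            converged = True
            break
        h = new
    return h, _two_locus_loglik(counts, h), converged


def _two_locus_loglik(counts: np.ndarray, h: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype table under haplotype freqs."""
    # genotype-pair probability from haplotype freqs assuming random union
    g = np.zeros((3, 3))
    # haplotypes: 0=DD', 1=Dd', 2=dD', 3=dd' (prime = second locus); dosage at
    # locus A from first symbol, locus B from second
    dosA = np.array([1, 1, 0, 0])
    dosB = np.array([1, 0, 1, 0])
    for i in range(4):
        for j in range(4):
            g[dosA[i] + dosA[j], dosB[i] + dosB[j]] += h[i] * h[j]
    with np.errstate(divide="ignore"):
        logg = np.log(g)
    mask = counts > 0
    return float((counts[mask] * logg[mask]).sum())


def _lr_statistic(counts: np.ndarray) -> tuple[float, bool]:
    """Likelihood-ratio LD statistic 2(lnL_full - lnL_indep) for a 3x3 table."""
    n = counts.sum()
    pa = (counts * np.arange(3)[:, None]).sum() / (2 * n)
    pb = (counts * np.arange(3)[None, :]).sum() / (2 * n)
    h0 = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    ll0 = _two_locus_loglik(counts, h0)
    _, ll1, converged = _em_haplotypes(counts)
    return max(0.0, 2.0 * (ll1 - ll0)), converged


@dataclass
class LDResult:
    p_value: float
    statistic: float
    haplotype_freqs: np.ndarray
    n_permutations: int
    em_converged: bool


def ld_test_pair(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
    exhaustive: bool = False,
) -> LDResult:
    """Permutation LD test between two loci from unphased genotypes.

    Haplotype frequencies are estimated by EM; significance of the
    likelihood-ratio statistic is calibrated by permuting one locus's genotype
    column (p = (#perm >= observed + 1)/(B + 1), seeded).  With
    ``exhaustive=True`` all n! column permutations are enumerated instead and
    p is the exact fraction of permutations at or above the observed statistic
    (small n only).
    """
    geno_a = np.asarray(geno_a)
    geno_b = np.asarray(geno_b)
    ok = (geno_a != MISSING) & (geno_b != MISSING)
    a, b = geno_a[ok].astype(int), geno_b[ok].astype(int)
    if len(a) < 2:
        raise ParameterError("LD test needs >= 2 individuals typed at both loci")

    def table(x, y):
        t = np.zeros((3, 3))
        np.add.at(t, (x, y), 1.0)
        return t

    observed_counts = table(a, b)
    stat, converged = _lr_statistic(observed_counts)
    haps, _, _ = _em_haplotypes(observed_counts)
    if exhaustive:
        from itertools import permutations

        perms = [np.array(pb) for pb in permutations(b)]
        exceed = sum(
            1 for pb in perms if _lr_statistic(table(a, pb))[0] >= stat - 1e-9
        )
        return LDResult(exceed / len(perms), stat, haps, len(perms), converged)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm_stat, _ = _lr_statistic(table(a, rng.permutation(b)))
        if perm_stat >= stat - 1e-9:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return LDResult(p, stat, haps, n_permutations, converged)


def bonferroni_threshold(alpha: float, m: int, pairwise: bool = False) -> float:
    """Corrected significance threshold: alpha/m, or 2*alpha/(m(m-1)) pairwise."""
    if m < 1:
        raise ParameterError("m must be >= 1")
    return 2.0 * alpha / (m * (m - 1)) if pairwise else alpha / m


def bonferroni(p_values: np.ndarray, m: int, alpha: float = 0.05, pairwise: bool = False) -> np.ndarray:
    """Flags p-values significant after Bonferroni correction (strict <)."""
    thr = bonferroni_threshold(alpha, m, pairwise)
    return np.asarray(p_values, dtype=float) < thr


# ---------------------------------------------------------------------------
# per-locus summary over a dataset
# ---------------------------------------------------------------------------


@dataclass
class LocusForensicStats:
    """All per-locus forensic parameters for one locus in one population."""

    locus: str
    population: str
    p: float
    n: int
    ho: float
    he: float
    pic: float
    pm: float
    pd: float
    pe: float
    tpi: float
    hwe_p: float


def locus_stats_table(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-locus forensic parameters for every population in a dataset."""
    rows = []
    for pop in ds.populations:
        sub = ds.subset(pop)
        for j, locus in enumerate(sub.loci):
            n_dd, n_di, n_ii = sub.genotype_counts(j)
            n = n_dd + n_di + n_ii
            if n == 0:
                continue
            p = (2 * n_dd + n_di) / (2 * n)
            ho = observed_heterozygosity(n_dd, n_di, n_ii)
            pm, pd_ = match_probability(n_dd, n_di, n_ii)
            rows.append(
                LocusForensicStats(
                    locus=locus.id,
                    population=pop,
                    p=p,
                    n=n,
                    ho=ho,
                    he=expected_heterozygosity_unbiased(p, n),
                    pic=pic(p),
                    pm=pm,
                    pd=pd_,
                    pe=power_of_exclusion(ho),
                    tpi=typical_paternity_index(ho) if ho < 1 else np.inf,
                    hwe_p=hwe_exact_test(n_dd, n_di, n_ii),
                ).__dict__
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["hwe_significant"] = bonferroni(df["hwe_p"].to_numpy(), m=len(ds.loci))
    return df
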