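"""Kinship likelihood ratios for biallelic loci and the sibling LR study.

The joint probability of a genotype pair under a relationship hypothesis with
IBD coefficients (k0, k1, k2) is

    P(g1, g2 | k) = P(g1) * [ k0*P(g2) + k1*T(g2 | g1) + k2*1(g1 = g2) ]

where P(.) are Hardy–Weinberg genotype probabilities at deletion frequency p
and T is the one-shared-allele transition kernel (the non-shared allele of g2
drawn fresh from the population).  Multi-locus LRs multiply over unlinked loci
and are accumulated in log10 space.

The Monte-Carlo study mirrors the standard forensic validation design:
simulate pairs under H1 (full or half siblings) and H2 (unrelated), compute
the H1/H2 LR for every pair, and tabulate the accuracy rate P(LR > t | H1)
and false-positive rate P(LR > t | H2) at a ladder of LR limits
(1, 10, 100, 1000, 10000 by default).  A call requires LR strictly above the
limit; ties count as negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DD, DI, II, MISSING, ParameterError

DEFAULT_LR_LIMITS = (1.0, 10.0, 100.0, 1000.0, 10000.0)


@dataclass(frozen=True)
class KinshipHypothesis:
    """A relationship expressed as IBD-sharing probabilities (k0, k1, k2)."""

    name: str
    k0: float
    k1: float
    k2: float

    def validate(self) -> None:
        ks = (self.k0, self.k1, self.k2)
        if any(k < 0 for k in ks):
            raise ParameterError("IBD coefficients must be nonnegative")
        if abs(sum(ks) - 1.0) > 1e-12:
            raise ParameterError("IBD coefficients must sum to 1")


FULL_SIBLING = KinshipHypothesis("full_sibling", 0.25, 0.5, 0.25)
# (1/2, 1/2, 0) is shared by half siblings, avuncular and grandparent pairs;
# we name the class after the half-sibling use here.
HALF_SIBLING = KinshipHypothesis("half_sibling", 0.5, 0.5, 0.0)
UNRELATED = KinshipHypothesis("unrelated", 1.0, 0.0, 0.0)

_GENOTYPES = (II, DI, DD)


def _hwe_probs(p: float) -> np.ndarray:
    """HWE genotype probabilities indexed by deletion dosage [II, DI, DD]."""
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


def _transition(p: float) -> np.ndarray:
    """One-IBD-allele transition matrix T[g1, g2], dosage-indexed.

    The shared allele is a uniform pick from g1's two alleles; the other
    allele of g2 is a fresh population draw.
    """
    q = 1.0 - p
    return np.array(
        [
            [q, p, 0.0],              # from II: shared I; fresh allele I (q) or D (p)
            [q / 2, 0.5, p / 2],      # from DI: shared I or D with prob 1/2 each
            [0.0, q, p],              # from DD: shared D
        ]
    )


def joint_matrix(p: float, hyp: KinshipHypothesis) -> np.ndarray:
    """3x3 joint genotype-pair probabilities P(g1, g2 | hyp), dosage-indexed."""
    if not (0.0 < p < 1.0):
        raise ParameterError("deletion frequency must lie strictly in (0, 1)")
    hyp.validate()
    probs = _hwe_probs(p)
    mat = hyp.k0 * np.outer(probs, probs)
    mat += hyp.k1 * probs[:, None] * _transition(p)
    mat += hyp.k2 * np.diag(probs)
    return mat


def pair_likelihood(g1: int, g2: int, p: float, hyp: KinshipHypothesis) -> float:
    """P(g1, g2 | hyp) for a single locus (genotypes as deletion dosage)."""
    if g1 not in _GENOTYPES or g2 not in _GENOTYPES:
        raise ParameterError("genotypes must be II, DI or DD codes")
    return float(joint_matrix(p, hyp)[g1, g2])


def kinship_lr(
    g1: np.ndarray,
    g2: np.ndarray,
    freqs: np.ndarray,
    h1: KinshipHypothesis,
    h2: KinshipHypothesis,
) -> tuple[float, float, int]:
    """Multi-locus LR of H1 vs H2 for one genotype pair.

    Loci where either individual is missing are skipped and counted.
    Returns (LR, log10 LR, n_skipped); an H2-impossible locus yields +inf.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    freqs = np.asarray(freqs, dtype=float)
    if g1.shape != g2.shape or g1.shape != freqs.shape:
        raise ParameterError("pair and frequency vectors must share loci")
    log10_lr = 0.0
    skipped = 0
    for a, b, p in zip(g1, g2, freqs):
        if a == MISSING or b == MISSING:
            skipped += 1
            continue
        num = pair_likelihood(int(a), int(b), float(p), h1)
        den = pair_likelihood(int(a), int(b), float(p), h2)
        if den == 0.0:
            return np.inf, np.inf, skipped
        log10_lr += np.log10(num) - np.log10(den)
    return float(10.0 ** log10_lr), float(log10_lr), skipped


def log10_lr_table(p: float, h1: KinshipHypothesis, h2: KinshipHypothesis) -> np.ndarray:
    """Per-locus 3x3 log10 LR lookup table (dosage-indexed)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        tab = np.log10(joint_matrix(p, h1)) - np.log10(joint_matrix(p, h2))
    return tab


def batch_log10_lr(
    g1: np.ndarray,
    g2: np.ndarray,
    freqs: np.ndarray,
    h1: KinshipHypothesis,
    h2: KinshipHypothesis,
) -> np.ndarray:
    """Vectorised log10 LR for (n_pairs, n_loci) genotype arrays."""
    out = np.zeros(g1.shape[0])
    for j, p in enumerate(freqs):
        tab = log10_lr_table(float(p), h1, h2)
        out += tab[g1[:, j], g2[:, j]]
    return out


def mean_lr_check(p: float, h1: KinshipHypothesis, h2: KinshipHypothesis) -> float:
    """E[LR | H2] over the 9 genotype pairs — analytically 1 for any p, h1, h2."""
    num = joint_matrix(p, h1)
    den = joint_matrix(p, h2)
    mask = den > 0
    return float(np.sum(den[mask] * (num[mask] / den[mask])))


@dataclass
class LRStudyResult:
    """Outcome of the Monte-Carlo kinship-discrimination study."""

    h1: KinshipHypothesis
    h2: KinshipHypothesis
    thresholds: tuple[float, ...]
    accuracy: np.ndarray          # P(LR > t | H1 pairs), per threshold
    false_positive: np.ndarray    # P(LR > t | H2 pairs), per threshold
    n_pairs: int
    seed: int
    log10_lr_h1: np.ndarray       # per-pair log10 LR, H1-simulated pairs
    log10_lr_h2: np.ndarray       # per-pair log10 LR, H2-simulated pairs

    def as_frame(self) -> pd.DataFrame:
        """Accuracy/FPR table as percentages at 2 dp (report style)."""
        return pd.DataFrame(
            {
                "lr_limit": self.thresholds,
                "accuracy_pct": np.round(100.0 * self.accuracy, 2),
                "false_positive_pct": np.round(100.0 * self.false_positive, 2),
            }
        )


def run_lr_study(
    freqs: np.ndarray,
    h1: KinshipHypothesis,
    n_pairs: int = 1000,
    thresholds: tuple[float, ...] = DEFAULT_LR_LIMITS,
    seed: int = 0,
    h2: KinshipHypothesis = UNRELATED,
) -> LRStudyResult:
    """Simulate the LR discrimination study for one relationship hypothesis.

    Simulates ``n_pairs`` genotype pairs under H1 and under H2 at the given
    deletion frequencies, computes the H1/H2 LR for every pair, and tabulates
    accuracy and false-positive rates at each LR limit (strict LR > t).
    Loci with p in {0, 1} carry no kinship information and are excluded.
    """
    from . import synth  # deferred: synth uses KinshipHypothesis

    if n_pairs < 1:
        raise ParameterError("n_pairs must be >= 1")
    thresholds = tuple(thresholds)
    if any(t <= 0 for t in thresholds) or list(thresholds) != sorted(thresholds):
        raise ParameterError("thresholds must be positive and ascending")
    freqs = np.asarray(freqs, dtype=float)
    keep = (freqs > 0.0) & (freqs < 1.0)
    if not keep.all():
        import logging

        logging.getLogger(__name__).warning(
            "excluding %d fixed loci from the LR study", int((~keep).sum())
        )
        freqs = freqs[keep]

    rng = np.random.default_rng(seed)
    a1, a2 = synth.simulate_pair(freqs, h1, seed=rng, n_pairs=n_pairs)
    b1, b2 = synth.simulate_pair(freqs, h2, seed=rng, n_pairs=n_pairs)
    ll_h1 = batch_log10_lr(a1, a2, freqs, h1, h2)
    ll_h2 = batch_log10_lr(b1, b2, freqs, h1, h2)
    log10_t = np.log10(thresholds)
    accuracy = np.array([(ll_h1 > t).mean() for t in log10_t])
    fpr = np.array([(ll_h2 > t).mean() for t in log10_t])
    return LRStudyResult(
        h1=h1,
        h2=h2,
        thresholds=thresholds,
        accuracy=accuracy,
        false_positive=fpr,
        n_pairs=n_pairs,
        seed=seed,
        log10_lr_h1=ll_h1,
        log10_lr_h2=ll_h2,
    )
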