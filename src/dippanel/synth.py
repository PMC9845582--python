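"""Synthetic genotype data matching the statistical structure of DIP panels.

Generates (a) deletion-frequency spectra as truncated normals parameterised by
a target mean/SD/range, (b) Hardy–Weinberg genotypes at unlinked loci,
(c) continentally structured populations under the Balding–Nichols model, and
(d) genotype pairs of relatives under IBD-coefficient hypotheses.  All
generators are bit-reproducible under a fixed seed.

Loci are simulated independently (no linkage) and without co-ancestry (theta)
correction; related pairs are produced by direct IBD-state sampling, which for
unlinked autosomal loci is distributionally identical to explicit parental
gene-dropping and is easier to verify by enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io import DD, DI, II, MISSING, FrequencyTable, GenotypeDataset, Locus, ParameterError
from .kinship import KinshipHypothesis


@dataclass(frozen=True)
class FrequencySpectrumSpec:
    """Truncated-normal spec for a panel's deletion-frequency spectrum.

    Defaults are the observed Yunnan Yi spectrum of a 43-locus autosomal DIP
    panel: mean 0.4993, SD 0.0954, range [0.3080, 0.6480].
    """

    n_loci: int = 43
    mean: float = 0.4993
    sd: float = 0.0954
    lower: float = 0.3080
    upper: float = 0.6480
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower < self.upper <= 1.0):
            raise ParameterError("truncation bounds must satisfy 0 <= lower < upper <= 1")
        if self.sd <= 0:
            raise ParameterError("sd must be positive")
        if self.n_loci < 1:
            raise ParameterError("n_loci must be >= 1")


@dataclass(frozen=True)
class StructureSpec:
    """Balding–Nichols spec for continentally structured populations."""

    ancestral_freqs: tuple[float, ...]
    fst_per_pop: dict[str, float]
    sizes: dict[str, int]
    continents: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.fst_per_pop) != set(self.sizes):
            raise ParameterError("fst_per_pop and sizes must name the same populations")
        for pop, f in self.fst_per_pop.items():
            if not (0.0 < f < 1.0):
                raise ParameterError(f"F_ST for {pop!r} must lie in (0, 1)")
        for pop, n in self.sizes.items():
            if n < 1:
                raise ParameterError(f"size for {pop!r} must be >= 1")


def sample_frequency_spectrum(spec: FrequencySpectrumSpec, population: str = "synthetic") -> FrequencyTable:
    """Draw a deletion-frequency spectrum from a truncated normal."""
    rng = np.random.default_rng(spec.seed)
    a = (spec.lower - spec.mean) / spec.sd
    b = (spec.upper - spec.mean) / spec.sd
    p = truncnorm.rvs(a, b, loc=spec.mean, scale=spec.sd, size=spec.n_loci, random_state=rng)
    table = pd.DataFrame(
        {
            "locus": [f"locus{i:03d}" for i in range(spec.n_loci)],
            "population": population,
            "p_del": p,
            "n": 1,
        }
    )
    return FrequencyTable(table)


def _hwe_genotypes(p: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, n_loci) deletion-dosage calls under HWE at frequencies p."""
    alleles = rng.random((n, len(p), 2)) < p[None, :, None]
    return alleles.sum(axis=2).astype(np.int8)


def simulate_population(
    freqs: np.ndarray,
    n: int,
    seed: int | np.random.Generator = 0,
    population: str = "synthetic",
    continent: str = "",
    locus_ids: list[str] | None = None,
) -> GenotypeDataset:
    """Simulate n unrelated individuals under HWE at the given frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ParameterError("frequencies must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    calls = _hwe_genotypes(freqs, n, rng)
    ids = locus_ids or [f"locus{i:03d}" for i in range(len(freqs))]
    samples = pd.DataFrame(
        {
            "sample_id": [f"{population}_{i:05d}" for i in range(n)],
            "population": population,
            "continent": continent,
        }
    )
    return GenotypeDataset([Locus(i) for i in ids], samples, calls)


def simulate_structured_populations(spec: StructureSpec) -> GenotypeDataset:
    """Simulate HWE genotypes for populations diverged under Balding–Nichols.

    Per population k and locus, the subpopulation deletion frequency is drawn
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral frequency p with
    F = fst_per_pop[k]; genotypes then follow HWE within the subpopulation.
    """
    rng = np.random.default_rng(spec.seed)
    p0 = np.asarray(spec.ancestral_freqs, dtype=float)
    if ((p0 <= 0) | (p0 >= 1)).any():
        raise ParameterError("ancestral frequencies must lie strictly in (0, 1)")
    parts = []
    for pop in sorted(spec.sizes):
        f = spec.fst_per_pop[pop]
        sub_p = rng.beta(p0 * (1 - f) / f, (1 - p0) * (1 - f) / f)
        parts.append(
            simulate_population(
                sub_p,
                spec.sizes[pop],
                seed=rng,
                population=pop,
                continent=spec.continents.get(pop, ""),
            )
        )
    loci = parts[0].loci
    samples = pd.concat([d.samples for d in parts], ignore_index=True)
    calls = np.vstack([d.calls for d in parts])
    return GenotypeDataset(loci, samples, calls)


def simulate_pair(
    freqs: np.ndarray,
    hypothesis: KinshipHypothesis,
    seed: int | np.random.Generator = 0,
    n_pairs: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate genotype pairs of relatives by direct IBD-state sampling.

    Per locus an IBD state m in {0, 1, 2} is drawn with probabilities
    (k0, k1, k2); the pair then shares m alleles identical by descent, the
    remaining alleles being independent draws at the deletion frequency.
    Returns two (n_pairs, n_loci) deletion-dosage arrays.
    """
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ParameterError("frequencies must lie in [0, 1]")
    hypothesis.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = (n_pairs, len(freqs))

    a = (rng.random(shape + (2,)) < freqs[None, :, None]).astype(np.int8)  # ind1 alleles
    b = (rng.random(shape + (2,)) < freqs[None, :, None]).astype(np.int8)  # fresh draws
    k = np.array([hypothesis.k0, hypothesis.k1, hypothesis.k2])
    m = rng.choice(3, size=shape, p=k)
    # which of ind1's two alleles is transmitted when exactly one is shared
    pick = rng.integers(0, 2, size=shape)
    shared = np.take_along_axis(a, pick[..., None], axis=2)[..., 0]

    g1 = a.sum(axis=2)
    g2 = b.sum(axis=2)
    one = m == 1
    g2[one] = shared[one] + b[..., 1][one]
    g2[m == 2] = g1[m == 2]
    return g1.astype(np.int8), g2.astype(np.int8)
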