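"""Population-genetic differentiation, informativeness, ordination and trees.

Implements:

* pairwise Weir–Cockerham (1984) theta, multi-locus as the ratio of summed
  variance components, with negative estimates retained (a clamped copy is
  available for distance-based methods);
* Nei's standard genetic distance Ds = -ln(Jxy / sqrt(Jx*Jy)) with the gene
  identities pooled over loci before the ratio (the PHYLIP gendist
  convention);
* Rosenberg's informativeness for assignment In (natural log by default, the
  log base is configurable);
* Saitou–Nei neighbor joining with deterministic label-order tie-breaking;
  negative branch lengths are set to zero with the length transferred to the
  adjacent branch, recorded in tree metadata;
* classical (Torgerson) MDS and PCA at individual (genotype-dosage) or
  population (frequency) level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DistanceMatrix, FrequencyTable, GenotypeDataset, ParameterError


# ---------------------------------------------------------------------------
# Weir–Cockerham theta
# ---------------------------------------------------------------------------


def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Weir–Cockerham per-locus variance components (a, b, c).

    Parameters are per-population arrays for one locus: sample sizes (diploid
    individuals), allele frequencies and observed heterozygote proportions.
    """
    r = len(n)
    n_bar = n.mean()
    n_c = (r * n_bar - (n**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n * p).sum() / (r * n_bar)
    s2 = (n * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n * h).sum() / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def weir_cockerham_theta(ds: GenotypeDataset, populations: list[str]) -> float:
    """Multi-locus Weir–Cockerham theta across the named populations.

    Summed variance components over loci: theta = sum(a) / sum(a + b + c).
    Negative estimates are retained.
    """
    subs = [ds.subset(pop) for pop in populations]
    num = den = 0.0
    for j in range(ds.n_loci):
        ns, ps, hs = [], [], []
        for sub in subs:
            n_dd, n_di, n_ii = sub.genotype_counts(j)
            tot = n_dd + n_di + n_ii
            if tot == 0:
                break
            ns.append(tot)
            ps.append((2 * n_dd + n_di) / (2 * tot))
            hs.append(n_di / tot)
        else:
            a, b, c = _wc_components(np.array(ns, float), np.array(ps), np.array(hs))
            num += a
            den += a + b + c
    if den == 0.0:
        return 0.0
    return num / den


def pairwise_fst(ds: GenotypeDataset) -> DistanceMatrix:
    """Pairwise multi-locus Weir–Cockerham theta between all populations.

    Populations with fewer than 2 individuals are excluded with a warning.
    Negative estimates are kept in the matrix; use ``.clamped()`` for
    distance-based downstream methods.
    """
    import logging

    pops = []
    for pop in ds.populations:
        if (ds.samples["population"] == pop).sum() < 2:
            logging.getLogger(__name__).warning(
                "population %s has < 2 individuals; excluded from F_ST", pop
            )
            continue
        pops.append(pop)
    if len(pops) < 2:
        raise ParameterError("pairwise F_ST needs >= 2 populations with >= 2 individuals")
    k = len(pops)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            theta = weir_cockerham_theta(ds, [pops[i], pops[j]])
            mat[i, j] = mat[j, i] = theta
    return DistanceMatrix(pops, mat, "fst")


# ---------------------------------------------------------------------------
# Nei's standard genetic distance
# ---------------------------------------------------------------------------


def nei_standard_distance(p_x: np.ndarray, p_y: np.ndarray) -> float:
    """Nei's standard distance between two populations from deletion freqs.

    Gene identities J are summed over all loci and both alleles before the
    ratio: Ds = -ln( Jxy / sqrt(Jx * Jy) ).
    """
    p_x = np.asarray(p_x, dtype=float)
    p_y = np.asarray(p_y, dtype=float)
    if p_x.shape != p_y.shape:
        raise ParameterError("populations must share the same locus set")
    jx = float((p_x**2 + (1 - p_x) ** 2).sum())
    jy = float((p_y**2 + (1 - p_y) ** 2).sum())
    jxy = float((p_x * p_y + (1 - p_x) * (1 - p_y)).sum())
    if jxy == 0.0:
        raise ParameterError("zero shared gene identity: Nei distance is infinite")
    return -math.log(jxy / math.sqrt(jx * jy))


def nei_distance_matrix(freqs: FrequencyTable) -> DistanceMatrix:
    """Pairwise Nei's standard distances between all populations of a table."""
    pops = freqs.populations
    loci = freqs.locus_ids
    vectors = {pop: freqs.freqs(pop, loci) for pop in pops}
    k = len(pops)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = nei_standard_distance(vectors[pops[i]], vectors[pops[j]])
    return DistanceMatrix(pops, mat, "nei_standard")


# ---------------------------------------------------------------------------
# informativeness for assignment
# ---------------------------------------------------------------------------


def informativeness_for_assignment(pop_freqs: np.ndarray, base: float = math.e) -> float:
    """Rosenberg's In for one biallelic locus across K populations.

    In = sum over alleles of ( -pbar*log(pbar) + sum_pops (p/K)*log(p) ) with
    0*log(0) := 0 and pbar the unweighted mean frequency.  Nonnegative; zero
    iff every population has identical frequencies.
    """
    p = np.asarray(pop_freqs, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ParameterError("frequencies must lie in [0, 1]")
    k = len(p)
    total = 0.0
    for allele_freqs in (p, 1.0 - p):
        pbar = allele_freqs.mean()
        if pbar > 0:
            total -= pbar * math.log(pbar)
        nz = allele_freqs[allele_freqs > 0]
        total += float((nz / k * np.log(nz)).sum())
    # identical frequencies give In = 0 analytically; snap accumulated
    # floating-point noise so the zero-iff-identical property holds exactly
    if abs(total) < 1e-12:
        total = 0.0
    return max(0.0, total) / math.log(base)


def informativeness_table(freqs: FrequencyTable, base: float = math.e) -> pd.DataFrame:
    """Per-locus In over all populations of a table, ranked descending."""
    pops = freqs.populations
    loci = freqs.locus_ids
    mat = np.column_stack([freqs.freqs(pop, loci) for pop in pops])
    values = [informativeness_for_assignment(row, base=base) for row in mat]
    df = pd.DataFrame({"locus": loci, "In": values})
    df["rank"] = df["In"].rank(ascending=False, method="first").astype(int)
    return df.sort_values("rank").reset_index(drop=True)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    label: str | None
    children: list[tuple["_Node", float]] = field(default_factory=list)

    def newick(self, decimals: int = 6) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(
            f"{child.newick(decimals)}:{length:.{decimals}f}"
            for child, length in self.children
        )
        return f"({inner})"


@dataclass
class TreeResult:
    """Unrooted NJ tree with Newick serialization and adjustment metadata."""

    root: _Node
    labels: list[str]
    negative_branches_adjusted: int = 0

    def newick(self, decimals: int = 6) -> str:
        return self.root.newick(decimals) + ";"


def neighbor_joining(dm: DistanceMatrix) -> TreeResult:
    """Saitou–Nei neighbor joining with the standard Q-criterion.

    Ties in Q are broken deterministically by label order.  Negative branch
    lengths are set to zero and the length transferred to the sister branch
    (so the pair's summed distance to their new parent is preserved); the
    number of adjustments is recorded.
    """
    labels = list(dm.labels)
    if len(labels) < 3:
        raise ParameterError("neighbor joining needs >= 3 taxa")
    d = dm.values.astype(float).copy()
    if not np.isfinite(d).all():
        raise ParameterError("distance matrix must be finite")
    nodes = [_Node(lbl) for lbl in labels]
    order = list(range(len(labels)))  # deterministic tie-break key
    active = list(range(len(labels)))
    adjustments = 0

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (m - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # pick minimal Q; break ties by (label-order of i, label-order of j)
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                key = (q[ii, jj], order[active[ii]], order[active[jj]])
                if best is None or key < best[0]:
                    best = (key, ii, jj)
        _, ii, jj = best
        i, j = active[ii], active[jj]
        dij = sub[ii, jj]
        li = 0.5 * dij + (row_sums[ii] - row_sums[jj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj, li = lj + li, 0.0
            adjustments += 1
        if lj < 0:
            li, lj = li + lj, 0.0
            adjustments += 1
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = _Node(None, [(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for kk in range(m):
            k = active[kk]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        order.append(min(order[i], order[j]))
        new_index = d.shape[0] - 1
        active = [k for k in active if k not in (i, j)] + [new_index]

    i, j = active
    length = max(d[i, j], 0.0)
    if d[i, j] < 0:
        adjustments += 1
    root = _Node(None, [(nodes[i], length / 2), (nodes[j], length / 2)])
    return TreeResult(root, labels, adjustments)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------


@dataclass
class Ordination:
    labels: list[str]
    coordinates: np.ndarray
    variance_fractions: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        cols = [f"dim{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude loading positive."""
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords


def classical_mds(dm: DistanceMatrix, dims: int = 2) -> Ordination:
    """Torgerson classical MDS: double-centering plus eigendecomposition."""
    if dims < 1:
        raise ParameterError("dims must be >= 1")
    d2 = dm.values**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    idx = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[idx], eigvecs[:, idx]
    positive = eigvals > max(eigvals.max(), 0.0) * 1e-12
    n_pos = int(positive.sum())
    if dims > n_pos:
        import logging

        logging.getLogger(__name__).warning(
            "requested %d dimensions but only %d positive eigenvalues; truncating",
            dims,
            n_pos,
        )
        dims = max(n_pos, 1)
    if n_pos == 0:
        coords = np.zeros((n, dims))
        fractions = np.zeros(dims)
    else:
        lam = eigvals[:dims].clip(min=0.0)
        coords = _fix_signs(eigvecs[:, :dims] * np.sqrt(lam))
        fractions = lam / eigvals[positive].sum()
    return Ordination(list(dm.labels), coords, fractions)


def pca(
    matrix: np.ndarray,
    labels: list[str],
    dims: int = 3,
) -> Ordination:
    """PCA of a column-centered matrix (rows: individuals or populations).

    Individual level: genotype dosage rows (missing values imputed by the
    column mean); population level: frequency rows.  Centering only, no
    scaling.  Variance fractions are relative to total variance (sum <= 1).
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 2:
        raise ParameterError("PCA needs >= 2 rows")
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    x = np.where(np.isnan(x), col_mean[None, :], x)
    x = x - x.mean(axis=0)
    dims = min(dims, min(x.shape) - 0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total_var = float((s**2).sum())
    coords = u[:, :dims] * s[:dims]
    fractions = (s[:dims] ** 2) / total_var if total_var > 0 else np.zeros(dims)
    return Ordination(list(labels), _fix_signs(coords), fractions)


def pca_individuals(ds: GenotypeDataset, dims: int = 3) -> Ordination:
    """Individual-level PCA on deletion-dosage genotypes."""
    return pca(ds.deletion_dosage(), list(ds.samples["sample_id"]), dims)


def pca_populations(freqs: FrequencyTable, dims: int = 3) -> Ordination:
    """Population-level PCA on deletion-frequency vectors."""
    pops = freqs.populations
    loci = freqs.locus_ids
    mat = np.vstack([freqs.freqs(pop, loci) for pop in pops])
    return pca(mat, pops, dims)
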