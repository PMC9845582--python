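"""Domain types and file I/O for biallelic deletion/insertion (DIP) panels.

A DIP locus has exactly two alleles: a short deletion variant ("D") and the
corresponding insertion variant ("I").  Genotypes are therefore one of three
classes — DD, DI, II — plus an explicit MISSING state.  Internally calls are
stored as the *deletion dosage*: the number of D alleles carried (II=0, DI=1,
DD=2, MISSING=-1), which makes the deletion-allele frequency a simple mean.
An insertion-dosage view (II=2, DI=1, DD=0) is provided for matrix maths that
follow the reference-allele convention.

File formats owned by this module:

* genotype TSV — columns ``sample_id, population, continent, <locus...>`` with
  cells in ``{DD, DI, ID, II, NA, ./.}`` ("ID" normalises to "DI");
* frequency CSV — columns ``locus, population, p_del, n``;
* distance CSV — square labelled matrix.

VCF import is a best-effort convenience for biallelic indel records and goes
through :mod:`pysam`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# deletion-dosage genotype codes
II = 0
DI = 1
DD = 2
MISSING = -1

_CODE_TO_LABEL = {II: "II", DI: "DI", DD: "DD", MISSING: "NA"}
_LABEL_TO_CODE = {"II": II, "DI": DI, "ID": DI, "DD": DD, "NA": MISSING, "./.": MISSING}

_META_COLUMNS = ("sample_id", "population", "continent")


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


class ParameterError(ValueError):
    """Raised when an argument is outside its documented domain."""


@dataclass(frozen=True)
class Locus:
    """A biallelic deletion/insertion marker (rsID naming convention)."""

    id: str
    alleles: tuple[str, str] = ("D", "I")

    def __post_init__(self) -> None:
        if not self.id:
            raise ParameterError("locus id must be nonempty")
        if len(self.alleles) != 2:
            raise ParameterError("a DIP locus has exactly two alleles")


@dataclass
class GenotypeDataset:
    """Samples x loci matrix of biallelic genotype calls with metadata.

    Attributes
    ----------
    loci : list of Locus
        Panel loci, in fixed panel order.
    samples : pandas.DataFrame
        One row per sample with columns ``sample_id``, ``population`` and
        ``continent`` (continent may be empty strings).
    calls : ndarray of int8, shape (n_samples, n_loci)
        Deletion-dosage codes; -1 marks a missing call.
    unknown_cell_count : int
        Number of unrecognised cells normalised to MISSING during parsing.
    """

    loci: list[Locus]
    samples: pd.DataFrame
    calls: np.ndarray
    unknown_cell_count: int = 0

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8).reshape(
            len(self.samples), len(self.loci)
        )
        ids = [loc.id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise ParameterError("locus ids must be unique within a panel")
        for col in _META_COLUMNS[:2]:
            if col not in self.samples.columns:
                raise ParameterError(f"samples frame lacks required column {col!r}")
        if "continent" not in self.samples.columns:
            self.samples = self.samples.assign(continent="")
        if (self.samples["population"].astype(str) == "").any():
            raise ParameterError("population labels must be nonempty")
        bad = ~np.isin(self.calls, (II, DI, DD, MISSING))
        if bad.any():
            raise ParameterError("genotype codes restricted to {II, DI, DD, MISSING}")

    # -- basic views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [loc.id for loc in self.loci]

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.samples["population"]))

    def deletion_dosage(self) -> np.ndarray:
        """Calls as float with NaN for missing (II=0, DI=1, DD=2)."""
        out = self.calls.astype(float)
        out[self.calls == MISSING] = np.nan
        return out

    def insertion_dosage(self) -> np.ndarray:
        """Insertion-allele dosage view (II=2, DI=1, DD=0; NaN missing)."""
        return 2.0 - self.deletion_dosage()

    def subset(self, population: str) -> "GenotypeDataset":
        mask = (self.samples["population"] == population).to_numpy()
        if not mask.any():
            raise ParameterError(f"no samples for population {population!r}")
        return GenotypeDataset(
            loci=self.loci,
            samples=self.samples.loc[mask].reset_index(drop=True),
            calls=self.calls[mask],
        )

    def genotype_counts(self, locus_index: int) -> tuple[int, int, int]:
        """(n_DD, n_DI, n_II) over non-missing calls at one locus."""
        col = self.calls[:, locus_index]
        return int((col == DD).sum()), int((col == DI).sum()), int((col == II).sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.locus_ids == other.locus_ids
            and self.samples[list(_META_COLUMNS)].equals(
                other.samples[list(_META_COLUMNS)]
            )
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class FrequencyTable:
    """Per-(locus, population) deletion-allele frequency with sample size.

    Backed by a DataFrame with columns ``locus, population, p_del, n`` where
    ``n`` counts diploid individuals with a non-missing call.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"locus", "population", "p_del", "n"}
        if not required.issubset(self.table.columns):
            raise ParameterError(f"frequency table needs columns {sorted(required)}")
        t = self.table
        if ((t["p_del"] < 0) | (t["p_del"] > 1)).any():
            raise ParameterError("frequencies must lie in [0, 1]")
        if (t["n"] < 1).any():
            raise ParameterError("sample sizes must be >= 1")
        if t.duplicated(["locus", "population"]).any():
            raise ParameterError("(locus, population) pairs must be unique")

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.table["population"]))

    @property
    def locus_ids(self) -> list[str]:
        return list(pd.unique(self.table["locus"]))

    def freqs(self, population: str, locus_ids: list[str] | None = None) -> np.ndarray:
        """Deletion frequencies for one population, in panel order."""
        sub = self.table[self.table["population"] == population]
        series = sub.set_index("locus")["p_del"]
        order = locus_ids if locus_ids is not None else list(series.index)
        return series.reindex(order).to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "FrequencyTable":
        return cls(pd.read_csv(path))


@dataclass
class DistanceMatrix:
    """Square symmetric population-distance matrix with labels."""

    labels: list[str]
    values: np.ndarray
    metric_name: str = "other"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ParameterError("matrix dimensions must match label count")
        if np.isnan(self.values).any():
            raise ParameterError("distance matrix contains NaN")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ParameterError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ParameterError("distance matrix diagonal must be zero")

    def clamped(self) -> "DistanceMatrix":
        """Copy with negative entries set to zero (for distance-based methods)."""
        vals = np.maximum(self.values, 0.0)
        np.fill_diagonal(vals, 0.0)
        return DistanceMatrix(self.labels, vals, self.metric_name)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def read_csv(cls, path, metric_name: str = "other") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float), metric_name)


# ---------------------------------------------------------------------------
# genotype TSV dialect
# ---------------------------------------------------------------------------


def read_genotype_table(path) -> GenotypeDataset:
    """Read the genotype TSV dialect into a validated :class:`GenotypeDataset`.

    Header must start with ``sample_id`` and ``population`` (``continent``
    optional); remaining columns are loci.  Cells outside the recognised
    genotype vocabulary are normalised to MISSING and counted.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise FormatError(f"{path}: empty file, missing header")
    header = lines[0].split("\t")
    if header[:2] != ["sample_id", "population"]:
        raise FormatError(
            f"{path}: header must start with 'sample_id\\tpopulation', got {header[:2]}"
        )
    has_continent = len(header) > 2 and header[2] == "continent"
    n_meta = 3 if has_continent else 2
    locus_names = header[n_meta:]
    loci = [Locus(name) for name in locus_names]

    meta_rows, call_rows = [], []
    unknown = 0
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}: line {lineno} has {len(cells)} fields, expected {len(header)}"
            )
        meta = cells[:n_meta] if has_continent else cells[:2] + [""]
        meta_rows.append(meta)
        row = []
        for cell in cells[n_meta:]:
            code = _LABEL_TO_CODE.get(cell.strip().upper() if cell.strip() != "./." else "./.")
            if code is None:
                unknown += 1
                code = MISSING
            row.append(code)
        call_rows.append(row)
    if unknown:
        logger.warning("%s: %d unrecognised genotype cells set to MISSING", path, unknown)
    samples = pd.DataFrame(meta_rows, columns=list(_META_COLUMNS))
    calls = (
        np.array(call_rows, dtype=np.int8)
        if call_rows
        else np.empty((0, len(loci)), dtype=np.int8)
    )
    return GenotypeDataset(loci, samples, calls, unknown_cell_count=unknown)


def write_genotype_table(ds: GenotypeDataset, path) -> None:
    """Write a dataset in the genotype TSV dialect (deterministic column order)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(list(_META_COLUMNS) + ds.locus_ids) + "\n")
        for i in range(ds.n_samples):
            meta = [str(ds.samples.iloc[i][c]) for c in _META_COLUMNS]
            geno = [_CODE_TO_LABEL[int(c)] for c in ds.calls[i]]
            fh.write("\t".join(meta + geno) + "\n")


def import_vcf(path) -> GenotypeDataset:
    """Import biallelic indel records from a VCF as DIP genotypes.

    The shorter of REF/ALT is taken as the deletion allele.  Phased and
    unphased genotypes are treated identically; multi-allelic records are
    skipped with a warning.  Population/continent metadata is left empty.
    """
    import pysam

    vf = pysam.VariantFile(path)
    if "GT" not in vf.header.formats:
        raise FormatError(f"{path}: VCF has no GT format field")
    sample_ids = list(vf.header.samples)
    loci: list[Locus] = []
    columns: list[list[int]] = []
    skipped = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            skipped += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        # shorter allele is the deletion; allele index carrying it:
        del_index = 0 if len(ref) < len(alt) else 1
        col = []
        for sid in sample_ids:
            gt = rec.samples[sid]["GT"]
            if gt is None or any(a is None for a in gt):
                col.append(MISSING)
            else:
                col.append(sum(1 for a in gt if a == del_index))
        loci.append(Locus(rec.id or f"{rec.chrom}:{rec.pos}"))
        columns.append(col)
    if skipped:
        logger.warning("%s: skipped %d non-biallelic records", path, skipped)
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "population": "unknown", "continent": ""}
    )
    calls = (
        np.array(columns, dtype=np.int8).T
        if columns
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeDataset(loci, samples, calls, unknown_cell_count=skipped)


def estimate_frequencies(ds: GenotypeDataset) -> FrequencyTable:
    """Estimate per-locus, per-population deletion-allele frequencies.

    p = (2*#DD + #DI) / (2 * #non-missing individuals); a locus with no
    non-missing call in a population is reported as an absent entry with a
    warning rather than a silent zero.
    """
    rows = []
    for pop in ds.populations:
        sub = ds.subset(pop)
        for j, locus in enumerate(sub.loci):
            n_dd, n_di, n_ii = sub.genotype_counts(j)
            n = n_dd + n_di + n_ii
            if n == 0:
                logger.warning(
                    "locus %s has no non-missing calls in population %s", locus.id, pop
                )
                continue
            rows.append(
                {
                    "locus": locus.id,
                    "population": pop,
                    "p_del": (2 * n_dd + n_di) / (2 * n),
                    "n": n,
                }
            )
    return FrequencyTable(pd.DataFrame(rows, columns=["locus", "population", "p_del", "n"]))
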