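import numpy as np
import pandas as pd
import pytest

from dippanel.io import DD, DI, II, GenotypeDataset, Locus


def make_dataset(counts_per_pop: dict[str, tuple[int, int, int]], locus_id="rs0", extra_loci=None):
    """Single-locus dataset from per-population (n_DD, n_DI, n_II) counts.

    ``extra_loci`` optionally adds further loci as {locus_id: {pop: counts}}.
    """
    loci = [Locus(locus_id)] + [Locus(lid) for lid in (extra_loci or {})]
    rows, calls = [], []
    for pop, (n_dd, n_di, n_ii) in counts_per_pop.items():
        genos = [DD] * n_dd + [DI] * n_di + [II] * n_ii
        for i, g in enumerate(genos):
            row = [g]
            for lid in extra_loci or {}:
                edd, edi, eii = extra_loci[lid][pop]
                egenos = [DD] * edd + [DI] * edi + [II] * eii
                row.append(egenos[i])
            calls.append(row)
            rows.append({"sample_id": f"{pop}_{i}", "population": pop, "continent": ""})
    return GenotypeDataset(loci, pd.DataFrame(rows), np.array(calls, dtype=np.int8))


@pytest.fixture
def hwe_counts_dataset():
    """One population under exact HWE proportions at p = 0.5 (n = 100)."""
    return make_dataset({"popA": (25, 50, 25)})
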