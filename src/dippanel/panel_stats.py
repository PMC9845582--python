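"""Across-loci combination of forensic parameters: CPM, TDP, CPE.

For k independent loci,

    CPM = prod_i PM_i
    TDP = 1 - prod_i (1 - PD_i)
    CPE = 1 - prod_i (1 - PE_i)

Products are accumulated in log space: over a 43-locus panel CPM reaches
magnitudes around 1e-18, which must survive combination and print in
scientific style (e.g. "1.11433E-18"), so each quantity is also reported as
a mantissa/exponent pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ParameterError


def _from_log10(log10_x: float) -> tuple[float, str]:
    """(float value, 'mantissaEexponent' string) from a base-10 log."""
    if log10_x == -math.inf:
        return 0.0, "0E0"
    exponent = math.floor(log10_x)
    mantissa = 10.0 ** (log10_x - exponent)
    return 10.0**log10_x, f"{mantissa:.5f}E{exponent:+d}"


@dataclass
class PanelStats:
    """Combined panel-level statistics for one population."""

    population: str
    k: int
    cpm: float
    tdp: float
    cpe: float
    cpm_sci: str
    log10_cpm: float

    def as_dict(self) -> dict:
        return {
            "population": self.population,
            "n_loci": self.k,
            "CPM": self.cpm,
            "CPM_scientific": self.cpm_sci,
            "TDP": self.tdp,
            "CPE": self.cpe,
        }


def combine_panel(
    pm: np.ndarray,
    pd_: np.ndarray,
    pe: np.ndarray,
    population: str = "",
) -> PanelStats:
    """Combine per-locus PM/PD/PE vectors into CPM, TDP and CPE.

    Locus order never changes the result; computation is in log space to
    avoid underflow on long panels.
    """
    pm = np.asarray(pm, dtype=float)
    pd_ = np.asarray(pd_, dtype=float)
    pe = np.asarray(pe, dtype=float)
    if pm.size == 0:
        raise ParameterError("combine_panel needs at least one locus")
    for name, v in (("PM", pm), ("PD", pd_), ("PE", pe)):
        if v.shape != pm.shape:
            raise ParameterError("PM, PD and PE vectors must have equal length")
        if ((v < 0) | (v > 1)).any():
            raise ParameterError(f"{name} values must lie in [0, 1]")

    with np.errstate(divide="ignore"):
        log10_cpm = float(np.log10(pm).sum())
        # TDP and CPE are complements of products of complements
        log_one_minus_tdp = float(np.log1p(-pd_).sum())
        log_one_minus_cpe = float(np.log1p(-pe).sum())
    cpm, cpm_sci = _from_log10(log10_cpm)
    tdp = -math.expm1(log_one_minus_tdp)
    cpe = -math.expm1(log_one_minus_cpe)
    return PanelStats(
        population=population,
        k=int(pm.size),
        cpm=cpm,
        tdp=tdp,
        cpe=cpe,
        cpm_sci=cpm_sci,
        log10_cpm=log10_cpm,
    )


def panel_stats_table(locus_table: pd.DataFrame) -> pd.DataFrame:
    """Panel combinations per population from a locus_stats table."""
    rows = []
    for pop, grp in locus_table.groupby("population", sort=False):
        stats = combine_panel(
            grp["pm"].to_numpy(), grp["pd"].to_numpy(), grp["pe"].to_numpy(), pop
        )
        rows.append(stats.as_dict())
    return pd.DataFrame(rows)
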