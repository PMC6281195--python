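"""Regulon size versus source-habitat climate.

Ecotypes collected from colder sites tend to deploy larger cold regulons.
This module regresses per-genotype gene counts (CBF-regulon or total COR)
on the minimum monthly low temperature average of the site the accession
was collected from, by ordinary least squares, and reports slope,
intercept and R².  With the three genotypes typically available the fit is
descriptive — a small-n caveat flag is set and no significance test is
attached, since any p-value at n = 3 would be decorative.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = ["ClimateFit", "fit_count_vs_temperature"]


@dataclass(frozen=True)
class ClimateFit:
    response: str
    slope: float  # genes per °C
    intercept: float
    r_squared: float
    n: int
    small_n_caveat: bool


def fit_count_vs_temperature(
    records: pd.DataFrame,
    response: str = "regulon_count",
    small_n_threshold: int = 5,
) -> ClimateFit:
    """OLS of a gene count on minimum monthly low temperature.

    ``records`` needs columns ``genotype``, ``min_monthly_low`` (°C) and
    the chosen ``response`` column (``regulon_count`` or ``cor_count``).
    Requires ≥ 2 records with distinct temperatures; identical temperatures
    leave the slope undefined and raise.
    """
    for col in ("min_monthly_low", response):
        if col not in records.columns:
            raise ValueError(f"missing required column {col!r}")
    x = records["min_monthly_low"].to_numpy(dtype=float)
    y = records[response].to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("gene counts must be non-negative")
    if len(x) < 2 or len(set(x.tolist())) < 2:
        raise ValueError("need >= 2 records with distinct temperatures")
    res = stats.linregress(x, y)
    return ClimateFit(
        response=response,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(x),
        small_n_caveat=len(x) < small_n_threshold,
    )
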