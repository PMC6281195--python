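"""Freezing-tolerance phenotype analysis from electrolyte-leakage curves.

An electrolyte-leakage freeze test exposes leaf tissue to a series of
sub-zero temperatures and measures ion efflux as a percentage of the total
releasable electrolytes.  The summary statistic is EL50 — the temperature at
which 50% of electrolytes leak; a lower (more negative) EL50 means a more
freezing-tolerant plant.  EL50 is estimated here from a third-order
polynomial fitted by ordinary least squares to the leakage-versus-temperature
curve, and the gain in freezing tolerance on cold acclimation is decomposed
into CBF-dependent and CBF-independent components by contrasting a wild-type
genotype with its *cbf123* triple mutant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "LeakageCurve",
    "EL50Estimate",
    "AcclimationDecomposition",
    "CurveComparison",
    "fit_el50",
    "decompose_acclimation",
    "compare_curves",
    "curves_from_dataframe",
]


@dataclass(frozen=True)
class LeakageCurve:
    """Mean % electrolyte leakage across test temperatures for one
    genotype × acclimation group.

    ``points`` rows are (temperature_C, mean_leakage_pct, se_pct,
    n_replicates), strictly ordered by temperature.
    """

    genotype: str
    acclimation: str  # "non_acclimated" | "cold_acclimated"
    points: tuple[tuple[float, float, float, int], ...]

    def __post_init__(self) -> None:
        temps = [p[0] for p in self.points]
        if sorted(temps) != temps or len(set(temps)) != len(temps):
            raise ValueError("temperatures must be strictly increasing")
        for t, leak, se, n in self.points:
            if not 0.0 <= leak <= 100.0:
                raise ValueError(
                    f"leakage {leak} out of [0, 100] at {t} degC "
                    f"({self.genotype}/{self.acclimation})"
                )

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def leakage(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)


@dataclass(frozen=True)
class EL50Estimate:
    """Cubic fit of leakage on temperature and its 50% crossing.

    ``coefficients`` are in descending power order (numpy polyval
    convention).  ``in_range`` is True when the selected crossing lies
    inside the tested temperature span; outside it is an extrapolation and
    should be treated with caution.
    """

    coefficients: tuple[float, float, float, float]
    el50: float
    in_range: bool
    rss: float
    genotype: str = ""
    acclimation: str = ""

    def predict(self, temperature: float | np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, temperature)


@dataclass(frozen=True)
class AcclimationDecomposition:
    """Split of the cold-acclimation EL50 shift into CBF-dependent and
    CBF-independent parts.

    delta_wt = WT non-acclimated EL50 − WT acclimated EL50 (positive when
    acclimation lowers EL50, i.e. improves tolerance); delta_mut is the same
    for the *cbf123* mutant.  Everything the mutant still achieves is
    CBF-independent; the remainder of the wild-type gain is CBF-dependent.
    """

    delta_wt: float
    delta_mut: float
    cbf_dependent: float
    cbf_independent: float
    fraction_cbf_dependent: float
    fraction_defined: bool = True

    @property
    def fraction_rounded_5pct(self) -> float:
        """Display rounding of the CBF-dependent fraction to the nearest 5%."""
        return round(self.fraction_cbf_dependent * 20) / 20


@dataclass(frozen=True)
class CurveComparison:
    genotypes: tuple[str, str]
    p_value: float  # 1-df genotype contrast, averaged over temperatures
    p_interaction: float  # genotype x temperature
    significance: str
    anova_table: pd.DataFrame = field(repr=False, compare=False, default=None)


def _significance_label(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def fit_el50(curve: LeakageCurve) -> EL50Estimate:
    """Fit an OLS cubic of mean leakage on temperature and locate EL50.

    The cubic can cross 50% up to three times.  The crossing reported is
    the one on the physically meaningful limb where leakage increases as
    temperature decreases (fitted slope < 0 in temperature), preferring
    crossings inside the tested span; among several such candidates the one
    closest to the temperature of steepest fitted decline is taken, which
    corresponds to the sigmoid midpoint of the underlying freeze-damage
    response.

    Raises
    ------
    ValueError
        If fewer than 4 points are supplied, the fitted cubic never crosses
        50%, or the fit is degenerate (e.g. constant 50% leakage).
    """
    T = curve.temperatures
    L = curve.leakage
    if len(T) < 4:
        raise ValueError("need at least 4 distinct temperatures for a cubic fit")
    coef = np.polyfit(T, L, 3)
    rss = float(np.sum((np.polyval(coef, T) - L) ** 2))

    shifted = coef - np.array([0.0, 0.0, 0.0, 50.0])
    # Strip numerically-zero leading coefficients so np.roots does not
    # produce spurious far-field roots for effectively lower-order fits.
    scale = max(np.max(np.abs(shifted)), 1.0)
    nz = np.abs(shifted) > 1e-12 * scale
    if not nz.any():
        raise ValueError("no unique 50% crossing: fitted curve is constant at 50%")
    trimmed = shifted[np.argmax(nz):]
    if len(trimmed) == 1:
        raise ValueError("no 50% crossing: fitted curve is constant")
    roots = np.roots(trimmed)
    real = roots[np.abs(roots.imag) < 1e-8 * max(1.0, np.max(np.abs(roots)))].real
    if real.size == 0:
        raise ValueError("no 50% crossing: cubic - 50 has no real root")

    deriv = np.polyder(coef)
    decreasing = real[np.polyval(deriv, real) < 0]
    candidates = decreasing if decreasing.size else real

    tmin, tmax = float(T.min()), float(T.max())
    inside = candidates[(candidates >= tmin) & (candidates <= tmax)]
    pool = inside if inside.size else candidates

    # temperature of steepest decline: minimiser of the derivative (a
    # parabola) over the tested span
    grid = np.linspace(tmin, tmax, 201)
    steepest = float(grid[np.argmin(np.polyval(deriv, grid))])
    el50 = float(pool[np.argmin(np.abs(pool - steepest))])

    return EL50Estimate(
        coefficients=tuple(float(c) for c in coef),
        el50=el50,
        in_range=bool(tmin <= el50 <= tmax),
        rss=rss,
        genotype=curve.genotype,
        acclimation=curve.acclimation,
    )


def _el50_value(x) -> float:
    return float(x.el50) if hasattr(x, "el50") else float(x)


def decompose_acclimation(wt_na, wt_ca, mut_na, mut_ca) -> AcclimationDecomposition:
    """Decompose the acclimation gain in freezing tolerance.

    Accepts :class:`EL50Estimate` objects or plain EL50 values (°C) for the
    wild type (``wt``) and the *cbf123* triple mutant (``mut``), each
    non-acclimated (``na``) and cold-acclimated (``ca``).

    The identity ``cbf_dependent + cbf_independent == delta_wt`` holds
    exactly by construction.
    """
    delta_wt = _el50_value(wt_na) - _el50_value(wt_ca)
    delta_mut = _el50_value(mut_na) - _el50_value(mut_ca)
    cbf_dep = delta_wt - delta_mut
    if delta_wt == 0.0:
        return AcclimationDecomposition(
            delta_wt=delta_wt, delta_mut=delta_mut, cbf_dependent=cbf_dep,
            cbf_independent=delta_mut, fraction_cbf_dependent=float("nan"),
            fraction_defined=False,
        )
    return AcclimationDecomposition(
        delta_wt=delta_wt, delta_mut=delta_mut, cbf_dependent=cbf_dep,
        cbf_independent=delta_mut, fraction_cbf_dependent=cbf_dep / delta_wt,
    )


def compare_curves(data: pd.DataFrame) -> CurveComparison:
    """Compare two genotypes' temperature-response curves by two-way ANOVA.

    ``data`` holds replicate-level measurements with columns ``genotype``,
    ``temperature_C``, ``leakage_pct`` (a ``replicate`` column is allowed
    and ignored).  Temperature enters as a categorical factor; sums of
    squares are Type II, so mild imbalance is tolerated.  The reported
    ``p_value`` is the single-degree-of-freedom contrast for the genotype
    difference averaged over temperatures — with two genotypes this is the
    genotype main effect — and the genotype × temperature interaction is
    reported alongside.
    """
    required = {"genotype", "temperature_C", "leakage_pct"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    genos = sorted(data["genotype"].unique())
    if len(genos) != 2:
        raise ValueError(f"exactly two genotypes required, got {genos}")
    counts = data.groupby(["genotype", "temperature_C"]).size()
    if (counts < 2).any():
        raise ValueError(
            "at least 2 replicates per genotype x temperature cell are "
            "required to estimate the error stratum"
        )
    df = data.copy()
    df["temperature_C"] = df["temperature_C"].astype(str)
    model = smf.ols("leakage_pct ~ C(genotype) * C(temperature_C)", data=df).fit()
    table = anova_lm(model, typ=2)
    p_geno = float(table.loc["C(genotype)", "PR(>F)"])
    p_inter = float(table.loc["C(genotype):C(temperature_C)", "PR(>F)"])
    return CurveComparison(
        genotypes=(genos[0], genos[1]),
        p_value=p_geno,
        p_interaction=p_inter,
        significance=_significance_label(p_geno),
        anova_table=table,
    )


def curves_from_dataframe(data: pd.DataFrame) -> list[LeakageCurve]:
    """Collapse replicate-level leakage data to per-group mean curves."""
    curves = []
    for (geno, acc), grp in data.groupby(["genotype", "acclimation"], sort=True):
        pts = []
        for t, sub in grp.groupby("temperature_C", sort=True):
            vals = sub["leakage_pct"].to_numpy(dtype=float)
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            pts.append((float(t), float(np.clip(vals.mean(), 0, 100)), se, len(vals)))
        curves.append(LeakageCurve(genotype=geno, acclimation=acc, points=tuple(pts)))
    return curves


def el50_table(estimates: list[EL50Estimate]) -> pd.DataFrame:
    """Tabulate EL50 fits, one row per genotype × acclimation group."""
    rows = []
    for e in estimates:
        c3, c2, c1, c0 = e.coefficients
        rows.append(
            dict(genotype=e.genotype, acclimation=e.acclimation,
                 coef3=c3, coef2=c2, coef1=c1, coef0=c0,
                 el50=e.el50, in_range=e.in_range, rss=e.rss)
        )
    return pd.DataFrame(rows)
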