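"""Keeling-plot estimation of the delta13C signature of emitted CO2.

As source CO2 accumulates over an ambient background, the observed
delta13C of the mixture is linear in the inverse concentration:

    delta = delta_s + (C_a / C) * (delta_a - delta_s)

so an ordinary least-squares fit of delta on 1/[CO2] has the source
signature delta_s as its intercept. Replicate intercepts are screened by
the regression r^2 (> 0.90) and by the coefficient of variation across
replicates (< 10%) before a per-sample source signature is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "IsotopeSeries",
    "KeelingFit",
    "KeelingResults",
    "KeelingModel",
    "SourceSignature",
    "GroupContrast",
    "fit_keeling",
    "aggregate_replicates",
    "group_contrast",
]


@dataclass(frozen=True)
class IsotopeSeries:
    """Paired CO2 concentration and delta13C observations from one jar."""

    sample_id: str
    replicate: int
    times: np.ndarray  # hours
    co2_ppm: np.ndarray
    d13c: np.ndarray  # permil VPDB

    def __post_init__(self) -> None:
        for name in ("times", "co2_ppm", "d13c"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.times.shape == self.co2_ppm.shape == self.d13c.shape):
            raise ValueError("times, co2_ppm and d13c must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.co2_ppm[np.isfinite(self.d13c)] <= 0):
            raise ValueError("co2_ppm must be positive wherever d13c is observed")


@dataclass(frozen=True)
class KeelingResults:
    """OLS fit of delta13C on inverse CO2 concentration.

    ``intercept`` estimates the source signature (permil VPDB);
    ``intercept_se`` is the usual OLS standard error.
    """

    sample_id: str
    replicate: int
    intercept: float
    slope: float
    r_squared: float
    intercept_se: float
    n_points: int

    def summary(self) -> str:
        return (
            f"Keeling fit: {self.sample_id} rep {self.replicate + 1}\n"
            f"  intercept (source d13C) {self.intercept:.3f} +/- {self.intercept_se:.3f} permil\n"
            f"  slope                   {self.slope:.1f} permil ppm\n"
            f"  r-squared               {self.r_squared:.4f}  (n = {self.n_points})"
        )

# the spec-facing alias: a fitted replicate record
KeelingFit = KeelingResults


class KeelingModel:
    """Model of delta13C versus inverse CO2 concentration for one replicate."""

    def __init__(self, series: IsotopeSeries):
        ok = np.isfinite(series.d13c) & np.isfinite(series.co2_ppm)
        if np.any(series.co2_ppm[ok] <= 0):
            raise ValueError("zero or negative concentration in isotope series")
        if int(ok.sum()) < 3:
            raise ValueError("at least 3 usable points are required for a Keeling fit")
        self.series = series
        self.inv_conc = 1.0 / series.co2_ppm[ok]
        self.d13c = series.d13c[ok]

    def fit(self) -> KeelingResults:
        x = sm.add_constant(self.inv_conc)
        res = sm.OLS(self.d13c, x).fit()
        tss = float(np.sum((self.d13c - self.d13c.mean()) ** 2))
        r2 = float(res.rsquared) if tss > 0 else float("nan")
        return KeelingResults(
            sample_id=self.series.sample_id,
            replicate=self.series.replicate,
            intercept=float(res.params[0]),
            slope=float(res.params[1]),
            r_squared=r2,
            intercept_se=float(res.bse[0]),
            n_points=int(self.d13c.size),
        )


    def plot(self, results: KeelingResults | None = None, ax=None):
        """Keeling plot: observed delta against 1/[CO2] with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if results is None:
            results = self.fit()
        ax.scatter(self.inv_conc, self.d13c, color="k", s=20)
        xs = np.linspace(0, self.inv_conc.max() * 1.05, 50)
        ax.plot(xs, results.intercept + results.slope * xs, color="tab:red")
        ax.set_xlabel(r"1/[CO$_2$] (ppm$^{-1}$)")
        ax.set_ylabel(r"$\delta^{13}$C (permil VPDB)")
        ax.set_title(
            f"{results.sample_id} rep {results.replicate + 1}: "
            f"intercept {results.intercept:.2f} permil"
        )
        return ax


def fit_keeling(series: IsotopeSeries) -> KeelingResults:
    """Fit a :class:`KeelingModel` to one replicate's isotope series."""
    return KeelingModel(series).fit()


@dataclass(frozen=True)
class SourceSignature:
    """Per-sample source delta13C aggregated over accepted replicates.

    ``accepted`` requires at least two replicates surviving the r^2
    screen and a coefficient of variation of their intercepts below
    ``cv_max``.
    """

    sample_id: str
    delta_flux: float  # permil VPDB, mean of accepted replicate intercepts
    cv: float
    n_used: int
    accepted: bool


def aggregate_replicates(
    fits: Sequence[KeelingResults],
    r2_min: float = 0.90,
    cv_max: float = 0.10,
) -> SourceSignature:
    """Apply the replicate QC rules and average surviving intercepts.

    Replicates with r^2 <= r2_min (strict threshold; ties excluded) are
    dropped. If at least two remain, their mean intercept and the CV
    (sample sd over absolute mean) are reported; acceptance additionally
    requires cv < cv_max. With fewer than two survivors the sample is
    not accepted.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no Keeling fits supplied")
    sample_id = fits[0].sample_id
    kept = [f for f in fits if np.isfinite(f.r_squared) and f.r_squared > r2_min]
    if len(kept) < 2:
        mean = float(np.mean([f.intercept for f in kept])) if kept else float("nan")
        return SourceSignature(sample_id, mean, float("nan"), len(kept), False)
    intercepts = np.array([f.intercept for f in kept])
    mean = float(intercepts.mean())
    cv = float(intercepts.std(ddof=1) / abs(mean)) if mean != 0 else float("inf")
    return SourceSignature(sample_id, mean, cv, len(kept), bool(cv < cv_max))


@dataclass(frozen=True)
class GroupContrast:
    """Welch two-sample comparison of source signatures between materials."""

    means: Mapping[str, float]
    difference: float
    t_statistic: float
    df: float
    p_value: float

    def summary(self) -> str:
        groups = ", ".join(f"{k}: {v:.2f} permil" for k, v in self.means.items())
        return (
            f"Group means  {groups}\n"
            f"Difference   {self.difference:.2f} permil\n"
            f"Welch t      {self.t_statistic:.2f} (df = {self.df:.1f}, p = {self.p_value:.3g})"
        )


def group_contrast(groups: Mapping[str, Sequence[float]]) -> GroupContrast:
    """Welch t contrast between two groups of source signatures.

    Parameters
    ----------
    groups : mapping of group label -> sequence of delta13C values
        Exactly two groups, each with at least two members (the unequal
        variance t is undefined otherwise).
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    (name_a, a), (name_b, b) = groups.items()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two members for a Welch t-test")
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupContrast(
        means={name_a: float(a.mean()), name_b: float(b.mean())},
        difference=float(a.mean() - b.mean()),
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )
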