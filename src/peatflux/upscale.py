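"""Upscale per-gram decomposition rates to annual national emissions.

A single mean biotic decomposition rate (mg CO2-C per g organic C per
day) applied to the mass of carbon extracted annually gives the
first-year emission:

    E [Mt C] = extraction [Mt C] * rate * 1e-3 * days

with a normal-approximation 95% CI from the rate's standard error. The
restoration sink converts an area under restoration and a long-term
areal uptake into the same units for comparison. Group summaries,
Welch t contrasts and Spearman rank correlations are provided as
reporting plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DAYS_PER_YEAR, G_TO_MT, HA_TO_M2, MG_PER_G_TO_FRACTION, Z_95
from .keeling import GroupContrast, group_contrast

__all__ = [
    "UpscaleInputs",
    "EmissionEstimate",
    "first_year_emission",
    "restoration_sink",
    "group_summary",
    "welch_contrasts",
    "spearman_matrix",
    "correlation_strength",
    "summarize",
]


@dataclass(frozen=True)
class UpscaleInputs:
    """Inputs of the national emission calculation.

    extraction : Mt C of peat removed per year.
    rate_mean, rate_se : mg CO2-C per g organic C per day.
    restored_area : ha of extracted peatland under restoration.
    sink_rate : g C per m2 per year long-term uptake after restoration.
    """

    extraction: float = 0.45
    rate_mean: float = 0.147
    rate_se: float = 0.017
    days: int = DAYS_PER_YEAR
    z: float = Z_95
    restored_area: float = 18_000.0
    sink_rate: float = 50.0

    def __post_init__(self) -> None:
        if self.extraction < 0 or self.rate_mean < 0 or self.rate_se < 0:
            raise ValueError("extraction, rate_mean and rate_se must be non-negative")
        if self.days <= 0:
            raise ValueError("days must be positive")
        if self.restored_area < 0:
            raise ValueError("restored_area must be non-negative")


@dataclass(frozen=True)
class EmissionEstimate:
    """First-year emission, Mt C, with a 95% confidence interval."""

    central: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower <= self.central <= self.upper:
            raise ValueError("require lower <= central <= upper")

    def summary(self) -> str:
        return (
            f"First-year emission: {self.central:.3f} Mt C "
            f"(95% CI {self.lower:.3f} to {self.upper:.3f} Mt C)"
        )


def first_year_emission(inputs: UpscaleInputs) -> EmissionEstimate:
    """Emission released in the first year after extraction.

    central = extraction * rate_mean * 1e-3 * days (the 1e-3 converts
    mg C per g C to a mass fraction); the CI applies the same chain to
    rate_mean -/+ z * rate_se.
    """
    def emit(rate: float) -> float:
        return inputs.extraction * rate * MG_PER_G_TO_FRACTION * inputs.days

    return EmissionEstimate(
        central=emit(inputs.rate_mean),
        lower=emit(max(inputs.rate_mean - inputs.z * inputs.rate_se, 0.0)),
        upper=emit(inputs.rate_mean + inputs.z * inputs.rate_se),
    )


def restoration_sink(restored_area: float, sink_rate: float) -> float:
    """Annual C uptake of restored peatland, Mt C per year.

    area [ha] * 1e4 m2/ha * sink [g C m-2 yr-1] * 1e-12 Mt/g.
    """
    if restored_area < 0:
        raise ValueError("restored_area must be non-negative")
    return restored_area * HA_TO_M2 * sink_rate * G_TO_MT


def group_summary(df: pd.DataFrame, by: str, variables: Sequence[str]) -> pd.DataFrame:
    """Mean, standard error and n per group for each variable."""
    rows = []
    for grp, sub in df.groupby(by):
        for var in variables:
            vals = sub[var].dropna().to_numpy(dtype=float)
            n = vals.size
            rows.append(
                {
                    by: grp,
                    "variable": var,
                    "mean": vals.mean() if n else np.nan,
                    "se": vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def welch_contrasts(df: pd.DataFrame, by: str, variables: Sequence[str]) -> pd.DataFrame:
    """Welch t contrast between the two groups of ``by``, per variable."""
    levels = sorted(df[by].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"welch_contrasts needs exactly 2 groups, found {len(levels)}")
    rows = []
    for var in variables:
        groups = {
            str(lvl): df.loc[df[by] == lvl, var].dropna().to_numpy(dtype=float)
            for lvl in levels
        }
        contrast: GroupContrast = group_contrast(groups)
        rows.append(
            {
                "variable": var,
                f"mean_{levels[0]}": contrast.means[str(levels[0])],
                f"mean_{levels[1]}": contrast.means[str(levels[1])],
                "difference": contrast.difference,
                "t": contrast.t_statistic,
                "df": contrast.df,
                "p_value": contrast.p_value,
            }
        )
    return pd.DataFrame(rows)


def correlation_strength(rho: float) -> str:
    """Verbal descriptor: |rho| > 0.5 strong, 0.3-0.5 moderate, else weak."""
    a = abs(rho)
    if a > 0.5:
        return "strong"
    if a >= 0.3:
        return "moderate"
    return "weak"


def spearman_matrix(
    df: pd.DataFrame, variables: Sequence[str], min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho (average ranks for ties) and p-values.

    Pairs with fewer than ``min_pairs`` complete observations are
    reported as missing.
    """
    k = len(variables)
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    pval = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    for i, a in enumerate(variables):
        for j, b in enumerate(variables):
            if j <= i:
                continue
            sub = df[[a, b]].dropna()
            if len(sub) < min_pairs:
                r = p = np.nan
            else:
                r, p = stats.spearmanr(sub[a], sub[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


def summarize(df: pd.DataFrame, by: str, variables: Sequence[str]) -> dict:
    """Group means +/- se, Welch contrasts and the Spearman matrix in one call."""
    rho, pval = spearman_matrix(df, variables)
    return {
        "group_summary": group_summary(df, by, variables),
        "welch": welch_contrasts(df, by, variables),
        "spearman_rho": rho,
        "spearman_p": pval,
    }
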