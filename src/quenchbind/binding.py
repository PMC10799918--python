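"""Double-logarithmic binding analysis and site-probe displacement.

For static quenching with n equivalent sites,
log10((F0 − F)/F) = log10 K_a + n log10 [Q]: the intercept of the
double-log plot gives the binding constant K_a (M⁻¹) and the slope the
number of binding sites n (n ≈ 1 means one non-cooperative site).  The
K_a uncertainty is multiplicative — 10^SE(intercept) — because the error
is additive on the log axis.

Competitive displacement compares K_a with and without a site probe
(warfarin marks Sudlow site I, ibuprofen site II): a fold-decrease above
the threshold means the ligand and the probe contest the same pocket.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from scipy import stats

from .spectra import TitrationSeries, ValidationError

__all__ = [
    "BindingFit",
    "DisplacementMode",
    "DisplacementResult",
    "double_log_fit",
    "displacement_analysis",
]


class DisplacementMode(str, Enum):
    COMPETITIVE = "competitive"
    COOPERATIVE = "cooperative"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class BindingFit:
    """Double-log regression output at one temperature.

    ``geom_error_factor`` is the ×/÷ multiplicative uncertainty on K_a
    (always >= 1); ``n_se`` the standard error of the site number.
    """

    K_a_M: float
    geom_error_factor: float
    n_sites: float
    n_se: float
    r_squared: float
    temperature_K: float
    n_points: int
    competitor: Optional[str] = None


@dataclass(frozen=True)
class DisplacementResult:
    K_a_without_M: float
    K_a_with_M: float
    fold_change: float
    mode: DisplacementMode
    competitor: Optional[str] = None

    @property
    def fold_change_2dp(self) -> float:
        return round(self.fold_change, 2)

    @property
    def fold_change_int(self) -> int:
        return int(round(self.fold_change))


def double_log_fit(
    series: TitrationSeries,
    emission_nm: float = 340.0,
) -> BindingFit:
    """Fit log10((F0−F)/F) vs log10[Q] over the nonzero concentrations.

    The zero-quencher trace only defines F0 (log 0 is undefined, so that
    point never enters the regression).  Points where F >= F0 — no
    detectable quenching — are excluded with a warning; at least three
    usable points are required.
    """
    if not series.has_reference:
        raise ValidationError("series lacks a zero-quencher (F0) trace")
    concs = series.quencher_concs_M
    if np.count_nonzero(concs) < 3:
        raise ValidationError("need at least 3 nonzero quencher concentrations")
    intensities = series.intensities_at(emission_nm)
    if np.any(intensities <= 0):
        raise ValidationError("non-positive fluorescence intensity")
    f0 = intensities[0]
    q = concs[1:]
    f = intensities[1:]
    usable = f < f0
    if not np.all(usable):
        warnings.warn(
            f"{np.count_nonzero(~usable)} point(s) with F >= F0 excluded "
            "from the double-log fit",
            stacklevel=2,
        )
    q, f = q[usable], f[usable]
    if q.size < 3:
        raise ValidationError("fewer than 3 usable points after exclusion")
    fit = stats.linregress(np.log10(q), np.log10((f0 - f) / f))
    return BindingFit(
        K_a_M=float(10.0**fit.intercept),
        geom_error_factor=float(10.0**fit.intercept_stderr),
        n_sites=float(fit.slope),
        n_se=float(fit.stderr),
        r_squared=float(fit.rvalue**2),
        temperature_K=series.temperature_K,
        n_points=int(q.size),
        competitor=series.competitor.name if series.competitor else None,
    )


def displacement_analysis(
    fit_without: BindingFit,
    fit_with: BindingFit,
    threshold: float = 1.5,
) -> DisplacementResult:
    """Compare binding constants with and without a site probe.

    ``fold_change = K_a(without) / K_a(with)``: above the threshold the
    probe displaces the ligand (competitive, shared pocket); below the
    reciprocal threshold binding is enhanced (cooperative).
    """
    if fit_without.temperature_K != fit_with.temperature_K:
        raise ValidationError(
            "displacement requires fits at the same temperature "
            f"({fit_without.temperature_K} K vs {fit_with.temperature_K} K)"
        )
    if threshold <= 1:
        raise ValidationError("threshold must exceed 1")
    fold = fit_without.K_a_M / fit_with.K_a_M
    if fold > threshold:
        mode = DisplacementMode.COMPETITIVE
    elif fold < 1.0 / threshold:
        mode = DisplacementMode.COOPERATIVE
    else:
        mode = DisplacementMode.NEUTRAL
    return DisplacementResult(
        K_a_without_M=fit_without.K_a_M,
        K_a_with_M=fit_with.K_a_M,
        fold_change=float(fold),
        mode=mode,
        competitor=fit_with.competitor,
    )
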