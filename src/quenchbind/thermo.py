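"""Van't Hoff thermodynamics and binding-force classification.

Regressing ln K_a against 1/T gives ΔH = −R·slope and ΔS = R·intercept
(R = 8.314 J mol⁻¹ K⁻¹); the Gibbs energy then follows from
ΔG(T) = ΔH − TΔS.  The sign pattern of (ΔH, ΔS) identifies the dominant
intermolecular force of complex formation:

====  ====  =======================================
ΔH    ΔS    dominant force
====  ====  =======================================
 +     +    hydrophobic interaction
 −     +    electrostatic / ionic interaction
 −     −    hydrogen bonding + van der Waals
 +     −    none (reaction non-spontaneous)
====  ====  =======================================

Units follow the field convention: ΔH and ΔG in kJ mol⁻¹, ΔS in
J mol⁻¹ K⁻¹.  ΔG is primarily computed from the regressed (ΔH, ΔS);
−RT ln K_a is reported alongside as a consistency diagnostic (the two
coincide only when the K_a lie exactly on the van't Hoff line).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import math

import numpy as np
from scipy import stats

from .spectra import ValidationError

__all__ = [
    "R_GAS",
    "ForceLabel",
    "ThermoResult",
    "vant_hoff",
    "gibbs",
    "gibbs_from_ka",
    "classify_forces",
]

R_GAS = 8.314  # J mol^-1 K^-1


class ForceLabel(str, Enum):
    HYDROPHOBIC = "hydrophobic"
    ELECTROSTATIC_IONIC = "electrostatic_ionic"
    HBOND_VDW = "hbond_vdw"
    NONSPONTANEOUS = "nonspontaneous"


@dataclass(frozen=True)
class ThermoResult:
    dH_kJ_mol: float
    dS_J_mol_K: float
    dG_kJ_mol_by_T: Mapping[float, float]
    dG_from_ka_kJ_mol_by_T: Mapping[float, float]
    r_squared: float
    force_label: ForceLabel
    spontaneous_by_T: Mapping[float, bool]
    minimal_design: bool  # exactly 2 temperatures: the line is exact by construction


def gibbs(dH_kJ_mol: float, dS_J_mol_K: float, T_K: float) -> float:
    """ΔG = ΔH − TΔS with ΔH in kJ/mol and ΔS in J/mol/K."""
    if T_K <= 0:
        raise ValidationError("temperature must be positive")
    return dH_kJ_mol - T_K * dS_J_mol_K * 1e-3


def gibbs_from_ka(K_a_M: float, T_K: float, R: float = R_GAS) -> float:
    """ΔG = −RT ln K_a, in kJ/mol."""
    if K_a_M <= 0 or T_K <= 0:
        raise ValidationError("K_a and temperature must be positive")
    return -R * T_K * math.log(K_a_M) / 1000.0


def classify_forces(dH_kJ_mol: float, dS_J_mol_K: float) -> ForceLabel:
    """Dominant-force call from the signs of ΔH and ΔS.

    A zero member inherits the sign of the non-zero one; both zero is a
    degenerate input classified as hydrogen-bond/van-der-Waals with a
    warning.
    """
    h, s = dH_kJ_mol, dS_J_mol_K
    if h == 0 and s == 0:
        warnings.warn("dH and dS both zero: force classification is degenerate")
        return ForceLabel.HBOND_VDW
    if h == 0:
        h = s
    if s == 0:
        s = h
    if h > 0 and s > 0:
        return ForceLabel.HYDROPHOBIC
    if h < 0 and s > 0:
        return ForceLabel.ELECTROSTATIC_IONIC
    if h < 0 and s < 0:
        return ForceLabel.HBOND_VDW
    return ForceLabel.NONSPONTANEOUS


def vant_hoff(
    ka_by_temp: Mapping[float, float],
    R: float = R_GAS,
    dG_temps: Optional[Sequence[float]] = None,
) -> ThermoResult:
    """Van't Hoff regression of ln K_a on 1/T.

    Parameters
    ----------
    ka_by_temp
        Binding constant (M⁻¹) per temperature (K); >= 2 distinct
        temperatures, all K_a > 0.
    R
        Gas constant, J mol⁻¹ K⁻¹.
    dG_temps
        Temperatures at which to evaluate ΔG; defaults to the input ones.
    """
    temps = np.array(sorted(ka_by_temp), dtype=float)
    if temps.size < 2:
        raise ValidationError("need K_a at >= 2 temperatures")
    if np.unique(temps).size != temps.size:
        raise ValidationError("duplicate temperatures")
    if np.any(temps <= 0):
        raise ValidationError("temperatures must be positive")
    kas = np.array([ka_by_temp[t] for t in temps], dtype=float)
    if np.any(kas <= 0):
        raise ValidationError("all K_a must be positive")
    fit = stats.linregress(1.0 / temps, np.log(kas))
    dH = -R * fit.slope / 1000.0  # kJ/mol
    dS = R * fit.intercept  # J/mol/K
    if dG_temps is None:
        dG_temps = temps
    dG = {float(t): gibbs(dH, dS, float(t)) for t in dG_temps}
    dG_ka = {
        float(t): gibbs_from_ka(float(ka_by_temp[t]), float(t), R)
        for t in temps
        if t in ka_by_temp
    }
    return ThermoResult(
        dH_kJ_mol=float(dH),
        dS_J_mol_K=float(dS),
        dG_kJ_mol_by_T=dG,
        dG_from_ka_kJ_mol_by_T=dG_ka,
        r_squared=float(fit.rvalue**2) if temps.size > 2 else 1.0,
        force_label=classify_forces(dH, dS),
        spontaneous_by_T={t: g < 0 for t, g in dG.items()},
        minimal_design=bool(temps.size == 2),
    )
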