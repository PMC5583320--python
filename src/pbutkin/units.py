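"""Unit conventions and conversions.

Internal convention throughout the package:

* concentrations of toxin, albumin and complex are molar (M = mol/L);
  mg/L appears only at I/O boundaries,
* flow rates are mL/min at the API surface and converted to L/min where
  they multiply molar concentrations,
* volumes are L, lengths are m.
"""

from __future__ import annotations

ML_PER_L = 1000.0
M3_PER_L = 1e-3
MIN_PER_H = 60.0


class InvalidParameterError(ValueError):
    """A physically inadmissible parameter value was supplied."""


def mass_to_molar(c_mg_per_l: float, molecular_weight: float) -> float:
    """Convert a mass concentration (mg/L) to molar concentration (M).

    Parameters
    ----------
    c_mg_per_l : mass concentration in mg/L (>= 0).
    molecular_weight : molar mass in g/mol (> 0).
    """
    if molecular_weight <= 0:
        raise InvalidParameterError(
            f"molecular weight must be positive, got {molecular_weight}"
        )
    if c_mg_per_l < 0:
        raise InvalidParameterError(f"concentration must be >= 0, got {c_mg_per_l}")
    return c_mg_per_l / (ML_PER_L * molecular_weight)


def molar_to_mass(c_molar: float, molecular_weight: float) -> float:
    """Convert a molar concentration (M) to mass concentration (mg/L)."""
    if molecular_weight <= 0:
        raise InvalidParameterError(
            f"molecular weight must be positive, got {molecular_weight}"
        )
    return c_molar * ML_PER_L * molecular_weight


def generation_to_molar_rate(g_mg_per_min: float, molecular_weight: float) -> float:
    """Convert a generation rate (mg/min) to a molar rate (mol/min)."""
    return mass_to_molar(g_mg_per_min, molecular_weight)


def plasma_flow_from_blood(q_blood: float, hematocrit: float) -> float:
    """Plasma flow rate from blood flow rate, Qp = Qb * (1 - Hct).

    Blood cells carry no dialyzable plasma water here; only the plasma
    fraction of the blood flow reaches the fiber lumen model.

    Parameters
    ----------
    q_blood : blood flow rate, mL/min.
    hematocrit : fraction of blood volume occupied by cells, in [0, 1).
    """
    if not 0.0 <= hematocrit < 1.0:
        raise InvalidParameterError(f"hematocrit must be in [0, 1), got {hematocrit}")
    if q_blood < 0:
        raise InvalidParameterError(f"blood flow must be >= 0, got {q_blood}")
    return q_blood * (1.0 - hematocrit)
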