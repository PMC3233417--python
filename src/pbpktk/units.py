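"""Unit conversions used at the model boundary.

Internally the toolkit works in a single unit system: hours, mg, litres,
mg/L.  Everything else (ppm in air, ng/mL in blood, ug/g creatinine in
urine) is converted at input or reporting time by the helpers here.
"""

from __future__ import annotations

from .errors import ParameterError

#: Molar volume of an ideal gas at 25 degC, 1 atm (L/mol). Conventional in
#: inhalation toxicology for ppm <-> mg/m3 conversion; overridable where a
#: different reference temperature is required.
MOLAR_VOLUME_L_PER_MOL = 24.45

MG_PER_L_TO_NG_PER_ML = 1000.0  # 1 mg/L == 1000 ng/mL


def ppm_to_mg_per_L(ppm: float, molecular_weight: float,
                    molar_volume: float = MOLAR_VOLUME_L_PER_MOL) -> float:
    """Convert a gas-phase concentration in ppm (v/v) to mg per litre of air.

    mg/L = ppm * MW / (1000 * molar volume); with the 24.45 L/mol default
    this is the familiar ppm * MW / 24450.
    """
    if molecular_weight <= 0:
        raise ParameterError(f"molecular weight must be positive, got {molecular_weight}")
    if ppm < 0:
        raise ParameterError(f"ppm must be non-negative, got {ppm}")
    return ppm * molecular_weight / (1000.0 * molar_volume)


def mg_per_L_to_ppm(mg_per_L: float, molecular_weight: float,
                    molar_volume: float = MOLAR_VOLUME_L_PER_MOL) -> float:
    """Inverse of :func:`ppm_to_mg_per_L`."""
    if molecular_weight <= 0:
        raise ParameterError(f"molecular weight must be positive, got {molecular_weight}")
    return mg_per_L * 1000.0 * molar_volume / molecular_weight


def mg_per_L_to_ng_per_mL(mg_per_L):
    return mg_per_L * MG_PER_L_TO_NG_PER_ML


def ng_per_mL_to_mg_per_L(ng_per_mL):
    return ng_per_mL / MG_PER_L_TO_NG_PER_ML
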