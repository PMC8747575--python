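"""Hildebrand solubility parameters from heats of vaporization.

For a low-molecular-weight liquid the cohesive energy is approximated by

    Ecoh = ΔHvap - R·T        [J/mol]

and the Hildebrand solubility parameter is the square root of the cohesive
energy density,

    δ = sqrt(Ecoh / Vm)       [MPa^1/2],

with the molar volume Vm in cm^3/mol (J/cm^3 = MPa). Two substances whose
δ values differ by more than 2 MPa^1/2 are deemed immiscible; the boundary
case |Δδ| = 2 is classified miscible by convention here.

Small molecules standing in for a polymer's repeating element (RE)
systematically overestimate the polymer's own δ; a linear calibration maps
the RE value onto the polymer scale. The packaged calibration is
δ_polymer = 0.602·δ_RE + 5.915 (fit against curated polymer-database
values, R^2 = 0.855, n = 16); :func:`fit_calibration` refits it from user
pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: CODATA gas constant, J mol^-1 K^-1
R_GAS = 8.314462618

#: default temperature for the Ecoh approximation, K
DEFAULT_TEMPERATURE = 298.15

#: empirical miscibility window half-width, MPa^1/2
MISCIBILITY_THRESHOLD = 2.0


class SolubilityError(ValueError):
    pass


def cohesive_energy(dhvap_kjmol: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Cohesive energy in J/mol from ΔHvap in kJ/mol at temperature T in K."""
    if temperature < 0:
        raise SolubilityError(f"temperature must be >= 0 K, got {temperature}")
    ecoh = dhvap_kjmol * 1000.0 - R_GAS * temperature
    if ecoh <= 0:
        raise SolubilityError(
            f"non-positive cohesive energy ({ecoh:.1f} J/mol); "
            "the solubility parameter is undefined"
        )
    return ecoh


def hildebrand_delta(ecoh_jmol: float, vm_cm3mol: float) -> float:
    """δ in MPa^1/2 from Ecoh in J/mol and molar volume in cm^3/mol."""
    if ecoh_jmol <= 0:
        raise SolubilityError(f"cohesive energy must be > 0, got {ecoh_jmol}")
    if vm_cm3mol <= 0:
        raise SolubilityError(f"molar volume must be > 0, got {vm_cm3mol}")
    return math.sqrt(ecoh_jmol / vm_cm3mol)


@dataclass(frozen=True)
class SolubilityRecord:
    """One substance's full ΔHvap → δ chain with its unit conventions."""

    name: str
    dhvap_kjmol: float
    temperature_k: float
    ecoh_jmol: float
    vm_cm3mol: float
    delta_mpa_sqrt: float

    @classmethod
    def from_dhvap(
        cls,
        name: str,
        dhvap_kjmol: float,
        vm_cm3mol: float,
        temperature_k: float = DEFAULT_TEMPERATURE,
    ) -> "SolubilityRecord":
        ecoh = cohesive_energy(dhvap_kjmol, temperature_k)
        return cls(
            name=name,
            dhvap_kjmol=float(dhvap_kjmol),
            temperature_k=float(temperature_k),
            ecoh_jmol=ecoh,
            vm_cm3mol=float(vm_cm3mol),
            delta_mpa_sqrt=hildebrand_delta(ecoh, vm_cm3mol),
        )


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from an RE solubility parameter to the polymer scale."""

    slope: float
    intercept: float  # MPa^1/2
    r2: float | None = None
    n: int | None = None

    def __call__(self, delta_re: float) -> float:
        return self.slope * delta_re + self.intercept


#: packaged RE → polymer calibration (slope dimensionless, intercept MPa^1/2)
PUBLISHED_CALIBRATION = CalibrationModel(slope=0.602, intercept=5.915, r2=0.855, n=16)

#: identity calibration: report the RE value unchanged
IDENTITY_CALIBRATION = CalibrationModel(slope=1.0, intercept=0.0)


def polymer_sp_from_re(
    delta_re: float, model: CalibrationModel = PUBLISHED_CALIBRATION
) -> float:
    """Polymer δ from the repeating-element δ via a linear calibration."""
    if not math.isfinite(delta_re):
        raise SolubilityError(f"non-finite RE solubility parameter: {delta_re}")
    return model(delta_re)


def fit_calibration(pairs) -> CalibrationModel:
    """Least-squares (δ_RE, δ_polymer) calibration; needs >= 3 pairs."""
    pairs = list(pairs)
    if len(pairs) < 3:
        raise SolubilityError(f"need at least 3 calibration pairs, got {len(pairs)}")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise SolubilityError("degenerate calibration input: all RE values equal")
    fit = stats.linregress(x, y)
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n=len(pairs),
    )


def miscibility(delta_1: float, delta_2: float, threshold: float = MISCIBILITY_THRESHOLD) -> str:
    """Miscibility call from the δ difference: immiscible iff |Δδ| > threshold."""
    if not (math.isfinite(delta_1) and math.isfinite(delta_2)):
        raise SolubilityError("miscibility needs finite solubility parameters")
    return "immiscible" if abs(delta_1 - delta_2) > threshold else "miscible"
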