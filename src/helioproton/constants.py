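"""Physical constants and packaged reference values.

All energies are kcal/mol, charges in elementary charges (e), lengths in
Angstrom, temperatures in Kelvin, unless a function says otherwise.
"""

from __future__ import annotations

import math

#: Gas constant, kcal/(mol K).  Plays the role of k_B for molar energies.
KB_KCAL: float = 1.987204258640832e-3

#: Default temperature (K) for all electrostatic and titration computations.
T_DEFAULT: float = 300.0

#: Coulomb constant in kcal*A/(mol*e^2): E = COULOMB_KCAL * q1*q2 / (eps*r).
COULOMB_KCAL: float = 332.06

#: Relative permittivity of the protein interior / bulk water.
EPS_PROTEIN: float = 4.0
EPS_WATER: float = 80.0

#: Default ionic strength, mol/L.
IONIC_STRENGTH_M: float = 0.1

#: Planck*c in eV*nm, for E (eV) <-> lambda (nm) conversion.
HC_EV_NM: float = 1239.84193

#: Avogadro's number scaled to particles per A^3 per mol/L.
_MOLAR_TO_PER_A3: float = 6.02214076e-4 * 1e-3 * 1e3  # 6.02214076e23 / 1e27


def kT(temperature: float = T_DEFAULT) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB_KCAL * temperature


def kT_ln10(temperature: float = T_DEFAULT) -> float:
    """k_B*T*ln(10) in kcal/mol — the energy of one pK unit (1.3726 at 300 K)."""
    return kT(temperature) * math.log(10.0)


def debye_kappa2(
    ionic_strength: float = IONIC_STRENGTH_M,
    eps: float = EPS_WATER,
    temperature: float = T_DEFAULT,
) -> float:
    """Squared inverse Debye length kappa^2 in A^-2 for a 1:1 electrolyte.

    Defined so that in a uniform solvent the linearized Poisson-Boltzmann
    equation reads  lap(phi) - kappa^2 phi = -4*pi*C*rho/eps  and a point
    charge gives the screened Coulomb (Yukawa) potential
    C*q*exp(-kappa*r)/(eps*r).
    """
    n = ionic_strength * _MOLAR_TO_PER_A3  # ion pairs per A^3
    return 8.0 * math.pi * COULOMB_KCAL * n / (eps * kT(temperature))


#: Experimental reference pKa values of the titratable model compounds.
REFERENCE_PKA: dict[str, float] = {
    "ARG": 12.0,
    "ASP": 4.0,
    "CYS": 9.5,
    "GLU": 4.4,
    "LYS": 10.4,
    "TYR": 9.6,
    "HIS_NE": 7.0,
    "HIS_ND": 6.6,
}

#: Which reference compounds titrate as acids (neutral protonated) vs bases.
SITE_KIND: dict[str, str] = {
    "ARG": "base",
    "ASP": "acid",
    "CYS": "acid",
    "GLU": "acid",
    "LYS": "base",
    "TYR": "acid",
    "HIS_NE": "base",
    "HIS_ND": "base",
}

#: Linear calibration from TD-DFT excitation energy to absorption energy (eV),
#: fitted across 13 microbial rhodopsins: E_abs = slope*E_td + intercept.
CALIBRATION_SLOPE: float = 1.754
CALIBRATION_INTERCEPT: float = -2.073

#: Absorption wavelength of heliorhodopsin 48C12 (nm): measured, and predicted
#: by the calibrated QM/MM computation.
LAMBDA_EXPERIMENT_NM: float = 551.0
LAMBDA_COMPUTED_NM: float = 557.0

#: Published serine side-chain contributions to the absorption wavelength (nm),
#: keyed by (residue, conformation tag).  Negative means the residue's charges
#: blue-shift the chromophore.  These come from charge-deletion TD-DFT runs and
#: are shipped as read-only reference data.
SERINE_CONTRIBUTIONS_NM: dict[tuple[str, str], float] = {
    ("Ser76", "pre-PT_SB>E107"): -9.0,
    ("Ser76", "post-PT_SB>E107"): 4.0,
    ("Ser111", "pre-PT_SB>E107"): -5.0,
    ("Ser237", "pre-PT_SB>E107"): -12.0,
}
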