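"""Absorption-wavelength calibration and residue-contribution bookkeeping.

Microbial-rhodopsin TD-DFT excitation energies correlate linearly with the
measured absorption energies; the calibration fitted across 13 rhodopsins,

    E_abs (eV) = 1.754 * E_TD-DFT - 2.073,

maps a computed excitation energy to a predicted absorption energy and
wavelength (lambda = hc / E_abs).  Residue contributions follow the
charge-deletion convention: delta_lambda = lambda(with the side-chain
charges) - lambda(without them), so a negative value means the residue
blue-shifts the chromophore and its mutation to alanine is predicted to
red-shift by the same amount.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .constants import (
    CALIBRATION_INTERCEPT,
    CALIBRATION_SLOPE,
    HC_EV_NM,
    LAMBDA_COMPUTED_NM,
    LAMBDA_EXPERIMENT_NM,
    SERINE_CONTRIBUTIONS_NM,
)

__all__ = [
    "AbsorptionPrediction",
    "calibrate",
    "invert_calibration",
    "energy_to_wavelength",
    "wavelength_to_energy",
    "contribution",
    "serine_reference_table",
]


@dataclass(frozen=True)
class AbsorptionPrediction:
    """Calibrated absorption prediction for one excitation energy."""

    E_excitation: float  # eV, TD-DFT input
    E_abs: float  # eV, after calibration
    wavelength: float  # nm


def energy_to_wavelength(e_ev: float) -> float:
    """lambda (nm) = hc / E (eV); requires a positive energy."""
    if e_ev <= 0:
        raise ValueError(f"photon energy must be positive, got {e_ev} eV")
    return HC_EV_NM / e_ev


def wavelength_to_energy(lam_nm: float) -> float:
    if lam_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {lam_nm} nm")
    return HC_EV_NM / lam_nm


def calibrate(E_td: float) -> AbsorptionPrediction:
    """Apply the 13-rhodopsin linear calibration and convert to nm."""
    e_abs = CALIBRATION_SLOPE * E_td + CALIBRATION_INTERCEPT
    if e_abs <= 0:
        raise ValueError(
            f"calibrated absorption energy {e_abs:.3f} eV is non-positive; "
            f"E_TD-DFT = {E_td} eV lies outside the calibration's validity"
        )
    return AbsorptionPrediction(
        E_excitation=float(E_td), E_abs=float(e_abs),
        wavelength=energy_to_wavelength(e_abs),
    )


def invert_calibration(lam_nm: float) -> float:
    """The excitation energy whose calibrated wavelength equals ``lam_nm``."""
    return (wavelength_to_energy(lam_nm) - CALIBRATION_INTERCEPT) / CALIBRATION_SLOPE


@dataclass(frozen=True)
class ContributionRow:
    """One residue's wavelength contribution (charge-deletion convention)."""

    residue: str
    delta_lambda: float  # nm; negative = residue decreases the wavelength
    conformation: str = ""

    @property
    def predicted_mutation_shift(self) -> float:
        """Predicted wavelength change upon removing the residue (e.g. Ser->Ala)."""
        return -self.delta_lambda


def contribution(
    lambda_with: float, lambda_without: float, residue: str, conformation: str = ""
) -> ContributionRow:
    """delta_lambda = lambda(with charges) - lambda(without charges), nm."""
    if lambda_with <= 0 or lambda_without <= 0:
        raise ValueError("wavelengths must be positive")
    return ContributionRow(
        residue=residue,
        delta_lambda=float(lambda_with - lambda_without),
        conformation=conformation,
    )


def serine_reference_table() -> pd.DataFrame:
    """The packaged serine contributions (nm) with conformation tags.

    These stem from charge-deletion TD-DFT runs on the chromophore and are
    shipped as read-only reference values together with the measured
    (551 nm) and computed (557 nm) absorption wavelengths.
    """
    rows = [
        {"residue": res, "conformation": conf, "delta_lambda_nm": val,
         "predicted_mutation_shift_nm": -val}
        for (res, conf), val in SERINE_CONTRIBUTIONS_NM.items()
    ]
    df = pd.DataFrame(rows)
    df.attrs["lambda_experiment_nm"] = LAMBDA_EXPERIMENT_NM
    df.attrs["lambda_computed_nm"] = LAMBDA_COMPUTED_NM
    return df
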