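#!/usr/bin/env python
"""Absorption-wavelength calibration and serine contributions.

Applies the 13-rhodopsin linear calibration to a range of excitation
energies, locates the excitation energy consistent with the 557 nm
computed absorption of heliorhodopsin 48C12 (experiment: 551 nm), and
tabulates the packaged serine side-chain contributions with their
predicted Ser->Ala mutation shifts.

Writes results/calibration_curve.csv and results/serine_contributions.csv.
"""

import pathlib

import numpy as np
import pandas as pd

from helioproton.constants import LAMBDA_COMPUTED_NM, LAMBDA_EXPERIMENT_NM
from helioproton.spectra import calibrate, invert_calibration, serine_reference_table

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    e_grid = np.linspace(2.3, 3.0, 36)
    preds = [calibrate(float(e)) for e in e_grid]
    curve = pd.DataFrame({
        "E_excitation_eV": e_grid,
        "E_abs_eV": [p.E_abs for p in preds],
        "lambda_nm": [p.wavelength for p in preds],
    })
    curve.to_csv(RESULTS / "calibration_curve.csv", index=False)

    e_557 = invert_calibration(LAMBDA_COMPUTED_NM)
    p = calibrate(e_557)
    print("Calibration E_abs = 1.754 E_exc - 2.073 (fit over 13 rhodopsins):")
    print(f"  lambda range {curve.lambda_nm.min():.0f}-{curve.lambda_nm.max():.0f} nm "
          f"for E_exc in [{e_grid[0]:.2f}, {e_grid[-1]:.2f}] eV")
    print(f"  E_exc = {e_557:.4f} eV maps to lambda = {p.wavelength:.1f} nm, the "
          f"computed absorption of heliorhodopsin 48C12 "
          f"(measured: {LAMBDA_EXPERIMENT_NM:.0f} nm, "
          f"{LAMBDA_COMPUTED_NM - LAMBDA_EXPERIMENT_NM:+.0f} nm deviation)")

    table = serine_reference_table()
    table.to_csv(RESULTS / "serine_contributions.csv", index=False)
    print("\nSerine contributions to the absorption wavelength "
          "(charge-deletion convention; negative = blue shift):")
    print(table.to_string(index=False))
    print("\nA residue that blue-shifts the chromophore predicts a red shift "
          "of the same size upon its mutation to alanine.")


if __name__ == "__main__":
    main()
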