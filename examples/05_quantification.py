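"""Absolute quantification from standard curves.

Fits the MRM calibration lines for 6mA and dA, quantifies a sample's
6mA/dA ratio in ppm, then inverts a qPCR standard curve to transcript
copies per cell (total copies divided by the 500,000 cells extracted).
"""

from sixma.calibration import copies_per_cell, fit_calibration, quantify_ratio_ppm
from sixma.synthio import CalibConfig, simulate_calibration

sim = simulate_calibration(CalibConfig(seed=1))

c6 = fit_calibration(sim.ms_standards_6ma["amount"], sim.ms_standards_6ma["response"],
                     analyte="6mA (266->150)")
cd = fit_calibration(sim.ms_standards_da["amount"], sim.ms_standards_da["response"],
                     analyte="dA (252->136)")
print(f"6mA curve: slope {c6.slope:.1f}, R2 {c6.r2:.5f}; "
      f"dA curve: slope {cd.slope:.4f}, R2 {cd.r2:.5f}")
ratio = quantify_ratio_ppm(sim.sample_area_6ma, sim.sample_area_da, c6, cd)
print(f"sample 6mA/dA ratio: {ratio.ppm:.3f} ppm (planted truth "
      f"{sim.truth['ratio_ppm']} ppm, 1% area noise)")

curve = fit_calibration(sim.qpcr_standards["log10_copies"], sim.qpcr_standards["ct"])
cpc = copies_per_cell(sim.sample_ct, curve, n_cells=sim.truth["n_cells"])
print(f"qPCR curve: slope {curve.slope:.4f} cycles/decade (ideal -3.3219); "
      f"sample: {cpc:.1f} copies/cell (planted truth {sim.truth['copies_per_cell']})")
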