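"""Absolute quantitation and two-group comparison.

Fits a weighted (1/x^2) calibration line on a synthetic spiked-standard
series with constant-CV noise, back-calculates an unknown, and compares
two small groups with the exact Mann-Whitney test.
"""

import numpy as np

from polysirm import compare_groups, fit_calibration

rng = np.random.default_rng(4)

# calibration standards (nM) with ~6% multiplicative area noise
conc = np.array([10, 25, 50, 100, 250, 500, 1000], dtype=float)
ratio = 0.004 * conc * np.exp(rng.normal(0, 0.06, conc.size))
curve = fit_calibration(conc, ratio, weighting="1/x2")
print(f"calibration: ratio = {curve.slope:.5f} * conc + {curve.intercept:.5f}")

unknown_ratio = 0.004 * 180 * np.exp(rng.normal(0, 0.06))
print(f"unknown back-calculated: {curve.back_calculate(unknown_ratio):.0f} nM "
      "(true 180 nM)")

# unpaired two-group comparison, exact Mann-Whitney for small n
ibd = [8.1, 12.3, 9.7, 15.2, 11.0, 13.8]
ctrl = [5.2, 6.9, 4.8, 7.5, 6.1, 5.9]
res = compare_groups(ibd, ctrl, test="mann_whitney", group_a="IBD", group_b="control")
print(f"\nMann-Whitney U = {res.statistic:.0f}, exact p = {res.p_value:.4f} "
      f"({res.stars})")
print("Exact enumeration over all group relabelings; p < 0.05 flags a"
      "\nsignificant difference in metabolite level between the groups.")
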