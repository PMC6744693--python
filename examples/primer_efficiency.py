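"""Primer efficiency from a dilution-series standard curve.

Builds a five-fold dilution series with a known amplification factor,
fits Cq against log10 concentration, and reports slope, r^2 and the
efficiency E = 10^(-1/slope).  QC passes when r^2 > 0.97 and E lies in
[1.9, 2.0] (within 5% of perfect doubling).
"""

import numpy as np

from normgene import primer_efficiency_from_slope, standard_curve

# ideal doubling: one cycle per 2-fold dilution -> slope = -1/log10(2)
slope = -1.0 / np.log10(2.0)
log_conc = -np.log10(5.0) * np.arange(5)  # five-fold dilution steps
cq = 22.0 + slope * log_conc

curve = standard_curve(zip(log_conc, cq))
print(f"slope      = {curve['slope']:.4f}")
print(f"r^2        = {curve['r_squared']:.4f}")
print(f"E          = {curve['E']:.4f}")
print(f"efficiency = {curve['efficiency_percent']:.2f}%")
print(f"qc_pass    = {curve['qc_pass']}")

# the closed form alone, for a slope read off an instrument report
e_factor, pct = primer_efficiency_from_slope(-3.5)
print(f"\nslope -3.5 -> E = {e_factor:.4f}, efficiency = {pct:.2f}% "
      "(sub-optimal primer)")
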