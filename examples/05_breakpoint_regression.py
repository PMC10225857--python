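"""Two-segment breakpoint regression on a log total-abundance series.

Builds a series that declines ~1.3%/yr then stabilizes after 1992, and
recovers the breakpoint and segment slopes.
"""

import numpy as np

import avitrend as av

rng = np.random.default_rng(2)
years = np.arange(1966, 2019)
log_total = (
    5.3
    - 0.0128 * (years - 1992) * (years <= 1992)
    + 0.0027 * (years - 1992) * (years > 1992)
    + rng.normal(0, 0.005, len(years))
)

fit = av.fit_piecewise(years, log_total)
print(f"breakpoint: {fit.breakpoint_year}")
print(f"slope before: {fit.slope1:.2f} %/yr (CI {fit.slope1_ci[0]:.2f}, {fit.slope1_ci[1]:.2f})")
print(f"slope after:  {fit.slope2:.2f} %/yr (CI {fit.slope2_ci[0]:.2f}, {fit.slope2_ci[1]:.2f})")
print(f"R2 = {fit.r2:.3f}")
# Slopes are 100 x the per-year change in the natural-log total, i.e.
# approximately percent per annum; the fit is continuous at the breakpoint.
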