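"""Climate suitability trends (CST) from an SDM or a suitability series.

Fits a logistic species-distribution model to synthetic occurrence data,
predicts annual suitability under a warming climate, and extracts the CST:
the slope of logit(suitability) against year.
"""

import numpy as np

import avitrend as av
from avitrend.cst import predict_annual_suitability

rng = np.random.default_rng(3)

# Occurrence over 2000 grid cells driven by two climate covariates with a
# humped (quadratic) response: suitability peaks at intermediate climates.
n_cells = 2000
climate = rng.normal(0, 1, (n_cells, 2))
eta = 0.4 + 0.9 * climate[:, 0] - 0.5 * climate[:, 0] ** 2 - 0.4 * climate[:, 1] ** 2
occurrence = (rng.random(n_cells) < 1 / (1 + np.exp(-eta))).astype(float)

sdm = av.fit_sdm(occurrence, climate)
print("SDM coefficients:", np.round(sdm.coef, 2))

# Annual climate: cells warm steadily by 0.02 sd/yr on the first covariate.
annual = {
    year: climate + np.array([0.02 * (year - 2000), 0.0])
    for year in range(2000, 2020)
}
suit = predict_annual_suitability(sdm, annual, "demo-species")
print("mean suitability 2000 vs 2019:",
      round(suit.suitability[0], 3), "->", round(suit.suitability[-1], 3))

cst = av.cst_slope(suit)
print(f"CST = {cst.slope:+.4f} logit units/yr (se {cst.se:.4f}, r2 {cst.r2:.2f})")
# A positive CST means modelled climatic conditions across the range are
# improving for this species; negative means deteriorating.
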