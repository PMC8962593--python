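"""Batch-fermentation kinetics from a bioreactor time series.

A synthetic batch run: exponential growth to stationary phase with
growth-coupled product formation.  Over the exponential window the growth
rate, product yield on biomass and specific production rate are computed.
"""

import numpy as np

from pathwayopt.fermentation import (
    FermentationSeries,
    compute_yield_and_qp,
    suggest_window,
)

rng = np.random.default_rng(3)
t = np.linspace(0, 26, 14)
mu_true, yield_true = 0.33, 62.9  # 1/h, mg product per g biomass
cdw = np.where(t <= 12, 0.09 * np.exp(mu_true * t), 0.09 * np.exp(mu_true * 12))
cdw = cdw * (1 + 0.02 * rng.standard_normal(len(t)))
product = yield_true * (cdw - cdw[0])

series = FermentationSeries(time=t, od600=cdw / 0.29, naringenin=product)
window = suggest_window(series, min_points=5)
print(f"suggested exponential window: {window[0]:.1f}-{window[1]:.1f} h")

params = compute_yield_and_qp(series, window)
print(f"mu   = {params.mu:.2f} 1/h   (log-linear R2 = {params.mu_r2:.3f})")
print(f"Y_PX = {params.y_px:.1f} mg/g CDW")
print(f"q_p  = {params.q_p:.1f} mg/g CDW/h  (= mu x Y_PX)")
# q_p is the rate a unit of biomass makes product while growing; it is the
# number to compare across strains and media.
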