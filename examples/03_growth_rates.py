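"""Exponential growth constants from OD600 plate-reader curves.

Generates two groups of synthetic wells (a control and a slower-growing
stressed strain), fits each curve by log-linear regression over the
automatically selected linear range, and compares the groups with Welch's
t-test.
"""

import numpy as np

from petite_dynamics import compare_rates, correlate_validation, fit_exponential_rate
from petite_dynamics import synthetic as syn

rng = np.random.default_rng(5)
control_true, stressed_true = 0.42, 0.21  # stress roughly halves the rate

groups = {}
for name, mu in (("control", control_true), ("stressed", stressed_true)):
    rates = []
    for i in range(8):
        true_rate = mu * (1 + 0.03 * rng.standard_normal())
        curve = syn.generate_growth_curve(rate=true_rate, noise_sd=0.002,
                                          seed=int(rng.integers(2**31)),
                                          curve_id=f"{name}_{i}")
        fit = fit_exponential_rate(curve)
        rates.append(fit.rate)
    groups[name] = rates
    print(f"{name}: mean fitted rate = {np.mean(rates):.3f} /h "
          f"(true mean {mu:.2f}), n = {len(rates)}")

t, p = compare_rates(groups["control"], groups["stressed"], tails=2)
print(f"\nWelch t = {t:.2f}, two-tailed p = {p:.2e}")
print("-> the stress-induced growth defect is detected at any usual alpha")

# validation-style correlation: fitted rates vs an independent score
score = 5.0 * (np.array(groups["control"] + groups["stressed"]) - 0.3)
score += rng.normal(0, 0.3, size=score.size)
r = correlate_validation(groups["control"] + groups["stressed"], score)
print(f"Pearson r between fitted rates and the noisy score = {r:.2f}")
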