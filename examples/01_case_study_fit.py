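"""Build a synthetic case study and fit the four candidate survival models.

Each arm of the increasing-hazard case study holds 200 patients followed for
12 months; survival times are deterministic mixture quantiles, so two runs
give identical data.  The table printed below shows, per arm and family, the
AIC of the maximum-likelihood fit, the AIC-based prior model probability,
and the 240-month restricted mean survival (the net benefit in life-months).
"""

import numpy as np

from survoi import build_case_dataset, fit_all_families, rmst

new, std = build_case_dataset("increasing")
print(f"arms: {new.arm_label} ({new.n_events} deaths, "
      f"{new.at_risk(12.0)} alive at 12 mo), "
      f"{std.arm_label} ({std.n_events} deaths, {std.at_risk(12.0)} alive)")

for arm in (new, std):
    ms = fit_all_families(arm)
    print(f"\n{arm.arm_label}")
    print(f"{'family':<12} {'AIC':>8} {'weight':>7} {'NB (life-months)':>17}")
    for fit, w in zip(ms.fits, ms.prior_weights):
        print(f"{fit.family:<12} {fit.aic:8.2f} {w:7.2f} "
              f"{rmst(fit.mle, 240.0):17.2f}")
    nb = ms.prior_weights @ np.array([rmst(f.mle, 240.0) for f in ms.fits])
    print(f"{'weighted avg':<12} {'':>8} {'':>7} {nb:17.2f}")

# A weight near 0.25 means the 12-month data barely separate the families,
# even though their 240-month extrapolations differ by a factor of two —
# that gap is what the model-averaged value-of-information analysis prices.
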