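"""Regression-based EVSI of extending follow-up by 12-48 months.

For each proposed extension, 6000 plausible follow-up datasets are simulated
for the patients still alive at month 12; each arm's simulated net benefit
is smoothed on (events, person-time) with a tensor-product spline, and the
EVSI is the expected gain from deciding after seeing the new data.  Runs in
seconds, versus hours for the nested Monte Carlo route.
"""

from survoi import build_case_dataset, fit_all_families, run_scenario

arms = build_case_dataset("increasing")
model_sets = [fit_all_families(a) for a in arms]
n_at_risk = [a.at_risk(12.0) for a in arms]

for label, models in (("single-model (Weibull)",
                       [ms["weibull"] for ms in model_sets]),
                      ("model-averaged", list(model_sets))):
    print(f"\n{label}")
    print(f"{'extension (mo)':>14} {'EVSI':>7} {'SE':>6}")
    estimates = run_scenario(models, n_at_risk, t1=12.0,
                             extensions=(12.0, 24.0, 36.0, 48.0),
                             horizon=240.0, k=6000, seed=42)
    for e in estimates:
        print(f"{e.extension:14.0f} {e.value:7.2f} {e.se:6.2f}")

# EVSI rises with the extension but with diminishing returns, approaching
# the EVPI ceiling; the model-averaged values are larger because longer
# follow-up also reveals which survival family extrapolates best.
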