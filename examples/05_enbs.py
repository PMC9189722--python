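"""Expected net benefit of sampling: how long should the trial continue?

Population EVSI (per-decision EVSI times the patients affected over a
10-year decision horizon, 5 new patients/month) is weighed against the cost
of continuing the trial (5 life-months per month).  Under approval-with-
research (AWR) patients receive the new treatment while data accumulate;
under only-in-research (OIR) approval is withheld, so the forgone benefit
of the better arm adds to the marginal cost and the optimum comes earlier.
"""

import numpy as np

from survoi import (ENBSConfig, build_case_dataset, enbs_curves,
                    evpi_from_models, fit_all_families, rmst, run_scenario)

arms = build_case_dataset("increasing")
model_sets = [fit_all_families(a) for a in arms]
n_at_risk = [a.at_risk(12.0) for a in arms]

estimates = run_scenario(list(model_sets), n_at_risk, 12.0,
                         (12.0, 24.0, 36.0, 48.0), 240.0, k=4000, seed=3)
evsi = [e.value for e in estimates]
nb = [float(ms.prior_weights @ np.array([rmst(f.mle, 240.0)
                                         for f in ms.fits]))
      for ms in model_sets]
evpi_ma = evpi_from_models(list(model_sets), 240.0, 100_000, 4)

cfg = ENBSConfig(trial_cost_rate=5.0, accrual=5.0, horizon_years=10.0)
curves = enbs_curves((12.0, 24.0, 36.0, 48.0), evsi, cfg,
                     incremental_nb=nb[0] - nb[1], evpi_value=evpi_ma)

print(f"model-averaged EVSI by extension: {np.round(evsi, 2)}")
print(f"optimal additional follow-up, AWR: {curves['optimum_awr']:.0f} months")
print(f"optimal additional follow-up, OIR: {curves['optimum_oir']:.0f} months")
# The AWR optimum is later than the OIR optimum: when patients already get
# the (apparently better) new treatment, waiting longer costs less.
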