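"""Parameter estimation on a synthetic concentration time series.

Generates a noise-free 6-point plasma series for indole-3-acetic acid
from known kinetic constants, then re-estimates those constants from a
deliberately wrong starting point.
"""

from dataclasses import replace

import pbutkin as pk
from pbutkin import presets
from pbutkin.calibration import (CalibrationProblem, estimate_parameters,
                                 generate_fixture)

config = replace(presets.DEFAULT_SESSION, n_x=16)
geometry = pk.dialyzer_preset("F180NR")
species = presets.calibrated_species("IAA")
truth = presets.calibrated_parameters("IAA")

fixture = generate_fixture(species, truth, presets.DEFAULT_ALBUMIN,
                           geometry, config, noise_sigma=0.0, seed=0)
print("sampled plasma totals (mg/L):",
      [round(c, 3) for c in fixture.c_total])

problem = CalibrationProblem(
    toxins={"IAA": fixture}, albumin=presets.DEFAULT_ALBUMIN,
    geometry=geometry, config=config,
    initial_guess={"IAA": dict(K_ip_T=700.0, K_ic_T=90.0, k1=4e3)})
fit = estimate_parameters(problem, n_starts=1, seed=0)

true_vals = presets.TOXIN_PRESETS["IAA"]
print(f"{'parameter':8s} {'true':>10s} {'estimated':>12s}")
for p in ("K_ip_T", "K_ic_T", "k1"):
    print(f"{p:8s} {true_vals[p]:10.3g} {fit.parameters['IAA'][p]:12.4g}")
print(f"residual relative error: {fit.relative_errors['IAA']:.2e}")
# With six well-placed samples and slow binding kinetics, all three
# constants are identifiable; for near-equilibrium binders (pCG, IS,
# pCS) the association rate k1 barely moves the plasma totals and the
# fit report's sensitivity column flags it.
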