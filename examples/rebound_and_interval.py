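"""Post-dialysis rebound and the inter-dialytic interval.

Runs an indoxyl sulfate session, lets the plasma concentration rebound
for two hours with the dialyzer disconnected, then simulates a 44-h
interval with 2 L of fluid intake to produce the next pre-dialysis
state.
"""

from dataclasses import replace

import pbutkin as pk
from pbutkin import presets
from pbutkin.units import molar_to_mass

toxin = "IS"
species = presets.calibrated_species(toxin)
params = presets.calibrated_parameters(toxin)
state0 = presets.calibrated_patient_state(toxin)
config = replace(presets.DEFAULT_SESSION, n_x=60)

session = pk.simulate_session(state0, params, species,
                              pk.dialyzer_preset("F180NR"), config)
rebound = pk.simulate_rebound(session.final_state, params, species,
                              duration=120.0)
next_pre = pk.simulate_interdialytic(rebound.final_state, params, species,
                                     interval=44.0 * 60.0 - 120.0,
                                     intake_volume=2.0)

mw = species.molecular_weight
c = lambda s: molar_to_mass(s.T_pl + s.PT_pl, mw)
print(f"{toxin} total plasma concentration (mg/L):")
print(f"  pre-dialysis            : {c(state0):.2f}")
print(f"  end of session          : {c(session.final_state):.2f}")
print(f"  after 120 min rebound   : {c(rebound.final_state):.2f}")
print(f"  next pre-dialysis (44 h): {c(next_pre):.2f}")
# The rebound reflects re-equilibration from the interstitial and
# intracellular pools; over the full interval, generation restores the
# concentration toward the previous pre-dialysis level.
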