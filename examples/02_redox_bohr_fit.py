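"""Fit the one-proton redox-Bohr model to a noisy E-pH campaign.

Simulates midpoint potentials of a strongly pH-dependent HiPIP
(pKa_ox 5.5, pKa_red 8.2) with 3 mV scatter over pH 4-10, fits the model,
and prints the recovered thermodynamic parameters.
"""

from photoferro import (RedoxScenario, bohr_amplitude, fit_redox_bohr,
                        gen_redox_dataset)

scenario = RedoxScenario.rpal4085_like(noise_sigma=3.0, seed=1)
data = gen_redox_dataset(scenario)[0]
fit = fit_redox_bohr(data)

truth = scenario.params
print(f"generating: E_alk={truth.e_alk:.1f} mV, "
      f"pKa_ox={truth.pka_ox}, pKa_red={truth.pka_red}")
print(f"fitted:     E_alk={fit.params.e_alk:.1f} mV, "
      f"pKa_ox={fit.params.pka_ox:.2f}, pKa_red={fit.params.pka_red:.2f}")
print(f"bound flags: {fit.bound_flags}")
print(f"Bohr amplitude: {bohr_amplitude(fit.params):.1f} mV "
      f"(truth {bohr_amplitude(truth):.1f} mV)")
print()
print("The Bohr amplitude (RT ln10/F x delta-pKa) is the total potential")
print("drop driven by the coupled protonation; ~160 mV here versus ~24 mV")
print("for a weakly coupled protein.")
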