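"""Quantify cytochrome oxidation from UV-vis spectra and check ET feasibility.

Unmixes a noisy series of two-state spectra (reduced Soret at 420 nm with
alpha/beta bands; oxidized Soret at 409 nm) into oxidized fractions, then
scans whether a redox-Bohr donor can reduce a ~430 mV acceptor across pH.
"""

from photoferro import (RedoxBohrParams, et_feasibility, gen_spectra_series,
                        oxidized_basis, reduced_basis, soret_peak, unmix)

red, ox = reduced_basis(), oxidized_basis()
print(f"Soret maxima: reduced {soret_peak(red):.1f} nm, "
      f"oxidized {soret_peak(ox):.1f} nm")

fractions = [0.0, 0.3, 0.7, 1.0]
spectra, truth = gen_spectra_series(fractions, noise_sigma=0.002, seed=1)
for f_true, spec in zip(truth["fractions"], spectra):
    res = unmix(spec, red, ox)
    print(f"planted f_ox={f_true:.2f}  recovered {res.fraction_oxidized:.3f}"
          f"  (Soret {res.soret_position:.1f} nm)")

print()
weak = RedoxBohrParams(330.0, 7.6, 8.0)    # small Bohr effect
strong = RedoxBohrParams(380.0, 5.5, 8.2)  # pronounced Bohr effect
for name, donor in (("weak-Bohr donor", weak), ("strong-Bohr donor", strong)):
    rep = et_feasibility(donor, acceptor_e_mv=430.0, ph_range=(6.0, 8.0))
    frac = rep.favorable.mean()
    print(f"{name}: downhill at {100 * frac:.0f}% of pH 6-8 grid, "
          f"crossing pH = {rep.crossing_ph}")
print()
print("The strongly pH-dependent donor rises above the ~430 mV acceptor at")
print("low pH, making electron transfer thermodynamically unfavorable in")
print("part of the physiological range - the weakly coupled donor stays")
print("downhill throughout.")
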