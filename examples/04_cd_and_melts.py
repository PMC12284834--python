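"""CD spectra: the 222/209 coiled-coil criterion and two-state melts.

Isolated helices show a 222/209 ellipticity ratio near 0.8; a packed
coiled coil pushes it above 0.9.  A simulated non-interacting mixture (the
weighted mean of monomer spectra) keeps the monomer ratio — a measured
spectrum exceeding it signals complex formation.  Thermal melts are fitted
to a two-state transition: a tetramer melting at 63 °C and a dimer at
61 °C are both recovered as cooperative transitions.
"""

from coilspect import combine_spectra, fit_two_state_melt, ratio_222_209
from coilspect.crick_synth import MeltSimSpec, simulate_cd, simulate_melt

helix = simulate_cd(kind="single_helix")          # ratio 0.8
tetramer = simulate_cd(kind="coiled_coil")        # ratio 0.95
print(f"single helix ratio  : {ratio_222_209(helix).ratio:.3f}  "
      f"coiled-coil call: {ratio_222_209(helix).coiled_coil}")
print(f"tetramer ratio      : {ratio_222_209(tetramer).ratio:.3f}  "
      f"coiled-coil call: {ratio_222_209(tetramer).coiled_coil}")

simulated_mix = combine_spectra([helix] * 4, [0.25] * 4)
print(f"simulated 4-monomer mixture ratio: "
      f"{ratio_222_209(simulated_mix).ratio:.3f} (stays at the monomer value)")

for label, tm in (("F1-F4 tetramer", 63.0), ("F2+F4 dimer", 61.0)):
    spec = MeltSimSpec(tm=tm, width=2.0)
    spec.noise_sd = 0.02 * spec.amplitude
    fit = fit_two_state_melt(simulate_melt(spec))
    print(f"{label:15s}: Tm {fit.tm:.2f} C  width {fit.width:.2f} C  "
          f"cooperative: {fit.cooperative}")
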