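"""Fit 1:1 Langmuir binding kinetics to a set of sensorgrams.

Synthetic surface-plasmon-resonance curves are simulated at several
analyte concentrations with seeded noise, then globally fit for the
association rate ka, dissociation rate kd and saturation response Rmax.
The dissociation constant is reported as the rate ratio KD = kd / ka.
"""

from qnsmech import fit_langmuir, make_sensorgram_set

ka_true, kd_true, rmax_true = 1.0e4, 1.0e-2, 120.0
curves, manifest = make_sensorgram_set(
    ka_true, kd_true, rmax_true, noise_sd=2.4, seed=7
)
print(f"simulated {len(curves)} sensorgrams, "
      f"concentrations {[f'{c.analyte_conc:.1e}' for c in curves]} M")

fit = fit_langmuir(curves)
print(f"ka   = {fit.ka:.3e} /M/s   (true {ka_true:.1e})")
print(f"kd   = {fit.kd:.3e} /s     (true {kd_true:.1e})")
print(f"Rmax = {fit.rmax:.1f} RU       (true {rmax_true:.0f})")
print(f"KD   = {fit.KD:.3e} M     (true {kd_true / ka_true:.1e})")
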