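"""Assay mathematics: extinction, kinetics, melts, CD signal changes.

Runs the deterministic assay-side calculations: extinction
coefficients from Trp/Tyr composition, a Michaelis-Menten fit of
synthetic initial velocities, narrative fold-changes between a
wild-type enzyme and variants, apparent Tm from a CD melt, and the
IP-signal percent change.
"""

from confcouple import (
    ExtinctionInput,
    extinction_coefficient,
    fit_michaelis_menten,
    fold_change,
    ip_percent_change,
    melting_temperature,
)
from confcouple.synthetic import generate_melt_curve, generate_mm_data

# 4 Trp + 19 Tyr per monomer vs a variant with one Tyr substituted
print("extinction coefficients (M^-1 cm^-1):")
print(f"  4 Trp, 19 Tyr: {extinction_coefficient(ExtinctionInput(4, 19))}")
print(f"  4 Trp, 18 Tyr: {extinction_coefficient(ExtinctionInput(4, 18))}")

S, v, truth = generate_mm_data(vmax=1.0, km=50.0, noise_sigma=0.01, seed=5)
model = fit_michaelis_menten(S, v, enzyme_conc=0.1)
print(f"\nMichaelis-Menten fit (true Vmax {truth['vmax']}, Km {truth['km']}):")
print(f"  Vmax = {model.vmax:.3f} +/- {model.vmax_se:.3f}")
print(f"  Km   = {model.km:.1f} +/- {model.km_se:.1f} uM")
print(f"  kcat = {model.kcat:.3f} 1/s   kcat/Km = {model.efficiency:.4f}")

# turnover numbers: wild type vs two cluster variants (1/s)
kcat_wt, kcat_varA, km_wt, km_varQ = 8.3e-1, 2.3e-2, 39.0, 1022.0
print(f"\nkcat fold-decrease variant A: "
      f"{fold_change(kcat_wt, kcat_varA):.1f}-fold")
print(f"Km fold-increase variant Q: "
      f"{fold_change(km_wt, km_varQ, 'increase', 'nearest-int'):.0f}-fold")

tc, melt_truth = generate_melt_curve(tm=74.0, slope=2.0)
print(f"\napparent Tm from the CD222 melt: {melting_temperature(tc):.1f} C "
      f"(planted {melt_truth['tm']})")

# IP CD313 signal: fully formed -> 0 %, fully depleted -> -100 %
print("\nIP signal percent change (printed convention):")
for cd_t in (5.0, 3.5, 2.0):
    pct = ip_percent_change(cd_t, cd_0=2.0, delta=3.0)
    print(f"  CD313 = {cd_t:.1f} mdeg -> {pct:6.1f} %")
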