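"""Estimate the complete-evaporation time T_eva from a weight time series.

Generates a synthetic applied-solution weight curve (10 mg of aqueous
solution declining to a 1% residue by 1.5 h, weighed every 0.25 h) and
recovers T_eva with the sustained-plateau criterion.
"""

from findose import estimate_teva, generate_evaporation_series

series = generate_evaporation_series(w0=10.0, teva_true=1.5, interval=0.25)
est = estimate_teva(series, rel_threshold=0.01)

for t, w in zip(series.times, series.weights):
    print(f"  t = {t:5.2f} h   weight = {w:6.3f} mg")
print(f"\nT_eva            : {est.Teva} h")
print(f"plateau weight   : {est.plateau_weight:.3f} mg")
print(f"criterion        : {est.criterion}")
print()
print("T_eva switches the absorption model from the solvent+SC phase to the")
print("SC-depot-only phase; 1.5 h is typical for 10-µL aqueous doses.")
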