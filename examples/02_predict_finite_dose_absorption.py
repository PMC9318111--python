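"""Predict percutaneous absorption of caffeine from a 10-µL finite dose.

Uses the packaged Strat-M permeation parameters for caffeine and the
standard in-use conditions (1 cm², evaporation complete at 1.5 h, 24 h
observation), then cross-checks the closed-form result against numerical
integration of the underlying rate equations.
"""

from findose import FiniteDoseConfig, ode_oracle, predict_absorption

KP, K, CV = 1.23e-3, 0.422, 1.00e4  # caffeine / Strat-M
cfg = FiniteDoseConfig()  # A=1 cm², V=0.01 cm³, Vsc=0.002 cm³, Teva=1.5 h, 24 h

pred = predict_absorption((KP, K), CV, cfg)
check = ode_oracle(KP, K, CV, cfg)

print(f"applied dose M0        : {pred.M0:.1f} µg")
print(f"phase 1 (0-1.5 h)  M1  : {pred.M1:.3f} µg permeated while solvent remains")
print(f"SC depot at Teva       : {pred.Msc_at_teva:.3f} µg")
print(f"phase 2 (1.5-24 h) M2  : {pred.M2:.3f} µg cleared from the SC depot")
print(f"surface residue        : {pred.surface_residue:.3f} µg (never penetrates)")
print(f"total absorbed         : {pred.total:.3f} µg")
print(f"absorption ratio       : {pred.ratio:.4f} (ODE oracle {check.ratio:.4f})")
print()
print("About 21% of the applied caffeine is absorbed within 24 h; the rest is")
print("stranded on the surface when the water evaporates at 1.5 h.")
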