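"""Dose penalty of low-pitch helical scanning.

At fixed per-rotation mAs the fluence delivered per unit scan length scales
as 1/pitch, so a pitch 0.1 scan deposits ~10x the dose of a pitch 1.0 scan.
This script measures that ratio with the Monte Carlo engine on the 16 cm
water CTDI cylinder.
"""

from ctdosim import studies

res = studies.pitch_dose_ratio(n_histories=100_000, seed=1)
for pitch, dose in sorted(res["doses"].items()):
    print(f"pitch {pitch:4.1f}: mean cylinder dose {dose:8.3f} (arb. units, "
          f"rel. 1-sigma {100 * res['rel_sigma'][pitch]:.2f}%)")
print(f"dose ratio pitch 0.1 : 1.0 = {res['ratio']:.2f}")
print("Expected ~10 from the 1/pitch law; the small deficit comes from the")
print("discrete field count over the finite scan range.")
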