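"""Full dosimetry chain for one patient-like phantom.

Synthetic thorax -> low-pitch helical (4DCT) and contiguous axial (3DCT)
scans -> CTDI conversion-factor calibration -> absolute mean organ doses.
"""

import ctdosim as cd
from ctdosim.calibration import reference_calibration

phantom, masks, _ = cd.make_thorax_phantom(cd.ThoraxSpec(effective_diameter_mm=300))
zr = cd.organ_scan_range(masks, phantom)

protocols = {
    "4DCT": cd.ScanProtocol(mode="helical", pitch=0.059, collimation=(16, 1.5),
                            scan_range=zr),
    "3DCT": cd.ScanProtocol(mode="axial", collimation=(16, 1.5), scan_range=zr),
}

# one reference measurement (a single axial rotation on the 16 cm water
# cylinder) sets the absolute scale for every scan of this beam quality
rec = reference_calibration(cd.FIXTURE_MEASURED_CGY, voxel_mm=4.0,
                            n_histories=60_000, seed=2)

records = {}
for label, proto in protocols.items():
    source = cd.SourceModel.for_protocol(proto)
    fields = (cd.helical_fields(proto) if proto.mode == "helical"
              else cd.axial_fields(proto))
    dose = cd.run_scan(phantom, fields, source, 150_000, seed=3)
    amap = cd.to_absolute(dose, phantom, rec, proto, override=True)
    records[label] = {o: cd.organ_mean_dose(amap, masks[o], "P0", label)
                      for o in ("lungs", "heart", "esophagus", "trachea",
                                "spinal_cord", "skin")}

print(f"scan range {zr[0]:.0f}-{zr[1]:.0f} mm, 120 kVp, 100 mAs/rotation\n")
print(f"{'organ':<12s} {'4DCT (cGy)':>12s} {'3DCT (cGy)':>12s} {'ratio':>7s}")
for organ in records["4DCT"]:
    d4 = records["4DCT"][organ].dose_cgy
    d3 = records["3DCT"][organ].dose_cgy
    print(f"{organ:<12s} {d4:12.2f} {d3:12.2f} {d4 / d3:7.1f}")
print("\nThe low-pitch helical scan deposits an order of magnitude more dose")
print("per organ than the axial scan at identical per-rotation output.")
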