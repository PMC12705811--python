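"""Closed-form bioassay effect sizes: viability/cytotoxicity, radical
scavenging, anti-hemolysis, IC50 interpolation, and the tumor
growth-inhibition table.
"""

import biofabopt as b

# Absorbance-ratio assays
pair = b.AbsorbancePair(a_test=0.151, a_control=0.5)
print(f"ABTS radical scavenging: {b.abts_inhibition_pct(pair):.1f} %")
mtt = b.AbsorbancePair(a_test=0.30, a_control=0.60)
print(f"viability {b.viability_pct(mtt):.1f} %, "
      f"cytotoxicity {b.cytotoxicity_pct(mtt):.1f} %")

# IC50 by log-linear interpolation of a cytotoxicity curve
doses = [1.0, 5.0, 25.0, 125.0]
_, resp = b.simulate_dose_response(ic50=13.9, hill=1.2, doses=doses)
print(f"interpolated IC50: {b.ic50_interpolate(doses, resp):.1f} ug/mL")

# Tumor growth inhibition for the bundled six-group murine study:
# volumes V = L*S^2/2 (cm^3), TGI% = 100 - 100*dT/dC on volume changes.
records = b.load_tumor_study()
control = records[0]
print(f"\n{'group':<16}{'V day0':>7}{'V day20':>8}{'TGI %':>7}")
for rec in records:
    v0, v20 = rec.volumes(rounding_dp=2)
    tgi = b.growth_inhibition_pct(control, rec, rounding_dp=2)
    print(f"{rec.group:<16}{v0:>7.2f}{v20:>8.2f}{tgi:>7.2f}")

# The combination group (DOX plus nanoparticles) nearly freezes tumor
# growth: its 20-day volume change is ~2% of the untreated control's.
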