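"""SEC calibration: which glycan changes move a peptide >= 2 fractions?

Evaluates the log-linear mass -> elution-volume model over the default
1500–4000 Da calibration (10–20 mL window, 20 x 0.5 mL fractions) and
prints the smallest mass gain resolvable at several base masses.
"""

from glycoshift import SECCalibration, fraction_for_mass, min_detectable_change
from glycoshift.masses import monosaccharide_mass

calib = SECCalibration()
print(f"Calibration: {calib.mass_low:.0f}–{calib.mass_high:.0f} Da over "
      f"{calib.v_start:.0f}–{calib.v_end:.0f} mL, slope {calib.slope:.2f} mL/decade")

hex_res = monosaccharide_mass("Hex", "residue", "average")
print(f"\n{'base mass':>10} {'fraction':>9} {'min gain for 2-frac shift':>26} "
      f"{'= how many Hex':>15}")
for base in (1700, 2000, 2400, 2800, 3200):
    d = min_detectable_change(calib, base, shift_threshold=2)
    print(f"{base:>10} {fraction_for_mass(base, calib):>9} {d:>23.1f} Da "
          f"{d / hex_res:>14.2f}")

print("\nA two-monosaccharide change (>= ~324 Da) therefore shifts a "
      "glycopeptide by >= 2 fractions anywhere below ~3.1 kDa; a single "
      "hexose (162 Da) does so only for the lightest glycopeptides.")
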