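"""Assign CHNOS formulae to a small negative-ESI peak list.

Builds three peaks at the theoretical [M-H]- masses of known molecules
(one slightly mass-shifted, one pure noise), runs the bounded
enumeration with plausibility filters, and prints the assignments.
"""

from domchemodiv import AssignmentConfig, MolecularFormula, Peak, assign_peaks, theoretical_mz

vanillin_like = MolecularFormula(c=10, h=12, o=5)    # lignin-region molecule
sugar_like = MolecularFormula(c=12, h=22, o=11)      # disaccharide composition

peaks = [
    Peak(mz=theoretical_mz(vanillin_like), intensity=850.0),          # exact mass
    Peak(mz=theoretical_mz(sugar_like) * (1 + 0.4e-6), intensity=430.0),  # +0.4 ppm error
    Peak(mz=433.721, intensity=55.0),   # mass defect far from any CHNOS composition
]

assigned, unassigned = assign_peaks(peaks, AssignmentConfig(tol_ppm=1.0))

print("assigned peaks:")
for ap in assigned:
    print(
        f"  m/z {ap.peak.mz:10.5f} -> {ap.formula.hill():12s} "
        f"error {ap.error_ppm:+.3f} ppm  (H/C {ap.formula.hc:.2f}, O/C {ap.formula.oc:.2f})"
    )
print(f"unassigned peaks: {[round(p.mz, 5) for p in unassigned]}")
print("\nAn assignment is the closest elemental composition within 1 ppm that")
print("passes the nitrogen rule, H/C-O/C windows and DBE >= 0; the last peak's")
print("mass defect matches no such composition, so it stays unassigned.")
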