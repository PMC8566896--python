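"""Intensity-weighted descriptors and chemodiversity of one DOM sample.

Builds a four-molecule profile with unequal intensities and prints the
weighted O/C, H/C, DBE and m/z, the Shannon chemodiversity and Pielou
evenness, and the van Krevelen class of each molecule.
"""

from domchemodiv import MolecularFormula, classify, normalize_intensities, summarize

records = [
    (MolecularFormula(c=20, h=36, o=2), 120.0),   # lipid-like: H/C 1.8, O/C 0.1
    (MolecularFormula(c=10, h=12, o=4), 540.0),   # lignin/CRAM-like: H/C 1.2, O/C 0.4
    (MolecularFormula(c=12, h=22, o=11), 230.0),  # carbohydrate-like: H/C 1.83, O/C 0.92
    (MolecularFormula(c=14, h=12, o=10), 110.0),  # tannin-like: H/C 0.86, O/C 0.71
]

profile = normalize_intensities(records, sample_id="demo")
summary = summarize(profile)

print("molecules (normalized intensity M_i, class):")
for f, w in zip(profile.formulas, profile.weight):
    print(f"  {f.hill():12s} M_i = {w:.3f}  {classify(f)}")
print(f"\nO/C_wa  = {summary.oc_wa:.4f}")
print(f"H/C_wa  = {summary.hc_wa:.4f}")
print(f"DBE_wa  = {summary.dbe_wa:.4f}")
print(f"m/z_wa  = {summary.mz_wa:.2f}")
print(f"Shannon = {summary.shannon:.4f} nats, Pielou = {summary.pielou:.4f}")
print("\nThe weighted averages are convex combinations of the per-molecule")
print("ratios; Shannon treats each formula as a 'species' weighted by M_i.")
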