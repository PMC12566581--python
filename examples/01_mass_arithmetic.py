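"""Exact-mass arithmetic: from elemental formula to [M+H]+ m/z.

Parses Hill-notation formulas of a few well-known parent compounds,
computes their neutral monoisotopic mass and protonated-adduct m/z, and
shows the signed ppm error against an 'observed' value.
"""

from phasemet import adduct_mz, monoisotopic_mass, parse_formula, ppm_difference

compounds = [
    ("Propiconazole", "C15H17Cl2N3O2"),
    ("Vanillin", "C8H8O3"),
    ("Caprolactam", "C6H11NO"),
    ("DEET", "C12H17NO"),
]

print(f"{'compound':<15}{'formula':<16}{'neutral M':>12}{'[M+H]+':>12}")
for name, text in compounds:
    formula = parse_formula(text)
    print(
        f"{name:<15}{formula.hill():<16}"
        f"{monoisotopic_mass(formula):>12.4f}{adduct_mz(formula):>12.4f}"
    )

observed, theoretical = 342.0805, adduct_mz(parse_formula("C15H17Cl2N3O2"))
print(
    f"\nobserved {observed:.4f} vs theoretical {theoretical:.4f}: "
    f"{ppm_difference(observed, theoretical):+.1f} ppm"
)
# The neutral mass is the sum of most-abundant-isotope masses; adding the
# proton mass (1.007276 Da) gives the m/z the instrument reports for the
# singly protonated ion.
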