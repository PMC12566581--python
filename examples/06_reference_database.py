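"""The shipped reference compound database and its bookkeeping.

Loads the transcribed neuroactive-compounds LC-MS/MS database, prints the
summary counts (parents, metabolites, dual-role compounds) and verifies
that the computed [M+H]+ values reproduce the printed m/z column.
"""

from phasemet import adduct_mz, load_reference_database, summarize

db = load_reference_database()
summary = summarize(db)
print(
    f"{summary.n_total} compounds: {summary.n_parents} parents, "
    f"{summary.n_metabolites} metabolites, "
    f"{summary.n_dual_role} in both roles"
)

agree = sum(
    1 for e in db if not e.mz_as_reported and abs(adduct_mz(e.formula) - e.mz) <= 3e-4
)
print(f"printed m/z reproduced by [M+H]+ arithmetic: {agree}/{len(db)}")
print(f"carried as-reported (unstated ion species / low-precision rows): "
      f"{sum(e.mz_as_reported for e in db)}")

print("\ndual-role compounds:")
for e in db:
    if e.compound_type == "Parent/Metabolite":
        print(f"  {e.name}  {e.formula.hill()}  m/z {e.mz:.4f}  RT {e.rt} min")
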