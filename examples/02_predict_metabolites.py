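"""Phase-I metabolite prediction and m/z matching.

Enumerates single-step phase-I transformation products of molinate, then
matches a short list of observed feature m/z values against the predicted
candidates at 10 ppm.
"""

from phasemet import match_predictions, parse_formula, predict_candidates

molinate = parse_formula("C9H17NOS")
candidates = predict_candidates(molinate, max_depth=1, parent_id="Molinate")

print("predicted single-step metabolites of molinate (C9H17NOS):")
for cand in candidates:
    chain = " + ".join(r.name for r in cand.chain.rules)
    print(f"  {cand.mz:9.4f}  {cand.formula.hill():<12} {chain}")

observed = [("feat_a", 204.1053), ("feat_b", 204.30), ("feat_c", 186.0947)]
print("\nmatches at 10 ppm:")
for fid, cand, err in match_predictions(observed, candidates, tol_ppm=10):
    print(f"  {fid}: {cand.formula.hill()} ({err:+.2f} ppm)")
# feat_a is the molinate sulfoxide m/z; feat_b is far off every candidate
# and is dropped; each match reports its signed mass error.
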