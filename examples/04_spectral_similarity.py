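"""MS2 similarity scoring and the 0.4 acceptance rule.

Scores a candidate metabolite spectrum against its putative parent with
both the cosine (peak-alignment) and spectral-entropy measures, classifies
it against the 0.4 threshold, and shows the individual-parent-sample
rescue path for a dissimilar candidate.
"""

from phasemet import (
    FragmentSpectrum,
    classify_candidate,
    entropy_similarity,
    similarity_score,
    verify_in_parent_sample,
)

parent = FragmentSpectrum(
    342.0771,
    ((69.0699, 100.0), (158.9763, 65.0), (204.9812, 40.0), (123.0441, 22.0)),
    name="propiconazole",
)
# shares three of four parent fragments
similar = FragmentSpectrum(
    358.0720,
    ((69.0699, 90.0), (158.9763, 70.0), (204.9812, 35.0), (240.0211, 30.0)),
    name="hydroxy-metabolite",
)
# shares nothing with the parent
dissimilar = FragmentSpectrum(
    356.0563, ((91.0542, 100.0), (131.0855, 45.0)), name="rearranged-metabolite", rt=7.72
)

for met in (similar, dissimilar):
    cos = similarity_score(met, parent)
    ent = entropy_similarity(met, parent)
    decision = classify_candidate(cos)
    print(f"{met.name}: cosine={cos:.3f} entropy={ent:.3f} -> {decision.verdict}")

# The dissimilar candidate is not discarded: it is re-examined in the S9
# run of the parent compound alone.
parent_only_run = [FragmentSpectrum(356.0563, ((91.0542, 80.0),), rt=7.70)]
verdict = verify_in_parent_sample(356.0563, 7.72, parent_only_run)
print(f"rearranged-metabolite in parent-only run -> {verdict}")
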