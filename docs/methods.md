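# Methods

This note records the models, defaults and design decisions behind
`phasemet`, and what the synthetic benchmarks do and do not demonstrate.

## Mass arithmetic

Formulas are element→count maps parsed from Hill notation; zero counts are
dropped and the supported element set is the shipped mass table
(C, H, N, O, S, P, F, Cl, Br, I, Na, K, Sn, Si). Monoisotopic masses are
most-abundant-isotope values from the AME2020/NIST compilation, stored as
a delimited resource (`data/monoisotopic_masses.tsv`) so the provenance is
inspectable and the table replaceable. The protonated adduct uses the
proton mass 1.007276 Da — the proton, not the hydrogen atom, so electron
bookkeeping is correct for +1 ions; this choice reproduces the reference
database's printed m/z values at 4 decimal places. Exported tables round
m/z half-even to 4 dp; full precision is kept internally. ppm error is
signed: 1e6 · (observed − theoretical)/theoretical.

Reference-database entries whose printed m/z is not the [M+H]⁺ of their
printed formula (one organotin parent with an unstated ion species, and a
handful of rule-suffixed metabolite rows printed with lower-precision
arithmetic, all deviating ≤ 2×10⁻³) are carried through as-reported and
flagged, never recomputed; the frozen list is
`phasemet.annotate.KNOWN_MZ_DEVIATIONS`.

## Phase-I rule engine

A transformation rule is a signed composition change; its mass delta is
always recomputed from the element counts, never stored separately. The
shipped table (`data/phase1_rules.tsv`, user-editable) is a reconstruction
of the common phase-I reaction set inferred from the compound-naming
conventions of the reference database: mono-/di-hydroxylation (+O, +O₂),
dehydrogenation (−H₂), hydrogenation (+H₂), methylation (+CH₂),
dealkylation/demethylation (−CH₂), desulphuration (−S+O), epoxide
hydration (+H₂O), oxidative deamination (−NH₃+O), dehydroxylation/
decarboxylation (−O), and decarboxylation (−CO₂). A non-oxidative
deamination (−NH₃) variant ships disabled: the oxidative form is the one
consistent with the reference database's deamination products.

Chains are unordered multisets of rules — only the net composition change
matters for m/z matching — enumerated to a configurable depth (the
targeted workflow convention is three iterations; the non-targeted default
here is depth 1). Candidates are deduplicated by net delta, net-zero
chains are dropped, and in formula mode a chain is feasible iff the net
delta leaves every element count non-negative (an infeasible single rule
prunes the chain rather than raising to the user). Formula-mode and
m/z-mode predictions agree to < 1e-4 Da wherever both apply; this is a
tested invariant. Matching uses a closed ±10 ppm interval by default
(configurable; 25 ppm is the documented ceiling for database comparisons),
with a 1e-12-relative guard so values at exactly the boundary are not lost
to floating-point round-off.

## Significance filter

The four criteria are evaluated per feature against the experimental
blanks and combined conjunctively; diagnostics name the first failing
criterion and carry volcano coordinates (log₂ fold-change, −log₁₀ p).
Readings the criteria leave open were resolved as follows:

- *Presence* counts treatment replicates only (intensity > 0), threshold
  ≥ 0.5; blanks are excluded from the denominator.
- *Fold-change* is the ratio of arithmetic means with a pseudo-count
  floor (default 1 intensity unit) on the blank mean, since blanks are
  frequently all-zero; the rule is strict (> 2).
- *S/N* prefers an upstream per-feature column when present; otherwise
  treatment mean over blank standard deviation, floored at the
  pseudo-count.
- *The t-test* pairs by replicate index when the two arms have equal
  replicate counts, else falls back to Welch's unpaired test; the method
  used is flagged per feature. Identical arms give p = 1; fewer than two
  replicates in either arm makes a feature untestable (excluded,
  flagged). p < 0.05 is strict, two-sided, and deliberately uncorrected
  for multiplicity — the workflow favors inclusivity at this stage
  because the MS² stages downstream provide the specificity.

Loosening any single threshold provably (and testedly) enlarges the
survivor set, and the filter agrees feature-by-feature with a brute-force
re-evaluation of the four rules on synthetic tables.

## MS² similarity

Spectra are noise-filtered (default floor 1 % of the base peak — spectrum
noise is a known depressor of similarity scores; set 0 to disable),
base-peak-normalized to 100 and aligned greedily: cross-spectrum peak
pairs within the fragment tolerance (default 0.01 Da; ppm mode available)
are matched in order of ascending m/z difference, each peak used at most
once, unmatched peaks keeping their own bin. Two scores are computed on
the aligned vectors:

- **cosine** (the default decision score), and
- **spectral-entropy similarity** 1 − (2·S_AB − S_A − S_B)/ln 4, with
  S_X the Shannon entropy of the probability-normalized intensities and
  S_AB that of the merged (averaged) spectrum.

Both are symmetric, bounded in [0, 1], equal 1 on self-comparison and
invariant to uniform intensity rescaling (tested properties). The
acceptance rule is closed at 0.4. Sub-threshold candidates are routed to
the rescue path: confirmed iff the individual-parent S9 run shows a
precursor within the m/z tolerance and, when both retention times are
known, within ±0.2 min, with any MS² signal above the noise floor. With
no parent-only data the candidate is reported `unresolved`, distinctly
from `rejected`. The cosine implementation is cross-checked in the test
suite against matchms's `CosineGreedy` on random spectra.

## Annotation and database assembly

Confidence is a pure function of the evidence record: authentic standard
→ 1, external fragmentation match → 2, else 3. Novelty is `novel` iff the
compound is known only from rule-based discovery or prediction software.
External spectral comparison is abstracted to a local library lookup
(match = precursor within 25 ppm and cosine ≥ 0.6 by default); live
database queries are out of scope for determinism.

A compound occurring as both parent and metabolite is condensed to a
single `Parent/Metabolite` entry keeping the parent's m/z and retention
time; conflicting formulas under one name are a hard error at condensation
time. Summary counts treat every database entry as one compound, with
dual-role entries contributing to both the parent and metabolite tallies
and once to the total, so total = parents + metabolites − dual-role
identically; rows sharing a name at different retention times (positional
isomers) remain separate entries, matching the reference table's own
arithmetic (274 = 92 + 180 + 2 rows; 94 parents, 182 metabolites).

## Synthetic data

The generator emulates the study design: `n_mixtures` (25) ×
`parents_per_mixture` (10) parents in `replicates` (3) treatment runs plus
`blanks` (3) experimental blanks. Random parents draw C₅–C₂₀ skeletons
with plausible H/N/O/S/Cl complements, constrained to [M+H]⁺ in the
instrument range 70–1000 and placed so that no parent m/z falls within
25 ppm of another parent m/z plus any single-rule delta (so parents are
never mistaken for each other's metabolites). Per feature, one log-normal
base abundance (location ln 1e7, scale 1.5 — spanning roughly the
1e5–1e9 range reported for real detections) is multiplied by small
log-normal replicate noise (CV 15 %, typical of LC-MS replicates); blank
noise is log-normal around 1e3. Decoys share one blank-level base
abundance between both arms (so they fail the fold-change and p-value
rules) and their m/z is kept ≥ 50 ppm from every candidate prediction of
the mixture's parents. Planted metabolite MS² spectra inherit fraction
`q` (default 0.8) of the parent's fragments *with identical intensities*
(so q = 1 gives an exact spectral copy and cosine 1), the remainder drawn
uniformly below precursor − 10 Da; no fragmentation chemistry is modeled.
Individual-parent runs carry the parent and its planted metabolites,
exercising the rescue path.

What passing the synthetic benchmarks shows: the stages compose correctly,
the filter matches its brute-force definition, recall of planted
metabolites is complete and decoy false positives are zero under low
blank noise. What it does not show: performance on real chromatography
(peak shapes, co-elution, isotope envelopes, adduct diversity, in-source
fragments are all absent), realistic fragmentation, or the true
false-discovery behavior of the 0.4 threshold on real spectra.

## Problem sizes and determinism

Tests and examples run the generator at 1–3 mixtures × 3–5 parents, which
exercises every code path in seconds; the default 25 × 10 configuration
runs in well under a minute. All randomness flows from
`numpy.random.default_rng(seed)`; a stored seed reproduces datasets
byte-identically, and property tests run derandomized.

## Known limitations

- Positive-mode [M+H]⁺ only; other adducts are expressible via
  `AdductSpec` but no adduct inference is attempted.
- The rule table is a reconstruction, not a verbatim literature set;
  users can ship their own TSV.
- `run_targeted` requires suspects with parseable formulas (rows that
  fail to parse are skipped with a warning).
- MSP/MGF I/O (via matchms) round-trips name, precursor m/z, retention
  time and peaks; other vendor metadata is not preserved.
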