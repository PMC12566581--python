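"""The two discovery workflows stitched from the pipeline stages.

``run_nta`` is the non-targeted arm: significance-filter the full-scan
features against blanks, predict phase-I metabolite m/z values from the
detected parents, match surviving features to the predictions, score each
match's MS2 spectrum against its putative parent, accept at similarity
>= 0.4, and re-examine low scorers in the individual-parent S9 run.

``run_targeted`` is the suspect-screening arm: match literature/predicted
metabolites to observed precursors, require presence in both the mixture
run and the individual-parent run, then assign annotation confidence via a
local spectral-library lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .annotate import EvidenceRecord, assign_confidence, classify_novelty
from .chem import adduct_mz, ppm_difference
from .filtering import FeatureTable, SignificanceThresholds, filter_significant
from .io import ParentCompound, Suspect
from .rules import TransformationRule, default_rule_table, match_predictions, predict_candidates
from .similarity import (
    AlignmentParams,
    EmptySpectrumError,
    FragmentSpectrum,
    classify_candidate,
    entropy_similarity,
    similarity_score,
    verify_in_parent_sample,
)

__all__ = ["NtaParams", "NtaHit", "NtaResult", "run_nta", "TargetedHit", "run_targeted"]


@dataclass(frozen=True)
class NtaParams:
    """All thresholds of the non-targeted workflow (study defaults)."""

    thresholds: SignificanceThresholds = field(default_factory=SignificanceThresholds)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    match_tol_ppm: float = 10.0
    similarity_threshold: float = 0.4
    rule_depth: int = 1
    rt_window: float = 0.2
    use_rescue: bool = True
    rules: Optional[Tuple[TransformationRule, ...]] = None


@dataclass(frozen=True)
class NtaHit:
    """One accepted candidate metabolite with its full per-stage record."""

    feature_id: str
    mz: float
    rt: float
    parent: str
    chain: str
    formula: str
    ppm_error: float
    cosine_score: float
    entropy_score: float
    verdict: str


@dataclass
class NtaResult:
    accepted: List[NtaHit]
    rejected: List[NtaHit]
    diagnostics: object  # feature-filter diagnostics frame
    stage_counts: Tuple[Tuple[str, int], ...]


def _detect_parents(
    table: FeatureTable, registry: Sequence[ParentCompound], tol_ppm: float
) -> Dict[str, Tuple[ParentCompound, str]]:
    """Parents whose [M+H]+ matches a feature within tolerance; the
    non-targeted arm can only predict from parents it can see."""
    detected: Dict[str, Tuple[ParentCompound, str]] = {}
    for parent in registry:
        target = adduct_mz(parent.formula)
        best = None
        for fid in table.features.index:
            err = ppm_difference(float(table.features.loc[fid, "mz"]), target)
            if abs(err) <= tol_ppm and (best is None or abs(err) < abs(best[1])):
                best = (fid, err)
        if best is not None:
            detected[parent.name] = (parent, best[0])
    return detected


def run_nta(
    table: FeatureTable,
    spectra: Dict[str, FragmentSpectrum],
    registry: Sequence[ParentCompound],
    parent_spectra: Dict[str, FragmentSpectrum],
    parent_only_spectra: Optional[Dict[str, List[FragmentSpectrum]]] = None,
    params: NtaParams = NtaParams(),
) -> NtaResult:
    """Run the full non-targeted discovery workflow on one mixture.

    ``spectra`` maps feature id -> MS2 spectrum from the mixture run;
    ``parent_spectra`` maps parent name -> parent MS2 spectrum;
    ``parent_only_spectra`` maps parent name -> spectra of the
    individual-parent S9 run (the rescue path; optional).
    """
    rules = list(params.rules) if params.rules else default_rule_table()

    survivors, diagnostics = filter_significant(table, params.thresholds)
    detected = _detect_parents(table, registry, params.match_tol_ppm)
    parent_feature_ids = {fid for _, fid in detected.values()}

    candidates = []
    for parent, _fid in detected.values():
        candidates.extend(
            predict_candidates(parent.formula, rules, params.rule_depth, parent.name)
        )

    feature_mzs = [
        (fid, float(table.features.loc[fid, "mz"]))
        for fid in survivors
        if fid not in parent_feature_ids
    ]
    matches = match_predictions(feature_mzs, candidates, params.match_tol_ppm)
    matched_features = {fid for fid, _, _ in matches}

    accepted: List[NtaHit] = []
    rejected: List[NtaHit] = []
    resolved: set = set()
    for fid, cand, err in matches:
        if fid in resolved:
            continue
        rt = float(table.features.loc[fid, "rt"])
        spectrum = spectra.get(fid)
        pspec = parent_spectra.get(cand.parent_id)
        cosine = entropy = 0.0
        if spectrum is not None and pspec is not None:
            try:
                cosine = similarity_score(spectrum, pspec, params.alignment)
                entropy = entropy_similarity(spectrum, pspec, params.alignment)
            except EmptySpectrumError:
                pass
        decision = classify_candidate(cosine, params.similarity_threshold)
        verdict = decision.verdict
        if verdict == "needs_parent_verification" and params.use_rescue:
            verdict = verify_in_parent_sample(
                cand.mz,
                rt,
                (parent_only_spectra or {}).get(cand.parent_id),
                params.match_tol_ppm,
                params.rt_window,
                params.alignment.noise_floor,
            )
        hit = NtaHit(
            feature_id=fid,
            mz=float(table.features.loc[fid, "mz"]),
            rt=rt,
            parent=cand.parent_id,
            chain=" + ".join(r.name for r in cand.chain.rules),
            formula=cand.formula.hill() if cand.formula else "",
            ppm_error=err,
            cosine_score=cosine,
            entropy_score=entropy,
            verdict=verdict,
        )
        if verdict in ("accepted", "confirmed_by_parent_sample"):
            accepted.append(hit)
            resolved.add(fid)
        else:
            rejected.append(hit)

    # keep only the final outcome per feature: a later candidate may have
    # accepted a feature an earlier candidate rejected
    rejected = [h for h in rejected if h.feature_id not in resolved]

    stage_counts = (
        ("features_total", len(table.features)),
        ("features_significant", len(survivors)),
        ("parents_detected", len(detected)),
        ("rule_matched", len(matched_features)),
        ("accepted", len({h.feature_id for h in accepted})),
    )
    return NtaResult(accepted, rejected, diagnostics, stage_counts)


@dataclass(frozen=True)
class TargetedHit:
    """One confirmed suspect metabolite."""

    name: str
    formula: str
    parent: str
    source: str
    mz: float
    rt: Optional[float]
    confidence: int
    novelty: str


def run_targeted(
    suspects: Sequence[Suspect],
    mixture_spectra: Sequence[FragmentSpectrum],
    parent_only_spectra: Dict[str, List[FragmentSpectrum]],
    spectral_library: Sequence[FragmentSpectrum] = (),
    tol_ppm: float = 10.0,
    db_tol_ppm: float = 25.0,
    library_match_threshold: float = 0.6,
    alignment: AlignmentParams = AlignmentParams(),
) -> List[TargetedHit]:
    """Suspect screening with dual-presence confirmation.

    A suspect is confirmed iff a precursor within ``tol_ppm`` of its
    [M+H]+ appears in the mixture-run spectra AND in the individual run of
    its parent compound.  Confidence is 2 when any local spectral-library
    record within ``db_tol_ppm`` scores cosine >= ``library_match_threshold``
    against the observed spectrum, else 3; suspects from prediction tools
    with no literature record are 'novel'.
    """
    hits: List[TargetedHit] = []
    for suspect in suspects:
        target = adduct_mz(suspect.formula)
        observed = next(
            (
                s
                for s in mixture_spectra
                if abs(ppm_difference(s.precursor_mz, target)) <= tol_ppm
            ),
            None,
        )
        if observed is None:
            continue
        own_run = parent_only_spectra.get(suspect.parent, [])
        in_parent_run = any(
            abs(ppm_difference(s.precursor_mz, target)) <= tol_ppm for s in own_run
        )
        if not in_parent_run:
            continue
        db_match = False
        for record in spectral_library:
            if abs(ppm_difference(record.precursor_mz, target)) > db_tol_ppm:
                continue
            try:
                if similarity_score(observed, record, alignment) >= library_match_threshold:
                    db_match = True
                    break
            except EmptySpectrumError:
                continue
        evidence = EvidenceRecord(
            suspect.name, suspect.source, external_fragmentation_match=db_match
        )
        hits.append(
            TargetedHit(
                name=suspect.name,
                formula=suspect.formula.hill(),
                parent=suspect.parent,
                source=suspect.source,
                mz=observed.precursor_mz,
                rt=observed.rt,
                confidence=assign_confidence(evidence),
                novelty=classify_novelty(evidence),
            )
        )
    return hits
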