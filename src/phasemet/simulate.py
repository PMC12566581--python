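"""Synthetic S9-experiment datasets with planted ground truth.

The generator emulates the study design end to end: parent compound
mixtures (25 mixtures of 10 parents by default) incubated in triplicate
alongside experimental blanks, phase-I metabolites planted at the parent
m/z plus a feasible rule-chain delta with log-normally distributed
treatment intensities far above blank noise, decoy features at random m/z
with blank-level intensities in both arms, and MS2 spectra in which each
planted metabolite inherits a fraction q of its parent's fragments
(identical intensities for inherited fragments, so q = 1 gives an exact
spectral copy).  Individual-parent S9 runs are simulated too, carrying the
parent and its planted metabolites, which exercises the
parent-only-sample rescue path.

Every feature is recorded in a ground-truth manifest, so pipeline recall
and false-positive rates are measured against a complete oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import ElementalFormula, adduct_mz, ppm_difference
from .filtering import FeatureTable
from .io import ParentCompound
from .rules import PredictedMetabolite, TransformationRule, default_rule_table, predict_candidates
from .similarity import FragmentSpectrum

__all__ = [
    "SimulationConfig",
    "MixtureData",
    "S9Dataset",
    "RecoveryReport",
    "generate_library",
    "simulate_s9_dataset",
    "end_to_end_recovery",
]

# Plausible small-molecule composition ranges for random parents.
_ELEMENT_CHOICES = (
    ("N", (0, 3)),
    ("O", (0, 4)),
    ("S", (0, 1)),
    ("Cl", (0, 2)),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one synthetic experiment.

    Defaults mirror the emulated design: 25 mixtures x 10 parents x 3
    replicates with 3 experimental blanks; treatment intensities are
    log-normal around 1e7 (the study reports abundances spanning
    1e5-1e9), blank noise log-normal around 1e3.
    """

    n_mixtures: int = 25
    parents_per_mixture: int = 10
    replicates: int = 3
    blanks: int = 3
    metabolites_per_parent: Tuple[int, int] = (1, 3)
    rule_depth: int = 1
    intensity_location: float = math.log(1e7)
    intensity_scale: float = 1.5
    blank_location: float = math.log(1e3)
    blank_scale: float = 0.5
    replicate_cv: float = 0.15
    fragment_count: Tuple[int, int] = (6, 12)
    shared_fragment_fraction: float = 0.8
    decoy_feature_count: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mixtures, self.parents_per_mixture, self.replicates, self.blanks) < 1:
            raise ValueError("all design counts must be >= 1")
        if not 0 <= self.shared_fragment_fraction <= 1:
            raise ValueError("shared_fragment_fraction must be in [0, 1]")


@dataclass
class MixtureData:
    """One parent-compound-mixture S9 run."""

    mixture_id: str
    parents: List[str]
    feature_table: FeatureTable
    spectra: Dict[str, FragmentSpectrum]  # feature id -> MS2 spectrum
    parent_spectra: Dict[str, FragmentSpectrum]  # parent name -> MS2 spectrum


@dataclass
class S9Dataset:
    """A full synthetic experiment: mixtures, individual-parent runs and
    the complete ground-truth manifest (one row per generated feature)."""

    library: List[ParentCompound]
    mixtures: List[MixtureData]
    parent_only_spectra: Dict[str, List[FragmentSpectrum]]
    manifest: pd.DataFrame


def _random_formula(rng: np.random.Generator) -> ElementalFormula:
    c = int(rng.integers(5, 21))
    h = int(rng.integers(c, 2 * c + 3))
    counts = {"C": c, "H": h}
    for el, (lo, hi) in _ELEMENT_CHOICES:
        n = int(rng.integers(lo, hi + 1))
        if n:
            counts[el] = n
    return ElementalFormula(counts)


def generate_library(
    n: int, seed: int = 0, rules: Optional[Sequence[TransformationRule]] = None
) -> List[ParentCompound]:
    """Generate ``n`` parent compounds with plausible CHNOS+halogen
    formulas, distinct [M+H]+ m/z inside the instrument range (70-1000),
    and mutually non-confusable masses: no parent's m/z falls within 25 ppm
    of another parent's m/z plus any single-rule delta."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if rules is None:
        rules = default_rule_table()
    deltas = [0.0] + [r.mass_delta for r in rules]
    parents: List[ParentCompound] = []
    mzs: List[float] = []
    attempts = 0
    while len(parents) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError("could not place distinct parent masses")
        formula = _random_formula(rng)
        mz = adduct_mz(formula)
        if not 70 <= mz <= 1000:
            continue
        clash = any(
            abs(ppm_difference(mz, other + d)) <= 25 or abs(ppm_difference(other, mz + d)) <= 25
            for other in mzs
            for d in deltas
            if other + d > 0 and mz + d > 0
        )
        if clash:
            continue
        rt = float(np.round(rng.uniform(0.5, 12.0), 2))
        parents.append(ParentCompound(f"P{len(parents) + 1:03d}", formula, rt))
        mzs.append(mz)
    return parents


def _spectrum(
    rng: np.random.Generator,
    precursor_mz: float,
    n_fragments: int,
    name: str,
    rt: Optional[float],
) -> FragmentSpectrum:
    mzs = rng.uniform(50.0, max(precursor_mz - 10.0, 60.0), size=n_fragments)
    intensities = rng.lognormal(math.log(30.0), 1.0, size=n_fragments)
    peaks = tuple(zip(np.round(mzs, 4), np.round(intensities, 2)))
    return FragmentSpectrum(precursor_mz, peaks, name=name, rt=rt)


def _child_spectrum(
    rng: np.random.Generator,
    parent: FragmentSpectrum,
    precursor_mz: float,
    q: float,
    n_fragments: int,
    name: str,
    rt: Optional[float],
) -> FragmentSpectrum:
    """Metabolite MS2 inheriting fraction q of the parent's fragments with
    identical intensities; the remainder are fresh random fragments."""
    n_shared = int(round(q * len(parent.peaks)))
    idx = rng.choice(len(parent.peaks), size=n_shared, replace=False)
    peaks = [parent.peaks[i] for i in sorted(idx)]
    n_new = max(n_fragments - n_shared, 0) if q < 1 else 0
    if n_new:
        extra = _spectrum(rng, precursor_mz, n_new, name, rt)
        peaks.extend(extra.peaks)
    return FragmentSpectrum(precursor_mz, tuple(peaks), name=name, rt=rt)


def _intensities(
    rng: np.random.Generator, location: float, scale: float, cv: float, n: int
) -> np.ndarray:
    """Replicate intensities: one log-normal base abundance per feature
    (the across-feature spread), multiplied by small log-normal
    replicate-to-replicate noise of coefficient of variation ``cv``."""
    base = rng.lognormal(location, scale)
    return np.round(base * rng.lognormal(0.0, cv, size=n), 1)


def simulate_s9_dataset(
    config: SimulationConfig, library: Optional[List[ParentCompound]] = None
) -> S9Dataset:
    """Generate a complete synthetic S9 experiment (see module docstring).

    The same seed reproduces the dataset byte-identically.
    """
    rng = np.random.default_rng(config.seed)
    rules = default_rule_table()
    n_parents = config.n_mixtures * config.parents_per_mixture
    if library is None:
        library = generate_library(n_parents, seed=int(rng.integers(2**31)), rules=rules)
    if len(library) < n_parents:
        raise ValueError("library smaller than mixtures x parents_per_mixture")
    by_name = {p.name: p for p in library}

    manifest_rows: List[dict] = []
    mixtures: List[MixtureData] = []
    parent_only: Dict[str, List[FragmentSpectrum]] = {}
    treatment_cols = [f"rep_{i + 1}" for i in range(config.replicates)]
    blank_cols = [f"blank_{i + 1}" for i in range(config.blanks)]

    for m in range(config.n_mixtures):
        mixture_id = f"PCM{m + 1:02d}"
        members = library[m * config.parents_per_mixture : (m + 1) * config.parents_per_mixture]
        feat_rows: List[dict] = []
        inten_rows: List[np.ndarray] = []
        spectra: Dict[str, FragmentSpectrum] = {}
        parent_spectra: Dict[str, FragmentSpectrum] = {}

        def add_feature(fid, mz, rt, treat, blank, spectrum, kind, parent="", chain="", formula=""):
            feat_rows.append({"id": fid, "mz": round(mz, 4), "rt": rt})
            inten_rows.append(np.concatenate([treat, blank]))
            if spectrum is not None:
                spectra[fid] = spectrum
            manifest_rows.append(
                {
                    "feature_id": fid,
                    "mixture": mixture_id,
                    "kind": kind,
                    "parent": parent,
                    "chain": chain,
                    "formula": formula,
                    "mz": round(mz, 4),
                }
            )

        for parent in members:
            pmz = adduct_mz(parent.formula)
            n_frag = int(rng.integers(*config.fragment_count))
            pspec = _spectrum(rng, pmz, n_frag, parent.name, parent.rt)
            parent_spectra[parent.name] = pspec
            own_run: List[FragmentSpectrum] = [pspec]

            fid = f"{mixture_id}_{parent.name}"
            treat = _intensities(rng, config.intensity_location, config.intensity_scale, config.replicate_cv, config.replicates)
            blank = _intensities(rng, config.blank_location, config.blank_scale, config.replicate_cv, config.blanks)
            add_feature(fid, pmz, parent.rt, treat, blank, pspec, "parent",
                        parent=parent.name, formula=parent.formula.hill())

            candidates = predict_candidates(parent.formula, rules, config.rule_depth, parent.name)
            k = int(rng.integers(config.metabolites_per_parent[0], config.metabolites_per_parent[1] + 1))
            k = min(k, len(candidates))
            chosen_idx = rng.choice(len(candidates), size=k, replace=False)
            for j, ci in enumerate(sorted(chosen_idx)):
                cand: PredictedMetabolite = candidates[ci]
                if not 70 <= cand.mz <= 1000:
                    continue
                met_rt = float(np.round(np.clip(parent.rt + rng.normal(0, 1.0), 0.3, 14.0), 2))
                met_id = f"{fid}_M{j + 1}"
                chain_names = " + ".join(r.name for r in cand.chain.rules)
                mspec = _child_spectrum(
                    rng, pspec, cand.mz, config.shared_fragment_fraction,
                    int(rng.integers(*config.fragment_count)), met_id, met_rt,
                )
                treat = _intensities(rng, config.intensity_location, config.intensity_scale, config.replicate_cv, config.replicates)
                blank = _intensities(rng, config.blank_location, config.blank_scale, config.replicate_cv, config.blanks)
                add_feature(met_id, cand.mz, met_rt, treat, blank, mspec, "metabolite",
                            parent=parent.name, chain=chain_names,
                            formula=cand.formula.hill() if cand.formula else "")
                own_run.append(replace(mspec, name=f"{met_id}_parent_only"))
            parent_only[parent.name] = own_run

        # Decoy features: blank-level intensity in both arms, at m/z values
        # kept away (>= 50 ppm) from every candidate of the mixture's parents.
        candidate_mzs = np.array(
            [c.mz for p in members for c in predict_candidates(p.formula, rules, config.rule_depth)]
            + [adduct_mz(p.formula) for p in members]
        )
        n_decoys = 0
        while n_decoys < config.decoy_feature_count:
            mz = float(rng.uniform(70.0, 1000.0))
            if np.min(np.abs(mz - candidate_mzs)) / mz * 1e6 < 50:
                continue
            n_decoys += 1
            did = f"{mixture_id}_D{n_decoys:02d}"
            rt = float(np.round(rng.uniform(0.3, 14.0), 2))
            # one shared base abundance: decoys sit at blank level in both arms
            base = rng.lognormal(config.blank_location, config.blank_scale)
            treat = np.round(base * rng.lognormal(0.0, config.replicate_cv, config.replicates), 1)
            blank = np.round(base * rng.lognormal(0.0, config.replicate_cv, config.blanks), 1)
            add_feature(did, mz, rt, treat, blank,
                        _spectrum(rng, mz, int(rng.integers(*config.fragment_count)), did, rt),
                        "decoy")

        features = pd.DataFrame(feat_rows).set_index("id")
        intensities = pd.DataFrame(
            np.vstack(inten_rows), index=features.index, columns=treatment_cols + blank_cols
        )
        roles = {c: "treatment" for c in treatment_cols}
        roles.update({c: "blank" for c in blank_cols})
        mixtures.append(
            MixtureData(mixture_id, [p.name for p in members],
                        FeatureTable(features, intensities, roles), spectra, parent_spectra)
        )

    manifest = pd.DataFrame(manifest_rows)
    return S9Dataset(list(library), mixtures, parent_only, manifest)


@dataclass(frozen=True)
class RecoveryReport:
    """Pipeline performance against the planted ground truth."""

    n_planted: int
    n_recovered: int
    n_false_positives: int
    n_decoys: int
    n_decoys_accepted: int
    recall: float
    precision: float
    decoy_fpr: float
    stage_counts: Tuple[Tuple[str, int], ...] = ()


def end_to_end_recovery(
    config: SimulationConfig,
    dataset: Optional[S9Dataset] = None,
    use_rescue: bool = True,
) -> RecoveryReport:
    """Run the full discovery pipeline on a synthetic experiment and score
    it against the manifest.

    Every accepted feature that is not a planted metabolite counts as a
    false positive — nothing is silently dropped from the accounting.
    """
    from .pipeline import NtaParams, run_nta

    if dataset is None:
        dataset = simulate_s9_dataset(config)
    params = NtaParams(rule_depth=config.rule_depth, use_rescue=use_rescue)

    planted = set(
        dataset.manifest.loc[dataset.manifest["kind"] == "metabolite", "feature_id"]
    )
    decoys = set(dataset.manifest.loc[dataset.manifest["kind"] == "decoy", "feature_id"])

    recovered: set = set()
    stage_totals: Dict[str, int] = {}
    for mixture in dataset.mixtures:
        members = [p for p in dataset.library if p.name in mixture.parents]
        result = run_nta(
            mixture.feature_table,
            mixture.spectra,
            members,
            mixture.parent_spectra,
            dataset.parent_only_spectra,
            params,
        )
        recovered |= {r.feature_id for r in result.accepted}
        for stage, count in result.stage_counts:
            stage_totals[stage] = stage_totals.get(stage, 0) + count

    true_hits = recovered & planted
    false_hits = recovered - planted
    return RecoveryReport(
        n_planted=len(planted),
        n_recovered=len(true_hits),
        n_false_positives=len(false_hits),
        n_decoys=len(decoys),
        n_decoys_accepted=len(recovered & decoys),
        recall=len(true_hits) / len(planted) if planted else 0.0,
        precision=len(true_hits) / len(recovered) if recovered else 1.0,
        decoy_fpr=len(recovered & decoys) / len(decoys) if decoys else 0.0,
        stage_counts=tuple(sorted(stage_totals.items())),
    )
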