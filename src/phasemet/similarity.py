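"""MS2 spectral similarity between a candidate metabolite and its parent.

Two scores are computed over greedily aligned fragment peaks: the cosine of
the aligned intensity vectors (the default decision score) and a spectral
entropy similarity, 1 - (2*S_AB - S_A - S_B)/ln 4, where S_X is the Shannon
entropy of a spectrum's probability-normalized intensities and S_AB that of
the merged spectrum.  Both are symmetric, live in [0, 1], equal 1 on
self-comparison and are invariant to uniform intensity rescaling.

Candidates scoring >= 0.4 are accepted outright; lower scorers are not
discarded but re-examined in the S9 run of the parent compound alone
(metabolites need not resemble their parent, and spectrum noise depresses
scores), and survive if the precursor shows MS2 signal there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "FragmentSpectrum",
    "AlignmentParams",
    "SimilarityDecision",
    "align_peaks",
    "similarity_score",
    "entropy_similarity",
    "classify_candidate",
    "verify_in_parent_sample",
]

SIMILARITY_THRESHOLD = 0.4


class EmptySpectrumError(ValueError):
    """Spectrum has no peaks left after noise filtering."""


@dataclass(frozen=True)
class FragmentSpectrum:
    """A centroided MS2 peak list for one precursor."""

    precursor_mz: float
    peaks: Tuple[Tuple[float, float], ...]
    name: str = ""
    rt: Optional[float] = None

    def __post_init__(self) -> None:
        peaks = tuple(
            (float(mz), float(i)) for mz, i in sorted(self.peaks, key=lambda p: p[0])
        )
        if any(i < 0 for _, i in peaks):
            raise ValueError("fragment intensities must be non-negative")
        object.__setattr__(self, "peaks", peaks)

    @property
    def mzs(self) -> np.ndarray:
        return np.array([mz for mz, _ in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])

    def base_peak(self) -> float:
        return float(self.intensities.max()) if self.peaks else 0.0

    def denoised(self, noise_floor: float) -> "FragmentSpectrum":
        """Drop peaks below ``noise_floor`` (a fraction of the base peak)."""
        if not self.peaks:
            return self
        cut = noise_floor * self.base_peak()
        kept = tuple(p for p in self.peaks if p[1] > cut or noise_floor == 0)
        return FragmentSpectrum(self.precursor_mz, kept, self.name, self.rt)


@dataclass(frozen=True)
class AlignmentParams:
    """Fragment alignment settings.

    ``fragment_tol`` is in Da by default (``tol_unit="ppm"`` switches to
    parts-per-million of the fragment m/z); ``noise_floor`` removes peaks
    below that fraction of the base peak before scoring.
    """

    fragment_tol: float = 0.01
    tol_unit: str = "da"
    noise_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.fragment_tol <= 0:
            raise ValueError("fragment tolerance must be positive")
        if not 0 <= self.noise_floor < 1:
            raise ValueError("noise floor must be in [0, 1)")
        if self.tol_unit not in ("da", "ppm"):
            raise ValueError("tol_unit must be 'da' or 'ppm'")

    def within(self, mz1: float, mz2: float) -> bool:
        if self.tol_unit == "ppm":
            return abs(mz1 - mz2) <= self.fragment_tol * 1e-6 * min(mz1, mz2)
        return abs(mz1 - mz2) <= self.fragment_tol


def align_peaks(
    s1: FragmentSpectrum,
    s2: FragmentSpectrum,
    params: AlignmentParams = AlignmentParams(),
) -> Tuple[np.ndarray, np.ndarray]:
    """Greedy nearest-match peak alignment.

    Peaks of the two noise-filtered, base-peak-normalized (to 100) spectra
    are placed on the union of fragment bins: cross-spectrum pairs within
    ``fragment_tol`` are matched greedily by ascending m/z difference, each
    peak used at most once; unmatched peaks occupy their own bin with a
    zero entry for the other spectrum.  Returns the two aligned intensity
    vectors.
    """
    a = s1.denoised(params.noise_floor)
    b = s2.denoised(params.noise_floor)
    if not a.peaks or a.base_peak() == 0 or not b.peaks or b.base_peak() == 0:
        raise EmptySpectrumError("spectrum empty after noise filtering")

    ia = 100.0 * a.intensities / a.base_peak()
    ib = 100.0 * b.intensities / b.base_peak()
    mza, mzb = a.mzs, b.mzs

    pairs = [
        (abs(mza[i] - mzb[j]), i, j)
        for i in range(len(mza))
        for j in range(len(mzb))
        if params.within(mza[i], mzb[j])
    ]
    pairs.sort()
    used_a: set = set()
    used_b: set = set()
    matched: List[Tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j))

    va: List[float] = []
    vb: List[float] = []
    for i, j in matched:
        va.append(ia[i])
        vb.append(ib[j])
    for i in range(len(mza)):
        if i not in used_a:
            va.append(ia[i])
            vb.append(0.0)
    for j in range(len(mzb)):
        if j not in used_b:
            va.append(0.0)
            vb.append(ib[j])
    return np.array(va), np.array(vb)


def similarity_score(
    s1: FragmentSpectrum,
    s2: FragmentSpectrum,
    params: AlignmentParams = AlignmentParams(),
) -> float:
    """Cosine similarity of the aligned intensity vectors, in [0, 1]."""
    va, vb = align_peaks(s1, s2, params)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(np.dot(va, vb) / (na * nb), 0.0, 1.0))


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def entropy_similarity(
    s1: FragmentSpectrum,
    s2: FragmentSpectrum,
    params: AlignmentParams = AlignmentParams(),
) -> float:
    """Spectral entropy similarity of the aligned spectra, in [0, 1]."""
    va, vb = align_peaks(s1, s2, params)
    if va.sum() == 0 or vb.sum() == 0:
        return 0.0
    pa = va / va.sum()
    pb = vb / vb.sum()
    s_a = _shannon(pa)
    s_b = _shannon(pb)
    s_ab = _shannon((pa + pb) / 2.0)
    score = 1.0 - (2.0 * s_ab - s_a - s_b) / math.log(4.0)
    return float(np.clip(score, 0.0, 1.0))


@dataclass(frozen=True)
class SimilarityDecision:
    """Outcome of the 0.4-threshold rule for one candidate."""

    score: float
    method: str = "peak-alignment"
    verdict: str = "accepted"


def classify_candidate(
    score: float, threshold: float = SIMILARITY_THRESHOLD, method: str = "peak-alignment"
) -> SimilarityDecision:
    """Accept at score >= threshold (closed); otherwise route the candidate
    to parent-only-sample verification."""
    if not 0 <= score <= 1:
        raise ValueError("score must be in [0, 1]")
    verdict = "accepted" if score >= threshold else "needs_parent_verification"
    return SimilarityDecision(float(score), method, verdict)


def verify_in_parent_sample(
    candidate_mz: float,
    candidate_rt: Optional[float],
    parent_sample_spectra: Optional[Sequence[FragmentSpectrum]],
    tol_ppm: float = 10.0,
    rt_window: float = 0.2,
    noise_floor: float = 0.01,
) -> str:
    """Rescue path for low-similarity candidates.

    Confirmed iff the individual-parent S9 run contains a precursor within
    ``tol_ppm`` (and within ``rt_window`` minutes when both retention times
    are known) with any MS2 signal above the noise floor; otherwise
    rejected.  With no parent-only data the candidate is left unresolved.
    """
    if parent_sample_spectra is None:
        return "unresolved"
    for spec in parent_sample_spectra:
        if abs(spec.precursor_mz - candidate_mz) > tol_ppm * 1e-6 * candidate_mz:
            continue
        if (
            candidate_rt is not None
            and spec.rt is not None
            and abs(spec.rt - candidate_rt) > rt_window
        ):
            continue
        if spec.denoised(noise_floor).peaks:
            return "confirmed_by_parent_sample"
    return "rejected"
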