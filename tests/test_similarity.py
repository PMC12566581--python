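"""MS2 similarity scores, the 0.4 rule, and the parent-sample rescue path."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phasemet import (
    AlignmentParams,
    FragmentSpectrum,
    align_peaks,
    classify_candidate,
    entropy_similarity,
    similarity_score,
    verify_in_parent_sample,
)
from phasemet.similarity import EmptySpectrumError

NOFLOOR = AlignmentParams(noise_floor=0.0)

spectra = st.lists(
    st.tuples(
        st.floats(min_value=50, max_value=500),
        st.floats(min_value=1.0, max_value=100.0),
    ),
    min_size=1,
    max_size=12,
).map(lambda peaks: FragmentSpectrum(600.0, tuple(peaks)))


class TestAlignPeaks:
    def test_identical_spectra_align_fully(self):
        s = FragmentSpectrum(300.0, ((100.0, 50.0), (150.0, 100.0), (200.0, 10.0)))
        va, vb = align_peaks(s, s, NOFLOOR)
        assert np.allclose(va, vb) and len(va) == 3

    def test_disjoint_spectra_have_orthogonal_support(self):
        s1 = FragmentSpectrum(300.0, ((100.0, 50.0), (150.0, 100.0)))
        s2 = FragmentSpectrum(300.0, ((120.0, 50.0), (170.0, 100.0)))
        va, vb = align_peaks(s1, s2, NOFLOOR)
        assert np.all((va == 0) | (vb == 0)) and len(va) == 4

    def test_tolerance_window_shares_bin(self):
        s1 = FragmentSpectrum(300.0, ((100.000, 100.0),))
        s2 = FragmentSpectrum(300.0, ((100.005, 100.0),))
        va, vb = align_peaks(s1, s2, AlignmentParams(fragment_tol=0.01, noise_floor=0))
        assert len(va) == 1 and va[0] == vb[0] == 100.0

    def test_each_peak_used_once(self):
        # two close peaks in s1, one in s2: only the nearest pairs up
        s1 = FragmentSpectrum(300.0, ((100.000, 80.0), (100.004, 100.0)))
        s2 = FragmentSpectrum(300.0, ((100.005, 100.0),))
        va, vb = align_peaks(s1, s2, AlignmentParams(fragment_tol=0.01, noise_floor=0))
        assert len(va) == 2
        assert sorted(zip(va, vb)) == [(80.0, 0.0), (100.0, 100.0)]

    def test_empty_after_noise_filter_raises(self):
        s = FragmentSpectrum(300.0, ((100.0, 0.0),))
        with pytest.raises(EmptySpectrumError):
            align_peaks(s, s, NOFLOOR)


class TestCosine:
    def test_self_score_is_one(self):
        s = FragmentSpectrum(300.0, ((100.0, 50.0), (150.0, 100.0)))
        assert similarity_score(s, s, NOFLOOR) == pytest.approx(1.0)

    def test_disjoint_score_is_zero(self):
        s1 = FragmentSpectrum(300.0, ((100.0, 50.0),))
        s2 = FragmentSpectrum(300.0, ((200.0, 50.0),))
        assert similarity_score(s1, s2, NOFLOOR) == 0.0

    def test_hand_computed_two_vector_cosine(self):
        # vectors (100, 50) vs (100, 0): 100*100 / (sqrt(12500)*100) = 0.8944
        s1 = FragmentSpectrum(300.0, ((100.0, 100.0), (200.0, 50.0)))
        s2 = FragmentSpectrum(300.0, ((100.0, 100.0),))
        assert similarity_score(s1, s2, NOFLOOR) == pytest.approx(0.894427, abs=1e-5)

    def test_agrees_with_matchms_cosine(self):
        """Independent cross-check against the reference implementation."""
        from matchms import Spectrum
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(3)
        for _ in range(10):
            mz1 = np.sort(rng.uniform(50, 500, 8))
            mz2 = np.sort(np.concatenate([mz1[:4], rng.uniform(50, 500, 4)]))
            i1, i2 = rng.uniform(10, 100, 8), rng.uniform(10, 100, 8)
            ours = similarity_score(
                FragmentSpectrum(600.0, tuple(zip(mz1, i1))),
                FragmentSpectrum(600.0, tuple(zip(mz2, i2))),
                NOFLOOR,
            )
            theirs = CosineGreedy(tolerance=0.01).pair(
                Spectrum(mz=mz1, intensities=i1, metadata_harmonization=False),
                Spectrum(mz=mz2, intensities=i2, metadata_harmonization=False),
            )
            assert ours == pytest.approx(float(theirs["score"]), abs=1e-6)


class TestEntropy:
    def test_self_score_is_one(self):
        s = FragmentSpectrum(300.0, ((100.0, 50.0), (150.0, 100.0)))
        assert entropy_similarity(s, s, NOFLOOR) == pytest.approx(1.0)

    def test_disjoint_single_peaks_score_zero(self):
        s1 = FragmentSpectrum(300.0, ((100.0, 80.0),))
        s2 = FragmentSpectrum(300.0, ((200.0, 80.0),))
        assert entropy_similarity(s1, s2, NOFLOOR) == pytest.approx(0.0, abs=1e-12)

    @given(spectra, spectra)
    def test_symmetric_and_bounded(self, s1, s2):
        try:
            a = entropy_similarity(s1, s2, NOFLOOR)
            b = entropy_similarity(s2, s1, NOFLOOR)
        except EmptySpectrumError:
            return
        assert 0 <= a <= 1 and a == pytest.approx(b, abs=1e-9)


@given(spectra, spectra, st.floats(min_value=0.1, max_value=10.0))
def test_scores_invariant_to_uniform_rescaling(s1, s2, factor):
    scaled = FragmentSpectrum(s2.precursor_mz, tuple((mz, i * factor) for mz, i in s2.peaks))
    assert similarity_score(s1, s2, NOFLOOR) == pytest.approx(
        similarity_score(s1, scaled, NOFLOOR), abs=1e-9
    )
    assert entropy_similarity(s1, s2, NOFLOOR) == pytest.approx(
        entropy_similarity(s1, scaled, NOFLOOR), abs=1e-9
    )


@given(spectra, spectra)
def test_cosine_symmetric_and_bounded(s1, s2):
    a = similarity_score(s1, s2, NOFLOOR)
    assert 0 <= a <= 1
    assert a == pytest.approx(similarity_score(s2, s1, NOFLOOR), abs=1e-9)


def test_subthreshold_noise_peaks_do_not_change_scores():
    params = AlignmentParams(noise_floor=0.01)
    s1 = FragmentSpectrum(300.0, ((100.0, 100.0), (150.0, 40.0)))
    s2 = FragmentSpectrum(300.0, ((100.0, 90.0), (170.0, 30.0)))
    noisy = FragmentSpectrum(
        300.0, s2.peaks + tuple((mz, 0.5) for mz in (111.0, 122.0, 133.0))
    )
    assert similarity_score(s1, noisy, params) == pytest.approx(
        similarity_score(s1, s2, params)
    )
    assert entropy_similarity(s1, noisy, params) == pytest.approx(
        entropy_similarity(s1, s2, params)
    )


def test_cosine_nondecreasing_in_shared_fraction():
    """More shared parent fragments never lowers the cosine score."""
    rng = np.random.default_rng(5)
    parent_peaks = tuple(zip(np.sort(rng.uniform(50, 280, 10)), rng.uniform(20, 100, 10)))
    parent = FragmentSpectrum(300.0, parent_peaks)
    scores = []
    for k in range(0, 11, 2):
        shared = parent_peaks[:k]
        novel = tuple(zip(rng.uniform(300, 500, 10 - k), rng.uniform(20, 100, 10 - k)))
        child = FragmentSpectrum(300.0, shared + novel)
        scores.append(similarity_score(parent, child, NOFLOOR))
    assert scores == sorted(scores)


class TestClassify:
    @pytest.mark.parametrize(
        "score, verdict",
        [
            (0.40, "accepted"),
            (0.39, "needs_parent_verification"),
            (1.0, "accepted"),
            (0.0, "needs_parent_verification"),
        ],
    )
    def test_threshold_closed_at_point_four(self, score, verdict):
        assert classify_candidate(score).verdict == verdict

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            classify_candidate(1.2)


class TestParentSampleRescue:
    def _spectra(self):
        return [FragmentSpectrum(204.1053, ((100.0, 50.0),), rt=6.4)]

    def test_present_confirms(self):
        assert (
            verify_in_parent_sample(204.1053, 6.45, self._spectra())
            == "confirmed_by_parent_sample"
        )

    def test_absent_rejects(self):
        assert verify_in_parent_sample(500.0, 6.45, self._spectra()) == "rejected"

    def test_rt_window_enforced(self):
        assert verify_in_parent_sample(204.1053, 9.0, self._spectra()) == "rejected"

    def test_no_data_unresolved(self):
        assert verify_in_parent_sample(204.1053, 6.45, None) == "unresolved"
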