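"""Blank-based significance filter: the four criteria and their conjunction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phasemet import (
    FeatureTable,
    SignificanceThresholds,
    blank_t_test,
    filter_significant,
    fold_change,
    presence_fraction,
    signal_to_noise,
)


class TestPresence:
    def test_partial(self, simple_table):
        assert presence_fraction("f2", simple_table) == pytest.approx(2 / 3)

    def test_all_nonzero(self, simple_table):
        assert presence_fraction("f1", simple_table) == 1.0

    def test_all_zero(self):
        features = pd.DataFrame({"mz": [100.0], "rt": [1.0]}, index=["f"])
        intensities = pd.DataFrame(
            {"rep_1": [0.0], "rep_2": [0.0], "blank_1": [5.0], "blank_2": [5.0]},
            index=["f"],
        )
        table = FeatureTable(features, intensities)
        assert presence_fraction("f", table) == 0.0

    def test_unknown_feature(self, simple_table):
        with pytest.raises(KeyError):
            presence_fraction("nope", simple_table)


class TestFoldChange:
    def test_direct_ratio(self):
        features = pd.DataFrame({"mz": [100.0], "rt": [1.0]}, index=["f"])
        intensities = pd.DataFrame(
            {"rep_1": [4000.0], "rep_2": [4000.0], "blank_1": [1000.0], "blank_2": [1000.0]},
            index=["f"],
        )
        assert fold_change("f", FeatureTable(features, intensities)) == pytest.approx(4.0)

    def test_pseudo_floor_engaged(self, simple_table):
        # f2 blanks are all zero: denominator floored at pseudo = 1
        assert fold_change("f2", simple_table, pseudo=1.0) == pytest.approx(1000.0)

    def test_equal_means(self):
        features = pd.DataFrame({"mz": [100.0], "rt": [1.0]}, index=["f"])
        intensities = pd.DataFrame(
            {"rep_1": [500.0], "rep_2": [500.0], "blank_1": [500.0], "blank_2": [500.0]},
            index=["f"],
        )
        assert fold_change("f", FeatureTable(features, intensities)) == pytest.approx(1.0)


class TestBlankTTest:
    def test_identical_arms_give_p_one(self):
        features = pd.DataFrame({"mz": [100.0], "rt": [1.0]}, index=["f"])
        intensities = pd.DataFrame(
            {"rep_1": [5.0], "rep_2": [7.0], "blank_1": [5.0], "blank_2": [7.0]},
            index=["f"],
        )
        p, method = blank_t_test("f", FeatureTable(features, intensities))
        assert p == 1.0 and method == "paired"

    def test_separated_arms_significant(self, simple_table):
        # paired t on (100,110,90) vs (1,2,1): t = 17.98, p = 0.00308
        p, method = blank_t_test("f1", simple_table)
        assert method == "paired"
        assert p == pytest.approx(0.0030788, abs=1e-5)

    def test_single_replicate_untestable(self):
        features = pd.DataFrame({"mz": [100.0], "rt": [1.0]}, index=["f"])
        intensities = pd.DataFrame(
            {"rep_1": [100.0], "blank_1": [1.0], "blank_2": [1.0]}, index=["f"]
        )
        p, method = blank_t_test("f", FeatureTable(features, intensities))
        assert method == "untestable" and np.isnan(p)

    def test_unequal_counts_fall_back_to_welch(self):
        features = pd.DataFrame({"mz": [100.0], "rt": [1.0]}, index=["f"])
        intensities = pd.DataFrame(
            {
                "rep_1": [100.0],
                "rep_2": [110.0],
                "rep_3": [95.0],
                "blank_1": [1.0],
                "blank_2": [2.0],
            },
            index=["f"],
        )
        p, method = blank_t_test("f", FeatureTable(features, intensities))
        assert method == "welch" and p < 0.05


def _brute_force_filter(table, th):
    """Independent criterion-by-criterion re-evaluation."""
    survivors = []
    for fid in table.features.index:
        treat = table.treatment(fid)
        blank = table.blanks(fid)
        pres = (treat > 0).sum() / len(treat) >= th.presence_fraction
        snr = signal_to_noise(fid, table, th.pseudo) >= th.snr_min
        fc = treat.mean() / max(blank.mean(), th.pseudo) > th.fc_min
        p, method = blank_t_test(fid, table)
        pv = method != "untestable" and np.isfinite(p) and p < th.p_max
        if pres and snr and fc and pv:
            survivors.append(fid)
    return survivors


@pytest.fixture
def planted_table():
    """20 features: 5 planted far above blanks, 15 at blank level."""
    rng = np.random.default_rng(11)
    ids = [f"t{i}" for i in range(5)] + [f"n{i}" for i in range(15)]
    features = pd.DataFrame(
        {"mz": rng.uniform(100, 900, 20), "rt": rng.uniform(1, 12, 20)}, index=ids
    )
    rows = []
    for i in range(20):
        if i < 5:
            base = 1e6
            treat = base * rng.lognormal(0, 0.05, 3)
            blank = rng.lognormal(np.log(100), 0.1, 3)
        else:
            base = rng.lognormal(np.log(100), 0.1)
            treat = base * rng.lognormal(0, 0.05, 3)
            blank = base * rng.lognormal(0, 0.05, 3)
        rows.append(np.concatenate([treat, blank]))
    intensities = pd.DataFrame(
        np.vstack(rows),
        index=ids,
        columns=["rep_1", "rep_2", "rep_3", "blank_1", "blank_2", "blank_3"],
    )
    return FeatureTable(features, intensities)


class TestFilterSignificant:
    def test_recovers_exactly_the_planted_features(self, planted_table):
        survivors, _ = filter_significant(planted_table)
        assert sorted(survivors) == [f"t{i}" for i in range(5)]

    def test_agrees_with_brute_force(self, planted_table, simple_table):
        th = SignificanceThresholds()
        for table in (planted_table, simple_table):
            survivors, _ = filter_significant(table, th)
            assert survivors == _brute_force_filter(table, th)

    def test_diagnostics_name_failing_criterion(self, simple_table):
        _, diag = filter_significant(simple_table)
        assert diag.loc["f3", "failed_criterion"] == "fold_change"
        assert not diag.loc["f3", "significant"]

    def test_volcano_coordinates_present(self, planted_table):
        _, diag = filter_significant(planted_table)
        assert {"log2_fold_change", "neg_log10_p"} <= set(diag.columns)
        t0 = diag.loc["t0"]
        assert t0["log2_fold_change"] == pytest.approx(np.log2(t0["fold_change"]))

    @pytest.mark.parametrize(
        "loosened",
        [
            {"presence_fraction": 0.1},
            {"snr_min": 0.5},
            {"fc_min": 1.0},
            {"p_max": 0.5},
        ],
    )
    def test_loosening_any_threshold_grows_survivors(self, planted_table, loosened):
        tight, _ = filter_significant(planted_table, SignificanceThresholds())
        loose, _ = filter_significant(
            planted_table, SignificanceThresholds(**loosened)
        )
        assert set(tight) <= set(loose)

    def test_invariant_under_column_permutation_within_role(self, planted_table):
        survivors, _ = filter_significant(planted_table)
        cols = ["rep_2", "rep_3", "rep_1", "blank_3", "blank_1", "blank_2"]
        permuted = FeatureTable(
            planted_table.features, planted_table.intensities[cols]
        )
        survivors_p, _ = filter_significant(permuted)
        assert set(survivors) == set(survivors_p)

    def test_snr_prefers_upstream_column(self, simple_table):
        features = simple_table.features.assign(snr=[50.0, 2.0, 10.0])
        table = FeatureTable(features, simple_table.intensities)
        assert signal_to_noise("f2", table) == 2.0
        survivors, diag = filter_significant(table)
        assert diag.loc["f2", "failed_criterion"] in ("presence", "snr")


def test_thresholds_validate():
    with pytest.raises(ValueError):
        SignificanceThresholds(p_max=1.5)
    with pytest.raises(ValueError):
        SignificanceThresholds(fc_min=-1)
    with pytest.raises(ValueError):
        SignificanceThresholds(mtc="bonferroni")


def test_table_requires_both_roles():
    features = pd.DataFrame({"mz": [100.0], "rt": [1.0]}, index=["f"])
    intensities = pd.DataFrame({"rep_1": [1.0], "rep_2": [2.0]}, index=["f"])
    with pytest.raises(ValueError):
        FeatureTable(features, intensities, {"rep_1": "treatment", "rep_2": "treatment"})
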