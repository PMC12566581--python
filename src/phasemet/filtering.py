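"""Blank-based significance filtering of full-scan LC-MS features.

A feature survives only if it jointly satisfies four criteria against the
experimental blanks: presence in at least half of the treatment replicates,
signal-to-noise >= 3, fold-change > 2, and a two-sided t-test p-value
< 0.05.  No multiple-testing correction is applied, deliberately, to keep
borderline metabolite candidates in play for the downstream MS2 stages.

Design choices the criteria leave open: "paired" between blanks and
treatment samples is taken as pairing by replicate index when the counts
match (Welch's unpaired test otherwise, flagged per feature); S/N uses an
upstream per-feature column when one exists, else treatment mean over blank
standard deviation with a pseudo-count floor; fold-change is the ratio of
arithmetic means with the same floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureTable",
    "SignificanceThresholds",
    "presence_fraction",
    "fold_change",
    "signal_to_noise",
    "blank_t_test",
    "filter_significant",
]

TREATMENT = "treatment"
BLANK = "blank"


@dataclass
class FeatureTable:
    """Features x samples intensity matrix with blank/treatment roles.

    ``features``: DataFrame indexed by feature id with columns
    ``mz`` and ``rt`` (minutes), optionally ``snr``.
    ``intensities``: DataFrame (same index) with one column per sample;
    missing measurements are stored as 0.
    ``roles``: sample name -> "treatment" | "blank".
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    roles: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("features and intensities must share an index")
        if not self.roles:
            self.roles = {
                c: BLANK if str(c).lower().startswith("blank") else TREATMENT
                for c in self.intensities.columns
            }
        unknown = set(self.roles.values()) - {TREATMENT, BLANK}
        if unknown:
            raise ValueError(f"unknown sample roles: {unknown}")
        if not self.treatment_columns or not self.blank_columns:
            raise ValueError("need at least one treatment and one blank sample")
        if (self.intensities.values < 0).any():
            raise ValueError("intensities must be non-negative")
        self.intensities = self.intensities.fillna(0.0).astype(float)

    @property
    def treatment_columns(self) -> List[str]:
        return [c for c in self.intensities.columns if self.roles[c] == TREATMENT]

    @property
    def blank_columns(self) -> List[str]:
        return [c for c in self.intensities.columns if self.roles[c] == BLANK]

    def treatment(self, feature_id) -> np.ndarray:
        return self._row(feature_id, self.treatment_columns)

    def blanks(self, feature_id) -> np.ndarray:
        return self._row(feature_id, self.blank_columns)

    def _row(self, feature_id, cols: List[str]) -> np.ndarray:
        if feature_id not in self.intensities.index:
            raise KeyError(f"unknown feature id {feature_id!r}")
        return self.intensities.loc[feature_id, cols].to_numpy(dtype=float)


@dataclass(frozen=True)
class SignificanceThresholds:
    """The four filter thresholds; defaults are the study settings."""

    presence_fraction: float = 0.5
    snr_min: float = 3.0
    fc_min: float = 2.0
    p_max: float = 0.05
    pseudo: float = 1.0
    mtc: str = "none"

    def __post_init__(self) -> None:
        if min(self.presence_fraction, self.snr_min, self.fc_min, self.p_max) <= 0:
            raise ValueError("thresholds must be strictly positive")
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must be in (0, 1)")
        if self.mtc != "none":
            raise ValueError("multiple-testing correction is deliberately disabled")


def presence_fraction(feature_id, table: FeatureTable) -> float:
    """Fraction of treatment replicates in which the feature was detected
    (intensity > 0); blanks are excluded from the denominator."""
    values = table.treatment(feature_id)
    return float(np.count_nonzero(values > 0) / values.size)


def fold_change(feature_id, table: FeatureTable, pseudo: float = 1.0) -> float:
    """mean(treatment) / max(mean(blank), pseudo)."""
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    return float(
        table.treatment(feature_id).mean()
        / max(table.blanks(feature_id).mean(), pseudo)
    )


def signal_to_noise(feature_id, table: FeatureTable, pseudo: float = 1.0) -> float:
    """Per-feature S/N: the upstream ``snr`` column when available, else
    treatment mean over blank standard deviation (sample SD, floored at
    ``pseudo``)."""
    if "snr" in table.features.columns:
        snr = table.features.loc[feature_id, "snr"]
        if np.isfinite(snr):
            return float(snr)
    blanks = table.blanks(feature_id)
    noise = blanks.std(ddof=1) if blanks.size > 1 else 0.0
    return float(table.treatment(feature_id).mean() / max(noise, pseudo))


def blank_t_test(feature_id, table: FeatureTable) -> Tuple[float, str]:
    """Two-sided t-test of the feature's treatment intensities against the
    blanks.

    Returns (p-value, method).  Pairing is by replicate index when the two
    arms have equal replicate counts ("paired"); otherwise Welch's unpaired
    test ("welch").  Arms with identical values give p = 1.0.  Fewer than
    two replicates in either arm make the feature untestable.
    """
    treat = table.treatment(feature_id)
    blank = table.blanks(feature_id)
    if treat.size < 2 or blank.size < 2:
        return float("nan"), "untestable"
    if treat.size == blank.size:
        diff = treat - blank
        if np.allclose(diff, 0):
            return 1.0, "paired"
        if np.allclose(diff, diff[0]):
            # constant non-zero difference: zero variance, certain difference
            return 0.0, "paired"
        return float(stats.ttest_rel(treat, blank).pvalue), "paired"
    if np.allclose(treat, treat[0]) and np.allclose(blank, blank[0]):
        return (1.0 if np.isclose(treat[0], blank[0]) else 0.0), "welch"
    return float(stats.ttest_ind(treat, blank, equal_var=False).pvalue), "welch"


def filter_significant(
    table: FeatureTable,
    thresholds: SignificanceThresholds = SignificanceThresholds(),
) -> Tuple[List, pd.DataFrame]:
    """Apply the four-criterion significance filter.

    Returns (surviving feature ids, diagnostics).  The diagnostics frame
    has one row per feature: the computed presence fraction, S/N,
    fold-change, p-value and test method, volcano coordinates
    (log2 fold-change, -log10 p), per-criterion pass flags and the name of
    the first failing criterion (empty for survivors).  Untestable features
    (too few replicates) are excluded and flagged.
    """
    rows = []
    for fid in table.features.index:
        pres = presence_fraction(fid, table)
        snr = signal_to_noise(fid, table, thresholds.pseudo)
        fc = fold_change(fid, table, thresholds.pseudo)
        p, method = blank_t_test(fid, table)
        checks = {
            "presence": pres >= thresholds.presence_fraction,
            "snr": snr >= thresholds.snr_min,
            "fold_change": fc > thresholds.fc_min,
            "p_value": bool(np.isfinite(p) and p < thresholds.p_max),
        }
        if method == "untestable":
            failed = "untestable"
        else:
            failed = next((name for name, ok in checks.items() if not ok), "")
        rows.append(
            {
                "feature_id": fid,
                "presence_fraction": pres,
                "snr": snr,
                "fold_change": fc,
                "p_value": p,
                "test_method": method,
                "log2_fold_change": float(np.log2(fc)) if fc > 0 else -np.inf,
                "neg_log10_p": float(-np.log10(p)) if np.isfinite(p) and p > 0 else np.inf,
                "pass_presence": checks["presence"],
                "pass_snr": checks["snr"],
                "pass_fold_change": checks["fold_change"],
                "pass_p_value": checks["p_value"],
                "significant": all(checks.values()) and method != "untestable",
                "failed_criterion": failed,
            }
        )
    diagnostics = pd.DataFrame(rows).set_index("feature_id")
    survivors = list(diagnostics.index[diagnostics["significant"]])
    return survivors, diagnostics
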