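"""Cohort-level co-occurrence statistics.

Cohorts are stratified by their KEAP1-NRF2-CUL3 alteration frequency
(default cut at 5%); samples are pooled within stratum and the SWI/SNF
alteration proportions of the two strata are compared with a two-proportion
z-test (pooled variance, no continuity correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alterations import (
    DEFAULT_NONSYNONYMOUS,
    DEFAULT_SWISNF_PANEL,
    NRF2_PANEL,
    alteration_frequencies,
)
from .cohort_io import CohortBundle

logger = logging.getLogger("nrf2screen")


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-proportion z-test (pooled variance, no continuity correction).

    z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)), two-sided normal p.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    phat = (x1 + x2) / (n1 + n2)
    if phat in (0.0, 1.0):
        raise ValueError("degenerate pooled proportion (0 or 1): zero variance")
    se = np.sqrt(phat * (1 - phat) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class CooccurrenceReport:
    """Stratified co-occurrence test outcome plus its own composition."""

    frequencies: pd.DataFrame  # per-cohort, from alteration_frequencies
    threshold: float
    high_cohorts: list[str]
    low_cohorts: list[str]
    pooled: dict[str, tuple[int, int]]  # stratum -> (swisnf altered, total)
    z: float | None
    p: float | None
    skipped: bool = False
    skip_reason: str = ""

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "high_cohorts": self.high_cohorts,
            "low_cohorts": self.low_cohorts,
            "pooled": {k: list(v) for k, v in self.pooled.items()},
            "z": self.z,
            "p": self.p,
            "skipped": self.skipped,
            "skip_reason": self.skip_reason,
            "frequencies": self.frequencies.to_dict(orient="records"),
        }


def cooccurrence_analysis(
    bundles: list[CohortBundle],
    swisnf_panel: tuple[str, ...] = DEFAULT_SWISNF_PANEL,
    nrf2_panel: tuple[str, ...] = NRF2_PANEL,
    threshold: float = 0.05,
    variant_classes: tuple[str, ...] = DEFAULT_NONSYNONYMOUS,
    pool_samples: bool = True,
) -> CooccurrenceReport:
    """Stratify cohorts at ``threshold`` NRF2-alteration frequency and test
    whether the high stratum carries more SWI/SNF-altered samples.

    ``pool_samples=True`` (default) pools raw sample counts within each
    stratum; the alternative compares unweighted means of cohort
    frequencies (reported, no test).
    """
    freqs = alteration_frequencies(bundles, swisnf_panel, nrf2_panel,
                                   variant_classes)
    high = freqs[freqs["frac_nrf2_altered"] >= threshold]
    low = freqs[freqs["frac_nrf2_altered"] < threshold]
    report = CooccurrenceReport(
        frequencies=freqs,
        threshold=threshold,
        high_cohorts=list(high["cohort"]),
        low_cohorts=list(low["cohort"]),
        pooled={},
        z=None, p=None,
    )
    if high.empty or low.empty:
        report.skipped = True
        report.skip_reason = (
            "all cohorts fall in one stratum; two-proportion test needs both"
        )
        logger.warning("cooccurrence_analysis: %s", report.skip_reason)
        return report
    if not pool_samples:
        report.skipped = True
        report.skip_reason = "pool_samples=False: frequencies reported, no test"
        return report
    x1 = int(high["n_swisnf_altered"].sum())
    n1 = int(high["n_samples"].sum())
    x2 = int(low["n_swisnf_altered"].sum())
    n2 = int(low["n_samples"].sum())
    report.pooled = {"high": (x1, n1), "low": (x2, n2)}
    report.z, report.p = two_proportion_z(x1, n1, x2, n2)
    return report
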