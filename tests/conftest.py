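"""Shared fixtures: synthetic cohorts and the end-to-end pipeline run.

Heavy objects (the default cohort and the full preprocessing + differential
run on it) are session-scoped so unit tests and the end-to-end recovery
tests share one computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from metacortex.differential import call_asd_metabolites, cluster_modules
from metacortex.peak_io import PeakTable, merge_modes
from metacortex.preprocess import (
    correct_order_effect,
    pmd_filter,
    upper_quartile_normalize,
)
from metacortex.synthetic_data import CohortConfig, generate_cohort


@dataclass
class Cohort:
    table: PeakTable
    meta: pd.DataFrame
    truth: pd.DataFrame  # indexed by peak_id


@dataclass
class PipelineRun:
    cohort: Cohort
    corrected: PeakTable
    drift_report: pd.DataFrame
    retained: PeakTable
    pmd_excluded: list[str]
    normalized: PeakTable
    differential: pd.DataFrame
    modules: pd.DataFrame


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """The study-condition cohort: 500 peaks, 152 samples, seed 7."""
    pos, neg, meta, truth = generate_cohort(CohortConfig(seed=7))
    return Cohort(merge_modes(pos, neg), meta, truth.set_index("peak_id"))


@pytest.fixture(scope="session")
def pipeline(default_cohort: Cohort) -> PipelineRun:
    """Full preprocessing + differential + module run on the default cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corrected, report = correct_order_effect(
            default_cohort.table, default_cohort.meta
        )
        retained, excluded = pmd_filter(corrected, default_cohort.meta)
        normalized = upper_quartile_normalize(retained)
        results = call_asd_metabolites(normalized, default_cohort.meta)
        modules, _ = cluster_modules(normalized, results, default_cohort.meta)
    return PipelineRun(
        default_cohort, corrected, report, retained, excluded,
        normalized, results, modules,
    )


@pytest.fixture(scope="session")
def drift_cohort() -> Cohort:
    """Drift-focused cohort: 200 peaks, a quarter with 2-SD linear drift."""
    cfg = CohortConfig(
        seed=11, n_peaks=200, fraction_drifted=0.25,
        fraction_asd_affected=0.0, fraction_pmd_sensitive=0.0,
        fraction_lineage_human=0.0, fraction_lineage_chimp=0.0,
    )
    pos, neg, meta, truth = generate_cohort(cfg)
    return Cohort(merge_modes(pos, neg), meta, truth.set_index("peak_id"))


@pytest.fixture(scope="session")
def null_cohort() -> Cohort:
    """Cohort with no planted effects of any kind."""
    cfg = CohortConfig(
        seed=19, fraction_asd_affected=0.0, fraction_drifted=0.0,
        fraction_pmd_sensitive=0.0, fraction_lineage_human=0.0,
        fraction_lineage_chimp=0.0,
    )
    pos, neg, meta, truth = generate_cohort(cfg)
    return Cohort(merge_modes(pos, neg), meta, truth.set_index("peak_id"))


def small_table(
    values: np.ndarray,
    mode: str = "positive",
    peak_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
    mz: np.ndarray | None = None,
    log2: bool = False,
) -> PeakTable:
    """Helper for hand-built fixture tables."""
    values = np.asarray(values, float)
    n_peaks, n_samples = values.shape
    return PeakTable(
        peak_ids=peak_ids or [f"P{i + 1:03d}" for i in range(n_peaks)],
        mode=np.full(n_peaks, mode, dtype=object),
        mz=mz if mz is not None else np.linspace(100, 900, n_peaks),
        rt=None,
        intensities=values,
        sample_ids=sample_ids or [f"S{j + 1:03d}" for j in range(n_samples)],
        log2=log2,
    )
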