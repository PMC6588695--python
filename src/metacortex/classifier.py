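"""Stability-selection classification of ASD vs control samples.

An L1-regularized logistic regression (fixed C) is fitted on many
stratified train/test subsamples of the cohort. Each metabolite's
importance is its empirical inclusion probability — the fraction of
subsamples in which it receives a nonzero coefficient — and classifier
performance is the mean ROC AUC over the held-out test sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from .exceptions import AnalysisError, ArgumentError
from .peak_io import PeakTable


@dataclass
class ClassifierConfig:
    """L1-logistic stability-selection settings (penalty is always l1)."""

    C: float = 100.0
    n_subsamples: int = 500
    test_fraction: float = 0.25
    top_k: int = 200
    seed: int = 0
    max_iter: int = 2000

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ArgumentError("C must be > 0")
        if not 0 < self.test_fraction < 1:
            raise ArgumentError("test_fraction must be in (0, 1)")
        if self.n_subsamples < 1:
            raise ArgumentError("n_subsamples must be >= 1")


@dataclass
class StabilityResult:
    """Per-peak inclusion probabilities, mean |coefficient|, and test AUCs."""

    table: pd.DataFrame          # peak_id, inclusion_probability, mean_abs_coef
    aucs: np.ndarray             # one test-set AUC per subsample
    n_convergence_failures: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))


def stability_selection(
    table: PeakTable,
    labels: np.ndarray,
    config: ClassifierConfig | None = None,
) -> StabilityResult:
    """Stability selection with L1 logistic regression.

    ``labels`` is a binary vector over the table's samples (1 = ASD).
    Per subsample: a stratified train/test split (seeded), per-peak
    z-standardization using training-fold statistics, an L1 fit at the
    configured C, the nonzero-coefficient set, and the test-set ROC AUC.
    Convergence failures are counted and reported, never dropped.
    """
    if config is None:
        config = ClassifierConfig()
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ArgumentError("labels must be binary 0/1")
    if min((y == 0).sum(), (y == 1).sum()) < 4:
        raise AnalysisError("both classes need >= 4 samples")
    x = table.log2_intensities().T  # samples x peaks

    splitter = StratifiedShuffleSplit(
        n_splits=config.n_subsamples,
        test_size=config.test_fraction,
        random_state=config.seed,
    )
    n_peaks = table.n_peaks
    inclusion = np.zeros(n_peaks)
    coef_sum = np.zeros(n_peaks)
    aucs = np.empty(config.n_subsamples)
    n_fail = 0
    for k, (tr, te) in enumerate(splitter.split(x, y)):
        mu = x[tr].mean(axis=0)
        sd = x[tr].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x_tr = (x[tr] - mu) / sd
        x_te = (x[te] - mu) / sd
        model = LogisticRegression(
            penalty="l1", C=config.C, solver="liblinear",
            max_iter=config.max_iter, random_state=config.seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(x_tr, y[tr])
            n_fail += sum(
                1 for w in caught if issubclass(w.category, ConvergenceWarning)
            )
        coefs = model.coef_.ravel()
        nonzero = coefs != 0
        inclusion += nonzero
        coef_sum += np.abs(coefs)
        scores = model.decision_function(x_te)
        if np.ptp(scores) == 0:
            aucs[k] = 0.5  # constant scores: no ranking information
        else:
            aucs[k] = roc_auc_score(y[te], scores)
    result = pd.DataFrame(
        {
            "peak_id": table.peak_ids,
            "inclusion_probability": inclusion / config.n_subsamples,
            "mean_abs_coef": coef_sum / config.n_subsamples,
        }
    )
    return StabilityResult(result, aucs, n_fail)


def rank_predictors(
    result: StabilityResult, top_k: int = 200, pad_zeros: bool = False
) -> list[str]:
    """Top-k peak ids by inclusion probability.

    Ties break by mean |coefficient|, then peak id. Peaks with zero
    inclusion probability are dropped (with a warning if that shortens the
    list) unless ``pad_zeros`` is set.
    """
    if top_k <= 0:
        raise ArgumentError("top_k must be > 0")
    t = result.table.sort_values(
        ["inclusion_probability", "mean_abs_coef", "peak_id"],
        ascending=[False, False, True],
        kind="stable",
    )
    if not pad_zeros:
        t = t[t["inclusion_probability"] > 0]
        if len(t) < top_k:
            warnings.warn(
                f"only {len(t)} peaks have nonzero inclusion probability; "
                f"returning fewer than top_k={top_k}"
            )
    return list(t["peak_id"].head(top_k))
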