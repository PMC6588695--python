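"""Confounder removal: injection-order drift, PMD-sensitive peaks, normalization.

Three steps run between raw aligned peak tables and any statistics:

1. ``correct_order_effect`` — per metabolite, the dependence of standardized
   log2 intensity on injection order is estimated with an RBF-kernel support
   vector regression (one hyperparameter set for all metabolites); the
   fitted order-effect curves are clustered with k-means and clusters that
   clearly track the measurement order are corrected (cluster-average curve
   subtracted) or discarded.
2. ``pmd_filter`` — metabolites sensitive to postmortem delay are found by
   fitting a natural cubic spline (age -> log2 intensity, 4 df) to reference
   samples with short PMD and excluding any metabolite whose prolonged-PMD
   probe samples fall outside the spline's 95% prediction band.
3. ``upper_quartile_normalize`` — per-sample scaling, within each ionization
   mode, so 75th-percentile intensities agree across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.svm import SVR

from .exceptions import AnalysisError, ArgumentError, NormalizationError, ValidationError
from .peak_io import MODES, PeakTable


@dataclass
class DriftConfig:
    """Injection-order drift correction settings.

    One SVR hyperparameter set serves all metabolites. A fitted-curve
    cluster is flagged as order-affected when its mean curve either has
    |Spearman rho| vs order >= ``discard_rho_threshold`` or a peak-to-trough
    amplitude >= ``discard_amplitude_threshold`` (standardized units) — an
    automated surrogate for visual evaluation — provided its amplitude
    exceeds ``min_flag_amplitude`` (near-flat clusters are never flagged).
    Flagged clusters are corrected by subtracting the cluster-average curve
    (``action="correct"``, default) or removed (``action="discard"``).
    """

    svr_c: float = 1.0
    svr_epsilon: float = 0.3
    svr_gamma: float | str = 1.0
    kmeans_k: int = 10
    kmeans_seed: int = 0
    discard_rho_threshold: float = 0.3
    discard_amplitude_threshold: float = 0.5
    min_flag_amplitude: float = 0.65
    action: str = "correct"

    def __post_init__(self) -> None:
        if self.kmeans_k < 2:
            raise ArgumentError("kmeans_k must be >= 2")
        if not 0 < self.discard_rho_threshold < 1:
            raise ArgumentError("discard_rho_threshold must be in (0, 1)")
        if self.action not in ("correct", "discard"):
            raise ArgumentError("action must be 'correct' or 'discard'")


@dataclass
class PmdConfig:
    """Postmortem-delay filter settings (spline df, CI level, PMD cutoff)."""

    spline_df: int = 4
    ci_level: float = 0.95
    short_pmd_max_hours: float = 1.0 / 3.0  # "< 20 min"
    probe_species: str = "macaque"

    def __post_init__(self) -> None:
        if self.spline_df < 2:
            raise ArgumentError("spline_df must be >= 2")
        if not 0 < self.ci_level < 1:
            raise ArgumentError("ci_level must be in (0, 1)")


def correct_order_effect(
    table: PeakTable,
    meta: pd.DataFrame,
    config: DriftConfig | None = None,
) -> tuple[PeakTable, pd.DataFrame]:
    """Remove measurement-order drift from a linear-scale peak table.

    Per metabolite: log2-transform, center to mean 0 and scale to SD 1; fit
    an RBF-SVR of standardized intensity vs injection order; evaluate the
    fitted curve on the common order grid. Curves are k-means clustered;
    flagged clusters (see :class:`DriftConfig`) are corrected by subtracting
    the cluster-average curve, or discarded. Corrected intensities are
    recalculated to the original magnitude scale. Returns the new table and
    a per-peak report (cluster id, flags, fitted curves).
    """
    if config is None:
        config = DriftConfig()
    if table.log2:
        raise ArgumentError("drift correction expects linear-scale intensities")
    meta_idx = meta.set_index("sample_id")
    order = meta_idx.loc[table.sample_ids, "injection_order"].to_numpy(float)
    if len(order) < 10:
        raise AnalysisError("drift correction needs at least 10 samples")
    if len(np.unique(order)) != len(order):
        raise ValidationError("injection orders must be unique")

    x = table.log2_intensities()
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant-intensity peak(s) excluded from "
            "SVR drift fitting and passed through unchanged"
        )

    grid_sort = np.argsort(order)
    t = (order - order.min()) / (order.max() - order.min())  # scaled order
    t_col = t[:, None]

    fit_idx = np.flatnonzero(~degenerate)
    curves = np.zeros((len(fit_idx), len(order)))
    for row, i in enumerate(fit_idx):
        z = (x[i] - mean[i]) / sd[i]
        svr = SVR(
            kernel="rbf", C=config.svr_c, epsilon=config.svr_epsilon,
            gamma=config.svr_gamma,
        )
        svr.fit(t_col, z)
        curves[row] = svr.predict(t_col)

    n_clusters = min(config.kmeans_k, len(fit_idx)) if len(fit_idx) else 0
    cluster_of = np.full(table.n_peaks, -1)
    flagged_clusters: set[int] = set()
    cluster_mean_curve: dict[int, np.ndarray] = {}
    if n_clusters >= 1:
        if n_clusters == 1:
            labels = np.zeros(len(fit_idx), dtype=int)
        else:
            km = KMeans(
                n_clusters=n_clusters, random_state=config.kmeans_seed, n_init=10
            )
            labels = km.fit_predict(curves[:, grid_sort])
        cluster_of[fit_idx] = labels
        order_grid = order[grid_sort]
        for c in range(n_clusters):
            mean_curve = curves[labels == c].mean(axis=0)
            cluster_mean_curve[c] = mean_curve
            amplitude = mean_curve.max() - mean_curve.min()
            if amplitude < config.min_flag_amplitude:
                continue
            rho = stats.spearmanr(mean_curve[grid_sort], order_grid).statistic
            if (
                abs(rho) >= config.discard_rho_threshold
                or amplitude >= config.discard_amplitude_threshold
            ):
                flagged_clusters.add(c)

    flagged = np.array(
        [c in flagged_clusters for c in cluster_of], dtype=bool
    )
    corrected = flagged & (config.action == "correct")
    discarded = flagged & (config.action == "discard")

    out = table.intensities.copy()
    for i in np.flatnonzero(corrected):
        z = (x[i] - mean[i]) / sd[i]
        z_corr = z - cluster_mean_curve[cluster_of[i]]
        out[i] = 2.0 ** (z_corr * sd[i] + mean[i])

    report = pd.DataFrame(
        {
            "peak_id": table.peak_ids,
            "cluster": cluster_of,
            "cluster_flagged": flagged,
            "corrected": corrected,
            "cluster_discarded": discarded,
            "degenerate": degenerate,
        }
    )
    new_table = replace(table, intensities=out)
    if discarded.any():
        new_table = new_table.subset_peaks(~discarded)
    return new_table, report


def pmd_filter(
    table: PeakTable,
    meta: pd.DataFrame,
    config: PmdConfig | None = None,
) -> tuple[PeakTable, list[str]]:
    """Exclude metabolites sensitive to postmortem delay.

    Reference samples: ``probe_species`` individuals with PMD below
    ``short_pmd_max_hours``. Probe samples: same species with longer PMD.
    Per metabolite, a natural cubic spline (``spline_df`` df) of log2
    intensity on age is fitted to the reference samples; each probe sample
    is compared against the prediction interval
    ``fit(age) +/- z(ci_level) * s * sqrt(1 + leverage)``. A metabolite is
    excluded when any probe falls strictly outside its interval. Probes
    whose age lies outside the reference age range are skipped (no
    extrapolation).
    """
    if config is None:
        config = PmdConfig()
    meta_idx = meta.set_index("sample_id")
    sub = meta_idx.loc[table.sample_ids]
    is_species = (sub["species"] == config.probe_species).to_numpy()
    pmd = sub["pmd_hours"].to_numpy(float)
    ref_cols = np.flatnonzero(is_species & (pmd <= config.short_pmd_max_hours))
    probe_cols = np.flatnonzero(is_species & (pmd > config.short_pmd_max_hours))
    if len(ref_cols) < 8:
        raise AnalysisError(
            f"need >= 8 short-PMD {config.probe_species} reference samples, "
            f"found {len(ref_cols)}"
        )
    if len(probe_cols) == 0:
        return table, []

    age = sub["age"].to_numpy(float)
    ref_age, probe_age = age[ref_cols], age[probe_cols]
    in_range = (probe_age >= ref_age.min()) & (probe_age <= ref_age.max())
    if not in_range.all():
        warnings.warn(
            f"{int((~in_range).sum())} prolonged-PMD probe(s) outside the "
            "reference age range skipped (no extrapolation)"
        )
        probe_cols = probe_cols[in_range]
        probe_age = probe_age[in_range]
    if len(probe_cols) == 0:
        return table, []

    design = dmatrix(
        "cr(age, df=df)", {"age": ref_age, "df": config.spline_df},
        return_type="dataframe",
    )
    x_ref = design.to_numpy()
    (x_probe,) = build_design_matrices(
        [design.design_info], {"age": probe_age, "df": config.spline_df}
    )
    x_probe = np.asarray(x_probe)

    xtx_inv = np.linalg.pinv(x_ref.T @ x_ref)
    hat = x_ref @ xtx_inv @ x_ref.T
    proj = x_probe @ xtx_inv @ x_ref.T            # probe predictions = proj @ y
    lev = np.einsum("ij,jk,ik->i", x_probe, xtx_inv, x_probe)
    dof = len(ref_cols) - np.trace(hat)
    zcrit = stats.norm.ppf(0.5 + config.ci_level / 2.0)

    y = table.log2_intensities()
    y_ref = y[:, ref_cols]
    y_probe = y[:, probe_cols]
    fitted = y_ref @ hat.T
    rss = ((y_ref - fitted) ** 2).sum(axis=1)
    s2 = rss / max(dof, 1.0)
    pred = y_ref @ proj.T                          # peaks x probes
    half = zcrit * np.sqrt(s2[:, None] * (1.0 + lev[None, :]))
    outside = np.abs(y_probe - pred) > half
    excluded_mask = outside.any(axis=1)
    excluded = [table.peak_ids[i] for i in np.flatnonzero(excluded_mask)]
    return table.subset_peaks(~excluded_mask), excluded


def upper_quartile_normalize(table: PeakTable) -> PeakTable:
    """Upper-quartile normalization, separately within each ionization mode.

    Per sample: divide by the 75th percentile of the sample's nonzero
    intensities in that mode, then multiply by the geometric mean of the
    per-sample quartiles so output stays near the input magnitude.
    """
    if table.log2:
        raise ArgumentError("normalization expects linear-scale intensities")
    out = table.intensities.copy()
    for mode in MODES:
        rows = np.flatnonzero(table.mode == mode)
        if len(rows) == 0:
            continue
        block = out[rows, :]
        quartiles = np.empty(table.n_samples)
        for j in range(table.n_samples):
            nz = block[:, j][block[:, j] > 0]
            if nz.size == 0:
                raise NormalizationError(
                    f"sample {table.sample_ids[j]!r} has all-zero intensities "
                    f"in {mode} mode"
                )
            quartiles[j] = np.percentile(nz, 75)
        restore = float(np.exp(np.mean(np.log(quartiles))))
        out[rows, :] = block / quartiles[None, :] * restore
    return replace(table, intensities=out)
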