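"""Age-covariate ANCOVA differential calling and temporal module clustering.

For each metabolite the best polynomial regression of log2 intensity on age
is chosen by adjusted R² on a reference group, and an F-test asks whether an
additive case/control offset improves that model. The test runs twice (each
diagnostic group as reference); p-values are Benjamini-Hochberg adjusted
within each run, and a metabolite is called ASD-related when both adjusted
values pass the threshold. Significant metabolites are clustered into
temporal modules with complete-linkage hierarchical clustering on
1 − Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .exceptions import AnalysisError, ArgumentError
from .peak_io import PeakTable


@dataclass
class DifferentialConfig:
    max_degree: int = 3
    alpha: float = 0.05
    n_modules: int = 4
    degree_tie_epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ArgumentError("alpha must be in (0, 1)")
        if self.max_degree < 1:
            raise ArgumentError("max_degree must be >= 1")


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def _poly_design(z_age: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(z_age, degree + 1, increasing=True)


def _adjusted_r2(y: np.ndarray, fitted: np.ndarray, n_params: int) -> float:
    n = len(y)
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return 0.0
    rss = ((y - fitted) ** 2).sum()
    r2 = 1.0 - rss / tss
    denom = n - n_params
    if denom <= 0:
        return -np.inf
    return 1.0 - (1.0 - r2) * (n - 1) / denom


def select_poly_degree(
    age: np.ndarray,
    y: np.ndarray,
    max_degree: int = 3,
    tie_epsilon: float = 1e-8,
) -> int:
    """Best polynomial degree for y ~ age by adjusted R².

    Age is centered and scaled before powers are constructed (conditioning);
    ties within ``tie_epsilon`` resolve to the smallest degree. The degree is
    capped so at least two residual degrees of freedom remain.
    """
    age = np.asarray(age, float)
    y = np.asarray(y, float)
    if len(age) != len(y):
        raise ArgumentError("age and y must have equal length")
    if np.ptp(age) == 0:
        raise ArgumentError("ages must not be all identical")
    cap = min(max_degree, len(y) - 2, len(np.unique(age)) - 1)
    if cap < max_degree:
        warnings.warn(
            f"polynomial degree capped at {cap} (n={len(y)} observations)"
        )
    z = _standardize(age)
    best_degree, best_score = 0, -np.inf
    for d in range(0, cap + 1):
        x = _poly_design(z, d)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        score = _adjusted_r2(y, x @ beta, d + 1)
        if score > best_score + tie_epsilon:
            best_degree, best_score = d, score
    return best_degree


def group_ancova(
    y: np.ndarray,
    age: np.ndarray,
    group: np.ndarray,
    reference: int | str,
    max_degree: int = 3,
    tie_epsilon: float = 1e-8,
) -> tuple[int, float, float, float]:
    """Nested-model F-test for an additive group offset over an age polynomial.

    The polynomial degree is chosen on the reference group's samples only;
    the null model (degree-d polynomial of standardized age) and the full
    model (null + group indicator) are then fitted on all samples. Returns
    (degree, F, p, group coefficient). F has (1, n − degree − 2) df.
    """
    y = np.asarray(y, float)
    age = np.asarray(age, float)
    group = np.asarray(group)
    ref_mask = group == reference
    if ref_mask.sum() == 0 or (~ref_mask).sum() == 0:
        raise ArgumentError("both groups must be non-empty")
    degree = select_poly_degree(
        age[ref_mask], y[ref_mask], max_degree, tie_epsilon
    )
    z = _standardize(age)
    x0 = _poly_design(z, degree)
    indicator = (~ref_mask).astype(float)  # 1 for the non-reference group
    x1 = np.column_stack([x0, indicator])
    beta0, *_ = np.linalg.lstsq(x0, y, rcond=None)
    beta1, *_ = np.linalg.lstsq(x1, y, rcond=None)
    rss0 = ((y - x0 @ beta0) ** 2).sum()
    rss1 = ((y - x1 @ beta1) ** 2).sum()
    df2 = len(y) - degree - 2
    if df2 <= 0:
        raise AnalysisError("not enough samples for the F-test")
    if rss1 <= 0:
        return degree, np.inf, 0.0, float(beta1[-1])
    f_stat = max(rss0 - rss1, 0.0) / (rss1 / df2)
    p = float(stats.f.sf(f_stat, 1, df2))
    return degree, float(f_stat), p, float(beta1[-1])


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), clipped at 1.

    NaN entries propagate as NaN with a warning; the remaining values are
    adjusted as if they were the full family.
    """
    p = np.asarray(p, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ArgumentError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() < p.size:
        warnings.warn("NaN p-values propagated as NaN q-values")
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def call_asd_metabolites(
    table: PeakTable,
    meta: pd.DataFrame,
    config: DifferentialConfig | None = None,
) -> pd.DataFrame:
    """Two-reference ANCOVA over all peaks; BH within each reference run.

    Only human samples enter. A peak is significant when its BH-adjusted
    p-value is <= alpha in both runs (control as reference and ASD as
    reference). ``effect_sign`` comes from the fitted ASD offset. Results are
    sorted by the larger of the two q-values, ties by peak id.
    """
    if config is None:
        config = DifferentialConfig()
    meta_idx = meta.set_index("sample_id")
    sub = meta_idx.loc[table.sample_ids]
    human = (sub["species"] == "human").to_numpy()
    if human.sum() < 2 * (config.max_degree + 2):
        raise AnalysisError("too few human samples for the ANCOVA")
    age = sub["age"].to_numpy(float)[human]
    group = np.array(
        ["ASD" if g == "ASD" else "control" for g in sub["group"][human]]
    )
    y_all = table.log2_intensities()[:, human]

    rows = []
    for i, peak_id in enumerate(table.peak_ids):
        y = y_all[i]
        d_c, f_c, p_c, coef_c = group_ancova(
            y, age, group, "control", config.max_degree, config.degree_tie_epsilon
        )
        d_a, f_a, p_a, _ = group_ancova(
            y, age, group, "ASD", config.max_degree, config.degree_tie_epsilon
        )
        rows.append((peak_id, d_c, f_c, p_c, d_a, f_a, p_a, coef_c))
    res = pd.DataFrame(
        rows,
        columns=[
            "peak_id",
            "degree_ref_control", "F_ref_control", "p_ref_control",
            "degree_ref_asd", "F_ref_asd", "p_ref_asd",
            "asd_offset",
        ],
    )
    res["q_ref_control"] = bh_adjust(res["p_ref_control"].to_numpy())
    res["q_ref_asd"] = bh_adjust(res["p_ref_asd"].to_numpy())
    res["q_max"] = res[["q_ref_control", "q_ref_asd"]].max(axis=1)
    res["significant"] = res["q_max"] <= config.alpha
    res["effect_sign"] = np.where(
        res["asd_offset"] >= 0, "up_in_ASD", "down_in_ASD"
    )
    return res.sort_values(["q_max", "peak_id"], kind="stable").reset_index(
        drop=True
    )


def nominal_cutoff(results: pd.DataFrame) -> float:
    """Largest nominal p among significant peaks (the run's implied cutoff)."""
    sig = results[results["significant"]]
    if sig.empty:
        return float("nan")
    return float(sig[["p_ref_control", "p_ref_asd"]].to_numpy().max())


def cluster_modules(
    table: PeakTable,
    results: pd.DataFrame,
    meta: pd.DataFrame,
    config: DifferentialConfig | None = None,
    age_grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster significant peaks into temporal modules.

    Feature vector per peak = standardized log2 intensities across all human
    samples (both groups); distance = 1 − Pearson correlation; complete
    linkage; tree cut at ``n_modules``. Returns (assignments, trajectories):
    assignments maps peak_id -> module index 1..n_modules; trajectories hold
    cubic-spline-smoothed mean ± SD standardized module profiles per group
    on a common age grid.
    """
    if config is None:
        config = DifferentialConfig()
    sig_ids = sorted(results.loc[results["significant"], "peak_id"])
    if len(sig_ids) < config.n_modules:
        raise AnalysisError(
            f"need >= {config.n_modules} significant peaks, got {len(sig_ids)}"
        )
    meta_idx = meta.set_index("sample_id")
    sub = meta_idx.loc[table.sample_ids]
    human = (sub["species"] == "human").to_numpy()
    age = sub["age"].to_numpy(float)[human]
    groups = np.array(
        ["ASD" if g == "ASD" else "control" for g in sub["group"][human]]
    )
    peak_pos = {p: i for i, p in enumerate(table.peak_ids)}
    x = table.log2_intensities()[:, human]

    feats, kept_ids = [], []
    for pid in sig_ids:
        v = x[peak_pos[pid]]
        if v.std(ddof=0) == 0:
            warnings.warn(f"zero-variance peak {pid!r} dropped from clustering")
            continue
        feats.append(_standardize(v))
        kept_ids.append(pid)
    feats = np.asarray(feats)
    corr = np.corrcoef(feats)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(z, t=config.n_modules, criterion="maxclust")
    assignments = pd.DataFrame({"peak_id": kept_ids, "module": labels})

    if age_grid is None:
        age_grid = np.linspace(age.min(), age.max(), 50)
    traj_rows = []
    for module in sorted(set(labels)):
        members = feats[labels == module]
        for grp in ("control", "ASD"):
            cols = groups == grp
            profile = members[:, cols].mean(axis=0)
            a = age[cols]
            df_spline = min(5, len(np.unique(a)) - 1)
            design = dmatrix(
                "cr(a, df=df)", {"a": a, "df": df_spline}, return_type="dataframe"
            )
            beta, *_ = np.linalg.lstsq(design.to_numpy(), profile, rcond=None)
            (grid_design,) = build_design_matrices(
                [design.design_info], {"a": age_grid, "df": df_spline}
            )
            fit = np.asarray(grid_design) @ beta
            resid_sd = float(np.std(profile - design.to_numpy() @ beta, ddof=0))
            for g_age, g_fit in zip(age_grid, fit):
                traj_rows.append((module, grp, g_age, g_fit, resid_sd))
    trajectories = pd.DataFrame(
        traj_rows, columns=["module", "group", "age", "mean", "sd"]
    )
    return assignments, trajectories
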