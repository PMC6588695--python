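"""Lineage-specificity of metabolite intensities (human vs chimpanzee).

Two callers assign each metabolite to the evolutionary lineage on which its
intensity changed, using macaque as the outgroup:

* **stringent** — the two-reference ANCOVA (species as the group factor, on
  human-equivalent ages) is run for each species pair; a human-specific
  metabolite is significant for human/chimp and human/macaque but not for
  chimp/macaque (and mirrored for chimpanzee-specific).
* **relaxed** — intensities are z-transformed across all samples pooled; a
  metabolite is human-specific when its human-macaque distance (absolute
  difference of species mean z) exceeds the chimp-macaque distance and both
  species deviate from macaque in the same direction (mirrored for
  chimpanzee-specific).

Module-level excess of human-specific over chimpanzee-specific differences
is quantified by repeated subsampling of equal numbers of samples per
species and recomputing the relaxed calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust, group_ancova
from .exceptions import AnalysisError, ArgumentError, ConfigError
from .peak_io import PeakTable

#: Rough developmental-pace ratios mapping nonhuman ages onto
#: human-equivalent years (documented package choice, configurable).
DEFAULT_AGE_SCALE = {"human": 1.0, "chimpanzee": 1.5, "macaque": 3.0}

PAIRS = (("human", "chimpanzee"), ("human", "macaque"), ("chimpanzee", "macaque"))


@dataclass
class EvolutionConfig:
    alpha: float = 0.05
    age_scale: dict = field(default_factory=lambda: dict(DEFAULT_AGE_SCALE))
    n_module_subsamples: int = 1000
    subsample_n: int = 30
    max_degree: int = 3
    controls_only: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ArgumentError("alpha must be in (0, 1)")
        if self.subsample_n < 2:
            raise ArgumentError("subsample_n must be >= 2")


def scale_ages(meta: pd.DataFrame, config: EvolutionConfig | None = None) -> pd.DataFrame:
    """Add a human-equivalent age column (species factor x age).

    Human ages are unchanged; nonhuman ages, prenatal (negative) included,
    are multiplied by the species' configured factor.
    """
    if config is None:
        config = EvolutionConfig()
    missing = set(meta["species"]) - set(config.age_scale)
    if missing:
        raise ConfigError(f"no age-scale factor for species: {sorted(missing)}")
    out = meta.copy()
    out["age_human_equivalent"] = [
        age * config.age_scale[sp] for age, sp in zip(out["age"], out["species"])
    ]
    return out


def _species_columns(
    table: PeakTable, meta: pd.DataFrame, controls_only: bool
) -> dict[str, np.ndarray]:
    meta_idx = meta.set_index("sample_id")
    sub = meta_idx.loc[table.sample_ids]
    cols: dict[str, np.ndarray] = {}
    for sp in ("human", "chimpanzee", "macaque"):
        mask = (sub["species"] == sp).to_numpy()
        if sp == "human" and controls_only:
            mask &= np.array([g == "control" for g in sub["group"]])
        cols[sp] = np.flatnonzero(mask)
    return cols


def stringent_lineage_calls(
    table: PeakTable,
    meta: pd.DataFrame,
    config: EvolutionConfig | None = None,
) -> pd.DataFrame:
    """Per-peak stringent lineage calls from three pairwise ANCOVA runs.

    Per species pair the two-reference ANCOVA runs on human-equivalent age;
    p-values are BH-adjusted within each reference run across peaks, and the
    pair is significant when both runs pass (q_pair = max of the two runs'
    q). Calls follow the human/chimp-specific rule with macaque as outgroup.
    """
    if config is None:
        config = EvolutionConfig()
    scaled = scale_ages(meta, config)
    cols = _species_columns(table, scaled, config.controls_only)
    for sp, idx in cols.items():
        if len(idx) < 8:
            raise AnalysisError(f"species {sp!r} has {len(idx)} samples; need >= 8")
    meta_idx = scaled.set_index("sample_id")
    ages_he = meta_idx.loc[table.sample_ids, "age_human_equivalent"].to_numpy(float)
    x = table.log2_intensities()

    q_pair: dict[tuple[str, str], np.ndarray] = {}
    for sp_a, sp_b in PAIRS:
        idx = np.concatenate([cols[sp_a], cols[sp_b]])
        species_vec = np.array(
            [sp_a] * len(cols[sp_a]) + [sp_b] * len(cols[sp_b])
        )
        age = ages_he[idx]
        p_a = np.empty(table.n_peaks)
        p_b = np.empty(table.n_peaks)
        for i in range(table.n_peaks):
            y = x[i, idx]
            _, _, p_a[i], _ = group_ancova(
                y, age, species_vec, sp_a, config.max_degree
            )
            _, _, p_b[i], _ = group_ancova(
                y, age, species_vec, sp_b, config.max_degree
            )
        q_pair[(sp_a, sp_b)] = np.maximum(bh_adjust(p_a), bh_adjust(p_b))

    q_hc = q_pair[("human", "chimpanzee")]
    q_hm = q_pair[("human", "macaque")]
    q_cm = q_pair[("chimpanzee", "macaque")]
    alpha = config.alpha
    calls = np.where(
        (q_hc <= alpha) & (q_hm <= alpha) & (q_cm > alpha),
        "human_specific",
        np.where(
            (q_hc <= alpha) & (q_cm <= alpha) & (q_hm > alpha),
            "chimp_specific",
            "none",
        ),
    )
    return pd.DataFrame(
        {
            "peak_id": table.peak_ids,
            "stringent": calls,
            "q_human_chimp": q_hc,
            "q_human_macaque": q_hm,
            "q_chimp_macaque": q_cm,
        }
    )


def _relaxed_calls_matrix(
    x: np.ndarray, human_cols: np.ndarray, chimp_cols: np.ndarray,
    macaque_cols: np.ndarray,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Vectorized relaxed calls on a log2 peaks x samples matrix.

    z-transform uses all provided species columns pooled, per peak.
    Returns (calls array, species-mean-z frame)."""
    pooled = np.concatenate([human_cols, chimp_cols, macaque_cols])
    sub = x[:, pooled]
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    degenerate = (sd == 0).ravel()
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / sd
    m_h = z[:, human_cols].mean(axis=1)
    m_c = z[:, chimp_cols].mean(axis=1)
    m_m = z[:, macaque_cols].mean(axis=1)
    d_h = m_h - m_m
    d_c = m_c - m_m
    same_sign = np.sign(d_h) == np.sign(d_c)
    human = (np.abs(d_h) > np.abs(d_c)) & same_sign & ~degenerate
    chimp = (np.abs(d_c) > np.abs(d_h)) & same_sign & ~degenerate
    calls = np.where(human, "human_specific", np.where(chimp, "chimp_specific", "none"))
    means = pd.DataFrame({"mean_z_human": m_h, "mean_z_chimp": m_c, "mean_z_macaque": m_m})
    return calls, means


def relaxed_lineage_calls(
    table: PeakTable,
    meta: pd.DataFrame,
    controls_only: bool = True,
) -> pd.DataFrame:
    """Per-peak relaxed lineage calls from species mean z-intensities."""
    cols = _species_columns(table, meta, controls_only)
    for sp, idx in cols.items():
        if len(idx) == 0:
            raise AnalysisError(f"species {sp!r} has no samples")
    x = table.log2_intensities()
    pooled = np.concatenate([cols["human"], cols["chimpanzee"], cols["macaque"]])
    degenerate = x[:, pooled].std(axis=1, ddof=0) == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance peak(s) assigned 'none'"
        )
    calls, means = _relaxed_calls_matrix(
        x, cols["human"], cols["chimpanzee"], cols["macaque"]
    )
    out = pd.DataFrame({"peak_id": table.peak_ids, "relaxed": calls})
    return pd.concat([out, means], axis=1)


def module_specificity_ratio(
    table: PeakTable,
    meta: pd.DataFrame,
    modules: pd.DataFrame,
    config: EvolutionConfig | None = None,
) -> pd.DataFrame:
    """Distribution of human:chimp specific-call ratios per module.

    Per subsample (seeded): ``subsample_n`` samples are drawn per species
    without replacement, relaxed calls recomputed, and the ratio of
    human-specific to chimpanzee-specific counts computed per module and
    genome-wide ("all"). Zero denominators yield +inf; summaries use median
    and quartiles, which stay finite when < 25% of draws are degenerate.
    """
    if config is None:
        config = EvolutionConfig()
    cols = _species_columns(table, meta, config.controls_only)
    for sp, idx in cols.items():
        if config.subsample_n > len(idx):
            raise ArgumentError(
                f"subsample_n={config.subsample_n} exceeds {sp} sample count "
                f"({len(idx)})"
            )
    x = table.log2_intensities()
    peak_pos = {p: i for i, p in enumerate(table.peak_ids)}
    module_rows: dict[str, np.ndarray] = {
        "all": np.arange(table.n_peaks, dtype=int)
    }
    for module in sorted(modules["module"].unique()):
        ids = modules.loc[modules["module"] == module, "peak_id"]
        module_rows[f"module_{module}"] = np.array(
            [peak_pos[p] for p in ids if p in peak_pos], dtype=int
        )

    rng = np.random.default_rng(config.seed)
    rows = []
    for draw in range(config.n_module_subsamples):
        pick = {
            sp: rng.choice(idx, size=config.subsample_n, replace=False)
            for sp, idx in cols.items()
        }
        calls, _ = _relaxed_calls_matrix(
            x, pick["human"], pick["chimpanzee"], pick["macaque"]
        )
        for name, rows_idx in module_rows.items():
            sub = calls[rows_idx]
            n_h = int((sub == "human_specific").sum())
            n_c = int((sub == "chimp_specific").sum())
            ratio = np.inf if n_c == 0 else n_h / n_c
            rows.append((draw, name, n_h, n_c, ratio))
    return pd.DataFrame(
        rows, columns=["draw", "category", "n_human", "n_chimp", "ratio"]
    )


def summarize_ratios(ratios: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of the subsampled ratios per category."""
    out = (
        ratios.groupby("category")["ratio"]
        .agg(
            median="median",
            q1=lambda s: float(np.percentile(s, 25)),
            q3=lambda s: float(np.percentile(s, 75)),
            n_infinite=lambda s: int(np.isinf(s).sum()),
        )
        .reset_index()
    )
    return out


def dataset_concordance(
    fc_self: pd.Series, fc_published: pd.Series
) -> tuple[float, np.ndarray, float]:
    """Agreement of human/macaque log2 fold changes across datasets.

    Returns (Pearson r over matched peaks, 2x2 sign-quadrant table,
    one-sided Fisher exact p on that table).
    """
    common = fc_self.index.intersection(fc_published.index)
    if len(common) < 3:
        raise AnalysisError(f"only {len(common)} matched peaks; need >= 3")
    a = fc_self.loc[common].to_numpy(float)
    b = fc_published.loc[common].to_numpy(float)
    r = float(stats.pearsonr(a, b).statistic)
    quad = np.array(
        [
            [int(((a > 0) & (b > 0)).sum()), int(((a > 0) & (b <= 0)).sum())],
            [int(((a <= 0) & (b > 0)).sum()), int(((a <= 0) & (b <= 0)).sum())],
        ]
    )
    _, p = stats.fisher_exact(quad, alternative="greater")
    return r, quad, float(p)


def human_macaque_log2fc(
    table: PeakTable, meta: pd.DataFrame, controls_only: bool = True
) -> pd.Series:
    """Per-peak log2 fold change of mean human vs mean macaque intensity."""
    cols = _species_columns(table, meta, controls_only)
    x = table.intensities if not table.log2 else 2.0 ** table.intensities
    mean_h = x[:, cols["human"]].mean(axis=1)
    mean_m = x[:, cols["macaque"]].mean(axis=1)
    return pd.Series(np.log2(mean_h / mean_m), index=table.peak_ids)
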