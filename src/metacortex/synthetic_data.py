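"""Synthetic cohort generator emulating the study's statistical structure.

The generator produces aligned peak tables (positive and negative ionization
modes), sample metadata, and per-peak ground truth for a four-cohort design:
human controls (n=40, ages 0-61 y), human ASD cases (n=32, ages 2-60 y),
chimpanzees (n=40, ages 0-42 y) and macaques (n=40, ages from 14 weeks
post-conception, i.e. -0.27 y, to 21 y; 38 with postmortem delay under
20 min and 2 prolonged-PMD probes at 5-6 h).

Signal model, per peak and sample, on log2 scale:

    y = baseline + trajectory(human-equivalent age)
        + ASD effect (ASD samples of affected peaks; module-shaped age
          weight x sign x effect size)
        + lineage shift (species offsets on lineage-shifted peaks, with a
          small concordant component in the sister species)
        + injection-order drift (drifted peaks)
        + PMD shift (prolonged-PMD probes of PMD-sensitive peaks)
        + Gaussian noise (homoscedastic on log2 scale)

and intensities are exponentiated to linear scale. Effect sizes are in
units of the residual noise SD. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import adduct_mz
from .evolution import DEFAULT_AGE_SCALE
from .exceptions import ConfigError
from .peak_io import PeakTable

#: Module archetypes: (trajectory shape on scaled age x in [-1, 1],
#: non-negative ASD age-weight on age in years, ASD effect sign).
#: Modules 1-2 are elevated in ASD; modules 3-4 decreased, module 3
#: predominantly during the first two decades of life. Shapes are drawn
#: from the cubic polynomial family (mutually near-orthogonal Legendre
#: terms; module 4 is anticorrelated with module 1), so age trajectories
#: stay within the model family the differential analysis assumes.
_ARCHETYPES = {
    1: (lambda x: x, lambda a: np.ones_like(a), +1),
    2: (lambda x: (3 * x**2 - 1) / 2, lambda a: np.ones_like(a), +1),
    3: (lambda x: (5 * x**3 - 3 * x) / 2, lambda a: np.exp(-np.clip(a, 0, None) / 20.0), -1),
    4: (lambda x: -x, lambda a: np.ones_like(a), -1),
}


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_control: int = 40
    n_asd: int = 32
    n_chimp: int = 40
    n_macaque: int = 40
    n_peaks: int = 500
    positive_fraction: float = 0.6
    age_range_control: tuple[float, float] = (0.0, 61.0)
    age_range_asd: tuple[float, float] = (2.0, 60.0)
    age_range_chimp: tuple[float, float] = (0.0, 42.0)
    age_range_macaque: tuple[float, float] = (-0.27, 21.0)
    fraction_asd_affected: float = 0.12
    effect_size_sd: float = 1.0
    module_trajectory_amplitude: float = 1.5
    fraction_drifted: float = 0.10
    drift_amplitude: float = 2.0
    fraction_pmd_sensitive: float = 0.04
    pmd_shift_sd: float = 5.0
    n_pmd_probes: int = 2
    fraction_lineage_human: float = 0.60
    fraction_lineage_chimp: float = 0.20
    lineage_shift_sd: float = 2.0
    sister_concordance: float = 0.1
    noise_sd: float = 0.5
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    trajectory_coef_sd: float = 0.3
    age_scale: dict = field(default_factory=lambda: dict(DEFAULT_AGE_SCALE))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_asd_affected", "fraction_drifted",
            "fraction_pmd_sensitive", "fraction_lineage_human",
            "fraction_lineage_chimp",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.fraction_lineage_human + self.fraction_lineage_chimp > 1:
            raise ConfigError("lineage fractions must sum to <= 1")
        if self.fraction_asd_affected + self.fraction_pmd_sensitive > 1:
            raise ConfigError(
                "ASD-affected and PMD-sensitive fractions must sum to <= 1 "
                "(PMD-sensitive peaks are drawn from the non-affected pool)"
            )
        if min(self.n_control, self.n_asd, self.n_chimp, self.n_macaque) < 4:
            raise ConfigError("all cohorts need >= 4 samples")
        if self.n_pmd_probes >= self.n_macaque:
            raise ConfigError("n_pmd_probes must be < n_macaque")


def _make_metadata(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []

    def cohort(prefix, n, species, group, age_lo, age_hi, pmd_lo, pmd_hi):
        ages = rng.uniform(age_lo, age_hi, n)
        pmds = rng.uniform(pmd_lo, pmd_hi, n)
        for k in range(n):
            rows.append(
                {
                    "sample_id": f"{prefix}{k + 1:03d}",
                    "species": species,
                    "group": group,
                    "age": float(ages[k]),
                    "sex": "M" if k % 2 == 0 else "F",
                    "pmd_hours": float(pmds[k]),
                    "rin": float(rng.uniform(6.0, 9.5)),
                    "batch": "batch1" if k % 2 == 0 else "batch2",
                }
            )

    cohort("HC", config.n_control, "human", "control",
           *config.age_range_control, 4.0, 30.0)
    cohort("HA", config.n_asd, "human", "ASD",
           *config.age_range_asd, 4.0, 30.0)
    cohort("CH", config.n_chimp, "chimpanzee", None,
           *config.age_range_chimp, 1.0, 10.0)
    cohort("MA", config.n_macaque, "macaque", None,
           *config.age_range_macaque, 0.05, 0.32)

    meta = pd.DataFrame(rows)
    # designate prolonged-PMD macaque probes; probe ages stay inside the
    # short-PMD reference age span so the filter never extrapolates
    mac = meta.index[meta["species"] == "macaque"].to_numpy()
    probes = rng.choice(mac, size=config.n_pmd_probes, replace=False)
    meta.loc[probes, "pmd_hours"] = rng.uniform(5.0, 6.0, config.n_pmd_probes)
    meta.loc[probes, "age"] = rng.uniform(2.0, 15.0, config.n_pmd_probes)
    meta["injection_order"] = rng.permutation(len(meta)) + 1
    return meta


def _assign_truth(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_peaks
    n_pos = int(round(n * config.positive_fraction))
    modes = np.array(["positive"] * n_pos + ["negative"] * (n - n_pos))
    peak_ids = [
        f"pos:P{i + 1:04d}" if i < n_pos else f"neg:N{i - n_pos + 1:04d}"
        for i in range(n)
    ]
    truth = pd.DataFrame({"peak_id": peak_ids, "mode": modes})
    truth["asd_affected"] = False
    truth["module"] = 0
    truth["asd_sign"] = 0
    truth["drifted"] = False
    truth["pmd_sensitive"] = False
    truth["lineage"] = "none"

    n_affected = int(round(n * config.fraction_asd_affected))
    affected = rng.choice(n, size=n_affected, replace=False)
    truth.loc[affected, "asd_affected"] = True
    for j, i in enumerate(np.sort(affected)):
        module = j % 4 + 1
        truth.loc[i, "module"] = module
        truth.loc[i, "asd_sign"] = _ARCHETYPES[module][2]

    n_drift = int(round(n * config.fraction_drifted))
    pool = np.setdiff1d(np.arange(n), [])
    drifted = rng.choice(pool, size=n_drift, replace=False)
    truth.loc[drifted, "drifted"] = True

    # PMD-sensitive peaks are disjoint from ASD-affected and drifted peaks so
    # each stage's recovery can be scored cleanly against its own truth
    n_pmd = int(round(n * config.fraction_pmd_sensitive))
    pool = np.flatnonzero(~truth["asd_affected"] & ~truth["drifted"])
    pmd = rng.choice(pool, size=n_pmd, replace=False)
    truth.loc[pmd, "pmd_sensitive"] = True

    n_lin_h = int(round(n * config.fraction_lineage_human))
    n_lin_c = int(round(n * config.fraction_lineage_chimp))
    lineage_pool = rng.permutation(n)
    truth.loc[lineage_pool[:n_lin_h], "lineage"] = "human"
    truth.loc[lineage_pool[n_lin_h:n_lin_h + n_lin_c], "lineage"] = "chimp"
    return truth


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[PeakTable, PeakTable, pd.DataFrame, pd.DataFrame]:
    """Generate (positive-mode table, negative-mode table, metadata, truth).

    Deterministic given ``config.seed``: a single PCG64 generator drives all
    draws in a fixed order (metadata, truth flags, per-peak parameters,
    noise).
    """
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng(config.seed)
    meta = _make_metadata(config, rng)
    truth = _assign_truth(config, rng)

    n_samples = len(meta)
    n = config.n_peaks
    species = meta["species"].to_numpy()
    group = np.array([g if g is not None else "NA" for g in meta["group"]])
    age = meta["age"].to_numpy(float)
    he_age = age * np.array([config.age_scale[sp] for sp in species])
    x_scaled = np.clip(he_age, -1.0, 63.0) / 32.0 - 1.0  # roughly [-1, 1]
    order_u = (meta["injection_order"].to_numpy(float) - 1) / (n_samples - 1)
    is_asd = group == "ASD"
    is_human = species == "human"
    is_chimp = species == "chimpanzee"
    pmd = meta["pmd_hours"].to_numpy(float)
    is_probe = (species == "macaque") & (pmd > 1.0 / 3.0)

    sigma = config.noise_sd
    baselines = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    mz = rng.uniform(100.0, 1200.0, n)
    rt = rng.uniform(0.5, 17.0, n)

    # per-peak draws, fixed order: trajectory coefficients, ASD weight
    # normalization, lineage sign, drift direction, then the noise matrix
    y = np.empty((n, n_samples))
    traj_coefs = rng.normal(0.0, config.trajectory_coef_sd, (n, 3))
    idio_coefs = rng.normal(0.0, 0.1, (n, 3))
    lineage_sign = rng.choice([-1.0, 1.0], n)
    drift_sign = rng.choice([-1.0, 1.0], n)
    noise = rng.normal(0.0, sigma, (n, n_samples))

    asd_ages = age[is_asd]
    for i in range(n):
        row = truth.iloc[i]
        yi = np.full(n_samples, baselines[i])
        if row["asd_affected"]:
            shape, weight, sign = _ARCHETYPES[int(row["module"])]
            base = shape(x_scaled)
            sd = base.std(ddof=0)
            if sd > 0:
                base = (base - base.mean()) / sd
            yi += config.module_trajectory_amplitude * sigma * base
            powers = np.vander(x_scaled, 4, increasing=True)[:, 1:]
            yi += powers @ idio_coefs[i]
            w = weight(age)
            w_norm = np.mean(weight(asd_ages))
            if w_norm > 0:
                w = w / w_norm
            yi += np.where(
                is_asd, sign * config.effect_size_sd * sigma * w, 0.0
            )
        else:
            powers = np.vander(x_scaled, 4, increasing=True)[:, 1:]
            yi += powers @ traj_coefs[i]
        if row["lineage"] == "human":
            delta = lineage_sign[i] * config.lineage_shift_sd * sigma
            yi += np.where(is_human, delta, 0.0)
            yi += np.where(is_chimp, config.sister_concordance * delta, 0.0)
        elif row["lineage"] == "chimp":
            delta = lineage_sign[i] * config.lineage_shift_sd * sigma
            yi += np.where(is_chimp, delta, 0.0)
            yi += np.where(is_human, config.sister_concordance * delta, 0.0)
        if row["drifted"]:
            yi += drift_sign[i] * config.drift_amplitude * sigma * (order_u - 0.5)
        if row["pmd_sensitive"]:
            yi += np.where(is_probe, config.pmd_shift_sd * sigma, 0.0)
        y[i] = yi + noise[i]

    intensities = 2.0 ** y
    sample_ids = list(meta["sample_id"])
    is_pos = (truth["mode"] == "positive").to_numpy()

    def strip(pid: str) -> str:
        return pid.split(":", 1)[1]

    pos_table = PeakTable(
        peak_ids=[strip(p) for p in truth.loc[is_pos, "peak_id"]],
        mode=np.full(int(is_pos.sum()), "positive", dtype=object),
        mz=mz[is_pos],
        rt=rt[is_pos],
        intensities=intensities[is_pos],
        sample_ids=sample_ids,
    )
    neg_table = PeakTable(
        peak_ids=[strip(p) for p in truth.loc[~is_pos, "peak_id"]],
        mode=np.full(int((~is_pos).sum()), "negative", dtype=object),
        mz=mz[~is_pos],
        rt=rt[~is_pos],
        intensities=intensities[~is_pos],
        sample_ids=sample_ids,
    )
    return pos_table, neg_table, meta, truth


# -- reference tables ---------------------------------------------------------

#: Monoisotopic masses (Da) of anchor compounds present in every generated
#: compound table.
ANCHOR_COMPOUNDS = [
    ("cmp_glucose", "D-glucose", 180.063388),
    ("cmp_gsh", "glutathione", 307.083806),
    ("cmp_gssg", "glutathione disulfide", 612.151962),
    ("cmp_oxoproline", "5-oxoproline", 129.042593),
]


def generate_reference_tables(
    n_compounds: int = 60,
    n_pathways: int = 10,
    seed: int = 0,
    planted: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (compounds, metabolite→gene, gene→pathway, gene log2FC).

    The compound table contains the anchor compounds plus random masses.
    When ``planted`` is set, the first pathway collects exactly the genes of
    the first eight compounds (an enriched-by-construction "glutathione
    metabolism"-like pathway) and those genes receive inflated |log2FC|;
    otherwise genes are spread uniformly and fold changes are all small.
    """
    rng = np.random.default_rng(seed)
    rows = list(ANCHOR_COMPOUNDS)
    for k in range(n_compounds - len(rows)):
        rows.append(
            (f"cmp_{k + 1:03d}", f"compound {k + 1}",
             float(np.round(rng.uniform(100.0, 900.0), 6)))
        )
    compounds = pd.DataFrame(
        rows, columns=["compound_id", "name", "monoisotopic_mass"]
    )
    compounds["source"] = "other"

    genes_per_compound = rng.integers(1, 4, len(compounds))
    met_gene_rows = []
    gene_counter = 0
    compound_genes: dict[str, list[str]] = {}
    for cid, k in zip(compounds["compound_id"], genes_per_compound):
        gs = []
        for _ in range(int(k)):
            if gene_counter > 0 and rng.random() < 0.2:  # shared enzymes
                gs.append(f"G{rng.integers(1, gene_counter + 1):04d}")
            else:
                gene_counter += 1
                gs.append(f"G{gene_counter:04d}")
        compound_genes[cid] = gs
        met_gene_rows += [(cid, g) for g in gs]
    met_gene = pd.DataFrame(met_gene_rows, columns=["compound_id", "gene_id"])

    all_genes = sorted(set(met_gene["gene_id"]))
    planted_compounds = list(compounds["compound_id"].iloc[:8])
    planted_genes = sorted(
        {g for c in planted_compounds for g in compound_genes[c]}
    )
    gp_rows = []
    if planted:
        for g in planted_genes:
            gp_rows.append((g, "pw_001", "glutathione-like metabolism"))
    start = 2 if planted else 1
    for p in range(start, n_pathways + 1):
        size = int(rng.integers(3, max(4, len(all_genes) // 4)))
        members = rng.choice(all_genes, size=min(size, len(all_genes)), replace=False)
        for g in members:
            gp_rows.append((g, f"pw_{p:03d}", f"pathway {p}"))
    gene_pathway = pd.DataFrame(
        gp_rows, columns=["gene_id", "pathway_id", "pathway_name"]
    )

    fc_rows = []
    for g in all_genes:
        if planted and g in planted_genes:
            fc = rng.choice([-1.0, 1.0]) * rng.normal(0.5, 0.1)
        else:
            fc = rng.normal(0.0, 0.08)
        fc_rows.append((g, float(fc)))
    gene_log2fc = pd.DataFrame(fc_rows, columns=["gene_id", "log2fc"])
    return compounds, met_gene, gene_pathway, gene_log2fc


def glutathione_mz_positive() -> float:
    """Convenience: exact [M+H] m/z of glutathione (annotation fixtures)."""
    return adduct_mz(307.083806, "[M+H]")
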