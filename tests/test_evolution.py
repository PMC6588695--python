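"""Age scaling, lineage-specificity callers, module ratios, concordance."""

import warnings

import numpy as np
import pandas as pd
import pytest

from metacortex.evolution import (
    EvolutionConfig,
    dataset_concordance,
    human_macaque_log2fc,
    module_specificity_ratio,
    relaxed_lineage_calls,
    scale_ages,
    stringent_lineage_calls,
    summarize_ratios,
)
from metacortex.exceptions import AnalysisError, ArgumentError, ConfigError
from metacortex.peak_io import PeakTable, merge_modes
from metacortex.synthetic_data import CohortConfig, generate_cohort

from conftest import small_table


def _species_meta(n_per=12):
    rows = []
    for sp, prefix in [("human", "H"), ("chimpanzee", "C"), ("macaque", "M")]:
        for k in range(n_per):
            rows.append(
                {
                    "sample_id": f"{prefix}{k:02d}",
                    "species": sp,
                    "group": "control" if sp == "human" else None,
                    "age": 1.0 + k,
                    "injection_order": len(rows) + 1,
                    "pmd_hours": 0.2,
                }
            )
    return pd.DataFrame(rows)


def _species_table(m_h, m_c, m_m, n_per=12, jitter=0.01, seed=0):
    """One peak whose species means (log2) are as requested."""
    rng = np.random.default_rng(seed)
    values = np.concatenate(
        [
            m_h + jitter * rng.standard_normal(n_per),
            m_c + jitter * rng.standard_normal(n_per),
            m_m + jitter * rng.standard_normal(n_per),
        ]
    )
    meta = _species_meta(n_per)
    table = small_table(
        values[None, :], sample_ids=list(meta["sample_id"]), log2=True
    )
    return table, meta


class TestScaleAges:
    def test_unit_factors_are_identity(self):
        meta = _species_meta()
        cfg = EvolutionConfig(age_scale={"human": 1.0, "chimpanzee": 1.0, "macaque": 1.0})
        out = scale_ages(meta, cfg)
        np.testing.assert_allclose(out["age_human_equivalent"], meta["age"])

    def test_species_factor_applied(self):
        meta = pd.DataFrame(
            [{"sample_id": "C1", "species": "chimpanzee", "group": None,
              "age": 10.0, "injection_order": 1}]
        )
        cfg = EvolutionConfig(age_scale={"chimpanzee": 1.5})
        assert scale_ages(meta, cfg)["age_human_equivalent"].iloc[0] == pytest.approx(15.0)

    def test_prenatal_age_sign_preserved(self):
        meta = pd.DataFrame(
            [{"sample_id": "M1", "species": "macaque", "group": None,
              "age": -0.10, "injection_order": 1}]
        )
        cfg = EvolutionConfig(age_scale={"macaque": 3.0})
        assert scale_ages(meta, cfg)["age_human_equivalent"].iloc[0] == pytest.approx(-0.30)

    def test_missing_factor_rejected(self):
        meta = _species_meta()
        with pytest.raises(ConfigError):
            scale_ages(meta, EvolutionConfig(age_scale={"human": 1.0}))


class TestRelaxedCalls:
    @pytest.mark.parametrize(
        "m_h,m_c,m_m,expected",
        [
            (1.0, 0.2, -0.6, "human_specific"),   # |1.6| > |0.8|, signs agree
            (0.2, 1.0, -0.6, "chimp_specific"),   # mirror case
            (0.5, 0.5, 0.5, "none"),              # zero distances
        ],
    )
    def test_rule_on_constructed_species_means(self, m_h, m_c, m_m, expected):
        table, meta = _species_table(m_h, m_c, m_m)
        calls = relaxed_lineage_calls(table, meta)
        assert calls["relaxed"].iloc[0] == expected

    def test_discordant_direction_is_none(self):
        # human far from macaque but chimpanzee moves the other way
        table, meta = _species_table(1.0, -0.4, 0.0, jitter=0.001)
        calls = relaxed_lineage_calls(table, meta)
        assert calls["relaxed"].iloc[0] == "none"

    def test_zero_variance_peak_is_none_with_warning(self):
        meta = _species_meta()
        table = small_table(
            np.full((1, len(meta)), 5.0), sample_ids=list(meta["sample_id"]), log2=True
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            calls = relaxed_lineage_calls(table, meta)
        assert calls["relaxed"].iloc[0] == "none"

    def test_affine_invariance_of_calls(self, default_cohort):
        table = default_cohort.table
        calls_a = relaxed_lineage_calls(table, default_cohort.meta)
        rng = np.random.default_rng(2)
        scale = rng.uniform(0.5, 3.0, table.n_peaks)
        x = table.log2_intensities() * scale[:, None] + rng.uniform(
            -5, 5, table.n_peaks
        )[:, None]
        transformed = PeakTable(
            peak_ids=table.peak_ids, mode=table.mode, mz=table.mz, rt=table.rt,
            intensities=x, sample_ids=table.sample_ids, log2=True,
        )
        calls_b = relaxed_lineage_calls(transformed, default_cohort.meta)
        assert (calls_a["relaxed"] == calls_b["relaxed"]).all()

    def test_label_swap_swaps_calls_exactly(self, default_cohort):
        meta = default_cohort.meta
        calls_a = relaxed_lineage_calls(
            default_cohort.table, meta, controls_only=False
        )
        swapped = meta.copy()
        swapped["species"] = swapped["species"].map(
            {"human": "chimpanzee", "chimpanzee": "human", "macaque": "macaque"}
        )
        swapped["group"] = None
        calls_b = relaxed_lineage_calls(
            default_cohort.table, swapped, controls_only=False
        )
        mapping = {
            "human_specific": "chimp_specific",
            "chimp_specific": "human_specific",
            "none": "none",
        }
        assert (calls_a["relaxed"].map(mapping) == calls_b["relaxed"]).all()


class TestStringentCalls:
    def test_planted_shifts_called_with_correct_lineage(self, default_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            calls = stringent_lineage_calls(
                default_cohort.table, default_cohort.meta
            ).set_index("peak_id")
        truth = default_cohort.truth
        human_planted = truth.index[truth["lineage"] == "human"]
        chimp_planted = truth.index[truth["lineage"] == "chimp"]
        assert (
            calls.loc[human_planted, "stringent"] == "human_specific"
        ).mean() >= 0.9
        assert (
            calls.loc[chimp_planted, "stringent"] == "chimp_specific"
        ).mean() >= 0.9
        null_peaks = truth.index[truth["lineage"] == "none"]
        assert (calls.loc[null_peaks, "stringent"] != "none").mean() <= 0.05

    def test_null_cohort_produces_no_calls(self, null_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            calls = stringent_lineage_calls(null_cohort.table, null_cohort.meta)
        assert (calls["stringent"] != "none").mean() <= 0.01

    def test_agreement_with_relaxed_on_strong_shifts(self):
        # strong terminal-branch shifts with a concordant sister component
        # far below the pairwise detection threshold
        cfg = CohortConfig(
            seed=13, n_peaks=2000, lineage_shift_sd=4.0, sister_concordance=0.10,
            fraction_lineage_human=0.025, fraction_lineage_chimp=0.0,
            fraction_asd_affected=0.0, fraction_drifted=0.0,
            fraction_pmd_sensitive=0.0,
        )
        pos, neg, meta, truth = generate_cohort(cfg)
        table = merge_modes(pos, neg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            relaxed = relaxed_lineage_calls(table, meta).set_index("peak_id")
            stringent = stringent_lineage_calls(table, meta).set_index("peak_id")
        planted = truth.set_index("peak_id")
        shifted = planted.index[planted["lineage"] == "human"]
        agree = (
            relaxed.loc[shifted, "relaxed"].to_numpy()
            == stringent.loc[shifted, "stringent"].to_numpy()
        ).mean()
        assert agree >= 0.9

    def test_insufficient_species_samples_refused(self):
        table, meta = _species_table(0.0, 0.0, 0.0, n_per=5)
        with pytest.raises(AnalysisError):
            stringent_lineage_calls(table, meta)


class TestModuleSpecificityRatio:
    def test_balanced_lineage_cohort_has_ratio_near_one(self):
        cfg = CohortConfig(
            seed=23, fraction_lineage_human=0.3, fraction_lineage_chimp=0.3,
            fraction_asd_affected=0.08,
        )
        pos, neg, meta, truth = generate_cohort(cfg)
        table = merge_modes(pos, neg)
        modules = truth[truth["asd_affected"]][["peak_id", "module"]]
        ratios = module_specificity_ratio(
            table, meta, modules,
            EvolutionConfig(seed=1, n_module_subsamples=200),
        )
        med = ratios.loc[ratios["category"] == "all", "ratio"].median()
        assert 0.5 <= med <= 2.0

    def test_default_cohort_recovers_three_to_one_excess(self, default_cohort):
        modules = default_cohort.truth.reset_index()
        modules = modules[modules["asd_affected"]][["peak_id", "module"]]
        ratios = module_specificity_ratio(
            default_cohort.table, default_cohort.meta, modules,
            EvolutionConfig(seed=7, n_module_subsamples=1000),
        )
        med = ratios.loc[ratios["category"] == "all", "ratio"].median()
        assert 2.0 <= med <= 4.5

    def test_degenerate_denominator_reported_as_inf(self):
        cfg = CohortConfig(
            seed=29, n_peaks=100, fraction_lineage_human=0.9,
            fraction_lineage_chimp=0.0, lineage_shift_sd=4.0,
            fraction_asd_affected=0.0, fraction_drifted=0.0,
            fraction_pmd_sensitive=0.0,
        )
        pos, neg, meta, truth = generate_cohort(cfg)
        table = merge_modes(pos, neg)
        modules = truth.iloc[:0][["peak_id", "module"]]
        ratios = module_specificity_ratio(
            table, meta, modules, EvolutionConfig(seed=2, n_module_subsamples=50),
        )
        sub = ratios[ratios["category"] == "all"]
        assert np.isinf(sub.loc[sub["n_chimp"] == 0, "ratio"]).all()
        summary = summarize_ratios(ratios)
        assert summary.loc[0, "median"] > 5

    def test_oversized_subsample_rejected(self, default_cohort):
        modules = default_cohort.truth.reset_index()[["peak_id", "module"]]
        with pytest.raises(ArgumentError):
            module_specificity_ratio(
                default_cohort.table, default_cohort.meta, modules,
                EvolutionConfig(subsample_n=100),
            )


class TestDatasetConcordance:
    def test_identity_gives_perfect_agreement(self):
        fc = pd.Series([0.5, -1.0, 2.0, -0.2], index=list("abcd"))
        r, quad, _ = dataset_concordance(fc, fc.copy())
        assert r == pytest.approx(1.0)
        assert quad[0, 1] == 0 and quad[1, 0] == 0

    def test_reflection_gives_negative_correlation(self):
        fc = pd.Series([0.5, -1.0, 2.0, -0.2], index=list("abcd"))
        r, _, _ = dataset_concordance(fc, -fc)
        assert r == pytest.approx(-1.0)

    def test_bivariate_normal_correlation_recovered(self):
        rng = np.random.default_rng(31)
        n = 31
        a = rng.standard_normal(n)
        b = 0.7 * a + np.sqrt(1 - 0.7**2) * rng.standard_normal(n)
        idx = [f"p{i}" for i in range(n)]
        r, _, _ = dataset_concordance(pd.Series(a, idx), pd.Series(b, idx))
        assert abs(r - 0.7) <= 0.25

    def test_too_few_matches_rejected(self):
        a = pd.Series([1.0, 2.0], index=["x", "y"])
        with pytest.raises(AnalysisError):
            dataset_concordance(a, a)

    def test_fold_changes_reflect_planted_human_shifts(self, default_cohort):
        fc = human_macaque_log2fc(default_cohort.table, default_cohort.meta)
        truth = default_cohort.truth
        shifted = truth.index[truth["lineage"] == "human"]
        null = truth.index[truth["lineage"] == "none"]
        assert fc.loc[shifted].abs().mean() > 3 * fc.loc[null].abs().mean()
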