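"""Polynomial degree selection, ANCOVA, BH adjustment, module clustering."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from metacortex.differential import (
    DifferentialConfig,
    bh_adjust,
    call_asd_metabolites,
    cluster_modules,
    group_ancova,
    select_poly_degree,
)
from metacortex.exceptions import AnalysisError, ArgumentError

from conftest import small_table


def bh_bruteforce(p):
    """Step-up definition: q(i) = min over j >= i of p(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        q[idx] = min(
            p[order[r - 1]] * m / r for r in range(rank, m + 1)
        )
    return np.clip(q, 0, 1)


class TestSelectPolyDegree:
    def test_exact_quadratic_ties_to_smallest(self):
        age = np.linspace(0, 60, 30)
        y = 2.0 - 0.5 * age + 0.01 * age**2
        assert select_poly_degree(age, y, max_degree=3) == 2

    def test_pure_noise_prefers_constant(self):
        # adjusted R^2 admits a spurious degree whenever its F exceeds 1
        # (probability ~0.32 under the null), so the constant model is the
        # modal but not near-certain choice
        rng = np.random.default_rng(12)
        age = rng.uniform(0, 61, 72)
        picks = np.array(
            [
                select_poly_degree(age, rng.normal(0, 1, 72), max_degree=3)
                for _ in range(200)
            ]
        )
        rate0 = np.mean(picks == 0)
        assert rate0 >= 0.4
        assert all(rate0 > np.mean(picks == d) for d in (1, 2, 3))

    def test_tiny_sample_caps_degree_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            d = select_poly_degree(
                np.array([1.0, 2.0, 3.0]), np.array([1.0, 4.0, 9.0]), max_degree=3
            )
        assert d <= 1

    def test_identical_ages_rejected(self):
        with pytest.raises(ArgumentError):
            select_poly_degree(np.ones(10), np.arange(10.0), 3)


class TestGroupAncova:
    def test_duplicated_groups_give_null_result(self):
        rng = np.random.default_rng(1)
        age_half = rng.uniform(0, 60, 36)
        y_half = rng.normal(0, 1, 36) + 0.02 * age_half
        age = np.concatenate([age_half, age_half])
        y = np.concatenate([y_half, y_half])
        group = np.array(["control"] * 36 + ["ASD"] * 36)
        _, f, p, coef = group_ancova(y, age, group, "control")
        assert coef == pytest.approx(0.0, abs=1e-10)
        assert f == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_offset_recovered_against_lstsq_oracle(self):
        rng = np.random.default_rng(2)
        age = rng.uniform(0, 60, 72)
        group = np.array(["control"] * 36 + ["ASD"] * 36)
        y = 1.0 + 0.5 * age + 2.0 * (group == "ASD") + rng.normal(0, 0.1, 72)
        degree, f, p, coef = group_ancova(y, age, group, "control")
        assert p < 1e-10
        assert coef == pytest.approx(2.0, abs=0.1)
        # independent oracle: direct least squares on the same design
        z = (age - age.mean()) / age.std()
        x = np.column_stack(
            [np.vander(z, degree + 1, increasing=True), group == "ASD"]
        ).astype(float)
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        assert coef == pytest.approx(beta[-1], abs=1e-9)

    def test_permutation_type_one_error(self):
        rng = np.random.default_rng(3)
        age = rng.uniform(0, 60, 72)
        group = np.array(["control"] * 36 + ["ASD"] * 36)
        y = 1.0 + 0.5 * age + 2.0 * (group == "ASD") + rng.normal(0, 0.1, 72)
        hits = 0
        n_perm = 500
        for _ in range(n_perm):
            perm = rng.permutation(group)
            _, _, p, _ = group_ancova(y, age, perm, "control")
            hits += p < 0.05
        assert abs(hits / n_perm - 0.05) < 0.03

    def test_empty_group_rejected(self):
        with pytest.raises(ArgumentError):
            group_ancova(
                np.arange(10.0),
                np.arange(10.0),
                np.array(["control"] * 10),
                "control",
            )


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])),
            [0.04, 0.04, 0.04, 0.04],
        )

    @pytest.mark.parametrize(
        "p,expected",
        [(np.ones(5), np.ones(5)), (np.array([0.3]), np.array([0.3]))],
    )
    def test_degenerate_inputs(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_nan_propagates_with_warning(self):
        with pytest.warns(UserWarning, match="NaN"):
            q = bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and not np.isnan(q[0])

    @given(st.integers(0, 2**31 - 1), st.integers(1, 40))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_stepup(self, seed, m):
        p = np.random.default_rng(seed).uniform(0, 1, m)
        np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ArgumentError):
            bh_adjust(np.array([0.1, 1.5]))


class TestCallAsdMetabolites:
    def test_planted_effects_recovered(self, pipeline):
        truth = pipeline.cohort.truth
        res = pipeline.differential
        sig = set(res.loc[res["significant"], "peak_id"])
        affected = set(truth.index[truth["asd_affected"]]) & set(
            pipeline.normalized.peak_ids
        )
        tp = len(sig & affected)
        assert tp / len(affected) >= 0.8
        assert (len(sig) - tp) / max(len(sig), 1) <= 0.1

    def test_effect_signs_match_module_direction(self, pipeline):
        truth = pipeline.cohort.truth
        res = pipeline.differential.set_index("peak_id")
        sig_affected = [
            p
            for p in truth.index[truth["asd_affected"]]
            if p in res.index and res.loc[p, "significant"]
        ]
        expected = {1: "up_in_ASD", 2: "up_in_ASD", 3: "down_in_ASD", 4: "down_in_ASD"}
        agree = np.mean(
            [
                res.loc[p, "effect_sign"] == expected[truth.loc[p, "module"]]
                for p in sig_affected
            ]
        )
        assert agree >= 0.95

    def test_null_cohort_yields_no_calls(self, null_cohort):
        res = call_asd_metabolites(null_cohort.table, null_cohort.meta)
        assert res["significant"].sum() == 0

    def test_permuted_labels_rarely_yield_calls(self, default_cohort):
        # under the global null, BH controls family-wise error at ~alpha per
        # replicate, so most replicates yield zero calls and the rest only
        # stray singletons
        meta = default_cohort.meta
        human_idx = meta.index[meta["species"] == "human"]
        counts = []
        for rep in range(20):
            rng = np.random.default_rng(500 + rep)
            shuffled = meta.copy()
            shuffled.loc[human_idx, "group"] = rng.permutation(
                meta.loc[human_idx, "group"].to_numpy()
            )
            res = call_asd_metabolites(default_cohort.table, shuffled)
            counts.append(int(res["significant"].sum()))
        assert sum(c == 0 for c in counts) >= 18
        assert max(counts) <= 2

    def test_invariant_to_peak_order(self, default_cohort):
        table = default_cohort.table
        rng = np.random.default_rng(0)
        perm = rng.permutation(table.n_peaks)
        res_a = call_asd_metabolites(table, default_cohort.meta)
        res_b = call_asd_metabolites(table.subset_peaks(perm), default_cohort.meta)
        merged = res_a.merge(res_b, on="peak_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(
            merged["p_ref_control_a"], merged["p_ref_control_b"], rtol=1e-9
        )
        assert (merged["significant_a"] == merged["significant_b"]).all()


class TestClusterModules:
    def test_anticorrelated_archetypes_split_cleanly(self):
        rng = np.random.default_rng(8)
        profile = np.sin(np.linspace(0, 3, 40))
        values = np.vstack(
            [profile + rng.normal(0, 0.01, 40) for _ in range(10)]
            + [-profile + rng.normal(0, 0.01, 40) for _ in range(10)]
        )
        table = small_table(2.0 ** (15 + values))
        meta = pd.DataFrame(
            {
                "sample_id": table.sample_ids,
                "species": "human",
                "group": ["control", "ASD"] * 20,
                "age": np.linspace(1, 60, 40),
                "injection_order": np.arange(1, 41),
                "pmd_hours": 1.0,
            }
        )
        results = pd.DataFrame(
            {"peak_id": table.peak_ids, "significant": True}
        )
        assign, _ = cluster_modules(
            table, results, meta, DifferentialConfig(n_modules=2)
        )
        labels = assign.set_index("peak_id").loc[table.peak_ids, "module"].to_numpy()
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_labels_invariant_to_peak_input_order(self, pipeline):
        table = pipeline.normalized
        rng = np.random.default_rng(1)
        perm = rng.permutation(table.n_peaks)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assign_b, _ = cluster_modules(
                table.subset_peaks(perm),
                pipeline.differential,
                pipeline.cohort.meta,
            )
        a = pipeline.modules.set_index("peak_id")["module"]
        b = assign_b.set_index("peak_id")["module"]
        assert adjusted_rand_score(a.loc[b.index], b) == 1.0

    def test_modules_recover_planted_archetypes(self, pipeline):
        truth = pipeline.cohort.truth
        merged = pipeline.modules.merge(
            truth["module"].rename("true_module"),
            left_on="peak_id",
            right_index=True,
        )
        merged = merged[merged["true_module"] > 0]
        assert adjusted_rand_score(merged["true_module"], merged["module"]) >= 0.8

    def test_too_few_significant_peaks(self, null_cohort):
        results = pd.DataFrame(
            {"peak_id": null_cohort.table.peak_ids[:2], "significant": [True, True]}
        )
        with pytest.raises(AnalysisError):
            cluster_modules(null_cohort.table, results, null_cohort.meta)
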