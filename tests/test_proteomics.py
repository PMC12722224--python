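"""Intensity-table statistics: normalization contracts, detection filter,
fold changes, solubility shifts, eigengenes, robust regression, and the
correlation network."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mataging.proteomics import (
    IntensityTable,
    correlation_network,
    detection_filter,
    filter_samples,
    fold_change_test,
    module_eigengene,
    normalize,
    robust_regression,
    solubility_shift,
    total_intensity,
    trait_correlation,
)
from mataging.synthetic_data import ProteomeParams, gen_proteome


def small_table(values: dict, fractions=None, ages=None, log2=False) -> IntensityTable:
    """Hand-built table; sample ids are the dict keys."""
    vals = pd.DataFrame(values)
    ids = list(vals.columns)
    fractions = fractions or {s: "membrane" for s in ids}
    ages = ages or {s: ("aged" if s.startswith("a") else "young") for s in ids}
    samples = pd.DataFrame(
        {
            "mouse": {s: s.split("__")[0] for s in ids},
            "age_group": ages,
            "sex": {s: "M" for s in ids},
            "region": {s: "midbrain" for s in ids},
            "fraction": fractions,
            "cognitive_status": {s: None for s in ids},
        }
    ).loc[ids]
    proteins = pd.DataFrame({"protein_class": "other"}, index=vals.index)
    return IntensityTable(vals, samples, proteins, log2=log2)


class TestNormalize:
    def test_identical_multisets_map_identically(self):
        t = small_table({"y1": [1.0, 4.0, 16.0], "y2": [16.0, 1.0, 4.0]})
        out = normalize(t)
        a = np.sort(out.values["y1"].to_numpy())
        b = np.sort(out.values["y2"].to_numpy())
        np.testing.assert_allclose(a, b)

    def test_rank_order_preserved(self, rng):
        t = small_table({f"s{i}": rng.lognormal(3, 1, 30) for i in range(4)})
        out = normalize(t)
        for s in t.values.columns:
            raw_rank = np.argsort(np.argsort(t.values[s]))
            new_rank = np.argsort(np.argsort(out.values[s]))
            np.testing.assert_array_equal(raw_rank, new_rank)

    def test_scaling_batch_effect_removed(self):
        table, _ = gen_proteome(
            ProteomeParams(n_proteins=120, planted_log2fc=0.0, dropout=0.0), seed=0
        )
        scaled = table.values.copy()
        half = scaled.columns[: len(scaled.columns) // 2]
        scaled[half] = scaled[half] * 2.0  # planted multiplicative batch
        t2 = IntensityTable(scaled, table.samples, table.proteins)
        n1 = normalize(table, per_fraction=False)
        n2 = normalize(t2, per_fraction=False)
        assert np.nanmax(np.abs(n1.values.to_numpy() - n2.values.to_numpy())) < 1e-9

    def test_idempotent_on_complete_tables(self):
        table, _ = gen_proteome(ProteomeParams(n_proteins=80, dropout=0.0), seed=1)
        once = normalize(table)
        twice = normalize(once)
        assert np.nanmax(np.abs(once.values.to_numpy() - twice.values.to_numpy())) < 1e-10

    def test_missing_entries_preserved(self):
        t = small_table({"y1": [1.0, np.nan, 16.0], "y2": [16.0, 1.0, 4.0]})
        out = normalize(t)
        assert out.values["y1"].isna().tolist() == [False, True, False]

    def test_empty_sample_raises(self):
        t = small_table({"y1": [np.nan, np.nan], "y2": [1.0, 2.0]})
        with pytest.raises(ValueError):
            normalize(t)


class TestDetectionFilter:
    def _table(self, pattern):
        vals = {f"s{i}": col for i, col in enumerate(np.array(pattern, float).T)}
        return small_table(vals)

    def test_three_of_four_retained(self):
        t = self._table([[1, 2, np.nan, 4]])
        assert len(detection_filter(t, 0.75).values) == 1

    def test_two_of_four_dropped(self):
        t = self._table([[1, np.nan, np.nan, 4]])
        assert len(detection_filter(t, 0.75).values) == 0

    def test_complete_table_unchanged(self, rng):
        t = small_table({f"s{i}": rng.uniform(1, 10, 20) for i in range(4)})
        out = detection_filter(t, 0.75)
        pd.testing.assert_frame_equal(out.values, t.values)


class TestTotalIntensity:
    def test_equal_value_across_five_fractions(self):
        from mataging.proteomics import FRACTION_ORDER

        vals = {f"m1__{f}": [8.0] for f in FRACTION_ORDER}
        t = small_table(vals, fractions={f"m1__{f}": f for f in FRACTION_ORDER})
        out = total_intensity(t)
        assert out.values.iloc[0, 0] == pytest.approx(np.log2(5 * 8.0))

    def test_single_fraction_presence(self):
        vals = {"m1__membrane": [8.0], "m1__insoluble": [np.nan]}
        t = small_table(vals, fractions={"m1__membrane": "membrane", "m1__insoluble": "insoluble"})
        assert total_intensity(t).values.iloc[0, 0] == pytest.approx(3.0)

    def test_matches_brute_force_sum(self, rng):
        table, _ = gen_proteome(ProteomeParams(n_proteins=40, dropout=0.2), seed=5)
        out = total_intensity(table)
        for sid in out.values.columns:
            mouse = out.samples.loc[sid, "mouse"]
            ids = table.samples.index[table.samples["mouse"] == mouse]
            manual = table.values[list(ids)].fillna(0.0).sum(axis=1)
            manual = np.log2(manual.where(table.values[list(ids)].notna().any(axis=1)))
            np.testing.assert_allclose(
                out.values[sid].to_numpy(), manual.to_numpy(), equal_nan=True
            )


class TestFoldChangeTest:
    def test_exact_doubling(self):
        t = small_table({"y1": [4.0], "y2": [4.0], "a1": [8.0], "a2": [8.0]})
        res = fold_change_test(t)
        assert res["fold_change"].iloc[0] == pytest.approx(2.0)
        assert res["log2_fold_change"].iloc[0] == pytest.approx(1.0)
        assert res["p_value"].iloc[0] == 0.0  # no scatter, pure offset

    def test_identical_groups(self):
        t = small_table({"y1": [4.0], "y2": [4.0], "a1": [4.0], "a2": [4.0]})
        res = fold_change_test(t)
        assert res["fold_change"].iloc[0] == pytest.approx(1.0)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_group_missing_flagged(self):
        t = small_table({"y1": [np.nan], "y2": [np.nan], "a1": [4.0], "a2": [5.0]})
        res = fold_change_test(t)
        assert np.isnan(res["fold_change"].iloc[0])

    def test_planted_effect_recovery(self):
        table, truth = gen_proteome(
            ProteomeParams(
                n_proteins=500, class_proportions={"matrisome": 1.0}, dropout=0.0,
                fractions=("membrane",), noise_sd=0.25,
            ),
            seed=11,
        )
        res = fold_change_test(table)
        assert res["log2_fold_change"].mean() == pytest.approx(1.0, abs=0.05)
        assert (res["p_value"] < 0.05).mean() >= 0.95  # power at n = 4/4

    def test_null_p_values_uniform(self):
        """Within one fraction, null p-values follow U(0, 1)."""
        table, _ = gen_proteome(
            ProteomeParams(n_proteins=2000, planted_log2fc=0.0, dropout=0.0,
                           fractions=("membrane",)),
            seed=2,
        )
        res = fold_change_test(table)
        ks = stats.kstest(res["p_value"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_bh_column_optional(self):
        t = small_table({"y1": [4.0, 1.0], "y2": [5.0, 2.0], "a1": [8.0, 1.5], "a2": [9.0, 2.5]})
        res = fold_change_test(t, bh_correct=True)
        assert "p_adj_bh" in res


class TestSolubilityShift:
    def _paired_table(self, young_diff, aged_diff, noise=0.01, n=4):
        rng = np.random.default_rng(0)
        vals, fractions = {}, {}
        for age, diff in (("young", young_diff), ("aged", aged_diff)):
            for i in range(n):
                base = 10.0 + rng.normal(0, noise)
                sid_s, sid_i = f"{age}{i}__membrane", f"{age}{i}__insoluble"
                vals[sid_s] = [2.0 ** (base + diff + rng.normal(0, noise))]
                vals[sid_i] = [2.0**base]
                fractions[sid_s] = "membrane"
                fractions[sid_i] = "insoluble"
        ages = {s: ("aged" if s.startswith("aged") else "young") for s in vals}
        return small_table(vals, fractions=fractions, ages=ages)

    def test_aged_shift_toward_soluble_detected(self):
        t = self._paired_table(young_diff=0.0, aged_diff=2.0)
        res = solubility_shift(t)
        assert res["direction"].iloc[0] == "more_soluble"
        assert res["p_value"].iloc[0] < 1e-4
        # hand-computed two-sample t-test on the per-mouse log2 differences
        young = [0.0] * 4
        aged = [2.0] * 4
        assert res["aged_log2fc"].iloc[0] == pytest.approx(2.0, abs=0.05)

    def test_identical_profiles_give_none(self):
        t = self._paired_table(young_diff=1.0, aged_diff=1.0, noise=0.05)
        assert solubility_shift(t)["direction"].iloc[0] == "none"

    def test_single_fraction_protein_excluded(self):
        vals = {"y0__insoluble": [4.0], "y1__insoluble": [5.0],
                "a0__insoluble": [4.0], "a1__insoluble": [5.0]}
        t = small_table(vals, fractions={s: "insoluble" for s in vals})
        assert len(solubility_shift(t)) == 0

    def test_false_positive_rate_near_alpha(self):
        """Exchangeable young and aged profiles classify ~alpha proteins."""
        table, _ = gen_proteome(
            ProteomeParams(n_proteins=400, planted_log2fc=0.0, dropout=0.0), seed=9
        )
        res = solubility_shift(table)
        fp = (res["direction"] != "none").mean()
        assert fp < 0.10


class TestModuleEigengene:
    def test_identical_profiles_recovered(self):
        profile = np.array([1.0, 2.0, 4.0, 8.0])
        t = small_table({f"s{i}": [profile[i]] * 3 for i in range(4)}, log2=True)
        eg = module_eigengene(t, t.values.index.tolist())
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eg.to_numpy() / np.linalg.norm(eg), z / np.linalg.norm(z), atol=1e-8)

    def test_sign_convention(self, rng):
        table, _ = gen_proteome(ProteomeParams(n_proteins=60, dropout=0.1), seed=4)
        members = table.values.index[:10].tolist()
        eg = module_eigengene(table, members)
        x = table.to_log2().values.loc[members]
        mean_profile = x.apply(lambda r: r.fillna(r.mean()), axis=1).mean(axis=0)
        assert np.corrcoef(eg, mean_profile)[0, 1] >= 0

    def test_planted_factor_recovered(self, rng):
        for seed in range(20):
            r2 = np.random.default_rng(seed)
            factor = r2.normal(0, 1, 12)
            mat = 0.8 * factor[None, :] + 0.2 * r2.normal(0, 1, (15, 12))
            t = small_table({f"s{i}": mat[:, i] for i in range(12)}, log2=True)
            eg = module_eigengene(t, t.values.index.tolist())
            assert abs(np.corrcoef(eg, factor)[0, 1]) >= 0.95

    def test_too_few_members_raises(self):
        t = small_table({"s0": [1.0, 2.0], "s1": [2.0, 3.0]})
        with pytest.raises(ValueError):
            module_eigengene(t, [t.values.index[0]])


class TestTraitCorrelation:
    def test_perfect_binary_separation(self):
        r, r2, p = trait_correlation([1.0, 1.0, 5.0, 5.0], [0, 0, 1, 1])
        assert abs(r) == pytest.approx(1.0)

    def test_orthogonal_trait(self, rng):
        vals = np.tile([1.0, -1.0], 50)
        trait = np.repeat([0, 1], 50)
        r, _, _ = trait_correlation(vals, trait)
        assert abs(r) < 1e-12

    def test_equals_pearson_with_dummy_coding(self, rng):
        vals = rng.normal(0, 1, 30)
        trait = rng.integers(0, 2, 30).astype(float)
        r, r2, p = trait_correlation(vals, trait)
        r_sp, p_sp = stats.pearsonr(vals, trait)
        assert r == pytest.approx(r_sp) and p == pytest.approx(p_sp)
        assert r2 == pytest.approx(r * r)


class TestRobustRegression:
    def test_clean_data_matches_ols(self, rng):
        x = rng.uniform(0, 10, 40)
        y = 2.0 * x + 1.0
        slope, intercept, p = robust_regression(x, y)
        assert slope == pytest.approx(2.0, abs=1e-6)
        assert intercept == pytest.approx(1.0, abs=1e-6)

    def test_constant_response(self, rng):
        x = rng.uniform(0, 10, 20)
        slope, _, _ = robust_regression(x, np.full(20, 3.0))
        assert slope == pytest.approx(0.0, abs=1e-10)

    def test_resists_gross_outliers(self, rng):
        slopes_r, slopes_ols = [], []
        for _ in range(100):
            x = rng.uniform(0, 10, 40)
            y = 2.0 * x + rng.normal(0, 0.5, 40)
            out = rng.uniform(size=40) < 0.1
            y[out] = 50.0  # gross outliers uncorrelated with the trend
            slopes_r.append(robust_regression(x, y)[0])
            slopes_ols.append(np.polyfit(x, y, 1)[0])
        assert abs(np.median(slopes_r) - 2.0) < 0.1
        assert abs(np.median(slopes_ols) - 2.0) > 0.2  # OLS is pulled by the outliers

    def test_constant_predictor_raises(self):
        with pytest.raises(ValueError):
            robust_regression(np.ones(10), np.arange(10.0))


class TestCorrelationNetwork:
    def test_duplicated_variable_gets_unit_edge(self, rng):
        x = rng.normal(0, 1, 20)
        m = pd.DataFrame([x, x, rng.normal(0, 1, 20)], index=["a", "a_copy", "b"])
        g = correlation_network(m)
        assert g["a"]["a_copy"]["weight"] == pytest.approx(1.0)

    def test_no_self_links(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (4, 15)), index=list("abcd"))
        g = correlation_network(m)
        assert all(u != v for u, v in g.edges)

    def test_independent_variables_weakly_connected(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (6, 200)))
        g = correlation_network(m)
        weights = [abs(d["weight"]) for _, _, d in g.edges(data=True)]
        assert max(weights) < 0.2

    def test_pairwise_deletion(self, rng):
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 0.1, 30)
        y[:5] = np.nan
        m = pd.DataFrame([x, y], index=["a", "b"])
        g = correlation_network(m)
        r_manual = stats.pearsonr(x[5:], y[5:])[0]
        assert g["a"]["b"]["weight"] == pytest.approx(r_manual)

    def test_isolated_variable_raises(self, rng):
        x = rng.normal(0, 1, 10)
        y = np.full(10, np.nan)
        y[0] = 1.0
        m = pd.DataFrame([x, y], index=["a", "b"])
        with pytest.raises(ValueError):
            correlation_network(m)


def test_filter_samples_subsets_metadata():
    table, _ = gen_proteome(ProteomeParams(n_proteins=10), seed=0)
    sub = filter_samples(table, fraction="membrane", age_group="young")
    assert (sub.samples["fraction"] == "membrane").all()
    assert (sub.samples["age_group"] == "young").all()
    assert list(sub.values.columns) == list(sub.samples.index)
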