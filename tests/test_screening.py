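import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methaplo.errors import ValidationError
from methaplo.io_formats import BetaMatrix
from methaplo.screening import (
    dmc_test,
    drop_high_missing_probes,
    intersect_dmcs,
    knn_impute,
    normalize,
    probe_blacklist_filter,
    restrict_to_genes,
    screen_cohorts,
)
from methaplo.simulate import simulate_beta_cohorts


def make_bm(values, groups, ann_overrides=None):
    values = pd.DataFrame(values)
    values.index = [f"cg{i}" for i in range(len(values))]
    values.index.name = "probe_id"
    values.columns = [f"s{j}" for j in range(values.shape[1])]
    n = len(values)
    ann = pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "position": np.arange(1, n + 1) * 100,
            "gene": [f"G{i}" for i in range(n)],
            "detection_flag": [0] * n,
            "bead_flag": [0] * n,
            "snp_flag": [0] * n,
            "multihit_flag": [0] * n,
            "cpg_flag": [1] * n,
        },
        index=values.index,
    )
    if ann_overrides:
        for col, vals in ann_overrides.items():
            ann[col] = vals
    return BetaMatrix(
        annotations=ann,
        values=values,
        groups=pd.Series(groups, index=values.columns, dtype=object),
    )


class TestBlacklist:
    def test_snp_flag_removed(self):
        bm = make_bm([[0.5, 0.5], [0.5, 0.5]], ["case", "control"],
                     {"snp_flag": [1, 0]})
        out = probe_blacklist_filter(bm)
        assert list(out.probe_ids) == ["cg1"]

    def test_chrx_removed(self):
        bm = make_bm([[0.5, 0.5], [0.5, 0.5]], ["case", "control"],
                     {"chrom": ["chrX", "chr1"]})
        out = probe_blacklist_filter(bm)
        assert list(out.probe_ids) == ["cg1"]

    def test_non_cpg_removed(self):
        bm = make_bm([[0.5, 0.5], [0.5, 0.5]], ["case", "control"],
                     {"cpg_flag": [0, 1]})
        out = probe_blacklist_filter(bm)
        assert list(out.probe_ids) == ["cg1"]

    def test_clean_autosomal_retained(self):
        bm = make_bm([[0.5, 0.5]], ["case", "control"])
        assert list(probe_blacklist_filter(bm).probe_ids) == ["cg0"]


class TestMissingProbes:
    def test_boundary_strict(self):
        rng = np.random.default_rng(0)
        vals = rng.random((2, 100))
        vals[0, :11] = np.nan  # 11% missing -> removed
        vals[1, :10] = np.nan  # 10% missing -> kept
        bm = make_bm(vals, ["case"] * 50 + ["control"] * 50)
        out = drop_high_missing_probes(bm, 0.10)
        assert list(out.probe_ids) == ["cg1"]

    def test_fully_observed_unchanged(self):
        bm = make_bm([[0.1, 0.2], [0.3, 0.4]], ["case", "control"])
        assert list(drop_high_missing_probes(bm).probe_ids) == ["cg0", "cg1"]

    def test_fully_missing_removed(self):
        bm = make_bm([[np.nan, np.nan], [0.3, 0.4]], ["case", "control"])
        assert list(drop_high_missing_probes(bm).probe_ids) == ["cg1"]


class TestKnnImpute:
    def test_identity_when_complete(self):
        bm = make_bm([[0.1, 0.2], [0.3, 0.4]], ["case", "control"])
        out = knn_impute(bm)
        assert out.values.equals(bm.values)

    def test_k1_copies_nearest(self):
        vals = np.array(
            [
                [0.10, 0.20, np.nan],
                [0.11, 0.21, 0.42],   # nearest to cg0
                [0.90, 0.95, 0.99],
            ]
        )
        bm = make_bm(vals, ["case", "control", "control"])
        out = knn_impute(bm, k=1)
        assert out.values.loc["cg0", "s2"] == pytest.approx(0.42)

    def test_observed_cells_unchanged(self):
        rng = np.random.default_rng(1)
        vals = rng.random((10, 6))
        vals[2, 3] = np.nan
        bm = make_bm(vals, ["case"] * 3 + ["control"] * 3)
        out = knn_impute(bm, k=3)
        mask = ~np.isnan(vals)
        np.testing.assert_array_equal(
            out.values.to_numpy()[mask], vals[mask]
        )
        assert not out.values.isna().any().any()

    def test_fewer_than_k_candidates_warns(self):
        vals = np.array([[0.1, np.nan], [0.2, 0.3]])
        bm = make_bm(vals, ["case", "control"])
        with pytest.warns(UserWarning, match="neighbor"):
            out = knn_impute(bm, k=5)
        assert out.values.loc["cg0", "s1"] == pytest.approx(0.3)

    def test_mask_and_recover_rmse(self):
        # smooth structure: blocks of probes share a per-sample profile
        rng = np.random.default_rng(2)
        n_blocks, block_size, n_samples = 5, 12, 40
        n_probes = n_blocks * block_size
        profiles = rng.uniform(0.2, 0.8, (n_blocks, n_samples))
        noise_sd = 0.05
        truth = np.clip(
            np.repeat(profiles, block_size, axis=0)
            + rng.normal(0, noise_sd, (n_probes, n_samples)),
            0, 1,
        )
        masked = truth.copy()
        holes = rng.random(truth.shape) < 0.05
        masked[holes] = np.nan
        bm = make_bm(masked, ["case"] * 20 + ["control"] * 20)
        out = knn_impute(bm, k=10)
        imputed = out.values.to_numpy()[holes]
        rmse = np.sqrt(np.mean((imputed - truth[holes]) ** 2))
        assert rmse < noise_sd

    def test_clipping(self):
        bm = make_bm([[0.1, 0.2], [0.3, 0.4]], ["case", "control"])
        out = knn_impute(bm, k=1)  # nothing missing; clip is a no-op path
        assert ((out.values >= 0) & (out.values <= 1)).all().all()


class TestDmcTest:
    def _cohort(self, n_per_group=20, n_probes=5, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        case = np.clip(rng.normal(0.5 + shift, 0.05, (n_probes, n_per_group)), 0, 1)
        ctrl = np.clip(rng.normal(0.5, 0.05, (n_probes, n_per_group)), 0, 1)
        vals = np.hstack([case, ctrl])
        return make_bm(vals, ["case"] * n_per_group + ["control"] * n_per_group)

    def test_identical_means_not_selected(self):
        vals = np.array([[0.2, 0.4, 0.2, 0.4]])
        bm = make_bm(vals, ["case", "case", "control", "control"])
        res = dmc_test(bm)
        assert res["delta_beta"].iloc[0] == pytest.approx(0.0)
        assert not res["selected"].iloc[0]

    def test_delta_boundary_strict(self):
        # delta exactly 0.014 < 0.015 threshold: never selected
        case = np.full(50, 0.514)
        ctrl = np.full(50, 0.500)
        case[0] += 1e-12  # tiny jitter to avoid zero variance
        vals = np.concatenate([case, ctrl])[None, :]
        bm = make_bm(vals, ["case"] * 50 + ["control"] * 50)
        res = dmc_test(bm)
        assert res["p_value"].iloc[0] < 1e-9
        assert abs(res["delta_beta"].iloc[0]) < 0.015
        assert not res["selected"].iloc[0]

    def test_matches_scipy_reference(self):
        bm = self._cohort(n_per_group=200, shift=0.05, seed=3)
        res = dmc_test(bm)
        cases = bm.values[bm.case_ids()].to_numpy()
        ctrls = bm.values[bm.control_ids()].to_numpy()
        for i in range(len(res)):
            t_ref, p_ref = stats.ttest_ind(cases[i], ctrls[i])
            assert res["t"].iloc[i] == pytest.approx(t_ref, abs=1e-8)
            assert res["p_value"].iloc[i] == pytest.approx(p_ref, abs=1e-8)
        assert res["selected"].all()

    def test_welch_variant(self):
        bm = self._cohort(seed=4)
        res = dmc_test(bm, welch=True)
        cases = bm.values[bm.case_ids()].to_numpy()
        ctrls = bm.values[bm.control_ids()].to_numpy()
        t_ref, p_ref = stats.ttest_ind(cases[0], ctrls[0], equal_var=False)
        assert res["t"].iloc[0] == pytest.approx(t_ref, abs=1e-10)

    def test_zero_variance_equal_means(self):
        vals = np.full((1, 8), 0.5)
        bm = make_bm(vals, ["case"] * 4 + ["control"] * 4)
        res = dmc_test(bm)
        assert res["p_value"].iloc[0] == 1.0
        assert not res["selected"].iloc[0]

    def test_zero_variance_unequal_means(self):
        vals = np.array([[0.6] * 4 + [0.5] * 4])
        bm = make_bm(vals, ["case"] * 4 + ["control"] * 4)
        with pytest.warns(UserWarning, match="zero variance"):
            res = dmc_test(bm)
        assert res["p_value"].iloc[0] == 0.0
        assert res["selected"].iloc[0]

    def test_delta_consistency_invariant(self):
        bm = self._cohort(seed=5)
        res = dmc_test(bm)
        np.testing.assert_allclose(
            res["delta_beta"],
            res["mean_beta_case"] - res["mean_beta_control"],
        )

    def test_label_swap_negates_delta(self):
        bm = self._cohort(seed=6)
        swapped = BetaMatrix(
            annotations=bm.annotations.copy(),
            values=bm.values.copy(),
            groups=bm.groups.map({"case": "control", "control": "case"}),
        )
        r1 = dmc_test(bm)
        r2 = dmc_test(swapped)
        np.testing.assert_allclose(r1["delta_beta"], -r2["delta_beta"])
        np.testing.assert_allclose(r1["p_value"], r2["p_value"], atol=1e-12)

    def test_sample_and_probe_order_invariance(self):
        bm = self._cohort(seed=7)
        perm_samples = list(bm.sample_ids[::-1])
        perm_probes = list(bm.probe_ids[::-1])
        bm_perm = BetaMatrix(
            annotations=bm.annotations.loc[perm_probes].copy(),
            values=bm.values.loc[perm_probes, perm_samples].copy(),
            groups=bm.groups.loc[perm_samples],
        )
        r1 = dmc_test(bm)
        r2 = dmc_test(bm_perm).loc[r1.index]
        np.testing.assert_allclose(r1["p_value"], r2["p_value"], atol=1e-12)


class TestIntersect:
    def _result(self, selected, delta):
        idx = [f"cg{i}" for i in range(len(selected))]
        return pd.DataFrame(
            {
                "delta_beta": delta,
                "p_value": [0.01] * len(selected),
                "direction": ["hyper" if d > 0 else "hypo" for d in delta],
                "selected": selected,
            },
            index=idx,
        )

    def test_disjoint_empty(self):
        a = self._result([True, False], [0.1, 0.1])
        b = self._result([False, True], [0.1, 0.1])
        assert len(intersect_dmcs(a, b)) == 0

    def test_concordant_hyper(self):
        a = self._result([True], [0.05])
        b = self._result([True], [0.03])
        out = intersect_dmcs(a, b)
        assert len(out) == 1
        assert out["direction"].iloc[0] == "hyper"
        assert out["concordant"].iloc[0]

    def test_discordant_flagged_not_dropped(self):
        a = self._result([True], [0.05])
        b = self._result([True], [-0.03])
        out = intersect_dmcs(a, b)
        assert len(out) == 1
        assert not out["concordant"].iloc[0]


class TestTypeIError:
    def test_null_selection_rate(self):
        # delta_thresh 0: selection rate ~ p_thresh within 3 MC SEs
        n_probes = 10_000
        rng = np.random.default_rng(8)
        vals = rng.normal(0.5, 0.05, (n_probes, 40)).clip(0, 1)
        bm = make_bm(vals, ["case"] * 20 + ["control"] * 20)
        res0 = dmc_test(bm, p_thresh=0.05, delta_thresh=0.0)
        rate = res0["selected"].mean()
        se = np.sqrt(0.05 * 0.95 / n_probes)
        assert abs(rate - 0.05) < 3 * se
        # adding the delta threshold can only reduce the rate
        res1 = dmc_test(bm, p_thresh=0.05, delta_thresh=0.015)
        assert res1["selected"].mean() <= rate


class TestScreenPipeline:
    def test_gene_restriction(self):
        bm = make_bm([[0.5, 0.5], [0.5, 0.5]], ["case", "control"])
        out = restrict_to_genes(bm, ["G1"])
        assert list(out.probe_ids) == ["cg1"]

    def test_normalize_identity(self):
        bm = make_bm([[0.5, 0.5]], ["case", "control"])
        assert normalize(bm) is bm

    def test_normalize_hook_called(self):
        bm = make_bm([[0.5, 0.5]], ["case", "control"])
        out = normalize(bm, method=lambda m: m.select_probes([]))
        assert len(out.probe_ids) == 0

    def test_power_run_detects_all_spikes(self):
        bm1, bm2 = simulate_beta_cohorts(
            n_probes=100, n_spiked=10, delta_beta=0.05, noise_sd=0.03,
            n1_case=200, n1_ctrl=200, n2_case=200, n2_ctrl=200, seed=9,
        )
        spiked = [f"cg{i:06d}" for i in range(10)]
        da, db, inter = screen_cohorts(bm1, bm2)
        assert da.loc[spiked, "selected"].all()
        assert db.loc[spiked, "selected"].all()
        assert set(spiked) <= set(inter.index)

    def test_min_group_size(self):
        bm = make_bm([[0.5, 0.5]], ["case", "control"])
        with pytest.raises(ValidationError):
            dmc_test(bm)
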