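import numpy as np
import pandas as pd
import pytest

import vepasl as v
from vepasl.maps import DerivedMaps
from vepasl.stats import mean_weighted_att, summaries_to_frame


def derived_from(direct, indirect, att=None):
    direct = np.asarray(direct, dtype=float)
    indirect = np.asarray(indirect, dtype=float)
    total = direct + indirect
    if att is None:
        att = np.where(total > 0, 1.0, np.nan)
    return DerivedMaps(
        total_cbf=total, weighted_att=att, direct_cbf=direct,
        indirect_cbf=indirect, ipsilateral_artery_id="RICA",
    )


class TestIndirectFraction:
    def test_no_indirect_gives_zero(self):
        d = derived_from(np.full((2, 2, 1), 30.0), np.zeros((2, 2, 1)))
        assert v.indirect_fraction(d, np.ones((2, 2, 1), bool)) == 0.0

    def test_all_indirect_gives_one(self):
        d = derived_from(np.zeros((2, 2, 1)), np.full((2, 2, 1), 30.0))
        assert v.indirect_fraction(d, np.ones((2, 2, 1), bool)) == 1.0

    def test_sum_ratio_hand_example(self):
        # voxels (direct 30, indirect 10) and (direct 0, indirect 20):
        # indirect/total = 30/60
        direct = np.array([30.0, 0.0]).reshape(2, 1, 1)
        indirect = np.array([10.0, 20.0]).reshape(2, 1, 1)
        d = derived_from(direct, indirect)
        assert v.indirect_fraction(d, np.ones((2, 1, 1), bool)) == pytest.approx(0.5)

    def test_invariant_to_uniform_rescaling(self):
        rng = np.random.default_rng(0)
        direct = rng.uniform(0, 40, (4, 4, 2))
        indirect = rng.uniform(0, 40, (4, 4, 2))
        roi = rng.random((4, 4, 2)) < 0.5
        a = v.indirect_fraction(derived_from(direct, indirect), roi)
        b = v.indirect_fraction(derived_from(3.7 * direct, 3.7 * indirect), roi)
        assert a == pytest.approx(b, rel=1e-12)

    def test_voxel_mean_variant(self):
        direct = np.array([30.0, 0.0]).reshape(2, 1, 1)
        indirect = np.array([10.0, 20.0]).reshape(2, 1, 1)
        d = derived_from(direct, indirect)
        got = v.indirect_fraction(d, np.ones((2, 1, 1), bool), method="voxel-mean")
        assert got == pytest.approx((10 / 40 + 20 / 20) / 2)

    def test_empty_roi_rejected(self):
        d = derived_from(np.ones((2, 2, 1)), np.ones((2, 2, 1)))
        with pytest.raises(ValueError):
            v.indirect_fraction(d, np.zeros((2, 2, 1), bool))

    def test_zero_total_flow_rejected(self):
        d = derived_from(np.zeros((2, 2, 1)), np.zeros((2, 2, 1)))
        with pytest.raises(ValueError):
            v.indirect_fraction(d, np.ones((2, 2, 1), bool))


class TestSurvivalTable:
    def _toy(self):
        # 20 voxels with hand-assigned direct/indirect values and fates
        rng = np.random.default_rng(8)
        direct = rng.uniform(0, 40, 20)
        indirect = rng.uniform(0, 85, 20)
        infarct = rng.random(20) < 0.4
        shape = (20, 1, 1)
        return (direct.reshape(shape), indirect.reshape(shape),
                infarct.reshape(shape), np.ones(shape, bool))

    def test_counts_match_exhaustive_enumeration(self):
        direct, indirect, infarct, peri = self._toy()
        table = v.survival_table(direct, indirect, infarct, peri,
                                 direct_cutoff=25.0, min_count=1)
        d, ind, inf = direct.ravel(), indirect.ravel(), infarct.ravel()
        for _, row in table.iterrows():
            expected_total = 0
            expected_surv = 0
            for i in range(20):
                if d[i] > 25.0:
                    continue
                if row["bin_left"] <= ind[i] < row["bin_right"]:
                    expected_total += 1
                    expected_surv += int(not inf[i])
            assert row["total"] == expected_total
            assert row["surviving"] == expected_surv

    def test_all_survivors_give_fraction_one(self):
        direct, indirect, _, peri = self._toy()
        infarct = np.zeros_like(peri)
        table = v.survival_table(direct, indirect, infarct, peri, min_count=1)
        nonempty = table[table["total"] > 0]
        assert (nonempty["fraction"] == 1.0).all()

    def test_direct_exactly_at_cutoff_retained(self):
        shape = (2, 1, 1)
        direct = np.array([25.0, 25.001]).reshape(shape)
        indirect = np.array([5.0, 5.0]).reshape(shape)
        table = v.survival_table(direct, indirect, np.zeros(shape, bool),
                                 np.ones(shape, bool), min_count=1)
        assert int(table["total"].sum()) == 1  # only the boundary voxel kept

    def test_no_cutoff_variant_and_direct_axis(self):
        direct, indirect, infarct, peri = self._toy()
        table = v.survival_table(direct, indirect, infarct, peri,
                                 direct_cutoff=None, axis="direct", min_count=1)
        assert int(table["total"].sum()) == 20

    def test_min_count_masks_sparse_bins(self):
        direct, indirect, infarct, peri = self._toy()
        table = v.survival_table(direct, indirect, infarct, peri, min_count=100)
        assert table["fraction"].isna().all()
        assert (table["total"] >= 0).all()


class TestBinomialSplitTest:
    def _table(self, counts):
        rows = []
        for left, (surv, tot) in counts.items():
            rows.append({"bin_left": left, "bin_right": left + 10.0,
                         "surviving": surv, "total": tot,
                         "fraction": surv / tot if tot else np.nan, "group": "all"})
        return pd.DataFrame(rows)

    def test_equal_proportions_give_p_one(self):
        table = self._table({10.0: (50, 100), 30.0: (50, 100)})
        lo, hi, p = v.binomial_split_test(table, split=20.0)
        assert lo == hi == 0.5
        assert p == pytest.approx(1.0)

    def test_matches_textbook_two_proportion_z(self):
        table = self._table({10.0: (6, 10), 30.0: (9, 10)})
        lo, hi, p = v.binomial_split_test(table, split=20.0)
        # pooled two-proportion z-test computed from first principles
        p1, p2, n1, n2 = 0.6, 0.9, 10, 10
        pool = (6 + 9) / 20
        z = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        from scipy.stats import norm
        expected = 2 * norm.sf(abs(z))
        assert p == pytest.approx(expected, rel=1e-10)

    def test_empty_side_rejected(self):
        table = self._table({10.0: (6, 10), 30.0: (0, 0)})
        with pytest.raises(ValueError):
            v.binomial_split_test(table, split=20.0)

    def test_split_inside_bin_rejected(self):
        table = self._table({10.0: (6, 10), 20.0: (8, 10), 30.0: (9, 10)})
        with pytest.raises(ValueError):
            v.binomial_split_test(table, split=25.0)


class TestRelativeIncrease:
    def _table(self, f_lo, f_hi, n=100):
        return pd.DataFrame([
            {"bin_left": 0.0, "bin_right": 10.0, "surviving": int(f_lo * n),
             "total": n, "fraction": f_lo, "group": "all"},
            {"bin_left": 70.0, "bin_right": 80.0, "surviving": int(f_hi * n),
             "total": n, "fraction": f_hi, "group": "all"},
        ])

    def test_no_change_is_zero_percent(self):
        assert v.relative_increase(self._table(0.5, 0.5)) == pytest.approx(0.0)

    def test_forty_five_percent_increase(self):
        assert v.relative_increase(self._table(0.5, 0.725)) == pytest.approx(45.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            v.relative_increase(self._table(0.0, 0.7))

    def test_missing_bin_rejected(self):
        with pytest.raises(ValueError):
            v.relative_increase(self._table(0.5, 0.7), low_bin=20.0)


def balanced_anova_oracle(frame, response):
    """Closed-form two-way ANOVA sums of squares for a balanced design."""
    y = frame[response].to_numpy()
    rois = sorted(frame["roi"].unique())
    tps = sorted(frame["timepoint"].unique())
    grand = y.mean()
    n = len(frame)
    cell = {
        (r, t): frame[(frame["roi"] == r) & (frame["timepoint"] == t)][response].to_numpy()
        for r in rois for t in tps
    }
    nc = len(next(iter(cell.values())))
    ss_roi = sum(
        len(tps) * nc * (frame[frame["roi"] == r][response].mean() - grand) ** 2
        for r in rois
    )
    ss_tp = sum(
        len(rois) * nc * (frame[frame["timepoint"] == t][response].mean() - grand) ** 2
        for t in tps
    )
    ss_int = sum(
        nc * (cell[(r, t)].mean()
              - frame[frame["roi"] == r][response].mean()
              - frame[frame["timepoint"] == t][response].mean() + grand) ** 2
        for r in rois for t in tps
    )
    ss_err = sum(((cell[k] - cell[k].mean()) ** 2).sum() for k in cell)
    df_err = n - len(rois) * len(tps)
    return {
        "F_roi": (ss_roi / (len(rois) - 1)) / (ss_err / df_err),
        "F_tp": (ss_tp / (len(tps) - 1)) / (ss_err / df_err),
    }


class TestTwoWayANOVA:
    def _frame(self, effect=0.2, noise=0.05, n=6, seed=1):
        rng = np.random.default_rng(seed)
        rows = []
        for pid in range(n):
            for tp in ("presentation", "1-month"):
                for roi, mu in (("surviving", 0.2 + effect), ("contralateral", 0.2)):
                    rows.append(v.PatientSummary(
                        patient_id=str(pid), timepoint=tp, roi=roi,
                        indirect_fraction=float(np.clip(rng.normal(mu, noise), 0, 1)),
                        mean_weighted_att_s=1.2,
                    ))
        return summaries_to_frame(rows)

    def test_balanced_f_statistics_match_closed_form(self):
        frame = self._frame()
        out = v.two_way_anova(frame, "indirect_fraction")
        oracle = balanced_anova_oracle(frame, "indirect_fraction")
        got_f_roi = float(out["anova"].loc["C(roi)", "F"])
        got_f_tp = float(out["anova"].loc["C(timepoint)", "F"])
        assert got_f_roi == pytest.approx(oracle["F_roi"], rel=1e-8)
        assert got_f_tp == pytest.approx(oracle["F_tp"], rel=1e-8)

    def test_identical_roi_values_give_null_effect(self):
        frame = self._frame(effect=0.0, noise=0.0)
        # add patient-level variation so the residual is non-degenerate
        rng = np.random.default_rng(2)
        frame["indirect_fraction"] = np.clip(
            0.2 + rng.normal(0, 0.03, len(frame)), 0, 1
        )
        # make both ROIs identical within each patient/timepoint
        piv = frame.pivot_table(index=["patient_id", "timepoint"],
                                values="indirect_fraction").reset_index()
        frame = frame.drop(columns="indirect_fraction").merge(
            piv, on=["patient_id", "timepoint"]
        )
        out = v.two_way_anova(frame, "indirect_fraction")
        assert out["anova"].loc["C(roi)", "F"] == pytest.approx(0.0, abs=1e-20)
        assert out["roi_p"] > 0.99

    def test_posthoc_gated_on_significance(self):
        strong = v.two_way_anova(self._frame(effect=0.3), "indirect_fraction")
        assert strong["roi_p"] < 0.05
        assert not strong["posthoc"].empty
        assert set(strong["posthoc"]["timepoint"]) == {"presentation", "1-month"}
        null = v.two_way_anova(self._frame(effect=0.0, noise=0.05), "indirect_fraction")
        if null["roi_p"] >= 0.05:
            assert null["posthoc"].empty

    def test_posthoc_matches_independent_t_test(self):
        from scipy.stats import ttest_ind

        frame = self._frame(effect=0.3)
        out = v.two_way_anova(frame, "indirect_fraction")
        row = out["posthoc"][out["posthoc"]["timepoint"] == "presentation"].iloc[0]
        grp = frame[frame["timepoint"] == "presentation"]
        a = grp[grp["roi"] == "contralateral"]["indirect_fraction"]
        b = grp[grp["roi"] == "surviving"]["indirect_fraction"]
        t, p = ttest_ind(a, b)
        assert row["p"] == pytest.approx(p, rel=1e-10)

    def test_single_level_factor_rejected(self):
        frame = self._frame()
        with pytest.raises(ValueError):
            v.two_way_anova(frame[frame["roi"] == "surviving"], "indirect_fraction")

    def test_invalid_indirect_fraction_rejected(self):
        with pytest.raises(ValueError):
            v.PatientSummary("p", "t", "surviving", indirect_fraction=1.2,
                             mean_weighted_att_s=1.0)


class TestMeanWeightedATT:
    def test_ignores_undefined_voxels(self):
        att = np.array([1.0, np.nan, 2.0]).reshape(3, 1, 1)
        d = DerivedMaps(total_cbf=np.ones((3, 1, 1)), weighted_att=att,
                        direct_cbf=np.ones((3, 1, 1)),
                        indirect_cbf=np.zeros((3, 1, 1)),
                        ipsilateral_artery_id="RICA")
        assert mean_weighted_att(d, np.ones((3, 1, 1), bool)) == pytest.approx(1.5)

    def test_all_undefined_rejected(self):
        att = np.full((2, 1, 1), np.nan)
        d = DerivedMaps(total_cbf=np.zeros((2, 1, 1)), weighted_att=att,
                        direct_cbf=np.zeros((2, 1, 1)),
                        indirect_cbf=np.zeros((2, 1, 1)),
                        ipsilateral_artery_id="RICA")
        with pytest.raises(ValueError):
            mean_weighted_att(d, np.ones((2, 1, 1), bool))
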