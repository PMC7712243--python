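"""Standardization, correlation structure, feature reduction and group tests."""

import math

import numpy as np
import pandas as pd
import pytest

from oxiscreen.cohort import (
    CohortTable,
    apply_standardizer,
    correlation_matrix,
    fit_standardizer,
    group_compare,
    reduce_by_correlation,
    select_by_mutual_information,
)
from oxiscreen.desat import AT_RISK, HEALTHY
from oxiscreen.signal_io import FEATURE_COLUMNS
from oxiscreen.synth import DEFAULT_GROUP_STATS, CohortSpec, make_cohort


def toy_table(columns: dict, labels=None, ahi=None, names=None) -> CohortTable:
    df = pd.DataFrame(columns)
    if labels is not None:
        df["label"] = labels
    if ahi is not None:
        df["ahi"] = ahi
    return CohortTable(df, names or list(columns))


class TestStandardizer:
    def test_closed_form_sample_sd(self):
        t = toy_table({"f": [1.0, 2.0, 3.0]}, names=["f"])
        z = apply_standardizer(fit_standardizer(t), t)
        np.testing.assert_allclose(z.data["f"], [-1.0, 0.0, 1.0])

    def test_self_application_centers_and_scales(self, reference_cohort):
        std = fit_standardizer(reference_cohort)
        z = apply_standardizer(std, reference_cohort)
        for name in z.feature_names:
            assert abs(z.data[name].mean()) < 1e-12
            assert z.data[name].std(ddof=1) == pytest.approx(1.0)

    def test_stored_parameters_applied_without_refit(self, reference_cohort):
        std = fit_standardizer(reference_cohort)
        other = make_cohort(CohortSpec(n_healthy=50, n_at_risk=5, seed=9))
        z = apply_standardizer(std, other)
        # a cohort with different group balance is not re-centered
        assert abs(z.data["odi3"].mean()) > 0.1

    def test_zero_variance_feature_dropped_with_warning(self):
        t = toy_table({"f": [1.0, 2.0, 4.0], "g": [3.0, 3.0, 3.0]}, names=["f", "g"])
        with pytest.warns(UserWarning, match="zero variance"):
            std = fit_standardizer(t)
        assert std.feature_names == ["f"]

    def test_missing_rows_dropped_on_construction(self):
        df = pd.DataFrame({"f": [1.0, np.nan, 3.0], "g": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="dropping 1"):
            t = CohortTable(df, ["f", "g"])
        assert t.n == 2


class TestCorrelation:
    def test_unit_diagonal_and_symmetry(self, reference_cohort):
        c = correlation_matrix(reference_cohort)
        np.testing.assert_allclose(np.diag(c), 1.0)
        np.testing.assert_allclose(c.values, c.values.T)
        assert (c.abs().values <= 1 + 1e-12).all()

    def test_independent_columns_uncorrelated(self):
        rng = np.random.default_rng(0)
        t = toy_table({"f": rng.normal(size=1000), "g": rng.normal(size=1000)},
                      names=["f", "g"])
        assert abs(correlation_matrix(t, include_ahi=False).loc["f", "g"]) < 0.1

    def test_clustered_generator_couples_desaturation_rates(self):
        t = make_cohort(CohortSpec(coupling="clustered", seed=3))
        c = correlation_matrix(t)
        assert c.loc["odi3", "odi4"] > 0.9
        assert c.loc["ndes2ph", "ndes3ph"] > 0.9

    def test_invariant_under_standardization(self, reference_cohort):
        raw = correlation_matrix(reference_cohort, include_ahi=False)
        z = apply_standardizer(fit_standardizer(reference_cohort), reference_cohort)
        np.testing.assert_allclose(
            raw.values, correlation_matrix(z, include_ahi=False).values, atol=1e-12
        )


class TestReduceByCorrelation:
    def test_identity_when_no_strong_pairs(self):
        rng = np.random.default_rng(1)
        cols = {n: rng.normal(size=200) for n in FEATURE_COLUMNS}
        t = toy_table(cols, names=list(FEATURE_COLUMNS))
        assert reduce_by_correlation(t) == list(FEATURE_COLUMNS)

    def test_hand_enumerated_three_feature_case(self):
        rng = np.random.default_rng(2)
        n = 2000
        f1 = rng.normal(size=n)
        f2 = 0.99 * f1 + np.sqrt(1 - 0.99**2) * rng.normal(size=n)  # r12 ~ 0.99
        f3 = rng.normal(size=n)
        ahi = f2 + 0.3 * rng.normal(size=n)  # f2 most label-relevant
        t = toy_table({"f1": f1, "f2": f2, "f3": f3}, ahi=ahi, names=["f1", "f2", "f3"])
        assert reduce_by_correlation(t) == ["f2", "f3"]

    def test_most_ahi_correlated_member_retained(self):
        t = make_cohort(CohortSpec(coupling="clustered", seed=7))
        kept = reduce_by_correlation(t)
        cluster = {"odi3", "odi4", "ndes2ph", "ndes3ph", "ndes4ph", "ndes5ph"}
        chosen = cluster & set(kept)
        assert len(chosen) == 1
        c = correlation_matrix(t)
        best = c.loc[sorted(cluster), "ahi"].abs().idxmax()
        assert chosen == {best}

    def test_row_order_invariance(self, reference_cohort):
        kept = reduce_by_correlation(reference_cohort)
        shuffled = reference_cohort.subset(
            np.random.default_rng(0).permutation(reference_cohort.n)
        )
        assert reduce_by_correlation(shuffled) == kept


class TestMutualInformation:
    @staticmethod
    def plugin_mi(x, y):
        """Plug-in discrete mutual information (natural log), the oracle."""
        mi = 0.0
        n = len(x)
        for xv in np.unique(x):
            for yv in np.unique(y):
                pxy = np.mean((x == xv) & (y == yv))
                if pxy > 0:
                    mi += pxy * math.log(pxy / (np.mean(x == xv) * np.mean(y == yv)))
        return mi

    def test_ranking_matches_plugin_oracle_on_discrete_toy(self):
        rng = np.random.default_rng(0)
        n = 400
        y = rng.integers(0, 2, n)
        f1 = y.astype(float)                                   # MI = H(y)
        flip = rng.random(n) < 0.3
        f2 = np.where(flip, 1 - y, y).astype(float)            # noisy copy
        f3 = rng.integers(0, 2, n).astype(float)               # independent
        oracle = [self.plugin_mi(f, y) for f in (f1, f2, f3)]
        assert oracle[0] > oracle[1] > oracle[2]
        labels = np.where(y == 1, AT_RISK, HEALTHY)
        t = toy_table({"f1": f1, "f2": f2, "f3": f3}, labels=labels,
                      names=["f1", "f2", "f3"])
        assert select_by_mutual_information(t, k=1) == ["f1"]
        assert select_by_mutual_information(t, k=2) == ["f1", "f2"]

    def test_uninformative_falls_back_to_canonical_order(self):
        rng = np.random.default_rng(1)
        n = 500
        cols = {name: rng.normal(size=n) for name in FEATURE_COLUMNS}
        labels = np.where(rng.integers(0, 2, n) == 1, AT_RISK, HEALTHY)
        t = toy_table(cols, labels=labels, names=list(FEATURE_COLUMNS))
        kept = select_by_mutual_information(t, k=3)
        assert kept == sorted(kept, key=list(FEATURE_COLUMNS).index)

    def test_unlabeled_table_rejected(self, reference_cohort):
        t = CohortTable(reference_cohort.data.drop(columns="label"))
        with pytest.raises(ValueError):
            select_by_mutual_information(t, k=2)


class TestGroupCompare:
    def test_report_shape_and_flags(self, reference_cohort):
        rep = group_compare(reference_cohort)
        assert list(rep.index) == list(FEATURE_COLUMNS)
        # the desaturation-rate features separate the groups decisively;
        # the cumulative-time indices overlap heavily after truncation at 0
        rate_feats = ["odi3", "odi4", "ndes2ph", "ndes3ph", "ndes4ph", "ndes5ph"]
        assert rep.loc[rate_feats, "significant"].all()
        assert (rep.loc[rate_feats, "mannwhitney_p"] < 1e-10).all()

    def test_identical_groups_not_significant(self):
        vals = np.tile(np.arange(20, dtype=float), 2)
        cols = {n: vals for n in FEATURE_COLUMNS}
        labels = [HEALTHY] * 20 + [AT_RISK] * 20
        t = toy_table(cols, labels=labels, names=list(FEATURE_COLUMNS))
        rep = group_compare(t)
        assert not rep["significant"].any()

    def test_type_one_error_rate_near_nominal(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            a, b = rng.normal(size=(2, 200))
            if stats.mannwhitneyu(a, b, alternative="two-sided").pvalue <= 0.05:
                rejections += 1
        assert 0.01 <= rejections / n_sim <= 0.11

    def test_power_on_reference_odi3_parameters(self):
        # healthy vs at-risk odi3 as published: detection essentially certain
        from scipy import stats as ss

        h_mean, h_sd = DEFAULT_GROUP_STATS["odi3"][HEALTHY]
        r_mean, r_sd = DEFAULT_GROUP_STATS["odi3"][AT_RISK]
        rng = np.random.default_rng(1)
        for _ in range(50):
            h = np.clip(rng.normal(h_mean, h_sd, 197), 0, None)
            r = np.clip(rng.normal(r_mean, r_sd, 256), 0, None)
            assert ss.mannwhitneyu(h, r).pvalue <= 0.05

    def test_single_group_rejected(self, reference_cohort):
        healthy_only = reference_cohort.subset(
            np.flatnonzero(reference_cohort.y == 0)
        )
        with pytest.raises(ValueError):
            group_compare(healthy_only)
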