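"""Sensitivity/specificity, AUC variants, cluster bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from adheremon import (
    BootstrapConfig,
    TwoByTwo,
    auc_binary,
    auc_model,
    cluster_bootstrap_ci,
    sens_spec,
)

tables = st.builds(
    TwoByTwo,
    n11=st.integers(0, 20), n10=st.integers(0, 20),
    n01=st.integers(1, 20), n00=st.integers(1, 20),
)


class TestSensSpec:
    def test_em_against_viral_load(self, em_vl_table):
        res = sens_spec(em_vl_table)
        assert round(100 * res.sensitivity, 1) == 22.9
        assert round(100 * res.specificity, 1) == 80.4
        assert (res.n_cases, res.n_controls) == (83, 168)

    def test_sr_against_viral_load(self, sr_vl_table):
        res = sens_spec(sr_vl_table)
        assert round(100 * res.sensitivity, 1) == 1.8
        assert round(100 * res.specificity, 1) == 96.7

    @pytest.mark.parametrize(
        "table, sens, spec",
        [(TwoByTwo(13, 27, 40, 92), 24.5, 77.3),   # ages 10-13, EM
         (TwoByTwo(6, 6, 24, 43), 20.0, 87.8)],    # ages 14-16, EM
    )
    def test_age_subgroups(self, table, sens, spec):
        res = sens_spec(table)
        assert round(100 * res.sensitivity, 1) == sens
        assert round(100 * res.specificity, 1) == spec

    def test_wilson_interval_matches_printed_ci(self, em_vl_table):
        """Specificity 135/168: the printed 73.6-85.7% CI is Wilson to ~0.1pp."""
        res = sens_spec(em_vl_table)
        assert res.specificity_ci[0] == pytest.approx(0.736, abs=0.002)
        assert res.specificity_ci[1] == pytest.approx(0.857, abs=0.002)

    def test_perfect_test(self):
        res = sens_spec(TwoByTwo(10, 0, 0, 20))
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    @pytest.mark.parametrize("table, match",
                             [(TwoByTwo(0, 5, 0, 5), "no cases"),
                              (TwoByTwo(5, 0, 5, 0), "no controls")])
    def test_empty_margin_named(self, table, match):
        with pytest.raises(ValueError, match=match):
            sens_spec(table)

    @given(tables)
    def test_wilson_ci_brackets_estimate_within_unit_interval(self, t):
        res = sens_spec(t)
        for est, (lo, hi) in [(res.sensitivity, res.sensitivity_ci),
                              (res.specificity, res.specificity_ci)]:
            assert 0.0 <= lo <= est <= hi <= 1.0


def _auc_pair_enumeration(t: TwoByTwo) -> float:
    """Oracle: Mann-Whitney probability over all case-control pairs of the
    0/1-coded test (poor = 1), ties counted one half."""
    cases = [1] * t.n11 + [0] * t.n01
    controls = [1] * t.n10 + [0] * t.n00
    wins = sum(c > d for c in cases for d in controls)
    ties = sum(c == d for c in cases for d in controls)
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


class TestAucBinary:
    def test_em_table_value(self, em_vl_table):
        assert auc_binary(em_vl_table) == pytest.approx(0.5163, abs=5e-4)
        assert auc_binary(em_vl_table) == pytest.approx(_auc_pair_enumeration(em_vl_table))

    def test_older_adolescents_table(self):
        t = TwoByTwo(6, 6, 24, 43)
        assert auc_binary(t) == pytest.approx((0.200 + 0.878) / 2, abs=5e-4)
        assert auc_binary(t) == pytest.approx(_auc_pair_enumeration(t))

    def test_uninformative_test(self):
        assert auc_binary(TwoByTwo(5, 5, 5, 5)) == pytest.approx(0.5)

    @given(tables)
    def test_matches_pair_enumeration(self, t):
        assert auc_binary(t) == pytest.approx(_auc_pair_enumeration(t))


class TestAucModel:
    def test_perfect_separation(self):
        auc, _ = auc_model([3, 5, 0, 1], [True, True, False, False])
        assert auc == 1.0

    def test_constant_score_warns_half(self):
        with pytest.warns(UserWarning, match="constant score"):
            auc, _ = auc_model([2, 2, 2, 2], [True, False, True, False])
        assert auc == 0.5

    def test_tie_counted_half(self):
        # cases {0,2,5} vs controls {0,1,4}: 5 wins + half a tie of 9 pairs
        auc, _ = auc_model([0, 2, 5, 0, 1, 4],
                           [True, True, True, False, False, False])
        assert auc == pytest.approx((5 + 0.5) / 9)

    def test_roc_points_span_unit_square(self):
        _, roc = auc_model([0, 2, 5, 0, 1, 4],
                           [True, True, True, False, False, False])
        assert roc["fpr"].iloc[0] == 0.0 and roc["tpr"].iloc[0] == 0.0
        assert roc["fpr"].iloc[-1] == 1.0 and roc["tpr"].iloc[-1] == 1.0

    @given(tables)
    def test_equals_binary_auc_on_dichotomous_scores(self, t):
        score = np.repeat([1, 1, 0, 0], [t.n11, t.n10, t.n01, t.n00])
        case = np.repeat([True, False, True, False], [t.n11, t.n10, t.n01, t.n00])
        if case.all() or (~case).all():
            return
        if np.ptp(score) == 0:
            return
        auc, _ = auc_model(score, case)
        assert auc == pytest.approx(auc_binary(t))

    @given(st.lists(st.integers(-50000, 50000), min_size=4, max_size=30,
                    unique=True),
           st.data())
    def test_monotone_transform_and_orientation(self, raw, data):
        case = data.draw(st.lists(st.booleans(), min_size=len(raw),
                                  max_size=len(raw)))
        case = np.array(case)
        if case.all() or (~case).all():
            return
        scores = np.array(raw) / 1000.0  # well-separated floats
        auc, _ = auc_model(scores, case)
        transformed, _ = auc_model(2.0 * scores + 3.0, case)
        assert transformed == pytest.approx(auc)
        flipped, _ = auc_model(-scores, case)
        assert flipped == pytest.approx(1 - auc)


class TestClusterBootstrap:
    @pytest.fixture()
    def clustered_data(self):
        rng = np.random.default_rng(9)
        rows = []
        for c in range(12):
            n = rng.integers(5, 15)
            rows.append(pd.DataFrame({
                "clinic_id": f"C{c}",
                "y": rng.normal(loc=c % 3, size=n)}))
        return pd.concat(rows, ignore_index=True)

    def test_fixed_seed_is_deterministic(self, clustered_data):
        cfg = BootstrapConfig(n_replicates=200, seed=5)
        ci1 = cluster_bootstrap_ci(lambda d: d["y"].mean(), clustered_data, cfg)
        ci2 = cluster_bootstrap_ci(lambda d: d["y"].mean(), clustered_data, cfg)
        assert (ci1.lower, ci1.upper) == (ci2.lower, ci2.upper)

    def test_single_cluster_degenerates_to_point(self):
        data = pd.DataFrame({"clinic_id": "C0", "y": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="fewer than 2 clusters"):
            ci = cluster_bootstrap_ci(lambda d: d["y"].mean(), data,
                                      BootstrapConfig(n_replicates=50, seed=1))
        assert ci.lower == ci.upper == pytest.approx(2.0)

    def test_ci_contains_point_estimate(self, clustered_data):
        est = clustered_data["y"].mean()
        ci = cluster_bootstrap_ci(lambda d: d["y"].mean(), clustered_data,
                                  BootstrapConfig(n_replicates=500, seed=3))
        assert ci.lower <= est <= ci.upper

    def test_failing_replicates_are_redrawn_and_counted(self):
        # one cluster has no cases; resamples drawing only it must be redrawn
        data = pd.DataFrame({
            "clinic_id": ["A"] * 5 + ["B"] * 5,
            "case": [True, True, False, False, True] + [False] * 5})

        def sens_like(d):
            if not d["case"].any():
                raise ValueError("no cases")
            return d["case"].mean()

        ci = cluster_bootstrap_ci(sens_like, data,
                                  BootstrapConfig(n_replicates=100, seed=2))
        assert ci.n_redraws > 0
        assert len(ci.estimates) == 100
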