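"""Exact no-replicate test, group test, majority vote, sharing test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sevscape import pairdiff
from sevscape.containers import DifferentialResult
from sevscape.synth import simulate_intensity_groups

from conftest import exact_binomial_oracle


class TestSingleSampleTest:
    @pytest.mark.parametrize(
        "x,y,na,nb,exp_fc,exp_p",
        [
            (5, 5, 1e6, 1e6, 1.0, 1.0),   # symmetric counts: maximally null
            (0, 0, 1e6, 1e6, 1.0, 1.0),   # double zero: degenerate null
        ],
    )
    def test_null_configurations(self, x, y, na, nb, exp_fc, exp_p):
        fc, p = pairdiff.single_sample_test(x, y, na, nb)
        assert fc == pytest.approx(exp_fc)
        assert p == pytest.approx(exp_p)

    def test_matches_enumeration_on_asymmetric_libraries(self):
        for x, y, na, nb in [(20, 2, 1e6, 1e6), (3, 30, 5e5, 2e6), (0, 12, 1e6, 1e6)]:
            _, p = pairdiff.single_sample_test(x, y, na, nb)
            assert p == pytest.approx(
                exact_binomial_oracle(x, x + y, na / (na + nb)), abs=1e-12
            )

    def test_pseudocount_keeps_fold_change_finite_at_zero(self):
        fc, _ = pairdiff.single_sample_test(10, 0, 1e6, 1e6)
        assert np.isfinite(fc) and fc == pytest.approx(10.5 / 0.5)

    def test_rejects_noninteger_and_negative_counts(self):
        with pytest.raises(ValueError):
            pairdiff.single_sample_test(1.5, 2, 1e6, 1e6)
        with pytest.raises(ValueError):
            pairdiff.single_sample_test(-1, 2, 1e6, 1e6)

    @given(
        x=st.integers(0, 40),
        y=st.integers(0, 40),
        ratio=st.floats(0.2, 5.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_p_in_unit_interval_and_oracle_agreement(self, x, y, ratio):
        na, nb = 1e6, 1e6 * ratio
        _, p = pairdiff.single_sample_test(x, y, na, nb)
        assert 0 < p <= 1
        assert p == pytest.approx(
            exact_binomial_oracle(x, x + y, na / (na + nb)), abs=1e-12
        )


class TestPerPatientContrast:
    def test_identical_samples_yield_no_up_calls(self, cohort_bundle):
        cohort, _ = cohort_bundle
        col = cohort.values["P1_T"]
        res = pairdiff.pairwise_exact_table(col, col.copy())
        assert len(res.up_set) == 0 and len(res.down_set) == 0

    def test_infinite_fc_threshold_empties_up_set(self, cohort_bundle):
        cohort, _ = cohort_bundle
        res = pairdiff.per_patient_contrast(cohort, "P1", "T", "N", fc_threshold=np.inf)
        assert res.up_set == set()

    def test_planted_shift_is_called_up(self, patient_contrasts, cohort_bundle):
        _, truth = cohort_bundle
        t_contrasts, _ = patient_contrasts
        # per-patient: the large planted shift at full depth is essentially
        # always recovered
        for res in t_contrasts.values():
            recovered = len(res.up_set & truth.tumor_up_genes)
            assert recovered >= 0.9 * len(truth.tumor_up_genes)

    def test_missing_sample_names_patient_and_source(self, cohort_bundle):
        cohort, _ = cohort_bundle
        with pytest.raises(ValueError, match="P1.*CAF|CAF.*P1"):
            pairdiff.per_patient_contrast(cohort, "P1", "T", "CAF")

    def test_detection_floor_marks_low_count_features_ns(self):
        a = pd.Series([0, 2, 100, 1000], index=list("abcd"))
        b = pd.Series([4, 0, 100, 1000], index=list("abcd"))
        res = pairdiff.pairwise_exact_table(a, b, detection_floor=5)
        t = res.table.set_index("feature")
        assert not t.loc["a", "tested"] and not t.loc["b", "tested"]
        assert t.loc["a", "direction"] == "ns"

    def test_adjusted_p_never_below_raw(self, patient_contrasts):
        t_contrasts, _ = patient_contrasts
        tab = t_contrasts["P1"].table
        assert (tab["p_adjusted"] >= tab["p_value"] - 1e-15).all()


def _fake_results(rng, n_features=100, n_patients=7):
    feats = [f"f{i}" for i in range(n_features)]
    results = []
    for _ in range(n_patients):
        direction = rng.choice(["up", "down", "ns"], size=n_features, p=[0.3, 0.2, 0.5])
        tab = pd.DataFrame(
            {
                "feature": feats,
                "fold_change": 2.0,
                "log2_fc": 1.0,
                "p_value": 0.01,
                "p_adjusted": 0.05,
                "direction": direction,
            }
        )
        results.append(DifferentialResult(table=tab, contrast={}))
    return results


class TestMajorityVote:
    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(42)
        results = _fake_results(rng)
        sig = pairdiff.majority_vote(results, min_support=4)
        # independent recount
        counts = {}
        for res in results:
            for _, row in res.table.iterrows():
                if row["direction"] == "up":
                    counts[row["feature"]] = counts.get(row["feature"], 0) + 1
        expected = {f for f, c in counts.items() if c >= 4}
        assert sig.members == expected
        assert all(sig.support[f] == counts[f] for f in sig.members)

    def test_boundary_at_exactly_min_support(self):
        rng = np.random.default_rng(0)
        results = _fake_results(rng, n_features=1, n_patients=7)
        ups = sum(r.table["direction"][0] == "up" for r in results)
        sig4 = pairdiff.majority_vote(results, min_support=max(ups, 1))
        sig_above = pairdiff.majority_vote(results, min_support=min(ups + 1, 7))
        if ups >= 1:
            assert "f0" in sig4.members
        assert "f0" not in sig_above.members

    def test_permutation_invariance_in_patient_order(self):
        rng = np.random.default_rng(7)
        results = _fake_results(rng)
        sig1 = pairdiff.majority_vote(results, 4)
        sig2 = pairdiff.majority_vote(results[::-1], 4)
        assert sig1.members == sig2.members and sig1.support == sig2.support

    def test_min_support_validation(self):
        rng = np.random.default_rng(1)
        results = _fake_results(rng)
        with pytest.raises(ValueError):
            pairdiff.majority_vote(results, 0)
        with pytest.raises(ValueError):
            pairdiff.majority_vote(results, 8)


class TestSharingTest:
    def test_worked_mRNA_vs_miRNA_example(self):
        # 27 of 5354 microRNAs vs 418 of 36173 mRNAs upregulated: the two
        # feature classes share tumor/normal cargo at clearly different rates
        stat, p = pairdiff.sharing_test(27, 5354, 418, 36173)
        assert p < 0.001

    def test_equal_proportions_give_zero_statistic(self):
        stat, p = pairdiff.sharing_test(10, 100, 20, 200)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_chi_square(self):
        # table [[3,7],[7,3]]: E = 5 everywhere, chi2 = 4*(2^2/5) = 3.2
        stat, p = pairdiff.sharing_test(3, 10, 7, 10)
        assert stat == pytest.approx(3.2)

    def test_degenerate_table_raises(self):
        with pytest.raises(ValueError):
            pairdiff.sharing_test(0, 10, 0, 10)


class TestGroupTest:
    def test_null_call_rate_near_alpha(self):
        matrix, _ = simulate_intensity_groups(
            n_features=2000, n_per_group=5, n_up=0, seed=3
        )
        groups = {s: m.source for s, m in matrix.metadata.items()}
        res = pairdiff.group_test(matrix, groups, "T", "N", fc_threshold=1.0, alpha=0.05)
        rate = (res.table["direction"] != "ns").mean()
        # binomial CI around alpha at 2000 features
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < 1.96 * se + 1e-9

    def test_zero_variance_features_report_p_one(self):
        values = pd.DataFrame(
            np.ones((5, 6)), index=[f"f{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(6)],
        )
        from sevscape.containers import ExpressionMatrix

        matrix = ExpressionMatrix(values, kind="intensity")
        groups = {f"s{i}": ("T" if i < 3 else "N") for i in range(6)}
        res = pairdiff.group_test(matrix, groups, "T", "N")
        assert (res.table["p_value"] == 1.0).all()
        assert (res.table["direction"] == "ns").all()

    def test_planted_four_fold_shift_called_up(self):
        matrix, up = simulate_intensity_groups(
            n_features=500, n_per_group=5, n_up=20, effect_log2fc=3.0, sigma=0.3, seed=5
        )
        groups = {s: m.source for s, m in matrix.metadata.items()}
        res = pairdiff.group_test(matrix, groups, "T", "N", fc_threshold=4.0)
        assert len(res.up_set & up) >= 18

    def test_small_group_rejected(self):
        matrix, _ = simulate_intensity_groups(n_features=10, n_per_group=5, n_up=0, seed=0)
        groups = {s: ("T" if s == matrix.sample_ids[0] else "N") for s in matrix.sample_ids}
        with pytest.raises(ValueError):
            pairdiff.group_test(matrix, groups, "T", "N")


class TestThresholdMonotonicity:
    def test_stricter_thresholds_shrink_the_signature(self, cohort_bundle):
        """Raising the FC threshold or lowering alpha never adds members."""
        cohort, _ = cohort_bundle
        patients = [f"P{i+1}" for i in range(3)]
        previous = None
        for fc, alpha in [(1.0, 0.10), (1.5, 0.05), (2.5, 0.01), (4.0, 0.001)]:
            results = [
                pairdiff.per_patient_contrast(cohort, p, "T", "N", fc_threshold=fc, alpha=alpha)
                for p in patients
            ]
            members = pairdiff.majority_vote(results, 2).members
            if previous is not None:
                assert members <= previous
            previous = members
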