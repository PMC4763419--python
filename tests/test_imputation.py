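"""Per-hospital MICE/PMM: m rule, separation contract, value preservation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import traumarisk as tr
from traumarisk.imputation import (
    ImputationError,
    choose_m,
    impute,
    incomplete_fractions,
    pool_pvalues,
    read_imputed_stack,
    write_imputed_stack,
)
from traumarisk.synthetic_cohort import MISSABLE_FIELDS


class TestChooseM:
    def test_published_examples(self):
        assert choose_m({"A": 0.51, "B": 0.40, "C": 0.22}) == 51
        assert choose_m({"A": 0.33, "B": 0.10, "C": 0.05}) == 33

    def test_complete_data_passthrough(self):
        assert choose_m({"A": 0.0, "B": 0.0}) == 0

    def test_floor_of_two_when_anything_missing(self):
        assert choose_m({"A": 0.004}) == 2

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            choose_m({"A": 1.2})

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=5),
           st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_worst_fraction(self, fracs, a, b):
        lo, hi = sorted([a, b])
        m_lo = choose_m(dict(enumerate(fracs + [lo])))
        m_hi = choose_m(dict(enumerate(fracs + [hi])))
        assert m_lo <= m_hi


@pytest.fixture(scope="module")
def imputed(masked_cohort):
    return impute(masked_cohort, m=5, seed=101)


class TestImpute:
    def test_complete_input_identical_copies(self, complete_cohort):
        res = impute(complete_cohort, m=2, seed=1)
        for d in res.datasets:
            pd.testing.assert_frame_equal(d, complete_cohort)

    def test_all_datasets_complete(self, imputed):
        for d in imputed.datasets:
            assert not d[list(MISSABLE_FIELDS)].isna().any().any()

    def test_observed_cells_unchanged(self, masked_cohort, imputed):
        for d in imputed.datasets:
            for v in MISSABLE_FIELDS:
                obs = masked_cohort[v].notna()
                np.testing.assert_array_equal(
                    d.loc[obs, v].to_numpy(), masked_cohort.loc[obs, v].to_numpy()
                )
            for col in masked_cohort.columns:
                if col not in MISSABLE_FIELDS:
                    np.testing.assert_array_equal(
                        d[col].to_numpy(), masked_cohort[col].to_numpy()
                    )

    def test_only_originally_missing_cells_differ_across_m(self, masked_cohort, imputed):
        a, b = imputed.datasets[0], imputed.datasets[1]
        differs = (a[list(MISSABLE_FIELDS)] != b[list(MISSABLE_FIELDS)]).any(axis=1)
        originally_missing = masked_cohort[list(MISSABLE_FIELDS)].isna().any(axis=1)
        assert differs[~originally_missing].sum() == 0

    def test_gcs_imputed_as_integer_in_range(self, masked_cohort, imputed):
        mis = masked_cohort["gcs"].isna()
        for d in imputed.datasets:
            vals = d.loc[mis, "gcs"]
            assert (vals == vals.round()).all()
            assert vals.between(3, 15).all()

    def test_imputed_values_in_observed_support(self, masked_cohort, imputed):
        """PMM draws donors from observed values of the same hospital."""
        d = imputed.datasets[0]
        for h in masked_cohort["hospital_id"].unique():
            sel = masked_cohort["hospital_id"] == h
            observed = set(masked_cohort.loc[sel & masked_cohort["sbp"].notna(), "sbp"])
            filled = set(d.loc[sel & masked_cohort["sbp"].isna(), "sbp"])
            assert filled <= observed

    def test_hospital_separation_contract(self, masked_cohort):
        """Permuting the rows of the other hospitals leaves hospital AA's
        imputed values unchanged for a fixed seed."""
        res_a = impute(masked_cohort, m=2, seed=55)
        is_a = masked_cohort["hospital_id"] == "AA"
        others = masked_cohort[~is_a]
        permuted = pd.concat(
            [masked_cohort[is_a], others.sample(frac=1.0, random_state=3)],
            ignore_index=True,
        )
        res_b = impute(permuted, m=2, seed=55)
        a0 = res_a.datasets[0][res_a.datasets[0]["hospital_id"] == "AA"]
        b0 = res_b.datasets[0][res_b.datasets[0]["hospital_id"] == "AA"]
        pd.testing.assert_frame_equal(
            a0.reset_index(drop=True), b0.reset_index(drop=True)
        )

    def test_mcar_pooled_mean_recovers_premask_mean(self):
        spec = dataclasses.replace(
            tr.default_spec("full", seed=8), n_per_hospital={"AA": 5000, "BB": 5000}
        )
        complete = tr.generate_cohort(spec)
        masked = tr.impose_missingness(complete, {"sbp": 0.2}, "MCAR", seed=2)
        res = impute(masked, m=10, seed=77)
        mis = masked["sbp"].isna()
        pooled = np.mean([d.loc[mis, "sbp"].mean() for d in res.datasets])
        se = complete["sbp"].std() / np.sqrt(mis.sum())
        assert pooled == pytest.approx(complete.loc[mis, "sbp"].mean(), abs=3 * se)

    def test_all_missing_in_hospital_fails_with_names(self, masked_cohort):
        broken = masked_cohort.copy()
        broken.loc[broken["hospital_id"] == "BB", "hr"] = np.nan
        with pytest.raises(ImputationError, match="BB.*hr"):
            impute(broken, m=2, seed=1)

    def test_m_lower_bound(self, masked_cohort):
        with pytest.raises(ValueError):
            impute(masked_cohort, m=1, seed=1)


class TestIncompleteFractions:
    def test_counts_model_variables_only(self, complete_cohort):
        masked = tr.impose_missingness(complete_cohort, {"delay_h": 0.5}, "MCAR", seed=1)
        fracs = incomplete_fractions(masked)
        assert all(f == 0 for f in fracs.values())  # delay does not count

    def test_matches_direct_count(self, masked_cohort):
        fracs = incomplete_fractions(masked_cohort)
        h = "AA"
        sub = masked_cohort[masked_cohort["hospital_id"] == h]
        direct = sub[["sbp", "hr", "gcs", "age"]].isna().any(axis=1).mean()
        assert fracs[h] == pytest.approx(direct)


class TestPoolPvalues:
    def test_direct_definition(self):
        med, iqr, sig = pool_pvalues([0.01, 0.02, 0.03])
        assert (med, sig) == (0.02, True)

    def test_singleton(self):
        med, iqr, sig = pool_pvalues([0.2])
        assert med == 0.2 and iqr == (0.2, 0.2) and not sig

    def test_against_percentile_oracle(self):
        rng = np.random.default_rng(33)
        p = rng.random(33)
        med, (q1, q3), _ = pool_pvalues(p)
        s = np.sort(p)
        # brute-force order statistics via linear interpolation definition
        def quantile(q):
            pos = q * (len(s) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            return s[lo] + (pos - lo) * (s[hi] - s[lo])
        assert med == pytest.approx(quantile(0.5))
        assert q1 == pytest.approx(quantile(0.25))
        assert q3 == pytest.approx(quantile(0.75))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_pvalues([])


def test_stacked_io_round_trip(tmp_path, masked_cohort, imputed):
    path = tmp_path / "stack.csv"
    write_imputed_stack(masked_cohort, imputed, path)
    original, datasets = read_imputed_stack(path)
    assert len(datasets) == imputed.m
    np.testing.assert_array_equal(
        original["sbp"].isna(), masked_cohort["sbp"].isna()
    )
    pd.testing.assert_frame_equal(
        datasets[0].reset_index(drop=True),
        imputed.datasets[0].reset_index(drop=True),
        check_dtype=False,
    )
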