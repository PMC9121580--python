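"""Six scoring methods: hand-worked examples, invariants, hot-deck oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ftndsim.dataset import ITEM_COLUMNS, ITEM_MAX
from ftndsim.exceptions import (
    DonorPoolError,
    DonorPoolWarning,
    InvalidDataError,
    UnimputableDatasetError,
)
from ftndsim.missingness import MissingnessConfig, draw_missingness
from ftndsim.scoring import (
    METHODS,
    gower_distance,
    hot_deck_donor_pools,
    score,
    score_cca,
    score_drop_one,
    score_hot_deck,
    score_item_mean,
    score_proration,
)

from conftest import make_data

M = np.nan


class TestSimpleMethods:
    def test_cca_examples(self):
        data = make_data([[3, 1, 1, 2, 0, 1], [3, 1, M, 2, 0, 1]])
        totals = score_cca(data).totals
        assert totals[0] == 8
        assert np.isnan(totals[1])

    def test_drop_one_examples(self):
        data = make_data([[2, 1, M, 1, 0, 1], [2, M, M, 1, 0, 1], [2, 1, 1, 1, 0, 1]])
        totals = score_drop_one(data).totals
        assert totals[0] == 5  # single missing item contributes zero
        assert np.isnan(totals[1])  # more than one missing -> missing total
        assert totals[2] == 6

    def test_item_mean_uses_observed_column_mean(self):
        data = make_data(
            [[2, 0, 0, 0, 0, 0], [3, 0, 0, 0, 0, 0], [1, 0, 0, 0, 0, 0], [M, 1, 1, 0, 1, 0]]
        )
        result = score_item_mean(data)
        assert result.totals[3] == pytest.approx(2.0 + 3)
        log = result.imputations
        assert log.loc[0, "item"] == "item1" and log.loc[0, "value"] == pytest.approx(2.0)

    def test_half_rule_blocks_sparse_subjects(self):
        data = make_data([[2, 1, M, M, M, M], [2, 1, 1, M, M, M], [1, 0, 1, 0, 1, 0]])
        hr = score_item_mean(data, half_rule=True)
        assert np.isnan(hr.totals[0])  # 2 observed < 3
        assert not np.isnan(hr.totals[1])  # exactly half observed
        plain = score_item_mean(data)
        assert not np.isnan(plain.totals[0])

    def test_item_mean_unimputable_column(self):
        data = make_data([[M, 1, 1, 0, 1, 0], [M, 0, 1, 0, 1, 0], [M, 1, 0, 1, 0, 1]])
        with pytest.raises(UnimputableDatasetError):
            score_item_mean(data)

    def test_proration_weighted_imputation(self):
        # items 2,3,5,6 observed as (1,1,1,0): 3 of 4 possible points
        data = make_data([[M, 1, 1, M, 1, 0]])
        result = score_proration(data)
        assert result.totals[0] == pytest.approx(7.5)
        values = dict(zip(result.imputations["item"], result.imputations["value"]))
        assert values == {"item1": pytest.approx(2.25), "item4": pytest.approx(2.25)}

    def test_proration_half_rule_and_zero_answers(self):
        data = make_data([[2, M, M, 1, M, M], [M, 0, 0, M, 0, 0], [1, 1, 0, 1, 0, 1]])
        result = score_proration(data)
        assert np.isnan(result.totals[0])  # only 2 items observed
        assert result.totals[1] == 0.0  # all-zero observed answers
        assert result.totals[2] == 4.0


class TestGowerDistance:
    def test_identical_records_zero(self):
        data = make_data([[1, 0, 1, 2, 0, 1]] * 2, gender=[1, 1], smoking_allowed=[0, 0])
        variables = ["gender", "smoking_allowed", *ITEM_COLUMNS]
        assert gower_distance(data.iloc[0], data.iloc[1], variables) == 0.0

    def test_hand_evaluated_mixed_distance(self):
        # gender equal, smoking_allowed different, item1 2 vs 3: (0 + 1 + 1/3)/3
        data = make_data([[2, 0, 0, 0, 0, 0], [3, 0, 0, 0, 0, 0]], smoking_allowed=[0, 1])
        d = gower_distance(data.iloc[0], data.iloc[1], ["gender", "smoking_allowed", "item1"])
        assert d == pytest.approx(4 / 9)

    def test_maximal_disagreement_is_one(self):
        data = make_data([[0, 0, 0, 0, 0, 0], [3, 1, 1, 3, 1, 1]], gender=[0, 1], smoking_allowed=[0, 1])
        variables = ["gender", "smoking_allowed", *ITEM_COLUMNS]
        assert gower_distance(data.iloc[0], data.iloc[1], variables) == pytest.approx(1.0)

    def test_missing_variable_rejected(self):
        data = make_data([[M, 0, 0, 0, 0, 0], [1, 0, 0, 0, 0, 0]])
        with pytest.raises(InvalidDataError):
            gower_distance(data.iloc[0], data.iloc[1], ["item1"])


def _brute_force_pools(data, k):
    """Exhaustive all-pairs Gower ranking, mirroring the documented donor rule."""
    items = data[list(ITEM_COLUMNS)].to_numpy(float)
    miss = np.isnan(items)
    pools = {}
    donors = [i for i in range(len(data)) if not miss[i].any()]
    for r in range(len(data)):
        if not miss[r].any():
            continue
        variables = ["gender", "smoking_allowed"] + [
            c for c, m in zip(ITEM_COLUMNS, miss[r]) if not m
        ]
        dists = {d: gower_distance(data.iloc[d], data.iloc[r], variables) for d in donors}
        kk = min(k, len(donors))
        kth = sorted(dists.values())[kk - 1]
        pools[r] = sorted(d for d, v in dists.items() if v <= kth + 1e-12)
    return pools


class TestHotDeck:
    def test_no_recipients_gives_plain_sums(self):
        data = make_data([[1, 0, 1, 2, 0, 1], [0, 1, 1, 1, 1, 0]])
        result = score_hot_deck(data, seed=0)
        assert np.array_equal(result.totals, [5, 4])
        assert len(result.imputations) == 0

    def test_exact_match_donor_is_in_pool(self):
        rows = [[2, 1, 0, 1, 0, 1]] * 6 + [[2, 1, 0, 1, 0, M]]
        data = make_data(rows, gender=[1, 0, 0, 0, 0, 0, 1], smoking_allowed=[1, 0, 0, 0, 0, 0, 1])
        pools = hot_deck_donor_pools(data, k=1)
        assert 0 in pools[6]  # the only subject agreeing on every distance variable

    def test_pools_match_brute_force_on_small_datasets(self, rng):
        for trial in range(25):
            n = int(rng.integers(6, 9))
            items = rng.integers(0, 2, size=(n, 6)).astype(float)
            items[:, 0] = rng.integers(0, 4, size=n)
            items[:, 3] = rng.integers(0, 4, size=n)
            # delete up to 2 items for a couple of subjects, keep >= k donors
            for r in rng.choice(n, size=2, replace=False):
                cols = rng.choice(6, size=int(rng.integers(1, 3)), replace=False)
                items[r, cols] = np.nan
            data = make_data(
                items,
                gender=rng.integers(0, 2, n),
                smoke_where=rng.choice([0, 1, 3], n),
                smoking_allowed=rng.integers(0, 2, n),
            )
            k = int(rng.integers(1, 5))
            try:
                pools = hot_deck_donor_pools(data, k=k)
            except DonorPoolError:
                continue
            expected = _brute_force_pools(data, k)
            assert {r: sorted(v) for r, v in pools.items()} == expected

    def test_single_donor_fills_all_missing_items(self):
        rows = [[0, 0, 0, 0, 0, 0], [1, 1, 1, 1, 1, 1], [2, 0, 1, 2, 0, 1],
                [3, 1, 0, 3, 1, 0], [1, 0, 0, 1, 0, 0], [M, M, 0, 1, 0, 0]]
        data = make_data(rows)
        result = score_hot_deck(data, k=5, seed=3)
        imputed = result.imputations
        assert set(imputed["item"]) == {"item1", "item2"}
        donors_items = {(r[0], r[1]) for r in rows[:5]}
        assert tuple(imputed["value"]) in donors_items  # one donor provided both

    def test_donor_draw_uniform_over_nearest_k(self):
        # 6 complete donors, the last strictly farthest from one recipient
        # missing items 1 and 4; donors carry distinct
        # (item1, item4) pairs so the realized donor is identifiable.
        rows = [
            [0, 0, 0, 0, 0, 0],
            [1, 0, 0, 1, 0, 0],
            [2, 0, 0, 2, 1, 0],
            [3, 0, 0, 3, 1, 1],
            [0, 1, 0, 1, 1, 1],
            [1, 1, 1, 2, 1, 1],
            [M, 0, 0, M, 0, 0],
        ]
        gender = [0, 0, 0, 0, 0, 1, 0]
        data = make_data(rows, gender=gender)
        pools = hot_deck_donor_pools(data, k=5)
        assert sorted(pools[6]) == [0, 1, 2, 3, 4]  # donor 5 is farthest
        pair_to_donor = {(r[0], r[3]): j for j, r in enumerate(rows[:6])}
        freq = np.zeros(6, dtype=int)
        for seed in range(4000):
            result = score_hot_deck(data, k=5, seed=seed)
            values = dict(zip(result.imputations["item"], result.imputations["value"]))
            freq[pair_to_donor[(values["item1"], values["item4"])]] += 1
        assert freq[5] == 0
        chi2 = (((freq[:5] - 800.0) ** 2) / 800.0).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=4)

    def test_totals_are_integers_and_values_donor_observed(self, calibrated_population):
        sample = calibrated_population.iloc[:300].reset_index(drop=True)
        config = MissingnessConfig(mechanism="MAR", p_sub=0.5, p_item=0.5).solved_for(sample)
        observed, _ = draw_missingness(sample, config, seed=9)
        result = score_hot_deck(observed, seed=10)
        assert np.all(result.totals == np.round(result.totals))
        items = observed[list(ITEM_COLUMNS)]
        for _, row in result.imputations.iterrows():
            assert row["value"] in items[row["item"]].dropna().to_numpy()

    def test_donor_shortfall_warns_then_strict_raises(self):
        rows = [[1, 0, 0, 1, 0, 0], [2, 1, 0, 2, 1, 0], [M, 0, 0, 1, 0, 0]]
        data = make_data(rows)
        with pytest.warns(DonorPoolWarning):
            score_hot_deck(data, k=5, seed=0)
        with pytest.raises(DonorPoolError):
            score_hot_deck(data, k=5, seed=0, strict=True)
        only_missing = make_data([[M, 0, 0, 1, 0, 0], [1, M, 0, 1, 0, 0]])
        with pytest.raises(DonorPoolError):
            score_hot_deck(only_missing, seed=0)


class TestCrossMethodInvariants:
    @pytest.fixture()
    def observed(self, calibrated_population):
        sample = calibrated_population.iloc[:400].reset_index(drop=True)
        config = MissingnessConfig(mechanism="MNAR", p_sub=0.5, p_item=0.5).solved_for(sample)
        observed, _ = draw_missingness(sample, config, seed=17)
        return observed

    def test_complete_data_all_methods_agree(self, calibrated_population):
        data = calibrated_population.iloc[:200].reset_index(drop=True)
        sums = data[list(ITEM_COLUMNS)].sum(axis=1).to_numpy(float)
        for method in METHODS:
            assert np.array_equal(score(data, method, seed=0).totals, sums), method

    def test_scored_count_ordering(self, observed):
        counts = {m: score(observed, m, seed=1).n_scored for m in METHODS}
        n = len(observed)
        assert counts["cca"] <= counts["drop_one"] <= counts["proration"]
        assert counts["proration"] == counts["hr_item_mean"]
        assert counts["proration"] <= counts["item_mean"]
        assert counts["item_mean"] == counts["hot_deck"] == n

    def test_proration_and_hr_item_mean_share_missing_sets(self, observed):
        pro = score(observed, "proration").totals
        hr = score(observed, "hr_item_mean").totals
        assert np.array_equal(np.isnan(pro), np.isnan(hr))

    def test_all_totals_within_scale_range(self, observed):
        for method in METHODS:
            totals = score(observed, method, seed=2).totals
            ok = totals[~np.isnan(totals)]
            assert (ok >= 0).all() and (ok <= 10).all()


@given(
    st.lists(
        st.tuples(
            st.one_of(st.none(), st.integers(0, 3)),
            st.one_of(st.none(), st.integers(0, 1)),
            st.one_of(st.none(), st.integers(0, 1)),
            st.one_of(st.none(), st.integers(0, 3)),
            st.one_of(st.none(), st.integers(0, 1)),
            st.one_of(st.none(), st.integers(0, 1)),
        ),
        min_size=1,
        max_size=12,
    )
)
def test_drop_one_and_proration_match_definitions(rows):
    """Property: totals follow the stated rules for any missingness pattern."""
    items = np.array([[np.nan if v is None else v for v in row] for row in rows], dtype=float)
    data = make_data(items)
    drop = score_drop_one(data).totals
    pro = score_proration(data).totals
    for i, row in enumerate(items):
        n_miss = int(np.isnan(row).sum())
        if n_miss == 0:
            assert drop[i] == np.nansum(row) and pro[i] == np.nansum(row)
        if n_miss == 1:
            assert drop[i] == np.nansum(row)
        if n_miss >= 2:
            assert np.isnan(drop[i])
        if n_miss > 3:
            assert np.isnan(pro[i])
        elif n_miss > 0:
            obs = ~np.isnan(row)
            ratio = np.nansum(row) / ITEM_MAX[obs].sum()
            assert pro[i] == pytest.approx(np.nansum(row) + ratio * ITEM_MAX[~obs].sum())
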